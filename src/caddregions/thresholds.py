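"""Per-region threshold derivation and reporting.

The pipeline mirrors a clinical-archive analysis: per region, benign and
pathogenic score distributions are compared with a Mann-Whitney U test
(Benjamini-Hochberg FDR across the regions actually tested), an optimal
cutpoint is derived from the ROC curve (Youden's J by default, F1 or a
0.4*J + 0.6*F1 blend per region on request), and a record is emitted with a
usability flag requiring both AUC > 0.7 and adjusted significance.

The scikit-learn estimator :class:`RegionThresholdClassifier` is the primary
interface; the module-level functions wrap the same logic for script use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .defaults import REGION_ORDER
from .regions import NONCODING_REGIONS, RegionCategory
from .stats import (
    bh_fdr,
    f1_cutpoint,
    mann_whitney_u,
    roc_curve,
    significance_label,
    weighted_cutpoint,
    youden_cutpoint,
)

__all__ = [
    "RegionScoreSample",
    "ThresholdRecord",
    "RegionThresholdClassifier",
    "is_usable",
    "samples_from_frame",
    "summarize_regions",
    "derive_thresholds",
    "compare_pathogenic_across_regions",
    "substitute_benign",
    "export_threshold_table",
    "read_threshold_table",
    "records_to_frame",
]

_CLASSES = ("benign", "pathogenic", "vus")


@dataclass
class RegionScoreSample:
    """Per-region score lists, split by collapsed clinical class."""

    region: str
    benign: np.ndarray
    pathogenic: np.ndarray
    vus: np.ndarray

    def __post_init__(self):
        self.region = str(self.region)
        self.benign = np.asarray(self.benign, dtype=float).ravel()
        self.pathogenic = np.asarray(self.pathogenic, dtype=float).ravel()
        self.vus = np.asarray(self.vus, dtype=float).ravel()


@dataclass
class ThresholdRecord:
    """One report row: region, cutpoint, test results, usability."""

    region: str
    threshold: float | None
    p_raw: float
    p_adj: float
    significance: str
    auc: float
    usable: bool
    n_benign: int
    n_pathogenic: int
    n_vus: int
    strategy: str


def is_usable(auc: float, significance: str, auc_usable: float = 0.7) -> bool:
    """A region's threshold is usable iff AUC exceeds 0.7 and the adjusted
    benign-vs-pathogenic test is significant (strict inequalities)."""
    if auc is None or not np.isfinite(auc):
        return False
    return bool(auc > auc_usable and significance != "ns")


def samples_from_frame(df: pd.DataFrame) -> list[RegionScoreSample]:
    """Split an annotated variant table into per-region score samples.

    Exonic variants and rows without a region are excluded; the nine
    noncoding regions are always present (possibly with empty lists).
    """
    samples = []
    for region in REGION_ORDER:
        sub = df[df["region"] == region] if "region" in df.columns else df.iloc[0:0]
        by_class = {
            c: sub.loc[sub["clin_class"] == c, "score"].to_numpy(dtype=float)
            for c in _CLASSES
        }
        samples.append(RegionScoreSample(region, by_class["benign"],
                                         by_class["pathogenic"], by_class["vus"]))
    return samples


def summarize_regions(df: pd.DataFrame) -> pd.DataFrame:
    """Per-region, per-class counts and within-region fractions.

    Regions with zero variants appear with zero counts; exonic rows are
    excluded from the summary.
    """
    out = pd.DataFrame(
        0,
        index=pd.Index(REGION_ORDER, name="region"),
        columns=[f"n_{c}" for c in _CLASSES],
        dtype=int,
    )
    if len(df) and "region" in df.columns:
        nc = df[df["region"].isin(REGION_ORDER)]
        tab = pd.crosstab(nc["region"], nc["clin_class"])
        for c in _CLASSES:
            if c in tab.columns:
                out.loc[tab.index, f"n_{c}"] = tab[c]
    total = out.sum(axis=1)
    out["n_total"] = total
    for c in _CLASSES:
        with np.errstate(invalid="ignore"):
            out[f"frac_{c}"] = np.where(total > 0, out[f"n_{c}"] / total.replace(0, 1), 0.0)
    return out


def _dispatch_cutpoint(sample: RegionScoreSample, strategy: str, w_youden: float):
    if strategy == "youden":
        return youden_cutpoint(roc_curve(sample.pathogenic, sample.benign))
    if strategy == "f1":
        return f1_cutpoint(sample.pathogenic, sample.benign)
    if strategy == "weighted":
        return weighted_cutpoint(sample.pathogenic, sample.benign, w_youden)
    raise ValueError(f"unknown cutpoint strategy {strategy!r}")


def derive_thresholds(
    samples: Sequence[RegionScoreSample],
    strategy_map: Mapping[str, str] | None = None,
    w_youden: float = 0.4,
    min_n: int = 2,
    auc_usable: float = 0.7,
) -> list[ThresholdRecord]:
    """Derive one ThresholdRecord per region sample.

    Regions with fewer than ``min_n`` benign or pathogenic scores are
    reported with an absent threshold and ``usable=False``.  BH adjustment
    runs across the regions actually tested, not a fixed family of nine.
    """
    if not samples:
        raise ValueError("at least one region sample is required")
    strategy_map = dict(strategy_map or {})
    tested: list[tuple[RegionScoreSample, str]] = []
    degenerate: list[RegionScoreSample] = []
    for s in samples:
        if len(s.benign) < min_n or len(s.pathogenic) < min_n:
            degenerate.append(s)
        else:
            tested.append((s, strategy_map.get(s.region, "youden")))

    p_raw = [mann_whitney_u(s.benign, s.pathogenic)[1] for s, _ in tested]
    p_adj = bh_fdr(p_raw) if p_raw else np.array([])

    records: dict[str, ThresholdRecord] = {}
    for (s, strategy), pr, pa in zip(tested, p_raw, p_adj):
        curve = roc_curve(s.pathogenic, s.benign)
        cut = _dispatch_cutpoint(s, strategy, w_youden)
        sig = significance_label(pa)
        records[s.region] = ThresholdRecord(
            region=s.region,
            threshold=cut.threshold,
            p_raw=float(pr),
            p_adj=float(pa),
            significance=sig,
            auc=curve.auc,
            usable=is_usable(curve.auc, sig, auc_usable),
            n_benign=len(s.benign),
            n_pathogenic=len(s.pathogenic),
            n_vus=len(s.vus),
            strategy=strategy,
        )
    for s in degenerate:
        records[s.region] = ThresholdRecord(
            region=s.region,
            threshold=None,
            p_raw=math.nan,
            p_adj=math.nan,
            significance="ns",
            auc=math.nan,
            usable=False,
            n_benign=len(s.benign),
            n_pathogenic=len(s.pathogenic),
            n_vus=len(s.vus),
            strategy=strategy_map.get(s.region, "youden"),
        )
    ordered = [r for r in REGION_ORDER if r in records]
    extra = [s.region for s in samples if s.region not in REGION_ORDER]
    return [records[r] for r in ordered + extra]


def compare_pathogenic_across_regions(
    samples: Sequence[RegionScoreSample],
) -> pd.DataFrame:
    """Pairwise MWU tests on pathogenic scores, BH-adjusted over the pairs.

    Returns a symmetric matrix of adjusted p-values with 1.0 on the
    diagonal.  Regions without pathogenic scores are omitted; fewer than two
    eligible regions is an error.
    """
    eligible = [s for s in samples if len(s.pathogenic) >= 1]
    if len(eligible) < 2:
        raise ValueError("need at least two regions with pathogenic scores")
    names = [s.region for s in eligible]
    pairs = [(i, j) for i in range(len(eligible)) for j in range(i + 1, len(eligible))]
    raw = [
        mann_whitney_u(eligible[i].pathogenic, eligible[j].pathogenic)[1]
        for i, j in pairs
    ]
    adj = bh_fdr(raw)
    mat = pd.DataFrame(1.0, index=names, columns=names)
    for (i, j), p in zip(pairs, adj):
        mat.iloc[i, j] = p
        mat.iloc[j, i] = p
    return mat


def substitute_benign(
    samples: Sequence[RegionScoreSample],
    common: pd.DataFrame,
    af_min: float = 0.01,
    exclude: Iterable[tuple] | None = None,
) -> list[RegionScoreSample]:
    """Replace per-region benign scores with common-variant scores.

    ``common`` is an annotated variant table carrying ``region``,
    ``score`` and ``allele_freq``; only variants with allele frequency
    strictly above ``af_min`` contribute.  ``exclude`` is a set of
    ``(chrom, pos, ref, alt)`` keys (normally the pathogenic variants of the
    dataset the samples came from) that must not leak into the benign side.
    Pathogenic and VUS lists are unchanged; a region losing every benign
    score is retained with an empty list.
    """
    keep = common[common["allele_freq"].astype(float) > af_min]
    if exclude:
        excl = set(exclude)
        keys = list(zip(keep["chrom"], keep["pos"].astype(int), keep["ref"], keep["alt"]))
        keep = keep[[k not in excl for k in keys]]
    by_region = {
        region: grp["score"].to_numpy(dtype=float)
        for region, grp in keep.groupby("region")
    }
    return [
        RegionScoreSample(
            s.region,
            by_region.get(s.region, np.array([], dtype=float)),
            s.pathogenic,
            s.vus,
        )
        for s in samples
    ]


_TABLE_COLUMNS = [
    "region",
    "threshold",
    "p_raw",
    "p_adj",
    "significance",
    "auc",
    "usable",
    "n_benign",
    "n_pathogenic",
    "n_vus",
    "strategy",
]


def records_to_frame(records: Sequence[ThresholdRecord]) -> pd.DataFrame:
    order = {r: i for i, r in enumerate(REGION_ORDER)}
    rows = sorted(records, key=lambda r: order.get(r.region, len(order)))
    return pd.DataFrame(
        [
            {
                "region": r.region,
                "threshold": r.threshold,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significance": r.significance,
                "auc": r.auc,
                "usable": r.usable,
                "n_benign": r.n_benign,
                "n_pathogenic": r.n_pathogenic,
                "n_vus": r.n_vus,
                "strategy": r.strategy,
            }
            for r in rows
        ],
        columns=_TABLE_COLUMNS,
    )


def export_threshold_table(records: Sequence[ThresholdRecord], path) -> None:
    """Write the per-region report as a TSV in the fixed region order.

    Floats are written with ``repr`` (shortest round-trip form) so a
    re-parse reproduces the records bit-exactly.
    """
    frame = records_to_frame(records).astype(object)
    for col in ("threshold", "p_raw", "p_adj", "auc"):
        frame[col] = [
            "NA" if v is None or (isinstance(v, float) and math.isnan(v)) else repr(float(v))
            for v in frame[col]
        ]
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_threshold_table(path) -> list[ThresholdRecord]:
    """Re-parse a TSV written by :func:`export_threshold_table`."""
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        float_precision="round_trip",
    )
    records = []
    for _, row in df.iterrows():
        records.append(
            ThresholdRecord(
                region=str(row["region"]),
                threshold=None if pd.isna(row["threshold"]) else float(row["threshold"]),
                p_raw=float(row["p_raw"]) if not pd.isna(row["p_raw"]) else math.nan,
                p_adj=float(row["p_adj"]) if not pd.isna(row["p_adj"]) else math.nan,
                significance=str(row["significance"]),
                auc=float(row["auc"]) if not pd.isna(row["auc"]) else math.nan,
                usable=bool(row["usable"] in (True, "True", "true", 1)),
                n_benign=int(row["n_benign"]),
                n_pathogenic=int(row["n_pathogenic"]),
                n_vus=int(row["n_vus"]),
                strategy=str(row["strategy"]),
            )
        )
    return records


class RegionThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Region-stratified score-threshold classifier.

    ``fit`` derives one score cutpoint per region from labelled variants and
    stores the full per-region report; ``predict`` then calls a variant
    pathogenic when its score reaches its region's cutpoint.

    Parameters
    ----------
    strategy:
        Default cutpoint rule: ``youden``, ``f1`` or ``weighted``.
    strategy_map:
        Optional per-region override, e.g. ``{"utr5": "weighted"}``.
    w_youden:
        Weight of Youden's J in the ``weighted`` blend (the remainder goes
        to F1).
    min_n:
        Minimum benign and pathogenic count for a region to be tested.
    auc_usable:
        Usability requires AUC strictly above this value.

    Attributes
    ----------
    records_ : list of ThresholdRecord
    thresholds_ : dict mapping region to derived cutpoint
    usable_regions_ : list of regions passing the usability rule
    table_ : pandas.DataFrame report in fixed region order
    """

    def __init__(
        self,
        strategy: str = "youden",
        strategy_map: Mapping[str, str] | None = None,
        w_youden: float = 0.4,
        min_n: int = 2,
        auc_usable: float = 0.7,
    ):
        self.strategy = strategy
        self.strategy_map = strategy_map
        self.w_youden = w_youden
        self.min_n = min_n
        self.auc_usable = auc_usable

    @staticmethod
    def _to_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            if "score" not in X.columns or "region" not in X.columns:
                raise ValueError("X must carry 'score' and 'region' columns")
            return X
        X = np.asarray(X, dtype=object)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("array X must have two columns: score, region")
        return pd.DataFrame({"score": X[:, 0].astype(float), "region": X[:, 1].astype(str)})

    def fit(self, X, y):
        df = self._to_frame(X).copy()
        y = np.asarray(y, dtype=object).ravel()
        if len(y) != len(df):
            raise ValueError("X and y lengths differ")
        bad = set(y) - {"benign", "pathogenic", "vus"}
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        df["clin_class"] = y
        samples = samples_from_frame(df)
        smap = {r: self.strategy for r in REGION_ORDER}
        smap.update(dict(self.strategy_map or {}))
        self.records_ = derive_thresholds(
            samples,
            strategy_map=smap,
            w_youden=self.w_youden,
            min_n=self.min_n,
            auc_usable=self.auc_usable,
        )
        self.thresholds_ = {
            r.region: r.threshold for r in self.records_ if r.threshold is not None
        }
        self.usable_regions_ = [r.region for r in self.records_ if r.usable]
        self.table_ = records_to_frame(self.records_)
        self.classes_ = np.array(["benign", "pathogenic"], dtype=object)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Margin ``score - threshold[region]``; -inf where no threshold."""
        if not hasattr(self, "thresholds_"):
            raise ValueError("classifier is not fitted")
        df = self._to_frame(X)
        thr = df["region"].map(self.thresholds_).to_numpy(dtype=float)
        margin = df["score"].to_numpy(dtype=float) - thr
        return np.where(np.isnan(margin), -np.inf, margin)

    def predict(self, X) -> np.ndarray:
        margin = self.decision_function(X)
        return np.where(margin >= 0, "pathogenic", "benign").astype(object)
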