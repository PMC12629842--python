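"""Region-threshold filtering of WGS-scale variant tables.

The cascade follows rare-disease practice: drop coding-exonic variants,
keep rare variants (allele frequency strictly below 1% by default; missing
frequency counts as novel, hence rare), keep variants at or above their
region-specific score threshold, and optionally restrict to de novo calls.
A median-split comparator (retain score >= the region's median, the
RAVA-FIRST-style rule) is provided for benchmarking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .defaults import default_thresholds

__all__ = [
    "FilterConfig",
    "FilterReport",
    "filter_variants",
    "region_median_filter",
    "VariantFilter",
]


@dataclass
class FilterConfig:
    """Configuration of the filtering cascade.

    A region absent from ``thresholds`` never passes the threshold stage
    (conservative: regions without a vetted cutoff are not trusted).
    """

    thresholds: Mapping[str, float]
    af_max: float = 0.01
    require_de_novo: bool = False
    strategy: str = "fixed_thresholds"

    def __post_init__(self):
        if not (0.0 < self.af_max <= 1.0):
            raise ValueError("af_max must lie in (0, 1]")
        if self.strategy not in ("fixed_thresholds", "region_median"):
            raise ValueError(f"unknown filter strategy {self.strategy!r}")
        for region, thr in dict(self.thresholds).items():
            if thr < 0:
                raise ValueError(f"negative threshold for {region}")


@dataclass
class FilterReport:
    """Attrition tally for every stage of the cascade."""

    n_input: int
    n_noncoding: int
    n_rare: int
    n_passing_threshold: int
    n_de_novo: int
    n_final: int
    per_region_passing: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_noncoding": self.n_noncoding,
            "n_rare": self.n_rare,
            "n_passing_threshold": self.n_passing_threshold,
            "n_de_novo": self.n_de_novo,
            "n_final": self.n_final,
            "per_region_passing": dict(self.per_region_passing),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _de_novo_mask(df: pd.DataFrame) -> pd.Series:
    if "de_novo" not in df.columns:
        return pd.Series(False, index=df.index)
    return df["de_novo"].map(lambda v: bool(v) if not pd.isna(v) else False)


def filter_variants(
    variants: pd.DataFrame, cfg: FilterConfig
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the cascade noncoding -> rare -> threshold -> (de novo).

    ``variants`` must carry ``region`` and ``score``; ``allele_freq`` and
    ``de_novo`` are optional (absent allele frequency is treated as 0).
    ``per_region_passing`` counts variants at the threshold stage, before
    any de novo restriction.
    """
    n_input = len(variants)
    region = variants["region"].astype(str) if n_input else pd.Series(dtype=str)
    nc = variants[(region != "exonic") & region.notna()] if n_input else variants
    n_noncoding = len(nc)

    if "allele_freq" in nc.columns:
        af = pd.to_numeric(nc["allele_freq"], errors="coerce").fillna(0.0)
    else:
        af = pd.Series(0.0, index=nc.index)
    rare = nc[af < cfg.af_max]
    n_rare = len(rare)

    if cfg.strategy == "region_median":
        med = rare.groupby("region")["score"].transform("median") if n_rare else None
        passing = rare[rare["score"] >= med] if n_rare else rare
    else:
        thr = rare["region"].map(dict(cfg.thresholds)) if n_rare else pd.Series(dtype=float)
        passing = rare[rare["score"] >= thr] if n_rare else rare
    n_passing = len(passing)
    per_region = passing["region"].value_counts().to_dict() if n_passing else {}

    n_de_novo = int(_de_novo_mask(variants).sum()) if n_input else 0
    if cfg.require_de_novo:
        if n_de_novo == 0:
            raise ValueError("no de novo annotation")
        final = passing[_de_novo_mask(passing)]
    else:
        final = passing

    report = FilterReport(
        n_input=n_input,
        n_noncoding=n_noncoding,
        n_rare=n_rare,
        n_passing_threshold=n_passing,
        n_de_novo=n_de_novo,
        n_final=len(final),
        per_region_passing=per_region,
    )
    return final, report


def region_median_filter(
    variants: pd.DataFrame,
) -> tuple[pd.DataFrame, FilterReport]:
    """Median-split comparator: per region, retain score >= that region's
    median of the input set itself (even sizes use the mid-mean).

    Exonic variants are excluded for comparability with the cascade; no
    frequency or de novo stage is applied.
    """
    n_input = len(variants)
    region = variants["region"].astype(str) if n_input else pd.Series(dtype=str)
    nc = variants[(region != "exonic") & region.notna()] if n_input else variants
    if len(nc):
        med = nc.groupby("region")["score"].transform("median")
        out = nc[nc["score"] >= med]
    else:
        out = nc
    per_region = out["region"].value_counts().to_dict() if len(out) else {}
    report = FilterReport(
        n_input=n_input,
        n_noncoding=len(nc),
        n_rare=len(nc),
        n_passing_threshold=len(out),
        n_de_novo=int(_de_novo_mask(variants).sum()) if n_input else 0,
        n_final=len(out),
        per_region_passing=per_region,
    )
    return out, report


class VariantFilter(BaseEstimator, TransformerMixin):
    """Transformer applying the region-threshold cascade to a variant table.

    Parameters
    ----------
    thresholds:
        Mapping region -> score cutoff, or None for the packaged defaults.
    af_max:
        Strict rarity cutoff on allele frequency.
    require_de_novo:
        Restrict the final set to de novo calls.
    strategy:
        ``fixed_thresholds`` (the cascade) or ``region_median`` (the
        median-split comparator at the threshold stage).

    After ``transform`` the stage tallies are available as ``report_``.
    """

    def __init__(
        self,
        thresholds: Mapping[str, float] | None = None,
        af_max: float = 0.01,
        require_de_novo: bool = False,
        strategy: str = "fixed_thresholds",
    ):
        self.thresholds = thresholds
        self.af_max = af_max
        self.require_de_novo = require_de_novo
        self.strategy = strategy

    def _config(self) -> FilterConfig:
        thr = dict(self.thresholds) if self.thresholds is not None else default_thresholds()
        return FilterConfig(
            thresholds=thr,
            af_max=self.af_max,
            require_de_novo=self.require_de_novo,
            strategy=self.strategy,
        )

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit(X)
        out, report = filter_variants(X, self.config_)
        self.report_ = report
        return out
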