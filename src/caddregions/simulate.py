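"""Synthetic inputs for the whole pipeline.

Generates toy gene models with a ground-truth region map, clinical-archive-
like variant sets (region composition, class composition, class-conditional
Phred-score distributions), a common-variant set, and trio-WGS-like sets
with a planted pathogenic ncRNA-exonic de novo variant.

Realism choices (see the methods note): region composition defaults to the
composition of noncoding clinically classified variants in a public archive
(normalized to a simplex); class-conditional scores are truncated Normals
on the Phred scale [0, 99], which keeps analytic oracles (optimal cutpoint,
AUC) in closed-enough form; the WGS background draws scores from the Phred
scale's own defining distribution, ``-10*log10(U)`` with U uniform, and an
allele-frequency spectrum with an 8% rare tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .regions import RegionCategory, TranscriptModel

__all__ = [
    "SyntheticSpec",
    "CLINVAR_REGION_PROPS",
    "DEFAULT_CLASS_PROPS",
    "DEFAULT_SCORE_DISTS",
    "WGS_REGION_PROPS",
    "generate_gene_model",
    "truth_positions_by_region",
    "generate_clinvar_like",
    "generate_common_like",
    "generate_trio_wgs",
]

SCORE_LO, SCORE_HI = 0.0, 99.0


def _normalize(props: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(props.values()))
    return {k: v / total for k, v in props.items()}


#: Archive-like noncoding region composition (printed percentages of the
#: reference composition, normalized to sum to one).
CLINVAR_REGION_PROPS: dict[str, float] = _normalize(
    {
        "intronic": 0.786,
        "utr3": 0.100,
        "splicing": 0.077,
        "utr5": 0.032,
        "ncRNA_intronic": 0.028,
        "upstream": 0.014,
        "ncRNA_exonic": 0.009,
        "intergenic": 0.002,
        "downstream": 0.002,
    }
)

#: Archive-like class composition of noncoding variants
#: (benign 446766 : pathogenic 40196 : VUS 102627, normalized).
DEFAULT_CLASS_PROPS: dict[str, float] = _normalize(
    {"benign": 446766.0, "pathogenic": 40196.0, "vus": 102627.0}
)

# (region, class) -> (mu, sigma) of a truncated Normal on [0, 99].
# Means echo the observed ordering pathogenic > VUS > benign per region,
# with splicing pathogenic scores highest and the poorly annotated regions
# (ncRNA intronic, downstream) lowest; they are configuration, not claims
# about any real score distribution.
DEFAULT_SCORE_DISTS: dict[tuple[str, str], tuple[float, float]] = {
    ("intronic", "benign"): (6.0, 4.0),
    ("intronic", "vus"): (11.0, 5.0),
    ("intronic", "pathogenic"): (19.0, 6.0),
    ("utr3", "benign"): (6.0, 4.0),
    ("utr3", "vus"): (10.0, 5.0),
    ("utr3", "pathogenic"): (16.0, 6.0),
    ("splicing", "benign"): (10.0, 5.0),
    ("splicing", "vus"): (18.0, 6.0),
    ("splicing", "pathogenic"): (28.0, 5.0),
    ("utr5", "benign"): (8.0, 4.0),
    ("utr5", "vus"): (12.0, 5.0),
    ("utr5", "pathogenic"): (20.0, 6.0),
    ("ncRNA_intronic", "benign"): (4.0, 3.0),
    ("ncRNA_intronic", "vus"): (7.0, 4.0),
    ("ncRNA_intronic", "pathogenic"): (10.0, 5.0),
    ("upstream", "benign"): (8.0, 4.0),
    ("upstream", "vus"): (10.0, 5.0),
    ("upstream", "pathogenic"): (12.0, 6.0),
    ("ncRNA_exonic", "benign"): (7.0, 4.0),
    ("ncRNA_exonic", "vus"): (12.0, 5.0),
    ("ncRNA_exonic", "pathogenic"): (18.0, 6.0),
    ("intergenic", "benign"): (6.0, 4.0),
    ("intergenic", "vus"): (9.0, 5.0),
    ("intergenic", "pathogenic"): (13.0, 6.0),
    ("downstream", "benign"): (5.0, 3.0),
    ("downstream", "vus"): (8.0, 4.0),
    ("downstream", "pathogenic"): (11.0, 5.0),
}

#: WGS-like region composition (~99% noncoding, intergenic/intronic heavy).
WGS_REGION_PROPS: dict[str, float] = {
    "intergenic": 0.44,
    "intronic": 0.39,
    "ncRNA_intronic": 0.05,
    "upstream": 0.03,
    "downstream": 0.03,
    "utr3": 0.025,
    "splicing": 0.01,
    "utr5": 0.008,
    "ncRNA_exonic": 0.007,
    "exonic": 0.01,
}


@dataclass
class SyntheticSpec:
    """Full generative description of an archive-like variant set."""

    region_props: Mapping[str, float] = field(
        default_factory=lambda: dict(CLINVAR_REGION_PROPS)
    )
    class_props: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPS)
    )
    score_dists: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_DISTS)
    )
    n_variants: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.region_props.values()) - 1.0) > 1e-9:
            raise ValueError("region_props must sum to 1")
        if any(p < 0 for p in self.region_props.values()):
            raise ValueError("region_props must be non-negative")
        if abs(sum(self.class_props.values()) - 1.0) > 1e-9:
            raise ValueError("class_props must sum to 1")
        if any(p < 0 for p in self.class_props.values()):
            raise ValueError("class_props must be non-negative")
        for (region, cls), (mu, sigma) in self.score_dists.items():
            if sigma <= 0:
                raise ValueError(f"sigma must be > 0 for ({region}, {cls})")
            if not (SCORE_LO <= mu <= SCORE_HI):
                raise ValueError(f"mu must lie in [0, 99] for ({region}, {cls})")
        if self.n_variants < 0:
            raise ValueError("n_variants must be >= 0")

    def to_dict(self) -> dict:
        return {
            "region_props": dict(self.region_props),
            "class_props": dict(self.class_props),
            "score_dists": {f"{r}|{c}": list(v) for (r, c), v in self.score_dists.items()},
            "n_variants": self.n_variants,
            "seed": self.seed,
        }


def sample_truncnorm(mu: float, sigma: float, size: int, rng: np.random.Generator):
    a = (SCORE_LO - mu) / sigma
    b = (SCORE_HI - mu) / sigma
    return truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


# ---------------------------------------------------------------------------
# Gene model + ground truth


def generate_gene_model(
    n_genes: int,
    seed: int,
    chrom: str = "chr21",
    upstream_bp: int = 1000,
    downstream_bp: int = 1000,
    splice_bp: int = 2,
    margin: int = 300,
) -> tuple[list[TranscriptModel], dict[tuple[str, int], RegionCategory]]:
    """Toy chromosome with coding and noncoding genes plus a ground-truth map.

    Genes are spaced so their flanking windows never overlap, which lets the
    ground truth be painted gene-by-gene with no precedence logic: margins
    are intergenic, strand-aware 1-kb windows are upstream/downstream, exons
    split into UTRs/CDS (or ncRNA exons), introns are intronic (with the
    first/last ``splice_bp`` bases relabelled splicing for coding genes) or
    ncRNA-intronic.  Every covered position, including the exact window and
    junction boundaries, appears in the map.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    window = max(upstream_bp, downstream_bp)
    transcripts: list[TranscriptModel] = []
    truth: dict[tuple[str, int], RegionCategory] = {}
    cursor = 10_000 + window + margin

    for i in range(n_genes):
        coding = i % 3 != 2
        strand = "+" if i % 2 == 0 else "-"
        n_exons = 3 if coding else int(rng.integers(2, 4))
        exon_lens = rng.integers(150, 351, size=n_exons)
        intron_lens = rng.integers(60, 251, size=n_exons - 1)

        tx_start = cursor
        exons: list[tuple[int, int]] = []
        p = tx_start
        for k in range(n_exons):
            exons.append((p, p + int(exon_lens[k]) - 1))
            p = exons[-1][1] + 1
            if k < n_exons - 1:
                p += int(intron_lens[k])
        tx_end = exons[-1][1]

        if coding:
            u5 = int(rng.integers(20, 81))
            u3 = int(rng.integers(20, 81))
            cds_start = exons[0][0] + u5
            cds_end = exons[-1][1] - u3
        else:
            cds_start = cds_end = None

        transcripts.append(
            TranscriptModel(
                transcript_id=f"t{i}",
                gene_id=f"g{i}",
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )

        # --- paint the ground truth for this gene's neighborhood
        def paint(lo: int, hi: int, cat: RegionCategory) -> None:
            for pos in range(lo, hi + 1):
                truth[(chrom, pos)] = cat

        paint(tx_start - window - margin, tx_start - window - 1, RegionCategory.INTERGENIC)
        paint(tx_end + window + 1, tx_end + window + margin, RegionCategory.INTERGENIC)
        if strand == "+":
            paint(tx_start - upstream_bp, tx_start - 1, RegionCategory.UPSTREAM)
            paint(tx_end + 1, tx_end + downstream_bp, RegionCategory.DOWNSTREAM)
        else:
            paint(tx_end + 1, tx_end + upstream_bp, RegionCategory.UPSTREAM)
            paint(tx_start - downstream_bp, tx_start - 1, RegionCategory.DOWNSTREAM)

        for k, (es, ee) in enumerate(exons):
            if coding:
                for pos in range(es, ee + 1):
                    if pos < cds_start:
                        cat = RegionCategory.UTR5 if strand == "+" else RegionCategory.UTR3
                    elif pos > cds_end:
                        cat = RegionCategory.UTR3 if strand == "+" else RegionCategory.UTR5
                    else:
                        cat = RegionCategory.EXONIC
                    truth[(chrom, pos)] = cat
            else:
                paint(es, ee, RegionCategory.NCRNA_EXONIC)
            if k < len(exons) - 1:
                intron_lo, intron_hi = ee + 1, exons[k + 1][0] - 1
                paint(
                    intron_lo,
                    intron_hi,
                    RegionCategory.INTRONIC if coding else RegionCategory.NCRNA_INTRONIC,
                )
                if coding:
                    for d in range(1, splice_bp + 1):
                        truth[(chrom, ee + d)] = RegionCategory.SPLICING
                        truth[(chrom, exons[k + 1][0] - d)] = RegionCategory.SPLICING

        gap = int(rng.integers(500, 1501))
        cursor = tx_end + window + margin + gap + window + margin

    return transcripts, truth


def truth_positions_by_region(
    truth: Mapping[tuple[str, int], RegionCategory],
) -> dict[str, np.ndarray]:
    """Group ground-truth positions by region value (positions sorted)."""
    pools: dict[str, list[int]] = {}
    chrom = None
    for (c, pos), cat in truth.items():
        chrom = c
        pools.setdefault(cat.value, []).append(pos)
    return {k: np.array(sorted(v), dtype=np.int64) for k, v in pools.items()}


# ---------------------------------------------------------------------------
# Variant sets

_BASES = np.array(list("ACGT"))


def _alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def _positions(
    rng: np.random.Generator,
    regions: np.ndarray,
    pools: Mapping[str, np.ndarray] | None,
    chrom: str,
    base: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Positions per variant: geometry-consistent draws from the ground-truth
    pools when available, otherwise synthetic coordinates."""
    n = regions.size
    pos = np.zeros(n, dtype=np.int64)
    chroms = np.full(n, chrom, dtype=object)
    if pools:
        for region in np.unique(regions):
            mask = regions == region
            pool = pools.get(str(region))
            if pool is not None and pool.size:
                pos[mask] = rng.choice(pool, size=int(mask.sum()), replace=True)
            else:
                pos[mask] = base + np.flatnonzero(mask)
    else:
        pos[:] = base + np.arange(n)
    return chroms, pos


def generate_clinvar_like(
    spec: SyntheticSpec,
    pools: Mapping[str, np.ndarray] | None = None,
    chrom: str = "chr21",
) -> pd.DataFrame:
    """Archive-like annotated variant set drawn from ``spec``.

    Returns a table with columns chrom, pos, ref, alt, score, allele_freq,
    clin_class, de_novo, region.  When ``pools`` (from
    :func:`truth_positions_by_region`) is given, positions are drawn from the
    matching region's ground-truth positions so a region re-annotation run
    reproduces the labels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_variants

    region_names = list(spec.region_props)
    regions = rng.choice(
        region_names, size=n, p=[spec.region_props[r] for r in region_names]
    ).astype(object)
    class_names = list(spec.class_props)
    classes = rng.choice(
        class_names, size=n, p=[spec.class_props[c] for c in class_names]
    ).astype(object)

    scores = np.zeros(n, dtype=float)
    for region in region_names:
        for cls in class_names:
            mask = (regions == region) & (classes == cls)
            k = int(mask.sum())
            if not k:
                continue
            if (region, cls) not in spec.score_dists:
                raise ValueError(f"score_dists missing entry for ({region}, {cls})")
            mu, sigma = spec.score_dists[(region, cls)]
            scores[mask] = sample_truncnorm(mu, sigma, k, rng)

    af = np.zeros(n, dtype=float)
    benign_mask = classes == "benign"
    af[benign_mask] = rng.uniform(1e-4, 0.5, size=int(benign_mask.sum()))
    af[~benign_mask] = 10.0 ** rng.uniform(-6.0, -2.31, size=int((~benign_mask).sum()))

    ref, alt = _alleles(rng, n)
    chroms, pos = _positions(rng, regions, pools, chrom, base=10_000_000)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "score": scores,
            "allele_freq": af,
            "clin_class": classes,
            "de_novo": False,
            "region": regions,
        }
    )


def generate_common_like(
    n_variants: int,
    seed: int,
    region_props: Mapping[str, float] | None = None,
    score_dists: Mapping[tuple[str, str], tuple[float, float]] | None = None,
    pools: Mapping[str, np.ndarray] | None = None,
    chrom: str = "chr21",
) -> pd.DataFrame:
    """Population-reference-like common-variant set (allele frequency > 1%).

    Scores follow the benign class-conditional distributions, emulating the
    expectation that common variants are overwhelmingly non-deleterious.
    """
    rng = np.random.default_rng(seed)
    props = _normalize(dict(region_props or CLINVAR_REGION_PROPS))
    dists = dict(score_dists or DEFAULT_SCORE_DISTS)
    region_names = list(props)
    regions = rng.choice(region_names, size=n_variants, p=[props[r] for r in region_names]).astype(object)
    scores = np.zeros(n_variants, dtype=float)
    for region in region_names:
        mask = regions == region
        k = int(mask.sum())
        if k:
            mu, sigma = dists[(region, "benign")]
            scores[mask] = sample_truncnorm(mu, sigma, k, rng)
    af = rng.uniform(0.0101, 0.5, size=n_variants)
    ref, alt = _alleles(rng, n_variants)
    chroms, pos = _positions(rng, regions, pools, chrom, base=50_000_000)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "score": scores,
            "allele_freq": af,
            "clin_class": "benign",
            "de_novo": False,
            "region": regions,
        }
    )


def generate_trio_wgs(
    n_variants: int,
    de_novo_count: int = 80,
    planted_score: float = 20.8,
    seed: int = 0,
    region_props: Mapping[str, float] | None = None,
    rare_fraction: float = 0.08,
    pools: Mapping[str, np.ndarray] | None = None,
    chrom: str = "chr21",
) -> pd.DataFrame:
    """Trio-WGS-like variant set with one planted pathogenic variant.

    The background draws regions from a WGS-like composition, scores from
    the Phred scale's defining distribution (``-10*log10(U)``) and an
    allele-frequency spectrum with a ``rare_fraction`` rare tail.
    ``de_novo_count`` background variants are flagged de novo (novel, AF 0).
    Exactly one extra de novo ncRNA-exonic variant is planted with
    ``planted_score`` and labelled pathogenic (an insertion, emulating a
    recurrent small-nuclear-RNA disease allele); everything else is
    ``unknown``.
    """
    if de_novo_count > n_variants:
        raise ValueError("de_novo_count must not exceed n_variants")
    rng = np.random.default_rng(seed)
    props = _normalize(dict(region_props or WGS_REGION_PROPS))
    region_names = list(props)
    regions = rng.choice(region_names, size=n_variants, p=[props[r] for r in region_names]).astype(object)

    scores = np.minimum(-10.0 * np.log10(rng.uniform(1e-12, 1.0, size=n_variants)), SCORE_HI)

    af = np.empty(n_variants, dtype=float)
    rare_mask = rng.uniform(size=n_variants) < rare_fraction
    af[~rare_mask] = rng.uniform(0.0101, 0.5, size=int((~rare_mask).sum()))
    af[rare_mask] = 10.0 ** rng.uniform(-6.0, np.log10(0.0099), size=int(rare_mask.sum()))

    de_novo = np.zeros(n_variants, dtype=bool)
    dn_idx = rng.choice(n_variants, size=de_novo_count, replace=False)
    de_novo[dn_idx] = True
    af[dn_idx] = 0.0

    ref, alt = _alleles(rng, n_variants)
    chroms, pos = _positions(rng, regions, pools, chrom, base=100_000_000)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "score": scores,
            "allele_freq": af,
            "clin_class": "unknown",
            "de_novo": de_novo,
            "region": regions,
        }
    )

    if pools and pools.get("ncRNA_exonic") is not None and len(pools["ncRNA_exonic"]):
        planted_pos = int(pools["ncRNA_exonic"][0])
    else:
        planted_pos = 99_999_999
    planted = pd.DataFrame(
        {
            "chrom": [chrom],
            "pos": [planted_pos],
            "ref": ["T"],
            "alt": ["TT"],
            "score": [planted_score],
            "allele_freq": [0.0],
            "clin_class": ["pathogenic"],
            "de_novo": [True],
            "region": ["ncRNA_exonic"],
        }
    )
    return pd.concat([df, planted], ignore_index=True)
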