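"""Packaged default region-specific thresholds.

These are the reference cutoffs obtained from a ClinVar-scale analysis of
CADD v1.7 Phred scores, shipped so the filtering stage can run without
re-deriving thresholds.  Regions whose discrimination was weak (AUC <= 0.7)
or non-significant carry a threshold value but are flagged unusable; the
filtering cascade still applies them, mirroring how the reference analysis
counted threshold-passing variants in every region.
"""

from __future__ import annotations

from .regions import NONCODING_REGIONS

# region -> (threshold, adjusted p, significance, AUC)
TABLE_DEFAULTS: dict[str, tuple[float, float, str, float]] = {
    "upstream": (34.0, 5.5983e-18, "***", 0.347),
    "utr5": (16.79, 5.2879e-23, "***", 0.714),
    "intronic": (12.76, 0.0, "***", 0.886),
    "splicing": (25.5, 0.0, "***", 0.904),
    "utr3": (11.08, 1.2086e-20, "***", 0.820),
    "ncRNA_exonic": (11.44, 4.3687e-72, "***", 0.872),
    "ncRNA_intronic": (3.03, 1.9291e-11, "***", 0.620),
    "downstream": (0.82, 1.6134e-01, "ns", 0.629),
    "intergenic": (11.0, 2.2073e-04, "**", 0.664),
}

#: report row order
REGION_ORDER: tuple[str, ...] = tuple(r.value for r in NONCODING_REGIONS)


def default_thresholds() -> dict[str, float]:
    """The nine packaged region thresholds, keyed by region."""
    return {region: vals[0] for region, vals in TABLE_DEFAULTS.items()}


def default_threshold_records():
    """Packaged defaults as ThresholdRecord rows (usability recomputed)."""
    from .thresholds import ThresholdRecord, is_usable

    records = []
    for region in REGION_ORDER:
        thr, p_adj, sig, auc = TABLE_DEFAULTS[region]
        records.append(
            ThresholdRecord(
                region=region,
                threshold=thr,
                p_raw=p_adj,
                p_adj=p_adj,
                significance=sig,
                auc=auc,
                usable=is_usable(auc, sig),
                n_benign=0,
                n_pathogenic=0,
                n_vus=0,
                strategy="packaged",
            )
        )
    return records
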