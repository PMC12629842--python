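"""Readers and writers for variant tables, gene models and configs.

VCF goes through pysam with fixed INFO keys (overridable): ``CADD_PHRED``
(Phred deleteriousness score), ``AF`` (population allele frequency),
``CLASS`` (clinical classification, collapsed at parse time), ``DENOVO``
(flag) and ``REGION``.  Parsing applies the archive's hygiene rules:
likely benign/pathogenic are folded into benign/pathogenic, conflicting
classifications are dropped, mitochondrial and unplaced contigs are
excluded, multi-allelic records are split one row per ALT.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .regions import TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "ReadStats",
    "DEFAULT_INFO_KEYS",
    "collapse_clinical_class",
    "read_variants",
    "write_variants",
    "write_gtf",
    "save_thresholds_config",
    "load_thresholds_config",
    "config_hash",
]

DEFAULT_INFO_KEYS = {
    "score": "CADD_PHRED",
    "af": "AF",
    "clin": "CLASS",
    "de_novo": "DENOVO",
    "region": "REGION",
}

#: primary assemblies only; anything else counts as unplaced
CONTIG_PATTERN = r"(chr)?([1-9]|1[0-9]|2[0-2]|X|Y)"
_MITO_NAMES = {"chrm", "chrmt", "m", "mt"}

_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "score",
    "allele_freq",
    "clin_class",
    "de_novo",
    "region",
]


@dataclass
class ReadStats:
    """Counters of records dropped while parsing a variant file."""

    n_rows: int = 0
    n_dropped_conflicting: int = 0
    n_dropped_mito: int = 0
    n_dropped_unplaced: int = 0


def collapse_clinical_class(raw) -> str | None:
    """Collapse a raw clinical classification string.

    Likely benign folds into ``benign``, likely pathogenic into
    ``pathogenic``, uncertain significance into ``vus``; conflicting
    classifications return ``None`` (caller drops the record); anything
    unrecognized is ``unknown``.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "unknown"
    s = str(raw).strip().lower().replace(" ", "_")
    if s in ("", ".", "nan", "none"):
        return "unknown"
    if "conflicting" in s:
        return None
    if "benign" in s:
        return "benign"
    if "pathogenic" in s:
        return "pathogenic"
    if "uncertain" in s or s == "vus":
        return "vus"
    if s in ("benign", "pathogenic", "vus", "unknown"):
        return s
    return "unknown"


def _contig_status(chrom: str, contig_regex: str) -> str:
    if chrom.lower() in _MITO_NAMES:
        return "mito"
    if re.fullmatch(contig_regex, chrom):
        return "ok"
    return "unplaced"


def _scalar(value, alt_index: int):
    """Pull the per-ALT element out of a possibly tuple-valued INFO field."""
    if isinstance(value, tuple):
        if len(value) == 0:
            return None
        return value[alt_index] if alt_index < len(value) else value[0]
    return value


def _read_vcf(path: Path, info_keys: dict, contig_regex: str) -> tuple[pd.DataFrame, ReadStats]:
    stats = ReadStats()
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            status = _contig_status(rec.chrom, contig_regex)
            if status == "mito":
                stats.n_dropped_mito += 1
                continue
            if status == "unplaced":
                stats.n_dropped_unplaced += 1
                continue
            info = rec.info
            raw_class = info.get(info_keys["clin"], None)
            if isinstance(raw_class, tuple):
                raw_class = ",".join(str(v) for v in raw_class)
            clin = collapse_clinical_class(raw_class)
            if clin is None:
                stats.n_dropped_conflicting += 1
                continue
            alts = rec.alts or ()
            for ai, alt in enumerate(alts):
                score = _scalar(info.get(info_keys["score"], None), ai)
                if score is None:
                    raise ValueError(
                        f"{path}: record {rec.chrom}:{rec.pos} {rec.ref}>{alt} "
                        f"has no {info_keys['score']} score"
                    )
                af = _scalar(info.get(info_keys["af"], None), ai)
                region = _scalar(info.get(info_keys["region"], None), ai)
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": int(rec.pos),
                        "ref": rec.ref,
                        "alt": alt,
                        "score": float(score),
                        "allele_freq": float(af) if af is not None else np.nan,
                        "clin_class": clin,
                        "de_novo": bool(info.get(info_keys["de_novo"], False)),
                        "region": str(region) if region is not None else None,
                    }
                )
    stats.n_rows = len(rows)
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return df, stats


def _read_tsv(path: Path, contig_regex: str) -> tuple[pd.DataFrame, ReadStats]:
    stats = ReadStats()
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ref", "alt", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns: {sorted(missing)}")
    chroms = df["chrom"].astype(str)
    status = chroms.map(lambda c: _contig_status(c, contig_regex))
    stats.n_dropped_mito = int((status == "mito").sum())
    stats.n_dropped_unplaced = int((status == "unplaced").sum())
    df = df[status == "ok"].copy()
    if "clin_class" in df.columns:
        collapsed = df["clin_class"].map(collapse_clinical_class)
        stats.n_dropped_conflicting = int(collapsed.isna().sum())
        df = df[collapsed.notna()].copy()
        df["clin_class"] = collapsed[collapsed.notna()]
    else:
        df["clin_class"] = "unknown"
    if "allele_freq" not in df.columns:
        df["allele_freq"] = np.nan
    if "de_novo" not in df.columns:
        df["de_novo"] = False
    else:
        df["de_novo"] = df["de_novo"].map(
            lambda v: str(v).strip().lower() in ("true", "1", "yes")
        )
    if "region" not in df.columns:
        df["region"] = None
    df = df[_COLUMNS].reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    df["score"] = df["score"].astype(float)
    stats.n_rows = len(df)
    return df, stats


def read_variants(
    path,
    fmt: str | None = None,
    info_keys: dict | None = None,
    contig_regex: str = CONTIG_PATTERN,
    return_stats: bool = False,
):
    """Read a variant table from VCF or TSV into the canonical DataFrame.

    Columns: chrom, pos, ref, alt, score, allele_freq, clin_class, de_novo,
    region.  Drop counts (conflicting classifications, mitochondrial and
    unplaced contigs) are logged; pass ``return_stats=True`` to receive them.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" or str(path).endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        df, stats = _read_vcf(path, dict(info_keys or DEFAULT_INFO_KEYS), contig_regex)
    elif fmt == "tsv":
        df, stats = _read_tsv(path, contig_regex)
    else:
        raise ValueError(f"unknown variant format {fmt!r}")
    dropped = stats.n_dropped_conflicting + stats.n_dropped_mito + stats.n_dropped_unplaced
    if dropped:
        logger.info(
            "%s: dropped %d conflicting, %d mitochondrial, %d unplaced-contig records",
            path,
            stats.n_dropped_conflicting,
            stats.n_dropped_mito,
            stats.n_dropped_unplaced,
        )
    return (df, stats) if return_stats else df


def _vcf_header(df: pd.DataFrame, info_keys: dict) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in pd.unique(df["chrom"].astype(str)):
        header.contigs.add(chrom)
    header.info.add(info_keys["score"], 1, "Float", "Phred-scaled deleteriousness score")
    header.info.add(info_keys["af"], "A", "Float", "Population allele frequency")
    header.info.add(info_keys["clin"], 1, "String", "Collapsed clinical classification")
    header.info.add(info_keys["de_novo"], 0, "Flag", "De novo variant")
    header.info.add(info_keys["region"], 1, "String", "Genomic region category")
    return header


def _write_vcf(df: pd.DataFrame, path: Path, info_keys: dict) -> None:
    header = _vcf_header(df, info_keys)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in df.itertuples(index=False):
            rec = out.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                alleles=(str(row.ref), str(row.alt)),
            )
            rec.info[info_keys["score"]] = float(row.score)
            af = getattr(row, "allele_freq", None)
            if af is not None and not pd.isna(af):
                rec.info[info_keys["af"]] = (float(af),)
            clin = getattr(row, "clin_class", None)
            if clin and str(clin) != "unknown":
                rec.info[info_keys["clin"]] = str(clin)
            if bool(getattr(row, "de_novo", False)):
                rec.info[info_keys["de_novo"]] = True
            region = getattr(row, "region", None)
            if region is not None and not pd.isna(region):
                rec.info[info_keys["region"]] = str(region)
            out.write(rec)


def write_variants(df: pd.DataFrame, path, fmt: str | None = None, info_keys: dict | None = None) -> None:
    """Write the canonical variant DataFrame as VCF 4.2 or TSV."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "vcf":
        _write_vcf(df, path, dict(info_keys or DEFAULT_INFO_KEYS))
    elif fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown variant format {fmt!r}")


def write_gtf(transcripts, path) -> None:
    """Write transcripts as a minimal GTF (transcript/exon/CDS features)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\tcaddregions\ttranscript\t{t.tx_start}\t{t.tx_end}"
                f"\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tcaddregions\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.is_coding:
                fh.write(
                    f"{t.chrom}\tcaddregions\tCDS\t{t.cds_start}\t{t.cds_end}"
                    f"\t.\t{t.strand}\t.\t{attrs}\n"
                )


def save_thresholds_config(thresholds: dict, path, af_max: float = 0.01, meta: dict | None = None) -> None:
    """Serialize a region->threshold map (plus the rarity cutoff) as JSON."""
    payload = {
        "thresholds": {str(k): float(v) for k, v in thresholds.items()},
        "af_max": float(af_max),
    }
    if meta:
        payload["meta"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_thresholds_config(path) -> dict:
    """Load a thresholds JSON; returns the full payload dict."""
    with open(path) as fh:
        payload = json.load(fh)
    if "thresholds" not in payload:
        raise ValueError(f"{path}: not a thresholds config (missing 'thresholds')")
    payload["thresholds"] = {str(k): float(v) for k, v in payload["thresholds"].items()}
    return payload


def config_hash(config: dict) -> str:
    """Stable short hash of a semantic configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
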