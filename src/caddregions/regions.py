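"""Gene models and noncoding region classification.

Every variant is assigned to exactly one genomic region category from
transcript geometry alone: 1-kb upstream/downstream windows around the
transcription start/end sites, 5'/3' UTR, intronic, splicing (intronic
positions within 2 bp of an exon-intron junction of a coding transcript),
exonic and intronic ncRNA (transcripts without a CDS), intergenic, and
coding-exonic.  The nine noncoding categories feed the threshold analysis;
``exonic`` is carried along only so it can be excluded downstream.

Coordinates are 1-based inclusive throughout (VCF/GTF convention); indels
are anchored at the leftmost REF base.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


class RegionCategory(str, Enum):
    """Closed vocabulary of genomic region categories."""

    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRONIC = "intronic"
    SPLICING = "splicing"
    NCRNA_EXONIC = "ncRNA_exonic"
    NCRNA_INTRONIC = "ncRNA_intronic"
    INTERGENIC = "intergenic"
    EXONIC = "exonic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The nine analyzed noncoding categories in the report's fixed row order.
NONCODING_REGIONS = (
    RegionCategory.UPSTREAM,
    RegionCategory.UTR5,
    RegionCategory.INTRONIC,
    RegionCategory.SPLICING,
    RegionCategory.UTR3,
    RegionCategory.NCRNA_EXONIC,
    RegionCategory.NCRNA_INTRONIC,
    RegionCategory.DOWNSTREAM,
    RegionCategory.INTERGENIC,
)

# Total precedence order applied when a position is explicable by several
# overlapping transcripts (higher rank wins).  Refines the gene-annotation
# convention exonic/splicing first, then ncRNA exons, UTRs, introns, ncRNA
# introns, flanking windows, intergenic; upstream beats downstream.
_PRECEDENCE = {
    RegionCategory.EXONIC: 9,
    RegionCategory.SPLICING: 8,
    RegionCategory.NCRNA_EXONIC: 7,
    RegionCategory.UTR5: 6,
    RegionCategory.UTR3: 5,
    RegionCategory.INTRONIC: 4,
    RegionCategory.NCRNA_INTRONIC: 3,
    RegionCategory.UPSTREAM: 2,
    RegionCategory.DOWNSTREAM: 1,
    RegionCategory.INTERGENIC: 0,
}


@dataclass
class TranscriptModel:
    """Stranded transcript geometry sufficient for region classification.

    ``exons`` are 1-based inclusive ``(start, end)`` intervals sorted by
    start; ``cds_start``/``cds_end`` are both ``None`` for noncoding
    transcripts (absent CDS <=> not coding).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    def validate(self) -> None:
        """Raise ``ValueError`` on any geometry invariant violation."""
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.transcript_id}: tx_start > tx_end")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start {s} > end {e}")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(
                    f"{self.transcript_id}: exon ({s},{e}) outside transcript bounds"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: partial CDS bounds")
        if self.is_coding:
            span_lo, span_hi = self.exons[0][0], self.exons[-1][1]
            if self.cds_start > self.cds_end:
                raise ValueError(f"{self.transcript_id}: cds_start > cds_end")
            if self.cds_start < span_lo or self.cds_end > span_hi:
                raise ValueError(f"{self.transcript_id}: CDS outside exon span")


@dataclass
class Variant:
    """One allele observation with its score and clinical annotations.

    ``score`` is the Phred-scaled deleteriousness score (>= 0);
    ``clin_class`` is the collapsed clinical class (likely benign folded
    into ``benign``, likely pathogenic into ``pathogenic``).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    score: float
    allele_freq: float | None = None
    clin_class: str = "unknown"
    de_novo: bool | None = None

    def validate(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if self.allele_freq is not None and not (0.0 <= self.allele_freq <= 1.0):
            raise ValueError("allele_freq must lie in [0, 1]")
        if self.clin_class not in ("benign", "pathogenic", "vus", "unknown"):
            raise ValueError(f"unknown clinical class {self.clin_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class GeneModel:
    """Per-chromosome interval index over a set of transcripts."""

    def __init__(self, transcripts: Iterable[TranscriptModel], window: int = 1000):
        self.window = int(window)
        self.transcripts: list[TranscriptModel] = list(transcripts)
        for t in self.transcripts:
            t.validate()
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        for t in self.transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, ts in self._by_chrom.items():
            tree = IntervalTree()
            for t in ts:
                tree.addi(t.tx_start - self.window, t.tx_end + self.window + 1, t)
            self._trees[chrom] = tree

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._by_chrom

    def overlapping(self, chrom: str, pos: int, window: int | None = None):
        """Transcripts whose window-extended span covers ``pos``.

        Over-inclusion is harmless: per-transcript classification re-checks
        the exact strand-aware windows.
        """
        w = self.window if window is None else int(window)
        if chrom not in self._by_chrom:
            return []
        if w <= self.window:
            return [iv.data for iv in self._trees[chrom][pos]]
        return [
            t
            for t in self._by_chrom[chrom]
            if t.tx_start - w <= pos <= t.tx_end + w
        ]


def _classify_in_transcript(
    t: TranscriptModel,
    pos: int,
    upstream_bp: int,
    downstream_bp: int,
    splice_bp: int,
) -> RegionCategory | None:
    """Category of ``pos`` relative to one transcript, or None if unrelated."""
    if t.tx_start <= pos <= t.tx_end:
        in_exon = any(s <= pos <= e for s, e in t.exons)
        if t.is_coding:
            if in_exon:
                if t.cds_start <= pos <= t.cds_end:
                    return RegionCategory.EXONIC
                if pos < t.cds_start:
                    return RegionCategory.UTR5 if t.strand == "+" else RegionCategory.UTR3
                return RegionCategory.UTR3 if t.strand == "+" else RegionCategory.UTR5
            # intron side: distance 1..splice_bp from a junction is splicing
            dist = None
            prev_ends = [e for _, e in t.exons if e < pos]
            next_starts = [s for s, _ in t.exons if s > pos]
            if prev_ends:
                dist = pos - max(prev_ends)
            if next_starts:
                d2 = min(next_starts) - pos
                dist = d2 if dist is None else min(dist, d2)
            if dist is not None and dist <= splice_bp:
                return RegionCategory.SPLICING
            return RegionCategory.INTRONIC
        return RegionCategory.NCRNA_EXONIC if in_exon else RegionCategory.NCRNA_INTRONIC
    if t.strand == "+":
        up_lo, up_hi = t.tx_start - upstream_bp, t.tx_start - 1
        dn_lo, dn_hi = t.tx_end + 1, t.tx_end + downstream_bp
    else:
        up_lo, up_hi = t.tx_end + 1, t.tx_end + upstream_bp
        dn_lo, dn_hi = t.tx_start - downstream_bp, t.tx_start - 1
    if up_lo <= pos <= up_hi:
        return RegionCategory.UPSTREAM
    if dn_lo <= pos <= dn_hi:
        return RegionCategory.DOWNSTREAM
    return None


_warned_chroms: set[str] = set()


def classify_position(
    model: GeneModel,
    chrom: str,
    pos: int,
    upstream_bp: int = 1000,
    downstream_bp: int = 1000,
    splice_bp: int = 2,
) -> RegionCategory:
    """Classify a genomic position into exactly one region category."""
    if pos < 1:
        raise ValueError("position must be >= 1")
    if not model.has_chrom(chrom):
        if chrom not in _warned_chroms:
            logger.warning(
                "chromosome %s absent from gene model; classifying as intergenic", chrom
            )
            _warned_chroms.add(chrom)
        return RegionCategory.INTERGENIC
    best = RegionCategory.INTERGENIC
    for t in model.overlapping(chrom, pos, max(upstream_bp, downstream_bp)):
        cat = _classify_in_transcript(t, pos, upstream_bp, downstream_bp, splice_bp)
        if cat is not None and _PRECEDENCE[cat] > _PRECEDENCE[best]:
            best = cat
    return best


def classify_variant(
    v: Variant,
    transcripts: GeneModel | Iterable[TranscriptModel],
    upstream_bp: int = 1000,
    downstream_bp: int = 1000,
    splice_bp: int = 2,
) -> RegionCategory:
    """Region category of a variant (anchored at its leftmost REF base).

    Classification is deterministic under the fixed category precedence and
    therefore independent of transcript iteration order.
    """
    model = (
        transcripts
        if isinstance(transcripts, GeneModel)
        else GeneModel(transcripts, window=max(upstream_bp, downstream_bp))
    )
    return classify_position(model, v.chrom, v.pos, upstream_bp, downstream_bp, splice_bp)


def annotate_variants(
    df: pd.DataFrame,
    model: GeneModel,
    upstream_bp: int = 1000,
    downstream_bp: int = 1000,
    splice_bp: int = 2,
) -> pd.DataFrame:
    """Return a copy of ``df`` with a ``region`` column added.

    ``df`` must carry ``chrom`` and ``pos`` columns.
    """
    regions = [
        classify_position(model, c, int(p), upstream_bp, downstream_bp, splice_bp).value
        for c, p in zip(df["chrom"], df["pos"])
    ]
    out = df.copy()
    out["region"] = regions
    return out


class RegionAnnotator(BaseEstimator, TransformerMixin):
    """Transformer adding the region category to a variant table.

    Parameters
    ----------
    gene_model:
        A :class:`GeneModel`, or a path to a gene-model file (then
        ``gene_format`` selects the dialect).
    upstream_bp, downstream_bp:
        Window sizes around the transcription start/end sites.
    splice_bp:
        Intronic distance from a junction still called splicing.
    """

    def __init__(
        self,
        gene_model=None,
        gene_format: str = "gtf",
        upstream_bp: int = 1000,
        downstream_bp: int = 1000,
        splice_bp: int = 2,
    ):
        self.gene_model = gene_model
        self.gene_format = gene_format
        self.upstream_bp = upstream_bp
        self.downstream_bp = downstream_bp
        self.splice_bp = splice_bp

    def _resolve_model(self) -> GeneModel:
        if isinstance(self.gene_model, GeneModel):
            return self.gene_model
        if isinstance(self.gene_model, (str, Path)):
            return load_gene_model(self.gene_model, self.gene_format)
        if self.gene_model is None:
            raise ValueError("gene_model is required")
        return GeneModel(self.gene_model, window=max(self.upstream_bp, self.downstream_bp))

    def fit(self, X=None, y=None):
        self.model_ = self._resolve_model()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "model_"):
            self.fit(X)
        return annotate_variants(
            X, self.model_, self.upstream_bp, self.downstream_bp, self.splice_bp
        )


# ---------------------------------------------------------------------------
# Gene-model loading


def _prevalidate_gtf(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated GTF fields"
                )
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"{path}: line {lineno}: feature end < start")
            if parts[6] not in ("+", "-", "."):
                raise ValueError(f"{path}: line {lineno}: bad strand {parts[6]!r}")


def _load_gtf(path: Path) -> list[TranscriptModel]:
    import gffutils

    _prevalidate_gtf(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out: list[TranscriptModel] = []
    for tr in db.features_of_type("transcript"):
        exons = sorted(
            (f.start, f.end) for f in db.children(tr, featuretype="exon")
        )
        cds = [(f.start, f.end) for f in db.children(tr, featuretype="CDS")]
        cds_start = min(s for s, _ in cds) if cds else None
        cds_end = max(e for _, e in cds) if cds else None
        t = TranscriptModel(
            transcript_id=tr.attributes.get("transcript_id", [tr.id])[0],
            gene_id=tr.attributes.get("gene_id", [""])[0],
            chrom=tr.seqid,
            strand=tr.strand,
            tx_start=tr.start,
            tx_end=tr.end,
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
        )
        try:
            t.validate()
        except ValueError as exc:
            logger.warning("rejecting transcript %s: %s", t.transcript_id, exc)
            continue
        out.append(t)
    return out


_REFGENE_COLS = [
    "name",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "exonCount",
    "exonStarts",
    "exonEnds",
]


def _load_refgene(path: Path) -> list[TranscriptModel]:
    """Bin-less refGene dialect: 0-based half-open on disk, converted here."""
    df = pd.read_csv(path, sep="\t", names=_REFGENE_COLS, comment="#", dtype=str)
    out: list[TranscriptModel] = []
    for idx, row in df.iterrows():
        lineno = int(idx) + 1
        try:
            tx_start = int(row["txStart"]) + 1
            tx_end = int(row["txEnd"])
            cds_start0, cds_end0 = int(row["cdsStart"]), int(row["cdsEnd"])
            n_exons = int(row["exonCount"])
            starts = [int(x) + 1 for x in str(row["exonStarts"]).rstrip(",").split(",")]
            ends = [int(x) for x in str(row["exonEnds"]).rstrip(",").split(",")]
            if len(starts) != n_exons or len(ends) != n_exons:
                raise ValueError("exonCount disagrees with exon lists")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {lineno}: malformed refGene record: {exc}")
        coding = cds_start0 < cds_end0
        t = TranscriptModel(
            transcript_id=str(row["name"]),
            gene_id=str(row["name"]),
            chrom=str(row["chrom"]),
            strand=str(row["strand"]),
            tx_start=tx_start,
            tx_end=tx_end,
            exons=list(zip(starts, ends)),
            cds_start=cds_start0 + 1 if coding else None,
            cds_end=cds_end0 if coding else None,
        )
        try:
            t.validate()
        except ValueError as exc:
            logger.warning("rejecting transcript %s: %s", t.transcript_id, exc)
            continue
        out.append(t)
    return out


def load_gene_model(path, fmt: str = "gtf", window: int = 1000) -> GeneModel:
    """Load transcripts from ``gtf`` or ``refgene_tsv`` into a :class:`GeneModel`.

    Malformed records raise ``ValueError`` naming the line; transcripts whose
    CDS falls outside the exon span are rejected with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "gtf":
        transcripts = _load_gtf(path)
    elif fmt == "refgene_tsv":
        transcripts = _load_refgene(path)
    else:
        raise ValueError(f"unknown gene-model format {fmt!r}")
    return GeneModel(transcripts, window=window)
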