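"""Longest-isoform transcript models built from a GTF annotation.

Every topology feature is computed against a single representative
transcript per gene: the isoform with the greatest exonic (mature
mRNA) length, ties broken by the lexicographically smallest
transcript id.  UTRs are inferred from the CDS when not annotated.

Coordinates are 0-based half-open internally; the GTF's 1-based
inclusive intervals are converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils

logger = logging.getLogger(__name__)

__all__ = ["TranscriptModel", "build_transcript_models", "validate_gtf"]

Interval = tuple[int, int]  # 0-based half-open genomic


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one gene's representative transcript.

    ``exons`` and ``cds`` are 0-based half-open genomic intervals in
    ascending genomic order; transcript orientation is handled by the
    coordinate-lifting methods.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    gene_span: Interval | None = None
    biotype: str | None = None
    n_isoforms: int = 1

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for (a, b) in self.exons:
            if b <= a:
                raise ValueError(f"{self.transcript_id}: empty exon [{a},{b})")
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.gene_span is None:
            self.gene_span = (self.exons[0][0], self.exons[-1][1])

    # -- basic geometry -----------------------------------------------------

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[Interval]:
        return [
            (b1, a2) for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site base."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    def exons_in_transcript_order(self) -> list[Interval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    # -- coordinate lifting -------------------------------------------------

    def genomic_to_transcript(self, pos: int) -> int | None:
        """0-based mature-transcript coordinate of a genomic base.

        Returns None for intronic or out-of-span positions.
        """
        offset = 0
        for a, b in self.exons_in_transcript_order():
            if a <= pos < b:
                if self.strand == "+":
                    return offset + (pos - a)
                return offset + (b - 1 - pos)
            offset += b - a
        return None

    def transcript_to_genomic(self, t: int) -> int:
        if not 0 <= t < self.exonic_length:
            raise ValueError(f"transcript coordinate {t} out of range")
        offset = 0
        for a, b in self.exons_in_transcript_order():
            size = b - a
            if t < offset + size:
                within = t - offset
                return a + within if self.strand == "+" else b - 1 - within
            offset += size
        raise AssertionError("unreachable")

    def exon_index_at(self, pos: int) -> int | None:
        """Index (in transcript order, 0 = first exon) of the exon
        containing a genomic position, or None."""
        for i, (a, b) in enumerate(self.exons_in_transcript_order()):
            if a <= pos < b:
                return i
        return None

    def intron_at(self, pos: int) -> Interval | None:
        for a, b in self.introns:
            if a <= pos < b:
                return (a, b)
        return None

    # -- CDS / UTR in transcript coordinates ---------------------------------

    @property
    def cds_span_t(self) -> Interval | None:
        """CDS as a half-open interval in transcript coordinates."""
        if not self.cds:
            return None
        ts = []
        for a, b in self.cds:
            ts.append(self.genomic_to_transcript(a))
            ts.append(self.genomic_to_transcript(b - 1))
        ts = [t for t in ts if t is not None]
        if not ts:
            return None
        return (min(ts), max(ts) + 1)

    @property
    def utr5_length(self) -> int:
        span = self.cds_span_t
        return span[0] if span else 0

    @property
    def cds_length(self) -> int:
        span = self.cds_span_t
        return span[1] - span[0] if span else 0

    @property
    def utr3_length(self) -> int:
        span = self.cds_span_t
        return self.exonic_length - span[1] if span else 0

    def region_of(self, pos: int) -> str:
        """'utr5' | 'cds' | 'utr3' | 'exon' | 'intron' | 'intergenic'."""
        t = self.genomic_to_transcript(pos)
        if t is None:
            if self.intron_at(pos) is not None:
                return "intron"
            return "intergenic"
        span = self.cds_span_t
        if span is None:
            return "exon"
        if t < span[0]:
            return "utr5"
        if t < span[1]:
            return "cds"
        return "utr3"

    def mature_sequence(self, genome) -> str:
        """Mature (spliced) transcript sequence, 5'->3', DNA alphabet."""
        from .encoders import reverse_complement

        chrom = genome[self.chrom]
        parts = [str(chrom[a:b]).upper() for a, b in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)


def validate_gtf(path) -> None:
    """Cheap structural validation; raises naming the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, found {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(
                    f"malformed GTF line {lineno}: non-integer coordinates"
                ) from None
            if start < 1 or end < start:
                raise ValueError(
                    f"malformed GTF line {lineno}: invalid interval {start}-{end}"
                )


def build_transcript_models(gtf_path) -> dict[str, TranscriptModel]:
    """One representative TranscriptModel per gene from a GTF.

    Keeps the transcript with the greatest exonic length per gene
    (ties: smallest transcript id); records the gene's isoform count
    from the full annotation before pruning.  Genes without exon
    records are skipped with a warning.
    """
    gtf_path = str(gtf_path)
    validate_gtf(gtf_path)
    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    tx_gene: dict[str, str] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        tx_gene[tid] = feat.attributes["gene_id"][0]
        exons.setdefault(tid, []).append((feat.start - 1, feat.end, feat.seqid, feat.strand))
    for feat in db.features_of_type("CDS"):
        tid = feat.attributes["transcript_id"][0]
        cds.setdefault(tid, []).append((feat.start - 1, feat.end))

    gene_spans: dict[str, Interval] = {}
    gene_biotype: dict[str, str] = {}
    gene_ids_seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gid = feat.attributes["gene_id"][0]
        gene_ids_seen.add(gid)
        gene_spans[gid] = (feat.start - 1, feat.end)
        bt = feat.attributes.get("gene_biotype") or feat.attributes.get("gene_type")
        if bt:
            gene_biotype[gid] = bt[0]

    by_gene: dict[str, list[str]] = {}
    for tid, gid in tx_gene.items():
        by_gene.setdefault(gid, []).append(tid)

    for gid in gene_ids_seen - set(by_gene):
        logger.warning("gene %s has no exon records; skipped", gid)

    models: dict[str, TranscriptModel] = {}
    for gid, tids in by_gene.items():
        def exonic_len(tid: str) -> int:
            return sum(b - a for a, b, _, _ in exons[tid])

        best = min(tids, key=lambda tid: (-exonic_len(tid), tid))
        ex = exons[best]
        chrom, strand = ex[0][2], ex[0][3]
        models[gid] = TranscriptModel(
            gene_id=gid,
            transcript_id=best,
            chrom=chrom,
            strand=strand,
            exons=[(a, b) for a, b, _, _ in ex],
            cds=cds.get(best, []),
            gene_span=gene_spans.get(gid),
            biotype=gene_biotype.get(
                gid, "protein_coding" if cds.get(best) else None
            ),
            n_isoforms=len(tids),
        )
    return models
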