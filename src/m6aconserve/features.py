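"""The 54-slot genome-derived feature vector and full-site featurization.

Slots are grouped the way the feature scheme is organized:

====== ============== ======================================================
slots  group          content
====== ============== ======================================================
1-15   dummy          binary transcript-region membership flags
16-19  rel_pos        relative position within 5'UTR / CDS / 3'UTR / mRNA
20-27  region_len     log2(1+length) of the containing regions
28-31  distance       splice-junction distances; nearest conserved site
32-33  conservation   phastCons-style score at the base / window mean
34-35  structure      predicted pairing of the window; center unpaired
36-43  regulator      overlap with regulator-binding interval tracks
44-48  gene_prop      exon/isoform counts, biotype, gene span, mRNA length
49-51  gc_z           GC-content z-scores (window / host exon / transcript)
52-54  omics          overlap with omics interval tracks (e.g. miRNA targets)
====== ============== ======================================================

Distances and lengths are log2(1+x)-transformed (heavy-tailed).  The
full feature vector prepends a sequence-encoding block; with the
default NCP+EIIP strategy and a 41-nt window that is 4*41 + 54 = 218
columns.  Everything is min-max normalized to [0,1] downstream, with
statistics fit on training data only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from bisect import bisect_left

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree
from sklearn.preprocessing import MinMaxScaler

from .encoders import encode_sequence_block, extract_window
from .fold import max_pairing_fold, parse_dotbracket
from .sites import GenomicSite
from .tracks import N_OMICS_SLOTS, N_REGULATOR_SLOTS, TrackSet
from .transcripts import TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSlot",
    "default_registry",
    "load_registry",
    "genomic_feature_names",
    "assign_sites_to_genes",
    "TranscriptomeStats",
    "compute_transcriptome_stats",
    "ConservedSiteIndex",
    "topology_features",
    "distance_features",
    "track_features",
    "structure_features",
    "gene_level_features",
    "featurize",
    "fit_minmax",
    "apply_minmax",
]

LONG_EXON_BP = 400
NEAR_CODON_BP = 100
NEAR_CONSERVED_BP = 2000


@dataclass(frozen=True)
class FeatureSlot:
    slot: int  # 1-based
    name: str
    group: str


_GROUP_OF_SLOT = (
    [(1, 15, "dummy"), (16, 19, "rel_pos"), (20, 27, "region_len"),
     (28, 31, "distance"), (32, 33, "conservation"), (34, 35, "structure"),
     (36, 43, "regulator"), (44, 48, "gene_prop"), (49, 51, "gc_z"),
     (52, 54, "omics")]
)

_DEFAULT_NAMES = [
    # 1-15: region dummies
    "dummy_5utr", "dummy_3utr", "dummy_cds", "dummy_exon", "dummy_intron",
    "dummy_first_exon", "dummy_last_exon", "dummy_long_exon400",
    "dummy_long_internal_exon400", "dummy_stop_codon_100nt",
    "dummy_start_codon_100nt", "dummy_tss_100nt", "dummy_transcript_body",
    "dummy_last_exon_5p400", "dummy_single_exon_tx",
    # 16-19: relative positions
    "relpos_5utr", "relpos_cds", "relpos_3utr", "relpos_transcript",
    # 20-27: region lengths
    "len_5utr", "len_cds", "len_3utr", "len_exon", "len_intron",
    "len_gene", "len_tx_span", "len_mature_mrna",
    # 28-31: distances
    "dist_junction_5p", "dist_junction_3p", "dist_nearest_conserved",
    "near_conserved_2kb",
    # 32-33: conservation
    "phastcons_site", "phastcons_window",
    # 34-35: structure
    "struct_paired_frac", "struct_center_unpaired",
    # 36-43: regulators
    *[f"regulator_overlap_{i}" for i in range(1, N_REGULATOR_SLOTS + 1)],
    # 44-48: gene properties
    "log2_exon_count", "log2_isoform_count", "is_protein_coding",
    "log2_gene_span", "log2_mature_len",
    # 49-51: GC z-scores
    "gc_z_window", "gc_z_exon", "gc_z_transcript",
    # 52-54: omics
    *[f"omics_overlap_{i}" for i in range(1, N_OMICS_SLOTS + 1)],
]


def _group_for(slot: int) -> str:
    for lo, hi, group in _GROUP_OF_SLOT:
        if lo <= slot <= hi:
            return group
    raise ValueError(f"slot {slot} outside 1..54")


def default_registry() -> list[FeatureSlot]:
    """The canonical ordered 54-slot registry."""
    return [
        FeatureSlot(slot=i + 1, name=name, group=_group_for(i + 1))
        for i, name in enumerate(_DEFAULT_NAMES)
    ]


def load_registry(path) -> list[FeatureSlot]:
    """Load a slot->name mapping from YAML, overriding default names.

    The YAML holds a mapping of slot numbers (1-54) to names; group
    membership is fixed by slot number, so the canonical naming can be
    swapped without code change.
    """
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    registry = default_registry()
    for slot, name in overrides.items():
        slot = int(slot)
        registry[slot - 1] = FeatureSlot(slot=slot, name=str(name),
                                         group=_group_for(slot))
    return registry


def genomic_feature_names(registry=None) -> list[str]:
    return [s.name for s in (registry or default_registry())]


# ---------------------------------------------------------------------------
# Site -> gene assignment


def assign_sites_to_genes(
    sites, models: dict[str, TranscriptModel]
) -> dict[str, str | None]:
    """Map site_id -> gene_id of the containing gene (same strand).

    Sites contained in no gene span map to None (and later keep a zero
    topology block).  Ties between containing genes resolve to the
    smallest gene_id.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for gid, model in models.items():
        key = (model.chrom, model.strand)
        a, b = model.gene_span
        trees.setdefault(key, IntervalTree()).addi(a, b, gid)
    out: dict[str, str | None] = {}
    n_unassigned = 0
    for site in sites:
        tree = trees.get((site.chrom, site.strand))
        hits = sorted(iv.data for iv in tree.at(site.position)) if tree else []
        out[site.site_id] = hits[0] if hits else None
        n_unassigned += not hits
    if n_unassigned:
        logger.warning(
            "%d sites fall outside every gene span; topology features zeroed",
            n_unassigned,
        )
    return out


# ---------------------------------------------------------------------------
# Transcriptome-wide summary statistics (for GC z-scores)


@dataclass
class TranscriptomeStats:
    tx_gc_mean: float
    tx_gc_sd: float
    exon_gc_mean: float
    exon_gc_sd: float


def _gc(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    return (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0


def compute_transcriptome_stats(
    models: dict[str, TranscriptModel], genome
) -> TranscriptomeStats:
    """Mean/SD (ddof=1) of mature-transcript GC and pooled exon GC."""
    tx_gc, exon_gc = [], []
    for model in models.values():
        chrom = genome[model.chrom]
        exon_seqs = [str(chrom[a:b]) for a, b in model.exons]
        tx_gc.append(_gc("".join(exon_seqs)))
        exon_gc.extend(_gc(s) for s in exon_seqs)

    def _mean_sd(xs):
        arr = np.asarray(xs, dtype=float)
        if arr.size == 0:
            return 0.0, 0.0
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    tm, ts = _mean_sd(tx_gc)
    em, es = _mean_sd(exon_gc)
    return TranscriptomeStats(tx_gc_mean=tm, tx_gc_sd=ts,
                              exon_gc_mean=em, exon_gc_sd=es)


def _zscore(x: float, mean: float, sd: float) -> float:
    if sd == 0:
        logger.warning("zero spread in reference distribution; z-score set to 0")
        return 0.0
    return (x - mean) / sd


# ---------------------------------------------------------------------------
# Nearest-conserved-site index


class ConservedSiteIndex:
    """Nearest-neighbor queries over conserved training-site positions,
    keyed by (chrom, strand), with the query site itself excluded."""

    def __init__(self, sites):
        self._pos: dict[tuple[str, str], list[int]] = {}
        for s in sites:
            self._pos.setdefault((s.chrom, s.strand), []).append(s.position)
        for key in self._pos:
            self._pos[key] = sorted(self._pos[key])
        self.empty = not self._pos

    def nearest_distance(self, site: GenomicSite) -> int | None:
        """Genomic distance to the nearest conserved site on the same
        chromosome and strand, excluding any site at the query's own
        position; None when no such site exists."""
        positions = self._pos.get((site.chrom, site.strand), [])
        candidates = [p for p in positions if p != site.position]
        if not candidates:
            return None
        i = bisect_left(candidates, site.position)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(candidates):
                d = abs(candidates[j] - site.position)
                best = d if best is None else min(best, d)
        return best


# ---------------------------------------------------------------------------
# Per-group extractors


def _log1p2(x: float) -> float:
    return float(np.log2(1.0 + x))


def topology_features(site: GenomicSite, model: TranscriptModel | None) -> np.ndarray:
    """Slots 1-27: region dummies, relative positions, region lengths.

    All zeros for sites assigned to no gene.
    """
    out = np.zeros(27)
    if model is None:
        return out
    pos = site.position
    t = model.genomic_to_transcript(pos)
    region = model.region_of(pos)
    in_exon = t is not None
    exon_idx = model.exon_index_at(pos)
    exons_t = model.exons_in_transcript_order()
    cds_span = model.cds_span_t

    # --- 1-15 dummies ---
    out[0] = region == "utr5"
    out[1] = region == "utr3"
    out[2] = region == "cds"
    out[3] = in_exon
    out[4] = region == "intron"
    if exon_idx is not None:
        a, b = exons_t[exon_idx]
        exon_len = b - a
        out[5] = exon_idx == 0
        out[6] = exon_idx == model.n_exons - 1
        out[7] = exon_len > LONG_EXON_BP
        out[8] = out[7] and 0 < exon_idx < model.n_exons - 1
        if exon_idx == model.n_exons - 1:
            # offset of the site within the last exon, 5'->3'
            off = (pos - a) if model.strand == "+" else (b - 1 - pos)
            out[13] = off < LONG_EXON_BP
    if t is not None and cds_span is not None:
        out[9] = abs(t - (cds_span[1] - 1)) <= NEAR_CODON_BP  # stop codon
        out[10] = abs(t - cds_span[0]) <= NEAR_CODON_BP       # start codon
    if t is not None:
        out[11] = t <= NEAR_CODON_BP                          # TSS
    span_a, span_b = model.span
    out[12] = span_a <= pos < span_b                          # transcript body
    out[14] = model.n_exons == 1

    # --- 16-19 relative positions (offset / region length, 0 outside) ---
    if t is not None:
        L = model.exonic_length
        if cds_span is not None:
            u5, (c0, c1) = model.utr5_length, cds_span
            if region == "utr5" and u5 > 0:
                out[15] = t / u5
            if region == "cds":
                out[16] = (t - c0) / (c1 - c0)
            if region == "utr3" and L - c1 > 0:
                out[17] = (t - c1) / (L - c1)
        out[18] = t / L
    elif region == "intron":
        # intronic sites carry a transcript-span position even though
        # they have no mature-mRNA coordinate
        sa, sb = model.span
        off = (pos - sa) if model.strand == "+" else (sb - 1 - pos)
        out[18] = off / (sb - sa)

    # --- 20-27 region lengths, log2(1+x) ---
    if cds_span is not None:
        out[19] = _log1p2(model.utr5_length)
        out[20] = _log1p2(model.cds_length)
        out[21] = _log1p2(model.utr3_length)
    if exon_idx is not None:
        a, b = exons_t[exon_idx]
        out[22] = _log1p2(b - a)
    intron = model.intron_at(pos)
    if intron is not None:
        out[23] = _log1p2(intron[1] - intron[0])
    ga, gb = model.gene_span
    out[24] = _log1p2(gb - ga)
    out[25] = _log1p2(model.span[1] - model.span[0])
    out[26] = _log1p2(model.exonic_length)
    return out


def distance_features(
    site: GenomicSite,
    model: TranscriptModel | None,
    conserved_index: ConservedSiteIndex | None,
) -> np.ndarray:
    """Slots 28-31: splice-junction distances and conserved-site proximity."""
    out = np.zeros(4)
    if model is not None and model.n_exons > 1:
        exon_idx = model.exon_index_at(site.position)
        if exon_idx is not None:
            a, b = model.exons_in_transcript_order()[exon_idx]
            if model.strand == "+":
                d5, d3 = site.position - a, b - 1 - site.position
            else:
                d5, d3 = b - 1 - site.position, site.position - a
            out[0] = _log1p2(d5)
            out[1] = _log1p2(d3)
    if conserved_index is None or conserved_index.empty:
        logger.warning(
            "no conserved training sites supplied; distance slots 30-31 zeroed"
        )
        return out
    d = conserved_index.nearest_distance(site)
    if d is not None:
        out[2] = _log1p2(d)
        out[3] = float(d < NEAR_CONSERVED_BP)
    return out


def track_features(
    site: GenomicSite, flank: int, tracks: TrackSet | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slots 32-33 (conservation), 36-43 (regulators), 52-54 (omics)."""
    cons = np.zeros(2)
    reg = np.zeros(N_REGULATOR_SLOTS)
    omics = np.zeros(N_OMICS_SLOTS)
    if tracks is None:
        return cons, reg, omics
    tracks.warn_unbound_once()
    if tracks.conservation is not None:
        cons[0] = tracks.conservation.value_at(site.chrom, site.position)
        cons[1] = tracks.conservation.window_mean(
            site.chrom, site.position - flank, site.position + flank + 1
        )
    for i, track in enumerate(tracks.regulators):
        reg[i] = float(track.overlaps(site.chrom, site.position))
    for i, track in enumerate(tracks.omics):
        omics[i] = float(track.overlaps(site.chrom, site.position))
    return cons, reg, omics


def structure_features(window, dotbracket: str | None = None) -> np.ndarray:
    """Slots 34-35: paired fraction and center-unpaired indicator.

    Uses the built-in maximum base-pairing fold unless a precomputed
    dot-bracket structure is supplied.  Windows containing N get zeros.
    """
    seq = window.bases
    if dotbracket is None:
        if "N" in seq:
            logger.warning(
                "site %s: window contains N, structure features zeroed",
                window.site_id,
            )
            return np.zeros(2)
        dotbracket = max_pairing_fold(seq)
    if len(dotbracket) != len(seq):
        raise ValueError("dot-bracket length does not match the window")
    n_pairs, mask = parse_dotbracket(dotbracket)
    paired_frac = 2 * n_pairs / len(seq)
    center_unpaired = float(not mask[window.center_index])
    return np.array([paired_frac, center_unpaired])


def gene_level_features(
    site: GenomicSite,
    model: TranscriptModel | None,
    stats: TranscriptomeStats,
    genome,
    window,
) -> np.ndarray:
    """Slots 44-48 (gene properties) and 49-51 (GC z-scores)."""
    out = np.zeros(8)
    out[5] = _zscore(_gc(window.bases.replace("U", "T")),
                     stats.tx_gc_mean, stats.tx_gc_sd)
    if model is None:
        return out
    out[0] = float(np.log2(model.n_exons))
    out[1] = float(np.log2(model.n_isoforms))
    out[2] = float(model.biotype == "protein_coding")
    ga, gb = model.gene_span
    out[3] = _log1p2(gb - ga)
    out[4] = _log1p2(model.exonic_length)
    chrom = genome[site.chrom]
    exon_idx = model.exon_index_at(site.position)
    if exon_idx is not None:
        a, b = model.exons_in_transcript_order()[exon_idx]
        out[6] = _zscore(_gc(str(chrom[a:b])), stats.exon_gc_mean,
                         stats.exon_gc_sd)
    tx_gc = _gc("".join(str(chrom[a:b]) for a, b in model.exons))
    out[7] = _zscore(tx_gc, stats.tx_gc_mean, stats.tx_gc_sd)
    return out


# ---------------------------------------------------------------------------
# Full featurization


def featurize(
    sites,
    models: dict[str, TranscriptModel],
    genome,
    tracks: TrackSet | None = None,
    conserved_training_sites=None,
    flank: int = 20,
    sequence_strategy: str = "ncp_eiip",
    include_genomic: bool = True,
    registry=None,
    center_check: str = "warn",
) -> pd.DataFrame:
    """Per-site feature matrix: sequence block then the 54 genomic slots.

    Returns a DataFrame indexed by site_id with a stable, documented
    column order.  ``conserved_training_sites`` feeds the
    nearest-conserved-site slots and must come from training data only.
    """
    sites = list(sites)
    registry = registry or default_registry()
    if len(registry) != 54:
        raise ValueError("genomic feature registry must have exactly 54 slots")
    gnames = [s.name for s in registry]
    assignment = assign_sites_to_genes(sites, models) if include_genomic else {}
    stats = (
        compute_transcriptome_stats(models, genome) if include_genomic else None
    )
    cons_index = (
        ConservedSiteIndex(conserved_training_sites)
        if conserved_training_sites is not None
        else None
    )

    rows, index, columns = [], [], None
    for site in sites:
        window = extract_window(genome, site, flank=flank,
                                center_check=center_check)
        try:
            seq_vec, seq_names = encode_sequence_block(
                window, flank, strategy=sequence_strategy
            )
            parts = [seq_vec]
            names = list(seq_names)
            if include_genomic:
                model = models.get(assignment.get(site.site_id))
                topo = topology_features(site, model)
                dist = distance_features(site, model, cons_index)
                cons, reg, omics = track_features(site, flank, tracks)
                struct = structure_features(window)
                gene = gene_level_features(site, model, stats, genome, window)
                genomic = np.concatenate([
                    topo, dist, cons, struct, reg, gene[:5], gene[5:], omics
                ])
                parts.append(genomic)
                names.extend(gnames)
            rows.append(np.concatenate(parts))
            index.append(site.site_id)
            if columns is None:
                columns = names
        except Exception as exc:
            raise RuntimeError(
                f"featurization failed for site {site.site_id} "
                f"({site.chrom}:{site.position}{site.strand})"
            ) from exc
    if not rows:
        cols = columns or []
        return pd.DataFrame(np.empty((0, len(cols))), columns=cols)
    return pd.DataFrame(np.vstack(rows), index=index, columns=columns)


# ---------------------------------------------------------------------------
# Min-max normalization (fit on training data only)


def fit_minmax(train: pd.DataFrame) -> MinMaxScaler:
    """Fit a per-feature [0,1] scaler on training vectors.

    Constant features map to 0; out-of-range test values clamp.
    """
    scaler = MinMaxScaler(clip=True)
    scaler.fit(train.to_numpy(dtype=float))
    scaler.feature_names_ = list(train.columns)
    return scaler


def apply_minmax(scaler: MinMaxScaler, vectors: pd.DataFrame) -> pd.DataFrame:
    names = getattr(scaler, "feature_names_", None)
    if names is not None and list(vectors.columns) != names:
        raise ValueError("feature columns do not match the fitted scaler")
    arr = scaler.transform(vectors.to_numpy(dtype=float))
    return pd.DataFrame(arr, index=vectors.index, columns=vectors.columns)
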