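"""Self-contained synthetic genomes with a planted conservation signal.

Generates everything the pipeline consumes — genome FASTA, gene
annotation GTF, single-base site BED, 23-tissue occurrence TSV,
conservation bedGraph and regulator/omics interval BEDs — with a
controllable class signal so the whole framework is testable without
any external download.

Candidate adenosines are placed only inside DRACH motif contexts on
mature transcripts, for conserved and non-conserved sites alike: the
two classes deliberately share the same sequence context, so the
planted signal lives in the genome-derived features, not in the
sequence.  At ``effect_strength`` e:

* conserved sites are preferentially placed in long (>400 bp) exons and
  within 100 nt of the stop codon (placement weight 1 + 4e per
  property);
* the conservation signal at site neighborhoods has mean 0.30 + 0.35e
  for conserved sites vs 0.30 for others (sd 0.15, clipped to [0,1]);
* regulator track i overlaps conserved sites with probability
  0.2 + 0.5e*f_i (f_i tapering over the eight tracks) vs 0.2;
* omics tracks use 0.15 + 0.3e vs 0.15.

At e = 0 the class distributions coincide and downstream AUROC is at
chance.  Tissue counts are planted exactly: 23/23 for conserved, a
uniform draw from {1..6} for tissue-specific sites and from {7..22}
for an excluded slice, so the labeling rules recover the planted
partition.

All randomness flows from numpy's PCG64 via ``default_rng([seed, k])``
with a fixed stream id k per stage, so every artifact is byte-identical
across reruns and platforms.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .sites import GenomicSite, write_sites_bed
from .transcripts import TranscriptModel, build_transcript_models

__all__ = ["SynthConfig", "SynthBundle", "generate_genome",
           "generate_annotation", "generate_sites_and_profiles",
           "generate_tracks", "generate_bundle"]

DRACH = re.compile(r"(?=[AGT][AG]AC[ACT])")  # DNA alphabet; A at offset +2


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 700_000
    n_genes: int = 200
    n_sites: int = 2000
    n_tissues: int = 23
    conserved_fraction: float = 0.30
    excluded_fraction: float = 0.15
    effect_strength: float = 1.0
    gc: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "n_sites",
                     "n_tissues"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.conserved_fraction < 1.0:
            raise ValueError("conserved_fraction must lie in (0, 1)")
        if not 0.0 <= self.effect_strength <= 1.0:
            raise ValueError("effect_strength must lie in [0, 1]")


@dataclass
class SynthBundle:
    """Paths of a generated dataset plus the planted ground truth."""

    genome_fa: Path
    gtf: Path
    sites_bed: Path
    profiles_tsv: Path
    tracks_config: Path
    truth: dict[str, str]  # site_id -> planted class
    config: SynthConfig


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_genome(config: SynthConfig, path) -> dict[str, str]:
    """Write an i.i.d.-base FASTA at the configured GC; returns seqs."""
    if config.chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    rng = _rng(config, 0)
    p = [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    bases = np.array(list("ACGT"))
    seqs = {}
    with open(path, "w") as fh:
        for c in range(1, config.n_chroms + 1):
            name = f"chr{c}"
            seq = "".join(rng.choice(bases, size=config.chrom_length, p=p))
            seqs[name] = seq
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return seqs


def generate_annotation(genome: dict[str, str], config: SynthConfig, path) -> None:
    """Write a GTF of non-overlapping genes with 1-10 exons each.

    Exon lengths mix short (80-400) and long (401-1000) draws so both
    sides of the 400 bp threshold are populated; most genes carry a CDS
    with flanking UTRs; a fraction gains a shorter second isoform.
    """
    rng = _rng(config, 1)
    chroms = sorted(genome)
    cursors = {c: 1500 for c in chroms}
    lines: list[str] = []
    gene_no = 0
    attempts = 0
    while gene_no < config.n_genes:
        attempts += 1
        if attempts > config.n_genes * 3:
            raise ValueError(
                "genes cannot fit on the configured chromosomes; "
                "increase chrom_length or reduce n_genes"
            )
        chrom = chroms[gene_no % len(chroms)]
        n_exons = int(rng.integers(1, 11))
        exon_lens = [
            int(rng.integers(401, 1001)) if rng.random() < 0.35
            else int(rng.integers(80, 401))
            for _ in range(n_exons)
        ]
        intron_lens = [int(rng.integers(80, 1201)) for _ in range(n_exons - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        start = cursors[chrom]
        if start + span + 1500 > len(genome[chrom]):
            cursors[chrom] = len(genome[chrom])  # chromosome full
            if all(v >= len(genome[c]) for c, v in cursors.items()):
                raise ValueError(
                    "genes cannot fit on the configured chromosomes; "
                    "increase chrom_length or reduce n_genes"
                )
            continue
        cursors[chrom] = start + span + int(rng.integers(500, 1500))

        gene_no += 1
        gid = f"G{gene_no:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el + (intron_lens[i] if i < n_exons - 1 else 0)
        exonic_len = sum(b - a for a, b in exons)

        coding = rng.random() < 0.9 and exonic_len >= 300
        biotype = "protein_coding" if coding else "lncRNA"
        tid = f"{gid}.t1"

        def fmt(feature, a, b, tx=None, extra=""):
            attrs = f'gene_id "{gid}"; gene_biotype "{biotype}";'
            if tx:
                attrs += f' transcript_id "{tx}";'
            return (
                f"{chrom}\tsynth\t{feature}\t{a + 1}\t{b}\t.\t{strand}\t.\t{attrs}"
            )

        lines.append(fmt("gene", start, start + span))
        lines.append(fmt("transcript", start, start + span, tx=tid))
        for a, b in exons:
            lines.append(fmt("exon", a, b, tx=tid))
        if coding:
            margin = exonic_len // 4
            utr5 = int(rng.integers(30, max(31, min(300, margin))))
            utr3 = int(rng.integers(30, max(31, min(300, margin))))
            model = TranscriptModel(
                gene_id=gid, transcript_id=tid, chrom=chrom, strand=strand,
                exons=list(exons),
            )
            c0, c1 = utr5, exonic_len - utr3  # transcript coords, half-open
            # project the CDS back onto exons
            for a, b in exons:
                ta = model.genomic_to_transcript(a)
                tb = model.genomic_to_transcript(b - 1)
                lo_t, hi_t = min(ta, tb), max(ta, tb)
                s, e = max(lo_t, c0), min(hi_t, c1 - 1)
                if s <= e:
                    g1 = model.transcript_to_genomic(s)
                    g2 = model.transcript_to_genomic(e)
                    lines.append(fmt("CDS", min(g1, g2), max(g1, g2) + 1, tx=tid))

        if n_exons >= 2 and rng.random() < 0.4:
            tid2 = f"{gid}.t2"
            sub = exons[:-1] if strand == "+" else exons[1:]
            lines.append(fmt("transcript", sub[0][0], sub[-1][1], tx=tid2))
            for a, b in sub:
                lines.append(fmt("exon", a, b, tx=tid2))

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _drach_candidates(models: dict[str, TranscriptModel], genome):
    """All DRACH-context adenosines on mature transcripts, annotated
    with the placement properties the planted signal uses."""
    candidates = []
    seen = set()
    for gid in sorted(models):
        model = models[gid]
        mature = model.mature_sequence(genome)
        cds_span = model.cds_span_t
        for match in DRACH.finditer(mature):
            t = match.start() + 2
            pos = model.transcript_to_genomic(t)
            key = (model.chrom, pos, model.strand)
            if key in seen:
                continue
            seen.add(key)
            exon_idx = model.exon_index_at(pos)
            a, b = model.exons_in_transcript_order()[exon_idx]
            long_exon = (b - a) > 400
            near_stop = (
                cds_span is not None and abs(t - (cds_span[1] - 1)) <= 100
            )
            candidates.append(
                (model.chrom, pos, model.strand, long_exon, near_stop)
            )
    return candidates


def generate_sites_and_profiles(
    models: dict[str, TranscriptModel],
    genome,
    config: SynthConfig,
    bed_path,
    tsv_path,
) -> dict[str, str]:
    """Place sites on DRACH adenosines and write BED6 + tissue TSV.

    Returns the planted truth: site_id -> conserved | nonconserved |
    excluded.
    """
    rng = _rng(config, 2)
    candidates = _drach_candidates(models, genome)
    if len(candidates) < config.n_sites:
        raise ValueError(
            f"only {len(candidates)} DRACH adenosines available for "
            f"{config.n_sites} sites; generate a larger genome"
        )
    e = config.effect_strength
    n_cons = round(config.n_sites * config.conserved_fraction)
    n_excl = round(config.n_sites * config.excluded_fraction)
    n_non = config.n_sites - n_cons - n_excl

    weights = np.array([
        1.0 + e * (4.0 * long + 4.0 * stop)
        for _, _, _, long, stop in candidates
    ])
    idx_cons = rng.choice(
        len(candidates), size=n_cons, replace=False, p=weights / weights.sum()
    )
    rest = np.setdiff1d(np.arange(len(candidates)), idx_cons)
    idx_other = rng.choice(rest, size=n_non + n_excl, replace=False)
    idx_non, idx_excl = idx_other[:n_non], idx_other[n_non:]

    chosen = []
    for cls, idxs in (("conserved", idx_cons), ("nonconserved", idx_non),
                      ("excluded", idx_excl)):
        for i in idxs:
            chrom, pos, strand, _, _ = candidates[i]
            chosen.append((chrom, pos, strand, cls))
    chosen.sort(key=lambda r: (r[0], r[1], r[2]))

    truth: dict[str, str] = {}
    sites, counts = [], {}
    for n, (chrom, pos, strand, cls) in enumerate(chosen, start=1):
        sid = f"s{n:06d}"
        truth[sid] = cls
        if cls == "conserved":
            count = config.n_tissues
        elif cls == "nonconserved":
            count = int(rng.integers(1, 7))
        else:
            count = int(rng.integers(7, config.n_tissues))
        counts[sid] = count
        sites.append(GenomicSite(site_id=sid, chrom=chrom, position=pos,
                                 strand=strand, tissue_count=count,
                                 tissue_total=config.n_tissues))
    write_sites_bed(sites, bed_path)

    with open(tsv_path, "w") as fh:
        header = ["site_id"] + [f"t{j:02d}" for j in range(1, config.n_tissues + 1)]
        fh.write("\t".join(header) + "\n")
        for site in sites:
            on = rng.choice(config.n_tissues, size=counts[site.site_id],
                            replace=False)
            row = np.zeros(config.n_tissues, dtype=int)
            row[on] = 1
            fh.write(site.site_id + "\t" + "\t".join(map(str, row)) + "\n")
    return truth


def generate_tracks(
    sites_with_class, genome: dict[str, str], config: SynthConfig, outdir
) -> Path:
    """Write the conservation bedGraph and 8+3 interval BEDs.

    Returns the path of a YAML tracks config binding them to slots.
    ``sites_with_class`` is an iterable of (chrom, pos, class) tuples.
    """
    outdir = Path(outdir)
    rng = _rng(config, 3)
    e = config.effect_strength
    sites_with_class = list(sites_with_class)

    # conservation: background segments plus per-site neighborhoods
    signal = {c: np.zeros(len(s)) for c, s in genome.items()}
    for chrom, arr in sorted(signal.items()):
        n_bg = max(1, len(arr) // 1500)
        starts = rng.integers(0, max(1, len(arr) - 60), size=n_bg)
        for s in starts:
            arr[s:s + 50] = rng.uniform(0.0, 0.3)
    for chrom, pos, cls in sites_with_class:
        mean = 0.30 + (0.35 * e if cls == "conserved" else 0.0)
        value = float(np.clip(rng.normal(mean, 0.15), 0.0, 1.0))
        arr = signal[chrom]
        arr[max(0, pos - 10):pos + 11] = value
    cons_path = outdir / "conservation.bedGraph"
    with open(cons_path, "w") as fh:
        for chrom in sorted(signal):
            arr = signal[chrom]
            boundaries = np.r_[0, np.nonzero(np.diff(arr))[0] + 1, len(arr)]
            for a, b in zip(boundaries[:-1], boundaries[1:]):
                if arr[a] != 0.0:
                    fh.write(f"{chrom}\t{a}\t{b}\t{arr[a]:.4f}\n")

    def interval_bed(path, p_cons, p_other):
        with open(path, "w") as fh:
            rows = []
            for chrom, pos, cls in sites_with_class:
                p = p_cons if cls == "conserved" else p_other
                if rng.random() < p:
                    lo = pos - int(rng.integers(5, 31))
                    hi = pos + int(rng.integers(5, 31))
                    rows.append((chrom, max(0, lo), hi))
            # decoy intervals away from any class signal
            for chrom, seq in sorted(genome.items()):
                for s in rng.integers(0, len(seq) - 100,
                                      size=max(1, len(seq) // 20000)):
                    rows.append((chrom, int(s), int(s) + int(rng.integers(20, 80))))
            for chrom, a, b in sorted(rows):
                fh.write(f"{chrom}\t{a}\t{b}\n")

    reg_paths, omics_paths = [], []
    for i in range(8):
        f_i = 1.0 - 0.08 * i
        path = outdir / f"regulator_{i + 1}.bed"
        interval_bed(path, 0.2 + 0.5 * e * f_i, 0.2)
        reg_paths.append(str(path))
    for i in range(3):
        path = outdir / f"omics_{i + 1}.bed"
        interval_bed(path, 0.15 + 0.3 * e, 0.15)
        omics_paths.append(str(path))

    config_path = outdir / "tracks.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(
            {"conservation": str(cons_path), "regulators": reg_paths,
             "omics": omics_paths},
            fh,
        )
    return config_path


def generate_bundle(config: SynthConfig, outdir) -> SynthBundle:
    """Generate the complete synthetic dataset into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_fa = outdir / "genome.fa"
    gtf = outdir / "annotation.gtf"
    sites_bed = outdir / "sites.bed"
    profiles_tsv = outdir / "profiles.tsv"

    genome = generate_genome(config, genome_fa)
    generate_annotation(genome, config, gtf)
    models = build_transcript_models(gtf)
    truth = generate_sites_and_profiles(models, genome, config, sites_bed,
                                        profiles_tsv)

    from .sites import read_sites_bed

    sites = read_sites_bed(sites_bed, tissue_total=config.n_tissues)
    swc = [(s.chrom, s.position, truth[s.site_id]) for s in sites]
    tracks_config = generate_tracks(swc, genome, config, outdir)

    with open(outdir / "synth_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2)
    return SynthBundle(
        genome_fa=genome_fa, gtf=gtf, sites_bed=sites_bed,
        profiles_tsv=profiles_tsv, tracks_config=tracks_config,
        truth=truth, config=config,
    )
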