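"""Candidate m6A sites, tissue-occurrence profiles and dataset assembly.

A candidate site is a single adenosine at base resolution with a strand
and a tissue-occurrence count out of the profiled tissue panel
(23 human tissues in the reference setting).  Sites are labeled by
cross-tissue conservation:

* **conserved** (dataset P): detected in every profiled tissue;
* **non-conserved / tissue-specific** (dataset N): detected in at least
  one but fewer than 30% of tissues (strict: exactly 30% is excluded);
* **excluded**: detected in no tissue, or in the ambiguous 30-100% band.

To use every positive while keeping classes balanced, dataset N is split
into k (default 10) disjoint near-equal sub-datasets; each is paired 1:1
with dataset P to train one ensemble member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split as _sk_split

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicSite",
    "LabeledPartition",
    "SplitPlan",
    "label_by_conservation",
    "split_negatives",
    "make_balanced_pairs",
    "train_test_split",
    "exclude_genes",
    "read_sites_bed",
    "write_sites_bed",
    "read_tissue_profiles",
    "write_partition_tsv",
    "read_partition_tsv",
]


@dataclass(frozen=True)
class GenomicSite:
    """One candidate adenosine at base resolution.

    ``position`` is the 0-based genomic coordinate of the modified base;
    ``tissue_count`` is the number of tissues the site was detected in,
    out of ``tissue_total`` profiled tissues.
    """

    site_id: str
    chrom: str
    position: int
    strand: str
    tissue_count: int = 0
    tissue_total: int = 23

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"site {self.site_id}: strand must be '+' or '-'")
        if self.position < 0:
            raise ValueError(f"site {self.site_id}: negative position")
        if self.tissue_total <= 0:
            raise ValueError(f"site {self.site_id}: tissue_total must be positive")
        if not 0 <= self.tissue_count <= self.tissue_total:
            raise ValueError(
                f"site {self.site_id}: tissue_count {self.tissue_count} outside "
                f"[0, {self.tissue_total}]"
            )


@dataclass
class LabeledPartition:
    """Disjoint conserved (P) / non-conserved (N) / excluded site-id sets."""

    conserved: set[str] = field(default_factory=set)
    nonconserved: set[str] = field(default_factory=set)
    excluded: set[str] = field(default_factory=set)

    def label_of(self, site_id: str) -> str:
        if site_id in self.conserved:
            return "conserved"
        if site_id in self.nonconserved:
            return "nonconserved"
        if site_id in self.excluded:
            return "excluded"
        raise KeyError(site_id)


@dataclass
class SplitPlan:
    """Reproducible train/test split of site ids."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    train_fraction: float


def label_by_conservation(
    profiles: Mapping[str, int],
    tissue_total: int,
    specific_fraction: float = 0.30,
) -> LabeledPartition:
    """Partition sites into conserved / non-conserved / excluded.

    A site is conserved iff it occurs in all ``tissue_total`` tissues,
    non-conserved iff it occurs in at least one tissue but in strictly
    less than ``specific_fraction`` of them, and excluded otherwise
    (zero occurrences, or the ambiguous band up to but not including
    full conservation).  The zero-count check precedes the fraction
    rule.
    """
    if tissue_total < 1:
        raise ValueError("tissue_total must be >= 1")
    if not profiles:
        raise ValueError("empty tissue-profile map")
    part = LabeledPartition()
    for site_id, count in profiles.items():
        if not 0 <= count <= tissue_total:
            raise ValueError(
                f"site {site_id}: tissue count {count} outside [0, {tissue_total}]"
            )
        if count == 0:
            part.excluded.add(site_id)
        elif count == tissue_total:
            part.conserved.add(site_id)
        elif count / tissue_total < specific_fraction:
            part.nonconserved.add(site_id)
        else:
            part.excluded.add(site_id)
    return part


def split_negatives(
    nonconserved_ids: Sequence[str], k: int = 10, seed: int = 0
) -> list[list[str]]:
    """Split ids into k disjoint sub-lists of near-equal size.

    Seeded shuffle followed by round-robin assignment: deterministic,
    covering, disjoint, sizes differing by at most one.
    """
    ids = list(nonconserved_ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if not ids:
        raise ValueError("cannot split an empty id list")
    if k > len(ids):
        raise ValueError(f"cannot form {k} non-empty subsets from {len(ids)} ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    return [shuffled[i::k] for i in range(k)]


def make_balanced_pairs(
    conserved_ids: Sequence[str],
    negative_subset: Sequence[str],
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """1:1 positive/negative training pair lists.

    The larger side is deterministically downsampled (seeded, without
    replacement) to the size of the smaller.
    """
    pos = list(conserved_ids)
    neg = list(negative_subset)
    if not pos or not neg:
        raise ValueError("both the positive and the negative side must be non-empty")
    m = min(len(pos), len(neg))
    rng = np.random.default_rng(seed)
    if len(pos) > m:
        pos = [pos[i] for i in sorted(rng.choice(len(pos), size=m, replace=False))]
    if len(neg) > m:
        neg = [neg[i] for i in sorted(rng.choice(len(neg), size=m, replace=False))]
    return pos, neg


def train_test_split(
    ids: Sequence[str],
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify_labels: Sequence | None = None,
) -> SplitPlan:
    """Seeded (optionally stratified) train/test split of site ids."""
    ids = list(ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 items to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    strat = None if stratify_labels is None else list(stratify_labels)
    train, test = _sk_split(
        ids, train_size=train_fraction, random_state=seed, stratify=strat
    )
    return SplitPlan(
        train_ids=list(train),
        test_ids=list(test),
        seed=seed,
        train_fraction=train_fraction,
    )


def exclude_genes(
    sites: Iterable[GenomicSite],
    site_to_gene: Mapping[str, str],
    gene_blocklist: Iterable[str],
) -> list[GenomicSite]:
    """Drop sites whose host gene is on the blocklist.

    Generic gene-exclusion filter (e.g. for housekeeping-gene
    sensitivity checks).  Sites missing from the map pass through with
    a warning; an empty blocklist is the identity.
    """
    block = set(gene_blocklist)
    kept = []
    unmapped = 0
    for site in sites:
        gene = site_to_gene.get(site.site_id)
        if gene is None:
            unmapped += 1
            kept.append(site)
        elif gene not in block:
            kept.append(site)
    if unmapped:
        logger.warning("%d sites had no gene assignment; passed through", unmapped)
    return kept


# ---------------------------------------------------------------------------
# File formats: BED6 sites, tissue-profile TSV, partition TSV


def read_sites_bed(path, tissue_total: int = 23) -> list[GenomicSite]:
    """Read single-base sites from BED6 (0-based half-open, width-1)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    if (df["end"] - df["start"] != 1).any():
        bad = df.loc[df["end"] - df["start"] != 1].iloc[0]
        raise ValueError(
            f"site {bad['name']}: BED interval must be exactly one base wide"
        )
    return [
        GenomicSite(
            site_id=row.name_, chrom=row.chrom, position=int(row.start),
            strand=row.strand, tissue_total=tissue_total,
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def write_sites_bed(sites: Iterable[GenomicSite], path) -> None:
    rows = [
        (s.chrom, s.position, s.position + 1, s.site_id, 0, s.strand)
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_tissue_profiles(path) -> tuple[dict[str, int], int]:
    """Read a tissue-profile TSV: site_id column then binary indicators.

    Returns ``(site_id -> occurrence count, number of tissue columns)``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("tissue-profile TSV needs a site_id column plus indicators")
    site_ids = df.iloc[:, 0]
    indicators = df.iloc[:, 1:]
    if not indicators.isin((0, 1)).all().all():
        raise ValueError("tissue indicator columns must be binary")
    counts = indicators.sum(axis=1).astype(int)
    return dict(zip(site_ids, counts)), indicators.shape[1]


def write_partition_tsv(partition: LabeledPartition, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("site_id\tlabel\n")
        for label in ("conserved", "nonconserved", "excluded"):
            for site_id in sorted(getattr(partition, label)):
                fh.write(f"{site_id}\t{label}\n")


def read_partition_tsv(path) -> LabeledPartition:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    part = LabeledPartition()
    for row in df.itertuples(index=False):
        getattr(part, row.label).add(row.site_id)
    return part
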