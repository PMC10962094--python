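"""End-to-end orchestration: files in, labeled feature matrices out.

The protocol implemented here: read sites + tissue profiles, label by
cross-tissue conservation, stratified 80/20 train/test split, featurize
every usable site (sequence block + 54 genomic slots), with the
nearest-conserved-site features computed against the *training* split's
conserved sites only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass

import pandas as pd
from pyfaidx import Fasta

from .features import featurize
from .sites import (
    GenomicSite,
    LabeledPartition,
    SplitPlan,
    label_by_conservation,
    read_sites_bed,
    read_tissue_profiles,
    train_test_split,
)
from .tracks import TrackSet
from .transcripts import build_transcript_models

logger = logging.getLogger(__name__)

__all__ = ["FeatureConfig", "PreparedDataset", "open_genome", "prepare_dataset",
           "config_hash"]


@dataclass(frozen=True)
class FeatureConfig:
    """Featurization settings that must match between train and predict."""

    flank: int = 20
    sequence_strategy: str = "ncp_eiip"
    include_genomic: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PreparedDataset:
    """Labeled, split and featurized dataset ready for the ensemble."""

    partition: LabeledPartition
    split: SplitPlan
    features: pd.DataFrame  # all usable sites (conserved + nonconserved)
    labels: pd.Series  # 1 = conserved, aligned with features.index
    conserved_train_sites: list[GenomicSite]
    feature_config: FeatureConfig

    def _select(self, ids, label):
        ids = [i for i in ids if self.labels.get(i) == label]
        return self.features.loc[ids]

    @property
    def pos_train(self) -> pd.DataFrame:
        return self._select(self.split.train_ids, 1)

    @property
    def neg_train(self) -> pd.DataFrame:
        return self._select(self.split.train_ids, 0)

    @property
    def pos_test(self) -> pd.DataFrame:
        return self._select(self.split.test_ids, 1)

    @property
    def neg_test(self) -> pd.DataFrame:
        return self._select(self.split.test_ids, 0)


def open_genome(path):
    """Open a FASTA with .fai-style random access."""
    return Fasta(str(path), sequence_always_upper=True)


def config_hash(payload: dict) -> str:
    """Short stable hash used to stamp every derived artifact."""
    canonical = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def prepare_dataset(
    genome_fa,
    gtf,
    sites_bed,
    profiles_tsv,
    tracks_config=None,
    seed: int = 0,
    train_fraction: float = 0.8,
    specific_fraction: float = 0.30,
    feature_config: FeatureConfig = FeatureConfig(),
    center_check: str = "warn",
) -> PreparedDataset:
    """Run labeling, splitting and featurization on input files."""
    genome = open_genome(genome_fa)
    models = build_transcript_models(gtf)
    profiles, tissue_total = read_tissue_profiles(profiles_tsv)
    raw_sites = read_sites_bed(sites_bed, tissue_total=tissue_total)
    missing = [s.site_id for s in raw_sites if s.site_id not in profiles]
    if missing:
        raise ValueError(
            f"{len(missing)} sites have no tissue profile "
            f"(first: {missing[0]})"
        )
    partition = label_by_conservation(profiles, tissue_total,
                                      specific_fraction=specific_fraction)
    usable = [
        s for s in raw_sites
        if s.site_id in partition.conserved
        or s.site_id in partition.nonconserved
    ]
    logger.info(
        "labeled %d conserved / %d nonconserved / %d excluded sites",
        len(partition.conserved), len(partition.nonconserved),
        len(partition.excluded),
    )
    labels = pd.Series(
        {s.site_id: int(s.site_id in partition.conserved) for s in usable}
    )
    plan = train_test_split(
        [s.site_id for s in usable], train_fraction=train_fraction, seed=seed,
        stratify_labels=[labels[s.site_id] for s in usable],
    )
    train_ids = set(plan.train_ids)
    conserved_train = [
        s for s in usable
        if s.site_id in partition.conserved and s.site_id in train_ids
    ]
    tracks = (
        TrackSet.from_config(tracks_config) if tracks_config is not None
        else None
    )
    feats = featurize(
        usable, models, genome,
        tracks=tracks,
        conserved_training_sites=conserved_train,
        flank=feature_config.flank,
        sequence_strategy=feature_config.sequence_strategy,
        include_genomic=feature_config.include_genomic,
        center_check=center_check,
    )
    return PreparedDataset(
        partition=partition,
        split=plan,
        features=feats,
        labels=labels.loc[feats.index],
        conserved_train_sites=conserved_train,
        feature_config=feature_config,
    )
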