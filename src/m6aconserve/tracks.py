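"""Auxiliary genome tracks: per-base conservation and interval overlap.

Conservation (phastCons-style) scores come from a bedGraph; regulator
binding (m6A reader/writer/eraser complexes and similar) and omics
annotations (e.g. microRNA target sites) come from BED interval files.
Any track left unconfigured contributes zeros so the pipeline degrades
gracefully.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = ["ConservationTrack", "IntervalTrack", "TrackSet"]

N_REGULATOR_SLOTS = 8
N_OMICS_SLOTS = 3


class ConservationTrack:
    """Point and window-mean queries over a bedGraph signal.

    Positions without coverage score 0.
    """

    def __init__(self, starts, ends, values):
        self._starts = {c: np.asarray(v) for c, v in starts.items()}
        self._ends = {c: np.asarray(v) for c, v in ends.items()}
        self._values = {c: np.asarray(v, dtype=float) for c, v in values.items()}

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        try:
            df = pd.read_csv(
                path, sep="\t", header=None, comment="#",
                names=["chrom", "start", "end", "value"],
                dtype={"chrom": str},
            )
        except Exception as exc:
            raise ValueError(f"cannot read bedGraph {path}: {exc}") from exc
        starts, ends, values = {}, {}, {}
        for chrom, grp in df.groupby("chrom", sort=True):
            grp = grp.sort_values("start")
            starts[chrom] = grp["start"].to_numpy()
            ends[chrom] = grp["end"].to_numpy()
            values[chrom] = grp["value"].to_numpy()
        return cls(starts, ends, values)

    def value_at(self, chrom: str, pos: int) -> float:
        starts = self._starts.get(chrom)
        if starts is None or starts.size == 0:
            return 0.0
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < self._ends[chrom][i]:
            return float(self._values[chrom][i])
        return 0.0

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean score over [start, end); uncovered bases count as 0."""
        if end <= start:
            raise ValueError("empty window")
        starts = self._starts.get(chrom)
        if starts is None or starts.size == 0:
            return 0.0
        ends = self._ends[chrom]
        vals = self._values[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        total = 0.0
        for i in range(lo, hi):
            overlap = min(end, ends[i]) - max(start, starts[i])
            if overlap > 0:
                total += overlap * vals[i]
        return total / (end - start)


class IntervalTrack:
    """Point-overlap queries against a BED interval set (strand-agnostic)."""

    def __init__(self, trees: dict[str, IntervalTree], name: str = ""):
        self._trees = trees
        self.name = name

    @classmethod
    def from_bed(cls, path, name: str | None = None) -> "IntervalTrack":
        try:
            df = pd.read_csv(
                path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                names=["chrom", "start", "end"], dtype={"chrom": str},
            )
        except Exception as exc:
            raise ValueError(f"cannot read BED {path}: {exc}") from exc
        trees: dict[str, IntervalTree] = {}
        for chrom, grp in df.groupby("chrom"):
            tree = IntervalTree()
            for s, e in zip(grp["start"], grp["end"]):
                if e > s:
                    tree.addi(int(s), int(e))
            trees[chrom] = tree
        return cls(trees, name=name or Path(path).stem)

    def overlaps(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos))


@dataclass
class TrackSet:
    """Configured bundle of tracks bound to feature slots.

    Up to 8 regulator interval tracks (slots 36-43) and 3 omics
    interval tracks (slots 52-54); one conservation signal (32-33).
    """

    conservation: ConservationTrack | None = None
    regulators: list[IntervalTrack] = field(default_factory=list)
    omics: list[IntervalTrack] = field(default_factory=list)
    _warned: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.regulators) > N_REGULATOR_SLOTS:
            raise ValueError(f"at most {N_REGULATOR_SLOTS} regulator tracks")
        if len(self.omics) > N_OMICS_SLOTS:
            raise ValueError(f"at most {N_OMICS_SLOTS} omics tracks")

    @classmethod
    def from_config(cls, config) -> "TrackSet":
        """Build from a dict or a YAML file path with keys
        ``conservation``, ``regulators``, ``omics``."""
        if not isinstance(config, dict):
            with open(config) as fh:
                config = yaml.safe_load(fh) or {}
        cons = config.get("conservation")
        return cls(
            conservation=(
                ConservationTrack.from_bedgraph(cons) if cons else None
            ),
            regulators=[
                IntervalTrack.from_bed(p) for p in config.get("regulators", [])
            ],
            omics=[IntervalTrack.from_bed(p) for p in config.get("omics", [])],
        )

    def warn_unbound_once(self) -> None:
        if self._warned:
            return
        missing = []
        if self.conservation is None:
            missing.append("conservation")
        if len(self.regulators) < N_REGULATOR_SLOTS:
            missing.append(
                f"{N_REGULATOR_SLOTS - len(self.regulators)} regulator slots"
            )
        if len(self.omics) < N_OMICS_SLOTS:
            missing.append(f"{N_OMICS_SLOTS - len(self.omics)} omics slots")
        if missing:
            logger.warning(
                "unbound track slots default to 0: %s", ", ".join(missing)
            )
        self._warned = True
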