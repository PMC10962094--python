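"""Strand-aware sequence windows and numeric sequence encodings.

A window of odd length ``2*flank + 1`` centered on the candidate
adenosine is lifted from the genome (reverse-complemented on the minus
strand, T converted to U, edges padded with N) and encoded by:

* **NCP** — nucleotide chemical properties, three binary indicators per
  base for ring count, functional group and hydrogen-bond strength:
  A=(1,1,1), C=(0,1,0), G=(1,0,0), U=(0,0,1);
* **EIIP** — electron-ion interaction pseudopotential, one scalar per
  base: A 0.1260, G 0.0806, C 0.1340, U 0.1335;
* **ND** — nucleotide density, the cumulative prefix frequency of the
  base observed at each position;
* **PseKNC** — pseudo K-tuple nucleotide composition: normalized k-mer
  frequencies followed by ``lam`` sequence-order correlation factors.

N (absent information, e.g. chromosome-edge padding) encodes to zeros.
All encoders are pure functions of the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceWindow",
    "extract_window",
    "encode_ncp",
    "encode_eiip",
    "encode_nd",
    "encode_pseknc",
    "encode_sequence_block",
    "SEQUENCE_STRATEGIES",
]

NCP_TABLE = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
    "U": (0, 0, 1),
    "N": (0, 0, 0),
}

EIIP_TABLE = {"A": 0.1260, "G": 0.0806, "C": 0.1340, "U": 0.1335, "N": 0.0}

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceWindow:
    """Odd-length RNA window centered on the candidate adenosine."""

    site_id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) % 2 == 0:
            raise ValueError(f"window for {self.site_id} must have odd length")
        bad = set(self.bases) - set("ACGUN")
        if bad:
            raise ValueError(
                f"window for {self.site_id} contains invalid characters {sorted(bad)}"
            )

    @property
    def center_index(self) -> int:
        return len(self.bases) // 2

    @property
    def center_base(self) -> str:
        return self.bases[self.center_index]


def extract_window(genome, site, flank: int = 20, center_check: str = "strict") -> SequenceWindow:
    """Lift the RNA window around a site from a genome.

    ``genome`` is any mapping of chromosome name to an indexable
    sequence (a ``pyfaidx.Fasta`` or a plain dict of strings).  On the
    minus strand the slice is reverse-complemented so the window reads
    5'->3' on the transcribed strand.  Positions outside the chromosome
    pad with N.  ``center_check`` is ``"strict"`` (error when the center
    base is not A), ``"warn"`` or ``"off"``.
    """
    if site.chrom not in genome:
        raise KeyError(f"chromosome {site.chrom!r} not present in the genome")
    chrom_seq = genome[site.chrom]
    chrom_len = len(chrom_seq)
    if not 0 <= site.position < chrom_len:
        raise ValueError(
            f"site {site.site_id}: position {site.position} outside "
            f"{site.chrom} (length {chrom_len})"
        )
    lo = site.position - flank
    hi = site.position + flank + 1
    seq = str(chrom_seq[max(lo, 0):min(hi, chrom_len)]).upper()
    seq = "N" * max(0, -lo) + seq + "N" * max(0, hi - chrom_len)
    if site.strand == "-":
        seq = reverse_complement(seq)
    seq = seq.replace("T", "U")
    window = SequenceWindow(site_id=site.site_id, bases=seq)
    if window.center_base != "A" and center_check != "off":
        msg = (
            f"site {site.site_id}: center base is {window.center_base!r}, "
            "expected A"
        )
        if center_check == "strict":
            raise ValueError(msg)
        logger.warning(msg)
    return window


def _lookup(window: SequenceWindow, table: dict):
    try:
        return [table[b] for b in window.bases]
    except KeyError as exc:  # pragma: no cover - guarded by SequenceWindow
        raise ValueError(f"character {exc} outside the RNA alphabet") from exc


def encode_ncp(window: SequenceWindow) -> np.ndarray:
    """Per-position chemical-property triples, flattened to length 3L."""
    return np.array(_lookup(window, NCP_TABLE), dtype=float).ravel()


def encode_eiip(window: SequenceWindow) -> np.ndarray:
    """Per-position EIIP pseudopotential values, length L."""
    return np.array(_lookup(window, EIIP_TABLE), dtype=float)


def encode_nd(window: SequenceWindow) -> np.ndarray:
    """Nucleotide density: prefix frequency of each position's base."""
    counts: dict[str, int] = {}
    out = np.empty(len(window.bases))
    for i, base in enumerate(window.bases):
        counts[base] = counts.get(base, 0) + 1
        out[i] = counts[base] / (i + 1)
    return out


def _kmers(k: int) -> list[str]:
    return ["".join(p) for p in product("ACGU", repeat=k)]


def _ncp_theta(a: str, b: str) -> float:
    """Squared property distance between two bases, averaged over the
    three NCP indicators (the correlation function's property set)."""
    pa, pb = NCP_TABLE[a], NCP_TABLE[b]
    return sum((x - y) ** 2 for x, y in zip(pa, pb)) / 3.0


def encode_pseknc(
    window: SequenceWindow, k: int = 3, lam: int = 2, weight: float = 0.5
) -> np.ndarray:
    """Pseudo K-tuple nucleotide composition, length ``4**k + lam``.

    The first ``4**k`` components are k-mer frequencies and the last
    ``lam`` are rank-j sequence-order correlation factors, jointly
    normalized so the full vector sums to one; the correlation block is
    scaled by ``weight``.  Windows containing N encode to zeros with a
    warning.
    """
    seq = window.bases
    L = len(seq)
    if lam >= L - k:
        raise ValueError(f"lam={lam} must be < window length - k = {L - k}")
    size = 4 ** k + lam
    if "N" in seq:
        logger.warning(
            "site %s: window contains N, PseKNC encodes to zeros", window.site_id
        )
        return np.zeros(size)
    kmer_index = {m: i for i, m in enumerate(_kmers(k))}
    freq = np.zeros(4 ** k)
    for i in range(L - k + 1):
        freq[kmer_index[seq[i:i + k]]] += 1
    freq /= freq.sum()
    theta = np.array([
        sum(_ncp_theta(seq[i], seq[i + j]) for i in range(L - j)) / (L - j)
        for j in range(1, lam + 1)
    ])
    denom = 1.0 + weight * theta.sum()
    return np.r_[freq / denom, weight * theta / denom]


# ---------------------------------------------------------------------------
# Sequence-block strategies (the comparison grid of encoder pairings)


def _positions(flank: int) -> list[int]:
    return list(range(-flank, flank + 1))


def _block_ncp(window, flank):
    names = [f"pos{i}_{c}" for i in _positions(flank) for c in "XYZ"]
    return encode_ncp(window), names


def _block_eiip(window, flank):
    return encode_eiip(window), [f"pos{i}_EIIP" for i in _positions(flank)]


def _block_nd(window, flank):
    return encode_nd(window), [f"pos{i}_ND" for i in _positions(flank)]


def _block_pseknc(window, flank, k=3, lam=2, weight=0.5):
    names = [f"pseknc_{m}" for m in _kmers(k)] + [
        f"pseknc_theta{j}" for j in range(1, lam + 1)
    ]
    return encode_pseknc(window, k=k, lam=lam, weight=weight), names


SEQUENCE_STRATEGIES = {
    "ncp_eiip": (_block_ncp, _block_eiip),
    "ncp_nd": (_block_ncp, _block_nd),
    "eiip_pseknc": (_block_eiip, _block_pseknc),
    "none": (),
}


def encode_sequence_block(
    window: SequenceWindow, flank: int, strategy: str = "ncp_eiip"
) -> tuple[np.ndarray, list[str]]:
    """Encode a window under a named strategy; returns (vector, names)."""
    try:
        blocks = SEQUENCE_STRATEGIES[strategy]
    except KeyError:
        raise ValueError(
            f"unknown sequence strategy {strategy!r}; "
            f"choose from {sorted(SEQUENCE_STRATEGIES)}"
        ) from None
    vecs, names = [], []
    for block in blocks:
        v, n = block(window, flank)
        vecs.append(v)
        names.extend(n)
    if not vecs:
        return np.empty(0), []
    return np.concatenate(vecs), names
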