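"""Maximum base-pairing RNA secondary structure (nested, no pseudoknots).

A deliberately simple, fully deterministic folding model used for the
two structure features: the Nussinov-style dynamic program maximizing
the number of Watson-Crick (AU, GC) plus GU-wobble pairs, with a
minimum hairpin loop of ``min_loop`` unpaired bases (default 3).
Traceback is deterministic: at each subproblem position i is paired to
the smallest admissible partner j that achieves the optimum, and is
left unpaired only when no pairing does.

A precomputed dot-bracket string (e.g. from a thermodynamic folder) can
be supplied downstream to override this model.
"""

from __future__ import annotations

__all__ = ["max_pairing_fold", "parse_dotbracket"]

_CAN_PAIR = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _CAN_PAIR


def max_pairing_fold(seq: str, min_loop: int = 3) -> str:
    """Fold ``seq`` and return the dot-bracket structure.

    N never pairs.  Runs in O(n^3); intended for short windows.
    """
    n = len(seq)
    if n == 0:
        return ""
    # dp[i][j] = max pairs in seq[i..j] inclusive
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(seq[i], seq[k]):
                    left = dp[i + 1][k - 1] if k - 1 > i else 0
                    right = dp[k + 1][j] if k + 1 <= j else 0
                    cand = left + right + 1
                    if cand > best:
                        best = cand
            dp[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = dp[i][j]
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if _can_pair(seq[i], seq[k]):
                left = dp[i + 1][k - 1] if k - 1 > i else 0
                right = dp[k + 1][j] if k + 1 <= j else 0
                if left + right + 1 == target:
                    structure[i] = "("
                    structure[k] = ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return "".join(structure)


def parse_dotbracket(structure: str) -> tuple[int, list[bool]]:
    """Return (number of pairs, per-position paired mask)."""
    depth = 0
    pairs = 0
    mask = []
    for c in structure:
        if c == "(":
            depth += 1
            pairs += 1
            mask.append(True)
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise ValueError("unbalanced dot-bracket string")
            mask.append(True)
        elif c == ".":
            mask.append(False)
        else:
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if depth != 0:
        raise ValueError("unbalanced dot-bracket string")
    return pairs, mask
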