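"""Dynamic-programming alignment primitives shared by the diff and locus modules.

Both DPs fill full score matrices row-by-row with numpy.  The horizontal
dependency (a gap extending along a row) is resolved with the prefix-scan
identity  S[i,j] = opt_{k<=j} ( v[k] + g*(j-k) ), computed via
``np.minimum.accumulate`` / ``np.maximum.accumulate``, so each row is O(m)
vector work instead of a Python inner loop.

Tie-breaking during traceback is fixed and deterministic everywhere:
diagonal (match/mismatch) is preferred over a gap, and a gap in the second
sequence (deletion from the first) is preferred over a gap in the first.
"""

from __future__ import annotations

import numpy as np

_MAX_CELLS = 200_000_000  # hard cap on DP matrix size


class AlignmentTooLargeError(RuntimeError):
    pass


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def edit_matrix(a: str, b: str) -> np.ndarray:
    """Unit-cost edit-distance matrix of shape (len(a)+1, len(b)+1)."""
    n, m = len(a), len(b)
    if (n + 1) * (m + 1) > _MAX_CELLS:
        raise AlignmentTooLargeError(f"edit DP of {n} x {m} exceeds the cell cap")
    ea, eb = _encode(a), _encode(b)
    scores = np.empty((n + 1, m + 1), dtype=np.int32)
    scores[0] = np.arange(m + 1, dtype=np.int32)
    col = np.arange(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        mismatch = (ea[i - 1] != eb).astype(np.int32)
        candidates = np.empty(m + 1, dtype=np.int32)
        candidates[0] = i
        candidates[1:] = np.minimum(
            scores[i - 1, 1:] + 1, scores[i - 1, :-1] + mismatch
        )
        scores[i] = np.minimum.accumulate(candidates - col) + col
    return scores


def edit_script(a: str, b: str) -> str:
    """Optimal edit script as a string over {M, X, D, I}.

    M: match, X: substitution, D: base of `a` absent from `b` (deletion),
    I: base of `b` absent from `a` (insertion).

    Among co-optimal tracebacks the policy is: first extend the gap opened
    by the following op (keeping indels contiguous instead of fragmenting
    them around coincidental matches), then diagonal, then deletion, then
    insertion.
    """
    scores = edit_matrix(a, b)
    ops: list[str] = []
    i, j = len(a), len(b)
    last = "M"
    while i > 0 or j > 0:
        diag_ok = False
        cost = 1
        if i > 0 and j > 0:
            cost = 0 if a[i - 1] == b[j - 1] else 1
            diag_ok = scores[i, j] == scores[i - 1, j - 1] + cost
        del_ok = i > 0 and scores[i, j] == scores[i - 1, j] + 1
        ins_ok = j > 0 and scores[i, j] == scores[i, j - 1] + 1
        if last == "D" and del_ok:
            op = "D"
        elif last == "I" and ins_ok:
            op = "I"
        elif diag_ok:
            op = "M" if cost == 0 else "X"
        elif del_ok:
            op = "D"
        else:
            op = "I"
        ops.append(op)
        last = op
        if op in ("M", "X"):
            i, j = i - 1, j - 1
        elif op == "D":
            i -= 1
        else:
            j -= 1
    return "".join(reversed(ops))


def nw_matrix(
    a_codes: np.ndarray, b_codes: np.ndarray, substitution: np.ndarray, gap: int
) -> np.ndarray:
    """Needleman-Wunsch score matrix with a linear gap penalty.

    `a_codes`/`b_codes` are integer-encoded sequences indexing into the
    `substitution` score matrix; `gap` is the (positive) per-base penalty.
    """
    n, m = len(a_codes), len(b_codes)
    if (n + 1) * (m + 1) > _MAX_CELLS:
        raise AlignmentTooLargeError(f"NW DP of {n} x {m} exceeds the cell cap")
    scores = np.empty((n + 1, m + 1), dtype=np.int32)
    col = np.arange(m + 1, dtype=np.int32)
    scores[0] = -gap * col
    for i in range(1, n + 1):
        pair_scores = substitution[a_codes[i - 1], b_codes]
        candidates = np.empty(m + 1, dtype=np.int32)
        candidates[0] = -gap * i
        candidates[1:] = np.maximum(
            scores[i - 1, 1:] - gap, scores[i - 1, :-1] + pair_scores
        )
        scores[i] = np.maximum.accumulate(candidates + gap * col) - gap * col
    return scores


def nw_traceback(
    a_codes: np.ndarray,
    b_codes: np.ndarray,
    substitution: np.ndarray,
    gap: int,
    scores: np.ndarray,
) -> list[tuple[int, int]]:
    """Aligned index pairs (i, j); -1 marks a gap in that sequence."""
    pairs: list[tuple[int, int]] = []
    i, j = len(a_codes), len(b_codes)
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            pair = substitution[a_codes[i - 1], b_codes[j - 1]]
            if scores[i, j] == scores[i - 1, j - 1] + pair:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
                continue
        if i > 0 and scores[i, j] == scores[i - 1, j] - gap:
            pairs.append((i - 1, -1))
            i -= 1
        else:
            pairs.append((-1, j - 1))
            j -= 1
    pairs.reverse()
    return pairs
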