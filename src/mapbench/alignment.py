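"""Canonical semi-global alignment for exact ground-truth accounting.

A simulated read is generated from a reference window by injecting edits, but
the *injected* edits are not the ground truth a mapper can be held to:
compensatory changes (delete a base, reinsert the same base) lower the true
edit count, and a deletion of the window's first or last base simply shortens
the region the read covers.  The canonical truth is therefore defined by a
minimal-cost global alignment of the read against its source window under
unit costs, with free end gaps on the reference side, indels shifted
maximally leftward among equal-cost placements.

The dynamic program is O(len(read) x len(window)) and JIT-compiled with
numba; a pure-Python fallback keeps the module importable without it.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


_BIG = np.int32(1 << 29)


@njit(cache=False)
def _semiglobal_kernel(read: np.ndarray, win: np.ndarray) -> tuple:
    """Fill the DP matrices and trace back one canonical optimal alignment.

    Returns (distance, j_start, j_end, n_ins, n_del, n_sub) where
    [j_start, j_end) is the 0-based window span covered by the alignment.
    Free leading/trailing window gaps: D[0, j] = 0 for all j and the answer
    is min_j D[n, j].  Alignments are ordered lexicographically by
    (total edits, substitutions): among minimal-cost alignments the one with
    the fewest substitutions (most matches) is canonical, so a cost-equal
    insertion/deletion pair is never silently recounted as substitutions.
    Ties for the end column resolve to the smallest j (leftmost end);
    traceback prefers diagonal moves, then insertions, then deletions,
    pushing interior gaps toward the read start.
    """
    n = read.shape[0]
    m = win.shape[0]
    D = np.empty((n + 1, m + 1), dtype=np.int32)  # total edits
    S = np.empty((n + 1, m + 1), dtype=np.int32)  # subs among minimal
    for j in range(m + 1):
        D[0, j] = 0
        S[0, j] = 0
    for i in range(1, n + 1):
        D[i, 0] = i
        S[i, 0] = 0
        ri = read[i - 1]
        for j in range(1, m + 1):
            mis = 0 if ri == win[j - 1] else 1
            cost = D[i - 1, j - 1] + mis
            subs = S[i - 1, j - 1] + mis
            up = D[i - 1, j] + 1
            us = S[i - 1, j]
            if up < cost or (up == cost and us < subs):
                cost = up
                subs = us
            left = D[i, j - 1] + 1
            ls = S[i, j - 1]
            if left < cost or (left == cost and ls < subs):
                cost = left
                subs = ls
            D[i, j] = cost
            S[i, j] = subs
    best = D[n, 0]
    best_s = S[n, 0]
    j_end = 0
    for j in range(1, m + 1):
        if D[n, j] < best or (D[n, j] == best and S[n, j] < best_s):
            best = D[n, j]
            best_s = S[n, j]
            j_end = j
    # traceback along (D, S)-consistent moves
    i = n
    j = j_end
    n_ins = 0
    n_del = 0
    n_sub = 0
    while i > 0:
        if j > 0:
            mis = 0 if read[i - 1] == win[j - 1] else 1
            if D[i, j] == D[i - 1, j - 1] + mis and S[i, j] == S[i - 1, j - 1] + mis:
                n_sub += mis
                i -= 1
                j -= 1
                continue
        if D[i, j] == D[i - 1, j] + 1 and S[i, j] == S[i - 1, j]:
            n_ins += 1
            i -= 1
            continue
        n_del += 1
        j -= 1
    return best, j, j_end, n_ins, n_del, n_sub


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def encode_bases(seq: str) -> np.ndarray:
    """Encode an ACGTN string as a uint8 code array (A=0..T=3, N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        bad = sorted(set(seq) - set("ACGTNacgtn"))
        raise ValueError(f"sequence contains invalid characters {bad}")
    return codes


def canonical_alignment(read: str, window: str) -> tuple[int, int, int, int, int]:
    """Align ``read`` against ``window`` (free end gaps on the window side).

    Returns ``(j_start, j_end, n_ins, n_del, n_sub)`` with ``[j_start, j_end)``
    the 0-based half-open window span covered and canonical per-base edit
    counts.  ``n_ins + n_del + n_sub`` equals the semi-global edit distance.
    """
    if not read:
        raise ValueError("read is empty")
    if not window:
        raise ValueError("window is empty")
    if read == window:  # fast path: the overwhelmingly common perfect case
        return 0, len(window), 0, 0, 0
    _, j_start, j_end, n_ins, n_del, n_sub = _semiglobal_kernel(
        encode_bases(read), encode_bases(window)
    )
    return j_start, j_end, n_ins, n_del, n_sub
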