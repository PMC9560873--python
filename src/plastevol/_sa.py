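"""Suffix-array utilities shared by the repeat finder and the IR detector.

Exact matching only: the sequence is encoded over {A,C,G,T} plus one unique
symbol per ambiguous (N) base and per separator, so no match can span an N
or a sequence boundary.
"""

from __future__ import annotations

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    try:
        return "".join(_COMP[b] for b in reversed(seq))
    except KeyError as exc:  # pragma: no cover
        raise ValueError(f"non-ACGTN character {exc} in sequence") from exc


def encode(seq: str, start_symbol: int = 4) -> tuple[np.ndarray, int]:
    """Integer-encode a DNA string; each N gets a fresh unique symbol.

    Returns (codes, next_free_symbol).
    """
    out = np.empty(len(seq), dtype=np.int64)
    nxt = start_symbol
    for i, b in enumerate(seq):
        c = _CODE.get(b)
        if c is None:
            if b != "N":
                raise ValueError(f"non-ACGTN character {b!r} at position {i}")
            out[i] = nxt
            nxt += 1
        else:
            out[i] = c
    return out, nxt


def suffix_array(s: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), vectorized)."""
    n = len(s)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    _, rank = np.unique(s, return_inverse=True)
    rank = rank.astype(np.int64)
    idx = np.arange(n, dtype=np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        new = np.empty(n, dtype=np.int64)
        diff = np.empty(n, dtype=bool)
        diff[0] = True
        diff[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new[order] = np.cumsum(diff) - 1
        rank = new
        if rank[order[-1]] == n - 1:
            return order
        k *= 2
        if k >= n:  # pragma: no cover - loop exits via full rank first
            return order


def lcp_array(s: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai LCP: lcp[i] = longest common prefix of suffixes sa[i-1], sa[i]."""
    n = len(s)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    sl = s.tolist()
    sal = sa.tolist()
    rl = rank.tolist()
    for i in range(n):
        r = rl[i]
        if r > 0:
            j = sal[r - 1]
            while i + h < n and j + h < n and sl[i + h] == sl[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


def maximal_pairs(s: np.ndarray, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal exact matching pairs (i, j, length), i < j, length >= min_len.

    A pair is maximal when it cannot be extended left (preceding symbols
    differ or a boundary is hit); right-maximality is implicit because the
    returned length is the exact longest common extension.
    """
    sa = suffix_array(s)
    lcp = lcp_array(s, sa)
    n = len(s)
    pairs: list[tuple[int, int, int]] = []
    # blocks of consecutive SA entries with adjacent LCP >= min_len
    start = 0
    k = 1
    while k <= n:
        if k == n or lcp[k] < min_len:
            if k - start >= 2:
                block = sa[start:k]
                # pairwise LCE = min of adjacent lcp values between the two rows
                for a in range(start, k):
                    m = n
                    for b in range(a + 1, k):
                        m = min(m, int(lcp[b]))
                        if m < min_len:
                            break
                        i, j = int(sa[a]), int(sa[b])
                        if i > j:
                            i, j = j, i
                        if i == 0 or j == 0 or s[i - 1] != s[j - 1]:
                            pairs.append((i, j, m))
            start = k
        k += 1
    return pairs
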