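"""Signed gene-order permutations and exact minimum-inversion (reversal) distance.

Plastome rearrangement is dominated by inversions.  Given the order and
orientation of shared single-copy loci in a target genome relative to a
reference, the minimum number of signed reversals needed to transform one
order into the other (the Hannenhalli-Pevzner reversal distance) is the
standard rearrangement distance reported for plastomes.

The exact distance is computed from the breakpoint graph::

    d = (n + 1) - c + h + f

where ``c`` is the number of alternating cycles, ``h`` the number of hurdles
(unoriented components that no other unoriented component would resolve for
free) and ``f`` is 1 for the rare "fortress" configuration in which every
hurdle is a super-hurdle and the hurdle count is odd.

A breadth-first / iterative-deepening oracle over the reversal graph is
provided for validation at small ``n``; it depends only on the elementary
fact that one reversal changes the cycle count by at most one, never on the
hurdle/fortress theory it is used to check.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SignedPermutation",
    "ReversalScenario",
    "InversionInterval",
    "hp_distance",
    "reversal_distance",
    "oracle_distance",
    "to_signed_permutation",
    "normalize_ssc",
    "map_reversals_to_intervals",
    "read_grimm",
    "write_grimm",
]


@dataclass(frozen=True)
class SignedPermutation:
    """A signed permutation of {1..n}; sign encodes strand/orientation."""

    elements: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(int(x) for x in self.elements))
        mags = sorted(abs(x) for x in self.elements)
        n = len(self.elements)
        if mags != list(range(1, n + 1)):
            raise ValueError(
                f"elements must be a signing of 1..{n}, got {self.elements}"
            )

    @property
    def n(self) -> int:
        return len(self.elements)

    @classmethod
    def identity(cls, n: int) -> "SignedPermutation":
        return cls(tuple(range(1, n + 1)))

    def is_identity(self) -> bool:
        return self.elements == tuple(range(1, self.n + 1))

    def reverse(self, i: int, j: int) -> "SignedPermutation":
        """Apply the signed reversal of the segment at positions i..j (0-based, inclusive)."""
        if not (0 <= i <= j < self.n):
            raise IndexError(f"reversal ({i},{j}) out of range for n={self.n}")
        e = self.elements
        mid = tuple(-x for x in reversed(e[i : j + 1]))
        return SignedPermutation(e[:i] + mid + e[j + 1 :])

    def __iter__(self):
        return iter(self.elements)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class ReversalScenario:
    """An ordered list of reversal steps (position intervals, 0-based inclusive)."""

    steps: tuple[tuple[int, int], ...] = ()

    def __len__(self) -> int:
        return len(self.steps)

    def apply(self, p: SignedPermutation) -> SignedPermutation:
        for i, j in self.steps:
            p = p.reverse(i, j)
        return p


@dataclass(frozen=True)
class InversionInterval:
    """A genomic inversion in flanking-breakpoint convention: length = end - start."""

    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("end_bp must exceed start_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


# ---------------------------------------------------------------------------
# Breakpoint graph
# ---------------------------------------------------------------------------


def _extended(p: SignedPermutation) -> list[int]:
    """Unsigned extension: +x -> (2x-1, 2x), -x -> (2x, 2x-1), framed by 0 and 2n+1."""
    u = [0]
    for x in p.elements:
        a = abs(x)
        if x > 0:
            u.extend((2 * a - 1, 2 * a))
        else:
            u.extend((2 * a, 2 * a - 1))
    u.append(2 * p.n + 1)
    return u


def _graph(p: SignedPermutation):
    """Return (cycles, gray_edges) of the breakpoint graph.

    gray edge i (i = 0..n) joins values 2i and 2i+1; it is returned as
    (lo_pos, hi_pos, oriented, cycle_id).
    """
    u = _extended(p)
    n = p.n
    m = 2 * n + 2
    pos = [0] * m
    for idx, v in enumerate(u):
        pos[v] = idx

    # black partner of value at even position 2i is the value at 2i+1 and vice versa
    black = [0] * m
    for i in range(n + 1):
        a, b = u[2 * i], u[2 * i + 1]
        black[a] = b
        black[b] = a
    gray = [0] * m
    for i in range(n + 1):
        gray[2 * i] = 2 * i + 1
        gray[2 * i + 1] = 2 * i

    cycle_id = [-1] * m
    ncyc = 0
    for start in range(m):
        if cycle_id[start] >= 0:
            continue
        v = start
        use_black = True
        while cycle_id[v] < 0:
            cycle_id[v] = ncyc
            v = black[v] if use_black else gray[v]
            use_black = not use_black
        ncyc += 1

    edges = []
    for i in range(n + 1):
        pa, pb = pos[2 * i], pos[2 * i + 1]
        lo, hi = (pa, pb) if pa < pb else (pb, pa)
        oriented = (hi - lo) % 2 == 0
        edges.append((lo, hi, oriented, cycle_id[2 * i]))
    return ncyc, edges


class _DSU:
    def __init__(self, n: int) -> None:
        self.p = list(range(n))

    def find(self, x: int) -> int:
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[ra] = rb


def _unoriented_components(edges) -> list[tuple[int, int]]:
    """Spans (lo, hi) of nontrivial unoriented components of the breakpoint graph."""
    k = len(edges)
    dsu = _DSU(k)
    by_cycle: dict[int, int] = {}
    for i, (_, _, _, cyc) in enumerate(edges):
        if cyc in by_cycle:
            dsu.union(i, by_cycle[cyc])
        else:
            by_cycle[cyc] = i
    # crossing gray edges belong to the same component
    order = sorted(range(k), key=lambda i: edges[i][0])
    active: list[int] = []
    for i in order:
        lo_i, hi_i = edges[i][0], edges[i][1]
        active = [j for j in active if edges[j][1] > lo_i]
        for j in active:
            if edges[j][0] < lo_i < edges[j][1] < hi_i:
                dsu.union(i, j)
        active.append(i)

    comp: dict[int, list[int]] = {}
    for i in range(k):
        comp.setdefault(dsu.find(i), []).append(i)
    spans = []
    for members in comp.values():
        lo = min(edges[i][0] for i in members)
        hi = max(edges[i][1] for i in members)
        if hi - lo <= 1:  # single adjacency, trivial
            continue
        if any(edges[i][2] for i in members):  # oriented component
            continue
        spans.append((lo, hi))
    return spans


def _hurdle_spans(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Hurdles among unoriented-component spans (nested or disjoint intervals).

    Minimal components are hurdles; additionally the maximum component is a
    hurdle when it contains every other unoriented component.
    """
    hurdles = []
    for s in spans:
        if not any(t != s and s[0] <= t[0] and t[1] <= s[1] for t in spans):
            hurdles.append(s)  # minimal
    for s in spans:
        if s in hurdles:
            continue
        if all(t == s or (s[0] <= t[0] and t[1] <= s[1]) for t in spans):
            hurdles.append(s)  # greatest, containing all others
            break
    return hurdles


def _hurdles_and_fortress(spans: Sequence[tuple[int, int]]) -> tuple[int, int]:
    hurdles = _hurdle_spans(spans)
    h = len(hurdles)
    if h == 0 or h % 2 == 0:
        return h, 0
    # fortress iff every hurdle is a super-hurdle: deleting it creates a new hurdle
    for s in hurdles:
        rest = [t for t in spans if t != s]
        new_hurdles = _hurdle_spans(rest)
        if set(new_hurdles) == set(hurdles) - {s}:
            return h, 0  # s is a simple hurdle
    return h, 1


def hp_distance(p: SignedPermutation) -> int:
    """Exact signed reversal distance via the Hannenhalli-Pevzner formula."""
    ncyc, edges = _graph(p)
    spans = _unoriented_components(edges)
    h, f = _hurdles_and_fortress(spans)
    return (p.n + 1) - ncyc + h + f


def reversal_distance(p: SignedPermutation) -> tuple[int, ReversalScenario]:
    """Minimum number of signed reversals to the identity, with one optimal scenario.

    The scenario is found greedily: the HP distance guarantees some reversal
    decreases the distance by exactly one at every step, so scanning all
    O(n^2) candidate reversals always makes progress.
    """
    d = hp_distance(p)
    steps: list[tuple[int, int]] = []
    cur = p
    remaining = d
    while remaining > 0:
        found = False
        for i in range(cur.n):
            for j in range(i, cur.n):
                q = cur.reverse(i, j)
                if hp_distance(q) == remaining - 1:
                    steps.append((i, j))
                    cur = q
                    remaining -= 1
                    found = True
                    break
            if found:
                break
        if not found:  # pragma: no cover - would indicate an hp_distance defect
            raise RuntimeError("no distance-decreasing reversal found")
    assert cur.is_identity()
    return d, ReversalScenario(tuple(steps))


# ---------------------------------------------------------------------------
# Independent search oracle
# ---------------------------------------------------------------------------

_ORACLE_MAX_N = 8


@lru_cache(maxsize=4)
def _bfs_table(n: int) -> dict[tuple[int, ...], int]:
    """Distance from the identity to every signed permutation of size n (full BFS)."""
    ident = tuple(range(1, n + 1))
    dist = {ident: 0}
    frontier = [ident]
    moves = [(i, j) for i in range(n) for j in range(i, n)]
    while frontier:
        nxt = []
        for e in frontier:
            d1 = dist[e] + 1
            for i, j in moves:
                q = e[:i] + tuple(-x for x in reversed(e[i : j + 1])) + e[j + 1 :]
                if q not in dist:
                    dist[q] = d1
                    nxt.append(q)
        frontier = nxt
    return dist


def _cycle_bound(elements: tuple[int, ...]) -> int:
    """Admissible lower bound: (n+1) - cycles; a reversal changes cycles by <= 1."""
    p = SignedPermutation(elements)
    ncyc, _ = _graph(p)
    return (p.n + 1) - ncyc


def oracle_distance(p: SignedPermutation) -> int:
    """Exact reversal distance by uninformed/graph search; validation only.

    Full breadth-first search over the reversal graph for n <= 6; for n = 7, 8
    an iterative-deepening search with the cycle-count lower bound (exact, and
    independent of hurdle/fortress theory).  Refuses n > 8.
    """
    if p.n > _ORACLE_MAX_N:
        raise ValueError(f"oracle_distance limited to n <= {_ORACLE_MAX_N}")
    if p.n <= 6:
        return _bfs_table(p.n)[p.elements]

    moves = [(i, j) for i in range(p.n) for j in range(i, p.n)]
    ident = tuple(range(1, p.n + 1))

    def dfs(elements: tuple[int, ...], g: int, bound: int) -> bool:
        lb = _cycle_bound(elements)
        if g + lb > bound:
            return False
        if elements == ident:
            return True
        for i, j in moves:
            q = elements[:i] + tuple(-x for x in reversed(elements[i : j + 1])) + elements[j + 1 :]
            if dfs(q, g + 1, bound):
                return True
        return False

    bound = _cycle_bound(p.elements)
    while not dfs(p.elements, 0, bound):
        bound += 1
    return bound


# ---------------------------------------------------------------------------
# Permutation construction from locus orders
# ---------------------------------------------------------------------------


def to_signed_permutation(
    target_order: Sequence[tuple[str, int]],
    reference_order: Sequence[tuple[str, int]],
) -> SignedPermutation:
    """Re-express a signed locus order in reference labels 1..n.

    Each order is a list of ``(locus, sign)`` with sign +1/-1.  Reference loci
    are numbered 1..n in reference order with positive sign; the target is
    rewritten in those labels, negated where its strand disagrees.
    """
    ref_loci = [name for name, _ in reference_order]
    tgt_loci = [name for name, _ in target_order]
    if set(ref_loci) != set(tgt_loci) or len(set(ref_loci)) != len(ref_loci):
        missing = set(ref_loci) ^ set(tgt_loci)
        raise ValueError(f"locus sets differ; symmetric difference: {sorted(missing)}")
    label = {}
    for k, (name, sign) in enumerate(reference_order, start=1):
        label[name] = (k, sign)
    out = []
    for name, sign in target_order:
        k, ref_sign = label[name]
        out.append(k if sign == ref_sign else -k)
    return SignedPermutation(tuple(out))


def normalize_ssc(
    order: Sequence[tuple[str, int]],
    ssc_loci: Iterable[str],
    flip: bool = True,
) -> list[tuple[str, int]]:
    """Flip (order-reverse and negate) the SSC-resident block of a locus order.

    The orientation of the small single-copy region is arbitrary in IR-present
    plastomes (the two isomers coexist in vivo), so comparisons must not count
    an SSC flip as a rearrangement.  The SSC loci must form one contiguous
    block of the order; otherwise the blocks straddle the boundary and an
    error is raised.
    """
    ssc = set(ssc_loci)
    idx = [k for k, (name, _) in enumerate(order) if name in ssc]
    if not idx:
        return list(order)
    lo, hi = min(idx), max(idx)
    if hi - lo + 1 != len(idx):
        inside = [order[k][0] for k in range(lo, hi + 1)]
        raise ValueError(
            f"SSC loci are not contiguous in the order; block {lo}..{hi} contains {inside}"
        )
    if not flip:
        return list(order)
    flipped = [(name, -sign) for name, sign in reversed(order[lo : hi + 1])]
    return list(order[:lo]) + flipped + list(order[hi + 1 :])


def distance_min_over_ssc(
    target_order: Sequence[tuple[str, int]],
    reference_order: Sequence[tuple[str, int]],
    ssc_loci: Iterable[str],
) -> tuple[int, ReversalScenario]:
    """Reversal distance minimized over the two SSC isomers of the reference."""
    best: tuple[int, ReversalScenario] | None = None
    for flip in (False, True):
        try:
            ref = normalize_ssc(reference_order, ssc_loci, flip=flip)
        except ValueError:
            if flip:
                break
            raise
        p = to_signed_permutation(target_order, ref)
        d, sc = reversal_distance(p)
        if best is None or d < best[0]:
            best = (d, sc)
    assert best is not None
    return best


def map_reversals_to_intervals(
    scenario: ReversalScenario,
    p: SignedPermutation,
    locus_names: Sequence[str],
    locus_coords: Mapping[str, tuple[int, int]],
) -> list[InversionInterval]:
    """Map each reversal step to a genomic interval in breakpoint convention.

    ``locus_names[k]`` is the locus labeled k+1 in the permutation;
    ``locus_coords`` maps locus name to its (start, end) 0-based half-open
    span in the target genome.  start_bp is the breakpoint before the
    leftmost affected locus and end_bp the breakpoint after the rightmost,
    so length_bp = end_bp - start_bp (Table-style flanking breakpoints).
    """
    intervals = []
    cur = p
    for i, j in scenario.steps:
        if j < i:
            raise ValueError("degenerate reversal spanning zero loci")
        affected = [abs(x) for x in cur.elements[i : j + 1]]
        coords = []
        for mag in affected:
            name = locus_names[mag - 1]
            if name not in locus_coords:
                raise KeyError(f"no coordinates for locus {name!r}")
            coords.append(locus_coords[name])
        start_bp = min(s for s, _ in coords)
        end_bp = max(e for _, e in coords)
        intervals.append(InversionInterval(start_bp, end_bp))
        cur = cur.reverse(i, j)
    return intervals


# ---------------------------------------------------------------------------
# GRIMM-style permutation files
# ---------------------------------------------------------------------------


def read_grimm(path) -> dict[str, SignedPermutation]:
    """Read a GRIMM-style file: ``>name`` stanzas of signed integers ending in ``$``."""
    perms: dict[str, SignedPermutation] = {}
    name = None
    buf: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if name is not None and buf:
                    perms[name] = SignedPermutation(tuple(buf))
                name = line[1:].strip()
                buf = []
            else:
                for tok in line.replace("$", " $ ").split():
                    if tok == "$":
                        break
                    buf.append(int(tok))
    if name is not None and buf:
        perms[name] = SignedPermutation(tuple(buf))
    return perms


def write_grimm(perms: Mapping[str, SignedPermutation], path) -> None:
    with open(path, "w") as fh:
        for name, p in perms.items():
            fh.write(f">{name}\n")
            fh.write(" ".join(str(x) for x in p.elements) + " $\n")


def random_signed_permutation(n: int, rng: random.Random) -> SignedPermutation:
    mags = list(range(1, n + 1))
    rng.shuffle(mags)
    return SignedPermutation(tuple(m if rng.random() < 0.5 else -m for m in mags))
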