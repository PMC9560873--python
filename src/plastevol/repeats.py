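"""Dispersed-repeat and SSR (microsatellite) detection with the standard
plastome-survey parameters: exact matches only, minimum dispersed-repeat
length 30 bp, MISA-style SSR unit minima (mono >= 10, di >= 6, tri..hexa
>= 5 units) and a 100-bp interruption window for compound SSRs.

Repeat censuses on quadripartite records are meant to run after
``collapse_ir`` so the two IR copies are not counted as a giant repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._sa import encode, maximal_pairs, revcomp
from .structure import InversionInterval

log = logging.getLogger(__name__)

DEFAULT_MIN_REPEAT_LEN = 30
#: MISA-style minimum unit counts per motif size
DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
DEFAULT_SSR_INTERRUPTION = 100
DEFAULT_ASSOCIATION_WINDOW = 500


@dataclass(frozen=True)
class RepeatCopy:
    start: int
    end: int  # 0-based half-open on the forward strand
    strand: str  # '+' | '-'


@dataclass(frozen=True)
class DispersedRepeat:
    """A family of >= 2 identical (or reverse-complement) copies."""

    sequence: str  # canonical: lexicographic min of (seq, revcomp(seq))
    copies: tuple[RepeatCopy, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def frequency(self) -> int:
        return len(self.copies)

    @property
    def orientation(self) -> str:
        strands = {c.strand for c in self.copies}
        if strands == {"+"}:
            return "direct"
        if len(strands) == 2:
            return "mixed" if self.frequency > 2 else "inverted"
        return "inverted"


@dataclass(frozen=True)
class SSRLocus:
    motif: str
    n_units: int
    start: int  # 0-based

    @property
    def unit_size(self) -> int:
        return len(self.motif)

    @property
    def end(self) -> int:
        return self.start + self.unit_size * self.n_units

    @property
    def length(self) -> int:
        return self.unit_size * self.n_units


@dataclass(frozen=True)
class CompoundSSR:
    members: tuple[SSRLocus, ...]

    @property
    def n_components(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RepeatInversionHit:
    repeat: DispersedRepeat
    inversion: InversionInterval
    endpoint_distances: tuple[int, int]  # (to start_bp, to end_bp) of nearest copy


# ---------------------------------------------------------------------------
# Dispersed repeats
# ---------------------------------------------------------------------------


def find_maximal_pairs(
    seq: str, min_len: int = DEFAULT_MIN_REPEAT_LEN, circular: bool = False
) -> list[tuple[RepeatCopy, RepeatCopy, int]]:
    """All maximal exact repeat pairs >= min_len, direct and inverted.

    Copies are reported on forward-strand coordinates; the second member of
    an inverted pair carries strand '-'.  With ``circular=True`` the scan
    appends a wrap-around pad of (min_len - 1) bases so origin-spanning
    repeats are seen once; pad-only artifacts are removed.
    """
    L = len(seq)
    scan = seq + (seq[: min_len - 1] if circular and L >= min_len else "")
    S = len(scan)
    codes, nxt = encode(scan)
    rc_codes, _ = encode(revcomp(scan), start_symbol=nxt + 1)
    s = np.concatenate([codes, np.array([nxt], dtype=np.int64), rc_codes])

    out = []
    seen = set()
    for i, j, ln in maximal_pairs(s, min_len):
        if j < S:  # both forward: direct pair
            a = RepeatCopy(i, i + ln, "+")
            b = RepeatCopy(j, j + ln, "+")
        elif i > S:  # both on the reverse strand: mirror of a direct pair
            continue
        else:  # one forward, one reverse: inverted pair
            r = j - (S + 1)
            b0 = S - r - ln
            iva, ivb = sorted([(i, i + ln), (b0, b0 + ln)])
            if iva == ivb:
                continue  # a perfect palindrome matching itself
            a = RepeatCopy(*iva, "+")
            b = RepeatCopy(*ivb, "-")
        # each inverted pair is seen twice (once per strand role)
        key = (a.start, a.end, b.start, b.end, a.strand != b.strand)
        if key in seen:
            continue
        seen.add(key)
        # overlap guard: tandem-style self overlap >= half the length is the
        # SSR module's jurisdiction
        ov = min(a.end, b.end) - max(a.start, b.start)
        if ov >= ln / 2:
            continue
        if circular and a.start >= L and b.start >= L:
            continue  # artifact entirely inside the pad
        out.append((a, b, ln))
    if circular:
        remapped = []
        for a, b, ln in out:
            if _wraps(a, L) and _wraps(b, L):
                continue
            def remap(c: RepeatCopy) -> RepeatCopy:
                if c.start >= L:
                    return RepeatCopy(c.start - L, c.end - L, c.strand)
                return c  # wrap-crossing copies keep end > L to mark the wrap
            remapped.append((remap(a), remap(b), ln))
        out = remapped
    return out


def _wraps(c: RepeatCopy, L: int) -> bool:
    return c.start < L <= c.end


def find_dispersed_repeats(
    seq: str,
    min_len: int = DEFAULT_MIN_REPEAT_LEN,
    max_mismatch: float = 0.0,
    circular: bool = False,
) -> list[DispersedRepeat]:
    """Group maximal repeat pairs into families of identical copies.

    Only exact matching is supported (max_mismatch must be 0).  Each family
    is keyed by its canonical sequence (lexicographic min of the string and
    its reverse complement); copies are the union of all pair members.
    """
    if max_mismatch != 0.0:
        raise NotImplementedError("only exact repeats (max_mismatch=0) are supported")
    if len(seq) < 2 * min_len:
        return []
    pairs = find_maximal_pairs(seq, min_len=min_len, circular=circular)
    fams: dict[str, set[RepeatCopy]] = {}
    ext = seq + seq[: min_len - 1] if circular else seq
    for a, b, ln in pairs:
        fwd = ext[a.start : a.end]  # a is always reported on the forward strand
        canon = min(fwd, revcomp(fwd))
        members = fams.setdefault(canon, set())
        for c in (a, b):
            read = ext[c.start : c.end]
            strand = "+" if read == canon else "-"
            members.add(RepeatCopy(c.start, c.end, strand))
    out = [
        DispersedRepeat(sequence=canon, copies=tuple(sorted(cs, key=lambda c: (c.start, c.strand))))
        for canon, cs in fams.items()
    ]
    out.sort(key=lambda r: (-r.length, r.copies[0].start))
    return out


def filter_redundant_repeats(repeats: Sequence[DispersedRepeat]) -> list[DispersedRepeat]:
    """Remove nested-family redundancy.

    For each containment pair (every copy of the shorter family lies within
    some copy of the longer family):

    1. if the longer family is at most 10 bp longer, the longer is dropped
       (a near-identical duplicate listing);
    2. otherwise, if the longer family has frequency >= 3, the contained
       shorter family is dropped (absorbed by the high-frequency repeat).

    Rules are applied in that order; the filter is idempotent.
    """
    repeats = list(repeats)

    def contained(short: DispersedRepeat, long_: DispersedRepeat) -> bool:
        return all(
            any(lc.start <= sc.start and sc.end <= lc.end for lc in long_.copies)
            for sc in short.copies
        )

    dropped: set[int] = set()
    # rule 1: drop long families barely extending a contained family
    for li, long_ in enumerate(repeats):
        for si, short in enumerate(repeats):
            if si == li or si in dropped or li in dropped:
                continue
            if short.length < long_.length <= short.length + 10 and contained(short, long_):
                dropped.add(li)
                break
    # rule 2: high-frequency long families absorb their sub-repeats
    for li, long_ in enumerate(repeats):
        if li in dropped:
            continue
        if long_.frequency < 3:
            continue
        for si, short in enumerate(repeats):
            if si == li or si in dropped:
                continue
            if short.length < long_.length and contained(short, long_):
                dropped.add(si)
    return [r for k, r in enumerate(repeats) if k not in dropped]


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def find_ssrs(
    seq: str,
    thresholds: Mapping[int, int] | None = None,
    interruption: int = DEFAULT_SSR_INTERRUPTION,
) -> tuple[list[SSRLocus], list[CompoundSSR]]:
    """Maximal perfect tandem repeats of 1-6 bp primitive motifs.

    A run qualifies when its number of complete units meets the per-unit-size
    minimum.  Runs whose motif is a power of a smaller motif are reported
    once, at the smaller unit size.  SSRs separated by <= ``interruption``
    bp are additionally grouped into compound loci.
    """
    th = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    L = len(seq)
    loci: list[SSRLocus] = []
    covered: list[tuple[int, int]] = []  # spans already claimed by smaller units
    for u in sorted(th):
        need = th[u]
        i = 0
        while i + u * 2 <= L or i + u <= L:
            motif = seq[i : i + u]
            if len(motif) < u or "N" in motif or not _is_primitive(motif):
                i += 1
                continue
            # extend the run of period u starting at i
            j = i + u
            while j < L and seq[j] == seq[j - u]:
                j += 1
            n_units = (j - i) // u
            if n_units >= need:
                start, end = i, i + n_units * u
                if not any(cs <= start and end <= ce for cs, ce in covered):
                    loci.append(SSRLocus(motif=motif, n_units=n_units, start=start))
                    covered.append((start, end))
                i = j  # a maximal run cannot restart inside itself
            else:
                i += 1
    loci.sort(key=lambda s: s.start)
    compounds: list[CompoundSSR] = []
    group: list[SSRLocus] = []
    for s in loci:
        if group and s.start - group[-1].end <= interruption:
            group.append(s)
        else:
            if len(group) >= 2:
                compounds.append(CompoundSSR(tuple(group)))
            group = [s]
    if len(group) >= 2:
        compounds.append(CompoundSSR(tuple(group)))
    return loci, compounds


def tandem_repeat_count(seq: str, **kwargs) -> int:
    """Number of SSR loci (compound SSRs counted per component, MISA style)."""
    loci, _ = find_ssrs(seq, **kwargs)
    return len(loci)


# ---------------------------------------------------------------------------
# Repeat / inversion association
# ---------------------------------------------------------------------------


def associate_repeats_with_inversions(
    repeats: Sequence[DispersedRepeat],
    inversions: Sequence[InversionInterval],
    window: int = DEFAULT_ASSOCIATION_WINDOW,
) -> list[RepeatInversionHit]:
    """Repeats with a copy within ``window`` bp of an inversion endpoint.

    Both coordinate sets must refer to the same genome.  A copy "hits" an
    endpoint when its span overlaps the endpoint or ends within ``window``
    bp of it.  One hit is emitted per (repeat, inversion) pair, carrying the
    minimum copy-to-endpoint distances.
    """
    hits = []
    for inv in inversions:
        for rep in repeats:
            d_start = min(_gap(c, inv.start_bp) for c in rep.copies)
            d_end = min(_gap(c, inv.end_bp) for c in rep.copies)
            if min(d_start, d_end) <= window:
                hits.append(
                    RepeatInversionHit(
                        repeat=rep, inversion=inv, endpoint_distances=(d_start, d_end)
                    )
                )
    return hits


def _gap(c: RepeatCopy, bp: int) -> int:
    if c.start <= bp <= c.end:
        return 0
    return c.start - bp if c.start > bp else bp - c.end


def longest_hit_per_inversion(
    hits: Sequence[RepeatInversionHit],
) -> dict[InversionInterval, int]:
    """Length of the longest associated repeat for each inversion (survey-table style)."""
    best: dict[InversionInterval, int] = {}
    for h in hits:
        cur = best.get(h.inversion, 0)
        if h.repeat.length > cur:
            best[h.inversion] = h.repeat.length
    return best


# ---------------------------------------------------------------------------
# Brute-force oracle (validation only)
# ---------------------------------------------------------------------------


def brute_force_maximal_pairs(
    seq: str, min_len: int = DEFAULT_MIN_REPEAT_LEN
) -> list[tuple[RepeatCopy, RepeatCopy, int]]:
    """O(L^2) shift-scan over both strands; independent of the suffix-array path."""
    L = len(seq)
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_mask = a == ord("N")
    out = []

    def runs(eq: np.ndarray):
        # maximal runs of True
        idx = np.flatnonzero(np.diff(np.concatenate([[0], eq.view(np.int8), [0]])))
        return zip(idx[::2], idx[1::2])

    # direct: seq vs seq shifted by d
    for d in range(1, L):
        m = L - d
        eq = (a[:m] == a[d:]) & ~n_mask[:m] & ~n_mask[d:]
        if not eq.any():
            continue
        for s, e in runs(eq):
            if e - s >= min_len:
                out.append((RepeatCopy(int(s), int(e), "+"), RepeatCopy(int(s + d), int(e + d), "+"), int(e - s)))
    # inverted: seq vs revcomp(seq)
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    rc_n = rc == ord("N")
    for off in range(-(L - 1), L):
        if off >= 0:
            x, y = a[off:], rc[: L - off]
            xm, ym = n_mask[off:], rc_n[: L - off]
            xs = off
            rs = 0
        else:
            x, y = a[: L + off], rc[-off:]
            xm, ym = n_mask[: L + off], rc_n[-off:]
            xs = 0
            rs = -off
        eq = (x == y) & ~xm & ~ym
        if not eq.any():
            continue
        for s, e in runs(eq):
            ln = e - s
            if ln < min_len:
                continue
            fa = (xs + s, xs + e)
            r0 = rs + s
            fb = (L - (r0 + ln), L - r0)
            if fb[0] < fa[0] or fb == fa:
                continue  # mirror duplicate / self-palindrome
            ov = min(fa[1], fb[1]) - max(fa[0], fb[0])
            if ov >= ln / 2:
                continue
            out.append((RepeatCopy(*fa, "+"), RepeatCopy(*fb, "-"), ln))
    return sorted(set(out), key=lambda t: (t[0].start, t[1].start, -t[2]))
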