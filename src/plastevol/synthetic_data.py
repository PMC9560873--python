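"""Synthetic plastomes, inversions, codon alignments and Brownian traits with
known ground truth.

The generator emulates the data regimes of a quadripartite plastome survey:
an LSC and SSC separated by exact reverse-complement IR copies carrying the
rRNA core; gene orders scrambled by a known number of inversions, optionally
mediated by planted inverted repeat pairs at the breakpoints; codon
alignments evolved under the same MG94 process the estimator fits; and
Brownian-motion traits with configurable group shifts.  Every generator is a
pure function of its configuration and seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._sa import revcomp
from .genome_io import Feature, GenomeRecord, RegionPartition
from .molevol import BranchTree, CodonAlignment, MG94Matrix, f3x4_frequencies

# approximate real plastid gene lengths (bp), used to shape the regions
LSC_GENES: tuple[tuple[str, str, int], ...] = (
    ("psbA", "CDS", 1062), ("matK", "CDS", 1530), ("atpA", "CDS", 1524),
    ("atpF", "CDS", 555), ("atpH", "CDS", 246), ("atpI", "CDS", 744),
    ("rps2", "CDS", 711), ("rpoC2", "CDS", 4140), ("rpoC1", "CDS", 2040),
    ("rpoB", "CDS", 3213), ("psbD", "CDS", 1062), ("psbC", "CDS", 1386),
    ("rps14", "CDS", 303), ("psaB", "CDS", 2205), ("psaA", "CDS", 2253),
    ("ycf3", "CDS", 507), ("rps4", "CDS", 606), ("ndhC", "CDS", 363),
    ("atpB", "CDS", 1497), ("rbcL", "CDS", 1428), ("accD", "CDS", 1530),
    ("ycf4", "CDS", 555), ("cemA", "CDS", 690), ("petA", "CDS", 963),
    ("psbB", "CDS", 1527), ("petB", "CDS", 648), ("rpoA", "CDS", 1014),
    ("rps11", "CDS", 417), ("rpl16", "CDS", 408), ("rps3", "CDS", 657),
)
IR_GENES: tuple[tuple[str, str, int], ...] = (
    ("rpl2", "CDS", 822), ("rpl23", "CDS", 282), ("ycf2", "CDS", 6840),
    ("ndhB", "CDS", 1533), ("rps7", "CDS", 468), ("rrn16", "rRNA", 1491),
    ("trnI-GAU", "tRNA", 72), ("trnA-UGC", "tRNA", 73), ("rrn23", "rRNA", 2810),
    ("rrn4.5", "rRNA", 103), ("rrn5", "rRNA", 121),
)
SSC_GENES: tuple[tuple[str, str, int], ...] = (
    ("ndhF", "CDS", 2241), ("rpl32", "CDS", 174), ("ccsA", "CDS", 966),
    ("ndhD", "CDS", 1503), ("psaC", "CDS", 246), ("ndhE", "CDS", 306),
    ("ndhG", "CDS", 531), ("ndhA", "CDS", 1092), ("rps15", "CDS", 273),
    ("ycf1", "CDS", 5400),
)

_SENSE_NO_STOP = None  # built lazily


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic plastome generator."""

    seed: int = 0
    gene_scale: float = 1.0  # multiply all gene lengths (smaller = faster fixtures)
    intergenic_mean: int = 200  # geometric-ish spacer length
    intergenic_gc: float = 0.35
    ir_deleted: str | None = None  # None | 'A' | 'B'
    n_lsc_genes: int = len(LSC_GENES)
    n_ssc_genes: int = len(SSC_GENES)


def _random_spacer(rng: random.Random, mean: int, gc: float) -> str:
    n = max(30, int(rng.expovariate(1 / mean)) + 1)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=p, k=n))


def _random_cds(rng: random.Random, length: int) -> str:
    """In-frame CDS: ATG + sense codons + TAA; length rounded to codons."""
    global _SENSE_NO_STOP
    if _SENSE_NO_STOP is None:
        from .seqstats import SENSE_CODONS

        _SENSE_NO_STOP = [c for c in SENSE_CODONS if c != "ATG"] + ["ATG"]
    n_codons = max(4, length // 3)
    body = rng.choices(_SENSE_NO_STOP, k=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _random_rna(rng: random.Random, length: int) -> str:
    return "".join(rng.choices("ACGT", k=max(30, length)))


def simulate_plastome(cfg: SimConfig) -> tuple[GenomeRecord, dict]:
    """Quadripartite plastome with exact IR copies; returns (record, ledger).

    The ledger records the planted region boundaries, the gene order per
    region, and which IR copy (if any) was deleted.
    """
    rng = random.Random(cfg.seed)

    def build_region(genes, strand_rng=True):
        seq_parts = []
        feats = []  # (name, kind, strand, rel_start, rel_end)
        pos = 0
        for name, kind, length in genes:
            spacer = _random_spacer(rng, cfg.intergenic_mean, cfg.intergenic_gc)
            seq_parts.append(spacer)
            pos += len(spacer)
            L = max(12, int(length * cfg.gene_scale))
            body = _random_cds(rng, L) if kind == "CDS" else _random_rna(rng, L)
            strand = "+" if (not strand_rng or rng.random() < 0.7) else "-"
            if strand == "-":
                seq_parts.append(revcomp(body))
            else:
                seq_parts.append(body)
            feats.append((name, kind, strand, pos, pos + len(body)))
            pos += len(body)
        tail = _random_spacer(rng, cfg.intergenic_mean, cfg.intergenic_gc)
        seq_parts.append(tail)
        pos += len(tail)
        return "".join(seq_parts), feats

    lsc_seq, lsc_feats = build_region(LSC_GENES[: cfg.n_lsc_genes])
    ira_seq, ira_feats = build_region(IR_GENES)
    ssc_seq, ssc_feats = build_region(SSC_GENES[: cfg.n_ssc_genes])

    irb_seq = revcomp(ira_seq)
    ir_len = len(ira_seq)

    # offsets in the LSC -> IR_A -> SSC -> IR_B layout
    off_a = len(lsc_seq)
    off_s = off_a + ir_len
    off_b = off_s + len(ssc_seq)
    total = off_b + ir_len
    seq = list(lsc_seq + ira_seq + ssc_seq + irb_seq)

    # forbid accidental extension of the IR match at its four boundaries
    def break_match(i: int, j: int):
        # position i must not equal complement of position j
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        if 0 <= i < total and 0 <= j < total and seq[i] == comp[seq[j]]:
            seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]

    break_match(off_a - 1, off_b + ir_len - 1 + 1 - 1)  # left of IR_A vs right of IR_B
    if off_b + ir_len < total:
        break_match(off_a - 1, off_b + ir_len)
    break_match(off_s, off_b - 1)  # right of IR_A vs left of IR_B
    seq = "".join(seq)

    feats: list[Feature] = []
    for name, kind, strand, s, e in lsc_feats:
        feats.append(Feature(name, kind, strand, ((s, e),)))
    for name, kind, strand, s, e in ira_feats:
        feats.append(Feature(name, kind, strand, ((off_a + s, off_a + e),)))
    for name, kind, strand, s, e in ssc_feats:
        feats.append(Feature(name, kind, strand, ((off_s + s, off_s + e),)))
    # IR_B carries mirrored duplicates of the IR_A genes
    for name, kind, strand, s, e in ira_feats:
        ms, me = ir_len - e, ir_len - s
        flipped = "-" if strand == "+" else "+"
        feats.append(Feature(name, kind, flipped, ((off_b + ms, off_b + me),)))

    part = RegionPartition(
        lsc=(0, off_a), ssc=(off_s, off_b), ir_a=(off_a, off_s), ir_b=(off_b, total),
        ir_status="both",
    )
    record = GenomeRecord(id=f"synth_{cfg.seed}", sequence=seq, features=tuple(feats), partition=part)

    if cfg.ir_deleted in ("A", "B"):
        cut = part.ir_a if cfg.ir_deleted == "A" else part.ir_b
        s0, e0 = cut
        new_seq = seq[:s0] + seq[e0:]
        new_feats = []
        for f in record.features:
            if f.start >= s0 and f.end <= e0:
                continue
            spans = tuple(
                (st - (e0 - s0) if st >= e0 else st, en - (e0 - s0) if en > e0 else en)
                for st, en in f.spans
            )
            new_feats.append(replace(f, spans=spans))

        def shift(iv):
            a, b = iv
            d = e0 - s0
            return (a - d if a >= e0 else a, b - d if b > e0 else b)

        status = "A_lost" if cfg.ir_deleted == "A" else "B_lost"
        kept = part.ir_b if cfg.ir_deleted == "A" else part.ir_a
        new_part = RegionPartition(
            lsc=shift(part.lsc),
            ssc=shift(part.ssc),
            ir_a=shift(kept) if cfg.ir_deleted == "B" else None,
            ir_b=shift(kept) if cfg.ir_deleted == "A" else None,
            ir_status=status,
        )
        record = GenomeRecord(
            id=record.id, sequence=new_seq, features=tuple(new_feats), partition=new_part
        )

    ledger = {
        "seed": cfg.seed,
        "ir_deleted": cfg.ir_deleted,
        "regions": {
            "lsc": list(record.partition.lsc),
            "ssc": list(record.partition.ssc),
            "ir_a": list(record.partition.ir_a) if record.partition.ir_a else None,
            "ir_b": list(record.partition.ir_b) if record.partition.ir_b else None,
        },
        "ir_len": ir_len,
        "genes": [f.locus_name for f in record.features],
    }
    return record, ledger


# ---------------------------------------------------------------------------
# Inversions
# ---------------------------------------------------------------------------


def apply_inversions(
    record: GenomeRecord,
    k: int,
    fraction_repeat_mediated: float = 0.15,
    repeat_len: int = 40,
    seed: int = 0,
    allow_adjacent: bool = True,
) -> tuple[GenomeRecord, list[dict]]:
    """Apply k random gene-boundary-respecting inversions; returns events.

    Breakpoints fall in intergenic gaps of single-copy regions (IR copies,
    when present, are never cut).  For the repeat-mediated fraction an
    inverted repeat pair of ``repeat_len`` (>= 30) bases is first planted in
    the two flanking gaps, then the segment between the pair is inverted, so
    the planted copies sit exactly at the inversion endpoints.  Events are
    recorded in flanking-breakpoint convention (length = end - start).
    With ``allow_adjacent=False`` the chosen gene intervals are pairwise
    separated by at least one untouched gene, which makes the planted count
    equal the true reversal distance.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if repeat_len < 30:
        raise ValueError("repeat_len must be >= 30 (dispersed-repeat threshold)")
    rng = random.Random(seed)
    if k == 0:
        return record, []

    part = record.partition
    feats = sorted(record.features, key=lambda f: f.start)
    # candidate loci: features inside single-copy regions (or anywhere if no partition)
    def in_sc(f: Feature) -> bool:
        if part is None or part.ir_status == "none":
            return True
        reg = part.region_of(f.start)
        return reg in ("lsc", "ssc")

    sc = [f for f in feats if in_sc(f)]
    events: list[dict] = []
    n = len(sc)
    if n < 2:
        raise ValueError("not enough single-copy genes to invert")
    n_rm = int(round(k * fraction_repeat_mediated))

    def region_of_feat(f):
        return part.region_of(f.start) if part is not None else "lsc"

    region_of_idx = [region_of_feat(f) for f in sc]
    # choose gene index intervals up front; inversions permute genes within a
    # contiguous run, so sorted-by-start indices and region labels are stable
    chosen: list[tuple[int, int]] = []
    if allow_adjacent:
        attempts = 0
        while len(chosen) < k:
            attempts += 1
            if attempts > 20000:
                raise ValueError(f"k={k} too large for {n} single-copy genes")
            i = rng.randrange(n)
            j = rng.randrange(i, min(n, i + 5))
            if region_of_idx[i] != region_of_idx[j] or (i, j) in chosen:
                continue
            chosen.append((i, j))
    else:
        # constructive placement: k single-region runs with >= 1 untouched
        # gene between any two, so each planted inversion stays independent
        max_w = max(1, min(4, (n - (k - 1)) // k)) if k else 1
        widths = [rng.randint(1, max_w) for _ in range(k)]
        occupied = sum(widths) + (k - 1)
        slack = n - occupied
        if slack < 0:
            raise ValueError(f"k={k} too large for {n} single-copy genes")
        for _ in range(200):
            cuts = sorted(rng.randint(0, slack) for _ in range(k))
            pos, trial_list, ok = 0, [], True
            for w, extra in zip(widths, [cuts[0]] + [cuts[t + 1] - cuts[t] for t in range(k - 1)]):
                start = pos + extra
                end = start + w - 1
                if region_of_idx[start] != region_of_idx[end]:
                    ok = False
                    break
                trial_list.append((start, end))
                pos = end + 2  # leave one untouched gene
            if ok:
                chosen = trial_list
                break
        if not chosen:
            raise ValueError(f"k={k} too large for {n} single-copy genes")
    chosen.sort()

    seq = record.sequence
    cur_feats = list(feats)
    rm_flags = [True] * n_rm + [False] * (len(chosen) - n_rm)
    rng.shuffle(rm_flags)
    for (i, j), mediated in zip(chosen, rm_flags):
        cur_feats.sort(key=lambda f: f.start)
        sc_now = [f for f in cur_feats if in_sc(f)]
        first, last = sc_now[i], sc_now[j]
        # breakpoints in the intergenic gaps flanking the chosen gene run,
        # clamped to the run's region so a neighbor in an adjacent region
        # (e.g. an IR gene) cannot pull the breakpoint outside it
        if part is not None and part.ir_status != "none":
            reg = part.region_of(first.start)
            rs, re = getattr(part, reg)
        else:
            rs, re = 0, len(seq)
        prev_end = max(
            (f.end for f in cur_feats if f.end <= first.start), default=0
        )
        next_start = min(
            (f.start for f in cur_feats if f.start >= last.end), default=len(seq)
        )
        prev_end = max(prev_end, rs)
        next_start = min(next_start, re)
        if mediated and (
            first.start - prev_end >= repeat_len and next_start - last.end >= repeat_len
        ):
            # breakpoints at the gene run limits; the planted pair occupies
            # the repeat_len gap bases just outside each breakpoint
            s, e = first.start, last.end
        else:
            mediated = False
            s = (prev_end + first.start) // 2
            e = (last.end + next_start) // 2
        seq, cur_feats, ev = _invert(seq, cur_feats, s, e, mediated, repeat_len, rng)
        events.append(ev)
    _flag_disturbed_events(events)
    out = GenomeRecord(
        id=record.id, sequence=seq, features=tuple(cur_feats), partition=record.partition
    )
    return out, events


def _flag_disturbed_events(events: list[dict]) -> None:
    """Mark mediated events whose planted copies a later event overwrote/moved.

    Inversions are length-preserving, so event coordinates stay valid in the
    final sequence; but a later overlapping event can relocate or overwrite a
    previously planted repeat copy, in which case the copy is no longer at
    the recorded endpoints and endpoint association cannot recover it.
    """
    for idx, ev in enumerate(events):
        ev["disturbed"] = False
        if not ev["repeat_mediated"]:
            continue
        rl = ev["repeat_len"]
        copies = [(ev["start_bp"] - rl, ev["start_bp"]), (ev["end_bp"], ev["end_bp"] + rl)]
        for later in events[idx + 1 :]:
            lrl = later["repeat_len"] or 0
            lo, hi = later["start_bp"] - lrl, later["end_bp"] + lrl
            if any(cs < hi and lo < ce for cs, ce in copies):
                ev["disturbed"] = True
                break


def _invert(seq, feats, s, e, mediated, repeat_len, rng):
    if mediated:
        unit = "".join(rng.choices("ACGT", k=repeat_len))
        # overwrite the intergenic bases immediately flanking the breakpoints
        seq = seq[: s - repeat_len] + unit + seq[s:e] + revcomp(unit) + seq[e + repeat_len :]
    mid = revcomp(seq[s:e])
    seq = seq[:s] + mid + seq[e:]
    new_feats = []
    for f in feats:
        if f.end <= s or f.start >= e:
            new_feats.append(f)
            continue
        if f.start < s or f.end > e:
            raise AssertionError("inversion breakpoint inside a feature")
        spans = tuple(sorted((s + e - en, s + e - st) for st, en in f.spans))
        strand = "-" if f.strand == "+" else "+"
        new_feats.append(replace(f, spans=spans, strand=strand))
    ev = {
        "start_bp": s,
        "end_bp": e,
        "length_bp": e - s,
        "repeat_mediated": bool(mediated),
        "repeat_len": repeat_len if mediated else None,
    }
    return seq, new_feats, ev


# ---------------------------------------------------------------------------
# Codon evolution
# ---------------------------------------------------------------------------


def simulate_codon_evolution(
    tree: BranchTree,
    n_codons: int,
    kappa: float = 2.0,
    omega: float | Mapping[str, float] = 0.2,
    pi: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[CodonAlignment, dict[str, tuple[float, float, float]]]:
    """Evolve codon sequences along the tree under MG94; returns truth per branch.

    ``omega`` may be a scalar or a per-edge-name map.  Branch lengths are the
    tree's, in expected substitutions per codon.  The returned truth maps
    edge name -> (dS, dN, omega).
    """
    if n_codons < 10:
        raise ValueError("n_codons too small")
    rng = np.random.default_rng(seed)
    if pi is None:
        pi = f3x4_frequencies()
    mg = MG94Matrix(pi, kappa=kappa)

    def om(v):
        if isinstance(omega, Mapping):
            return float(omega[tree.edge_names[v]])
        return float(omega)

    states = {tree.root: rng.choice(len(pi), size=n_codons, p=pi)}
    truth = {}
    for v in reversed(tree.postorder):  # preorder
        p = tree.parent[v]
        if p < 0:
            continue
        t = float(tree.lengths[v])
        P = mg.transition_matrix(om(v), t)
        P = P / P.sum(axis=1, keepdims=True)
        parent_states = states[p]
        u = rng.random(n_codons)
        cdf = np.cumsum(P, axis=1)
        states[v] = (u[:, None] > cdf[parent_states]).sum(axis=1)
        ds, dn = mg.ds_dn(t, om(v))
        truth[tree.edge_names[v]] = (ds, dn, om(v))

    from .seqstats import SENSE_CODONS

    seqs = {}
    for v in tree.tips:
        seqs[tree.labels[v]] = "".join(SENSE_CODONS[s] for s in states[v])
    return CodonAlignment(seqs, gene_set="simulated"), truth


# ---------------------------------------------------------------------------
# Brownian traits
# ---------------------------------------------------------------------------


def simulate_brownian_traits(
    tree: BranchTree,
    sigma2: float | Mapping[str, float],
    group_of: Mapping[str, str],
    group_shifts: Mapping[str, Mapping[str, float]] | None = None,
    variables: Sequence[str] = ("trait",),
    seed: int = 0,
):
    """Brownian-motion tip values per variable, plus per-group shifts.

    ``group_shifts`` maps variable -> group -> additive shift applied at the
    tips after simulation.  Returns a pandas DataFrame indexed by taxon with
    one column per variable and a ``group`` column.
    """
    import pandas as pd

    from .phylostats import brownian_vcv

    rng = np.random.default_rng(seed)
    C, labels = brownian_vcv(tree)
    L = np.linalg.cholesky(C + 1e-12 * np.mean(np.diag(C)) * np.eye(len(labels)))
    data = {}
    for var in variables:
        s2 = float(sigma2[var]) if isinstance(sigma2, Mapping) else float(sigma2)
        y = np.sqrt(s2) * (L @ rng.standard_normal(len(labels)))
        if group_shifts and var in group_shifts:
            shifts = group_shifts[var]
            y = y + np.array([shifts.get(group_of[t], 0.0) for t in labels])
        data[var] = y
    df = pd.DataFrame(data, index=labels)
    df["group"] = [group_of[t] for t in labels]
    return df
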