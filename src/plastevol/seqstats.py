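"""Base composition, codon usage (RSCU, GC3), and indel/SNV frequencies.

Frequencies follow the base-wise convention: number of mutated bases divided
by the total plastome length of the target, reported separately per sequence
class (protein-coding, rRNA, intergenic).  A per-class-length normalization
is emitted alongside for diagnostics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

STOP_CODONS = {"TAA", "TAG", "TGA"}

_STD = CodonTable.unambiguous_dna_by_id[1]
#: amino acid -> synonymous codon family (standard code, stops excluded)
CODON_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _STD.forward_table.items():
    CODON_FAMILIES.setdefault(_aa, ())
    CODON_FAMILIES[_aa] = CODON_FAMILIES[_aa] + (_codon,)
SENSE_CODONS = tuple(sorted(_STD.forward_table))


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T); N bases are ignored entirely."""
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq.upper())
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


@dataclass(frozen=True)
class CodonUsageTable:
    counts: Mapping[str, int]
    rscu: Mapping[str, float]  # missing families absent from the map
    gc: float
    gc3: float
    preferred: Mapping[str, str]  # amino acid -> highest-RSCU codon


def codon_iter(cds: str):
    for k in range(0, len(cds) - len(cds) % 3, 3):
        yield cds[k : k + 3]


def rscu(cds_set: Sequence[str], gene_names: Sequence[str] | None = None) -> CodonUsageTable:
    """Relative synonymous codon usage over a set of in-frame CDS.

    RSCU(c) = k * n_c / sum(family counts) for a family of size k.  GC3 is
    the G+C fraction of third codon positions, stop codons and codons
    containing N excluded.  Internal stop codons are rejected.
    """
    names = gene_names or [f"cds_{k}" for k in range(len(cds_set))]
    counts: Counter[str] = Counter()
    third = Counter()
    all_bases = Counter()
    for name, cds in zip(names, cds_set):
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"CDS {name} length {len(cds)} not divisible by 3")
        codons = list(codon_iter(cds))
        for pos, c in enumerate(codons):
            if c in STOP_CODONS:
                if pos != len(codons) - 1:
                    raise ValueError(f"internal stop codon {c} in {name} at codon {pos}")
                continue
            all_bases.update(c)
            if "N" in c:
                continue
            counts[c] += 1
            third[c[2]] += 1
    rscu_vals: dict[str, float] = {}
    preferred: dict[str, str] = {}
    for aa, family in CODON_FAMILIES.items():
        total = sum(counts[c] for c in family)
        if total == 0:
            continue  # unused family: RSCU undefined, reported as missing
        k = len(family)
        for c in family:
            rscu_vals[c] = k * counts[c] / total
        preferred[aa] = max(family, key=lambda c: (rscu_vals[c], c))
    n3 = sum(third.values())
    gc3 = (third["G"] + third["C"]) / n3 if n3 else float("nan")
    denom = sum(all_bases[b] for b in "ACGT")
    gc = (all_bases["G"] + all_bases["C"]) / denom if denom else float("nan")
    return CodonUsageTable(counts=dict(counts), rscu=rscu_vals, gc=gc, gc3=gc3, preferred=preferred)


# ---------------------------------------------------------------------------
# Indel / SNV frequencies from alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassFrequencies:
    """Mutated-base counts and frequencies per sequence class."""

    counts: Mapping[str, int]  # class -> mutated bases
    events: Mapping[str, int]  # class -> events (indel runs / SNV sites)
    class_lengths: Mapping[str, int]  # aligned (ungapped-target) length per class
    total_len: int  # target plastome length

    def frequency(self, cls: str) -> float:
        """Mutated bases / total plastome bases (the headline convention)."""
        return self.counts.get(cls, 0) / self.total_len

    def class_frequency(self, cls: str) -> float:
        """Mutated bases / class length (diagnostic alternative)."""
        L = self.class_lengths.get(cls, 0)
        return self.counts.get(cls, 0) / L if L else float("nan")


def _check_pair(alignment: Mapping[str, str], target: str, reference: str):
    if reference not in alignment:
        raise KeyError(f"reference {reference!r} absent from alignment")
    if target not in alignment:
        raise KeyError(f"target {target!r} absent from alignment")
    t, r = alignment[target], alignment[reference]
    if len(t) != len(r):
        raise ValueError("alignment rows differ in length")
    return t.upper(), r.upper()


def indel_frequency(
    alignments: Mapping[str, Mapping[str, str]],
    target: str,
    reference: str,
    total_len: int,
) -> ClassFrequencies:
    """Base-wise indel frequency of target vs reference, per sequence class.

    ``alignments`` maps class name (e.g. ``protein_coding``, ``rRNA``,
    ``intergenic``) to an aligned FASTA dict.  A column counts as an indel
    base when exactly one of target/reference is gapped.
    """
    counts: dict[str, int] = {}
    events: dict[str, int] = {}
    lens: dict[str, int] = {}
    for cls, aln in alignments.items():
        t, r = _check_pair(aln, target, reference)
        n = 0
        ev = 0
        in_run = False
        for tb, rb in zip(t, r):
            gap = (tb == "-") != (rb == "-")
            if gap:
                n += 1
                if not in_run:
                    ev += 1
                in_run = True
            else:
                in_run = False
        counts[cls] = n
        events[cls] = ev
        lens[cls] = sum(1 for b in t if b != "-")
    return ClassFrequencies(counts=counts, events=events, class_lengths=lens, total_len=total_len)


def snv_frequency(
    alignments: Mapping[str, Mapping[str, str]],
    target: str,
    reference: str,
    total_len: int,
) -> ClassFrequencies:
    """Base-wise SNV frequency: columns where both rows have bases that differ."""
    counts: dict[str, int] = {}
    lens: dict[str, int] = {}
    for cls, aln in alignments.items():
        t, r = _check_pair(aln, target, reference)
        n = sum(
            1
            for tb, rb in zip(t, r)
            if tb not in "-N" and rb not in "-N" and tb != rb
        )
        counts[cls] = n
        lens[cls] = sum(1 for b in t if b != "-")
    return ClassFrequencies(counts=counts, events=dict(counts), class_lengths=lens, total_len=total_len)
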