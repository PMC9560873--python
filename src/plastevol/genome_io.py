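"""Annotated plastome records: GenBank/FASTA I/O, quadripartite partitioning,
IR collapsing and shared single-copy locus orders.

Internal coordinates are 0-based half-open on the linearized circle; GenBank
I/O converts to/from the flat file's 1-based inclusive convention (Biopython
performs the same conversion, so spans round-trip bijectively).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._sa import encode, maximal_pairs, revcomp

log = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "other")

#: case-insensitive locus-symbol synonyms (canonical form on the right)
SYNONYMS = {
    "rrn16s": "rrn16",
    "rrn23s": "rrn23",
    "rrn4.5s": "rrn4.5",
    "rrn5s": "rrn5",
    "16s rrna": "rrn16",
    "23s rrna": "rrn23",
}


def normalize_locus(name: str) -> str:
    """Case-normalized gene symbol with synonyms resolved; unknown names pass through."""
    key = name.strip()
    canon = SYNONYMS.get(key.lower())
    return canon if canon is not None else key


@dataclass(frozen=True)
class Feature:
    """One annotated locus: gene symbol, kind, strand and (possibly joined) spans."""

    locus_name: str
    kind: str  # CDS | tRNA | rRNA | other
    strand: str  # '+' | '-'
    spans: tuple[tuple[int, int], ...]  # 0-based half-open
    pseudo: bool = False

    def __post_init__(self) -> None:
        if not self.locus_name:
            raise ValueError("locus_name must be nonempty")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for s, e in self.spans:
            if e - s < 1:
                raise ValueError(f"span [{s},{e}) has length < 1")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.spans)

    @property
    def end(self) -> int:
        return max(e for _, e in self.spans)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.spans)


@dataclass(frozen=True)
class RegionPartition:
    """Quadripartite partition LSC / SSC / IR_A / IR_B (intervals 0-based half-open)."""

    lsc: tuple[int, int]
    ssc: tuple[int, int]
    ir_a: tuple[int, int] | None
    ir_b: tuple[int, int] | None
    ir_status: str  # both | A_lost | B_lost | none

    def region_of(self, pos: int) -> str:
        for name, iv in (
            ("lsc", self.lsc),
            ("ssc", self.ssc),
            ("ir_a", self.ir_a),
            ("ir_b", self.ir_b),
        ):
            if iv is not None and iv[0] <= pos < iv[1]:
                return name
        return "unassigned"


@dataclass(frozen=True)
class GenomeRecord:
    """A circular annotated plastome."""

    id: str
    sequence: str
    features: tuple[Feature, ...] = ()
    partition: RegionPartition | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("sequence must be nonempty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        feats = tuple(sorted(self.features, key=lambda f: (f.start, f.end)))
        object.__setattr__(self, "features", feats)
        for f in feats:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.locus_name} extends past sequence end "
                    f"({f.end} > {len(self.sequence)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_census(self) -> dict[str, int]:
        """Count of features per kind (pseudogenes excluded)."""
        out = {k: 0 for k in FEATURE_KINDS}
        for f in self.features:
            if not f.pseudo:
                out[f.kind] += 1
        return out

    def feature_sequence(self, f: Feature) -> str:
        parts = [self.sequence[s:e] for s, e in f.spans]
        seq = "".join(parts)
        return revcomp(seq) if f.strand == "-" else seq


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O
# ---------------------------------------------------------------------------

_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "gene": "other"}


def _feature_name(sf: SeqFeature) -> str | None:
    for key in ("gene", "locus_tag", "product"):
        if key in sf.qualifiers:
            return normalize_locus(sf.qualifiers[key][0])
    return None


def read_genbank(path) -> GenomeRecord:
    """Parse a GenBank flat file into a GenomeRecord.

    GenBank 1-based inclusive coordinates become 0-based half-open; join()
    locations are preserved as multi-span features; /pseudo is honored.
    """
    try:
        rec = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    seq = str(rec.seq).upper()
    if len(seq) == 0:
        raise ValueError(f"zero-length sequence in {path}")

    feats: list[Feature] = []
    named_spans: set[tuple[str, tuple]] = set()
    deferred_genes: list[Feature] = []
    for sf in rec.features:
        kind = _KIND_MAP.get(sf.type)
        if kind is None:
            continue
        name = _feature_name(sf)
        if name is None:
            continue
        spans = tuple(
            (int(part.start), int(part.end)) for part in sf.location.parts
        )
        strand = "-" if sf.location.strand == -1 else "+"
        feat = Feature(
            locus_name=name,
            kind=kind,
            strand=strand,
            spans=spans,
            pseudo="pseudo" in sf.qualifiers or "pseudogene" in sf.qualifiers,
        )
        if sf.type == "gene":
            deferred_genes.append(feat)
        else:
            feats.append(feat)
            named_spans.add((name, spans))
    # keep a bare `gene` only when no CDS/tRNA/rRNA feature names the same locus
    typed_names = {f.locus_name for f in feats}
    for g in deferred_genes:
        if g.locus_name not in typed_names:
            feats.append(g)
    return GenomeRecord(id=rec.id or rec.name, sequence=seq, features=tuple(feats))


def write_genbank(record: GenomeRecord, path) -> None:
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16].replace(" ", "_"),
        description="",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand=strand) for s, e in f.spans]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = f.kind if f.kind != "other" else "gene"
        quals = {"gene": [f.locus_name]}
        if f.pseudo:
            quals["pseudo"] = [""]
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write(rec, path, "genbank")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def census_table(records: Iterable[GenomeRecord]) -> "pandas.DataFrame":
    """Per-locus census (record_id, locus, kind, strand, start, end, pseudo)."""
    import pandas as pd

    rows = []
    for rec in records:
        for f in rec.features:
            rows.append(
                dict(
                    record_id=rec.id,
                    locus=f.locus_name,
                    kind=f.kind,
                    strand=f.strand,
                    start=f.start,
                    end=f.end,
                    pseudo=f.pseudo,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Quadripartite partitioning
# ---------------------------------------------------------------------------


def partition_regions(record: GenomeRecord, min_ir_len: int = 1000) -> RegionPartition:
    """Detect the IR_A/IR_B pair and label LSC (longer gap) and SSC (shorter gap).

    The IRs are the longest pair of exact reverse-complement duplications of
    length >= min_ir_len with non-overlapping copies.  When rRNA features are
    annotated, a candidate containing the rRNA core is preferred among
    equally long candidates (canonical plastome IRs carry the rRNA operon).
    """
    if min_ir_len < 100:
        raise ValueError("min_ir_len must be >= 100")
    seq = record.sequence
    L = len(seq)
    if L < 2 * min_ir_len:
        return _no_ir_partition(L)

    codes, nxt = encode(seq)
    rc_codes, _ = encode(revcomp(seq), start_symbol=nxt + 1)
    import numpy as np

    s = np.concatenate([codes, np.array([nxt], dtype=np.int64), rc_codes])
    cands = []
    for i, j, ln in maximal_pairs(s, min_ir_len):
        if i < L and j > L:  # one copy forward, one on the reverse strand
            r = j - (L + 1)
            a = (i, i + ln)
            b = (L - r - ln, L - r)
            lo, hi = (a, b) if a[0] <= b[0] else (b, a)
            if lo[1] <= hi[0]:  # non-overlapping copies
                cands.append((ln, lo, hi))
    if not cands:
        return _no_ir_partition(L)

    cands.sort(key=lambda c: (-c[0], c[1][0]))
    best = cands[0]
    rrna_spans = [(f.start, f.end) for f in record.features if f.kind == "rRNA"]
    if rrna_spans:
        def has_rrna(c):
            return any(
                (c[1][0] <= s and e <= c[1][1]) or (c[2][0] <= s and e <= c[2][1])
                for s, e in rrna_spans
            )

        if not has_rrna(best):
            with_rrna = [c for c in cands if has_rrna(c)]
            if with_rrna:
                log.warning(
                    "%s: longest IR candidate lacks the rRNA core; choosing the "
                    "longest rRNA-containing candidate instead",
                    record.id,
                )
                best = with_rrna[0]
    ln, ir_a, ir_b = best
    gap1 = (ir_a[1], ir_b[0])  # between the copies
    gap2_len = (L - ir_b[1]) + ir_a[0]  # wrapping gap
    if gap1[1] - gap1[0] >= gap2_len:
        lsc, ssc = gap1, (ir_b[1], ir_a[0] + L)
    else:
        lsc, ssc = (ir_b[1], ir_a[0] + L), gap1
    # wrap-around interval reported modulo L as (start, end) with end <= L where possible
    lsc = _mod_interval(lsc, L)
    ssc = _mod_interval(ssc, L)
    return RegionPartition(lsc=lsc, ssc=ssc, ir_a=ir_a, ir_b=ir_b, ir_status="both")


def _mod_interval(iv: tuple[int, int], L: int) -> tuple[int, int]:
    s, e = iv
    if s >= L:
        s, e = s - L, e - L
    return (s, e)


def _no_ir_partition(L: int) -> RegionPartition:
    # IR-absent records: the whole sequence is "single copy"; SSC is empty
    return RegionPartition(lsc=(0, L), ssc=(L, L), ir_a=None, ir_b=None, ir_status="none")


def collapse_ir(record: GenomeRecord) -> GenomeRecord:
    """Remove the IR_B copy (the one following SSC in LSC->IR_A->SSC->IR_B order).

    Feature coordinates are remapped; features entirely inside IR_B are
    dropped (their IR_A duplicates remain).  Records without both IRs are
    returned unchanged with a warning.  Idempotent.
    """
    part = record.partition
    if part is None:
        part = partition_regions(record)
    if part.ir_status != "both" or part.ir_b is None:
        if part.ir_status != "none":
            log.warning("%s: collapse_ir is a no-op (ir_status=%s)", record.id, part.ir_status)
        return record
    s, e = part.ir_b
    cut = e - s
    new_seq = record.sequence[:s] + record.sequence[e:]
    new_feats = []
    for f in record.features:
        if f.start >= s and f.end <= e:
            continue  # lives in IR_B; IR_A copy retained
        if f.start < e and f.end > s and not (f.start >= s and f.end <= e):
            log.warning("%s: feature %s straddles IR_B boundary; dropped", record.id, f.locus_name)
            continue
        spans = tuple(
            (st - cut if st >= e else st, en - cut if en > e else en) for st, en in f.spans
        )
        new_feats.append(replace(f, spans=spans))

    def shift(iv):
        if iv is None:
            return None
        a, b = iv
        return (a - cut if a >= e else a, b - cut if b > e else b)

    new_part = RegionPartition(
        lsc=shift(part.lsc),
        ssc=shift(part.ssc),
        ir_a=shift(part.ir_a),
        ir_b=None,
        ir_status="B_lost",
    )
    return GenomeRecord(
        id=record.id, sequence=new_seq, features=tuple(new_feats), partition=new_part
    )


def classify_ir_loss(record: GenomeRecord, reference: GenomeRecord) -> str:
    """Classify a single-IR record as A_lost or B_lost against a quadripartite reference.

    The retained rRNA core is located between its flanking single-copy
    neighbors; if the upstream neighbor is an LSC gene of the reference the
    retained copy occupies the IR_A position (so IR_B was lost), and vice
    versa.
    """
    ref_part = reference.partition or partition_regions(reference)
    if ref_part.ir_status != "both":
        raise ValueError("reference must have both IRs")
    part = record.partition or partition_regions(record)
    if part.ir_status == "both":
        return "both"
    ref_lsc_genes = {
        f.locus_name for f in reference.features if ref_part.region_of(f.start) == "lsc"
    }
    ref_ssc_genes = {
        f.locus_name for f in reference.features if ref_part.region_of(f.start) == "ssc"
    }
    rrnas = [f for f in record.features if f.kind == "rRNA"]
    if not rrnas:
        return "none"
    core_start = min(f.start for f in rrnas)
    upstream = [f for f in record.features if f.end <= core_start and f.kind != "rRNA"]
    for f in reversed(upstream):
        if f.locus_name in ref_lsc_genes:
            return "B_lost"
        if f.locus_name in ref_ssc_genes:
            return "A_lost"
    return "A_lost"


# ---------------------------------------------------------------------------
# Shared single-copy locus orders
# ---------------------------------------------------------------------------


def shared_locus_order(
    records: Sequence[GenomeRecord], reference_id: str
) -> dict[str, list[tuple[str, int]]]:
    """Signed order of loci present exactly once in every record.

    IRs must be collapsed first (multi-copy loci are excluded with a
    warning).  Sign is +1 when the strand matches the reference copy's
    strand, -1 otherwise.
    """
    by_id = {r.id: r for r in records}
    if reference_id not in by_id:
        raise KeyError(f"reference record {reference_id!r} not among inputs")

    counts_per_rec = []
    for rec in records:
        counts: dict[str, int] = {}
        for f in rec.features:
            if not f.pseudo:
                counts[f.locus_name] = counts.get(f.locus_name, 0) + 1
        counts_per_rec.append(counts)
    shared = set(counts_per_rec[0])
    for counts in counts_per_rec[1:]:
        shared &= set(counts)
    single = {g for g in shared if all(c[g] == 1 for c in counts_per_rec)}
    multi = {g for g in shared if any(c[g] > 1 for c in counts_per_rec)}
    if multi:
        log.warning("excluding multi-copy loci: %s", sorted(multi))
    if len(single) < 3:
        raise ValueError(
            f"insufficient shared loci: {len(single)} single-copy loci shared by all records"
        )

    ref_strand = {
        f.locus_name: f.strand for f in by_id[reference_id].features if f.locus_name in single
    }
    out: dict[str, list[tuple[str, int]]] = {}
    for rec in records:
        feats = [f for f in rec.features if f.locus_name in single]
        feats.sort(key=lambda f: f.start)
        out[rec.id] = [
            (f.locus_name, 1 if f.strand == ref_strand[f.locus_name] else -1) for f in feats
        ]
    return out


def locus_coordinates(record: GenomeRecord) -> dict[str, tuple[int, int]]:
    """Map locus name -> (start, end) span for single-copy loci of a record."""
    out: dict[str, tuple[int, int]] = {}
    seen_twice = set()
    for f in record.features:
        if f.locus_name in out:
            seen_twice.add(f.locus_name)
        out[f.locus_name] = (f.start, f.end)
    for name in seen_twice:
        del out[name]
    return out
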