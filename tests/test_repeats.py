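"""Dispersed repeats, the redundancy filter, SSRs and endpoint association."""

import random

import pytest

from plastevol._sa import revcomp
from plastevol.repeats import (
    DispersedRepeat,
    RepeatCopy,
    associate_repeats_with_inversions,
    brute_force_maximal_pairs,
    filter_redundant_repeats,
    find_dispersed_repeats,
    find_maximal_pairs,
    find_ssrs,
    tandem_repeat_count,
)
from plastevol.structure import InversionInterval


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestDispersedRepeats:
    def test_planted_direct_repeat(self):
        rng = random.Random(1)
        bg = random_seq(rng, 3000)
        unit = random_seq(rng, 40)
        seq = bg[:1000] + unit + bg[1000:2000] + unit + bg[2000:]
        fams = find_dispersed_repeats(seq)
        # the family is maximal, so it may extend a little beyond the unit
        planted = [
            f for f in fams
            if f.length >= 40 and (unit in f.sequence or unit in revcomp(f.sequence))
        ]
        assert len(planted) == 1
        assert planted[0].frequency == 2
        assert planted[0].orientation == "direct"

    def test_planted_inverted_repeat(self):
        rng = random.Random(2)
        bg = random_seq(rng, 3000)
        unit = random_seq(rng, 35)
        seq = bg[:800] + unit + bg[800:2200] + revcomp(unit) + bg[2200:]
        fams = find_dispersed_repeats(seq)
        planted = [f for f in fams if f.length >= 35]
        assert len(planted) == 1
        assert planted[0].orientation == "inverted"

    def test_random_sequence_has_no_long_repeats(self):
        rng = random.Random(3)
        seq = random_seq(rng, 10_000)
        assert find_dispersed_repeats(seq) == []
        assert brute_force_maximal_pairs(seq) == []

    def test_mismatch_tolerance_unsupported(self):
        with pytest.raises(NotImplementedError):
            find_dispersed_repeats("ACGT" * 100, max_mismatch=0.1)

    def test_candidate_split_at_ambiguous_base(self):
        rng = random.Random(4)
        bg = random_seq(rng, 2000)
        unit = random_seq(rng, 80)
        broken = unit[:40] + "N" + unit[41:]
        seq = bg[:500] + unit + bg[500:1200] + broken + bg[1200:]
        fams = find_dispersed_repeats(seq)
        # the N splits the second copy: no family may span the ambiguous base
        for fam in fams:
            assert "N" not in fam.sequence

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, seed):
        rng = random.Random(100 + seed)
        L = rng.randint(1500, 4000)
        seq = list(random_seq(rng, L))
        for _ in range(rng.randint(1, 4)):
            ln = rng.randint(30, 60)
            src = rng.randint(0, L - ln)
            dst = rng.randint(0, L - ln)
            unit = "".join(seq[src : src + ln])
            ins = unit if rng.random() < 0.5 else revcomp(unit)
            seq[dst : dst + ln] = ins
        seq = "".join(seq)
        fast = {
            (a.start, a.end, a.strand, b.start, b.end, b.strand, ln)
            for a, b, ln in find_maximal_pairs(seq)
        }
        brute = {
            (a.start, a.end, a.strand, b.start, b.end, b.strand, ln)
            for a, b, ln in brute_force_maximal_pairs(seq)
        }
        assert fast == brute


def _fam(seq_str, starts, strand="+"):
    copies = tuple(RepeatCopy(s, s + len(seq_str), strand) for s in starts)
    return DispersedRepeat(sequence=seq_str, copies=copies)


class TestRedundancyFilter:
    def test_slightly_longer_containing_family_dropped(self):
        short = _fam("A" * 40, (100, 500))
        long_ = _fam("A" * 45, (98, 498))  # 5 bp longer, contains both copies
        kept = filter_redundant_repeats([short, long_])
        assert kept == [short]

    def test_high_frequency_long_family_absorbs_contained(self):
        long_ = _fam("G" * 60, (100, 500, 900))
        short = _fam("G" * 30, (110, 510))
        kept = filter_redundant_repeats([long_, short])
        assert kept == [long_]

    def test_no_containment_keeps_all(self):
        a = _fam("A" * 40, (0, 1000))
        b = _fam("C" * 40, (2000, 3000))
        assert filter_redundant_repeats([a, b]) == [a, b]

    def test_idempotent(self):
        fams = [
            _fam("A" * 40, (100, 500)),
            _fam("A" * 45, (98, 498)),
            _fam("G" * 60, (2000, 2500, 2900)),
            _fam("G" * 30, (2010, 2510)),
        ]
        once = filter_redundant_repeats(fams)
        assert filter_redundant_repeats(once) == once


class TestSSR:
    def test_mono_threshold(self):
        assert [(l.motif, l.n_units) for l in find_ssrs("CGT" + "A" * 10 + "CGTCG")[0]] == [("A", 10)]
        assert find_ssrs("CGT" + "A" * 9 + "CGTCG")[0] == []

    @pytest.mark.parametrize(
        "motif,minimum",
        [("AT", 6), ("ACT", 5), ("ACGT", 5), ("ACGTC", 5), ("ACGTCT", 5)],
    )
    def test_unit_size_thresholds(self, motif, minimum):
        pad = "GG"  # cannot phase-extend any of the test motifs
        hit = pad + motif * minimum + pad
        miss = pad + motif * (minimum - 1) + pad
        assert any(l.motif == motif and l.n_units == minimum for l in find_ssrs(hit)[0])
        assert not any(l.motif == motif for l in find_ssrs(miss)[0])

    def test_non_primitive_motif_reported_once(self):
        # A x 12 must be one mono SSR, not also (AA) x 6
        loci, _ = find_ssrs("CGT" + "A" * 12 + "CGT")
        assert len(loci) == 1 and loci[0].motif == "A"

    def test_maximality(self):
        loci, _ = find_ssrs("C" + "AT" * 7 + "GG")
        (l,) = loci
        assert l.start == 1 and l.n_units == 7

    def test_compound_within_interruption_window(self):
        rng = random.Random(12)
        spacer = random_seq(rng, 50)
        assert find_ssrs(spacer)[0] == []  # precondition: SSR-free spacer
        seq = "G" * 5 + "A" * 10 + spacer + "AT" * 6 + "G" * 5
        loci, compounds = find_ssrs(seq)
        assert len(loci) == 2
        assert len(compounds) == 1 and compounds[0].n_components == 2
        assert tandem_repeat_count(seq) == 2  # compound counted per component

    def test_far_apart_not_compound(self):
        seq = "G" * 5 + "A" * 10 + "C" * 150 + "T" * 10 + "G" * 5
        loci, compounds = find_ssrs(seq)
        assert len(loci) >= 2
        # the separating C run is itself an SSR; ignore chains through it
        mono_at = {l.motif: l for l in loci}
        assert "A" in mono_at and "T" in mono_at


class TestAssociation:
    def test_window_boundary(self):
        inv = InversionInterval(10_000, 20_000)
        near = _fam("A" * 40, (10_000 - 499 - 40,))  # ends 499 bp before start_bp
        far = _fam("C" * 40, (10_000 - 501 - 40,))  # ends 501 bp before start_bp
        far_both = _fam("G" * 40, (15_000,))  # interior copy: overlaps neither endpoint zone?
        hits = associate_repeats_with_inversions([near, far], [inv], window=500)
        assert [h.repeat for h in hits] == [near]
        assert hits[0].endpoint_distances[0] == 499

    def test_overlapping_copy_distance_zero(self):
        inv = InversionInterval(1000, 5000)
        fam = _fam("A" * 40, (990,))
        (hit,) = associate_repeats_with_inversions([fam], [inv], window=500)
        assert hit.endpoint_distances[0] == 0
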