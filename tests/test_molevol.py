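"""Codon model machinery: back-translation, likelihood nesting, LRT, classes."""

import numpy as np
import pytest

from plastevol.molevol import (
    BranchTree,
    CodonAlignment,
    IR_GENES_ANGIOSPERM,
    IR_GENES_GYMNOSPERM,
    MG94Matrix,
    back_translate,
    branch_model_test,
    classify_genes,
    ds_ratio_table,
    f3x4_frequencies,
    fit_codon_model,
    lrt,
    terminal_ds,
)
from plastevol.synthetic_data import simulate_codon_evolution


class TestBackTranslate:
    def test_plain(self):
        out = back_translate({"t": "MK"}, {"t": "ATGAAA"})
        assert out.sequences["t"] == "ATGAAA"

    def test_gap_becomes_triple_dash(self):
        out = back_translate({"t": "M-K"}, {"t": "ATGAAA"})
        assert out.sequences["t"] == "ATG---AAA"

    def test_terminal_stop_dropped(self):
        out = back_translate({"t": "MK"}, {"t": "ATGAAATAA"})
        assert out.sequences["t"] == "ATGAAA"

    def test_translation_mismatch_reports_position(self):
        with pytest.raises(ValueError, match="residue 1"):
            back_translate({"t": "MM"}, {"t": "ATGAAA"})

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="residues"):
            back_translate({"t": "MKL"}, {"t": "ATGAAA"})

    def test_round_trip_on_simulated(self, eight_taxon_tree):
        from Bio.Seq import Seq

        aln, _ = simulate_codon_evolution(eight_taxon_tree, n_codons=50, seed=9)
        prots = {t: str(Seq(s).translate()) for t, s in aln.sequences.items()}
        out = back_translate(prots, aln.sequences)
        assert out.sequences == aln.sequences


class TestMG94Matrix:
    def test_rows_sum_to_zero(self):
        mg = MG94Matrix(f3x4_frequencies(), kappa=2.5)
        Q = mg.q(omega=0.4)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)

    def test_stationary_distribution(self):
        pi = f3x4_frequencies(seqs=["ATGAAACCCGGGTTT" * 10])
        mg = MG94Matrix(pi, kappa=2.0)
        Q = mg.q(omega=0.7)
        assert np.allclose(pi @ Q, 0, atol=1e-12)

    def test_detailed_balance(self):
        pi = f3x4_frequencies()
        Q = MG94Matrix(pi, kappa=3.0).q(omega=0.2)
        F = pi[:, None] * Q
        assert np.allclose(F, F.T, atol=1e-14)

    def test_dn_ds_ratio_equals_omega(self):
        mg = MG94Matrix(f3x4_frequencies(), kappa=2.0)
        for om in (0.1, 0.5, 2.0):
            ds, dn = mg.ds_dn(t=0.3, omega=om)
            assert dn / ds == pytest.approx(om, rel=1e-10)

    def test_gtr_exchangeabilities_accepted(self):
        pi = f3x4_frequencies()
        mg = MG94Matrix(pi, exchangeability=[1.0, 2.0, 0.7, 1.1, 2.4, 1.0])
        Q = mg.q(omega=0.3)
        F = pi[:, None] * Q
        assert np.allclose(F, F.T, atol=1e-14)


class TestFit:
    def test_identical_sequences_zero_rates(self):
        tree = BranchTree.from_newick("(A:0.1,B:0.1);")
        aln = CodonAlignment({"A": "ATGAAACCC" * 20, "B": "ATGAAACCC" * 20})
        res = fit_codon_model(aln, tree, mode="one_ratio")
        for ds, dn, _ in res.per_branch.values():
            assert ds < 1e-4 and dn < 1e-4

    def test_likelihood_nesting(self, eight_taxon_tree):
        aln, _ = simulate_codon_evolution(
            eight_taxon_tree, n_codons=200, omega=0.3, seed=3
        )
        one = fit_codon_model(aln, eight_taxon_tree, mode="one_ratio")
        two = fit_codon_model(
            aln, eight_taxon_tree, mode="two_ratio", foreground=["A", "B"],
            kappa0=one.kappa, omega0=one.omega, init_lengths=one.lengths,
        )
        free = fit_codon_model(
            aln, eight_taxon_tree, mode="free_ratio",
            kappa0=one.kappa, omega0=one.omega, init_lengths=one.lengths,
        )
        assert two.lnL >= one.lnL - 1e-4
        assert free.lnL >= two.lnL - 1e-2

    def test_two_ratio_requires_foreground(self, eight_taxon_tree):
        aln, _ = simulate_codon_evolution(eight_taxon_tree, n_codons=30, seed=4)
        with pytest.raises(ValueError, match="foreground"):
            fit_codon_model(aln, eight_taxon_tree, mode="two_ratio")

    def test_foreground_omega_recovered(self):
        tree = BranchTree.from_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        omega = {e: 0.1 for e in ("A", "B", "C", "D", "node1", "node2")}
        omega["A"] = 1.2
        aln, truth = simulate_codon_evolution(tree, n_codons=1500, omega=omega, seed=5)
        res = fit_codon_model(aln, tree, mode="two_ratio", foreground=["A"])
        assert res.omega_foreground == pytest.approx(1.2, abs=0.35)
        assert res.omega == pytest.approx(0.1, abs=0.05)

    def test_terminal_ds_accessor(self, eight_taxon_tree):
        aln, truth = simulate_codon_evolution(eight_taxon_tree, n_codons=300, seed=6)
        res = fit_codon_model(aln, eight_taxon_tree, mode="one_ratio")
        ds = terminal_ds(res, eight_taxon_tree)
        assert set(ds) == {"A", "B", "C", "D", "E", "F", "G", "H"}
        assert all(v >= 0 for v in ds.values())


class TestLRT:
    def test_equal_likelihoods_give_p_one(self):
        assert lrt(-100.0, -100.0) == pytest.approx(1.0)

    def test_chi2_critical_value(self):
        # 2*delta = 3.841 is the chi2_1 5% critical point
        assert lrt(0.0, 3.841 / 2, df=1) == pytest.approx(0.05, abs=1e-3)

    def test_small_delta_regime(self):
        # 2*delta = 0.27 -> p ~ 0.60, the non-significant regime
        assert lrt(0.0, 0.135, df=1) == pytest.approx(0.603, abs=0.002)

    def test_optimizer_fault_detected(self):
        with pytest.raises(ValueError, match="optimizer"):
            lrt(-50.0, -60.0)


class TestGeneClasses:
    def test_other_hk_and_ps(self):
        assigned = classify_genes(["accD", "rbcL", "clpP", "ccsA"])
        assert assigned["accD"] == "other-HK"
        assert assigned["clpP"] == "other-HK"
        assert assigned["rbcL"] == "other-PS"
        assert assigned["ccsA"] == "other-PS"

    def test_prefix_families(self):
        assigned = classify_genes(["atpA", "ndhF", "psaB", "psbA", "rpl2", "rpoC1", "rps4", "petD", "chlB"])
        assert assigned == {
            "atpA": "atp", "ndhF": "ndh", "psaB": "psa", "psbA": "psb",
            "rpl2": "rpl", "rpoC1": "rpo", "rps4": "rps", "petD": "pet", "chlB": "chl",
        }

    def test_unknown_gene_flagged(self):
        assert classify_genes(["infA"])["infA"] == "unclassified"

    def test_ir_gene_sets_by_lineage(self):
        assert "rpl2" in IR_GENES_ANGIOSPERM
        assert "rpl2" not in IR_GENES_GYMNOSPERM
        assert {"ycf2", "ndhB", "rps12", "rps7"} == set(IR_GENES_GYMNOSPERM)


class TestDsRatios:
    def test_equal_rates_give_unit_ratio(self):
        df = ds_ratio_table({"a": 0.2, "b": 0.05}, {"a": 0.2, "b": 0.05})
        assert (df["ratio"] == 1.0).all()
        assert (df["flag"] == "intermediate").all()

    def test_flag_thresholds(self):
        df = ds_ratio_table(
            {"low": 0.04, "high": 0.8, "mid": 0.2}, {"low": 0.1, "high": 0.2, "mid": 0.2}
        ).set_index("key")
        assert df.loc["low", "flag"] == "IR-like"  # ratio 0.4 < 0.5
        assert df.loc["high", "flag"] == "SC-like"  # ratio 4.0 > 3.7
        assert df.loc["mid", "flag"] == "intermediate"

    def test_zero_denominator_flagged(self):
        df = ds_ratio_table({"a": 0.3}, {"a": 0.0})
        assert df.loc[0, "flag"] == "undefined"
        assert np.isnan(df.loc[0, "ratio"])
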