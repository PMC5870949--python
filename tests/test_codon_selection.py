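"""GY94/F3X4 codon model: frequencies, rate matrix, likelihood, LRT."""

import numpy as np
import pytest

from navdup.codon_selection import (
    CODON_INDEX,
    CodonLikelihood,
    CodonModelParams,
    N_CODONS,
    _EigenQ,
    f3x4_frequencies,
    fit_branch_model,
    foreground_profile_contains,
    gy94_rate_matrix,
    lrt,
    uniform_frequencies,
    _NONSYN,
    _SINGLE,
)
from navdup.sequence_io import CodonAlignment, SENSE_CODONS, read_newick
from navdup.synthetic_data import simulate_multitaxon_codon


class TestF3x4:
    def test_uniform_nucleotide_usage_gives_uniform_codons(self):
        # one codon of each base per position -> uniform position freqs
        aln = CodonAlignment([("a", "AAACCCGGGTTT")])
        freqs = f3x4_frequencies(aln)
        np.testing.assert_allclose(freqs.pi, np.full(N_CODONS, 1 / 61))

    def test_frequencies_sum_to_one_and_concentrate_on_composition(self):
        aln = CodonAlignment([("a", "AAAAAAAAAAAAGGG")])
        freqs = f3x4_frequencies(aln)
        assert freqs.pi.sum() == pytest.approx(1.0)
        assert freqs.pi[CODON_INDEX["AAA"]] == freqs.pi.max()

    def test_hand_computed_product_table(self):
        # two sequences, four codons; count nucleotides by hand per position
        aln = CodonAlignment([("a", "ATGAAA"), ("b", "ATGCCC")])
        # pos1: A,A,A,C ; pos2: T,A,T,C ; pos3: G,A,G,C
        p1 = {"A": 0.75, "C": 0.25, "G": 0.0, "T": 0.0}
        p2 = {"A": 0.25, "C": 0.25, "G": 0.0, "T": 0.5}
        p3 = {"A": 0.25, "C": 0.25, "G": 0.5, "T": 0.0}
        raw = {c: p1[c[0]] * p2[c[1]] * p3[c[2]] for c in SENSE_CODONS}
        total = sum(raw.values())
        freqs = f3x4_frequencies(aln)
        for c in ("ATG", "AAA", "CCC", "ACG"):
            assert freqs.pi[CODON_INDEX[c]] == pytest.approx(raw[c] / total)

    def test_gap_only_position_rejected(self):
        with pytest.raises(ValueError, match="no unambiguous"):
            f3x4_frequencies(CodonAlignment([("a", "---")]))


class TestRateMatrix:
    def test_rows_sum_to_zero(self):
        Q = gy94_rate_matrix(2.0, 0.5, uniform_frequencies())
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        Q = gy94_rate_matrix(2.0, 0.0, uniform_frequencies())
        off = Q[_NONSYN & _SINGLE]
        assert np.all(off == 0.0)

    def test_detailed_balance(self):
        aln = CodonAlignment([("a", "ATGAAACTTGGGTGC"), ("b", "ATGAAGCTCGGATGT")])
        freqs = f3x4_frequencies(aln)
        Q = gy94_rate_matrix(3.1, 0.4, freqs)
        flux = freqs.pi[:, None] * Q
        np.testing.assert_allclose(flux, flux.T, atol=1e-14)

    def test_unit_expected_substitution_rate(self):
        freqs = uniform_frequencies()
        Q = gy94_rate_matrix(2.0, 0.5, freqs)
        assert -np.dot(freqs.pi, np.diag(Q)) == pytest.approx(1.0)

    def test_transition_matrix_rows_sum_to_one_and_stationarity(self):
        freqs = uniform_frequencies()
        eig = _EigenQ(gy94_rate_matrix(2.0, 0.5, freqs), freqs.pi)
        P = eig.expm(0.37)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(freqs.pi @ P, freqs.pi, atol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gy94_rate_matrix(-1.0, 0.5, uniform_frequencies())
        with pytest.raises(ValueError):
            gy94_rate_matrix(2.0, -0.1, uniform_frequencies())


class TestLogLikelihood:
    def test_degenerate_tree_gives_sum_of_log_pi(self, star_tree):
        aln = CodonAlignment([("out", "ATGAAA"), ("p1", "ATGAAA"),
                              ("p2", "ATGAAA")])
        freqs = uniform_frequencies()
        eng = CodonLikelihood(aln, star_tree, freqs=freqs)
        params = CodonModelParams(
            kappa=2.0, omega={"background": 0.3},
            branch_lengths=np.zeros(3), freqs=freqs)
        expected = 2 * np.log(1 / 61)
        assert eng.log_likelihood(params) == pytest.approx(expected)

    def brute_force_star(self, aln, freqs, kappa, omegas, ts):
        """Exhaustive enumeration over the internal state of a 3-taxon
        star tree (independent oracle for the pruning algorithm)."""
        Ps = [
            _EigenQ(gy94_rate_matrix(kappa, w, freqs), freqs.pi).expm(t)
            for w, t in zip(omegas, ts)
        ]
        S = aln.n_codons
        total = 0.0
        for col in range(1, S + 1):
            codons = [CODON_INDEX.get(aln.codon(r, col), -1)
                      for r in range(3)]
            site = 0.0
            for anc in range(N_CODONS):
                term = freqs.pi[anc]
                for P, c in zip(Ps, codons):
                    term *= 1.0 if c < 0 else P[anc, c]
                site += term
            total += np.log(site)
        return total

    def test_pruning_equals_exhaustive_enumeration(self, star_tree,
                                                   tiny_codon_alignment):
        freqs = uniform_frequencies()
        eng = CodonLikelihood(tiny_codon_alignment, star_tree, freqs=freqs)
        # two-ratio: p1 branch foreground; postorder edge order is
        # (out, p1, p2) for this tree
        params = CodonModelParams(
            kappa=2.3, omega={"background": 0.2, "foreground": 1.4},
            branch_lengths=np.array([0.5, 0.15, 0.25]), freqs=freqs)
        omegas = eng.edge_omegas(params.omega)
        expected = self.brute_force_star(
            tiny_codon_alignment, freqs, 2.3, omegas,
            params.branch_lengths)
        got = eng.log_likelihood(params)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_pruning_with_gap_codon_matches_enumeration(self, star_tree):
        aln = CodonAlignment([("out", "ATGAAA"), ("p1", "---AAG"),
                              ("p2", "ATAAAA")])
        freqs = uniform_frequencies()
        eng = CodonLikelihood(aln, star_tree, freqs=freqs)
        params = CodonModelParams(
            kappa=2.0, omega={"background": 0.3},
            branch_lengths=np.array([0.4, 0.2, 0.3]), freqs=freqs)
        expected = self.brute_force_star(
            aln, freqs, 2.0, eng.edge_omegas(params.omega),
            params.branch_lengths)
        assert eng.log_likelihood(params) == pytest.approx(expected, rel=1e-10)

    def test_four_taxon_pruning_equals_double_enumeration(self):
        tree = read_newick("((A:0.2,B:0.3):0.15,(C:0.25,D:0.1):0.05);")
        aln = CodonAlignment([("A", "ATGAAA"), ("B", "ATGAAG"),
                              ("C", "ATAAAA"), ("D", "ATGCAA")])
        freqs = uniform_frequencies()
        eng = CodonLikelihood(aln, tree, freqs=freqs)
        kappa, w = 1.8, 0.35
        # enumeration over the two internal nodes (root has children
        # int1=(A,B) and int2=(C,D))
        eigQ = _EigenQ(gy94_rate_matrix(kappa, w, freqs), freqs.pi)
        t = {"A": 0.2, "B": 0.3, "C": 0.25, "D": 0.1, "i1": 0.15, "i2": 0.05}
        P = {k: eigQ.expm(v) for k, v in t.items()}
        total = 0.0
        for col in range(1, aln.n_codons + 1):
            cod = {rid: CODON_INDEX[aln.codon(i, col)]
                   for i, (rid, _) in enumerate(aln.records)}
            site = 0.0
            for root in range(N_CODONS):
                left = sum(
                    P["i1"][root, x] * P["A"][x, cod["A"]] * P["B"][x, cod["B"]]
                    for x in range(N_CODONS))
                right = sum(
                    P["i2"][root, y] * P["C"][y, cod["C"]] * P["D"][y, cod["D"]]
                    for y in range(N_CODONS))
                site += freqs.pi[root] * left * right
            total += np.log(site)
        # postorder edge order: A, B, (A,B), C, D, (C,D)
        params = CodonModelParams(
            kappa=kappa, omega={"background": w},
            branch_lengths=np.array([0.2, 0.3, 0.15, 0.25, 0.1, 0.05]),
            freqs=freqs)
        assert eng.log_likelihood(params) == pytest.approx(total, rel=1e-8)

    def test_consistent_relabeling_leaves_likelihood_unchanged(self):
        freqs = uniform_frequencies()
        tree1 = read_newick("(out:0.5,p1:0.15,p2:0.15);")
        tree2 = read_newick("(x:0.5,y:0.15,z:0.15);")
        a1 = CodonAlignment([("out", "ATGAAA"), ("p1", "ATGAAG"),
                             ("p2", "ATAAAA")])
        a2 = CodonAlignment([("x", "ATGAAA"), ("y", "ATGAAG"),
                             ("z", "ATAAAA")])
        params = CodonModelParams(
            kappa=2.0, omega={"background": 0.3},
            branch_lengths=np.array([0.5, 0.15, 0.15]), freqs=freqs)
        l1 = CodonLikelihood(a1, tree1, freqs=freqs).log_likelihood(params)
        l2 = CodonLikelihood(a2, tree2, freqs=freqs).log_likelihood(params)
        assert l1 == pytest.approx(l2, rel=1e-12)

    def test_drop_gap_columns_switch(self, star_tree):
        aln = CodonAlignment([("out", "ATGAAA"), ("p1", "---AAG"),
                              ("p2", "ATAAAA")])
        eng_keep = CodonLikelihood(aln, star_tree,
                                   freqs=uniform_frequencies())
        eng_drop = CodonLikelihood(aln, star_tree,
                                   freqs=uniform_frequencies(),
                                   drop_gap_columns=True)
        assert eng_keep.n_sites == 2 and eng_drop.n_sites == 1


class TestFitting:
    def test_two_ratio_never_worse_than_one_ratio(self, star_tree):
        aln = simulate_multitaxon_codon(
            star_tree, 2.0, {"background": 0.2}, 150, seed=5,
            freqs=uniform_frequencies())
        f0 = fit_branch_model(aln, star_tree, model="one_ratio", n_starts=1,
                              freqs=uniform_frequencies())
        f1 = fit_branch_model(aln, star_tree, model="two_ratio", n_starts=1,
                              freqs=uniform_frequencies())
        assert f1.lnl >= f0.lnl - 1e-6

    def test_two_ratio_requires_foreground_flags(self):
        tree = read_newick("(out:0.5,p1:0.15,p2:0.15);")
        aln = CodonAlignment([("out", "ATGAAA"), ("p1", "ATGAAG"),
                              ("p2", "ATAAAA")])
        with pytest.raises(ValueError, match="foreground"):
            fit_branch_model(aln, tree, model="two_ratio")

    def test_parameter_recovery_on_simulated_data(self, star_tree):
        freqs = uniform_frequencies()
        aln = simulate_multitaxon_codon(
            star_tree, kappa=2.0,
            omega={"background": 0.09, "foreground": 1.58},
            n_codons=1800, seed=11, freqs=freqs)
        fit = fit_branch_model(aln, star_tree, model="two_ratio",
                               n_starts=2, seed=0, freqs=freqs)
        assert fit.converged
        assert fit.omega_background == pytest.approx(0.09, abs=0.03)
        assert fit.omega_foreground == pytest.approx(1.58, rel=0.35)
        assert foreground_profile_contains(aln, star_tree, fit, 1.58)

    def test_branch_length_recovery_within_ten_percent(self, star_tree):
        # averaged over replicates: per-replicate scatter at 1,000 codons
        # is itself ~7% Monte-Carlo error on the long branch
        freqs = uniform_frequencies()
        estimates = []
        for seed in (0, 1, 2, 3, 4):
            aln = simulate_multitaxon_codon(
                star_tree, 2.0, {"background": 0.2}, 1000, seed=seed,
                freqs=freqs)
            fit = fit_branch_model(aln, star_tree, model="one_ratio",
                                   n_starts=1, freqs=freqs)
            estimates.append(dict(zip(fit.edge_labels,
                                      fit.params.branch_lengths)))
        true_t = {"out": 0.5, "p1": 0.15, "p2": 0.15}
        for label, truth in true_t.items():
            mean_est = np.mean([e[label] for e in estimates])
            assert mean_est == pytest.approx(truth, rel=0.10)

    def test_fix_branch_lengths_keeps_tree_values(self, star_tree):
        freqs = uniform_frequencies()
        aln = simulate_multitaxon_codon(
            star_tree, 2.0, {"background": 0.2}, 200, seed=8, freqs=freqs)
        fit = fit_branch_model(aln, star_tree, model="one_ratio",
                               n_starts=1, freqs=freqs,
                               fix_branch_lengths=True)
        np.testing.assert_allclose(
            sorted(fit.params.branch_lengths), sorted([0.15, 0.15, 0.5]))


class TestLrt:
    class F:
        def __init__(self, lnl):
            self.lnl = lnl

    def test_paper_scale_statistic_is_highly_significant(self):
        res = lrt(self.F(-10000.0), self.F(-10000.0 + 38.8 / 2), df=1)
        assert res.statistic == pytest.approx(38.8)
        assert res.p_value < 1e-4

    def test_equal_likelihoods_give_zero_statistic(self):
        res = lrt(self.F(-50.0), self.F(-50.0))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_worse_alternative_warns_and_clips(self):
        with pytest.warns(UserWarning, match="refit"):
            res = lrt(self.F(-50.0), self.F(-51.0))
        assert res.statistic == 0.0
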