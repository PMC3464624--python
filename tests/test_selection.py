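"""GY94 likelihood, model fits, sliding windows, composition diagnostic."""

import itertools

import numpy as np
import pytest

from copyevol import codon as cd
from copyevol.selection import (CodonAlignment, GY94Likelihood,
                                compare_models, composition_chisq,
                                fit_branch_class_model, gy94_loglik,
                                sliding_window_dnds, split_within_label)
from copyevol.simulate import CodonSimConfig, simulate_codon_alignment
from copyevol.trees import LabeledTree


def _three_taxon_tree(lengths=(0.2, 0.3, 0.25, 0.15), labels=("w", "w", "b", "w")):
    tree = LabeledTree()
    root = tree.add_node(name="root")
    inner = tree.add_node(parent=root, length=lengths[2], label=labels[2])
    tree.add_node(name="A", parent=inner, length=lengths[0], label=labels[0])
    tree.add_node(name="B", parent=inner, length=lengths[1], label=labels[1])
    tree.add_node(name="C", parent=root, length=lengths[3], label=labels[3])
    return tree


def _brute_force_loglik(aln, tree, kappa, omega_by_label, pi):
    """Oracle: sum over all internal-state assignments (61^2 for the
    rooted 3-taxon tree) per column."""
    P = {}
    for idx in tree.postorder():
        if idx == tree.root:
            continue
        node = tree.nodes[idx]
        Q = cd.gy94_rate_matrix(kappa, omega_by_label[node.label], pi)
        P[idx] = cd.ReversibleTransition(Q, pi).probability_matrix(node.length)
    name_to_idx = {tree.nodes[i].name: i for i in tree.leaves}
    inner = [i for i in range(len(tree.nodes))
             if i != tree.root and not tree.is_leaf(i)][0]
    iA, iB, iC = name_to_idx["A"], name_to_idx["B"], name_to_idx["C"]
    total = 0.0
    mat = {n: cd.codon_indices(aln[n]) for n in aln}
    for col in range(len(mat["A"])):
        a, b, c = mat["A"][col], mat["B"][col], mat["C"][col]
        s = 0.0
        for r, v in itertools.product(range(61), range(61)):
            term = pi[r] * P[inner][r, v] * P[iA][v, a] * P[iB][v, b] \
                * P[iC][r, c]
            s += term
        total += np.log(s)
    return total


class TestGY94Loglik:
    def test_matches_enumeration_oracle(self):
        tree = _three_taxon_tree()
        pi = np.full(61, 1 / 61)
        cfg = CodonSimConfig(n_codons=10, omega_by_branch_class={"w": 0.1,
                                                                 "b": 0.8},
                             codon_frequencies=pi, seed=1)
        aln = simulate_codon_alignment(tree, cfg)
        omega = {"w": 0.1, "b": 0.8}
        fast = gy94_loglik(aln, tree, kappa=2.0, omega_by_label=omega, pi=pi)
        slow = _brute_force_loglik(aln, tree, 2.0, omega, pi)
        assert fast == pytest.approx(slow, abs=1e-8)

    def test_single_taxon_is_log_pi(self):
        tree = LabeledTree()
        tree.add_node(name="A")
        pi = np.full(61, 1 / 61)
        seq = "ATGGCT"
        lnl = gy94_loglik({"A": seq}, tree, kappa=2.0,
                          omega_by_label={}, pi=pi)
        idx = cd.codon_indices(seq)
        assert lnl == pytest.approx(np.log(pi[idx]).sum())

    def test_zero_branch_lengths_identical_sequences(self):
        tree = _three_taxon_tree(lengths=(0, 0, 0, 0))
        pi = np.full(61, 1 / 61)
        seq = "ATGGCTAAACCC"
        aln = {n: seq for n in "ABC"}
        lnl = gy94_loglik(aln, tree, kappa=2.0,
                          omega_by_label={"w": 0.2, "b": 0.2}, pi=pi)
        assert lnl == pytest.approx(np.log(pi[cd.codon_indices(seq)]).sum())

    def test_taxon_order_invariance(self):
        tree = _three_taxon_tree()
        pi = np.full(61, 1 / 61)
        cfg = CodonSimConfig(n_codons=40, omega_by_branch_class={"w": 0.1,
                                                                 "b": 0.5},
                             codon_frequencies=pi, seed=2)
        aln = simulate_codon_alignment(tree, cfg)
        omega = {"w": 0.1, "b": 0.5}
        a = gy94_loglik(aln, tree, 2.0, omega, pi)
        shuffled = dict(reversed(list(aln.items())))
        b = gy94_loglik(shuffled, tree, 2.0, omega, pi)
        assert a == pytest.approx(b, abs=1e-8)

    def test_deterministic_across_runs(self):
        tree = _three_taxon_tree()
        pi = np.full(61, 1 / 61)
        aln = simulate_codon_alignment(
            tree, CodonSimConfig(n_codons=30,
                                 omega_by_branch_class={"w": 0.2, "b": 0.2},
                                 codon_frequencies=pi, seed=3))
        vals = {gy94_loglik(aln, tree, 1.9, {"w": 0.2, "b": 0.3}, pi)
                for _ in range(5)}
        assert len(vals) == 1

    def test_ambiguous_codons_partial_likelihood(self):
        tree = _three_taxon_tree()
        pi = np.full(61, 1 / 61)
        aln = {"A": "ATGNNN", "B": "ATGAAA", "C": "ATGAAA"}
        lnl = gy94_loglik(aln, tree, 2.0, {"w": 0.2, "b": 0.2}, pi)
        assert np.isfinite(lnl)


@pytest.fixture(scope="module")
def simulated():
    from copyevol.simulate import branch_class_tree
    tree = branch_class_tree()
    pi = np.full(61, 1 / 61)
    cfg = CodonSimConfig(
        n_codons=1200,
        omega_by_branch_class={"within": 0.05, "between": 0.05},
        codon_frequencies=pi, seed=8)
    return CodonAlignment(simulate_codon_alignment(tree, cfg)), tree, pi


class TestModelFits:
    def test_aic_definition(self, simulated):
        aln, tree, pi = simulated
        fit = fit_branch_class_model(aln, tree, scheme="one-ratio", pi=pi,
                                     compute_se=False, starts=(0.1,))
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.lnl)
        assert fit.k == 1

    def test_nested_model_lnl_ordering(self, simulated):
        aln, tree, pi = simulated
        f1 = fit_branch_class_model(aln, tree, scheme="one-ratio", pi=pi,
                                    compute_se=False, starts=(0.1,))
        f2 = fit_branch_class_model(aln, tree, scheme="by-label", pi=pi,
                                    compute_se=False, starts=(0.1,))
        assert f2.lnl >= f1.lnl - 1e-6
        assert f2.k == 2

    def test_one_ratio_data_extra_omega_agrees(self, simulated):
        """Data generated under a single ratio: the two-ratio fit's omegas
        coincide (|difference| small)."""
        aln, tree, pi = simulated
        f2 = fit_branch_class_model(aln, tree, scheme="by-label", pi=pi,
                                    compute_se=False, starts=(0.1,))
        w = f2.estimates
        assert abs(w["omega_within"] - w["omega_between"]) < 0.05

    def test_standard_errors_finite(self, simulated):
        aln, tree, pi = simulated
        fit = fit_branch_class_model(aln, tree, scheme="one-ratio", pi=pi,
                                     compute_se=True, starts=(0.1,))
        assert np.isfinite(fit.se["omega"])
        assert fit.se["omega"] < fit.estimates["omega"]

    def test_split_within_label(self):
        from copyevol.simulate import branch_class_tree
        tree = branch_class_tree(n_classes=2, types_per_class=2)
        relabeled = split_within_label(tree, {"c1t1", "c1t2"},
                                       within_label="within",
                                       new_label="within1")
        assert "within1" in relabeled.branch_labels
        labels = [n.label for i, n in enumerate(relabeled.nodes)
                  if i != relabeled.root and relabeled.is_leaf(i)]
        assert labels.count("within1") == 2


class TestCompareModels:
    def test_table3_aic_ranking(self):
        from copyevol.selection import ModelFit
        fits = [
            ModelFit("m1", lnl=-15025, k=1, estimates={}, se={},
                     converged=True, n_starts=1),
            ModelFit("m2", lnl=-15000, k=2, estimates={}, se={},
                     converged=True, n_starts=1),
            ModelFit("m3", lnl=-14989, k=3, estimates={}, se={},
                     converged=True, n_starts=1),
        ]
        table = compare_models(fits)
        assert table["aic"].tolist() == [29984, 30004, 30052]
        assert table["delta_aic"].tolist() == [0, 20, 68]
        assert table.iloc[0]["model"] == "m3"

    def test_single_fit_errors(self):
        from copyevol.selection import ModelFit
        with pytest.raises(ValueError):
            compare_models([ModelFit("m", -1, 1, {}, {}, True, 1)])

    def test_tie_breaks_to_fewer_parameters(self):
        from copyevol.selection import ModelFit
        fits = [ModelFit("big", -10, 3, {}, {}, True, 1),
                ModelFit("small", -12, 1, {}, {}, True, 1)]
        table = compare_models(fits)
        assert table.iloc[0]["model"] == "small"


class TestSlidingWindow:
    def test_identical_groups_error(self):
        aln = {"a": "ATGGCTAAA" * 10, "b": "ATGGCTAAA" * 10}
        with pytest.raises(ValueError):
            sliding_window_dnds(aln, {"a": 1, "b": 1})

    def test_identical_sequences_undefined_windows(self):
        aln = {"a": "ATGGCTAAA" * 10, "b": "ATGGCTAAA" * 10}
        out = sliding_window_dnds(aln, {"a": 1, "b": 2}, window=5, step=2)
        assert out["undefined"].all()
        assert (out["mean_dn"].fillna(0) == 0).all()

    def test_degenerate_window_equals_global(self):
        rng = np.random.default_rng(4)
        sense = list(cd.SENSE_CODONS)
        a = "".join(rng.choice(sense, 30))
        b = "".join(c if rng.random() < 0.7 else str(rng.choice(sense))
                    for c in [a[i:i + 3] for i in range(0, len(a), 3)])
        out = sliding_window_dnds({"a": a, "b": b}, {"a": 1, "b": 2},
                                  window=30, step=5)
        assert len(out) == 1
        r = cd.ng86_pairwise(a, b)
        if not r.undefined:
            assert out.iloc[0]["mean_dn"] == pytest.approx(r.dn, abs=1e-10)
            assert out.iloc[0]["mean_ds"] == pytest.approx(r.ds, abs=1e-10)

    def test_high_omega_block_ranks_highest(self):
        tree = LabeledTree()
        root = tree.add_node(name="root")
        tree.add_node(name="a", parent=root, length=0.4, label="x")
        tree.add_node(name="b", parent=root, length=0.4, label="x")
        cfg = CodonSimConfig(
            n_codons=300, seed=6,
            site_classes=[(1 / 3, {"x": 0.02}), (1 / 3, {"x": 3.0}),
                          (1 / 3, {"x": 0.02})])
        aln = simulate_codon_alignment(tree, cfg)
        out = sliding_window_dnds(aln, {"a": 1, "b": 2}, window=15, step=5)
        ok = out.dropna(subset=["dnds"])
        top = ok.sort_values("dnds", ascending=False).head(5)
        # the elevated block spans codons 100-200
        mids = (top["start_codon"] + top["end_codon"]) / 2
        assert (mids.between(90, 210)).mean() >= 0.8


class TestCompositionChisq:
    def test_identical_composition_zero_statistic(self):
        seqs = {"a": "ACGT" * 50, "b": "TGCA" * 50, "c": "GTCA" * 50}
        stat, p = composition_chisq(seqs, n_sim=50, seed=1)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p > 0.5

    def test_skewed_sequence_detected(self):
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("ACGT"), 600))
        seqs = {f"s{i}": base for i in range(4)}
        seqs["skewed"] = "G" * 300 + "C" * 300
        stat, p = composition_chisq(seqs, n_sim=200, seed=3)
        assert p < 0.01

    def test_homogeneous_calibration(self):
        """Sequences simulated under a homogeneous process: rejection rate
        at alpha = 0.05 stays near nominal."""
        tree = LabeledTree()
        root = tree.add_node(name="root")
        for n in ("a", "b", "c", "d"):
            tree.add_node(name=n, parent=root, length=0.2, label="x")
        rejected = 0
        trials = 40
        for seed in range(trials):
            aln = simulate_codon_alignment(
                tree, CodonSimConfig(n_codons=120,
                                     omega_by_branch_class={"x": 0.5},
                                     seed=seed))
            _, p = composition_chisq(aln, n_sim=99, seed=seed + 1000)
            rejected += p <= 0.05
        assert 0 <= rejected / trials <= 0.15

    def test_paper_scale_statistic_is_large_for_heterogeneous_data(self):
        # heterogeneous composition in long sequences gives a chi-sq in the
        # hundreds-to-thousands range, the regime reported for real data
        rng = np.random.default_rng(7)
        seqs = {}
        for i in range(20):
            p = np.array([0.25, 0.25, 0.25, 0.25])
            p = p + (rng.random(4) - 0.5) * 0.15
            p = p / p.sum()
            seqs[f"s{i}"] = "".join(rng.choice(list("ACGT"), 1200, p=p))
        stat, pval = composition_chisq(seqs, n_sim=30, seed=8)
        assert stat > 100
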