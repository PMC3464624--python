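"""Synthetic-data generator: configs, truth bookkeeping, clone libraries."""

import warnings

import numpy as np
import pytest
from scipy import stats

from copyevol.alignment import pairwise_difference
from copyevol.simulate import (CloneSimConfig, CodonSimConfig,
                               FamilySimConfig, simulate_clone_library,
                               simulate_codon_alignment, simulate_family,
                               simulate_region_annotation)


class TestConfigs:
    def test_family_invariants(self):
        with pytest.raises(ValueError):
            FamilySimConfig(pair_divergence=1.5)
        with pytest.raises(ValueError):
            FamilySimConfig(n_classes=9, copy_types_per_species=8)
        with pytest.raises(ValueError):
            FamilySimConfig(intron_length_range=(2, 10))

    def test_low_type_divergence_warns(self):
        with pytest.warns(UserWarning):
            FamilySimConfig(between_type_divergence=0.05)

    def test_clone_invariants(self):
        with pytest.raises(ValueError):
            CloneSimConfig(clones_per_sample=0)
        with pytest.raises(ValueError):
            CloneSimConfig(per_base_error=0.2)

    def test_codon_frequencies_validated(self):
        with pytest.raises(ValueError):
            CodonSimConfig(codon_frequencies=np.ones(61))
        with pytest.raises(ValueError):
            CodonSimConfig(codon_frequencies=np.ones(64) / 64)


class TestSimulateFamily:
    def test_no_losses_full_copy_count(self, small_family):
        copies, truth, _ = small_family
        for sp in truth.species:
            assert len(truth.copies_of(sp)) == 16  # 2 x copy_types

    def test_pair_partners_near_identical(self, small_family):
        _, truth, _ = small_family
        t = truth.copies["sp1_type1a"]
        partner = truth.copies[t.partner_id]
        assert partner.partner_id == t.copy_id
        d = pairwise_difference(t.genomic, partner.genomic)
        assert d < 0.03

    def test_copy_types_divergent(self, small_family):
        _, truth, _ = small_family
        a = truth.copies["sp1_type1a"].cds
        b = truth.copies["sp1_type6a"].cds  # same class, different type
        assert pairwise_difference(a, b) > 0.05

    def test_zero_pair_divergence_identical_partners(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            copies, truth, _ = simulate_family(
                FamilySimConfig(n_species=1, pair_divergence=0.0, seed=3))
        t = truth.copies["sp1_type2a"]
        assert copies[t.copy_id] == copies[t.partner_id]

    def test_truth_patterns_match_catalogue(self, small_family):
        _, truth, _ = small_family
        n_sites = len(truth.catalogue)
        patterns = {t.pattern for t in truth.copies.values()}
        assert all(len(p) == n_sites for p in patterns)
        assert len(patterns) == 8
        assert len({t.class_label for t in truth.copies.values()}) == 5
        # every site is used by at least one class
        assert np.vstack(sorted(patterns)).max(axis=0).min() == 1

    def test_losses_reduce_copy_count(self):
        copies, truth, tree = simulate_family(
            FamilySimConfig(n_species=2, loss_probability=0.4, seed=9))
        assert len(copies) < 64
        assert set(tree.leaf_names) == set(copies)

    def test_tree_covers_copies_with_labels(self, small_family):
        copies, truth, tree = small_family
        assert set(tree.leaf_names) == set(copies)
        assert tree.branch_labels == {"within", "between"}

    def test_low_pair_divergence_warns_against_collapse(self):
        with pytest.warns(UserWarning, match="collapse"):
            simulate_family(FamilySimConfig(n_species=1, pair_divergence=0.005,
                                            seed=0))

    def test_intron_lengths_in_configured_ranges(self, small_family):
        _, truth, _ = small_family
        t = truth.copies["sp1_type1a"]
        # reconstruct intron lengths from genomic vs cds length difference
        total = len(t.genomic) - len(t.cds)
        assert total > 0


class TestSimulateCloneLibrary:
    def test_zero_error_clones_equal_sources(self, small_family):
        copies, truth, _ = small_family
        sp1 = {c: truth.copies[c].genomic for c in truth.copies_of("sp1")}
        lib, mapping = simulate_clone_library(
            sp1, CloneSimConfig(clones_per_sample=30, per_base_error=0.0,
                                seed=1), sample_id="sp1")
        assert len(lib) == 30
        for cid, seq in lib.records:
            assert seq == sp1[mapping[cid]]

    def test_truth_mapping_total_and_single_valued(self, small_libraries):
        libs, mapping = small_libraries
        for lib in libs.values():
            for cid, _ in lib.records:
                assert cid in mapping

    def test_error_rate_matches_expectation(self, small_family):
        copies, truth, _ = small_family
        src = {"only": truth.copies["sp1_type1a"].genomic}
        L = len(src["only"])
        rate = 35 / 9000
        lib, mapping = simulate_clone_library(
            src, CloneSimConfig(clones_per_sample=400, per_base_error=rate,
                                seed=2))
        dists = [sum(a != b for a, b in zip(seq, src["only"]))
                 for _, seq in lib.records]
        mean = np.mean(dists)
        se = np.std(dists, ddof=1) / np.sqrt(len(dists))
        assert abs(mean - L * rate) < 3 * se + 1e-9

    def test_large_concentration_near_uniform(self, small_family):
        """With a huge Dirichlet concentration copy sampling approaches
        uniform (chi-square GOF not rejected at alpha=0.01 in most seeds)."""
        copies, truth, _ = small_family
        sp1 = {c: truth.copies[c].genomic for c in truth.copies_of("sp1")}
        k = len(sp1)
        not_rejected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            lib, mapping = simulate_clone_library(
                sp1, CloneSimConfig(clones_per_sample=320,
                                    abundance_concentration=1e7,
                                    per_base_error=0.0, seed=seed))
            counts = np.bincount(
                [sorted(sp1).index(mapping[cid]) for cid, _ in lib.records],
                minlength=k)
            p = stats.chisquare(counts).pvalue
            not_rejected += p > 0.01
        assert not_rejected >= n_seeds - 1

    def test_empty_copies_error(self):
        with pytest.raises(ValueError):
            simulate_clone_library({}, CloneSimConfig())


class TestCodonAlignmentSim:
    def test_zero_branch_lengths_identical(self):
        from copyevol.trees import LabeledTree
        tree = LabeledTree()
        root = tree.add_node(name="root")
        for n in "abc":
            tree.add_node(name=n, parent=root, length=0.0, label="x")
        aln = simulate_codon_alignment(
            tree, CodonSimConfig(n_codons=50,
                                 omega_by_branch_class={"x": 0.5}, seed=4))
        assert len(set(aln.values())) == 1

    def test_no_stop_codons(self, small_family):
        from copyevol.codon import STOP_CODONS
        _, truth, _ = small_family
        for t in list(truth.copies.values())[:4]:
            codons = {t.cds[i:i + 3] for i in range(0, len(t.cds), 3)}
            assert not codons & set(STOP_CODONS)

    def test_unknown_branch_label_fatal(self):
        from copyevol.trees import LabeledTree
        tree = LabeledTree()
        root = tree.add_node(name="root")
        tree.add_node(name="a", parent=root, length=0.1, label="mystery")
        tree.add_node(name="b", parent=root, length=0.1, label="x")
        with pytest.raises(ValueError, match="mystery"):
            simulate_codon_alignment(
                tree, CodonSimConfig(omega_by_branch_class={"x": 0.5}))

    def test_site_classes_partition_codons(self):
        from copyevol.trees import LabeledTree
        tree = LabeledTree()
        root = tree.add_node(name="root")
        tree.add_node(name="a", parent=root, length=0.3, label="x")
        tree.add_node(name="b", parent=root, length=0.3, label="x")
        cfg = CodonSimConfig(
            n_codons=300, seed=5,
            site_classes=[(0.5, {"x": 0.0001}), (0.5, {"x": 2.0})])
        aln = simulate_codon_alignment(tree, cfg)
        assert all(len(s) == 900 for s in aln.values())
        from copyevol.codon import ng86_pairwise
        left = ng86_pairwise(aln["a"][:450], aln["b"][:450])
        right = ng86_pairwise(aln["a"][450:], aln["b"][450:])
        assert left.nonsyn_diffs < right.nonsyn_diffs


class TestRegionAnnotation:
    def test_functional_regions_avoid_divergent_sites(self, small_family):
        _, truth, _ = small_family
        regions = simulate_region_annotation(truth, seed=1)
        func = regions[regions["category"] == "functional"]
        div = set(truth.divergent_sites)
        for _, row in func.iterrows():
            covered = set(range(int(row["start"]) - 1, int(row["end"])))
            assert not covered & div

    def test_categories_valid(self, small_family):
        _, truth, _ = small_family
        regions = simulate_region_annotation(truth, seed=1)
        assert set(regions["category"]) == {"structural", "functional"}
        assert (regions["start"] >= 1).all()
        assert (regions["end"] >= regions["start"]).all()
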