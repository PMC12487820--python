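import numpy as np
import pandas as pd
import pytest

import treede as td
from treede.simulate import LOW_SIGNAL_FC, _largest_remainder


class TestDesign:
    def test_gene_class_counts_exact(self):
        design = td.SimDesign(n_genes=1000, seed=3)
        truth = td.make_design(design)
        from collections import Counter
        c = Counter(truth.genes.values())
        assert c["null"] == 800
        assert c["all_de"] == 100
        assert c["one_de"] == 100

    def test_largest_remainder_sums_and_rounds(self):
        assert _largest_remainder(10, (0.8, 0.1, 0.1)) == [8, 1, 1]
        assert _largest_remainder(7, (0.8, 0.1, 0.1)) == [6, 1, 0] or \
            sum(_largest_remainder(7, (0.8, 0.1, 0.1))) == 7
        for n in (1, 3, 48, 99):
            sizes = _largest_remainder(n, (0.8, 0.1, 0.1))
            assert sum(sizes) == n
            assert all(s >= 0 for s in sizes)

    def test_null_design_has_unit_fold_changes(self):
        truth = td.make_design(td.SimDesign(n_genes=50, null=True, seed=1))
        assert (truth.transcripts["fold_change"] == 1.0).all()
        assert not truth.transcripts["de"].any()
        assert truth.de_transcripts == []

    def test_fold_changes_within_range(self):
        truth = td.make_design(td.SimDesign(n_genes=300, seed=5))
        fc = truth.transcripts.loc[truth.transcripts["de"], "fold_change"]
        mag = np.maximum(fc, 1 / fc)
        assert len(fc) > 0
        assert (mag >= 2.0).all() and (mag <= 6.0).all()
        # both directions occur
        assert (fc > 1).any() and (fc < 1).any()

    def test_low_signal_range_bound(self):
        design = td.SimDesign(n_genes=300, fc_range=LOW_SIGNAL_FC, seed=6)
        truth = td.make_design(design)
        fc = truth.transcripts.loc[truth.transcripts["de"], "fold_change"]
        mag = np.maximum(fc, 1 / fc)
        assert (np.log2(mag) <= np.log2(2.8) + 1e-12).all()
        assert (mag >= 1.4).all()

    def test_one_de_gene_flags_highest_expressed_transcript(self):
        truth = td.make_design(td.SimDesign(n_genes=200, seed=7))
        for gene, cls in truth.genes.items():
            txps = truth.gene_map[gene]
            sub = truth.transcripts.loc[txps]
            if cls == "one_de" and len(txps) > 1:
                assert sub["de"].sum() <= 1
                if sub["de"].any():
                    assert sub["de"].idxmax() == sub["baseline_mean"].idxmax()
            elif cls == "all_de":
                assert sub["de"].all()
                assert sub["fold_change"].nunique() == 1

    def test_transcripts_per_gene_range(self):
        truth = td.make_design(td.SimDesign(
            n_genes=100, transcripts_per_gene=(2, 4), seed=8))
        sizes = {len(v) for v in truth.gene_map.values()}
        assert sizes <= {2, 3, 4}

    def test_design_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            td.SimDesign(frac_null=0.5, frac_all_de=0.1, frac_one_de=0.1)
        with pytest.raises(ValueError, match="fc_range"):
            td.SimDesign(fc_range=(0.9, 2.0))
        with pytest.raises(ValueError, match="uncertainty"):
            td.SimDesign(uncertainty=1.5)
        with pytest.raises(ValueError, match="transcripts_per_gene"):
            td.SimDesign(transcripts_per_gene=(3, 2))


class TestCounts:
    def test_shape_and_labels(self):
        design = td.SimDesign(n_genes=20, seed=2)
        truth = td.make_design(design)
        counts = td.simulate_counts(truth, design)
        assert counts.shape == (12, len(truth.transcripts))
        assert list(counts.index) == td.simulate.sample_ids(design)
        assert list(td.simulate.condition_labels(design)) == \
            ["c1"] * 6 + ["c2"] * 6

    def test_group_means_track_fold_change(self):
        # FC=4 with low dispersion: empirical group ratio lands near 4
        rng = np.random.default_rng(11)
        base = np.exp(rng.normal(6, 0.3, size=50))
        df = pd.DataFrame({
            "gene": [f"g{i}" for i in range(50)],
            "baseline_mean": base,
            "fold_change": 4.0,
            "de": True,
        }, index=[f"t{i}" for i in range(50)])
        truth = td.SimTruth(df, {f"g{i}": "all_de" for i in range(50)},
                            {f"g{i}": [f"t{i}"] for i in range(50)})
        design = td.SimDesign(n_genes=50, n_per_group=30, disp_b=0.001, seed=11)
        counts = td.simulate_counts(truth, design, rng)
        ratio = counts.iloc[30:].mean() / counts.iloc[:30].mean()
        assert ratio.median() == pytest.approx(4.0, rel=0.25)
        assert ((ratio > 3.0) & (ratio < 5.0)).mean() > 0.9

    def test_lib_size_scales_means(self):
        design = td.SimDesign(n_genes=100, seed=4, null=True)
        truth = td.make_design(design)
        small = td.simulate_counts(truth, design,
                                   np.random.default_rng(0))
        big_design = td.SimDesign(n_genes=100, seed=4, null=True, lib_size=10.0)
        big = td.simulate_counts(truth, big_design, np.random.default_rng(0))
        assert big.values.sum() / small.values.sum() == pytest.approx(10.0, rel=0.05)


class TestReplicates:
    def _setup(self, uncertainty, seed=0, n_genes=30, **kw):
        design = td.SimDesign(n_genes=n_genes, n_replicates=30, seed=seed,
                              uncertainty=uncertainty, **kw)
        rng = np.random.default_rng(seed)
        truth = td.make_design(design, rng)
        counts = td.simulate_counts(truth, design, rng)
        tensor = td.simulate_replicates(counts, truth.gene_map,
                                        uncertainty, design, rng)
        return design, truth, counts, tensor

    def test_gene_totals_conserved_every_replicate(self):
        design, truth, counts, tensor = self._setup(0.7, seed=3)
        col = {t: j for j, t in enumerate(tensor.feature_ids)}
        for gene, txps in truth.gene_map.items():
            cols = [col[t] for t in txps]
            true_total = counts[txps].to_numpy().sum(axis=1)
            rep_totals = tensor.counts[:, cols, :].sum(axis=1)
            np.testing.assert_allclose(
                rep_totals,
                np.broadcast_to(true_total[:, None], rep_totals.shape),
                atol=1e-9)

    def test_zero_uncertainty_gives_identical_replicates(self):
        design, truth, counts, tensor = self._setup(0.0, seed=5)
        np.testing.assert_allclose(
            tensor.counts,
            np.broadcast_to(tensor.counts[:, :, :1], tensor.counts.shape))
        np.testing.assert_allclose(tensor.point, counts.to_numpy())

    def test_point_estimate_is_replicate_mean(self):
        design, truth, counts, tensor = self._setup(0.5, seed=6)
        np.testing.assert_allclose(tensor.point, tensor.counts.mean(axis=2))

    def test_uncertain_leaves_versus_stable_parent(self):
        # one two-transcript gene at full ambiguity: leaves have inflated
        # infRV while their aggregate sits at the floor
        counts = pd.DataFrame(
            [[400.0, 200.0]] * 6, columns=["t1", "t2"],
            index=[f"s{i}" for i in range(6)])
        design = td.SimDesign(n_genes=1, n_replicates=50, seed=9)
        tensor = td.simulate_replicates(counts, {"g1": ["t1", "t2"]},
                                        1.0, design, np.random.default_rng(9))
        tree = td.from_nested(("t1", "t2"))
        mirv = td.mean_infrv(tensor, tree)
        leaf_vals = [mirv[int(v)] for v in tree.leaves]
        assert mirv[tree.root] == pytest.approx(0.01)
        assert min(leaf_vals) > 0.4

    def test_singleton_genes_untouched(self):
        design, truth, counts, tensor = self._setup(
            0.9, seed=8, transcripts_per_gene=(1, 1))
        np.testing.assert_allclose(
            tensor.counts,
            np.broadcast_to(counts.to_numpy()[:, :, None],
                            tensor.counts.shape))


class TestFixtureTree:
    def test_anticorrelated_pair_merges_first(self):
        # genes g1 (ambiguous pair) and g2 (independent pair): only the
        # ambiguous pair should be merged below the root
        counts = pd.DataFrame(
            [[300.0, 300.0, 300.0, 300.0]] * 6,
            columns=["a1", "a2", "b1", "b2"],
            index=[f"s{i}" for i in range(6)])
        design = td.SimDesign(n_genes=2, n_replicates=50, seed=13)
        tensor = td.simulate_replicates(
            counts, {"g1": ["a1", "a2"]}, 0.8, design,
            np.random.default_rng(13))
        # b1/b2 got no ambiguity: their replicates are constant
        tree = td.build_fixture_tree(tensor)
        sets = {frozenset(tree.leaf_set(v)) for v in tree.inner_nodes}
        assert frozenset({"a1", "a2"}) in sets
        assert frozenset({"b1", "b2"}) not in sets

    def test_parent_mirv_not_above_children_mean(self):
        design = td.SimDesign(n_genes=40, n_replicates=30, seed=17)
        truth, counts, tensor, tree, cond = td.simulate_experiment(design)
        mirv = td.mean_infrv(tensor, tree)
        for v in tree.inner_nodes:
            if v == tree.root:
                continue
            child_mean = np.mean([mirv[c] for c in tree.children[v]])
            # each accepted merge reduced mean infRV by more than the tol
            assert mirv[v] <= child_mean + 0.01

    def test_all_leaves_present(self):
        design = td.SimDesign(n_genes=25, n_replicates=20, seed=19)
        truth, counts, tensor, tree, cond = td.simulate_experiment(design)
        assert tree.leaf_set(tree.root) == set(counts.columns)

    def test_zero_uncertainty_yields_star(self):
        design = td.SimDesign(n_genes=15, n_replicates=20, seed=21,
                              uncertainty=0.0)
        truth, counts, tensor, tree, cond = td.simulate_experiment(design)
        assert len(tree.inner_nodes) == 1  # root only

    def test_too_few_features_rejected(self):
        tensor = td.ReplicateTensor.from_replicates(
            np.ones((3, 1, 4)), ["a"], ["s1", "s2", "s3"])
        with pytest.raises(ValueError):
            td.build_fixture_tree(tensor)


class TestEndToEnd:
    def test_seed_determinism(self):
        design = td.SimDesign(n_genes=30, n_replicates=15, seed=77)
        t1 = td.simulate_experiment(design)
        t2 = td.simulate_experiment(design)
        pd.testing.assert_frame_equal(t1[0].transcripts, t2[0].transcripts)
        pd.testing.assert_frame_equal(t1[1], t2[1])
        np.testing.assert_array_equal(t1[2].counts, t2[2].counts)
        assert td.write_newick(t1[3]) == td.write_newick(t2[3])
        assert list(t1[4]) == list(t2[4])

    def test_different_seeds_differ(self):
        a = td.simulate_experiment(td.SimDesign(n_genes=30, n_replicates=10, seed=1))
        b = td.simulate_experiment(td.SimDesign(n_genes=30, n_replicates=10, seed=2))
        assert not np.array_equal(a[2].counts, b[2].counts)
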