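import numpy as np
import pytest

from evoassay.assays import dose_response_auc
from evoassay.synthetic import (
    EvoSimParams,
    FlowSimParams,
    GradientSimParams,
    balanced_tree_newick,
    gen_codon_alignment,
    gen_dose_series,
    gen_flow_pair,
    gen_gradient_profile,
    gen_protein_msa,
    make_covariation_fixture,
)

TREE8 = balanced_tree_newick(8, 0.2)


class TestFlowPair:
    def test_totals_equal_n_events(self):
        null, agonist = gen_flow_pair(FlowSimParams(n_events=5000, seed=1))
        assert null.total == 5000
        assert agonist.total == 5000

    def test_identical_edges(self):
        null, agonist = gen_flow_pair(FlowSimParams(seed=2))
        assert np.array_equal(null.bin_edges, agonist.bin_edges)

    def test_zero_fraction_same_distribution(self):
        # responder_fraction 0: agonist drawn from the null component
        null, agonist = gen_flow_pair(
            FlowSimParams(responder_fraction=0.0, n_events=20000, seed=3)
        )
        centers = null.bin_centers
        m_null = (null.counts * centers).sum() / null.total
        m_ago = (agonist.counts * centers).sum() / agonist.total
        assert m_ago == pytest.approx(m_null, abs=0.02)

    def test_saturation_all_mass_shifted(self):
        params = FlowSimParams(
            responder_fraction=1.0, shift=2.0, null_log_sd=0.1, n_events=10000, seed=4
        )
        null, agonist = gen_flow_pair(params)
        cut = params.null_log_mean + 1.0  # far above null support at sd 0.1
        above = agonist.counts[null.bin_centers > cut].sum()
        assert above == agonist.total

    def test_seeded_determinism(self):
        p = FlowSimParams(n_events=10_000, responder_fraction=0.3, shift=0.5, seed=3)
        a1, b1 = gen_flow_pair(p)
        a2, b2 = gen_flow_pair(p)
        assert np.array_equal(a1.counts, a2.counts)
        assert np.array_equal(b1.counts, b2.counts)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            FlowSimParams(responder_fraction=1.5)

    def test_empty_range(self):
        with pytest.raises(ValueError):
            FlowSimParams(bin_range=(3.0, 3.0))


class TestGradientProfile:
    def test_flat_when_no_amplitude_no_noise(self):
        params = GradientSimParams(
            amplitudes={c: (0.0, 0.0) for c in ("CD4", "LCK", "CTxB")},
            background_offset=7.0,
            noise_sd=0.0,
        )
        p = gen_gradient_profile(params)
        assert np.allclose(p.raw.to_numpy(), 7.0)

    def test_single_drm_peak_max_at_center(self):
        params = GradientSimParams(
            drm_center=3,
            amplitudes={
                "CD4": (50.0, 0.0),
                "LCK": (50.0, 0.0),
                "CTxB": (50.0, 0.0),
            },
            noise_sd=0.0,
        )
        p = gen_gradient_profile(params)
        assert p.raw["LCK"].idxmax() == 3

    def test_fraction1_background_only(self):
        p = gen_gradient_profile(GradientSimParams(drm_center=1.0, noise_sd=0.0,
                                                   background_offset=4.0))
        assert np.allclose(p.raw.loc[1], 4.0)

    def test_seeded_determinism(self):
        params = GradientSimParams(noise_sd=2.0, seed=11)
        p1, p2 = gen_gradient_profile(params), gen_gradient_profile(params)
        assert p1.raw.equals(p2.raw)

    def test_center_out_of_range(self):
        with pytest.raises(ValueError):
            GradientSimParams(drm_center=0.5)


class TestDoseSeries:
    def test_seventh_concentration_is_41nM(self):
        s = gen_dose_series(top_conc_uM=30.0, dilution=3.0, n_points=7, cv=0.0)
        assert s.conc_nM[6] == pytest.approx(30000.0 / 729.0)
        assert s.conc_nM[6] == pytest.approx(41.15, abs=0.01)

    def test_cv_zero_replicates_equal_mean(self):
        s = gen_dose_series(fourpl=(0.0, 100.0, 300.0, 1.0), cv=0.0, n_reps=3)
        for reps in s.replicates:
            assert len(set(reps)) == 1

    def test_flat_curve_auc_closed_form(self):
        # bottom == top: constant response; trapezoid AUC = top * x-span
        s = gen_dose_series(fourpl=(50.0, 50.0, 300.0, 1.0), cv=0.0, n_points=7)
        span = np.log10(s.conc_nM[0]) - np.log10(s.conc_nM[-1])
        assert dose_response_auc(s) == pytest.approx(50.0 * span)

    def test_determinism(self):
        s1 = gen_dose_series(cv=0.3, seed=5)
        s2 = gen_dose_series(cv=0.3, seed=5)
        assert s1.replicates == s2.replicates

    def test_dilution_must_exceed_one(self):
        with pytest.raises(ValueError):
            gen_dose_series(dilution=1.0)


class TestProteinMsa:
    def test_conserved_columns_invariant(self):
        msa = gen_protein_msa(
            EvoSimParams(tree=TREE8, site_classes=("conserved",) * 5, seed=1)
        )
        for c in range(5):
            assert len(set(msa.protein[:, c])) == 1

    def test_covary_pair_is_bijection(self):
        classes = ("neutral", "covary:1", "neutral", "covary:1", "neutral")
        msa = gen_protein_msa(EvoSimParams(tree=TREE8, site_classes=classes, seed=7))
        col_i, col_j = msa.protein[:, 1], msa.protein[:, 3]
        mapping = {}
        for a, b in zip(col_i, col_j):
            assert mapping.setdefault(a, b) == b
        # bijection: distinct states map to distinct states
        assert len(set(mapping.values())) == len(mapping)

    def test_fixed_seed_identical(self):
        p = EvoSimParams(tree=TREE8, site_classes=("neutral",) * 10, seed=3)
        m1, m2 = gen_protein_msa(p), gen_protein_msa(p)
        assert np.array_equal(m1.protein, m2.protein)

    def test_covary_label_must_appear_twice(self):
        with pytest.raises(ValueError):
            EvoSimParams(tree=TREE8, site_classes=("covary:1", "neutral"))

    def test_malformed_newick(self):
        from evoassay.evolution.trees import TreeFormatError

        with pytest.raises(TreeFormatError):
            gen_protein_msa(
                EvoSimParams(tree="((a,b,;", site_classes=("neutral",) * 2)
            )


class TestCodonAlignment:
    def test_omega_zero_translation_invariant(self):
        msa = gen_codon_alignment(
            EvoSimParams(tree=TREE8, site_classes=("purifying:0.0",) * 10, seed=2)
        )
        for c in range(10):
            assert len(set(msa.protein[:, c])) == 1

    def test_zero_branch_lengths_identical_sequences(self):
        tree = balanced_tree_newick(4, 0.0)
        msa = gen_codon_alignment(
            EvoSimParams(tree=tree, site_classes=("neutral",) * 6, seed=3)
        )
        seqs = set(msa.codon_sequences().values())
        assert len(seqs) == 1

    def test_determinism(self):
        p = EvoSimParams(tree=TREE8, site_classes=("neutral",) * 8, kappa=2.0, seed=4)
        m1, m2 = gen_codon_alignment(p), gen_codon_alignment(p)
        assert np.array_equal(m1.codon, m2.codon)

    def test_codon_layer_translates_to_protein(self):
        # MsaBundle validates translation consistency on construction
        gen_codon_alignment(
            EvoSimParams(tree=TREE8, site_classes=("neutral", "purifying:0.2"), seed=5)
        )

    def test_covary_rejected_at_codon_level(self):
        with pytest.raises(ValueError):
            gen_codon_alignment(
                EvoSimParams(tree=TREE8, site_classes=("covary:1", "covary:1"))
            )

    def test_tree_without_lengths_rejected(self):
        from evoassay.evolution.trees import TreeFormatError

        with pytest.raises(TreeFormatError):
            gen_codon_alignment(
                EvoSimParams(tree="(a,(b,(c,d)));", site_classes=("neutral",))
            )


class TestCovariationFixture:
    def test_pair_count(self):
        _, pairs = make_covariation_fixture()
        assert len(pairs) == 401 * 400 // 2  # C(401, 2) = 80,200

    def test_planted_values(self):
        sites, pairs = make_covariation_fixture()
        indexed = pairs.set_index(["pos_i", "pos_j"])["mi_raw"]
        assert indexed.loc[(1, 2)] == 9.0
        assert indexed.loc[(59, 60)] == 0.1
        assert (pairs["mi_raw"] == 9.0).sum() == 401
        assert sites.loc[58, "conservation"] == -1.0
        assert sites.loc[59, "conservation"] == 0.0

    def test_deterministic(self):
        s1, p1 = make_covariation_fixture()
        s2, p2 = make_covariation_fixture()
        assert s1.equals(s2) and p1.equals(p2)


class TestBalancedTree:
    def test_tip_count(self):
        from evoassay.evolution.trees import TreeIndex

        for n in (2, 5, 16):
            tree = TreeIndex.from_newick(balanced_tree_newick(n, 0.1))
            assert len(tree.tip_labels) == n

    def test_uniform_branch_lengths(self):
        from evoassay.evolution.trees import TreeIndex

        tree = TreeIndex.from_newick(balanced_tree_newick(16, 0.25))
        lengths = [tree.edge_length[i] for i in range(tree.n_nodes) if i != tree.root]
        assert np.allclose(lengths, 0.25)
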