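"""Cross-modal coupling statistics: correlation, contribution, permutation."""

import numpy as np
import pandas as pd
import pytest

from crossfc.coupling import (
    CouplingError,
    CrossModalCoupling,
    apply_sensitivity_filter,
    crossmodal_correlation,
    distance_fc_correlation,
    group_permutation_test,
    hemisphere_restricted_analysis,
    individual_level_coupling,
    spatial_contribution,
    split_half_consistency,
    subnetwork_coupling_tests,
)
from crossfc.core import CohortStack, Connectome, devectorize, group_average

from conftest import make_null_stack, make_toy_atlas, study_like_design

ALL_BANDS = ("delta", "theta", "alpha", "beta", "gamma")


class TestCrossmodalCorrelation:
    def test_identical_matrices(self):
        v = np.random.default_rng(0).uniform(0, 1, 10)
        assert crossmodal_correlation(v, v) == pytest.approx(1.0)

    def test_anti_correlated(self):
        v = np.random.default_rng(1).standard_normal(10)
        assert crossmodal_correlation(v, -v) == pytest.approx(-1.0)

    def test_matches_zscore_identity(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(2278), rng.standard_normal(2278)
        r = crossmodal_correlation(x, y)
        zx = (x - x.mean()) / np.sqrt(((x - x.mean()) ** 2).sum())
        zy = (y - y.mean()) / np.sqrt(((y - y.mean()) ** 2).sum())
        assert abs(r - zx @ zy) < 1e-12

    def test_degenerate_inputs(self):
        with pytest.raises(CouplingError):
            crossmodal_correlation(np.ones(10), np.arange(10.0))
        with pytest.raises(CouplingError):
            crossmodal_correlation(np.arange(2.0), np.arange(2.0))


class TestSpatialContribution:
    def test_self_correlation_gives_squared_z(self):
        x = np.random.default_rng(0).standard_normal(20)
        cm = spatial_contribution(x, x)
        assert np.all(cm.c >= 0)
        assert cm.c.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(cm.c, cm.z_x**2)

    def test_three_edge_toy_against_direct_arithmetic(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        cm = spatial_contribution(x, y)
        # brute-force evaluation of the printed formula
        zx = (x - x.mean()) / np.sqrt(((x - x.mean()) ** 2).sum())
        zy = (y - y.mean()) / np.sqrt(((y - y.mean()) ** 2).sum())
        r = float(np.sum(zx * zy))
        assert cm.r == pytest.approx(r, abs=1e-15)
        assert np.allclose(cm.c, zx * zy / r, atol=1e-15)

    def test_identity_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x, y = rng.standard_normal(50), rng.standard_normal(50)
            cm = spatial_contribution(x, y)
            assert abs(cm.c.sum() - 1.0) < 1e-9
            assert np.abs(cm.c * cm.r - cm.z_x * cm.z_y).max() < 1e-9

    def test_zero_correlation_undefined(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        with pytest.raises(CouplingError):
            spatial_contribution(x, y)


class TestSplitHalf:
    def _stack_from_edges(self, rows, r):
        from crossfc.core import SubjectRecord

        subs = []
        for k, v in enumerate(rows):
            rec = SubjectRecord(f"s{k}", "control", 30.0, "F", "site256")
            rec.connectomes[("fmri", "none")] = Connectome(
                devectorize(v, r), "fmri", "none", f"s{k}"
            )
            subs.append(rec)
        return CohortStack(subs)

    def test_two_identical_connectomes(self):
        v = np.random.default_rng(0).uniform(-0.5, 0.5, 6)
        stack = self._stack_from_edges([v, v], 4)
        res = split_half_consistency(stack, "control", "fmri")
        assert res.mean_r == pytest.approx(1.0)

    def test_n4_enumerates_three_splits(self):
        rng = np.random.default_rng(1)
        stack = self._stack_from_edges([rng.uniform(-0.5, 0.5, 10) for _ in range(4)], 5)
        res = split_half_consistency(stack, "control", "fmri")
        assert res.exhaustive and res.n_splits == 3

    def test_reliability_grows_with_group_size(self, desikan):
        from crossfc.simulate import generate_cohort
        from test_simulate import single_group_design

        means = []
        for n in (10, 20):
            stack, _ = generate_cohort(single_group_design(0.4, n=n, seed=40), desikan)
            res = split_half_consistency(stack, "control", "fmri", n_iter=300, seed=0)
            means.append(res.mean_r)
        assert means[1] > means[0] > 0.5

    def test_single_subject_rejected(self):
        stack = self._stack_from_edges([np.zeros(6)], 4)
        with pytest.raises(CouplingError):
            split_half_consistency(stack, "control", "fmri")


class TestGroupPermutationTest:
    def test_duplicated_cohort_centers_the_null(self):
        base = make_null_stack(8, 20, seed=5, groups=("control",))
        dup = []
        for k, s in enumerate(base.subjects):
            import copy

            c = copy.deepcopy(s)
            c.subject_id = f"dup-{k}"
            c.group = "rTLE"
            dup.append(c)
        stack = CohortStack(base.subjects + dup)
        res = group_permutation_test(stack, "control", "rTLE", "alpha",
                                     n_perm=400, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert 0.2 <= res.p_perm <= 0.8

    def test_planted_difference_detected(self, planted_stack):
        stack, _ = planted_stack
        res = group_permutation_test(stack, "control", "rTLE", "theta",
                                     direction="greater", n_perm=2000, seed=1)
        assert res.r_b > res.r_a
        assert res.p_perm < 0.01

    def test_small_n_perm_warns(self, planted_stack):
        stack, _ = planted_stack
        with pytest.warns(UserWarning):
            group_permutation_test(stack, "control", "rTLE", "alpha", n_perm=50, seed=2)


class TestSubnetworks:
    def test_icn_masks_partition_against_inter_edges(self, desikan):
        masks = [desikan.intra_network_mask(net) for net in desikan.networks]
        intra = np.stack(masks).sum(axis=0)
        inter = (intra == 0).sum()
        assert intra.max() == 1
        assert intra.sum() + inter == desikan.n_edges

    def test_planted_dmn_beta_decoupling_is_localized(self, planted_stack):
        stack, _ = planted_stack
        df = subnetwork_coupling_tests(
            stack, contrasts=(("control", "lTLE", "less"),), n_perm=2500, seed=3
        )
        coup = df[df.test == "coupling"].set_index(["band", "network"])
        best = coup["p_perm"].idxmin()
        assert best == ("beta", "default-mode")
        assert coup.loc[best, "p_perm"] < 0.05

    def test_bonferroni_cell_threshold_adapts_to_battery(self, planted_stack):
        stack, _ = planted_stack
        full = subnetwork_coupling_tests(
            stack, contrasts=(("control", "lTLE", "less"),), n_perm=150, seed=4
        )
        assert np.allclose(full["bonferroni_alpha"], 0.05 / (5 * 7))
        one_band = subnetwork_coupling_tests(
            stack, bands=("beta",), contrasts=(("control", "lTLE", "less"),),
            n_perm=150, seed=4,
        )
        assert np.allclose(one_band["bonferroni_alpha"], 0.05 / 7)


class TestExploratory:
    def test_distance_decay_gives_negative_correlation(self, desikan):
        d = desikan.edge_distances()
        conn = Connectome(devectorize(np.exp(-0.01 * d), 68), "eeg", "alpha")
        assert distance_fc_correlation(desikan, conn) < 0

    def test_distance_independent_connectome_uncorrelated(self, desikan):
        rng = np.random.default_rng(6)
        conn = Connectome(devectorize(rng.uniform(0, 1, desikan.n_edges), 68), "eeg", "alpha")
        assert abs(distance_fc_correlation(desikan, conn)) < 0.1

    def test_synthetic_group_means_decay_with_distance(self, planted_stack, desikan):
        stack, _ = planted_stack
        for modality, band in (("fmri", "none"), ("eeg", "alpha")):
            mean = group_average(stack, "control", modality, band)
            assert distance_fc_correlation(desikan, mean) < -0.1

    def test_hemisphere_battery_and_global_effect_direction(self, planted_stack):
        stack, _ = planted_stack
        results = {
            h: hemisphere_restricted_analysis(
                stack, h, bands=("theta",),
                contrasts=(("control", "rTLE", "greater"),),
                n_perm=500, seed=7,
            )[0]
            for h in ("L", "R")
        }
        # the planted effect is global: same direction in both hemispheres
        assert results["L"].statistic > 0 and results["R"].statistic > 0

    def test_unknown_hemisphere_rejected(self, planted_stack):
        stack, _ = planted_stack
        from crossfc.atlas import AtlasValidationError

        with pytest.raises(AtlasValidationError):
            hemisphere_restricted_analysis(stack, "X", n_perm=100)


class TestSensitivityFilters:
    def test_ied_filter_removes_exactly_high_rate_patients(self):
        stack = make_null_stack(6, 6, seed=8, groups=("control", "rTLE"))
        high = [s.subject_id for s in stack.subjects[6:8]]
        for s in stack.subjects[6:8]:
            s.ied_per_min = 1.5
        for s in stack.subjects[8:]:
            s.ied_per_min = 0.5
        filtered = apply_sensitivity_filter(stack, "ied_le_1")
        kept = {s.subject_id for s in filtered.subjects}
        assert set(high).isdisjoint(kept)
        assert len(filtered) == len(stack) - 2

    def test_hs_stratification_partitions_patients(self):
        stack = make_null_stack(8, 6, seed=9, groups=("control", "rTLE", "lTLE"))
        hs = apply_sensitivity_filter(stack, "hs_only")
        non = apply_sensitivity_filter(stack, "non_hs_only")
        patients = {s.subject_id for s in stack.subjects if s.is_patient}
        split = {s.subject_id for s in hs.subjects if s.is_patient} | {
            s.subject_id for s in non.subjects if s.is_patient
        }
        assert split == patients

    def test_emptying_filter_raises(self):
        stack = make_null_stack(4, 6, seed=10, groups=("control", "rTLE"))
        for s in stack.subjects:
            if s.is_patient:
                s.is_hs = False
        with pytest.raises(CouplingError):
            apply_sensitivity_filter(stack, "hs_only")

    def test_individual_level_ordering_matches_group_analysis(self, planted_stack):
        stack, _ = planted_stack
        df = individual_level_coupling(stack)
        row = df[(df.contrast == "rTLE vs control") & (df.band == "theta")].iloc[0]
        assert row["mean_b"] > row["mean_a"]
        assert row["bonferroni_alpha"] == pytest.approx(0.01)


class TestModelFacade:
    def test_fit_summary_and_group_table(self, planted_stack):
        stack, _ = planted_stack
        model = CrossModalCoupling(stack, bands=("theta", "gamma"))
        results = model.fit(n_perm=500, seed=11)
        summary = results.summary()
        assert set(summary["band"]) == {"theta", "gamma"}
        assert len(summary) == 4  # 2 contrasts x 2 bands
        assert ((summary["p_perm"] > 0) & (summary["p_perm"] <= 1)).all()
        table = results.group_coupling_table()
        direct = crossmodal_correlation(
            group_average(stack, "rTLE", "eeg", "theta"),
            group_average(stack, "rTLE", "fmri"),
        )
        assert table.loc["rTLE", "theta"] == pytest.approx(direct, abs=1e-12)

    def test_results_reproducible_from_seed(self, planted_stack):
        stack, _ = planted_stack
        model = CrossModalCoupling(stack, bands=("alpha",))
        p1 = model.fit(n_perm=300, seed=12).summary()["p_perm"]
        p2 = model.fit(n_perm=300, seed=12).summary()["p_perm"]
        assert (p1 == p2).all()
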