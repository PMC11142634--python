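"""fMRI cleaning chain: FD, scrubbing, nuisance regression, band-pass, FC."""

import numpy as np
import pytest

from crossfc.fmri import (
    BoldRegionSeries,
    FmriPipelineError,
    bandpass,
    fmri_connectome,
    fmri_pipeline,
    framewise_displacement,
    nuisance_regress,
    scrub,
)


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero(self):
        assert np.all(framewise_displacement(np.ones((20, 6))) == 0)

    def test_single_translation_step(self):
        mp = np.zeros((8, 6))
        mp[5:, 0] = 0.3  # step between volumes 4 -> 5
        fd = framewise_displacement(mp)
        assert fd[5] == pytest.approx(0.3)
        assert np.all(np.delete(fd, 5) == 0)

    def test_combined_translation_rotation(self):
        mp = np.zeros((2, 6))
        mp[1] = [0.1, 0.1, 0.1, 0.002, 0.002, 0.002]
        # 0.3 mm translation + 50 mm * 0.006 rad arc = 0.6 mm
        assert framewise_displacement(mp)[1] == pytest.approx(0.6)

    def test_wrong_column_count(self):
        with pytest.raises(FmriPipelineError):
            framewise_displacement(np.zeros((5, 5)))


class TestScrub:
    def test_nothing_removed_when_still(self):
        series = np.random.default_rng(0).standard_normal((3, 20))
        out, mask = scrub(series, np.zeros(20))
        assert out.shape == series.shape and mask.n_removed == 0

    def test_single_superthreshold_volume(self):
        series = np.tile(np.arange(4.0), (2, 1))
        fd = np.array([0.0, 0.0, 0.6, 0.0])
        out, mask = scrub(series, fd)
        assert out.shape[1] == 3 and mask.n_removed == 1
        assert not mask.keep[2]

    def test_matches_bruteforce_count(self):
        rng = np.random.default_rng(3)
        fd = rng.exponential(0.3, 200)
        fd[0] = 0.0
        series = rng.standard_normal((5, 200))
        _, mask = scrub(series, fd)
        assert mask.n_removed == sum(1 for v in fd if v > 0.5)

    def test_too_few_survivors_is_exclusion_signal(self):
        with pytest.raises(FmriPipelineError):
            scrub(np.zeros((2, 20)), np.full(20, 1.0))


class TestNuisanceRegression:
    def test_region_equal_to_confound_vanishes(self):
        rng = np.random.default_rng(0)
        conf = rng.standard_normal((100, 3))
        data = np.vstack([conf[:, 0], rng.standard_normal(100)])
        res = nuisance_regress(data, conf)
        assert np.abs(res[0]).max() < 1e-10

    def test_orthogonal_confounds_only_demean(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((2, 200))
        conf = rng.standard_normal((200, 2))
        # orthogonalize confounds against [1, data rows]
        basis = np.column_stack([np.ones(200), data.T])
        proj = basis @ np.linalg.lstsq(basis, conf, rcond=None)[0]
        conf_orth = conf - proj
        res = nuisance_regress(data, conf_orth)
        assert np.allclose(res, data - data.mean(axis=1, keepdims=True), atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((5, 100))
        conf = rng.standard_normal((100, 9))
        x = np.column_stack([np.ones(100), conf])
        oracle = data.T - x @ np.linalg.inv(x.T @ x) @ x.T @ data.T
        assert np.abs(nuisance_regress(data, conf) - oracle.T).max() < 1e-8

    def test_collinear_design_named(self):
        conf = np.random.default_rng(0).standard_normal((50, 2))
        conf = np.column_stack([conf, conf[:, 0] * 2.0])  # column 2 collinear
        with pytest.raises(FmriPipelineError, match="column 2"):
            nuisance_regress(np.random.default_rng(1).standard_normal((2, 50)), conf)


class TestBandpass:
    TR = 2.0
    T = 500

    def _gain(self, freq):
        t = np.arange(self.T) * self.TR
        x = np.sin(2 * np.pi * freq * t)[None, :]
        y = bandpass(x, self.TR)
        core = slice(50, -50)  # avoid filtfilt edge transients
        return np.sqrt((y[0, core] ** 2).mean() / (x[0, core] ** 2).mean())

    def test_dc_removed(self):
        assert np.abs(bandpass(np.ones((1, self.T)), self.TR)).max() < 1e-10

    def test_passband_gain(self):
        assert 0.9 <= self._gain(0.04) <= 1.0

    def test_stopband_gain(self):
        assert self._gain(0.2) <= 0.1

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(FmriPipelineError):
            bandpass(np.ones((1, 100)), tr_s=10.0, high_hz=0.08)  # nyquist 0.05


class TestFmriConnectome:
    def test_duplicated_region_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        conn = fmri_connectome(np.vstack([x, x, rng.standard_normal(50)]))
        assert conn.values[0, 1] == pytest.approx(1.0)

    def test_printed_collinear_toy(self):
        rows = np.array(
            [[1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12], [6, 5, 4, 3, 2, 1]], dtype=float
        )
        # only 6 volumes: bypass the pipeline minimum by repeating the pattern
        rows = np.hstack([rows, rows])
        conn = fmri_connectome(rows)
        assert conn.values[0, 1] == pytest.approx(1.0)
        assert conn.values[0, 2] == pytest.approx(-1.0)
        assert conn.values[1, 2] == pytest.approx(-1.0)

    def test_white_noise_uncorrelated(self):
        rng = np.random.default_rng(1)
        conn = fmri_connectome(rng.standard_normal((3, 10_000)))
        assert np.abs(conn.edge_vector()).max() < 0.05

    def test_zero_variance_region_zeroed_with_warning(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((3, 40))
        data[1] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            conn = fmri_connectome(data)
        assert np.all(conn.values[1] == 0) and np.all(conn.values[:, 1] == 0)
        assert np.isfinite(conn.values).all()

    def test_region_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((6, 80))
        perm = rng.permutation(6)
        direct = fmri_connectome(data[perm]).values
        permuted = fmri_connectome(data).values[np.ix_(perm, perm)]
        assert np.allclose(direct, permuted, atol=1e-12)


def test_full_pipeline_recovers_targets_and_scrubs(toy_atlas):
    from conftest import small_site
    from crossfc.simulate import SimulationDesign, generate_cohort, sample_region_timeseries

    design = SimulationDesign(
        group_sizes={"control": {"site256": 3}},
        coupling_target={"control": {b: 0.4 for b in ("delta", "theta", "alpha", "beta", "gamma")}},
        dmn_flag=None,
        site_params=small_site(n_volumes=300, n_segments=6),
        seed=5,
    )
    stack, _ = generate_cohort(design, toy_atlas)
    for idx, rec in enumerate(stack.subjects):
        ts = sample_region_timeseries(design, rec.connectomes, rec.site, idx)
        bold = BoldRegionSeries(ts.bold, tr_s=ts.tr_s, confounds=ts.confounds)
        conn, mask = fmri_pipeline(bold, ts.motion, subject_id=rec.subject_id)
        target = rec.connectome("fmri").edge_vector()
        assert np.corrcoef(target, conn.edge_vector())[0, 1] > 0.6
        # spikes planted by the generator are detected
        fd = framewise_displacement(ts.motion)
        assert mask.n_removed == int((fd > 0.5).sum())


def test_connectome_rmse_decreases_with_scan_length(toy_atlas):
    from conftest import small_site
    from crossfc.simulate import SimulationDesign, generate_cohort, sample_region_timeseries

    rmses = []
    for t_len in (60, 600):
        design = SimulationDesign(
            group_sizes={"control": {"site256": 3}},
            coupling_target={"control": {b: 0.4 for b in ("delta", "theta", "alpha", "beta", "gamma")}},
            dmn_flag=None,
            motion_spike_rate=0.0,
            site_params=small_site(n_volumes=t_len, n_segments=6),
            seed=9,
        )
        stack, _ = generate_cohort(design, toy_atlas)
        errs = []
        for idx, rec in enumerate(stack.subjects):
            ts = sample_region_timeseries(design, rec.connectomes, rec.site, idx)
            conn = fmri_connectome(ts.bold)  # raw correlation vs target covariance
            errs.append(conn.edge_vector() - rec.connectome("fmri").edge_vector())
        rmses.append(np.sqrt(np.mean(np.square(errs))))
    assert rmses[1] < rmses[0]
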