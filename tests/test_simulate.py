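"""Synthetic cohort generator: target correlations, series, behavior, profiles."""

import numpy as np
import pandas as pd
import pytest

from cbtc import fc as _fc
from cbtc.simulate import (
    DEFAULT_AFFECTED_EDGES,
    SimulationConfig,
    build_target_correlation,
    nearest_psd_correlation,
    simulate_behavior,
    simulate_cohort,
    simulate_timeseries,
    simulate_voxel_profiles,
)


class TestTargetCorrelation:
    def test_zero_delta_gives_identical_groups(self, manifest):
        c1, _ = build_target_correlation(manifest, 0.4, "control",
                                         DEFAULT_AFFECTED_EDGES, 0.0)
        c2, _ = build_target_correlation(manifest, 0.4, "patient",
                                         DEFAULT_AFFECTED_EDGES, 0.0)
        np.testing.assert_array_equal(c1.to_numpy(), c2.to_numpy())

    def test_matrix_is_psd_and_unit_diagonal(self, manifest):
        corr, perturb = build_target_correlation(manifest, 0.4, "patient",
                                                 DEFAULT_AFFECTED_EDGES, 0.15)
        mat = corr.to_numpy()
        np.testing.assert_allclose(np.diag(mat), 1.0)
        np.testing.assert_allclose(mat, mat.T)
        assert np.linalg.eigvalsh(mat).min() >= -1e-10
        assert perturb < 0.05

    def test_affected_entries_attenuated_in_patients_only(self, manifest):
        pat, _ = build_target_correlation(manifest, 0.4, "patient",
                                          DEFAULT_AFFECTED_EDGES, 0.15)
        ctl, _ = build_target_correlation(manifest, 0.4, "control",
                                          DEFAULT_AFFECTED_EDGES, 0.15)
        assert ctl.loc["R:CAU_M1", "R:M1"] == pytest.approx(0.4, abs=0.05)
        assert pat.loc["R:CAU_M1", "R:M1"] == pytest.approx(0.25, abs=0.05)
        # the attenuation is specific: an untouched edge keeps the baseline
        assert pat.loc["L:CAU_M1", "L:M1"] == pytest.approx(0.4, abs=0.05)

    def test_sparse_manifest_needs_no_repair(self, manifest):
        # a modest rho0 on a loop-sparse graph is already PSD: repair is identity
        corr, perturb = build_target_correlation(manifest, 0.3, "control")
        assert perturb == 0.0
        assert np.linalg.eigvalsh(corr.to_numpy()).min() > 0

    def test_rho0_bounds_enforced(self, manifest):
        with pytest.raises(ValueError):
            build_target_correlation(manifest, 1.0, "control")


def test_nearest_psd_repairs_an_indefinite_matrix():
    bad = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
    assert np.linalg.eigvalsh(bad).min() < 0
    rep, perturb = nearest_psd_correlation(bad)
    assert np.linalg.eigvalsh(rep).min() >= 0
    np.testing.assert_allclose(np.diag(rep), 1.0)
    assert 0 < perturb < 0.2


class TestTimeseries:
    def test_same_seed_is_bit_identical(self):
        corr = np.eye(4)
        a = simulate_timeseries(corr, 50, seed=5)
        b = simulate_timeseries(corr, 50, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_identity_correlation_stays_near_zero(self):
        x = simulate_timeseries(np.eye(6), 2000, seed=1)
        emp = np.corrcoef(x)
        off = emp[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_targeted_correlation_recovered_at_long_t(self):
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        x = simulate_timeseries(corr, 5000, seed=2)
        assert np.corrcoef(x)[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_non_psd_input_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_timeseries(bad, 10, seed=0)


class TestBehavior:
    def test_zero_weights_no_noise_is_clipped_rounded_offset(self):
        z = pd.Series({"e": 0.4})
        assert simulate_behavior(z, [], 0.0, offset=30.4, scale=10, seed=0) == 30
        assert simulate_behavior(z, [], 0.0, offset=900, scale=10, seed=0) == 66
        assert simulate_behavior(z, [], 0.0, offset=-900, scale=10, seed=0) == 0

    def test_always_within_instrument_range(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            z = pd.Series({"e": rng.normal(0, 3)})
            score = simulate_behavior(z, [("e", 1.0)], 20.0, 30, 40, rng)
            assert 0 <= score <= 66

    def test_monotone_in_a_positive_weight_edge(self):
        scores = [simulate_behavior(pd.Series({"e": z}), [("e", 1.0)], 0.0, 20, 30, 0)
                  for z in np.linspace(-0.5, 0.5, 9)]
        assert scores == sorted(scores)


class TestProfiles:
    def test_rows_are_probability_vectors(self):
        ps = simulate_voxel_profiles("CAU", ("M1", "DLPFC", "MPFC"), 30, 10.0, seed=0)
        np.testing.assert_allclose(ps.probs.sum(axis=1), 1.0)
        assert (ps.probs >= 0).all()
        assert ps.probs.shape == (90, 3)
        assert (np.bincount(ps.true_labels) == 30).all()

    def test_concentration_peaks_on_true_target(self):
        ps = simulate_voxel_profiles("CAU", ("M1", "DLPFC"), 50, 1000.0, seed=0)
        assert (ps.probs.argmax(axis=1) == ps.true_labels).mean() > 0.99


class TestCohort:
    def test_group_counts_and_record_validity(self, cohort64):
        groups = [s.group for s in cohort64.subjects]
        assert groups.count("patient") == 64 and groups.count("control") == 64
        for s in cohort64.subjects:
            if s.group == "patient":
                assert 0 <= s.ue_fma <= 66
                # flipping convention: ipsilesional is R for everyone
                assert s.flipped == (s.lesion_side == "L")
            else:
                assert s.ue_fma is None and not s.flipped

    def test_series_dimensions_match_manifest_regions(self, cohort64, manifest):
        n_regions = len(manifest.regions(("cortical", "subdivision")))
        mat = next(iter(cohort64.series.values()))
        assert mat.shape == (n_regions, 200)

    def test_seed_reproducibility(self, manifest):
        cfg = SimulationConfig(n_patients=4, n_controls=4, n_timepoints=50, seed=9)
        a = simulate_cohort(cfg, manifest)
        b = simulate_cohort(SimulationConfig(n_patients=4, n_controls=4,
                                             n_timepoints=50, seed=9), manifest)
        assert [s.ue_fma for s in a.subjects] == [s.ue_fma for s in b.subjects]
        for sid in a.series:
            np.testing.assert_array_equal(a.series[sid], b.series[sid])

    def test_group_effect_shows_on_affected_edges(self, manifest):
        cfg = SimulationConfig(n_patients=64, n_controls=64, n_timepoints=500,
                               delta=0.15, seed=21)
        ds = simulate_cohort(cfg, manifest)
        fc = _fc.extract_fc_vector(ds.series, manifest, "loops")
        pat = [s.id for s in ds.subjects if s.group == "patient"]
        ctl = [s.id for s in ds.subjects if s.group == "control"]
        for key in DEFAULT_AFFECTED_EDGES:
            gap = fc.loc[ctl, key].mean() - fc.loc[pat, key].mean()
            # z gap approx arctanh(0.4) - arctanh(0.25); sampling sd of the
            # mean difference is ~ sqrt(2/64)/sqrt(T-3): demand > 3 sigma
            se = np.sqrt(2 / 64) * (1 / np.sqrt(500 - 3))
            assert gap > 3 * se

    def test_invalid_edge_reference_rejected(self, manifest):
        cfg = SimulationConfig(affected_edges=("short:R:FOO-BAR",))
        with pytest.raises(ValueError, match="not in manifest"):
            simulate_cohort(cfg, manifest)
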