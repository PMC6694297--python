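"""Synthetic cohort generator: planted maps, band-limited sources, signal
model, determinism and behavioral coupling."""

import numpy as np
import pytest
from scipy import signal as ss

from rsnlong.cohort import (BlobSpec, CohortDesign, default_ground_truth,
                            make_network_maps, make_timecourses,
                            planted_amplitude_table, simulate_behavior,
                            simulate_cohort, simulate_cohort_records,
                            synthesize_subject)
from tests.conftest import two_blob_truth


class TestNetworkMaps:
    GRID = (20, 20, 10)

    def _spec(self):
        return BlobSpec(radius_xy=4.2, radius_z=3.0, exponent=10,
                        min_support=300, min_separation=7.0)

    def test_four_networks_contract(self):
        mask = np.ones(self.GRID, bool)
        maps = make_network_maps(self.GRID, mask, 4, self._spec(), seed=0)
        assert maps.shape == (4, mask.sum())
        assert (maps >= 0).all()
        assert np.allclose(maps.max(axis=1), 1.0)
        assert ((maps > 0.05).sum(axis=1) >= 300).all()
        r = np.corrcoef(maps)
        assert np.abs(r[~np.eye(4, dtype=bool)]).max() < 0.5

    def test_single_network(self):
        mask = np.ones(self.GRID, bool)
        maps = make_network_maps(self.GRID, mask, 1, self._spec(), seed=1)
        assert maps.shape[0] == 1
        assert np.corrcoef(maps[0], maps[0])[0, 1] == pytest.approx(1.0)

    def test_deterministic(self):
        mask = np.ones(self.GRID, bool)
        a = make_network_maps(self.GRID, mask, 3, self._spec(), seed=5)
        b = make_network_maps(self.GRID, mask, 3, self._spec(), seed=5)
        np.testing.assert_array_equal(a, b)

    def test_too_small_mask_raises_sizing_error(self):
        mask = np.ones((6, 6, 4), bool)
        with pytest.raises(ValueError, match="mask too small"):
            make_network_maps((6, 6, 4), mask, 8, self._spec(), seed=0)


class TestTimecourses:
    def test_unit_sd_and_band_power(self):
        tr, band = 2.0, (0.01, 0.08)
        c = make_timecourses(200, tr, band, seed=0, n_courses=5)
        assert c.shape == (5, 200)
        np.testing.assert_allclose(c.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(c.std(axis=1, ddof=1), 1, atol=1e-12)
        f, p = ss.periodogram(c, fs=1 / tr, axis=1)
        in_band = (f >= band[0]) & (f <= band[1])
        frac = p[:, in_band].sum(axis=1) / p.sum(axis=1)
        assert (frac >= 0.9).all()

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            make_timecourses(100, 2.0, (0.2, 0.3), seed=0)

    def test_deterministic(self):
        a = make_timecourses(80, 2.0, (0.01, 0.1), seed=9)
        b = make_timecourses(80, 2.0, (0.01, 0.1), seed=9)
        np.testing.assert_array_equal(a, b)


class TestSynthesizeSubject:
    def test_noiseless_single_network_is_rank_one(self, tiny_design):
        truth = two_blob_truth(tiny_design, noise_sd=0.0)
        truth.network_maps = truth.network_maps[:1]
        truth.network_names = ("net_a",)
        truth.amp_intercept = np.ones((2, 1))
        truth.amp_slope = np.zeros((2, 1))
        truth.cognition_coupling = np.zeros(1)
        truth.motion_coupling = 0.0
        data, _ = synthesize_subject(truth, tiny_design, 0, 6.0, 0.0, seed=3)
        # every voxel series is a scalar multiple of the planted course
        blob = np.argsort(truth.network_maps[0])[-5:]
        ref = data[blob[-1]].astype(float)
        for v in blob:
            c = np.corrcoef(data[v].astype(float), ref)[0, 1]
            assert abs(c) > 1 - 1e-6

    def test_amplitude_monotone_in_age(self, tiny_design):
        truth = two_blob_truth(tiny_design, noise_sd=0.0)
        truth.amp_slope = np.array([[0.05, 0.05], [0.0, 0.0]])
        truth.motion_coupling = 0.0
        young, _ = synthesize_subject(truth, tiny_design, 0, 5.0, 0.0, seed=4)
        old, _ = synthesize_subject(truth, tiny_design, 0, 18.0, 0.0, seed=4)
        assert old.std() > young.std()

    def test_linearity_in_amplitude(self, tiny_design):
        truth = two_blob_truth(tiny_design, noise_sd=0.0)
        truth.motion_coupling = 0.0
        base, _ = synthesize_subject(truth, tiny_design, 1, 8.0, 0.0, seed=5)
        truth.amp_intercept = 2 * truth.amp_intercept
        truth.amp_slope = 2 * truth.amp_slope
        doubled, _ = synthesize_subject(truth, tiny_design, 1, 8.0, 0.0, seed=5)
        np.testing.assert_allclose(doubled, 2 * base, atol=1e-5)

    def test_bad_group_rejected(self, tiny_design, tiny_truth):
        with pytest.raises(ValueError):
            synthesize_subject(tiny_truth, tiny_design, 2, 6.0)


class TestSimulateCohort:
    def test_reference_design_has_84_acquisitions(self):
        assert CohortDesign().n_acquisitions == 84

    def test_records_deterministic(self, tiny_design, tiny_truth):
        a = simulate_cohort_records(tiny_design, tiny_truth)
        b = simulate_cohort_records(tiny_design, tiny_truth)
        assert len(a) == 2
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.data, rb.data)
            np.testing.assert_array_equal(ra.motion, rb.motion)
            assert ra.age_months == rb.age_months

    def test_minimal_design_on_disk(self, tiny_design, tiny_truth, tmp_path):
        man = simulate_cohort(tiny_design, tiny_truth, tmp_path / "c")
        assert len(man["acquisitions"]) == 2
        assert (tmp_path / "c" / "cohort.tsv").exists()
        assert (tmp_path / "c" / "behavior.tsv").exists()

    def test_rerun_same_seed_identical_checksums(self, tiny_design, tiny_truth,
                                                 tmp_path):
        m1 = simulate_cohort(tiny_design, tiny_truth, tmp_path / "a")
        m2 = simulate_cohort(tiny_design, tiny_truth, tmp_path / "b")
        for a, b in zip(m1["acquisitions"], m2["acquisitions"]):
            assert a["sha256"] == b["sha256"]


class TestDefaultGroundTruth:
    def test_planted_subnetworks_satisfy_matching_rule(self):
        """The planted DMN sub-blobs must themselves pass the z > 2.3
        overlap > 250 rule against the union parent, so recovery is
        well-posed."""
        design = CohortDesign()
        truth = default_ground_truth(design)
        maps = truth.network_maps

        def zsc(v):
            return (v - v.mean()) / v.std(ddof=1)

        union = sum(maps[k] for k in truth.dmn_subnets)
        zu = zsc(union)
        for k in truth.dmn_subnets:
            overlap = int(((zu > 2.3) & (zsc(maps[k]) > 2.3)).sum())
            assert overlap > 250

    def test_effect_and_null_slopes(self):
        truth = default_ground_truth(CohortDesign())
        assert (truth.amp_slope[0, :2] > 0).all()   # WT rising
        assert (truth.amp_slope[1, :2] < 0).all()   # Tg falling
        assert np.all(truth.amp_slope[:, 2:] == 0)  # null + DMN stable


class TestBehavior:
    def _table(self, tiny_design, truth, n=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            rows.append({"subject_id": f"s{i}", "group": i % 2,
                         "age_months": 6.0, "timepoint": "t1",
                         "net_a": rng.uniform(0.5, 1.5),
                         "net_b": rng.uniform(0.5, 1.5)})
        import pandas as pd
        return pd.DataFrame(rows)

    def test_null_coupling_is_independent(self, tiny_design, tiny_truth):
        from scipy.stats import spearmanr
        tiny_truth.cognition_coupling = np.zeros(2)
        tab = self._table(tiny_design, tiny_truth, n=10)
        beh = simulate_behavior(tiny_truth, tab, noise_sd=1.0, seed=5)
        rho, _ = spearmanr(tab["net_a"], beh["n_trials"])
        assert abs(rho) < 0.3

    def test_strong_coupling_monotone(self, tiny_design, tiny_truth):
        from scipy.stats import spearmanr
        tiny_truth.cognition_coupling = np.array([1.0, 0.0])
        tab = self._table(tiny_design, tiny_truth, n=30)
        beh = simulate_behavior(tiny_truth, tab, noise_sd=0.0, seed=2)
        rho, _ = spearmanr(tab["net_a"], beh["correct_ratio"])
        assert rho > 0.999

    def test_ranges(self, tiny_design, tiny_truth):
        tab = self._table(tiny_design, tiny_truth, n=50)
        beh = simulate_behavior(tiny_truth, tab, noise_sd=2.0, seed=3)
        assert beh["n_trials"].between(0, 90).all()
        assert beh["correct_ratio"].between(0, 1).all()

    def test_planted_amplitude_table_layout(self, tiny_design, tiny_truth):
        recs = simulate_cohort_records(tiny_design, tiny_truth)
        tab = planted_amplitude_table(recs, tiny_truth.network_names)
        assert {"subject_id", "timepoint", "net_a", "net_b"} <= set(tab.columns)
        assert len(tab) == 2
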