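"""Mixed-effects fits, rank tests, FDR and brain-behavior correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rsnlong.cohort import CohortDesign
from rsnlong.experiment import simulate_metric_table
from rsnlong.longstats import (bh_fdr, fit_lme, fit_lme_per_group,
                               analyze_metric, group_tests, kruskal_wallis,
                               significance_tier, spearman_behavior)


def exact_table(beta=(1.0, 0.5, 0.1, -0.2)):
    """Noise-free longitudinal data generated exactly from the fixed-effect
    part of the mixed model (zero offsets, zero residual)."""
    b0, b1, b2, b3 = beta
    rows = []
    for g in range(2):
        for s in range(4):
            for age in (5.0, 8.0, 11.0, 14.0, 17.0):
                a = age + 0.1 * s  # break exact collinearity across subjects
                rows.append({
                    "subject_id": f"g{g}s{s}", "group": g, "age_months": a,
                    "timepoint": "t", "amplitude": b0 + b1 * g + b2 * a
                    + b3 * g * a})
    return pd.DataFrame(rows)


class TestFitLme:
    def test_zero_noise_identifiability(self):
        res = fit_lme(exact_table())
        np.testing.assert_allclose(res.estimates, [1.0, 0.5, 0.1, -0.2],
                                   atol=1e-6)
        assert res.sigma_subject == pytest.approx(0.0, abs=1e-4)
        assert res.sigma_resid == pytest.approx(0.0, abs=1e-4)

    def test_recovers_planted_interaction_with_noise(self):
        rng = np.random.default_rng(0)
        est = [fit_lme(simulate_metric_table(rng)).beta("group_x_age")
               for _ in range(20)]
        mean, se = np.mean(est), np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(mean - (-0.03)) < 3 * se

    def test_rejects_bad_group_coding(self):
        df = exact_table()
        df["group"] = df["group"] + 1
        with pytest.raises(ValueError):
            fit_lme(df)

    def test_requires_repeated_measures(self):
        df = exact_table().groupby("subject_id").head(1)
        with pytest.raises(ValueError):
            fit_lme(df)


class TestPerGroupGating:
    def test_interaction_triggers_per_group_fits(self):
        out = analyze_metric(exact_table())  # strong planted interaction
        assert set(out["per_group"]) == {0, 1}
        g0 = out["per_group"][0]
        assert g0.beta("age") == pytest.approx(0.1, abs=1e-6)
        g1 = out["per_group"][1]
        assert g1.beta("age") == pytest.approx(-0.1, abs=1e-6)

    def test_no_interaction_no_per_group_fits(self):
        rng = np.random.default_rng(5)
        df = simulate_metric_table(rng, beta=(1.0, 0.0, 0.01, 0.0))
        out = analyze_metric(df)
        if out["full"].p("group_x_age") >= 0.05:
            assert out["per_group"] == {}

    def test_per_group_rejects_mixed_groups(self):
        with pytest.raises(ValueError):
            fit_lme_per_group(exact_table())


def kw_oracle(*samples):
    """Hand rank formula: H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2, with
    tie correction."""
    all_vals = np.concatenate(samples)
    n = all_vals.size
    ranks = sps.rankdata(all_vals)
    start = 0
    h = 0.0
    for s in samples:
        r = ranks[start:start + s.size]
        h += s.size * (r.mean() - (n + 1) / 2) ** 2
        start += s.size
    h *= 12 / (n * (n + 1))
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    return h / tie


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, p = kruskal_wallis(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        # 12/42*(36/3 + 225/3) - 21 = 27/7
        assert h == pytest.approx(27 / 7, abs=1e-10)

    def test_label_permutation_invariance(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(6)
        assert kruskal_wallis(a, b)[0] == pytest.approx(
            kruskal_wallis(b, a)[0], abs=1e-12)

    def test_matches_rank_formula_on_all_splits(self):
        vals = np.arange(1.0, 7.0)
        for comb in itertools.combinations(range(6), 3):
            a = vals[list(comb)]
            b = vals[[i for i in range(6) if i not in comb]]
            h, _ = kruskal_wallis(a, b)
            assert h == pytest.approx(kw_oracle(a, b), abs=1e-10)

    def test_ties_handled(self):
        h, _ = kruskal_wallis(np.array([1.0, 1, 2]), np.array([2.0, 3, 3]))
        assert h == pytest.approx(kw_oracle(np.array([1.0, 1, 2]),
                                            np.array([2.0, 3, 3])), abs=1e-10)

    def test_identical_values_p_one(self):
        with pytest.warns(UserWarning):
            h, p = kruskal_wallis(np.array([2.0, 2]), np.array([2.0, 2]))
        assert h == 0.0 and p == 1.0


def bh_oracle(p):
    """Literal step-up definition: adj_i = min over j>=i of p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return np.minimum(adj, 1.0)


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_uniform_ladder_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05]),
                                   [0.05] * 5, atol=1e-12)

    def test_matches_bruteforce_on_grid_lists(self):
        grid = [0.001, 0.005, 0.01, 0.04, 0.05, 0.1, 0.3, 0.6, 0.9]
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(1, 9))
            p = rng.choice(grid, size=n)
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestTiersAndGroupTests:
    @pytest.mark.parametrize("p,expected", [
        (0.049, "significant"), (0.05, "tendency"), (0.099, "tendency"),
        (0.1, "none"), (0.5, "none")])
    def test_tier_boundaries(self, p, expected):
        assert significance_tier(p) == expected

    def test_group_tests_family_and_monotonicity(self):
        rng = np.random.default_rng(3)
        df = simulate_metric_table(rng, beta=(1.0, 0.3, 0.0, -0.05))
        df["network"] = "netX"
        df["shape"] = df["amplitude"] + rng.normal(0, 0.05, len(df))
        out = group_tests(df)
        assert set(out["timepoint"]) == {"t1", "t2", "t3", "t4", "t5"}
        assert (out["p_fdr"] >= out["p_raw"] - 1e-12).all()
        for (_, _), fam in out.groupby(["network", "metric"]):
            np.testing.assert_allclose(
                fam["p_fdr"].to_numpy(),
                bh_oracle(fam["p_raw"].to_numpy()), atol=1e-12)


class TestSpearmanBehavior:
    def _tables(self, n=9, coupled=True, seed=0):
        rng = np.random.default_rng(seed)
        amp = rng.uniform(0.5, 1.5, n)
        met = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)], "group": 0,
            "age_months": 6.0, "timepoint": "t1", "network": "netA",
            "amplitude": amp, "shape": rng.standard_normal(n)})
        score = amp if coupled else rng.uniform(0, 1, n)
        beh = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)], "timepoint": "t1",
            "n_trials": (score * 50).astype(int),
            "correct_ratio": score})
        return met, beh

    def test_monotone_transform_gives_rho_one(self):
        met, beh = self._tables(coupled=True)
        out = spearman_behavior(met, beh, metrics=("amplitude",),
                                measures=("correct_ratio",))
        assert out["spearman_rho"].iloc[0] == pytest.approx(1.0)

    def test_sign_antisymmetry(self):
        met, beh = self._tables(coupled=True, n=12)
        flipped = beh.assign(correct_ratio=-beh["correct_ratio"])
        a = spearman_behavior(met, beh, metrics=("amplitude",),
                              measures=("correct_ratio",))
        b = spearman_behavior(met, flipped, metrics=("amplitude",),
                              measures=("correct_ratio",))
        assert a["spearman_rho"].iloc[0] == pytest.approx(
            -b["spearman_rho"].iloc[0], abs=1e-12)

    def test_small_stratum_skipped(self):
        met, beh = self._tables(n=3)
        with pytest.warns(UserWarning, match="skipped"):
            out = spearman_behavior(met, beh)
        assert out.empty


def _planted_amplitude_frame(design, truth):
    """Planted per-acquisition amplitudes without generating volumes."""
    import pandas as pd

    from rsnlong.cohort import planted_amplitudes
    root = np.random.SeedSequence(design.seed)
    rows, i_s = [], 0
    seeds = root.spawn(sum(design.n_subjects))
    for g in range(2):
        for s in range(design.n_subjects[g]):
            srng = np.random.default_rng(seeds[i_s])
            i_s += 1
            offset = srng.normal(0.0, truth.subject_sd, truth.n_networks)
            for p, tp in enumerate(design.timepoints):
                if s >= design.group_sizes[g][p]:
                    continue
                age = float(design.age_means[g][p]
                            + srng.normal(0, design.age_sds[g][p]))
                row = {"subject_id": f"g{g}s{s:02d}", "group": g,
                       "age_months": age, "timepoint": tp}
                amp = planted_amplitudes(truth, g, age, offset)
                row.update({nm: amp[k]
                            for k, nm in enumerate(truth.network_names)})
                rows.append(row)
    return pd.DataFrame(rows)


class TestBehaviorPowerCheck:
    def test_spearman_stage_flags_coupled_network(self):
        """Behavioral scores coupled to one network's planted amplitude:
        across seeded replicates, the Spearman stage flags that network in
        at least one stratum and in strictly more strata than any uncoupled
        network.  Power is limited by within-stratum amplitude variation
        (subject offsets) relative to amplitude measurement noise, so the
        check runs at low (5%) measurement noise."""
        from dataclasses import replace

        from rsnlong.cohort import CohortDesign, default_ground_truth, \
            simulate_behavior
        nets = ("somatosensorial_I", "somatosensorial_II", "sensorimotor")
        ok, n_rep = 0, 50
        for i in range(n_rep):
            design = replace(CohortDesign(), seed=60_000 + i)
            truth = default_ground_truth(design)
            tab = _planted_amplitude_frame(design, truth)
            beh = simulate_behavior(truth, tab, noise_sd=0.1,
                                    seed=design.seed + 7)
            rng = np.random.default_rng(design.seed + 99)
            mrows = []
            for _, r in tab.iterrows():
                for nm in nets:
                    mrows.append({
                        "subject_id": r.subject_id, "group": r.group,
                        "age_months": r.age_months, "timepoint": r.timepoint,
                        "network": nm,
                        "amplitude": r[nm] * (1 + rng.normal(0, 0.05)),
                        "shape": np.nan})
            out = spearman_behavior(pd.DataFrame(mrows),
                                    beh, metrics=("amplitude",))
            flags = out[out.significant].groupby("network").size()
            coupled = flags.get("somatosensorial_I", 0)
            uncoupled = max(flags.get("somatosensorial_II", 0),
                            flags.get("sensorimotor", 0))
            ok += (coupled >= 1 and coupled > uncoupled)
        assert ok / n_rep >= 0.8
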