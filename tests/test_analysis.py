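import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinepath.analysis import (
    ReferencePaths,
    compute_trial_metrics,
    many_to_one_posthoc,
    one_way_anova,
    summarize_blocks,
)
from kinepath.containers import Trajectory
from kinepath.metrics import discrete_frechet
from kinepath.paths import effort_optimal_trajectory, min_jerk_trajectory
from kinepath.synth import ExperimentDataset, GroupSpec, TrialRecord


# ---------------------------------------------------------------------- ANOVA


def test_anova_all_equal_and_degenerate():
    res = one_way_anova([[1.0, 1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
    assert res.F == 0.0 and res.p_value == 1.0 and res.degenerate
    res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
    assert np.isinf(res.F) and res.p_value == 0.0 and res.degenerate
    with pytest.raises(ValueError):
        one_way_anova([[1.0, 2.0]])


def test_anova_two_groups_equals_squared_t(rng):
    a, b = rng.normal(0, 1, 9), rng.normal(0.5, 1, 7)
    res = one_way_anova([a, b])
    t, p = stats.ttest_ind(a, b)
    assert res.F == pytest.approx(t**2, rel=1e-12)
    assert res.p_value == pytest.approx(p, rel=1e-12)


def test_anova_matches_scipy_and_hand_sums(rng):
    groups = [rng.normal(m, 1.0, 6) for m in (0.0, 0.3, 1.0)]
    res = one_way_anova(groups)
    F, p = stats.f_oneway(*groups)
    assert res.F == pytest.approx(F, rel=1e-12)
    assert res.p_value == pytest.approx(p, rel=1e-12)
    assert (res.df_between, res.df_within) == (2, 15)
    # worked sums-of-squares arithmetic on a small fixed table
    tbl = [[3.0, 4.0, 5.0], [6.0, 7.0, 8.0], [9.0, 10.0, 11.0]]
    grand = 7.0
    ssb = 3 * ((4 - grand) ** 2 + (7 - grand) ** 2 + (10 - grand) ** 2)  # 54
    ssw = 6.0
    expected_F = (ssb / 2) / (ssw / 6)
    assert one_way_anova(tbl).F == pytest.approx(expected_F, rel=1e-12)


# ----------------------------------------------------------------- post-hoc


def test_posthoc_refuses_low_precision(rng):
    groups = [rng.normal(size=5) for _ in range(3)]
    with pytest.raises(ValueError, match="n_mc"):
        many_to_one_posthoc(groups, n_mc=500)


def test_posthoc_single_contrast_equals_unadjusted(rng):
    a, b = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
    res = many_to_one_posthoc([a, b], control=0, n_mc=50_000, seed=3)
    # with one contrast there is no multiplicity: Bonferroni = unadjusted
    assert res.p_adjusted[0] == pytest.approx(res.p_unadjusted[0], abs=1e-12)


def test_posthoc_bracketed_by_unadjusted_and_bonferroni(rng):
    for _ in range(20):
        k = rng.integers(3, 5)
        groups = [rng.normal(rng.normal(0, 0.5), 1.0, rng.integers(4, 9)) for _ in range(k)]
        res = many_to_one_posthoc(groups, control=0, n_mc=2_000, seed=int(rng.integers(1e6)))
        assert np.all(res.p_adjusted >= res.p_unadjusted - 1e-12)
        assert np.all(res.p_adjusted <= res.p_bonferroni + 1e-12)


def test_posthoc_matches_scipy_dunnett():
    rng = np.random.default_rng(2024)
    control = rng.normal(0.0, 1.0, 8)
    g2 = rng.normal(1.2, 1.0, 8)
    g3 = rng.normal(0.4, 1.0, 8)
    res = many_to_one_posthoc([control, g2, g3], control=0, n_mc=200_000, seed=11)
    ref = stats.dunnett(g2, g3, control=control)
    np.testing.assert_allclose(res.p_adjusted, ref.pvalue, atol=0.01)


def test_posthoc_null_is_unremarkable(rng):
    groups = [rng.normal(0, 1, 8) for _ in range(3)]
    res = many_to_one_posthoc(groups, control=0, n_mc=20_000, seed=1)
    assert np.all(res.p_adjusted >= res.p_unadjusted - 1e-12)
    assert np.all(res.p_adjusted <= 1.0)


def test_posthoc_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        many_to_one_posthoc([[1.0, 1.0], [2.0, 2.0]], n_mc=1000)


# ----------------------------------------------------- references & metrics


def test_point_mass_energy_reference_is_straight(layout):
    refs = ReferencePaths(layout)
    pair = (0, 1)
    s = refs.straight(pair)
    e = refs.energy(pair, "point_mass")
    np.testing.assert_allclose(s.points, e.points)


def test_reference_disk_cache_roundtrip(layout, tmp_path):
    refs = ReferencePaths(layout, cache_dir=tmp_path)
    p1 = refs.energy((0, 1))
    files = list(tmp_path.glob("geodesic_*.json"))
    assert len(files) == 1
    refs2 = ReferencePaths(layout, cache_dir=tmp_path)
    p2 = refs2.energy((0, 1))
    np.testing.assert_allclose(p1.points, p2.points, atol=1e-15)


def _kinematic_trial(group, subject, block, trial, pair, traj):
    return TrialRecord(group=group, subject=subject, block=block, trial=trial,
                       start_target=pair[0], end_target=pair[1], trajectory=traj)


def _toy_dataset(layout, trials):
    from kinepath.synth import ExperimentConfig, default_group_specs

    return ExperimentDataset(trials=trials, config=ExperimentConfig(),
                             specs=default_group_specs(), layout=layout)


def test_trial_metrics_on_reference_trajectories(pend, layout):
    a, b = layout.center(0), layout.center(1)
    mj = min_jerk_trajectory(a, b, 1.0, rate=100.0)
    eff = effort_optimal_trajectory(pend, a, b)
    ds = _toy_dataset(layout, [
        _kinematic_trial(2, 1, 1, 0, (0, 1), mj),
        _kinematic_trial(1, 1, 1, 0, (0, 1), eff),
    ])
    m = compute_trial_metrics(ds)
    # a perfect straight reach sits on the straight reference (up to clipping)
    assert m.loc[0, "dfd_straight"] < 2e-3
    # a reach on the effort-optimal path is near the least-energy geodesic
    assert m.loc[1, "dfd_energy"] < 5e-3
    assert m.loc[1, "dfd_straight"] > m.loc[0, "dfd_straight"]


def test_trial_metrics_flags_still_trials(layout):
    t = np.linspace(0, 1, 101)
    still = Trajectory(t=t, pos=np.tile(layout.center(0), (101, 1)), vel=np.zeros((101, 2)))
    ds = _toy_dataset(layout, [
        _kinematic_trial(2, 1, 1, 0, (0, 1),
                         min_jerk_trajectory(layout.center(0), layout.center(1), 1.0)),
        _kinematic_trial(2, 1, 1, 1, (0, 1), still),
    ])
    m = compute_trial_metrics(ds)
    assert not m.loc[0, "excluded"]
    assert m.loc[1, "excluded"] and "movement" in m.loc[1, "reason"]
    subj, _ = summarize_blocks(m)
    assert subj["n_trials"].tolist() == [1]


# ------------------------------------------------------------------ summaries


def _metrics_frame(rows):
    return pd.DataFrame(rows, columns=["group", "subject", "block", "trial",
                                       "start_target", "end_target",
                                       "dfd_straight", "dfd_energy", "excluded", "reason"])


def test_summarize_identical_trials_zero_width():
    rows = [(1, 1, 1, k, 0, 1, 0.01, 0.02, False, "") for k in range(5)]
    subj, grp = summarize_blocks(_metrics_frame(rows))
    assert subj["dfd_straight"].iloc[0] == pytest.approx(0.01)
    assert grp["dfd_straight_ci"].iloc[0] == 0.0  # single subject: no interval


def test_summarize_duplication_invariance(rng):
    rows = []
    for s in (1, 2, 3):
        for k in range(4):
            rows.append((1, s, 1, k, 0, 1, rng.uniform(0, 0.02), rng.uniform(0, 0.02),
                         False, ""))
    base = _metrics_frame(rows)
    doubled = pd.concat([base, base], ignore_index=True)
    s1, g1 = summarize_blocks(base)
    s2, g2 = summarize_blocks(doubled)
    np.testing.assert_allclose(s1["dfd_straight"], s2["dfd_straight"])
    np.testing.assert_allclose(g1["dfd_straight_ci"], g2["dfd_straight_ci"])


def test_summarize_three_value_ci_oracle():
    vals = [0.010, 0.014, 0.018]
    rows = [(1, s, 1, 0, 0, 1, v, v, False, "") for s, v in enumerate(vals, 1)]
    _, grp = summarize_blocks(_metrics_frame(rows))
    sd = np.std(vals, ddof=1)
    expected = stats.t.ppf(0.975, 2) * sd / np.sqrt(3)
    assert grp["dfd_straight"].iloc[0] == pytest.approx(np.mean(vals))
    assert grp["dfd_straight_ci"].iloc[0] == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        summarize_blocks(_metrics_frame([]))
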