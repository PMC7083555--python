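import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from conftest import make_control_cohort
from normdev.inference import (
    TfceParams,
    association_tests,
    bh_adjust,
    group_contrast_map,
    group_mean_map,
    holm_correct,
    quasibinomial_wald,
    score_group_test,
    signed_tfce,
    tfce_transform,
)
from normdev.deviations import bh_reject
from normdev.normative import DeviationStack


def holm_oracle(p, m=None):
    """Definitional step-down Holm with monotonicity (explicit loop)."""
    p = list(p)
    m_eff = m if m is not None else len(p)
    order = sorted(range(len(p)), key=lambda i: p[i])
    adj = [0.0] * len(p)
    prev = 0.0
    for rank, idx in enumerate(order):
        value = min(1.0, (m_eff - rank) * p[idx])
        prev = max(prev, value)
        adj[idx] = prev
    return np.array(adj)


def tfce_oracle(stat_map, H, E, dh, structure):
    """Threshold-sum TFCE at matched midpoint steps (independent per-label loop)."""
    from scipy import ndimage

    s = np.asarray(stat_map, dtype=float)
    out = np.zeros_like(s)
    hmax = s.max(initial=0.0)
    for step in range(int(np.ceil(hmax / dh))):
        h = (step + 0.5) * dh
        labels, n = ndimage.label(s >= h, structure=structure)
        for lab in range(1, n + 1):
            comp = labels == lab
            out[comp] += comp.sum() ** E * h**H * dh
    return out


def make_stack(z, mask=None):
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if mask is None:
        side = int(np.ceil(z.shape[1] ** (1 / 3)))
        mask = np.zeros((side, side, side), dtype=bool)
        mask.ravel()[: z.shape[1]] = True
    return DeviationStack(
        z, [f"s{i}" for i in range(len(z))], mask, np.eye(4), ["test"] * len(z)
    )


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_correct([0.03]) == pytest.approx([0.03])

    def test_two_values_by_definition(self):
        assert holm_correct([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_sandwich_property(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(1e-4, 1, rng.integers(1, 10))
            adj = holm_correct(p)
            assert (adj >= p - 1e-15).all()
            assert (adj <= np.minimum(1.0, len(p) * p) + 1e-15).all()

    def test_matches_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.uniform(1e-4, 1, rng.integers(1, 8))
            assert holm_correct(p) == pytest.approx(holm_oracle(p))

    def test_family_larger_than_tests(self):
        assert holm_correct([0.01], m=8) == pytest.approx([0.08])
        assert holm_correct([0.01, 0.02], m=8) == pytest.approx(
            holm_oracle([0.01, 0.02], m=8)
        )

    def test_empty(self):
        assert holm_correct([]).size == 0

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            holm_correct([0.0])
        with pytest.raises(ValueError):
            holm_correct([0.5], m=0)


class TestBhAdjust:
    def test_consistent_with_step_up(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 20)) ** 2
            for q in (0.01, 0.05, 0.2):
                assert np.array_equal(bh_adjust(p) <= q, bh_reject(p, q))

    def test_monotone_in_p(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.5]))
        assert adj[0] <= adj[1] <= adj[2]


class TestTfce:
    def test_all_zero(self):
        assert not tfce_transform(np.zeros((4, 4, 4))).any()

    def test_single_voxel_closed_form(self):
        s = np.zeros((7, 7, 7))
        h0 = 3.0
        s[3, 3, 3] = h0
        params = TfceParams(H=2.0, E=0.5, dh=h0 / 200)
        out = tfce_transform(s, params)
        # lone voxel, extent 1: integral of h^2 dh = h0^3/3
        assert out[3, 3, 3] == pytest.approx(h0**3 / 3, rel=0.02)
        assert out.sum() == pytest.approx(out[3, 3, 3])

    def test_scaling_monotonicity(self):
        rng = np.random.default_rng(3)
        s = np.abs(rng.standard_normal((5, 5, 5)))
        params = TfceParams(dh=0.02)
        assert (tfce_transform(2.0 * s, params) >= tfce_transform(s, params) - 1e-12).all()

    def test_matches_fine_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            s = np.maximum(rng.standard_normal((5, 5, 5)), 0.0) * 2
            dh = float(s.max()) / 50
            params = TfceParams(dh=dh)
            mine = tfce_transform(s, params)
            oracle = tfce_oracle(s, 2.0, 0.5, dh, params.structure())
            assert np.allclose(mine, oracle, rtol=1e-9, atol=1e-12)

    def test_connectivity_changes_components(self):
        s = np.zeros((4, 4, 4))
        s[0, 0, 0] = s[1, 1, 1] = 2.0  # diagonal neighbors: joined only at 26
        v26 = tfce_transform(s, TfceParams(connectivity=26, dh=0.05))[0, 0, 0]
        v6 = tfce_transform(s, TfceParams(connectivity=6, dh=0.05))[0, 0, 0]
        assert v26 > v6

    def test_signed_handles_negative_tail(self):
        s = np.zeros((5, 5, 5))
        s[1, 1, 1] = 3.0
        s[3, 3, 3] = -3.0
        out = signed_tfce(s, TfceParams(dh=0.03))
        assert out[1, 1, 1] > 0 and out[3, 3, 3] < 0
        assert out[1, 1, 1] == pytest.approx(-out[3, 3, 3])

    def test_nonfinite_rejected(self):
        s = np.zeros((3, 3, 3))
        s[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            tfce_transform(s)

    def test_bad_params(self):
        with pytest.raises(ValueError):
            TfceParams(H=-1)
        with pytest.raises(ValueError):
            TfceParams(connectivity=10)


class TestGroupMeanMap:
    def test_all_zero_stat_zero_nothing_significant(self):
        gm = group_mean_map(make_stack(np.zeros((6, 27))), n_perm=200, seed=0)
        assert not gm.stat.any()
        assert not gm.significant_mask.any()
        assert (gm.p_uncorrected[gm.mask] == 1.0).all()

    def test_min_p_with_999_flips(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((12, 27)) * 0.1
        z[:, 0] += 50.0  # overwhelming signal at voxel 0
        gm = group_mean_map(make_stack(z), n_perm=999, seed=1)
        assert gm.p_uncorrected[gm.mask][0] == pytest.approx(1 / 1000)
        assert gm.n_permutations == 999

    def test_exhaustive_enumeration_small_n(self):
        z = np.array([[1.0], [2.0], [1.5]])
        mask = np.ones((1, 1, 1), dtype=bool)
        gm = group_mean_map(make_stack(z, mask), n_perm=500, seed=2)
        # 2^3 = 8 sign patterns, all-same-|t| achieved by global flips only
        assert gm.p_uncorrected[0, 0, 0] == pytest.approx(2 / 8)

    def test_determinism(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal((20, 27))
        a = group_mean_map(make_stack(z), n_perm=300, seed=3)
        b = group_mean_map(make_stack(z), n_perm=300, seed=3)
        assert np.array_equal(a.p_uncorrected, b.p_uncorrected)

    def test_p_uniform_under_null(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((24, 512))
        gm = group_mean_map(make_stack(z), n_perm=250, seed=4)
        p = gm.p_uncorrected[gm.mask]
        assert stats.kstest(p, "uniform").pvalue > 0.001

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            group_mean_map(make_stack(np.zeros((1, 8))), n_perm=100)

    def test_few_permutations_warn(self):
        with pytest.warns(UserWarning):
            group_mean_map(make_stack(np.zeros((4, 8))), n_perm=50, seed=0)


class TestGroupContrastMap:
    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(8)
        a = make_stack(rng.standard_normal((10, 27)))
        b = make_stack(rng.standard_normal((12, 27)) - 0.5)
        m1 = group_contrast_map(a, b, tfce=None, n_perm=50, seed=5)
        m2 = group_contrast_map(b, a, tfce=None, n_perm=50, seed=5)
        assert np.allclose(m1.stat, -m2.stat)

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal((15, 64))
        a, b = make_stack(z), make_stack(z.copy())
        res = group_contrast_map(a, b, tfce=TfceParams(), q=0.05, n_perm=200, seed=6)
        assert not res.significant_mask.any()

    def test_strong_localized_effect_detected(self):
        rng = np.random.default_rng(10)
        mask = np.ones((4, 4, 4), dtype=bool)
        zc = rng.standard_normal((30, 64))
        zp = rng.standard_normal((30, 64))
        zp[:, :8] -= 3.0
        res = group_contrast_map(
            make_stack(zc, mask), make_stack(zp, mask), tfce=None, q=0.05, n_perm=300, seed=7
        )
        sig = res.significant_mask.ravel()
        assert sig[:8].all()
        assert sig[8:].sum() <= 3

    def test_min_p_invariant(self):
        rng = np.random.default_rng(11)
        a = make_stack(rng.standard_normal((10, 27)))
        b = make_stack(rng.standard_normal((10, 27)))
        res = group_contrast_map(a, b, tfce=None, n_perm=99, seed=8)
        p = res.p_uncorrected[res.mask]
        assert p.min() >= 1 / 100
        assert res.n_permutations == 99

    def test_empty_group_rejected(self):
        a = make_stack(np.zeros((5, 8)))
        empty = DeviationStack(np.empty((0, 8)), [], a.mask, np.eye(4), [])
        with pytest.raises(ValueError):
            group_contrast_map(a, empty)

    def test_size_one_group_warns(self):
        rng = np.random.default_rng(12)
        a = make_stack(rng.standard_normal((6, 8)))
        b = make_stack(rng.standard_normal((1, 8)))
        with pytest.warns(UserWarning):
            group_contrast_map(a, b, tfce=None, n_perm=100, seed=9)


def make_scores(events, trials, ids):
    return pd.DataFrame(
        {
            "subject_id": ids,
            "pct_positive": 0.0,
            "pct_negative": 100.0 * np.asarray(events) / trials,
            "n_mask_voxels": trials,
            "method": "fixed-threshold",
            "threshold": 2.6,
        }
    )


def make_cohort_for(ids, diagnoses):
    return pd.DataFrame(
        {
            "subject_id": ids,
            "age": 40.0,
            "sex": "female",
            "diagnosis": diagnoses,
            "hyperactivity": 0,
            "inattention": 0,
            "medication": "no",
            "comorbidity": 0,
        }
    )


class TestScoreGroupTest:
    def test_identical_groups_null(self):
        ids = [f"s{i}" for i in range(20)]
        events = [5] * 20
        scores = make_scores(events, 1000, ids)
        cohort = make_cohort_for(ids, ["control"] * 10 + ["patient"] * 10)
        res = score_group_test(scores, cohort)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p > 0.99

    def test_strong_effect_detected_with_direction(self):
        rng = np.random.default_rng(13)
        ids = [f"s{i}" for i in range(60)]
        events = np.concatenate(
            [rng.poisson(5, 30), rng.poisson(15, 30)]
        )
        scores = make_scores(events, 1000, ids)
        cohort = make_cohort_for(ids, ["control"] * 30 + ["patient"] * 30)
        res = score_group_test(scores, cohort)
        assert res.p < 1e-4
        assert res.effect_direction == 1
        est = res.group_estimates
        assert est["patient"]["pct"] > est["control"]["pct"]
        assert est["control"]["ci_low"] < est["control"]["pct"] < est["control"]["ci_high"]

    def test_closed_form_matches_statsmodels(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            n = 30
            events = rng.integers(1, 50, n)
            trials = np.full(n, 500)
            group = rng.integers(0, 2, n)
            if group.sum() in (0, n):
                continue
            wald, coef = quasibinomial_wald(events, trials, group)
            exog = sm.add_constant(group.astype(float))
            fit = sm.GLM(
                events / trials,
                exog,
                family=sm.families.Binomial(),
                var_weights=trials,
            ).fit(scale="X2")
            assert wald == pytest.approx(float((fit.params[1] / fit.bse[1]) ** 2), rel=1e-6)
            assert coef == pytest.approx(float(fit.params[1]), rel=1e-8)

    def test_permutation_p_agrees_with_wald(self):
        rng = np.random.default_rng(15)
        ids = [f"s{i}" for i in range(40)]
        events = np.concatenate([rng.poisson(8, 20), rng.poisson(12, 20)])
        scores = make_scores(events, 800, ids)
        cohort = make_cohort_for(ids, ["control"] * 20 + ["patient"] * 20)
        res = score_group_test(scores, cohort, n_perm=2000, seed=0)
        # moderate effect: asymptotic and permutation p agree within MC error
        assert res.permutation_p == pytest.approx(res.p, abs=0.05)

    def test_zero_trials_rejected(self):
        ids = ["a", "b"]
        scores = make_scores([0, 0], 1000, ids)
        scores["n_mask_voxels"] = 0
        cohort = make_cohort_for(ids, ["control", "patient"])
        with pytest.raises(ValueError):
            score_group_test(scores, cohort)

    def test_one_group_missing_rejected(self):
        ids = ["a", "b"]
        scores = make_scores([1, 2], 100, ids)
        cohort = make_cohort_for(ids, ["control", "control"])
        with pytest.raises(ValueError):
            score_group_test(scores, cohort)


class TestAssociationTests:
    def make_patients(self, n, seed):
        cohort = make_control_cohort(n, seed).assign(diagnosis="patient")
        rng = np.random.default_rng(seed + 1)
        cohort["hyperactivity"] = rng.integers(0, 10, n)
        cohort["inattention"] = rng.integers(0, 10, n)
        cohort["medication"] = rng.choice(["yes", "no"], n)
        cohort["comorbidity"] = rng.poisson(1.0, n)
        return cohort

    def test_beta_of_covariate_against_itself(self):
        cohort = self.make_patients(50, 20)
        scores = make_scores(np.zeros(50, dtype=int), 100, cohort["subject_id"])
        scores["pct_negative"] = cohort["age"].to_numpy()
        table = association_tests(scores, cohort, covariates=("age",), family_size=1)
        assert table.loc[0, "beta"] == pytest.approx(1.0)

    def test_null_covariates_not_significant(self):
        rng = np.random.default_rng(21)
        cohort = self.make_patients(80, 22)
        scores = make_scores(rng.poisson(10, 80), 1000, cohort["subject_id"])
        table = association_tests(scores, cohort)
        assert (table["p_corrected"] > 0.01).all()
        assert set(table["covariate"]) == {
            "age",
            "hyperactivity",
            "inattention",
            "medication",
            "comorbidity",
        }

    def test_age_linked_scores_detected(self):
        rng = np.random.default_rng(23)
        cohort = self.make_patients(150, 24)
        signal = 0.05 * cohort["age"].to_numpy() + rng.normal(0, 0.5, 150)
        scores = make_scores(np.zeros(150, dtype=int), 100, cohort["subject_id"])
        scores["pct_negative"] = signal
        table = association_tests(scores, cohort, family_size=8)
        row = table[table["covariate"] == "age"].iloc[0]
        assert row["beta"] > 0
        assert row["p_corrected"] < 0.05

    def test_constant_covariate_skipped(self):
        cohort = self.make_patients(30, 25)
        cohort["comorbidity"] = 2
        scores = make_scores(np.arange(30), 1000, cohort["subject_id"])
        table = association_tests(scores, cohort)
        assert "comorbidity" not in set(table["covariate"])

    def test_family_size_respected(self):
        cohort = self.make_patients(40, 26)
        scores = make_scores(np.arange(40), 1000, cohort["subject_id"])
        table = association_tests(scores, cohort, covariates=("age",), family_size=8)
        assert table.loc[0, "p_corrected"] == pytest.approx(
            min(1.0, 8 * table.loc[0, "p"])
        )
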