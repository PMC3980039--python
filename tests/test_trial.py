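"""Between-arm statistics: ANCOVA LSM changes and Kruskal-Wallis."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mealmodel.trial import ChangeRecord, ancova_lsm_change, kruskal_wallis_change


def _records(arms: dict, baselines=None, hba1c=None):
    out = []
    i = 0
    for arm, endpoints in arms.items():
        for j, e in enumerate(endpoints):
            b = 10.0 if baselines is None else baselines[arm][j]
            h = False if hba1c is None else hba1c[arm][j]
            out.append(ChangeRecord(f"S{i:03d}", arm, b, e, h))
            i += 1
    return out


def _ancova_oracle(records, comparator):
    """Brute-force normal-equations OLS with explicit LSM rows."""
    arms = sorted({r.arm for r in records})
    arms = [comparator] + [a for a in arms if a != comparator]
    y = np.array([r.endpoint_value for r in records])
    base = np.array([r.baseline_value for r in records])
    strat = np.array([float(r.baseline_hba1c_high) for r in records])
    cols = [np.ones(len(records))]
    if np.ptp(base) > 0:
        cols.append(base)
    if np.ptp(strat) > 0:
        cols.append(strat)
    for a in arms[1:]:
        cols.append(np.array([1.0 if r.arm == a else 0.0 for r in records]))
    X = np.column_stack(cols)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(records) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return arms, X, beta, cov, dof


class TestAncova:
    def test_inert_covariates_reduce_to_raw_mean_difference(self):
        recs = _records({"A": [11.0, 12.0, 13.0], "B": [13.0, 14.0, 15.0]})
        res = ancova_lsm_change(recs, comparator_arm="B")
        contrast = res.contrasts[0]
        assert contrast.arm == "A"
        assert contrast.diff == pytest.approx(-2.0)
        by_arm = {a.arm: a for a in res.arms}
        assert by_arm["A"].lsm_change == pytest.approx(2.0)
        assert by_arm["B"].lsm_change == pytest.approx(4.0)

    def test_matches_normal_equations_oracle_on_random_designs(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            arms = {f"arm{k}": rng.normal(20, 5, rng.integers(4, 9)) for k in range(3)}
            baselines = {a: rng.normal(18, 4, len(v)) for a, v in arms.items()}
            hba1c = {a: rng.random(len(v)) < 0.3 for a, v in arms.items()}
            recs = _records(
                {a: list(v) for a, v in arms.items()},
                {a: list(v) for a, v in baselines.items()},
                {a: list(v) for a, v in hba1c.items()},
            )
            res = ancova_lsm_change(recs, "arm0")
            names, X, beta, cov, dof = _ancova_oracle(recs, "arm0")
            for j, contrast in enumerate(res.contrasts):
                k = X.shape[1] - len(res.contrasts) + j
                assert contrast.diff == pytest.approx(beta[k], abs=1e-8)
                assert contrast.sem == pytest.approx(np.sqrt(cov[k, k]), abs=1e-8)

    def test_translation_of_endpoints_shifts_lsm_not_contrasts(self):
        rng = np.random.default_rng(5)
        arms = {a: list(rng.normal(20, 3, 6)) for a in ("A", "B")}
        base = {a: list(rng.normal(18, 2, 6)) for a in ("A", "B")}
        recs = _records(arms, base)
        shifted = _records(
            {a: [e + 7.0 for e in v] for a, v in arms.items()}, base
        )
        r1 = ancova_lsm_change(recs, "A")
        r2 = ancova_lsm_change(shifted, "A")
        assert r2.contrasts[0].diff == pytest.approx(r1.contrasts[0].diff, abs=1e-9)
        for a1, a2 in zip(r1.arms, r2.arms):
            assert a2.lsm_change == pytest.approx(a1.lsm_change + 7.0, abs=1e-9)

    def test_log_scale_reports_original_scale_estimates(self):
        rng = np.random.default_rng(9)
        arms = {a: list(rng.lognormal(3, 0.4, 8)) for a in ("A", "B")}
        base = {a: list(rng.lognormal(3, 0.4, 8)) for a in ("A", "B")}
        recs = _records(arms, base)
        raw = ancova_lsm_change(recs, "A", log_scale=False)
        logged = ancova_lsm_change(recs, "A", log_scale=True)
        # point estimates unchanged, significance from the log model
        assert logged.contrasts[0].diff == pytest.approx(raw.contrasts[0].diff)
        assert logged.contrasts[0].p_value != pytest.approx(raw.contrasts[0].p_value)
        assert logged.log_scale

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(11)
        recs = _records({a: list(rng.normal(20, 3, 10)) for a in ("A", "B", "C")})
        res = ancova_lsm_change(recs, "A")
        for c in res.contrasts:
            assert c.ci_low <= c.diff <= c.ci_high
            assert c.sem > 0

    def test_empty_or_tiny_arm_errors(self):
        recs = _records({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0]})
        with pytest.raises(ValueError, match="fewer than 3"):
            ancova_lsm_change(recs, "A")
        with pytest.raises(ValueError, match="absent"):
            ancova_lsm_change(recs[:3], "B")


def _kw_oracle_h(groups):
    """Independent H computation: rank formula with tie correction."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size)
    sorted_vals = pooled[order]
    i = 0
    pos = np.arange(1.0, pooled.size + 1)
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = pos[i : j + 1].mean()
        i = j + 1
    n = pooled.size
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(sorted_vals, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_identical_groups_give_h_zero_p_one(self):
        recs = _records({"A": [11.0, 12.0, 13.0], "B": [11.0, 12.0, 13.0]})
        h, p = kruskal_wallis_change(recs)
        assert h == 0.0
        assert p == 1.0

    def test_matches_rank_oracle_on_six_observations(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([10.0, 11.0, 12.0])]
        recs = _records({"A": [11.0, 12.0, 13.0], "B": [20.0, 21.0, 22.0]})
        h, p = kruskal_wallis_change(recs)  # changes are exactly those groups
        assert h == pytest.approx(_kw_oracle_h(groups), abs=1e-12)
        # exhaustive permutation of group labels: the observed split is the
        # most extreme, so the exact p-value is 2/C(6,3)
        pooled = np.concatenate(groups)
        perm_h = [
            _kw_oracle_h([pooled[list(c)], np.delete(pooled, list(c))])
            for c in itertools.combinations(range(6), 3)
        ]
        exact_p = np.mean(np.asarray(perm_h) >= h - 1e-12)
        assert exact_p == pytest.approx(0.1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        arms = {a: list(rng.normal(0, 1, 6)) for a in ("A", "B", "C")}
        base = {a: [0.0] * 6 for a in arms}
        h1, _ = kruskal_wallis_change(_records(arms, base))
        h2, _ = kruskal_wallis_change(
            _records({a: list(np.exp(v)) for a, v in arms.items()}, base)
        )
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_too_few_records_error(self):
        recs = _records({"A": [1.0, 2.0], "B": [3.0]})
        with pytest.raises(ValueError):
            kruskal_wallis_change(recs)
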