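"""Panel likelihood, optimization, hazard ratios and screening."""

import numpy as np
import pandas as pd
import pytest

from adlmsm import reference
from adlmsm.cohort import CohortConfig, generate_cohort
from adlmsm.ctmc import TRANSITIONS, build_intensity_matrix
from adlmsm.fitting import (
    FittedModel,
    ModelSpec,
    crude_initial_estimates,
    fit,
    hazard_ratios,
    panel_log_likelihood,
    univariate_screen,
)
from conftest import expm_series, make_dataset

REFERENCE_THETA = np.array([np.log(reference.INTENSITIES[t]) for t in TRANSITIONS])


def brute_force_loglik(params, ds, spec):
    """Independent oracle: per-pair evaluation with a power-series expm."""
    theta, betas = spec.split(np.asarray(params, dtype=float))
    total = 0.0
    for _, row in ds.pairs(spec.covariates).iterrows():
        rates = {}
        for j, trans in enumerate(spec.transitions):
            eta = theta[j]
            for c, per in betas.items():
                if trans in per:
                    eta += per[trans] * row[c]
            rates[trans] = np.exp(eta)
        Q = build_intensity_matrix(rates, n_states=3)
        P = expm_series(Q * row["dt"], n_terms=60)
        total += np.log(P[int(row["from_state"]) - 1, int(row["to_state"]) - 1])
    return total


def test_loglik_single_pair_equals_log_p11():
    """One subject seen healthy a year apart contributes log P11(1) = log 0.8022."""
    ds = make_dataset([("A", 0.0, 1), ("A", 1.0, 1)])
    ll = panel_log_likelihood(REFERENCE_THETA, ds)
    assert ll == pytest.approx(np.log(0.8022), abs=5e-4)
    assert ll == pytest.approx(-0.22036, abs=5e-4)


def test_loglik_empty_dataset_is_zero():
    assert panel_log_likelihood(REFERENCE_THETA, make_dataset([])) == 0.0


def test_loglik_additive_over_identical_subjects():
    one = make_dataset([("A", 0.0, 2), ("A", 1.0, 3)])
    two = make_dataset([("A", 0.0, 2), ("A", 1.0, 3), ("B", 0.0, 2), ("B", 1.0, 3)])
    assert panel_log_likelihood(REFERENCE_THETA, two) == pytest.approx(
        2 * panel_log_likelihood(REFERENCE_THETA, one), rel=1e-12
    )


def test_loglik_matches_brute_force_oracle(rng):
    """Grouped likelihood equals per-pair power-series evaluation to 1e-10,
    including covariates and unequal observation gaps."""
    rows = []
    for i in range(5):
        times = np.cumsum(rng.uniform(0.5, 1.8, size=3))
        x = float(i % 2)
        rows.append((f"S{i}", 0.0, int(rng.integers(1, 4)), x))
        for t in times:
            rows.append((f"S{i}", float(t), int(rng.integers(1, 4)), x))
    ds = make_dataset(rows, schema={"x": "binary"})
    spec = ModelSpec(covariates=("x",))
    params = np.concatenate([REFERENCE_THETA, rng.normal(0, 0.3, size=6)])
    assert panel_log_likelihood(params, ds, spec) == pytest.approx(
        brute_force_loglik(params, ds, spec), abs=1e-10
    )


def test_loglik_returns_neg_inf_not_exception():
    ds = make_dataset([("A", 0.0, 1), ("A", 1.0, 3)])
    params = REFERENCE_THETA.copy()
    params[:] = -40.0  # beyond the overflow guard: probability of moving ~ 0
    assert panel_log_likelihood(params, ds) == -np.inf


def test_crude_initial_estimates_from_reference_frequencies():
    Q0 = crude_initial_estimates(reference.TRANSITION_FREQUENCIES, mean_interval=1.0)
    assert Q0[0, 1] == pytest.approx(1556 / 8379, rel=1e-12)
    assert np.allclose(Q0.sum(axis=1), 0.0, atol=1e-12)
    # scale invariance
    Q0_doubled = crude_initial_estimates(2 * reference.TRANSITION_FREQUENCIES)
    assert np.allclose(Q0, Q0_doubled, atol=1e-15)


def test_crude_initial_estimates_floors_zero_counts():
    freq = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 5]])
    Q0 = crude_initial_estimates(freq)
    off = Q0[~np.eye(3, dtype=bool)]
    assert (off == 1e-4).all()


def test_crude_initial_estimates_all_zero_warns():
    with pytest.warns(UserWarning, match="all-zero"):
        Q0 = crude_initial_estimates(np.zeros((3, 3)))
    assert np.allclose(Q0.sum(axis=1), 0.0, atol=1e-15)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = CohortConfig(n_subjects=1200, seed=11, wave_missingness=0.0)
    ds, truth = generate_cohort(cfg)
    return ds, truth


@pytest.fixture(scope="module")
def small_fit(small_cohort):
    ds, _ = small_cohort
    return fit(ds)


def test_fit_recovers_generating_intensities(small_cohort, small_fit):
    """Covariate-free fit on simulated data recovers the large generating
    intensities within 3 Wald SEs on the log scale."""
    f = small_fit
    assert f.converged
    se = f.standard_errors()
    for j, trans in enumerate(TRANSITIONS):
        if trans in ((1, 3), (3, 1)):  # tiny rates: order of magnitude only
            continue
        theta_true = np.log(reference.INTENSITIES[trans])
        assert abs(f.params[j] - theta_true) < 3 * se[j], trans


def test_fit_improves_on_initial_loglik(small_cohort, small_fit):
    ds, _ = small_cohort
    Q0 = crude_initial_estimates(
        np.array([[1, 1, 1], [1, 1, 1], [1, 1, 1]])
    )  # deliberately poor start for the comparison below
    poor = panel_log_likelihood(np.log(Q0[~np.eye(3, dtype=bool)]).reshape(-1), ds)
    assert small_fit.log_likelihood >= poor


def test_fit_invariant_to_subject_relabelling(small_cohort, small_fit):
    ds, _ = small_cohort
    ids = sorted(ds.data["subject_id"].unique())
    relabel = dict(zip(ids, reversed(ids)))
    permuted = ds.data.assign(subject_id=ds.data["subject_id"].map(relabel))
    from adlmsm.panel_data import PanelDataset

    f2 = fit(PanelDataset(permuted, ds.schema), compute_covariance=False)
    assert np.allclose(f2.params, small_fit.params, atol=1e-8)


def _toy_fitted(beta, se):
    spec = ModelSpec(covariates=("x",), covariate_transitions={"x": ((1, 2),)})
    params = np.concatenate([REFERENCE_THETA, [beta]])
    cov = np.zeros((7, 7))
    cov[6, 6] = se**2
    return FittedModel(
        spec=spec, params=params, covariance=cov, log_likelihood=0.0,
        converged=True, n_iter=1, gradient_norm=0.0,
    )


def test_hazard_ratio_null_effect():
    tbl = hazard_ratios(_toy_fitted(0.0, 0.1))
    row = tbl.iloc[0]
    assert row.hr == pytest.approx(1.0)
    assert (row.ci_low, row.ci_high) == (pytest.approx(0.822, abs=1e-3), pytest.approx(1.217, abs=1e-3))
    assert not row.significant


def test_hazard_ratio_degenerate_se():
    row = hazard_ratios(_toy_fitted(np.log(2.0), 0.0)).iloc[0]
    assert row.hr == pytest.approx(2.0, rel=1e-12)
    assert row.ci_low == pytest.approx(2.0, rel=1e-12)
    assert row.significant


def test_hazard_ratio_requires_covariance():
    f = _toy_fitted(0.0, 0.1)
    f.covariance = None
    with pytest.raises(ValueError, match="covariance"):
        hazard_ratios(f)


def test_hazard_ratio_log_linearity():
    """Doubling a generating log effect roughly doubles the recovered log HR."""
    results = {}
    for mult, seed in [(1.0, 5), (2.0, 5)]:
        beta = 0.7 * mult
        cfg = CohortConfig(
            n_subjects=1500, seed=seed, wave_missingness=0.0,
            extra_binary={"expo": 0.5},
            effects={"expo": {(2, 1): beta}},
        )
        ds, _ = generate_cohort(cfg)
        spec = ModelSpec(covariates=("expo",), covariate_transitions={"expo": ((2, 1),)})
        f = fit(ds, spec, compute_covariance=False)
        results[mult] = f.params[-1]
    assert results[2.0] / results[1.0] == pytest.approx(2.0, abs=0.5)


def test_univariate_screen_empty_and_structure(small_cohort):
    ds, _ = small_cohort
    assert univariate_screen(ds, []) == {}
    out = univariate_screen(ds, ["female"])
    assert set(out) == {"female"}
    tbl = out["female"]
    assert len(tbl) == 6  # one HR per transition
    assert (tbl["ci_low"] <= tbl["hr"]).all() and (tbl["hr"] <= tbl["ci_high"]).all()
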