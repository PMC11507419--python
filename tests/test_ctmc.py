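"""Generator assembly, matrix exponentials, covariate modulation, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adlmsm import reference
from adlmsm.ctmc import (
    CovariateModel,
    build_intensity_matrix,
    covariate_intensity,
    observe_at,
    simulate_path,
    transition_probability,
)
from conftest import expm_series

rates_strategy = st.lists(
    st.floats(min_value=0.0, max_value=2.0, allow_nan=False), min_size=6, max_size=6
)


def _random_Q(vals):
    keys = [(1, 2), (1, 3), (2, 1), (2, 3), (3, 1), (3, 2)]
    return build_intensity_matrix(dict(zip(keys, vals)))


def test_build_intensity_matrix_reference_diagonal(reference_Q):
    assert np.allclose(np.diag(reference_Q), [-0.2767, -0.6957, -0.1272], atol=1e-12)
    assert np.allclose(reference_Q.sum(axis=1), 0.0, atol=1e-12)


def test_build_intensity_matrix_rejects_bad_rates():
    with pytest.raises(ValueError, match=">= 0"):
        build_intensity_matrix({(1, 2): -0.1})
    with pytest.raises(ValueError, match="diagonal"):
        build_intensity_matrix({(1, 1): 0.5})
    assert (build_intensity_matrix({(1, 2): 0.0}, n_states=3) == 0).all()


def test_covariate_intensity_null_effect_recovers_baseline(reference_Q):
    model = CovariateModel(
        log_baseline={t: np.log(q) for t, q in reference.INTENSITIES.items()},
        coefficients={t: {"x": 0.0} for t in reference.INTENSITIES},
        covariates=("x",),
    )
    assert np.allclose(covariate_intensity(model, {"x": 3.7}), reference_Q, atol=1e-12)


def test_covariate_intensity_proportionality(reference_Q):
    """A log-2 coefficient on every transition doubles every intensity."""
    model = CovariateModel(
        log_baseline={t: np.log(q) for t, q in reference.INTENSITIES.items()},
        coefficients={t: {"x": np.log(2.0)} for t in reference.INTENSITIES},
        covariates=("x",),
    )
    assert np.allclose(covariate_intensity(model, {"x": 1.0}), 2.0 * reference_Q, atol=1e-10)


def test_covariate_intensity_single_transition_hazard_ratio():
    """An effect of log 4.65 on 1->3 multiplies only q13 by 4.65."""
    model = CovariateModel(
        log_baseline={t: np.log(q) for t, q in reference.INTENSITIES.items()},
        coefficients={(1, 3): {"needs_allowances": np.log(4.65)}},
        covariates=("needs_allowances",),
    )
    Q = covariate_intensity(model, {"needs_allowances": 1.0})
    assert Q[0, 2] == pytest.approx(4.65 * 0.0003, rel=1e-10)
    assert Q[1, 0] == pytest.approx(0.4731, rel=1e-10)


def test_covariate_intensity_schema_mismatch():
    model = CovariateModel(log_baseline={(1, 2): 0.0}, covariates=("x",))
    with pytest.raises(ValueError, match="missing"):
        covariate_intensity(model, {})


def test_transition_probability_limits(reference_Q):
    assert np.allclose(transition_probability(reference_Q, 0.0), np.eye(3), atol=1e-12)
    assert np.allclose(transition_probability(np.zeros((3, 3)), 5.0), np.eye(3), atol=1e-12)
    P = transition_probability(reference_Q, 1.0)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
    assert P.min() >= 0.0


@settings(deadline=None, max_examples=60)
@given(vals=rates_strategy, t=st.floats(min_value=0.0, max_value=3.0, allow_nan=False))
def test_transition_probability_matches_power_series(vals, t):
    Q = _random_Q(vals)
    assert np.allclose(transition_probability(Q, t), expm_series(Q * t), atol=1e-10)


@settings(deadline=None, max_examples=60)
@given(
    vals=rates_strategy,
    a=st.floats(min_value=0.0, max_value=2.0, allow_nan=False),
    b=st.floats(min_value=0.0, max_value=2.0, allow_nan=False),
)
def test_chapman_kolmogorov(vals, a, b):
    """P(a+b) = P(a) P(b) for a time-homogeneous chain."""
    Q = _random_Q(vals)
    lhs = transition_probability(Q, a + b)
    rhs = transition_probability(Q, a) @ transition_probability(Q, b)
    assert np.allclose(lhs, rhs, atol=1e-8)


def test_small_interval_linearization(reference_Q):
    """P(dt) = I + Q dt + O(dt^2)."""
    dt = 1e-4
    P = transition_probability(reference_Q, dt)
    assert np.allclose(P, np.eye(3) + reference_Q * dt, atol=10 * dt**2)


def test_simulate_path_frozen_chain(rng):
    path = simulate_path(np.zeros((3, 3)), 2, t_max=10.0, rng=rng)
    assert path.entries == ((0.0, 2),)


def test_simulate_path_sojourn_and_embedded_chain(reference_Q, rng):
    """Monte-Carlo sojourn mean in state 2 vs 1/0.6957, and first-jump split
    out of state 3 vs the embedded-chain probability 0.1204/0.1272."""
    sojourns = []
    for _ in range(4000):
        path = simulate_path(reference_Q, 2, t_max=50.0, rng=rng)
        if len(path.entries) > 1:
            sojourns.append(path.entries[1][0])
    mean = np.mean(sojourns)
    assert mean == pytest.approx(1 / 0.6957, rel=0.06)

    to_mild = total = 0
    for _ in range(4000):
        path = simulate_path(reference_Q, 3, t_max=80.0, rng=rng)
        if len(path.entries) > 1:
            total += 1
            to_mild += path.entries[1][1] == 2
    assert to_mild / total == pytest.approx(0.1204 / 0.1272, abs=0.03)


def test_observe_at_right_continuous_readoff():
    from adlmsm.ctmc import Trajectory

    path = Trajectory(((0.0, 1), (0.5, 2)), t_max=2.0)
    assert observe_at(path, [0.0, 1.0]) == [1, 2]
    assert observe_at(path, [0.5]) == [2]  # the state entered at t is the state at t
    with pytest.raises(ValueError, match="horizon"):
        observe_at(path, [3.0])


def test_simulated_panel_frequencies_match_probability_rows(reference_Q, rng):
    """One-step frequencies from simulated paths converge to expm(Q) rows."""
    P = transition_probability(reference_Q, 1.0)
    counts = np.zeros((3, 3))
    for _ in range(3000):
        s0 = int(rng.integers(1, 4))
        path = simulate_path(reference_Q, s0, t_max=1.0, rng=rng)
        s1 = observe_at(path, [1.0])[0]
        counts[s0 - 1, s1 - 1] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    assert np.allclose(freq, P, atol=0.05)
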