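"""Prevalence-based goodness of fit.

The fitted model is assessed by comparing, at each assessment time, the
observed percentage of subjects in each disability state against the
percentage expected when every subject's baseline state is propagated
forward through the fitted transition probability matrix ``P(t)``.  Close
agreement of the two curves over the follow-up indicates an adequate fit.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ctmc import transition_probability
from .fitting import FittedModel
from .panel_data import PanelDataset, observed_prevalence

__all__ = ["expected_prevalence", "gof_report", "prevalence_comparison"]


def expected_prevalence(
    model: FittedModel | np.ndarray,
    ds: PanelDataset,
    times: Sequence[float],
    covariate_aware: bool = True,
    n_states: int = 3,
) -> pd.DataFrame:
    """Model-expected state percentages at each requested time.

    For each subject still under observation at ``t`` (last assessment time
    >= ``t``; there is no absorbing state), the row
    ``P_{baseline_state -> .}(t)`` is accumulated and the totals are
    normalized to percentages.  With ``covariate_aware`` (default) ``P`` uses
    each subject's baseline covariates; otherwise — or when ``model`` is a
    bare intensity matrix — a single marginal generator is used.  Times
    beyond the last observation in the data are still computed but flagged in
    the ``extrapolated`` column.
    """
    base = ds.baseline()
    last_time = ds.data.groupby("subject_id")["time"].max()
    t_end = float(ds.data["time"].max())

    is_fit = isinstance(model, FittedModel)
    if is_fit and covariate_aware and model.spec.covariates:
        covs = list(model.spec.covariates)
        missing = [c for c in covs if c not in base.columns]
        if missing:
            raise ValueError(f"dataset lacks model covariates: {missing}")
        z_cols = base[covs].to_numpy(dtype=float)
        patterns, inverse = np.unique(z_cols, axis=0, return_inverse=True)
    else:
        covs = []
        patterns, inverse = np.zeros((1, 0)), np.zeros(len(base), dtype=int)

    Q_for = (
        (lambda z: model.intensity_matrix(dict(zip(covs, z))))
        if is_fit
        else (lambda _z: np.asarray(model, dtype=float))
    )
    Qs = [Q_for(patterns[g]) for g in range(len(patterns))]

    rows = []
    for t in times:
        if t < 0:
            raise ValueError(f"requested time {t} is negative")
        at_risk = base["subject_id"].map(last_time) >= float(t)
        if t > t_end:
            # beyond the follow-up no subject is formally under observation;
            # extrapolate by propagating the whole cohort (flagged below)
            at_risk = at_risk | True
        counts = np.zeros(n_states)
        for g, Q in enumerate(Qs):
            sel = at_risk.to_numpy() & (inverse == g)
            if not sel.any():
                continue
            P = transition_probability(Q, float(t))
            start = base.loc[sel, "state"].to_numpy() - 1
            for s0 in np.unique(start):
                counts += np.sum(start == s0) * P[s0]
        n = counts.sum()
        row: dict[str, float] = {"time": float(t), "n": float(np.round(n)), "extrapolated": t > t_end}
        for s in range(1, n_states + 1):
            row[f"state_{s}"] = 100.0 * counts[s - 1] / n if n > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("time")


def gof_report(
    observed: pd.DataFrame, expected: pd.DataFrame, n_states: int = 3
) -> tuple[pd.DataFrame, Mapping[str, float]]:
    """Combine observed and expected prevalence tables and summarize discrepancy.

    Both tables must share the same time grid (as produced by
    :func:`adlmsm.panel_data.observed_prevalence` and
    :func:`expected_prevalence`).  Returns the combined long table and, per
    state, the maximum absolute percentage-point discrepancy across times.
    """
    if not np.allclose(observed.index.to_numpy(), expected.index.to_numpy()):
        raise ValueError(
            f"time grids differ: observed {list(observed.index)} vs expected {list(expected.index)}"
        )
    state_cols = [f"state_{s}" for s in range(1, n_states + 1)]
    rows = []
    for t in observed.index:
        for col in state_cols:
            rows.append(
                {
                    "time": float(t),
                    "state": int(col.split("_")[1]),
                    "observed_pct": float(observed.loc[t, col]),
                    "expected_pct": float(expected.loc[t, col]),
                    "n_observed": int(observed.loc[t, "n"]),
                }
            )
    table = pd.DataFrame(rows)
    table["discrepancy"] = table["observed_pct"] - table["expected_pct"]
    summary = {
        f"state_{s}": float(
            table.loc[table["state"] == s, "discrepancy"].abs().max()
        )
        for s in range(1, n_states + 1)
    }
    return table, summary


def prevalence_comparison(
    model: FittedModel | np.ndarray,
    ds: PanelDataset,
    times: Sequence[float],
    tolerance: float = 0.5,
    covariate_aware: bool = True,
) -> tuple[pd.DataFrame, Mapping[str, float]]:
    """Convenience wrapper: observed vs expected prevalence on one time grid."""
    obs = observed_prevalence(ds, times, tolerance=tolerance)
    exp = expected_prevalence(model, ds, times, covariate_aware=covariate_aware)
    return gof_report(obs, exp)
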