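"""Long-format panel data: ingestion, validation, filtering and summaries.

One row per subject per assessment, with the observation time in years since
baseline, the three-level disability state (or an ADL total score it is
derived from), and covariate values recorded at that assessment.  The
likelihood of the multi-state model consumes consecutive within-subject
observation pairs; transitions between assessments are interval-censored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adl_scale import classify_state

__all__ = [
    "PanelDataset",
    "read_panel",
    "apply_inclusion_criteria",
    "count_transitions",
    "observed_prevalence",
]

#: Covariate kinds understood by the model: continuous, ordered (ordinal score)
#: or binary (0/1 with 0 the reference level).
COVARIATE_KINDS = ("continuous", "ordered", "binary")


@dataclass
class PanelDataset:
    """Validated long-format panel: columns ``subject_id``, ``time``, ``state`` + covariates.

    ``schema`` maps each covariate column to its kind.  Within each subject
    times are strictly increasing; states are integer codes 1..3.
    """

    data: pd.DataFrame
    schema: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"subject_id", "time", "state"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"panel data missing required columns: {sorted(missing)}")
        for name, kind in self.schema.items():
            if name not in self.data.columns:
                raise ValueError(f"schema covariate {name!r} not present in the data")
            if kind not in COVARIATE_KINDS:
                raise ValueError(f"unknown covariate kind {kind!r} for {name!r}")
        df = self.data.sort_values(["subject_id", "time"], kind="mergesort").reset_index(drop=True)
        if (df["time"] < 0).any():
            bad = df.loc[df["time"] < 0]
            raise ValueError(f"negative observation times for rows:\n{bad}")
        if not df["state"].isin([1, 2, 3]).all():
            bad = df.loc[~df["state"].isin([1, 2, 3])]
            raise ValueError(f"states outside {{1,2,3}} for rows:\n{bad}")
        dup = df.duplicated(subset=["subject_id", "time"], keep=False)
        if dup.any():
            raise ValueError(
                "duplicate (subject, time) observations:\n" + df.loc[dup].to_string()
            )
        df["state"] = df["state"].astype(int)
        self.data = df

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(self.schema)

    def pairs(self, covariates: Sequence[str] = ()) -> pd.DataFrame:
        """Consecutive within-subject observation pairs.

        Returns a frame with ``from_state``, ``to_state``, ``dt`` and, for
        each requested covariate, its value at the start of the interval
        (covariates are held constant across each interval).
        """
        df = self.data
        same = df["subject_id"] == df["subject_id"].shift(-1)
        out = pd.DataFrame(
            {
                "subject_id": df["subject_id"],
                "from_state": df["state"],
                "to_state": df["state"].shift(-1),
                "dt": df["time"].shift(-1) - df["time"],
            }
        )
        for c in covariates:
            if c not in df.columns:
                raise ValueError(f"covariate {c!r} not in the dataset")
            out[c] = df[c]
        out = out.loc[same].reset_index(drop=True)
        out["to_state"] = out["to_state"].astype(int)
        return out

    def baseline(self) -> pd.DataFrame:
        """First observation per subject (state and covariates at baseline)."""
        return (
            self.data.sort_values(["subject_id", "time"], kind="mergesort")
            .groupby("subject_id", sort=False)
            .first()
            .reset_index()
        )


def read_panel(
    source: str | Path | io.TextIOBase,
    column_map: Mapping[str, object],
    sep: str | None = None,
) -> PanelDataset:
    """Read a delimited long-format panel file into a :class:`PanelDataset`.

    Parameters
    ----------
    source
        CSV/TSV path or open text handle.
    column_map
        Mapping with keys ``subject``, ``time`` or ``wave``, ``state`` or
        ``adl_total``, optionally ``covariates`` (list of names, or mapping
        name -> kind) and ``death_flag``.  A ``wave`` column is converted to
        years as wave x 1.0 (annual assessments); an ``adl_total`` column is
        classified into states via the 20-point cutpoints.
    """
    df = pd.read_csv(source, sep=sep, engine="python" if sep is None else "c")

    def _col(key: str) -> str | None:
        name = column_map.get(key)
        if name is None:
            return None
        if name not in df.columns:
            raise ValueError(f"mapped column {name!r} (for {key!r}) not found in the file")
        return str(name)

    subj = _col("subject")
    if subj is None:
        raise ValueError("column_map must map 'subject'")
    out = pd.DataFrame({"subject_id": df[subj]})

    time_col, wave_col = _col("time"), _col("wave")
    if time_col is not None:
        out["time"] = pd.to_numeric(df[time_col], errors="raise").astype(float)
    elif wave_col is not None:
        out["time"] = pd.to_numeric(df[wave_col], errors="raise").astype(float) * 1.0
    else:
        raise ValueError("column_map must map 'time' or 'wave'")

    state_col, adl_col = _col("state"), _col("adl_total")
    if state_col is not None:
        states = pd.to_numeric(df[state_col], errors="raise")
    elif adl_col is not None:
        totals = pd.to_numeric(df[adl_col], errors="raise")
        states = totals.map(lambda t: classify_state(t).code)
    else:
        raise ValueError("column_map must map 'state' or 'adl_total'")
    out["state"] = states

    cov_spec = column_map.get("covariates", {})
    if isinstance(cov_spec, Mapping):
        schema = {str(k): str(v) for k, v in cov_spec.items()}
    else:
        schema = {str(name): "continuous" for name in cov_spec}
    for name in schema:
        if name not in df.columns:
            raise ValueError(f"mapped covariate column {name!r} not found in the file")
        out[name] = pd.to_numeric(df[name], errors="raise")

    death_col = _col("death_flag")
    if death_col is not None:
        deceased = df.loc[df[death_col].astype(bool), subj].unique()
        out = out.loc[~out["subject_id"].isin(deceased)].reset_index(drop=True)

    return PanelDataset(out, schema)


def apply_inclusion_criteria(
    ds: PanelDataset, min_age: float = 60.0, age_covariate: str | None = "age"
) -> tuple[PanelDataset, dict[str, int]]:
    """Apply the cohort inclusion criteria and report exclusions.

    Subjects are removed when their baseline age is below ``min_age`` (pass
    ``age_covariate=None`` to skip the age rule) or when they have fewer than
    two observations — both assessments are needed to contribute a transition
    interval.  Age is applied first; the report counts removals per rule.
    """
    report = {"age_below_minimum": 0, "fewer_than_two_assessments": 0}
    df = ds.data
    keep = df

    if age_covariate is not None:
        if age_covariate not in df.columns:
            raise ValueError(
                f"age covariate {age_covariate!r} not in the dataset; "
                "pass age_covariate=None to skip age filtering"
            )
        base = ds.baseline()
        too_young = set(base.loc[base[age_covariate] < min_age, "subject_id"])
        report["age_below_minimum"] = len(too_young)
        keep = keep.loc[~keep["subject_id"].isin(too_young)]

    counts = keep.groupby("subject_id")["time"].size()
    single = set(counts.index[counts < 2])
    report["fewer_than_two_assessments"] = len(single)
    keep = keep.loc[~keep["subject_id"].isin(single)].reset_index(drop=True)
    return PanelDataset(keep, ds.schema), report


def count_transitions(ds: PanelDataset, n_states: int = 3) -> np.ndarray:
    """Transition frequency matrix over all consecutive observation pairs.

    Entry ``[r-1, s-1]`` counts pairs observed in state ``r`` then state
    ``s`` at the next assessment, regardless of the interval length; the
    diagonal counts same-state pairs.
    """
    counts = np.zeros((n_states, n_states), dtype=int)
    pairs = ds.pairs()
    if len(pairs):
        np.add.at(counts, (pairs["from_state"].to_numpy() - 1, pairs["to_state"].to_numpy() - 1), 1)
    return counts


def observed_prevalence(
    ds: PanelDataset,
    times: Sequence[float],
    tolerance: float = 0.5,
    n_states: int = 3,
) -> pd.DataFrame:
    """Observed state percentages at each requested time.

    Each subject contributes their observation closest to the requested time,
    provided it falls within ``tolerance`` years.  Percentages sum to 100 at
    every time where at least one subject matched; unmatched times get NaN
    percentages and ``n = 0``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    rows = []
    df = ds.data
    for t in times:
        if t < 0:
            raise ValueError(f"requested time {t} is negative")
        gap = (df["time"] - float(t)).abs()
        near = df.assign(gap=gap).loc[gap <= tolerance]
        matched = (
            near.sort_values(["subject_id", "gap"], kind="mergesort")
            .groupby("subject_id", sort=False)
            .first()
        )
        n = len(matched)
        if n == 0:
            rows.append({"time": float(t), "n": 0, **{f"state_{s}": np.nan for s in range(1, n_states + 1)}})
            continue
        pct = {
            f"state_{s}": 100.0 * (matched["state"] == s).sum() / n
            for s in range(1, n_states + 1)
        }
        rows.append({"time": float(t), "n": n, **pct})
    return pd.DataFrame(rows).set_index("time")
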