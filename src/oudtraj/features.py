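"""Start-stop person-period construction with time-indexed concept features.

Every concept (or pooled concept group) contributes five transforms evaluated
at risk-set time ``t`` on the transition's clock:

``cnt_30d, cnt_90d, cnt_365d``
    occurrences in the half-open window ``(t - w, t]``;
``cum``
    occurrences up to and including ``t``;
``days_since_last``
    ``t`` minus the day of the most recent occurrence at or before ``t``.

Count transforms are reported on the ``log(1 + x)`` scale so that hazard
ratios read "per unit of log(1 + count)"; ``days_since_last`` stays in days.
A person who never had the concept gets ``days_since_last`` equal to the
follow-up horizon plus one (a finite sentinel, always paired with ``cum`` 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: transform names, in canonical column order
TRANSFORMS = ("cnt_30d", "cnt_90d", "cnt_365d", "cum", "days_since_last")

_WINDOWED = {"cnt_30d": 30, "cnt_90d": 90, "cnt_365d": 365}


@dataclass(frozen=True)
class FeatureSpec:
    """Conventions for the time-indexed feature transforms.

    Parameters
    ----------
    windows : increasing window lengths in days for the count transforms.
    horizon_days : follow-up horizon; the ``days_since_last`` sentinel for a
        never-observed concept is ``horizon_days + 1``.
    log_counts : apply ``log(1 + x)`` to the four count transforms.
    """

    windows: tuple[int, int, int] = (30, 90, 365)
    horizon_days: int = 730
    log_counts: bool = True

    def __post_init__(self) -> None:
        if list(self.windows) != sorted(set(self.windows)):
            raise ValueError("windows must be strictly increasing")
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be positive")

    @property
    def sentinel(self) -> int:
        return self.horizon_days + 1


def transform_counts(x):
    """Map a nonnegative count ``x`` to ``log(1 + x)`` (natural log)."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    out = np.log1p(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def feature_name(concept: str, transform: str) -> str:
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    return f"{concept}_{transform}"


def feature_names(concepts: Iterable[str]) -> list[str]:
    """All feature column names for ``concepts``, concept-major order."""
    return [feature_name(c, t) for c in concepts for t in TRANSFORMS]


def parse_feature_name(name: str) -> tuple[str, str]:
    """Invert :func:`feature_name`; raises ``ValueError`` if unparseable."""
    for t in TRANSFORMS:
        suffix = "_" + t
        if name.endswith(suffix) and len(name) > len(suffix):
            return name[: -len(suffix)], t
    raise ValueError(f"{name!r} does not parse to (concept, transform)")


def evaluate_concept(days: np.ndarray, t, spec: FeatureSpec) -> dict[str, np.ndarray]:
    """Evaluate the five transforms for one sorted day array at times ``t``.

    ``days`` are absolute event days (sorted ascending); ``t`` is an array of
    absolute evaluation times.  Windows are half-open ``(t - w, t]``: an event
    exactly ``w`` days before ``t`` is excluded, an event on day ``t`` itself
    is included.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    days = np.asarray(days, dtype=float)
    upto = np.searchsorted(days, t, side="right")  # events with day <= t
    out: dict[str, np.ndarray] = {}
    for name, w in zip(("cnt_30d", "cnt_90d", "cnt_365d"), spec.windows):
        lo = np.searchsorted(days, t - w, side="right")  # events with day > t-w
        out[name] = (upto - lo).astype(float)
    out["cum"] = upto.astype(float)
    if days.size:
        last = np.where(upto > 0, days[np.maximum(upto - 1, 0)], -np.inf)
        out["days_since_last"] = np.where(upto > 0, t - last, float(spec.sentinel))
    else:
        out["days_since_last"] = np.full(t.shape, float(spec.sentinel))
    if spec.log_counts:
        for name in ("cnt_30d", "cnt_90d", "cnt_365d", "cum"):
            out[name] = np.log1p(out[name])
    return out


def _day_arrays(
    events: pd.DataFrame,
    concepts: Sequence[str],
    groups: Mapping[str, Iterable[str]] | None,
) -> dict[str, np.ndarray]:
    """Sorted day array per feature stream (individual concepts + groups)."""
    if np.any(events["day"].to_numpy() < 0):
        raise ValueError("negative event days are not allowed")
    by_concept = {
        c: np.sort(g["day"].to_numpy(dtype=float))
        for c, g in events.groupby("concept_id", sort=False)
    }
    empty = np.empty(0, dtype=float)
    streams = {c: by_concept.get(c, empty) for c in concepts}
    for gname, members in (groups or {}).items():
        pooled = np.sort(
            np.concatenate([by_concept.get(m, empty) for m in members] or [empty])
        )
        streams[gname] = pooled
    return streams


def build_person_periods(
    events: pd.DataFrame,
    record,
    spec: FeatureSpec,
    concepts: Sequence[str],
    groups: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Build the start-stop rows for one person's transition record.

    ``events`` holds this person's events (columns ``concept_id, day``);
    ``record`` is a mapping-like with ``person_id, origin_day, event,
    duration``.  Rows are split at every day a feature stream jumps (a new
    event of a used concept); features on a row are frozen at their value at
    ``t_start``.  The event indicator is set only on the terminal row of an
    event record.
    """
    origin = int(record["origin_day"])
    duration = int(record["duration"])
    if duration <= 0:
        raise ValueError("record duration must be positive")
    streams = _day_arrays(events, concepts, groups)

    end_abs = origin + duration
    all_days = np.unique(np.concatenate([d for d in streams.values()] or [np.empty(0)]))
    # split where a used stream changes, strictly inside the at-risk interval
    splits = all_days[(all_days > origin) & (all_days < end_abs)] - origin
    t_start = np.concatenate([[0.0], splits])
    t_stop = np.concatenate([splits, [float(duration)]])

    cols: dict[str, np.ndarray] = {}
    abs_eval = origin + t_start
    for stream, days in streams.items():
        vals = evaluate_concept(days, abs_eval, spec)
        for tname, arr in vals.items():
            cols[feature_name(stream, tname)] = arr

    out = pd.DataFrame(
        {
            "person_id": record["person_id"],
            "t_start": t_start,
            "t_stop": t_stop,
            "event": 0,
            **cols,
        }
    )
    if int(record["event"]) == 1:
        out.loc[out.index[-1], "event"] = 1
    return out


def expand_static(demographics: pd.DataFrame) -> pd.DataFrame:
    """Expand static covariates; categoricals become indicator columns.

    Numeric columns pass through unchanged.  Object/categorical columns are
    dummy-coded with the most frequent level as the (dropped) reference.
    """
    parts: list[pd.DataFrame] = []
    for col in demographics.columns:
        s = demographics[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).to_frame())
        else:
            ref = s.mode().iloc[0]
            dummies = pd.get_dummies(s, prefix=col, dtype=float)
            dummies = dummies.drop(columns=[f"{col}_{ref}"])
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def build_design(
    events: pd.DataFrame,
    records: pd.DataFrame,
    spec: FeatureSpec,
    concepts: Sequence[str] | None = None,
    groups: Mapping[str, Iterable[str]] | None = None,
    demographics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stack person-period rows for every record of one transition.

    ``records`` is the output of :func:`oudtraj.phenotyping.derive_transitions`
    restricted to one transition.  ``concepts`` defaults to every concept id
    present in ``events`` (sorted); pass an explicit list to keep the design
    stable across shards.  ``demographics`` (indexed by ``person_id``) is
    expanded once and carried unchanged on every row of a person.
    """
    if concepts is None:
        concepts = sorted(events["concept_id"].unique())
    static = expand_static(demographics) if demographics is not None else None
    by_person = dict(tuple(events.groupby("person_id", sort=False)))
    empty = events.iloc[:0]

    frames: list[pd.DataFrame] = []
    for rec in records.to_dict("records"):
        pev = by_person.get(rec["person_id"], empty)
        frames.append(build_person_periods(pev, rec, spec, concepts, groups))
    if not frames:
        cols = ["person_id", "t_start", "t_stop", "event"]
        return pd.DataFrame(columns=cols + feature_names(concepts))
    design = pd.concat(frames, ignore_index=True)
    if static is not None:
        design = design.join(static, on="person_id")
        if design[static.columns].isna().any().any():
            raise ValueError("demographics missing for some persons")
    return design
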