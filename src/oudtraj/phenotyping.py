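"""Derive the three time-to-event transitions from a concept-event stream.

Three single transitions are phenotyped per person, each with end-of-data
censoring:

* **onset** — time from cohort entry (day 0) to the first event in the OUD
  concept set; one record per person.
* **remission** — among persons with at least one OUD event, time from the
  last OUD event to the first remission-coded event.
* **relapse** — among persons with a remission event, time from remission to
  the first subsequent OUD event (strictly after the remission day).

Only the first remission and first relapse are modelled; repeat cycles are
out of scope.  Records whose duration would be zero (e.g. an OUD event and a
remission code on the same day) are dropped with a logged warning, because
the start-stop risk-interval formulation requires strictly positive length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRANSITIONS = ("onset", "remission", "relapse")

#: columns of the transition-record table
RECORD_COLUMNS = [
    "person_id",
    "transition",
    "origin_day",
    "event_day",
    "censor_day",
    "event",
    "duration",
]


@dataclass(frozen=True)
class TransitionRecord:
    """One person's time-to-event record for one transition."""

    person_id: object
    transition: str
    origin_day: int
    event_day: int | None
    censor_day: int
    event: int

    @property
    def duration(self) -> int:
        end = self.event_day if self.event else self.censor_day
        return int(end) - int(self.origin_day)


def _record(person_id, transition, origin, event_day, censor_day):
    event = int(event_day is not None)
    end = event_day if event else censor_day
    duration = int(end) - int(origin)
    if duration <= 0:
        logger.warning(
            "dropping zero/negative-duration %s record for person %s "
            "(origin=%s, end=%s)",
            transition,
            person_id,
            origin,
            end,
        )
        return None
    return {
        "person_id": person_id,
        "transition": transition,
        "origin_day": int(origin),
        "event_day": event_day if event else pd.NA,
        "censor_day": int(censor_day),
        "event": event,
        "duration": duration,
    }


def derive_transitions(
    events: pd.DataFrame,
    oud_concepts: set,
    remission_concepts: set,
    end_of_data: int,
    persons=None,
) -> pd.DataFrame:
    """Build the onset / remission / relapse record table.

    Parameters
    ----------
    events : table with columns ``person_id, concept_id, day``.
    oud_concepts, remission_concepts : disjoint concept-id sets defining the
        qualifying OUD events and the remission codes.
    end_of_data : last observed day; all records are censored here.
    persons : optional iterable fixing the cohort; defaults to every person
        appearing in ``events``.
    """
    if oud_concepts & remission_concepts:
        raise ValueError("OUD and remission concept sets must be disjoint")
    if end_of_data <= 0:
        raise ValueError("end_of_data must be positive")
    if persons is None:
        persons = sorted(events["person_id"].unique())

    ev = events[events["day"] <= end_of_data]
    oud_days = {
        p: np.sort(g["day"].to_numpy())
        for p, g in ev[ev["concept_id"].isin(oud_concepts)].groupby("person_id")
    }
    rem_days = {
        p: np.sort(g["day"].to_numpy())
        for p, g in ev[ev["concept_id"].isin(remission_concepts)].groupby("person_id")
    }

    rows = []
    for p in persons:
        od = oud_days.get(p, np.empty(0, dtype=int))
        rd = rem_days.get(p, np.empty(0, dtype=int))

        # --- onset: cohort entry -> first OUD event
        first_oud = int(od[0]) if od.size else None
        rec = _record(p, "onset", 0, first_oud, end_of_data)
        if rec:
            rows.append(rec)
        if first_oud is None:
            if rd.size:
                logger.warning(
                    "person %s has remission codes but no OUD event; skipped", p
                )
            continue

        # --- remission: last OUD event -> first remission code at/after it
        rd_valid = rd[rd >= first_oud]
        if rd.size and not rd_valid.size:
            logger.warning(
                "person %s: all remission codes precede the first OUD event; "
                "skipped",
                p,
            )
        rem_day = int(rd_valid[0]) if rd_valid.size else None
        if rem_day is not None:
            origin = int(od[od <= rem_day][-1])
        else:
            origin = int(od[-1])  # last OUD event before censoring
        rec = _record(p, "remission", origin, rem_day, end_of_data)
        if rec:
            rows.append(rec)
        if rem_day is None or rec is None:
            continue

        # --- relapse: remission -> first OUD event strictly after it
        after = od[od > rem_day]
        relapse_day = int(after[0]) if after.size else None
        rec = _record(p, "relapse", rem_day, relapse_day, end_of_data)
        if rec:
            rows.append(rec)

    out = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    out["event_day"] = out["event_day"].astype("Int64")
    return out


def read_concept_set(path) -> set[str]:
    """Read a concept set file: one concept id per line, ``#`` comments."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
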