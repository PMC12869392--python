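"""Synthetic concept-event cohorts with planted hazard structure.

The cohort generator emulates sparse, irregular EHR/survey event streams:
each (person, concept) stream is an inhomogeneous Poisson process — a
person-level gamma frailty times a concept-level rate times block-wise
log-normal intensity multipliers — so windowed counts genuinely vary within
a person.  The three opioid-use-disorder transitions (onset, remission,
relapse) are then drawn sequentially from proportional-hazards models whose
log-hazard is a planted linear predictor over exactly the windowed features
the :mod:`oudtraj.features` module computes (evaluated on the person's event
grid, hazard piecewise-constant between events, sampled by inversion).
Observable marker events (an ``oud`` concept at onset and relapse, a ``rem``
concept at remission) are appended to the stream so the phenotyping module
can re-derive the truth; the latent truth table is returned alongside for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .features import FeatureSpec, evaluate_concept, parse_feature_name
from .phenotyping import TRANSITIONS

#: concept ids reserved for the phenotype markers
OUD_CONCEPT = "oud"
REMISSION_CONCEPT = "rem"

_DOMAIN_PREFIX = {"condition": "cond", "drug": "rx", "survey": "svy", "procedure": "proc"}

EVENT_COLUMNS = ["person_id", "concept_id", "domain", "day"]
TRUTH_COLUMNS = ["person_id", "transition", "event_day", "censored"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a lean two-year cohort: 2000 persons, a handful of
    condition/drug/survey/procedure concepts plus null "noise" conditions,
    each stream firing about 0.6 times per year, and one planted log-hazard
    effect per transition on a windowed feature.
    """

    n_persons: int = 2000
    n_concepts: Mapping[str, int] = field(
        default_factory=lambda: {"condition": 3, "drug": 2, "survey": 2, "procedure": 1}
    )
    followup_days: int = 730
    baseline_hazard: Mapping[str, float] = field(
        default_factory=lambda: {"onset": 5e-4, "remission": 2e-3, "relapse": 1.5e-3}
    )
    planted_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "onset": {"cond1_cnt_30d": 1.0},
            "remission": {"rx1_cnt_90d": 0.7},
            "relapse": {"cond2_cum": 0.5},
        }
    )
    noise_concepts: int = 8
    seed: int = 0
    # event-stream intensity model
    events_per_year: float = 0.6
    frailty_shape: float = 2.0
    block_days: int = 90
    block_sigma: float = 0.7

    def __post_init__(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if not self.n_concepts or any(v <= 0 for v in self.n_concepts.values()):
            raise ValueError("n_concepts must be positive per domain")
        if self.followup_days <= 0:
            raise ValueError("followup_days must be positive")
        for tr in TRANSITIONS:
            if self.baseline_hazard.get(tr, 0.0) <= 0:
                raise ValueError(f"baseline_hazard[{tr!r}] must be > 0")
        if self.noise_concepts < 0:
            raise ValueError("noise_concepts must be nonnegative")
        if self.events_per_year <= 0 or self.frailty_shape <= 0:
            raise ValueError("intensity parameters must be positive")
        concepts = set(self.concept_ids())
        for tr, effects in self.planted_effects.items():
            if tr not in TRANSITIONS:
                raise ValueError(f"unknown transition {tr!r}")
            for name in effects:
                concept, _ = parse_feature_name(name)  # raises if malformed
                if concept not in concepts:
                    raise ValueError(
                        f"planted feature {name!r} references unknown concept"
                    )

    def concept_ids(self) -> list[str]:
        """Regular (non-marker) concept ids, with their domains implied."""
        out = []
        for domain in ("condition", "drug", "survey", "procedure"):
            k = self.n_concepts.get(domain, 0)
            prefix = _DOMAIN_PREFIX[domain]
            out.extend(f"{prefix}{i}" for i in range(1, k + 1))
        out.extend(f"noise{i}" for i in range(1, self.noise_concepts + 1))
        return out

    def concept_domains(self) -> dict[str, str]:
        dom = {}
        for domain in ("condition", "drug", "survey", "procedure"):
            prefix = _DOMAIN_PREFIX[domain]
            for i in range(1, self.n_concepts.get(domain, 0) + 1):
                dom[f"{prefix}{i}"] = domain
        for i in range(1, self.noise_concepts + 1):
            dom[f"noise{i}"] = "condition"
        return dom


def _sample_event_streams(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Inhomogeneous Poisson event streams for every (person, concept)."""
    concepts = cfg.concept_ids()
    domains = cfg.concept_domains()
    n_blocks = int(np.ceil(cfg.followup_days / cfg.block_days))
    daily = cfg.events_per_year / 365.0

    frailty = rng.gamma(cfg.frailty_shape, 1.0 / cfg.frailty_shape, size=cfg.n_persons)
    rows_p, rows_c, rows_d = [], [], []
    for j, concept in enumerate(concepts):
        # block multipliers: (person, block), log-normal with unit median
        mult = rng.lognormal(0.0, cfg.block_sigma, size=(cfg.n_persons, n_blocks))
        lam = daily * frailty[:, None] * mult * cfg.block_days
        counts = rng.poisson(lam)
        pid, blk = np.nonzero(counts)
        reps = counts[pid, blk]
        pid = np.repeat(pid, reps)
        blk = np.repeat(blk, reps)
        days = blk * cfg.block_days + rng.integers(
            0, cfg.block_days, size=pid.size
        )
        keep = days < cfg.followup_days
        rows_p.append(pid[keep])
        rows_c.append(np.full(keep.sum(), j))
        rows_d.append(days[keep])
    events = pd.DataFrame(
        {
            "person_id": np.concatenate(rows_p),
            "concept_id": np.concatenate(rows_c),
            "day": np.concatenate(rows_d).astype(int),
        }
    )
    events["concept_id"] = pd.Categorical.from_codes(
        events["concept_id"], categories=concepts
    ).astype(str)
    events = events.drop_duplicates().sort_values(
        ["person_id", "concept_id", "day"], kind="mergesort"
    )
    events["domain"] = events["concept_id"].map(domains)
    return events[EVENT_COLUMNS].reset_index(drop=True)


def _draw_transition_time(
    effects: Mapping[str, float],
    streams: Mapping[str, np.ndarray],
    grid_days: np.ndarray,
    base: float,
    origin: float,
    horizon: float,
    spec: FeatureSpec,
    rng: np.random.Generator,
):
    """Inversion sampling on a piecewise-constant proportional hazard.

    The hazard over ``[origin, origin + horizon)`` is
    ``base * exp(sum_f beta_f x_f(t))`` with the planted features frozen
    between the person's event-grid days — exactly the evaluation convention
    the features module uses when it splits person-period rows, so the
    fitted Cox model is correctly specified for the planted coefficients.
    Returns the continuous waiting time or ``None`` if no event before the
    horizon.
    """
    grid_abs = grid_days[(grid_days > origin) & (grid_days < origin + horizon)]
    knots = np.concatenate([[0.0], np.unique(grid_abs) - origin, [horizon]])
    eval_abs = origin + knots[:-1]
    lp = np.zeros(eval_abs.size)
    for fname, beta in effects.items():
        concept, transform = parse_feature_name(fname)
        vals = evaluate_concept(streams[concept], eval_abs, spec)[transform]
        lp += beta * vals
    haz = base * np.exp(lp)
    seg = np.diff(knots)
    cum = np.concatenate([[0.0], np.cumsum(haz * seg)])
    target = rng.exponential()
    if target >= cum[-1]:
        return None
    k = int(np.searchsorted(cum, target, side="right") - 1)
    return knots[k] + (target - cum[k]) / haz[k]


def simulate_cohort_events(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the observable event table and the latent truth table.

    Returns
    -------
    events : ``person_id, concept_id, domain, day`` — background concept
        events plus the planted ``oud``/``rem`` phenotype markers.
    truth : ``person_id, transition, event_day, censored`` — one row per
        at-risk transition per person.
    """
    rng = np.random.default_rng(cfg.seed)
    events = _sample_event_streams(cfg, rng)
    spec = FeatureSpec(horizon_days=cfg.followup_days)
    end = float(cfg.followup_days)

    by_person = dict(tuple(events.groupby("person_id", sort=True)))
    needed = sorted(
        {parse_feature_name(f)[0] for eff in cfg.planted_effects.values() for f in eff}
    )

    truth_rows = []
    marker_rows = []
    empty = np.empty(0, dtype=float)
    for pid in range(cfg.n_persons):
        pev = by_person.get(pid)
        if pev is not None:
            streams = {
                c: np.sort(
                    pev.loc[pev["concept_id"] == c, "day"].to_numpy(dtype=float)
                )
                for c in needed
            }
            grid_days = np.unique(pev["day"].to_numpy(dtype=float))
        else:
            streams = {c: empty for c in needed}
            grid_days = empty

        def draw(transition, origin):
            t = _draw_transition_time(
                cfg.planted_effects.get(transition, {}),
                streams,
                grid_days,
                cfg.baseline_hazard[transition],
                origin,
                end - origin,
                spec,
                rng,
            )
            if t is None:
                return None
            return int(min(origin + np.ceil(t), end))

        onset_day = draw("onset", 0.0)
        truth_rows.append((pid, "onset", onset_day, int(onset_day is None)))
        if onset_day is None:
            continue
        marker_rows.append((pid, OUD_CONCEPT, "condition", onset_day))

        rem_day = draw("remission", float(onset_day))
        truth_rows.append((pid, "remission", rem_day, int(rem_day is None)))
        if rem_day is None:
            continue
        marker_rows.append((pid, REMISSION_CONCEPT, "condition", rem_day))

        rel_day = draw("relapse", float(rem_day))
        truth_rows.append((pid, "relapse", rel_day, int(rel_day is None)))
        if rel_day is not None:
            marker_rows.append((pid, OUD_CONCEPT, "condition", rel_day))

    markers = pd.DataFrame(marker_rows, columns=EVENT_COLUMNS)
    events = pd.concat([events, markers], ignore_index=True).sort_values(
        ["person_id", "day", "concept_id"], kind="mergesort"
    )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth["event_day"] = truth["event_day"].astype("Int64")
    return events.reset_index(drop=True), truth


# ---------------------------------------------------------------------------
# knowledge-graph evidence tables
# ---------------------------------------------------------------------------

EVIDENCE_BRANCHES = (
    "replication",
    "mvp",
    "oud_only",
    "mtag",
    "posterior",
    "p_rank",
    "none",
)


@dataclass(frozen=True)
class SimKGConfig:
    """Conditions for the synthetic gene / pathway / drug evidence tables."""

    n_seed_genes: int = 8
    n_bridge_genes: int = 4
    n_pathways: int = 3
    n_drugs: int = 10
    evidence_mix: Mapping[str, float] = field(
        default_factory=lambda: {b: 1.0 / len(EVIDENCE_BRANCHES) for b in EVIDENCE_BRANCHES}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_seed_genes", "n_bridge_genes", "n_pathways", "n_drugs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if set(self.evidence_mix) - set(EVIDENCE_BRANCHES):
            raise ValueError("unknown evidence branch in evidence_mix")
        total = sum(self.evidence_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError("evidence_mix proportions must sum to 1")


def simulate_kg_tables(cfg: SimKGConfig):
    """Generate a gene-evidence table, GMT pathway sets and a drug-target table.

    Each seed gene carries exactly one evidence branch (drawn from
    ``evidence_mix``).  The first pathway always holds at least two seed
    genes plus every bridge gene, so pathway bridging is exercised; the drug
    table always contains at least one approved, one research-only and one
    missing-potency pair.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i}" for i in range(1, cfg.n_seed_genes + 1)]
    bridge = [f"B{i}" for i in range(1, cfg.n_bridge_genes + 1)]

    branches = list(
        rng.choice(
            EVIDENCE_BRANCHES,
            size=cfg.n_seed_genes,
            p=[cfg.evidence_mix.get(b, 0.0) for b in EVIDENCE_BRANCHES],
        )
    )
    rows = []
    for g, br in zip(genes, branches):
        row = {
            "gene": g,
            "r_rep": pd.NA,
            "flag_mvp": 0,
            "flag_oud_only": 0,
            "flag_mtag": 0,
            "posterior": pd.NA,
            "p_rank": pd.NA,
        }
        if br == "replication":
            row["r_rep"] = int(rng.integers(1, 4))
        elif br == "mvp":
            row["flag_mvp"] = 1
        elif br == "oud_only":
            row["flag_oud_only"] = 1
        elif br == "mtag":
            row["flag_mtag"] = 1
        elif br == "posterior":
            row["posterior"] = round(float(rng.uniform()), 4)
        elif br == "p_rank":
            row["p_rank"] = int(rng.integers(1, 51))
        rows.append(row)
    gene_table = pd.DataFrame(rows)

    # pathway 1: >= 2 seed genes + all bridge genes; others random mixtures
    n_in_first = max(2, min(cfg.n_seed_genes, 3))
    pathways = [("PW1", "bridging pathway", genes[:n_in_first] + bridge)]
    for k in range(2, cfg.n_pathways + 1):
        members = list(
            rng.choice(genes + bridge, size=min(3, len(genes)), replace=False)
        )
        pathways.append((f"PW{k}", "synthetic pathway", members))

    targets = genes + bridge
    rows = []
    for i in range(1, cfg.n_drugs + 1):
        gene = targets[int(rng.integers(0, len(targets)))]
        pchembl = round(float(rng.uniform(4.5, 9.0)), 2)
        app = int(rng.uniform() < 0.3)
        res = int((not app) and rng.uniform() < 0.3)
        rows.append(
            {
                "gene": gene,
                "drug_id": f"D{i}",
                "drug_name": f"drug{i}",
                "pchembl": pchembl,
                "ant": int(rng.uniform() < 0.5),
                "ago": int(rng.uniform() < 0.3),
                "ph3": int(app or rng.uniform() < 0.4),
                "app": app,
                "bbb": int(rng.uniform() < 0.5),
                "res": res,
            }
        )
    drug_table = pd.DataFrame(rows)
    # guarantee the contractual corner cases
    drug_table.loc[0, ["app", "ph3", "res"]] = [1, 1, 0]
    drug_table.loc[1, ["res", "app"]] = [1, 0]
    drug_table.loc[2, "pchembl"] = pd.NA
    return gene_table, pathways, drug_table
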