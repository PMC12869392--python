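import numpy as np
import pandas as pd
import pytest

from oudtraj.features import FeatureSpec, build_design
from oudtraj.phenotyping import derive_transitions
from oudtraj.simulate import (
    OUD_CONCEPT,
    REMISSION_CONCEPT,
    SimConfig,
    SimKGConfig,
    simulate_cohort_events,
    simulate_kg_tables,
)


@pytest.fixture(scope="session")
def cohort1000():
    """A moderate cohort with the default planted effects, shared across tests."""
    cfg = SimConfig(n_persons=1000, seed=3)
    events, truth = simulate_cohort_events(cfg)
    return cfg, events, truth


@pytest.fixture(scope="session")
def transitions1000(cohort1000):
    cfg, events, _ = cohort1000
    records = derive_transitions(
        events, {OUD_CONCEPT}, {REMISSION_CONCEPT}, end_of_data=cfg.followup_days
    )
    return records


@pytest.fixture(scope="session")
def onset_design1000(cohort1000, transitions1000):
    cfg, events, _ = cohort1000
    predictors = events[~events["concept_id"].isin({OUD_CONCEPT, REMISSION_CONCEPT})]
    spec = FeatureSpec(horizon_days=cfg.followup_days)
    recs = transitions1000[transitions1000["transition"] == "onset"]
    return build_design(predictors, recs, spec)


@pytest.fixture(scope="session")
def kg_tables():
    return simulate_kg_tables(SimKGConfig(seed=7))


def random_projection(seed, max_nodes=20):
    """A random disease-gene-drug transition structure for PPR checks."""
    import networkx as nx

    from oudtraj.kg import OUD_NODE, project_and_normalize

    rng = np.random.default_rng(seed)
    n_genes = int(rng.integers(2, max(3, (max_nodes - 2) // 2)))
    n_drugs = int(rng.integers(1, max(2, max_nodes - 1 - n_genes)))
    g = nx.DiGraph()
    g.add_node(OUD_NODE, type="OUD")
    genes = [f"g{i}" for i in range(n_genes)]
    drugs = [f"d{i}" for i in range(n_drugs)]
    for gene in genes:
        g.add_node(gene, type="gene", seed=True)
        g.add_edge(OUD_NODE, gene, type="HAS_GENE", weight=float(rng.uniform(0.1, 1)))
    for drug in drugs:
        g.add_node(drug, type="drug", name=drug, approved=0, bbb=0)
    for gene in genes:
        for drug in drugs:
            if rng.uniform() < 0.5:
                g.add_edge(
                    gene, drug, type="TARGETED_BY", weight=float(rng.uniform(0.5, 3))
                )
    return project_and_normalize(g)


def dense_ppr_oracle(proj, s, alpha):
    """Independent PPR oracle: dense solve of (I - alpha*Ptilde^T) r = (1-alpha) s
    with dangling rows of P replaced by s."""
    P = proj.P.toarray()
    P[proj.dangling] = s
    n = len(proj.nodes)
    return np.linalg.solve(np.eye(n) - alpha * P.T, (1 - alpha) * s)


def toy_rows(n=30, seed=8):
    """A small random start-stop frame with continuous stop times (no ties)
    and a few persons carrying two intervals with a covariate change."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n):
        x = float(rng.normal())
        z = float(rng.normal())
        stop = float(rng.uniform(1, 10))
        event = int(rng.uniform() < 0.6)
        if pid % 3 == 0 and stop > 2:  # split into two intervals
            mid = stop / 2
            rows.append((pid, 0.0, mid, 0, x, z))
            rows.append((pid, mid, stop, event, x + 0.5, z))
        else:
            rows.append((pid, 0.0, stop, event, x, z))
    return pd.DataFrame(
        rows, columns=["person_id", "t_start", "t_stop", "event", "x", "z"]
    )
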