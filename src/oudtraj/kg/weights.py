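"""Evidence-to-weight formulas for the therapy knowledge graph.

Disease→gene weights come from a piecewise association score over GWAS /
meta-analysis evidence; gene→drug weights combine a clipped potency term
(pChEMBL) with fixed mechanism and development-status increments.  Both are
floored at a small ``eps`` so every edge keeps positive random-walk mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class KGParams:
    """Tunable constants of the graph construction and ranking.

    eps : positive floor for every edge weight (and the "no evidence" score).
    c_max : cap on the direct disease-gene weight.
    gamma : bridging penalty in (0, 1]; scales the pathway bonus.
    m_min : minimum number of direct seed genes a pathway needs to bridge.
    b_max : cap on the total number of bridged genes (best bonuses kept).
    alpha : PageRank damping factor in (0, 1).
    tol, max_iter : power-iteration stopping rule (L1 change / iteration cap).
    approved_prior : total personalization mass shared by approved drugs.
    """

    eps: float = 1e-6
    c_max: float = 1.0
    gamma: float = 0.5
    m_min: int = 2
    b_max: int = 50
    alpha: float = 0.85
    tol: float = 1e-10
    max_iter: int = 200
    approved_prior: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.eps < self.c_max:
            raise ValueError("need 0 < eps < c_max")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.m_min < 1:
            raise ValueError("m_min must be >= 1")
        if self.b_max < 0:
            raise ValueError("b_max must be >= 0")
        if not 0 <= self.alpha < 1:
            # alpha=0 degenerates to r = s; allowed for the trivial case
            raise ValueError("alpha must be in [0, 1)")
        if not 0 <= self.approved_prior < 1:
            raise ValueError("approved_prior must be in [0, 1)")


@dataclass(frozen=True)
class GeneEvidence:
    """One gene's GWAS/meta-analysis evidence record (absent fields = None)."""

    gene: str
    r_rep: Optional[int] = None
    flag_mvp: bool = False
    flag_oud_only: bool = False
    flag_mtag: bool = False
    posterior: Optional[float] = None
    p_rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.r_rep is not None and self.r_rep < 0:
            raise ValueError("replication count must be nonnegative")
        if self.posterior is not None and not 0 <= self.posterior <= 1:
            raise ValueError("posterior must lie in [0, 1]")
        if self.p_rank is not None and self.p_rank < 1:
            raise ValueError("p_rank must be a positive rank")


@dataclass(frozen=True)
class DrugTargetEvidence:
    """One gene-drug pair: potency plus mechanism / status indicators."""

    gene: str
    drug_id: str
    drug_name: str
    pchembl: Optional[float] = None
    ant: int = 0  # antagonist / inhibitor
    ago: int = 0  # agonist / activator
    ph3: int = 0  # clinical phase >= 3
    app: int = 0  # approved
    bbb: int = 0  # blood-brain-barrier permeable
    res: int = 0  # research-only compound

    def __post_init__(self) -> None:
        for f in ("ant", "ago", "ph3", "app", "bbb", "res"):
            if getattr(self, f) not in (0, 1):
                raise ValueError(f"indicator {f} must be 0 or 1")


def gene_association_score(ev: GeneEvidence, params: KGParams) -> float:
    """Piecewise association score ``a_g`` (pre-cap); first match wins.

    Branch precedence: replication count, MVP cross-ancestry flag, OUD-only
    study flag, OUD-only MTAG flag, fine-mapping posterior, p-value rank,
    else the ``eps`` floor.  The p-rank branch uses ``ln(3 + rank / e)``;
    its printed source form is ambiguous, so it is isolated here.
    """
    if ev.r_rep is not None:
        return 0.5 + 0.3 * ev.r_rep
    if ev.flag_mvp:
        return 1.0
    if ev.flag_oud_only:
        return 0.8
    if ev.flag_mtag:
        return 0.5
    if ev.posterior is not None:
        return 0.2 + ev.posterior
    if ev.p_rank is not None:
        return float(np.log(3.0 + ev.p_rank / np.e))
    return params.eps


def compute_direct_gene_weight(ev: GeneEvidence, params: KGParams) -> tuple[float, float]:
    """Return ``(a_g, w_direct)`` with the cap ``max(eps, min(a_g, c_max))``."""
    a = gene_association_score(ev, params)
    return a, max(params.eps, min(a, params.c_max))


def clip01(x: float) -> float:
    """``clip(x, 0, 1) = min(1, max(0, x))``."""
    return min(1.0, max(0.0, x))


def gene_drug_raw_score(ev: DrugTargetEvidence) -> float:
    """Raw target score ``t``: potency term plus indicator increments.

    ``t = 1 + clip((pChEMBL - 5)/4, 0, 1) + 0.2*ant + 0.1*ago + 0.3*ph3
    + 0.7*app + 0.2*bbb - 0.5*res`` with the potency term 0 when pChEMBL is
    absent.  Approval implies late phase: ``app=1`` forces the ph3 term on.
    """
    potency = 0.0 if ev.pchembl is None else clip01((ev.pchembl - 5.0) / 4.0)
    ph3 = max(ev.ph3, ev.app)
    return (
        1.0
        + potency
        + 0.2 * ev.ant
        + 0.1 * ev.ago
        + 0.3 * ph3
        + 0.7 * ev.app
        + 0.2 * ev.bbb
        - 0.5 * ev.res
    )


def compute_gene_drug_weight(ev: DrugTargetEvidence, params: KGParams) -> float:
    """Edge weight ``w = max(eps, t)``."""
    return max(params.eps, gene_drug_raw_score(ev))
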