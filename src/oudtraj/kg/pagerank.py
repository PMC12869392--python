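"""Personalized PageRank over the projected therapy graph.

The ranking vector is the fixed point of

    r = alpha * P^T r + (1 - alpha) * s

with the random walk restarting to the personalization vector ``s``
(centred on the disease node, optionally sharing mass with approved drugs)
and dangling-node mass redirected to ``s`` so that ``sum(r) = 1``.
"""

from __future__ import annotations

import numpy as np

from .graph import OUD_NODE, Projection
from .weights import KGParams


class PageRankConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"power iteration did not reach tolerance in {max_iter} "
            f"iterations (L1 residual {residual:.3e})"
        )


def build_personalization(
    proj: Projection,
    approved_drugs: list[str] | None = None,
    params: KGParams | None = None,
) -> np.ndarray:
    """Restart vector: unit mass on OUD, minus an optional approved prior.

    With ``approved_prior > 0`` and k approved drugs, each approved drug gets
    ``approved_prior / k`` and the disease node keeps the remainder, so the
    vector always sums to one.
    """
    params = params or KGParams()
    if OUD_NODE not in proj.index:
        raise ValueError("projection lacks the disease node")
    s = np.zeros(len(proj.nodes))
    approved = [d for d in (approved_drugs or []) if d in proj.index]
    if params.approved_prior > 0 and approved:
        share = params.approved_prior / len(approved)
        for d in approved:
            s[proj.index[d]] = share
        s[proj.index[OUD_NODE]] = 1.0 - params.approved_prior
    else:
        s[proj.index[OUD_NODE]] = 1.0
    return s


def personalized_pagerank(
    proj: Projection, s: np.ndarray, params: KGParams | None = None
) -> np.ndarray:
    """Power iteration with dangling mass redirected to ``s``."""
    params = params or KGParams()
    s = np.asarray(s, dtype=float)
    if s.shape != (len(proj.nodes),) or np.any(s < 0) or not np.isclose(s.sum(), 1.0):
        raise ValueError("s must be a probability vector over the projection nodes")
    PT = proj.P.T.tocsr()
    r = s.copy()
    for _ in range(params.max_iter):
        dangling_mass = float(r[proj.dangling].sum())
        r_new = params.alpha * (PT @ r + dangling_mass * s) + (1 - params.alpha) * s
        delta = float(np.abs(r_new - r).sum())
        r = r_new
        if delta < params.tol:
            return r / r.sum()
    raise PageRankConvergenceError(delta, params.max_iter)
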