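"""Symmetric two-state Mk model: likelihood and rate estimation.

Transition probabilities over a branch of length t are
p_same = (1 + exp(-2qt)) / 2 and p_diff = (1 - exp(-2qt)) / 2.
The likelihood is computed by Felsenstein pruning with the root weighted by
the model's prior (stationary (1/2, 1/2) by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .tree import PhyloTree, TreeError

__all__ = ["MkModel", "MkFit", "transition_matrix", "mk_loglik", "mk_fit"]


@dataclass(frozen=True)
class MkModel:
    """Symmetric 2-state rate q plus a root state prior."""

    q: float
    root_prior: tuple = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("rate q must be >= 0")
        p = self.root_prior
        if len(p) != 2 or abs(p[0] + p[1] - 1.0) > 1e-12 or min(p) < 0:
            raise ValueError("root_prior must be two non-negative numbers summing to 1")


@dataclass(frozen=True)
class MkFit:
    model: MkModel
    loglik: float
    at_boundary: bool


def transition_matrix(q: float, t: float) -> np.ndarray:
    e = np.exp(-2.0 * q * t)
    same, diff = 0.5 * (1.0 + e), 0.5 * (1.0 - e)
    return np.array([[same, diff], [diff, same]])


def _tip_partial(state) -> np.ndarray:
    if state not in (0, 1):
        raise ValueError(f"tip states must be 0 or 1, got {state!r}")
    out = np.zeros(2)
    out[int(state)] = 1.0
    return out


def node_partials(tree: PhyloTree, tip_states: Mapping[str, int], q: float) -> dict:
    """Conditional likelihood vectors (data below node | node state)."""
    missing = [t for t in tree.tip_labels() if t not in tip_states]
    if missing:
        raise ValueError(f"missing tip states: {sorted(missing)}")
    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            partials[id(node)] = _tip_partial(tip_states[node.label])
        else:
            vec = np.ones(2)
            for child in node.children:
                pmat = transition_matrix(q, child.length)
                vec = vec * (pmat @ partials[id(child)])
            partials[id(node)] = vec
    return partials


def mk_loglik(tree: PhyloTree, tip_states: Mapping[str, int], model: MkModel) -> float:
    partials = node_partials(tree, tip_states, model.q)
    root_vec = partials[id(tree.root)]
    like = float(np.dot(model.root_prior, root_vec))
    if like <= 0.0:
        return -np.inf
    return float(np.log(like))


def mk_fit(
    tree: PhyloTree,
    tip_states: Mapping[str, int],
    q_max: Optional[float] = None,
    root_prior: tuple = (0.5, 0.5),
) -> MkFit:
    """Maximum-likelihood rate by bounded 1-D optimization.

    A constant character yields q = 0 with the boundary flag set; a rate
    estimate within 1% of ``q_max`` is also flagged as a boundary hit.
    """
    if tree.n_tips < 2:
        raise TreeError("rate estimation needs at least 2 tips")
    states = {tip_states[t] for t in tree.tip_labels()}
    if len(states) == 1:
        model = MkModel(0.0, root_prior)
        return MkFit(model=model, loglik=mk_loglik(tree, tip_states, model),
                     at_boundary=True)
    if q_max is None:
        # ~50 expected changes per mean root-to-tip path is an ample ceiling
        mean_depth = np.mean([tree.root_to_tip_length(t) for t in tree.tip_labels()])
        q_max = 50.0 / mean_depth if mean_depth > 0 else 100.0

    def neg(q: float) -> float:
        return -mk_loglik(tree, tip_states, MkModel(q, root_prior))

    res = minimize_scalar(neg, bounds=(0.0, q_max), method="bounded",
                          options={"xatol": 1e-8})
    q_hat = float(res.x)
    at_boundary = q_hat < 1e-6 or q_hat > 0.99 * q_max
    model = MkModel(q_hat, root_prior)
    return MkFit(model=model, loglik=float(-res.fun), at_boundary=at_boundary)
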