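"""Stochastic character mapping for the symmetric two-state model.

Each simulation samples internal-node states from their joint conditional
distribution (pruning pass + preorder sampling), then draws each branch's
change count conditioned on its endpoints by uniformization.  With the
uniformization rate set to q, the auxiliary chain has no self-transitions,
so every virtual jump is a real state change and the conditioned count is
Poisson(q t) restricted to the parity implied by the endpoints.  Change
times, when requested, are uniform order statistics on the branch.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .mk import MkModel, node_partials, transition_matrix
from .tree import PhyloTree, TreeError

__all__ = ["SimmapResult", "stochastic_map", "sample_branch_changes", "sample_branch_path"]

_MAX_TERMS = 2000


def _parity_tables(lam: float):
    """Cumulative distributions of Poisson(lam) restricted to even / odd n."""
    if lam == 0.0:
        return np.array([1.0]), np.array([1.0])  # odd side is unreachable
    nmax = int(lam + 12.0 * np.sqrt(lam) + 30)
    nmax = min(max(nmax, 10), _MAX_TERMS)
    n = np.arange(nmax + 1)
    logw = n * np.log(lam) - np.cumsum(np.concatenate(([0.0], np.log(np.maximum(n[1:], 1)))))
    w = np.exp(logw - logw.max())
    even, odd = w[0::2], w[1::2]
    return np.cumsum(even) / even.sum(), np.cumsum(odd) / odd.sum()


def sample_branch_changes(
    q: float, t: float, start, end=None, rng: Optional[np.random.Generator] = None,
    size: int = 1,
) -> np.ndarray:
    """Sample state-change counts on one branch.

    With ``end=None`` the path is unconditioned: counts are Poisson(q t).
    Conditioned on endpoints, counts follow Poisson(q t) restricted to even
    (equal endpoints) or odd (unequal) values.
    """
    rng = np.random.default_rng() if rng is None else rng
    lam = q * t
    if end is None:
        return rng.poisson(lam, size=size)
    cum_even, cum_odd = _parity_tables(lam)
    u = rng.random(size)
    if int(start) == int(end):
        return 2 * np.searchsorted(cum_even, u)
    if lam == 0.0:
        raise ValueError("unequal endpoints are impossible with q*t = 0")
    return 2 * np.searchsorted(cum_odd, u) + 1


def sample_branch_path(
    q: float, t: float, start, end=None, rng: Optional[np.random.Generator] = None
) -> list:
    """One path as [(state, duration), ...] segments covering the branch."""
    rng = np.random.default_rng() if rng is None else rng
    n = int(sample_branch_changes(q, t, start, end, rng, size=1)[0])
    times = np.sort(rng.random(n)) * t
    bounds = np.concatenate(([0.0], times, [t]))
    state = int(start)
    segments = []
    for k in range(n + 1):
        segments.append((state, float(bounds[k + 1] - bounds[k])))
        state ^= 1
    return segments


@dataclass(frozen=True)
class SimmapResult:
    n_sims: int
    #: total state changes across the tree, one entry per simulation
    change_counts: np.ndarray
    #: node key -> posterior probability of state 1 (internal nodes + root)
    node_posterior: dict
    #: branch key -> mean change count over simulations
    branch_mean_changes: dict
    #: branch key -> per-simulation sampled paths (only when keep_paths=True)
    paths: Optional[dict] = None

    @property
    def mean_changes(self) -> float:
        return float(np.mean(self.change_counts))


def _node_key(node, index: int) -> str:
    return node.label if node.label else f"node{index}"


def stochastic_map(
    tree: PhyloTree,
    tip_states: Mapping[str, int],
    model: MkModel,
    n_sims: int = 10_000,
    seed: int = 0,
    keep_paths: bool = False,
) -> SimmapResult:
    """Sample full character histories conditional on tip data."""
    if not tree.is_binary():
        raise TreeError(
            "stochastic mapping requires a binary tree; resolve polytomies first"
        )
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    q = model.q
    partials = node_partials(tree, tip_states, q)

    nodes = list(tree.preorder())
    keys = {id(n): _node_key(n, i) for i, n in enumerate(nodes)}
    states: dict[int, np.ndarray] = {}

    root = tree.root
    root_w = np.asarray(model.root_prior) * partials[id(root)]
    p1 = root_w[1] / root_w.sum()
    states[id(root)] = (rng.random(n_sims) < p1).astype(np.int8)

    # preorder: sample each node's state conditional on its parent's state
    for node in nodes:
        for child in node.children:
            if child.is_tip:
                states[id(child)] = np.full(
                    n_sims, int(tip_states[child.label]), dtype=np.int8
                )
                continue
            pmat = transition_matrix(q, child.length)
            w = pmat * partials[id(child)][None, :]  # w[p, s]
            row_sum = w.sum(axis=1)
            # a zero row belongs to a parent state of zero posterior mass
            p1_given = np.where(row_sum > 0, w[:, 1] / np.where(row_sum > 0, row_sum, 1.0), 0.0)
            parent_states = states[id(node)]
            u = rng.random(n_sims)
            states[id(child)] = (u < p1_given[parent_states]).astype(np.int8)

    total = np.zeros(n_sims, dtype=np.int64)
    branch_mean: dict[str, float] = {}
    paths: Optional[dict] = {} if keep_paths else None
    for node in nodes:
        for child in node.children:
            lam = q * child.length
            cum_even, cum_odd = _parity_tables(lam)
            same = states[id(node)] == states[id(child)]
            u = rng.random(n_sims)
            n_even = 2 * np.searchsorted(cum_even, u)
            n_odd = 2 * np.searchsorted(cum_odd, u) + 1
            counts = np.where(same, n_even, n_odd)
            total += counts
            key = keys[id(child)]
            branch_mean[key] = float(np.mean(counts))
            if keep_paths:
                branch_paths = []
                for s in range(n_sims):
                    n_changes = int(counts[s])
                    times = np.sort(rng.random(n_changes)) * child.length
                    bounds = np.concatenate(([0.0], times, [child.length]))
                    state = int(states[id(node)][s])
                    segs = []
                    for k in range(n_changes + 1):
                        segs.append((state, float(bounds[k + 1] - bounds[k])))
                        state ^= 1
                    branch_paths.append(segs)
                paths[key] = branch_paths

    node_posterior = {
        keys[id(n)]: float(np.mean(states[id(n)]))
        for n in nodes
        if not n.is_tip
    }
    return SimmapResult(
        n_sims=n_sims,
        change_counts=total,
        node_posterior=node_posterior,
        branch_mean_changes=branch_mean,
        paths=paths,
    )


def write_simmap_summary(result: SimmapResult, counts_path, nodes_path) -> None:
    """CSV writers: per-simulation change counts; per-node posteriors."""
    with open(counts_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["simulation", "n_changes"])
        for i, c in enumerate(result.change_counts):
            writer.writerow([i, int(c)])
    with open(nodes_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node", "p_state1"])
        for key, p in result.node_posterior.items():
            writer.writerow([key, f"{p:.6f}"])
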