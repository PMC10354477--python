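"""Independent oracles used by the test suite.

Everything here is deliberately written without touching the implementation
paths it checks: gene-dropping IBD estimation for pedigree relatedness,
brute-force likelihood enumeration and Fitch parsimony for the Mk model,
and small random generators for pedigrees and trees.
"""

from __future__ import annotations

import itertools

import numpy as np

from kincomp.pedigree import Pedigree, PedigreeRecord


# -- gene dropping -----------------------------------------------------------


def gene_drop_relatedness(ped: Pedigree, i: str, j: str, n_drops: int, rng):
    """Monte Carlo numerator relatedness 2*f via founder-allele transmission.

    Returns (estimate, standard error).  Founders receive globally unique
    allele pairs; each drop transmits one random allele per parent; f is the
    mean IBD indicator over the four cross-individual allele pairs.
    """
    alleles: dict[str, np.ndarray] = {}
    counter = 0
    for ident in ped.ids:  # topological order: parents first
        rec = ped.record(ident)
        mat = np.empty((n_drops, 2), dtype=np.int64)
        for col, parent in enumerate((rec.dam, rec.sire)):
            if parent is None:
                mat[:, col] = counter
                counter += 1
            else:
                pick = rng.integers(0, 2, size=n_drops)
                mat[:, col] = alleles[parent][np.arange(n_drops), pick]
        alleles[ident] = mat
    ai, aj = alleles[i], alleles[j]
    ibd = np.zeros(n_drops)
    for a, b in itertools.product(range(2), range(2)):
        ibd += ai[:, a] == aj[:, b]
    f_per_drop = ibd / 4.0
    r_hat = 2.0 * float(f_per_drop.mean())
    se = 2.0 * float(f_per_drop.std(ddof=1)) / np.sqrt(n_drops) if n_drops > 1 else 0.0
    return r_hat, se


# -- random pedigrees --------------------------------------------------------


def random_pedigree(n: int, rng, p_founder: float = 0.3) -> Pedigree:
    """Random acyclic pedigree of n individuals; parents drawn from earlier ids."""
    records = []
    females: list[str] = []
    males: list[str] = []
    for k in range(n):
        ident = f"ind{k:03d}"
        sex = "F" if rng.random() < 0.5 else "M"
        dam = sire = None
        if k > 1 and rng.random() > p_founder:
            if females and rng.random() < 0.9:
                dam = females[int(rng.integers(len(females)))]
            if males and rng.random() < 0.9:
                sire = males[int(rng.integers(len(males)))]
        records.append(PedigreeRecord(id=ident, dam=dam, sire=sire, sex=sex))
        (females if sex == "F" else males).append(ident)
    return Pedigree(records)


# -- Mk model ----------------------------------------------------------------


def _p_same(q: float, t: float) -> float:
    return 0.5 * (1.0 + np.exp(-2.0 * q * t))


def enumerate_mk_likelihood(tree, tip_states, q, root_prior=(0.5, 0.5)) -> float:
    """Exact likelihood by summing over all internal-node state assignments."""
    internals = [n for n in tree.preorder() if not n.is_tip]
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        for tip in tree.tips():
            assign[id(tip)] = tip_states[tip.label]
        prob = root_prior[assign[id(tree.root)]]
        for node in tree.preorder():
            for child in node.children:
                same = assign[id(node)] == assign[id(child)]
                ps = _p_same(q, child.length)
                prob *= ps if same else (1.0 - ps)
        total += prob
    return total


def fitch_parsimony(tree, tip_states) -> int:
    """Minimum number of state changes (Fitch small parsimony, binary states)."""
    score = 0
    sets: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_tip:
            sets[id(node)] = frozenset([tip_states[node.label]])
            continue
        child_sets = [sets[id(c)] for c in node.children]
        inter = frozenset.intersection(*child_sets)
        if inter:
            sets[id(node)] = inter
        else:
            sets[id(node)] = frozenset.union(*child_sets)
            score += 1
    return score


def random_binary_tree(n_tips: int, rng, mean_branch: float = 1.0):
    """Random topology by sequential joining; exponential branch lengths."""
    from kincomp.phylo.tree import Node, PhyloTree

    nodes = [
        Node(label=f"t{k}", length=float(rng.exponential(mean_branch)) + 1e-3)
        for k in range(n_tips)
    ]
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes)))) if len(nodes) else None
        parent = Node(length=float(rng.exponential(mean_branch)) + 1e-3)
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return PhyloTree(root)


# -- plain Bayesian logistic sampler (oracle for the sigma -> 0 limit) -------


def plain_logistic_mh(y, x, beta_sd=10.0, n_iter=6000, warmup=2000, seed=0):
    """Independent random-walk MH sampler for Bayesian logistic regression."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    x = np.asarray(x, float)

    def log_post(beta):
        eta = beta[0] + beta[1] * x
        return float(
            np.sum(y * eta - np.logaddexp(0.0, eta))
            - 0.5 * np.sum(beta**2) / beta_sd**2
        )

    beta = np.zeros(2)
    lp = log_post(beta)
    scale = 0.3
    draws = []
    for it in range(n_iter):
        prop = beta + scale * rng.normal(size=2)
        lp_prop = log_post(prop)
        if np.log(rng.random()) < lp_prop - lp:
            beta, lp = prop, lp_prop
        if it >= warmup:
            draws.append(beta.copy())
    return np.asarray(draws)
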