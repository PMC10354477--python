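"""Synthetic data with known ground truth.

Three generators back the test pyramid:

* :func:`simulate_unit_pedigree` — forward-time breeding of one social unit
  from founding matrilines, with philopatric recruitment, per-generation
  immigration of unrelated founders and configurable paternity.  The
  construction records are used to derive the expected composition label of
  the final adult cohort without consulting the classifier under test.
* :func:`noisy_relatedness` — marker-style dyadic estimates: true pedigree
  relatedness plus unbounded Gaussian noise, with matriline labels taken
  from birth units.
* :func:`simulate_binary_trait` — a symmetric 2-state Markov chain run tip-
  ward along a tree.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .composition import ClusterEvidence, CompositionLabel, SocialUnit
from .pedigree import Pedigree, PedigreeRecord, write_pedigree

__all__ = [
    "SimParams",
    "SimResult",
    "simulate_unit_pedigree",
    "noisy_relatedness",
    "simulate_binary_trait",
    "write_simulation",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the forward-time unit simulator.

    litter_size is the fixed litter size under ``litter_distribution="fixed"``
    and the Poisson mean (zero-truncated) under ``"poisson"``.  Paternity
    ``"single_sire"`` gives every litter of a generation the same new founder
    sire; ``"random_sires"`` draws each litter's sire from a pool of
    ``n_sires`` new founder males per generation.
    """

    n_breeding_females: int
    litter_size: float = 2
    litter_distribution: str = "fixed"
    n_generations: int = 2
    immigration_rate: float = 0.0
    paternity: str = "single_sire"
    n_sires: int = 1
    sex_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_breeding_females < 1:
            raise ValueError("n_breeding_females must be >= 1")
        if self.litter_size < 1:
            raise ValueError("litter_size must be >= 1")
        if self.litter_distribution not in ("fixed", "poisson"):
            raise ValueError("litter_distribution must be 'fixed' or 'poisson'")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if not 0.0 <= self.immigration_rate <= 1.0:
            raise ValueError("immigration_rate must be in [0, 1]")
        if self.paternity not in ("single_sire", "random_sires"):
            raise ValueError("paternity must be 'single_sire' or 'random_sires'")
        if self.n_sires < 1:
            raise ValueError("n_sires must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class SimResult:
    params: SimParams
    pedigree: Pedigree
    units: dict  # sex -> SocialUnit or None
    ground_truth: dict  # sex -> CompositionLabel or None
    lines: dict  # individual -> matriline label
    immigrants: frozenset


def _draw_litter_size(params: SimParams, rng: np.random.Generator) -> int:
    if params.litter_distribution == "fixed":
        return int(params.litter_size)
    for _ in range(10_000):  # zero-truncated Poisson by rejection
        n = int(rng.poisson(params.litter_size))
        if n >= 1:
            return n
    return 1


def _expected_label(
    members: list[str], parent_map: dict
) -> Optional[CompositionLabel]:
    """Composition expected from the construction records alone.

    Depth-2 shared-ancestor bookkeeping on the simulator's own parent map;
    deliberately does not call the kin classifier it is used to validate.
    """
    if len(members) < 2:
        return None

    def anc2(ident: str) -> set:
        ps = {p for p in parent_map.get(ident, (None, None)) if p is not None}
        gps = set()
        for p in ps:
            gps.update(g for g in parent_map.get(p, (None, None)) if g is not None)
        return ps | gps

    anc = {m: anc2(m) for m in members}
    any_kin = any_nonkin = False
    for a, b in combinations(members, 2):
        kin = (
            b in anc[a]
            or a in anc[b]
            or bool(anc[a] & anc[b])
        )
        if kin:
            any_kin = True
        else:
            any_nonkin = True
    if any_kin and any_nonkin:
        return CompositionLabel.MIX_RELATED
    if any_kin:
        return CompositionLabel.RELATED
    return CompositionLabel.UNRELATED


def simulate_unit_pedigree(params: SimParams) -> SimResult:
    """Breed one social unit forward in time and report its expected label.

    Generation 0 is the founding females (mutually unrelated founders, one
    matriline each).  Each later generation, every breeding female produces
    a litter; daughters are recruited philopatrically and become the next
    breeding cohort, sons form the male cohort.  With probability
    ``immigration_rate`` per generation one unrelated adult female founder
    immigrates into the current cohort.  The returned units are the adult
    same-sex cohorts of the final generation.
    """
    rng = np.random.default_rng(params.seed)
    imm_rng, breed_rng = rng.spawn(2)

    records: list[PedigreeRecord] = []
    parent_map: dict[str, tuple] = {}
    lines: dict[str, str] = {}
    immigrants: set[str] = set()

    founders = [f"F{i:03d}" for i in range(params.n_breeding_females)]
    for f in founders:
        records.append(PedigreeRecord(id=f, sex="F", birth_unit=f))
        parent_map[f] = (None, None)
        lines[f] = f

    current_females = list(founders)
    final_females = list(founders)
    final_males: list[str] = []

    for gen in range(1, params.n_generations + 1):
        sire_pool = (
            [f"S{gen:02d}"]
            if params.paternity == "single_sire"
            else [f"S{gen:02d}_{k}" for k in range(params.n_sires)]
        )
        used_sires: set[str] = set()
        daughters: list[str] = []
        sons: list[str] = []
        child_no = 0
        for mom in current_females:
            litter = _draw_litter_size(params, breed_rng)
            sire = (
                sire_pool[0]
                if len(sire_pool) == 1
                else sire_pool[int(breed_rng.integers(len(sire_pool)))]
            )
            used_sires.add(sire)
            for _ in range(litter):
                child = f"G{gen}_{child_no:04d}"
                child_no += 1
                sex = "F" if breed_rng.random() < params.sex_ratio else "M"
                records.append(
                    PedigreeRecord(
                        id=child,
                        dam=mom,
                        sire=sire,
                        sex=sex,
                        birth_unit=lines[mom],
                    )
                )
                parent_map[child] = (mom, sire)
                lines[child] = lines[mom]
                (daughters if sex == "F" else sons).append(child)
        for sire in sorted(used_sires):
            records.append(PedigreeRecord(id=sire, sex="M"))
            parent_map[sire] = (None, None)

        if float(imm_rng.random()) < params.immigration_rate:
            imm = f"I{gen:02d}"
            records.append(PedigreeRecord(id=imm, sex="F", birth_unit=imm))
            parent_map[imm] = (None, None)
            lines[imm] = imm
            immigrants.add(imm)
            daughters.append(imm)

        current_females = daughters
        final_females, final_males = daughters, sons

    ped = Pedigree(records)
    units: dict[str, Optional[SocialUnit]] = {}
    truth: dict[str, Optional[CompositionLabel]] = {}
    for sex, cohort in (("F", final_females), ("M", final_males)):
        if len(cohort) >= 2:
            units[sex] = SocialUnit(
                unit_id="sim", period=f"gen{params.n_generations}", sex=sex,
                members=tuple(cohort),
            )
            truth[sex] = _expected_label(cohort, parent_map)
        else:
            units[sex] = None
            truth[sex] = None

    return SimResult(
        params=params,
        pedigree=ped,
        units=units,
        ground_truth=truth,
        lines=lines,
        immigrants=frozenset(immigrants),
    )


def noisy_relatedness(
    ped: Pedigree, ids, sd: float, seed: int
) -> ClusterEvidence:
    """Marker-style estimates: true r plus Gaussian(0, sd), symmetric.

    Line labels are taken from each individual's birth unit.  Estimates are
    unbounded, so negative values occur, as with real marker estimators.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    ids = list(ids)
    rng = np.random.default_rng(seed)
    r_hat: dict[frozenset, float] = {}
    for a, b in combinations(ids, 2):
        true_r = ped.relatedness(a, b)
        noise = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
        r_hat[frozenset((a, b))] = true_r + noise
    line_labels = {i: ped.record(i).birth_unit for i in ids}
    return ClusterEvidence(r_hat=r_hat, lines=line_labels)


def cluster_evidence_to_long(ev: ClusterEvidence) -> pd.DataFrame:
    rows = [
        {"i": a, "j": b, "r_hat": val}
        for key, val in sorted(ev.r_hat.items(), key=lambda kv: sorted(kv[0]))
        for a, b in [sorted(key)]
    ]
    return pd.DataFrame(rows, columns=["i", "j", "r_hat"])


def simulate_binary_trait(tree, q: float, root_state, seed: int) -> dict:
    """Evolve a binary trait tip-ward under the symmetric 2-state chain.

    ``root_state`` is 0, 1 or "stationary" (equal-probability draw).  Each
    branch flips the state with probability (1 - exp(-2 q t)) / 2.  Returns
    a tip-label -> state map.
    """
    if q < 0:
        raise ValueError("rate q must be >= 0")
    rng = np.random.default_rng(seed)
    if root_state == "stationary":
        state0 = int(rng.random() < 0.5)
    elif root_state in (0, 1):
        state0 = int(root_state)
    else:
        raise ValueError("root_state must be 0, 1 or 'stationary'")

    tips: dict[str, int] = {}

    def descend(node, state: int) -> None:
        for child in node.children:
            if child.length is None:
                raise ValueError(f"branch above {child.label or 'internal node'} has no length")
            p_flip = 0.5 * (1.0 - np.exp(-2.0 * q * child.length))
            child_state = state ^ int(rng.random() < p_flip)
            if child.is_tip:
                tips[child.label] = child_state
            else:
                descend(child, child_state)

    root = tree.root
    if root.is_tip:
        tips[root.label] = state0
    else:
        descend(root, state0)
    return tips


def write_simulation(result: SimResult, out_dir) -> None:
    """Write pedigree TSV, unit membership CSV and a params/seed sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pedigree(result.pedigree, out / "pedigree.tsv")
    rows = []
    for sex, unit in result.units.items():
        if unit is None:
            continue
        for member in unit.members:
            rows.append(
                {
                    "unit_id": unit.unit_id,
                    "period": unit.period,
                    "individual_id": member,
                    "sex": sex,
                    "age_class": "adult",
                }
            )
    pd.DataFrame(
        rows, columns=["unit_id", "period", "individual_id", "sex", "age_class"]
    ).to_csv(out / "units.csv", index=False)
    meta = dataclasses.asdict(result.params)
    meta["ground_truth"] = {
        sex: (label.value if label is not None else None)
        for sex, label in result.ground_truth.items()
    }
    with open(out / "metadata.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
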