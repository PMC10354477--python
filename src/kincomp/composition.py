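"""Social-unit filtering and group-level kinship composition.

A social unit here is the set of adult same-sex members of one unit-period.
Composition is the categorical attribute of its dyads: all kin (related),
all non-kin (unrelated) or both (mix-related), plus a continuous proportion
of kin dyads.  Units containing any undetermined dyad are inconclusive —
they are surfaced rather than silently dropped.

Two evidence routes are provided: full pedigree classification
(:func:`classify_composition`) and the weaker genetic-cluster rule
(:func:`classify_from_clusters`), which can only ever certify mix-related.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .kin import KinStatus, classify_all_dyads
from .pedigree import Pedigree

__all__ = [
    "CompositionLabel",
    "SocialUnit",
    "CompositionResult",
    "ClusterEvidence",
    "filter_social_unit",
    "classify_composition",
    "mean_relatedness",
    "classify_from_clusters",
    "load_unit_memberships",
    "write_composition_results",
]


class CompositionLabel(str, Enum):
    RELATED = "RELATED"
    UNRELATED = "UNRELATED"
    MIX_RELATED = "MIX_RELATED"
    INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class SocialUnit:
    """Adult members of one sex in one unit-period."""

    unit_id: str
    period: str
    sex: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"unit sex must be 'F' or 'M', got {self.sex!r}")
        if len(self.members) < 2:
            raise ValueError(
                f"social unit {self.unit_id!r} needs >=2 members, got {len(self.members)}"
            )
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate member ids in unit {self.unit_id!r}")

    @property
    def n_dyads(self) -> int:
        n = len(self.members)
        return n * (n - 1) // 2


@dataclass(frozen=True)
class CompositionResult:
    unit_id: str
    period: str
    sex: str
    label: CompositionLabel
    n_kin: int
    n_nonkin: int
    n_undetermined: int
    #: kin fraction of determined dyads; None when any dyad is undetermined
    proportion_kin: Optional[float]

    @property
    def n_dyads(self) -> int:
        return self.n_kin + self.n_nonkin + self.n_undetermined


def filter_social_unit(
    members: Iterable[tuple],
    sex: str,
    unit_id: str = "unit",
    period: str = "",
) -> Optional[SocialUnit]:
    """Retain the adult members of one sex; None when <2 remain (not a unit).

    ``members`` rows are (id, sex, age_class); age_class defaults to "adult"
    when omitted.  Contradictory duplicate rows raise; identical duplicates
    are collapsed.
    """
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    seen: dict[str, tuple] = {}
    for row in members:
        if len(row) == 2:
            ident, msex = row
            age = "adult"
        else:
            ident, msex, age = row[:3]
        if ident in seen and seen[ident] != (msex, age):
            raise ValueError(
                f"contradictory duplicate rows for member {ident!r}: "
                f"{seen[ident]} vs {(msex, age)}"
            )
        seen[ident] = (msex, age)
    kept = [i for i, (msex, age) in seen.items() if msex == sex and age == "adult"]
    if len(kept) < 2:
        return None
    return SocialUnit(unit_id=unit_id, period=period, sex=sex, members=tuple(kept))


def classify_composition(
    ped: Pedigree, unit: SocialUnit, policy: str = "strict"
) -> CompositionResult:
    """Label a unit from pairwise dyad classification on the pedigree."""
    absent = [m for m in unit.members if m not in ped]
    if absent:
        raise ValueError(
            f"unit {unit.unit_id!r} members absent from pedigree: {sorted(absent)}"
        )
    statuses = classify_all_dyads(ped, unit.members, policy)
    n_kin = sum(1 for s in statuses if s.status is KinStatus.KIN)
    n_nonkin = sum(1 for s in statuses if s.status is KinStatus.NON_KIN)
    n_und = sum(1 for s in statuses if s.status is KinStatus.UNDETERMINED)
    if n_und > 0:
        label, prop = CompositionLabel.INCONCLUSIVE, None
    else:
        prop = n_kin / (n_kin + n_nonkin)
        if n_nonkin == 0:
            label = CompositionLabel.RELATED
        elif n_kin == 0:
            label = CompositionLabel.UNRELATED
        else:
            label = CompositionLabel.MIX_RELATED
    return CompositionResult(
        unit_id=unit.unit_id,
        period=unit.period,
        sex=unit.sex,
        label=label,
        n_kin=n_kin,
        n_nonkin=n_nonkin,
        n_undetermined=n_und,
        proportion_kin=prop,
    )


def mean_relatedness(ped: Pedigree, unit: SocialUnit) -> float:
    """Mean pairwise numerator relatedness over all n(n-1)/2 dyads."""
    absent = [m for m in unit.members if m not in ped]
    if absent:
        raise ValueError(
            f"unit {unit.unit_id!r} members absent from pedigree: {sorted(absent)}"
        )
    total = sum(
        ped.relatedness(a, b) for a, b in combinations(unit.members, 2)
    )
    return total / unit.n_dyads


@dataclass(frozen=True)
class ClusterEvidence:
    """Dyadic relatedness estimates plus a line label per individual.

    ``r_hat`` maps unordered pairs (frozensets of two ids) to estimates;
    ``lines`` maps each individual to its matriline / birth-unit / breeding
    line label (None = unknown).
    """

    r_hat: Mapping[frozenset, float]
    lines: Mapping[str, Optional[str]]

    @classmethod
    def from_long(
        cls,
        table: pd.DataFrame,
        lines: Mapping[str, Optional[str]],
    ) -> "ClusterEvidence":
        """Build from a long table with columns i, j, r_hat.

        Duplicated symmetric entries must agree; the first value wins.
        """
        r: dict[frozenset, float] = {}
        for row in table.itertuples(index=False):
            key = frozenset((row.i, row.j))
            if key in r and abs(r[key] - row.r_hat) > 1e-9:
                raise ValueError(f"conflicting r_hat entries for pair {set(key)}")
            r.setdefault(key, float(row.r_hat))
        return cls(r_hat=r, lines=dict(lines))


def classify_from_clusters(
    ev: ClusterEvidence,
    unit: SocialUnit,
    epsilon: float = 0.0,
    tol: float = 1e-9,
) -> CompositionResult:
    """Mix-relatedness from genetic clusters and line labels.

    The unit is mix-related when at least one line's within-line mean
    estimate is positive (> epsilon) and at least one pair of lines has a
    between-line mean that is zero/negative (<= epsilon).  This route can
    never certify related or unrelated, so anything else is inconclusive.
    """
    members = list(unit.members)
    line_of = {}
    for m in members:
        if m not in ev.lines:
            raise ValueError(f"no line label for member {m!r}")
        line_of[m] = ev.lines[m]
    labels = {v for v in line_of.values() if v is not None}
    if len(labels) < 2:
        raise ValueError("cluster classification needs >=2 distinct line labels")

    pairs = list(combinations(members, 2))
    for a, b in pairs:
        if frozenset((a, b)) not in ev.r_hat:
            raise ValueError(f"missing r_hat for within-unit dyad ({a!r}, {b!r})")

    within: dict[str, list[float]] = {}
    between: dict[frozenset, list[float]] = {}
    for a, b in pairs:
        la, lb = line_of[a], line_of[b]
        val = ev.r_hat[frozenset((a, b))]
        if la is None or lb is None:
            continue
        if la == lb:
            within.setdefault(la, []).append(val)
        else:
            between.setdefault(frozenset((la, lb)), []).append(val)

    positive_lines = {
        line for line, vals in within.items() if sum(vals) / len(vals) > epsilon + tol
    }
    zero_pairs = {
        lp for lp, vals in between.items() if sum(vals) / len(vals) <= epsilon + tol
    }

    # Dyads in certified clusters get a determinate status; the rest stay
    # undetermined, so mix-related results from this route can carry
    # undetermined dyads (unlike the pedigree route).
    n_kin = n_nonkin = 0
    for a, b in pairs:
        la, lb = line_of[a], line_of[b]
        if la is not None and la == lb and la in positive_lines:
            n_kin += 1
        elif (
            la is not None
            and lb is not None
            and la != lb
            and frozenset((la, lb)) in zero_pairs
        ):
            n_nonkin += 1
    n_und = len(pairs) - n_kin - n_nonkin

    if positive_lines and zero_pairs:
        label = CompositionLabel.MIX_RELATED
    else:
        label = CompositionLabel.INCONCLUSIVE
    prop = n_kin / (n_kin + n_nonkin) if n_und == 0 and (n_kin + n_nonkin) else None
    return CompositionResult(
        unit_id=unit.unit_id,
        period=unit.period,
        sex=unit.sex,
        label=label,
        n_kin=n_kin,
        n_nonkin=n_nonkin,
        n_undetermined=n_und,
        proportion_kin=prop,
    )


# -- I/O ---------------------------------------------------------------------


def load_unit_memberships(path) -> list[SocialUnit]:
    """Read unit membership CSV: unit_id, period, individual_id, sex, age_class.

    Returns one SocialUnit per (unit_id, period, sex) with >=2 adult members.
    """
    table = pd.read_csv(path, dtype=str).fillna("")
    required = {"unit_id", "period", "individual_id", "sex"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"membership file missing columns: {sorted(missing)}")
    if "age_class" not in table.columns:
        table["age_class"] = "adult"
    table.loc[table["age_class"] == "", "age_class"] = "adult"
    units = []
    for (unit_id, period, sex), grp in table.groupby(
        ["unit_id", "period", "sex"], sort=True
    ):
        if sex not in ("F", "M"):
            continue
        unit = filter_social_unit(
            [
                (r.individual_id, r.sex, r.age_class)
                for r in grp.itertuples(index=False)
            ],
            sex=sex,
            unit_id=unit_id,
            period=period,
        )
        if unit is not None:
            units.append(unit)
    return units


def write_composition_results(
    results: Iterable[CompositionResult],
    path,
    mean_r: Optional[Mapping[tuple, float]] = None,
) -> None:
    """CSV writer; mean_r optionally keyed by (unit_id, period, sex)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "unit_id",
                "period",
                "sex",
                "label",
                "proportion_kin",
                "n_kin",
                "n_nonkin",
                "n_undetermined",
                "mean_r",
            ]
        )
        for res in results:
            key = (res.unit_id, res.period, res.sex)
            mr = mean_r.get(key) if mean_r else None
            writer.writerow(
                [
                    res.unit_id,
                    res.period,
                    res.sex,
                    res.label.value,
                    "" if res.proportion_kin is None else f"{res.proportion_kin:.6f}",
                    res.n_kin,
                    res.n_nonkin,
                    res.n_undetermined,
                    "" if mr is None else f"{mr:.6f}",
                ]
            )
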