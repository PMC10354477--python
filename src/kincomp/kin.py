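"""Two-generation categorical kin / non-kin classification of dyads.

A dyad is kin when one member is the other's parent or grandparent, or when
the two share at least one known parent or grandparent.  When none of those
hold, the verdict depends on the completeness policy:

``strict``
    Non-kin only when *both* individuals have fully recorded depth-2
    ancestry (two parents, four grandparent links); otherwise the dyad is
    undetermined.  Absence of evidence is not treated as evidence of absence.
``permissive``
    Non-kin whenever no shared known ancestor exists.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Iterable, Sequence

from .pedigree import Pedigree, PedigreeError

__all__ = [
    "KinStatus",
    "KinBasis",
    "DyadKinStatus",
    "classify_dyad",
    "classify_all_dyads",
    "write_dyad_statuses",
]


class KinStatus(str, Enum):
    KIN = "KIN"
    NON_KIN = "NON_KIN"
    UNDETERMINED = "UNDETERMINED"


class KinBasis(str, Enum):
    """Reason for a verdict, in reporting priority order."""

    PARENT_OFFSPRING = "PARENT_OFFSPRING"
    GRANDPARENT_GRANDOFFSPRING = "GRANDPARENT_GRANDOFFSPRING"
    SHARED_PARENT = "SHARED_PARENT"
    SHARED_GRANDPARENT = "SHARED_GRANDPARENT"
    NO_SHARED_KNOWN_ANCESTOR = "NO_SHARED_KNOWN_ANCESTOR"
    INSUFFICIENT_PEDIGREE = "INSUFFICIENT_PEDIGREE"


_KIN_BASES = {
    KinBasis.PARENT_OFFSPRING,
    KinBasis.GRANDPARENT_GRANDOFFSPRING,
    KinBasis.SHARED_PARENT,
    KinBasis.SHARED_GRANDPARENT,
}

_POLICIES = ("strict", "permissive")


@dataclass(frozen=True)
class DyadKinStatus:
    i: str
    j: str
    status: KinStatus
    basis: KinBasis

    def __post_init__(self) -> None:
        kin = self.basis in _KIN_BASES
        if kin != (self.status is KinStatus.KIN):
            raise ValueError(f"basis {self.basis} inconsistent with status {self.status}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.i, self.j))


def classify_dyad(
    ped: Pedigree, i: str, j: str, policy: str = "strict"
) -> DyadKinStatus:
    """Classify one same-unit dyad under the two-generation criterion."""
    if policy not in _POLICIES:
        raise ValueError(f"policy must be one of {_POLICIES}, got {policy!r}")
    if i == j:
        raise PedigreeError(f"cannot classify a self-pair ({i!r})")
    anc_i = ped.ancestors_to_depth2(i)
    anc_j = ped.ancestors_to_depth2(j)

    if j in anc_i.parents or i in anc_j.parents:
        basis = KinBasis.PARENT_OFFSPRING
    elif j in anc_i.grandparents or i in anc_j.grandparents:
        basis = KinBasis.GRANDPARENT_GRANDOFFSPRING
    elif anc_i.parents & anc_j.parents:
        basis = KinBasis.SHARED_PARENT
    elif anc_i.all & anc_j.all:
        basis = KinBasis.SHARED_GRANDPARENT
    elif policy == "permissive" or (
        ped.has_complete_depth2(i) and ped.has_complete_depth2(j)
    ):
        return DyadKinStatus(i, j, KinStatus.NON_KIN, KinBasis.NO_SHARED_KNOWN_ANCESTOR)
    else:
        return DyadKinStatus(i, j, KinStatus.UNDETERMINED, KinBasis.INSUFFICIENT_PEDIGREE)
    return DyadKinStatus(i, j, KinStatus.KIN, basis)


def classify_all_dyads(
    ped: Pedigree, ids: Sequence[str], policy: str = "strict"
) -> list[DyadKinStatus]:
    """One status per unordered pair of ``ids`` — n(n-1)/2 entries."""
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 ids to form a dyad")
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be distinct")
    return [classify_dyad(ped, a, b, policy) for a, b in combinations(ids, 2)]


def write_dyad_statuses(statuses: Iterable[DyadKinStatus], path) -> None:
    """Long CSV: i, j, status, basis."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["i", "j", "status", "basis"])
        for st in statuses:
            writer.writerow([st.i, st.j, st.status.value, st.basis.value])
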