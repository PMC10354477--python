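"""Pedigree data model, depth-2 ancestry queries and pedigree relatedness.

A :class:`Pedigree` is a validated, acyclic parent map over individuals.
Relatedness is computed with the tabular (recursive) method on a
topologically ordered additive relationship matrix, so every coefficient is
exact given the recorded links.  Founders (individuals with both parents
unknown) are assumed mutually unrelated and non-inbred.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "UNKNOWN",
    "PedigreeError",
    "PedigreeWarning",
    "PedigreeRecord",
    "AncestorSet",
    "Pedigree",
    "load_pedigree",
    "ancestors_to_depth2",
    "kinship_coefficient",
    "relatedness",
    "write_relatedness_matrix",
]

#: Sentinel for an unrecorded parent / sex / birth unit.
UNKNOWN = None

_MISSING_TOKENS = {"", ".", "NA", "na", "None"}


class PedigreeError(ValueError):
    """Raised for structural problems: duplicate ids, cycles, unknown ids."""


class PedigreeWarning(UserWarning):
    """Warning channel for recoverable pedigree issues (auto-added founders)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: identity, parent links, sex and birth unit."""

    id: str
    dam: Optional[str] = None
    sire: Optional[str] = None
    sex: Optional[str] = None  # "F", "M" or None
    birth_unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in (None, "F", "M"):
            raise PedigreeError(f"invalid sex {self.sex!r} for individual {self.id!r}")
        if self.id in (None, ""):
            raise PedigreeError("individual id must be a non-empty string")
        if self.dam == self.id or self.sire == self.id:
            raise PedigreeError(f"individual {self.id!r} listed as its own parent")


@dataclass(frozen=True)
class AncestorSet:
    """Known ancestors of one individual up to depth two."""

    parents: frozenset[str] = field(default_factory=frozenset)
    grandparents: frozenset[str] = field(default_factory=frozenset)

    @property
    def all(self) -> frozenset[str]:
        return self.parents | self.grandparents


class Pedigree:
    """Acyclic parent map with relatedness queries.

    Parameters
    ----------
    records:
        Iterable of :class:`PedigreeRecord` (or argument tuples).  Parents
        referenced but not listed are auto-created as founders and reported
        through :class:`PedigreeWarning`.
    """

    def __init__(self, records: Iterable[PedigreeRecord | tuple]) -> None:
        recs: dict[str, PedigreeRecord] = {}
        for rec in records:
            if not isinstance(rec, PedigreeRecord):
                rec = PedigreeRecord(*rec)
            if rec.id in recs:
                raise PedigreeError(f"duplicate individual id {rec.id!r}")
            recs[rec.id] = rec

        auto_founders = []
        for rec in list(recs.values()):
            for parent, sex in ((rec.dam, "F"), (rec.sire, "M")):
                if parent is not None and parent not in recs:
                    recs[parent] = PedigreeRecord(id=parent, sex=sex)
                    auto_founders.append(parent)
        if auto_founders:
            warnings.warn(
                "auto-created founder records for referenced parents: "
                + ", ".join(sorted(auto_founders)),
                PedigreeWarning,
                stacklevel=2,
            )

        self._records = recs
        self.auto_founders = tuple(sorted(auto_founders))
        self._order = self._topological_order()
        self._index = {i: k for k, i in enumerate(self._order)}
        self._A: Optional[np.ndarray] = None  # additive relationship cache

    # -- construction helpers -------------------------------------------------

    def _topological_order(self) -> list[str]:
        """Kahn's algorithm; parents precede offspring.  Raises on cycles."""
        n_parents = {}
        children: dict[str, list[str]] = {i: [] for i in self._records}
        for rec in self._records.values():
            parents = [p for p in (rec.dam, rec.sire) if p is not None]
            n_parents[rec.id] = len(parents)
            for p in parents:
                children[p].append(rec.id)
        queue = sorted(i for i, n in n_parents.items() if n == 0)
        order = []
        while queue:
            i = queue.pop(0)
            order.append(i)
            for c in sorted(children[i]):
                n_parents[c] -= 1
                if n_parents[c] == 0:
                    queue.append(c)
        if len(order) < len(self._records):
            cycle = self._find_cycle(set(self._records) - set(order))
            raise PedigreeError(
                "pedigree contains an ancestry cycle: " + " -> ".join(cycle)
            )
        return order

    def _find_cycle(self, candidates: set[str]) -> list[str]:
        start = sorted(candidates)[0]
        path, seen = [start], {start}
        node = start
        while True:
            rec = self._records[node]
            nxt = next(p for p in (rec.dam, rec.sire) if p in candidates)
            if nxt in seen:
                return path[path.index(nxt):] + [nxt]
            path.append(nxt)
            seen.add(nxt)
            node = nxt

    # -- basic queries --------------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, individual: str) -> bool:
        return individual in self._records

    def __iter__(self):
        return iter(self._order)

    @property
    def ids(self) -> tuple[str, ...]:
        """Individual ids in topological (parents-first) order."""
        return tuple(self._order)

    def record(self, individual: str) -> PedigreeRecord:
        self._check(individual)
        return self._records[individual]

    def parents(self, individual: str) -> frozenset[str]:
        rec = self.record(individual)
        return frozenset(p for p in (rec.dam, rec.sire) if p is not None)

    def is_founder(self, individual: str) -> bool:
        rec = self.record(individual)
        return rec.dam is None and rec.sire is None

    def ancestors_to_depth2(self, individual: str) -> AncestorSet:
        """Known parents and known grandparents of ``individual``."""
        parents = self.parents(individual)
        grandparents: set[str] = set()
        for p in parents:
            grandparents.update(self.parents(p))
        return AncestorSet(parents=parents, grandparents=frozenset(grandparents))

    def has_complete_depth2(self, individual: str) -> bool:
        """True if both parents and all four grandparent links are recorded."""
        rec = self.record(individual)
        if rec.dam is None or rec.sire is None:
            return False
        for p in (rec.dam, rec.sire):
            prec = self._records[p]
            if prec.dam is None or prec.sire is None:
                return False
        return True

    def _check(self, individual: str) -> None:
        if individual not in self._records:
            raise PedigreeError(f"unknown individual id {individual!r}")

    # -- relatedness ----------------------------------------------------------

    def _additive_matrix(self) -> np.ndarray:
        """Full numerator relationship matrix A in topological order.

        A[i,i] = 1 + F_i;  A[i,j] = 2 f(i,j) for i != j.
        """
        if self._A is not None:
            return self._A
        n = len(self._order)
        A = np.zeros((n, n))
        idx = self._index
        for k, ident in enumerate(self._order):
            rec = self._records[ident]
            d = idx[rec.dam] if rec.dam is not None else -1
            s = idx[rec.sire] if rec.sire is not None else -1
            A[k, k] = 1.0 + (0.5 * A[d, s] if d >= 0 and s >= 0 else 0.0)
            for j in range(k):
                a = 0.0
                if d >= 0:
                    a += 0.5 * A[d, j]
                if s >= 0:
                    a += 0.5 * A[s, j]
                A[k, j] = A[j, k] = a
        self._A = A
        return A

    def kinship(self, i: str, j: str) -> float:
        """Kinship coefficient f(i, j); f(i, i) = (1 + F_i) / 2."""
        self._check(i)
        self._check(j)
        A = self._additive_matrix()
        return 0.5 * A[self._index[i], self._index[j]]

    def relatedness(self, i: str, j: str, *, normalized: bool = False) -> float:
        """Numerator relatedness r = 2 f(i, j).

        With ``normalized=True`` the coefficient is divided by
        sqrt((1 + F_i)(1 + F_j)), which matters only for inbred pedigrees.
        """
        self._check(i)
        self._check(j)
        A = self._additive_matrix()
        ii, jj = self._index[i], self._index[j]
        r = A[ii, jj]
        if normalized:
            r /= np.sqrt(A[ii, ii] * A[jj, jj])
        return float(r)

    def relatedness_matrix(self, ids: Optional[Sequence[str]] = None) -> np.ndarray:
        """Pairwise numerator relatedness for ``ids`` (default: everyone)."""
        if ids is None:
            ids = self._order
        for i in ids:
            self._check(i)
        A = self._additive_matrix()
        sel = [self._index[i] for i in ids]
        return A[np.ix_(sel, sel)]


# -- module-level operations ------------------------------------------------


def load_pedigree(path) -> Pedigree:
    """Read a pedigree from a TSV file.

    The file must be tab-separated UTF-8 with a header row containing at
    least ``id``, ``dam`` and ``sire`` (``sex`` and ``birth_unit`` optional).
    ``.`` or an empty field denotes an unknown value.
    """
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise PedigreeError(f"empty pedigree file: {path}")
        missing = {"id", "dam", "sire"} - set(reader.fieldnames)
        if missing:
            raise PedigreeError(
                f"pedigree file {path} missing columns: {sorted(missing)}"
            )

        def clean(value: Optional[str]) -> Optional[str]:
            if value is None or value.strip() in _MISSING_TOKENS:
                return None
            return value.strip()

        for row in reader:
            records.append(
                PedigreeRecord(
                    id=row["id"].strip(),
                    dam=clean(row.get("dam")),
                    sire=clean(row.get("sire")),
                    sex=clean(row.get("sex")),
                    birth_unit=clean(row.get("birth_unit")),
                )
            )
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write a pedigree as TSV ('.' = unknown), topological row order."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id", "dam", "sire", "sex", "birth_unit"])
        for ident in ped.ids:
            rec = ped.record(ident)
            writer.writerow(
                [
                    rec.id,
                    rec.dam or ".",
                    rec.sire or ".",
                    rec.sex or ".",
                    rec.birth_unit or ".",
                ]
            )


def ancestors_to_depth2(ped: Pedigree, individual: str) -> AncestorSet:
    return ped.ancestors_to_depth2(individual)


def kinship_coefficient(ped: Pedigree, i: str, j: str) -> float:
    return ped.kinship(i, j)


def relatedness(ped: Pedigree, i: str, j: str, *, normalized: bool = False) -> float:
    return ped.relatedness(i, j, normalized=normalized)


def write_relatedness_matrix(ped: Pedigree, path, ids: Optional[Sequence[str]] = None) -> None:
    """Write the square relatedness matrix as CSV, 6 decimal places."""
    if ids is None:
        ids = ped.ids
    matrix = ped.relatedness_matrix(ids)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", *ids])
        for ident, row in zip(ids, matrix):
            writer.writerow([ident, *(f"{v:.6f}" for v in row)])
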