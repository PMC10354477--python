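"""Packaged species-level kinship-composition dataset and its summaries.

The shipped fixture is a transcription of the species table of the source
publication (one row per sex/species datapoint aggregate).  ``summarize``
recomputes the headline statistics and ``crosscheck_counts`` compares
totals recomputed from the fixture against the totals printed in the
publication's results text, reporting — not correcting — any discrepancy.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

from .composition import CompositionLabel

__all__ = [
    "SpeciesRecord",
    "DatasetSummary",
    "load_species_table",
    "summarize",
    "crosscheck_counts",
    "packaged_table_path",
]

_COMPOSITION = {"related": CompositionLabel.RELATED,
                "unrelated": CompositionLabel.UNRELATED,
                "mix-related": CompositionLabel.MIX_RELATED}
_DISPERSAL = {"philopatric", "disperse", "unclear"}
_BREEDING = {"singular", "plural"}
_LITTER = {"monotocous", "polytocous"}

#: Summary totals printed in the source publication's results text, used by
#: crosscheck_counts as the comparison baseline.
REPORTED_TOTALS = {
    "n_species": 18,
    "total_datapoints": 76,
    "female_datapoints": 67,
    "female_units": 62,
    "female_populations": 21,
    "female_species": 17,
    "male_datapoints": 11,
    "male_units": 11,
    "male_populations": 5,
    "male_species": 5,
}


@dataclass(frozen=True)
class SpeciesRecord:
    species: str
    sex: str
    composition: CompositionLabel
    n_populations: int
    n_units: int
    n_datapoints: int
    mean_unit_size: float
    sd_unit_size: Optional[float]
    dispersal: str
    breeding: Optional[str]
    litter: Optional[str]


@dataclass(frozen=True)
class DatasetSummary:
    n_species: int
    n_related_species: int
    n_mix_species: int
    n_unrelated_species: int
    species_by_sex_label: dict  # (sex, label) -> species count
    datapoints_by_sex: dict  # sex -> datapoint total
    female_unit_size_by_label: dict  # label -> (mean, sd or None, n)


def packaged_table_path():
    """Path to the shipped species-table CSV."""
    return resources.files("kincomp.data") / "table1.csv"


def load_species_table(path=None) -> list[SpeciesRecord]:
    """Load the species table (packaged fixture when ``path`` is None)."""
    src = packaged_table_path() if path is None else path
    records: list[SpeciesRecord] = []
    with open(src, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            comp = row["composition"].strip()
            if comp not in _COMPOSITION:
                raise ValueError(f"row {lineno}: invalid composition {comp!r}")
            sex = row["sex"].strip()
            if sex not in ("F", "M"):
                raise ValueError(f"row {lineno}: invalid sex {sex!r}")
            dispersal = row["dispersal"].strip()
            if dispersal not in _DISPERSAL:
                raise ValueError(f"row {lineno}: invalid dispersal {dispersal!r}")
            breeding = row["breeding"].strip() or None
            if breeding is not None and breeding not in _BREEDING:
                raise ValueError(f"row {lineno}: invalid breeding {breeding!r}")
            litter = row["litter"].strip() or None
            if litter is not None and litter not in _LITTER:
                raise ValueError(f"row {lineno}: invalid litter {litter!r}")
            sd_raw = row["sd_unit_size"].strip()
            records.append(
                SpeciesRecord(
                    species=row["species"].strip(),
                    sex=sex,
                    composition=_COMPOSITION[comp],
                    n_populations=int(row["n_populations"]),
                    n_units=int(row["n_units"]),
                    n_datapoints=int(row["n_datapoints"]),
                    mean_unit_size=float(row["mean_unit_size"]),
                    sd_unit_size=float(sd_raw) if sd_raw else None,
                    dispersal=dispersal,
                    breeding=breeding,
                    litter=litter,
                )
            )
    if not records:
        raise ValueError(f"species table {src} contains no data rows")
    return records


def _mean_sd(values: Sequence[float]):
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def summarize(records: Sequence[SpeciesRecord]) -> DatasetSummary:
    """Counts by label and sex, plus female mean-of-species-mean unit sizes.

    A species counts toward a label when any of its rows carries it; unit
    sizes are aggregated one value per sex/species (the table reports a
    single datapoint per sex/species), with sample sd (n-1 denominator).
    """
    if not records:
        raise ValueError("no records to summarize")
    species = sorted({r.species for r in records})
    by_label = {
        label: sorted({r.species for r in records if r.composition is label})
        for label in (
            CompositionLabel.RELATED,
            CompositionLabel.UNRELATED,
            CompositionLabel.MIX_RELATED,
        )
    }
    species_by_sex_label = {}
    for sex in ("F", "M"):
        for label in (
            CompositionLabel.RELATED,
            CompositionLabel.UNRELATED,
            CompositionLabel.MIX_RELATED,
        ):
            species_by_sex_label[(sex, label)] = len(
                {r.species for r in records if r.sex == sex and r.composition is label}
            )
    datapoints_by_sex = {
        sex: sum(r.n_datapoints for r in records if r.sex == sex)
        for sex in ("F", "M")
    }
    female_unit_size_by_label = {}
    for label in (CompositionLabel.RELATED, CompositionLabel.MIX_RELATED):
        sizes = [
            r.mean_unit_size
            for r in records
            if r.sex == "F" and r.composition is label
        ]
        if sizes:
            mean, sd = _mean_sd(sizes)
            female_unit_size_by_label[label] = (mean, sd, len(sizes))
    return DatasetSummary(
        n_species=len(species),
        n_related_species=len(by_label[CompositionLabel.RELATED]),
        n_mix_species=len(by_label[CompositionLabel.MIX_RELATED]),
        n_unrelated_species=len(by_label[CompositionLabel.UNRELATED]),
        species_by_sex_label=species_by_sex_label,
        datapoints_by_sex=datapoints_by_sex,
        female_unit_size_by_label=female_unit_size_by_label,
    )


def crosscheck_counts(records: Sequence[SpeciesRecord]) -> dict:
    """Recompute totals from the fixture and compare with published totals.

    Returns {quantity: {"computed", "reported", "agree"}}.  Discrepancies
    are surfaced, never silently corrected (the published female datapoint
    and unit totals do not match the column sums of the published table).
    """
    females = [r for r in records if r.sex == "F"]
    males = [r for r in records if r.sex == "M"]
    computed = {
        "n_species": len({r.species for r in records}),
        "total_datapoints": sum(r.n_datapoints for r in records),
        "female_datapoints": sum(r.n_datapoints for r in females),
        "female_units": sum(r.n_units for r in females),
        "female_populations": sum(r.n_populations for r in females),
        "female_species": len({r.species for r in females}),
        "male_datapoints": sum(r.n_datapoints for r in males),
        "male_units": sum(r.n_units for r in males),
        "male_populations": sum(r.n_populations for r in males),
        "male_species": len({r.species for r in males}),
    }
    return {
        key: {
            "computed": computed[key],
            "reported": REPORTED_TOTALS[key],
            "agree": computed[key] == REPORTED_TOTALS[key],
        }
        for key in REPORTED_TOTALS
    }
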