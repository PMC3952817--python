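"""Domain types and I/O for ordinal observations of the germarium.

Observations are rank-only (ordinal) statements about how a measured species
is distributed over the four germline regions — GSC, CB, Cyst, Posterior —
under some genetic condition.  The somatic cap cell (CC) is compartment 0 and
is never observed.  Observations are grouped into three data categories
(WildType, Mutant, Behavioral) that are fitted as independent objectives.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

GERMLINE_REGIONS = ("GSC", "CB", "Cyst", "Posterior")
CATEGORIES = ("WildType", "Mutant", "Behavioral")
PERTURBATION_KINDS = ("null", "heterozygous", "doubled", "overexpress")

#: Species that may appear as a measured quantity in an observation.
#: "Phenotype" is a derived output (trailing-window mean Brat, reporting
#: fusome vs. spectrosome morphology).
OBSERVABLE_SPECIES = ("pMad", "Bam", "Nos", "Brat", "Phenotype", "dMyc", "Dpp")

#: Species that may be genetically perturbed.  "Rec" is the Dpp receptor and
#: "Mad" the unphosphorylated transducer (perturbing Mad scales pMad
#: production).
PERTURBABLE_SPECIES = ("Dpp", "Rec", "Mad", "Bam", "Nos", "Brat", "dMyc", "pMad")

_KIND_ORDER = {k: i for i, k in enumerate(PERTURBATION_KINDS)}


class ObservationFormatError(ValueError):
    """Malformed observation file (missing column, bad header)."""


class ObservationValidationError(ValueError):
    """Observation content violates the domain invariants."""


@dataclass(frozen=True)
class RegionMap:
    """Mapping of germline regions to contiguous 1-based cell indices.

    The cap cell is compartment 0 and is held outside the germline index
    range; the default geometry is 17 germline cells plus the CC for 18
    compartments, with GSC={1}, CB={2}, Cyst={3..9}, Posterior={10..17}.
    """

    region_names: tuple[str, ...] = ("CC",) + GERMLINE_REGIONS
    cell_index_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "GSC": (1, 1),
            "CB": (2, 2),
            "Cyst": (3, 9),
            "Posterior": (10, 17),
        }
    )

    def __post_init__(self) -> None:
        ranges = [self.cell_index_ranges[r] for r in self.germline_regions]
        expect = 1
        for (lo, hi), name in zip(ranges, self.germline_regions):
            if lo != expect or hi < lo:
                raise ObservationValidationError(
                    f"region {name!r}: ranges must be contiguous, non-overlapping "
                    f"and cover 1..n (got {lo}..{hi}, expected start {expect})"
                )
            expect = hi + 1

    @property
    def germline_regions(self) -> tuple[str, ...]:
        return tuple(r for r in self.region_names if r != "CC")

    @property
    def n_cells_germline(self) -> int:
        return max(hi for _, hi in self.cell_index_ranges.values())

    @property
    def n_cells_total(self) -> int:
        return self.n_cells_germline + 1  # + cap cell

    def cells(self, region: str) -> list[int]:
        """1-based germline cell indices belonging to ``region``."""
        lo, hi = self.cell_index_ranges[region]
        return list(range(lo, hi + 1))

    def slice0(self, region: str) -> slice:
        """0-based slice into a 17-vector of germline-cell values."""
        lo, hi = self.cell_index_ranges[region]
        return slice(lo - 1, hi)

    def region_of_cell(self, cell: int) -> str:
        for r in self.germline_regions:
            lo, hi = self.cell_index_ranges[r]
            if lo <= cell <= hi:
                return r
        raise KeyError(f"cell {cell} outside germline range")


@dataclass(frozen=True)
class GeneticCondition:
    """A set of genetic perturbations; the empty set is Wild Type.

    At most one perturbation per species, with one sanctioned exception:
    a species may carry {null, overexpress} together, encoding ectopic
    expression in a null background (e.g. dMyc −/− with dMyc OE).
    """

    perturbations: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        per_species: dict[str, set[str]] = {}
        for species, kind in self.perturbations:
            if kind not in PERTURBATION_KINDS:
                raise ObservationValidationError(f"unknown perturbation kind {kind!r}")
            per_species.setdefault(species, set()).add(kind)
        for species, kinds in per_species.items():
            if len(kinds) > 1 and kinds != {"null", "overexpress"}:
                raise ObservationValidationError(
                    f"species {species!r} carries conflicting perturbations {sorted(kinds)}"
                )

    @property
    def is_wild_type(self) -> bool:
        return not self.perturbations

    @property
    def label(self) -> str:
        return condition_label(self)

    def species_perturbed(self) -> set[str]:
        return {s for s, _ in self.perturbations}

    @staticmethod
    def wild_type() -> "GeneticCondition":
        return GeneticCondition(frozenset())

    @staticmethod
    def of(*pairs: tuple[str, str]) -> "GeneticCondition":
        return GeneticCondition(frozenset(pairs))


def condition_label(c: GeneticCondition) -> str:
    """Canonical text label, deterministically ordered by species then kind.

    null → ``X-/-``; heterozygous → ``X+/-``; doubled → ``2xX``;
    overexpress → ``X OE``; the empty condition is ``WT``.  Perturbations are
    ordered doubled, null, heterozygous, overexpress (ties by species name),
    matching the field's ``2xBrat Bam-/-`` style.
    """
    if c.is_wild_type:
        return "WT"
    label_order = {"doubled": 0, "null": 1, "heterozygous": 2, "overexpress": 3}
    parts = []
    for species, kind in sorted(c.perturbations,
                                key=lambda p: (label_order[p[1]], p[0].lower())):
        if kind == "null":
            parts.append(f"{species}-/-")
        elif kind == "heterozygous":
            parts.append(f"{species}+/-")
        elif kind == "doubled":
            parts.append(f"2x{species}")
        else:
            parts.append(f"{species} OE")
    return " ".join(parts)


def parse_condition_label(label: str) -> GeneticCondition:
    """Inverse of :func:`condition_label`."""
    label = label.strip()
    if label in ("", "WT"):
        return GeneticCondition.wild_type()
    tokens = label.split()
    pairs: list[tuple[str, str]] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if i + 1 < len(tokens) and tokens[i + 1] == "OE":
            pairs.append((tok, "overexpress"))
            i += 2
        elif tok.endswith("-/-"):
            pairs.append((tok[:-3], "null"))
            i += 1
        elif tok.endswith("+/-"):
            pairs.append((tok[:-3], "heterozygous"))
            i += 1
        elif tok.startswith("2x"):
            pairs.append((tok[2:], "doubled"))
            i += 1
        else:
            raise ObservationValidationError(f"cannot parse condition token {tok!r} in {label!r}")
    return GeneticCondition(frozenset(pairs))


@dataclass(frozen=True)
class OrdinalObservation:
    """One qualitative measurement: per-region ranks of one species.

    ``ranks`` maps region name → rank in 1..n_categories; regions absent from
    the mapping are masked (unobserved).  ``dynamic`` observations are scored
    on the post-division 12 h protocol rather than the 24 h steady state.
    """

    index: int
    species: str
    condition: GeneticCondition
    ranks: Mapping[str, int]
    n_categories: int = 2
    category: str = "WildType"
    dynamic: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.species not in OBSERVABLE_SPECIES:
            raise ObservationValidationError(
                f"observation {self.index}: unknown species {self.species!r}"
            )
        if self.category not in CATEGORIES:
            raise ObservationValidationError(
                f"observation {self.index}: unknown category {self.category!r}"
            )
        if self.n_categories < 1:
            raise ObservationValidationError(
                f"observation {self.index}: n_categories must be >= 1"
            )
        if not self.ranks:
            raise ObservationValidationError(
                f"observation {self.index}: at least one region must be observed"
            )
        for region, rank in self.ranks.items():
            if region not in GERMLINE_REGIONS:
                raise ObservationValidationError(
                    f"observation {self.index}: unknown region {region!r}"
                )
            if not (1 <= int(rank) <= self.n_categories):
                raise ObservationValidationError(
                    f"observation {self.index}: rank {rank} for region {region!r} "
                    f"outside 1..{self.n_categories}"
                )
        object.__setattr__(self, "ranks", dict(self.ranks))

    @property
    def observed_regions(self) -> tuple[str, ...]:
        return tuple(r for r in GERMLINE_REGIONS if r in self.ranks)


@dataclass
class ObservationSet:
    """A collection of observations sharing one region map."""

    observations: list[OrdinalObservation]
    region_map: RegionMap = field(default_factory=RegionMap)

    def __post_init__(self) -> None:
        indices = [o.index for o in self.observations]
        if len(indices) != len(set(indices)):
            raise ObservationValidationError("observation indices must be unique")

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    def by_category(self, category: str) -> "ObservationSet":
        return ObservationSet(
            [o for o in self.observations if o.category == category], self.region_map
        )

    def subset(self, indices: Iterable[int]) -> "ObservationSet":
        keep = set(indices)
        return ObservationSet(
            [o for o in self.observations if o.index in keep], self.region_map
        )


_CSV_COLUMNS = [
    "index", "species", "condition", "category", "dynamic", "n_categories",
    "rank_GSC", "rank_CB", "rank_Cyst", "rank_Posterior",
]


def read_observations(path: str | Path, region_map: RegionMap | None = None) -> ObservationSet:
    """Read observations from the package's CSV dialect.

    Header: ``index,species,condition,category,dynamic,n_categories,
    rank_GSC,rank_CB,rank_Cyst,rank_Posterior``; masked regions are empty
    cells.  Rank values outside ``1..n_categories`` raise
    :class:`ObservationValidationError` naming the offending row.
    """
    region_map = region_map or RegionMap()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationFormatError(f"missing column(s) {missing} in {path}")
    observations = []
    for _, row in df.iterrows():
        ranks = {}
        for region in GERMLINE_REGIONS:
            cell = row[f"rank_{region}"].strip()
            if cell:
                ranks[region] = int(float(cell))
        try:
            observations.append(
                OrdinalObservation(
                    index=int(row["index"]),
                    species=row["species"].strip(),
                    condition=parse_condition_label(row["condition"]),
                    ranks=ranks,
                    n_categories=int(row["n_categories"]),
                    category=row["category"].strip(),
                    dynamic=str(row["dynamic"]).strip().lower() in ("true", "1", "yes"),
                )
            )
        except ObservationValidationError as err:
            raise ObservationValidationError(f"row index={row['index']}: {err}") from err
    return ObservationSet(observations, region_map)


def write_observations(obs_set: ObservationSet, path: str | Path) -> None:
    """Write observations in the CSV dialect read by :func:`read_observations`."""
    records = []
    for o in obs_set:
        rec = {
            "index": o.index,
            "species": o.species,
            "condition": condition_label(o.condition),
            "category": o.category,
            "dynamic": str(o.dynamic),
            "n_categories": o.n_categories,
        }
        for region in GERMLINE_REGIONS:
            rec[f"rank_{region}"] = o.ranks.get(region, "")
        records.append(rec)
    pd.DataFrame.from_records(records, columns=_CSV_COLUMNS).to_csv(path, index=False)


def packaged_fixture() -> ObservationSet:
    """The 25-observation compiled dataset of germarium expression data.

    Rank encodings follow the published qualitative interpretations; regions
    with unmodeled regulation (posterior Bam repression by RBP9, posterior Nos
    re-expression) are masked.  Behavioral observations are the heterozygote
    negative phenotypes (indices 10, 18–20) and the post-division dynamic
    constraints (21–25).
    """
    from ._compiled_data import COMPILED_ROWS

    observations = [
        OrdinalObservation(
            index=r["index"],
            species=r["species"],
            condition=parse_condition_label(r["condition"]),
            ranks=r["ranks"],
            n_categories=2,
            category=r["category"],
            dynamic=r["dynamic"],
            note=r["note"],
        )
        for r in COMPILED_ROWS
    ]
    return ObservationSet(observations, RegionMap())


def replace(obj, **changes):
    """dataclasses.replace re-export, handy for building condition variants."""
    return dataclasses.replace(obj, **changes)
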