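"""Range-to-grid rasterization.

Species distributions are recorded in two coarse domains — a list of
administrative units ("counties") and an elevational interval — while all
downstream diversity metrics operate on equal-area grid cells.  This module
converts the former into the latter with the two-condition presence rule: a
species is present in a cell iff (i) at least one of its counties intersects
the cell and (ii) its elevational interval overlaps the cell's elevational
range (closed intervals; a shared endpoint counts as overlap).

Because counties are coarser than cells, rasterization can only over-predict
occupancy ("coarsening bias"); the elevational condition trims part of that
excess.  Both properties are exercised by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LifeForm",
    "SpeciesRange",
    "GridCell",
    "CommunityMatrix",
    "rasterize_ranges",
    "richness",
]


class LifeForm(str, Enum):
    WOODY = "woody"
    HERBACEOUS = "herbaceous"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SpeciesRange:
    """Horizontal (county-level) plus vertical (elevational) range of one species.

    An empty ``county_ids`` set means the species occurs nowhere (it is kept in
    the pool so matrix columns stay aligned with the phylogeny).
    """

    species_id: str
    county_ids: frozenset[str]
    elev_min: float
    elev_max: float
    life_form: LifeForm = LifeForm.UNKNOWN

    def __post_init__(self) -> None:
        if self.elev_min > self.elev_max:
            raise ValueError(
                f"species {self.species_id!r}: elev_min {self.elev_min} > "
                f"elev_max {self.elev_max}"
            )


@dataclass(frozen=True)
class GridCell:
    """One grid cell: geometry is half-open in lon/lat, closed in elevation."""

    cell_id: str
    lon_min: float
    lat_min: float
    elev_min: float
    elev_max: float
    county_ids: frozenset[str] = field(default_factory=frozenset)
    step: float = 0.5

    def __post_init__(self) -> None:
        if self.elev_min > self.elev_max:
            raise ValueError(
                f"cell {self.cell_id!r}: elev_min {self.elev_min} > "
                f"elev_max {self.elev_max}"
            )


class CommunityMatrix:
    """Cells x species presence/absence with per-species life forms.

    Thin wrapper around a 0/1 :class:`pandas.DataFrame` (rows = cells, columns
    = species) that preserves the life-form annotation needed for the
    per-life-form richness and PD breakdowns.
    """

    def __init__(self, data: pd.DataFrame, life_form: Mapping[str, str] | pd.Series | None = None):
        values = data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("community matrix entries must be 0 or 1")
        self.data = data.astype(np.int8)
        if life_form is None:
            life_form = {s: LifeForm.UNKNOWN.value for s in data.columns}
        self.life_form = pd.Series(
            {s: str(LifeForm(life_form[s]).value) for s in data.columns},
            name="life_form",
        )

    @property
    def cells(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def richness(self, subset: str = "all") -> pd.Series:
        return richness(self, subset)

    def subset_species(self, subset: str) -> pd.DataFrame:
        """Columns restricted to one life form ('all' keeps everything)."""
        if subset == "all":
            return self.data
        try:
            form = LifeForm(subset)
        except ValueError as exc:
            raise ValueError(
                f"unknown life-form filter {subset!r}; expected 'all', 'woody' or 'herbaceous'"
            ) from exc
        keep = self.life_form[self.life_form == form.value].index
        return self.data.loc[:, keep]

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "cell"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, life_form: Mapping[str, str] | None = None) -> "CommunityMatrix":
        data = pd.read_csv(path, index_col="cell")
        return cls(data, life_form)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, CommunityMatrix) and self.data.equals(other.data)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = sorted(seen[seen.duplicated()].unique())
        raise ValueError(f"duplicate {what} ids: {dupes}")


def rasterize_ranges(
    ranges: Iterable[SpeciesRange],
    cells: Iterable[GridCell],
) -> CommunityMatrix:
    """Apply the two-condition presence rule to every (cell, species) pair.

    presence(cell, s) = 1  iff  counties(s) ∩ counties(cell) ≠ ∅
                            and [s.elev_min, s.elev_max] ∩ [cell.elev_min, cell.elev_max] ≠ ∅

    with closed elevational intervals (ties at a shared endpoint overlap).
    """
    ranges = list(ranges)
    cells = list(cells)
    _check_unique([r.species_id for r in ranges], "species")
    _check_unique([c.cell_id for c in cells], "cell")

    n_c, n_s = len(cells), len(ranges)
    occ = np.zeros((n_c, n_s), dtype=np.int8)
    for j, r in enumerate(ranges):
        if not r.county_ids:
            continue
        for i, c in enumerate(cells):
            if (
                not r.county_ids.isdisjoint(c.county_ids)
                and r.elev_min <= c.elev_max
                and c.elev_min <= r.elev_max
            ):
                occ[i, j] = 1
    data = pd.DataFrame(
        occ,
        index=[c.cell_id for c in cells],
        columns=[r.species_id for r in ranges],
    )
    life = {r.species_id: r.life_form.value for r in ranges}
    return CommunityMatrix(data, life)


def richness(matrix: CommunityMatrix, subset: str = "all") -> pd.Series:
    """Number of species present per cell, optionally restricted to a life form."""
    sub = matrix.subset_species(subset)
    counts = sub.sum(axis=1).astype(int)
    counts.name = subset
    return counts


def richness_table(matrix: CommunityMatrix) -> pd.DataFrame:
    """Per-cell richness for all species and for each life form."""
    return pd.DataFrame(
        {
            "all": richness(matrix, "all"),
            "woody": richness(matrix, "woody"),
            "herbaceous": richness(matrix, "herbaceous"),
        }
    ).rename_axis("cell")


# ---------------------------------------------------------------------------
# CSV interchange (formats shared with the synthetic-data generator)

def ranges_from_frame(df: pd.DataFrame) -> list[SpeciesRange]:
    """Build SpeciesRange records from an occurrences table.

    Expected columns: species, county_ids (';'-joined, may be empty),
    elev_min, elev_max, life_form.
    """
    out = []
    for row in df.itertuples(index=False):
        raw = row.county_ids
        counties = frozenset() if (not isinstance(raw, str) or raw == "") else frozenset(raw.split(";"))
        out.append(
            SpeciesRange(
                species_id=str(row.species),
                county_ids=counties,
                elev_min=float(row.elev_min),
                elev_max=float(row.elev_max),
                life_form=LifeForm(getattr(row, "life_form", "unknown")),
            )
        )
    return out


def cells_from_frame(df: pd.DataFrame, step: float = 0.5) -> list[GridCell]:
    """Build GridCell records from a grid table.

    Expected columns: cell, lon_min, lat_min, elev_min, elev_max,
    county_ids (';'-joined).
    """
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GridCell(
                cell_id=str(row.cell),
                lon_min=float(row.lon_min),
                lat_min=float(row.lat_min),
                elev_min=float(row.elev_min),
                elev_max=float(row.elev_max),
                county_ids=frozenset(str(row.county_ids).split(";")),
                step=step,
            )
        )
    return out
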