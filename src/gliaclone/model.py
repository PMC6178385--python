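"""Core data model for multicolor clonal data.

Combinatorial genomic labeling tags ventricular-zone progenitors with a random
subset of 12 fluorescent marks (6 fluorophores, each either cytoplasmic or
nuclear).  All descendants inherit the integrated marks, so cells sharing a
combination are read as one clone.  This module holds the in-memory containers
(:class:`ColorCombination`, :class:`Cell`, :class:`Clone`,
:class:`SampleDataset`), the clone-table CSV/TSV reader and writer, and the
homogeneous/heterogeneous clone classifier.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_MARKS",
    "MARK_NAMES",
    "P30_TYPES",
    "P0_TYPES",
    "ColorCombination",
    "Cell",
    "Clone",
    "SampleDataset",
    "CloneClass",
    "classify_clone",
    "clone_census",
    "read_clone_table",
    "write_clone_table",
    "datasets_to_frame",
    "read_supplementary_xlsx",
]

N_MARKS = 12

_FLUOROPHORES = ("YFP", "mKO", "mCherry", "mCerulean", "mTSapphire", "EGFP")
#: 6 fluorophores x {cytoplasmic, nuclear} = 12 mark slots, fixed order.
MARK_NAMES = tuple(
    f"{fp}_{loc}" for fp in _FLUOROPHORES for loc in ("cyt", "nuc")
)

#: Mature astrocyte types scored at P30.  CNA (cerebellar-nuclei astrocytes)
#: are retained in the data model but excluded from quantitative statistics.
P30_TYPES = ("BG", "GLA", "WMA", "CNA")

#: Precursor categories scored at birth (P0): Purkinje-cell-layer precursor,
#: granular-layer astrocyte precursor, prospective-white-matter cell, and
#: ventricular cell (still at the VZ).
P0_TYPES = ("PCLp", "GLAp", "PWM", "VC")

_WALLS = ("wall_A", "wall_B", "unknown")


@dataclass(frozen=True)
class ColorCombination:
    """A 12-mark binary label identifying a clone.

    The all-false combination denotes "unlabeled" and is only meaningful when
    counting theoretical combinations; a labeled cell must carry >= 1 mark.
    """

    marks: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.marks) != N_MARKS:
            raise ValueError(
                f"a color combination has exactly {N_MARKS} mark slots, "
                f"got {len(self.marks)}"
            )
        object.__setattr__(self, "marks", tuple(bool(m) for m in self.marks))

    @property
    def n_set(self) -> int:
        return sum(self.marks)

    def to_string(self) -> str:
        """Canonical 12-character '0'/'1' encoding (lossless round-trip)."""
        return "".join("1" if m else "0" for m in self.marks)

    @classmethod
    def from_string(cls, s: str) -> "ColorCombination":
        s = s.strip()
        if len(s) != N_MARKS or set(s) - {"0", "1"}:
            raise ValueError(f"not a canonical {N_MARKS}-bit combination: {s!r}")
        return cls(tuple(c == "1" for c in s))

    @classmethod
    def from_index(cls, index: int) -> "ColorCombination":
        """Combination for an integer in [0, 2**12); bit i -> mark slot i."""
        if not 0 <= index < 2**N_MARKS:
            raise ValueError(f"index out of range: {index}")
        return cls(tuple(bool((index >> i) & 1) for i in range(N_MARKS)))

    def mark_names(self) -> tuple[str, ...]:
        return tuple(n for n, m in zip(MARK_NAMES, self.marks) if m)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


@dataclass(frozen=True)
class Cell:
    """One labeled cell.

    ``clone_key`` is the canonical 12-bit combination string for StarTrack-style
    data or a color token (e.g. ``"RFP"``) for Confetti-style data.  The
    medio-lateral position of a cell is its 1-based parasagittal
    ``section_index`` (counted from the lateral-most section); explicit 3D
    coordinates in micrometers (M-L, A-P, D-V axes) take precedence for
    spatial analyses when present.
    """

    cell_id: str
    clone_key: str
    cell_type: str
    lobule: str
    wall: str = "unknown"
    section_index: int = 1
    coords: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.section_index < 1:
            raise ValueError("section_index is 1-based and must be >= 1")
        if self.wall not in _WALLS:
            raise ValueError(f"wall must be one of {_WALLS}, got {self.wall!r}")
        if self.coords is not None:
            coords = tuple(float(c) for c in self.coords)
            if len(coords) != 3 or not all(np.isfinite(coords)):
                raise ValueError(f"coords must be 3 finite floats, got {self.coords!r}")
            object.__setattr__(self, "coords", coords)


@dataclass
class Clone:
    """A non-empty set of same-key cells from one sample."""

    cells: list[Cell]
    sample_id: str

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("a clone contains at least one cell")
        keys = {c.clone_key for c in self.cells}
        if len(keys) != 1:
            raise ValueError(f"cells of one clone share one clone_key, got {keys}")

    @property
    def clone_key(self) -> str:
        return self.cells[0].clone_key

    @property
    def size(self) -> int:
        return len(self.cells)

    @property
    def type_counts(self) -> Counter:
        return Counter(c.cell_type for c in self.cells)

    @property
    def sections(self) -> list[int]:
        return [c.section_index for c in self.cells]

    def coords_array(self) -> np.ndarray:
        """(n, 3) coordinate array; raises if any cell lacks coordinates."""
        if any(c.coords is None for c in self.cells):
            raise ValueError("clone has cells without 3D coordinates")
        return np.array([c.coords for c in self.cells], dtype=float)

    @property
    def has_coords(self) -> bool:
        return all(c.coords is not None for c in self.cells)


@dataclass
class SampleDataset:
    """All clones of one animal/timepoint."""

    sample_id: str
    eporation_age: str  # E12, E14 or a Confetti-induction age such as P6
    analysis_age: str  # P0 or P30
    clones: list[Clone] = field(default_factory=list)
    section_thickness: float = 50.0
    region_volume: Optional[tuple[float, float, float]] = None  # box in um

    def __post_init__(self) -> None:
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be positive (um)")

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def n_cells(self) -> int:
        return sum(c.size for c in self.clones)

    def iter_cells(self) -> Iterable[Cell]:
        for clone in self.clones:
            yield from clone.cells


@dataclass(frozen=True)
class CloneClass:
    """Homogeneous (one cell type) / heterogeneous (several) classification.

    P30 subtypes: WMA, GLA, BG, CNA for HomCs; "BG+GLA+WMA" (triple),
    "BG+GLA" (double) or "other" for HetCs.  P0 subtypes: PCLp, GLAp, PWM, VZ
    for HomCs; "PCLp+GLAp", "cortical+PWM" or "other" for HetCs.
    """

    category: str  # HomC or HetC
    subtype: str

    @property
    def is_homogeneous(self) -> bool:
        return self.category == "HomC"


_P0_CORTICAL = {"PCLp", "GLAp"}


def classify_clone(clone: Clone, timepoint: str) -> CloneClass:
    """Classify a clone by the set of astrocyte (precursor) types it contains.

    Deterministic and total on every non-empty type subset of the
    timepoint-appropriate vocabulary; mixing P0 and P30 vocabularies in one
    clone is an error.
    """
    if timepoint not in ("P0", "P30"):
        raise ValueError(f"timepoint must be 'P0' or 'P30', got {timepoint!r}")
    vocab = set(P30_TYPES if timepoint == "P30" else P0_TYPES)
    other_vocab = set(P0_TYPES if timepoint == "P30" else P30_TYPES)
    types = set(clone.type_counts)
    if types & other_vocab and not types <= vocab:
        raise ValueError(
            f"clone mixes {timepoint} and other-timepoint cell types: {sorted(types)}"
        )
    unknown = types - vocab
    if unknown:
        raise ValueError(
            f"unknown cell type(s) {sorted(unknown)} for {timepoint}; "
            f"allowed: {sorted(vocab)}"
        )

    if len(types) == 1:
        (t,) = types
        if timepoint == "P0" and t == "VC":
            return CloneClass("HomC", "VZ")
        return CloneClass("HomC", t)

    if timepoint == "P30":
        if types == {"BG", "GLA", "WMA"}:
            return CloneClass("HetC", "BG+GLA+WMA")
        if types == {"BG", "GLA"}:
            return CloneClass("HetC", "BG+GLA")
        return CloneClass("HetC", "other")

    # P0 heterogeneous clones
    if types == {"PCLp", "GLAp"}:
        return CloneClass("HetC", "PCLp+GLAp")
    if "PWM" in types and types - {"PWM"} <= _P0_CORTICAL and types - {"PWM"}:
        return CloneClass("HetC", "cortical+PWM")
    return CloneClass("HetC", "other")


def clone_census(datasets: Sequence[SampleDataset]) -> pd.DataFrame:
    """Clone counts and fractions by class and subtype, per analysis age.

    Returns a tidy frame with columns ``analysis_age, category, subtype,
    count, fraction``; fractions sum to 1 within each analysis age.
    """
    if not datasets:
        raise ValueError("clone_census requires at least one dataset")
    rows = []
    for ds in datasets:
        for clone in ds.clones:
            cls = classify_clone(clone, ds.analysis_age)
            rows.append((ds.analysis_age, cls.category, cls.subtype))
    frame = pd.DataFrame(rows, columns=["analysis_age", "category", "subtype"])
    counts = (
        frame.groupby(["analysis_age", "category", "subtype"])
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby("analysis_age")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts


# ---------------------------------------------------------------------------
# Clone-table I/O
# ---------------------------------------------------------------------------

#: Required columns of the clone-table CSV/TSV schema.
REQUIRED_COLUMNS = (
    "sample_id",
    "eporation_age",
    "analysis_age",
    "clone_key",
    "cell_id",
    "cell_type",
    "lobule",
    "wall",
    "section_index",
)
_COORD_COLUMNS = ("x_um", "y_um", "z_um")


class SchemaError(ValueError):
    """A clone table is missing required columns."""


def _read_frame(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype={"clone_key": str, "cell_id": str})


def read_clone_table(path) -> list[SampleDataset]:
    """Read a clone-table CSV/TSV into :class:`SampleDataset` objects.

    One row per labeled cell; cells are grouped into clones by
    ``(sample_id, clone_key)``.  Rows that fail validation raise a
    ``ValueError`` naming the offending row number and token.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = _read_frame(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"clone table {path} is missing columns: {missing}")
    return frame_to_datasets(frame)


def frame_to_datasets(frame: pd.DataFrame) -> list[SampleDataset]:
    """Convert a validated clone-table DataFrame to datasets."""
    allowed = set(P30_TYPES) | set(P0_TYPES)
    has_coords = all(c in frame.columns for c in _COORD_COLUMNS)
    datasets = []
    for (sample_id, epo, age), sub in frame.groupby(
        ["sample_id", "eporation_age", "analysis_age"], sort=True
    ):
        thickness = (
            float(sub["section_thickness"].iloc[0])
            if "section_thickness" in sub.columns
            else 50.0
        )
        clones = []
        for _, grp in sub.groupby("clone_key", sort=True):
            cells = []
            for row_no, row in grp.iterrows():
                ct = str(row["cell_type"])
                if ct not in allowed:
                    raise ValueError(
                        f"row {row_no}: unknown cell type {ct!r}; "
                        f"allowed tokens: {sorted(allowed)}"
                    )
                coords = None
                if has_coords and not any(pd.isna(row[c]) for c in _COORD_COLUMNS):
                    coords = tuple(float(row[c]) for c in _COORD_COLUMNS)
                cells.append(
                    Cell(
                        cell_id=str(row["cell_id"]),
                        clone_key=str(row["clone_key"]),
                        cell_type=ct,
                        lobule=str(row["lobule"]),
                        wall=str(row["wall"]),
                        section_index=int(row["section_index"]),
                        coords=coords,
                    )
                )
            clones.append(Clone(cells=cells, sample_id=str(sample_id)))
        datasets.append(
            SampleDataset(
                sample_id=str(sample_id),
                eporation_age=str(epo),
                analysis_age=str(age),
                clones=clones,
                section_thickness=thickness,
            )
        )
    return datasets


def datasets_to_frame(datasets: Sequence[SampleDataset]) -> pd.DataFrame:
    """Flatten datasets back to the tidy one-row-per-cell schema."""
    rows = []
    for ds in datasets:
        for clone in ds.clones:
            for cell in clone.cells:
                x, y, z = cell.coords if cell.coords is not None else (np.nan,) * 3
                rows.append(
                    {
                        "sample_id": ds.sample_id,
                        "eporation_age": ds.eporation_age,
                        "analysis_age": ds.analysis_age,
                        "clone_key": cell.clone_key,
                        "cell_id": cell.cell_id,
                        "cell_type": cell.cell_type,
                        "lobule": cell.lobule,
                        "wall": cell.wall,
                        "section_index": cell.section_index,
                        "x_um": x,
                        "y_um": y,
                        "z_um": z,
                        "section_thickness": ds.section_thickness,
                    }
                )
    return pd.DataFrame(rows)


def write_clone_table(datasets: Sequence[SampleDataset], path) -> None:
    """Write datasets as CSV/TSV (separator chosen by file extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    datasets_to_frame(datasets).to_csv(path, sep=sep, index=False)


def read_supplementary_xlsx(
    path, column_mapping: Mapping[str, str], sheet_name=0, **dataset_kwargs
) -> list[SampleDataset]:
    """Adapter for supplementary spreadsheets with nonstandard column names.

    ``column_mapping`` maps spreadsheet columns onto the clone-table schema,
    e.g. ``{"Animal": "sample_id", "Cell type": "cell_type", ...}``.
    """
    frame = pd.read_excel(path, sheet_name=sheet_name).rename(
        columns=dict(column_mapping)
    )
    for col, default in dataset_kwargs.items():
        if col not in frame.columns:
            frame[col] = default
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"mapped spreadsheet is missing columns: {missing}")
    return frame_to_datasets(frame)


def all_nonempty_type_subsets(timepoint: str = "P30") -> list[frozenset]:
    """The 15 non-empty subsets of the timepoint's type vocabulary."""
    vocab = P30_TYPES if timepoint == "P30" else P0_TYPES
    out = []
    for r in range(1, len(vocab) + 1):
        out.extend(frozenset(s) for s in itertools.combinations(vocab, r))
    return out
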