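"""Discrete-time stochastic simulator of astroglial lineages.

Tests the hypothesis that all cerebellar astrocytes descend from a single
homogeneous multipotent-progenitor (MP) pool.  Lineages are grown in
synchronous generations: the root is generation 0 and is an MP with
probability ``root_mp_fraction`` (otherwise a size-1 clone of a postmitotic
astrocyte typed from the observed unicellular-clone fractions).  Every MP
alive at generation ``g`` divides into 2 daughters; each daughter
independently remains an MP with probability ``pMP`` or exits the cell cycle
and differentiates into BG, GLA or WMA with generation-dependent
probabilities (the fate schedule, derived from birthdating fractions).
Because ``2 * pMP < 1`` the MP population is a subcritical branching process
and clones terminate almost surely; the expected final clone size is
``root_mp_fraction * 2(1 - pMP)/(1 - 2 pMP) + (1 - root_mp_fraction)``.

The module also provides the grid fit of ``pMP`` against an observed clone
size distribution, the generation <-> age mapping via size-distribution
matching, birth-time snapshots mapped onto P0 precursor categories, and
model-vs-data comparison reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .model import Clone, CloneClass

__all__ = [
    "ASTRO_TYPES",
    "FateSchedule",
    "SimParams",
    "FitConfig",
    "SimulatedClone",
    "SimulatedCohort",
    "expected_final_size",
    "simulate_clone",
    "simulate_cohort",
    "simulate_final_sizes",
    "ReentryProbabilityFit",
    "fit_pmp",
    "map_generation",
    "snapshot_at_generation",
    "snapshot_census",
    "compare_to_empirical",
]

#: Fixed type order of fate-schedule rows and census arrays.
ASTRO_TYPES = ("BG", "GLA", "WMA")

#: Simulated mature types -> P0 precursor categories.
P0_TYPE_MAP = {"BG": "PCLp", "GLA": "GLAp", "WMA": "PWM"}


class FateSchedule:
    """Generation-indexed differentiation probabilities over (BG, GLA, WMA).

    Row ``g`` applies to postmitotic daughters born into generation ``g``.
    Rows must each sum to 1 within 1e-9.  When a lineage outlives the
    schedule, behavior follows ``extend``: repeat the last row (default) or
    raise.
    """

    def __init__(self, rows: np.ndarray, extend: bool = True) -> None:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != 3:
            raise ValueError("each schedule row has 3 probabilities (BG, GLA, WMA)")
        if rows.shape[0] == 0:
            raise ValueError("schedule must have at least one row")
        sums = rows.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("every schedule row must sum to 1 (+-1e-9)")
        if np.any(rows < 0):
            raise ValueError("schedule probabilities must be non-negative")
        self.rows = rows
        self.extend = extend

    def __len__(self) -> int:
        return self.rows.shape[0]

    def row(self, g: int) -> np.ndarray:
        if g < len(self):
            return self.rows[g]
        if self.extend:
            return self.rows[-1]
        raise IndexError(
            f"fate schedule exhausted at generation {g} (length {len(self)})"
        )

    @classmethod
    def uniform(cls, n_generations: int = 1) -> "FateSchedule":
        return cls(np.full((n_generations, 3), 1.0 / 3.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(ASTRO_TYPES)).rename_axis(
            "generation"
        )


@dataclass
class SimParams:
    """Simulator parameters.

    Defaults are the E12 study conditions; the E14 counterparts are
    ``pMP=0.44``, ``root_mp_fraction=0.60``, ``n_clones=98``.
    """

    pmp: float = 0.465
    root_mp_fraction: float = 0.70
    root_postmitotic_type_fractions: tuple[float, float, float] = (
        1 / 3,
        1 / 3,
        1 / 3,
    )
    n_clones: int = 275
    n_replicates: int = 5
    #: safety cap only -- at the study's reentry probabilities the MP ratio
    #: is 2*pMP = 0.93 per generation, so ~0.93^g lineages are still alive
    #: at generation g; 200 generations leaves < 1e-6 unterminated
    max_generations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pmp < 0.5:
            raise ValueError(
                "pmp must be in [0, 0.5): 2*pmp < 1 guarantees almost-sure "
                "termination of the MP branching process"
            )
        if not 0 <= self.root_mp_fraction <= 1:
            raise ValueError("root_mp_fraction must be in [0, 1]")
        fr = np.asarray(self.root_postmitotic_type_fractions, dtype=float)
        if fr.shape != (3,) or abs(fr.sum() - 1.0) > 1e-9 or np.any(fr < 0):
            raise ValueError("root type fractions must be 3 probabilities summing to 1")


@dataclass
class FitConfig:
    """Grid-search configuration for the pMP fit."""

    pmp_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.40, 0.50001, 0.005), 3)
    )
    clones_per_grid_point: int = 3000
    replicates: int = 5
    bin_upper_quantile: float = 0.99

    def __post_init__(self) -> None:
        grid = np.asarray(self.pmp_grid, dtype=float)
        # the grid may touch 0.5 (critical process): the generation cap in
        # the size simulator still bounds every lineage
        if np.any((grid < 0) | (grid > 0.5)):
            raise ValueError("pmp grid must lie within [0, 0.5]")
        self.pmp_grid = grid


def expected_final_size(pmp: float, root_mp_fraction: float = 1.0) -> float:
    """Analytic expected final clone size of the branching process.

    An MP root yields ``2(1 - p)/(1 - 2p)`` differentiated cells in
    expectation; a postmitotic root yields exactly 1.
    """
    if not 0 <= pmp < 0.5:
        raise ValueError("pmp must be in [0, 0.5)")
    mp_part = 2.0 * (1.0 - pmp) / (1.0 - 2.0 * pmp)
    return root_mp_fraction * mp_part + (1.0 - root_mp_fraction)


@dataclass
class SimulatedCohort:
    """Vectorized record of a simulated cohort.

    ``mp[g, i]`` is the number of MPs of clone ``i`` alive at generation
    ``g``; ``births[g, i, t]`` the number of postmitotic cells of type
    ``ASTRO_TYPES[t]`` born into generation ``g`` (generation-0 rows hold
    postmitotic roots).
    """

    mp: np.ndarray  # (G+1, n) int
    births: np.ndarray  # (G+1, n, 3) int
    params: SimParams

    @property
    def n_clones(self) -> int:
        return self.mp.shape[1]

    @property
    def n_generations(self) -> int:
        return self.mp.shape[0] - 1

    @property
    def terminal(self) -> np.ndarray:
        """Per-clone flag: no MPs remain at the last simulated generation."""
        return self.mp[-1] == 0

    def final_sizes(self) -> np.ndarray:
        """Differentiated cells per clone (leftover MPs of non-terminal
        clones are counted so sizes never read 0)."""
        return self.births.sum(axis=(0, 2)) + self.mp[-1]

    def final_type_counts(self) -> np.ndarray:
        """(n, 3) differentiated-cell counts per clone and type."""
        return self.births.sum(axis=0)

    def sizes_at(self, g: int) -> np.ndarray:
        """Cells alive at generation g: MPs plus postmitotic born at <= g."""
        if not 0 <= g <= self.n_generations:
            raise ValueError(f"generation {g} outside simulated range")
        return self.mp[g] + self.births[: g + 1].sum(axis=(0, 2))

    def type_counts_at(self, g: int) -> np.ndarray:
        return self.births[: g + 1].sum(axis=0)


@dataclass
class SimulatedClone:
    """Single-clone view: (type, birth_generation) pairs."""

    cells: list[tuple[str, int]]
    terminal: bool
    n_generations: int

    @property
    def size(self) -> int:
        return len(self.cells)

    def type_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t, _ in self.cells:
            out[t] = out.get(t, 0) + 1
        return out


def _root_init(
    params: SimParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw root states: (mp0 bool array, (n, 3) postmitotic-root births)."""
    is_mp = rng.random(n) < params.root_mp_fraction
    births0 = np.zeros((n, 3), dtype=np.int64)
    n_post = int((~is_mp).sum())
    if n_post:
        types = rng.choice(
            3, size=n_post, p=np.asarray(params.root_postmitotic_type_fractions)
        )
        births0[~is_mp] = np.eye(3, dtype=np.int64)[types]
    return is_mp.astype(np.int64), births0


def simulate_cohort(
    params: SimParams,
    schedule: FateSchedule,
    n_clones: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedCohort:
    """Simulate ``n_clones`` independent lineages (vectorized over clones)."""
    n = params.n_clones if n_clones is None else n_clones
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    mp0, births0 = _root_init(params, n, rng)
    mp_hist = [mp0]
    births_hist = [births0]
    g = 0
    while mp_hist[-1].sum() > 0 and g < params.max_generations:
        g += 1
        daughters = 2 * mp_hist[-1]
        new_mp = rng.binomial(daughters, params.pmp)
        diff = daughters - new_mp
        births = np.zeros((n, 3), dtype=np.int64)
        if diff.sum() > 0:
            births = rng.multinomial(diff, schedule.row(g))
        mp_hist.append(new_mp)
        births_hist.append(births)
    return SimulatedCohort(
        mp=np.stack(mp_hist), births=np.stack(births_hist), params=params
    )


def simulate_clone(
    params: SimParams,
    schedule: FateSchedule,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedClone:
    """Simulate a single lineage and return its cells with birth generations."""
    cohort = simulate_cohort(params, schedule, n_clones=1, rng=rng)
    cells: list[tuple[str, int]] = []
    for g in range(cohort.n_generations + 1):
        for t_idx, t in enumerate(ASTRO_TYPES):
            cells.extend([(t, g)] * int(cohort.births[g, 0, t_idx]))
    terminal = bool(cohort.terminal[0])
    if not terminal:
        cells.extend([("MP", cohort.n_generations)] * int(cohort.mp[-1, 0]))
    return SimulatedClone(
        cells=cells, terminal=terminal, n_generations=cohort.n_generations
    )


def simulate_final_sizes(
    pmp: float,
    n_clones: int,
    root_mp_fraction: float = 0.70,
    max_generations: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Final clone sizes only (no fate types) -- the fast path for fitting."""
    rng = rng if rng is not None else np.random.default_rng(0)
    mp = (rng.random(n_clones) < root_mp_fraction).astype(np.int64)
    sizes = (mp == 0).astype(np.int64)  # postmitotic roots are size-1 clones
    g = 0
    while mp.sum() > 0 and g < max_generations:
        g += 1
        daughters = 2 * mp
        mp = rng.binomial(daughters, pmp)
        sizes += daughters - mp
    sizes += mp  # leftover MPs of clones hitting the generation cap
    return sizes


def _size_histogram(sizes: np.ndarray, edges: np.ndarray) -> np.ndarray:
    h, _ = np.histogram(sizes, bins=edges)
    return h / max(len(sizes), 1)


def _size_bin_edges(sizes: np.ndarray, upper_quantile: float) -> np.ndarray:
    """Unit-width bins 1..q99 of the observed sizes plus one overflow bin."""
    top = max(2, int(np.ceil(np.quantile(sizes, upper_quantile))))
    return np.concatenate([np.arange(0.5, top + 0.5), [np.inf]])


class ReentryProbabilityFit(BaseEstimator):
    """Grid fit of the MP cell-cycle reentry probability pMP.

    For every grid value, ``replicates`` cohorts of
    ``clones_per_grid_point`` lineages are simulated; the fitted ``pmp_`` is
    the grid value minimizing the sum of squared residuals (SSR) between the
    replicate-mean simulated clone-size relative-frequency histogram and the
    observed one (unit-width bins up to the observed 99th percentile with a
    single overflow bin).  Ties break toward the lower pMP.

    Follows the scikit-learn estimator protocol: ``fit(sizes)`` sets
    ``pmp_``, ``ssr_`` and ``grid_``.
    """

    def __init__(
        self,
        pmp_grid=None,
        clones_per_grid_point: int = 3000,
        replicates: int = 5,
        root_mp_fraction: float = 0.70,
        max_generations: int = 200,
        bin_upper_quantile: float = 0.99,
        random_state: int = 0,
    ):
        self.pmp_grid = pmp_grid
        self.clones_per_grid_point = clones_per_grid_point
        self.replicates = replicates
        self.root_mp_fraction = root_mp_fraction
        self.max_generations = max_generations
        self.bin_upper_quantile = bin_upper_quantile
        self.random_state = random_state

    def fit(self, X, y=None):
        sizes = np.asarray(X, dtype=float).ravel()
        if sizes.size == 0:
            raise ValueError("empirical clone sizes must be non-empty")
        grid = (
            np.round(np.arange(0.40, 0.50001, 0.005), 3)
            if self.pmp_grid is None
            else np.asarray(self.pmp_grid, dtype=float)
        )
        edges = _size_bin_edges(sizes, self.bin_upper_quantile)
        target = _size_histogram(sizes, edges)
        rng = np.random.default_rng(self.random_state)
        ssr = np.empty(grid.size)
        for i, p in enumerate(grid):
            hists = [
                _size_histogram(
                    simulate_final_sizes(
                        p,
                        self.clones_per_grid_point,
                        self.root_mp_fraction,
                        self.max_generations,
                        rng,
                    ),
                    edges,
                )
                for _ in range(self.replicates)
            ]
            ssr[i] = float(np.sum((np.mean(hists, axis=0) - target) ** 2))
        self.grid_ = grid
        self.ssr_ = ssr
        self.pmp_ = float(grid[int(np.argmin(ssr))])  # argmin takes lowest tie
        self.bin_edges_ = edges
        return self


def fit_pmp(
    empirical_sizes: Sequence[int],
    config: FitConfig | None = None,
    root_mp_fraction: float = 0.70,
    seed: int = 0,
) -> float:
    """Functional wrapper over :class:`ReentryProbabilityFit`."""
    config = config or FitConfig()
    est = ReentryProbabilityFit(
        pmp_grid=config.pmp_grid,
        clones_per_grid_point=config.clones_per_grid_point,
        replicates=config.replicates,
        bin_upper_quantile=config.bin_upper_quantile,
        root_mp_fraction=root_mp_fraction,
        random_state=seed,
    )
    return est.fit(empirical_sizes).pmp_


def map_generation(
    empirical_p0_sizes: Sequence[int],
    params: SimParams,
    schedule: FateSchedule,
    n_clones: int = 3000,
    bin_upper_quantile: float = 0.99,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Find the generation whose simulated alive-clone-size distribution best
    matches the observed birth (P0) clone sizes.

    Distance is SSR on binned relative frequencies (same binning as the pMP
    fit); ties break toward the smaller generation.
    """
    sizes = np.asarray(empirical_p0_sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("empirical P0 sizes must be non-empty")
    cohort = simulate_cohort(params, schedule, n_clones=n_clones, rng=rng)
    edges = _size_bin_edges(sizes, bin_upper_quantile)
    target = _size_histogram(sizes, edges)
    ssr = np.array(
        [
            float(np.sum((_size_histogram(cohort.sizes_at(g), edges) - target) ** 2))
            for g in range(cohort.n_generations + 1)
        ]
    )
    return int(np.argmin(ssr))


def snapshot_at_generation(
    cohort: SimulatedCohort, g: int, mp_handling: str = "pwm"
) -> list[Optional[CloneClass]]:
    """Classify every clone at a birth-time snapshot into P0 categories.

    Differentiated cells present at generation ``g`` map BG -> PCLp,
    GLA -> GLAp, WMA -> PWM.  MPs alive at ``g`` are undifferentiated
    precursors residing in the prospective white matter, so the default
    (``mp_handling="pwm"``) counts them in the PWM compartment; the
    ``"exclude"`` mode drops them (clones with no differentiated cell then
    classify as ``None``).
    """
    if mp_handling not in ("pwm", "exclude"):
        raise ValueError("mp_handling must be 'pwm' or 'exclude'")
    counts = cohort.type_counts_at(g)  # (n, 3) in ASTRO_TYPES order
    mps = cohort.mp[g]
    out: list[Optional[CloneClass]] = []
    for i in range(cohort.n_clones):
        present = {
            P0_TYPE_MAP[t]
            for t_idx, t in enumerate(ASTRO_TYPES)
            if counts[i, t_idx] > 0
        }
        if mp_handling == "pwm" and mps[i] > 0:
            present.add("PWM")
        if not present:
            out.append(None)
            continue
        if len(present) == 1:
            out.append(CloneClass("HomC", next(iter(present))))
        elif present == {"PCLp", "GLAp"}:
            out.append(CloneClass("HetC", "PCLp+GLAp"))
        elif "PWM" in present:
            out.append(CloneClass("HetC", "cortical+PWM"))
        else:  # pragma: no cover - unreachable with 3 categories
            out.append(CloneClass("HetC", "other"))
    return out


def snapshot_census(classes: Sequence[Optional[CloneClass]]) -> pd.DataFrame:
    """Tidy counts/fractions of snapshot classes (``None`` entries dropped)."""
    kept = [c for c in classes if c is not None]
    if not kept:
        raise ValueError("no classifiable clones in snapshot")
    frame = pd.DataFrame(
        [(c.category, c.subtype) for c in kept], columns=["category", "subtype"]
    )
    counts = frame.groupby(["category", "subtype"]).size().rename("count").reset_index()
    counts["fraction"] = counts["count"] / counts["count"].sum()
    return counts


def _clone_subtype_p30(type_counts: dict[str, int]) -> tuple[str, str]:
    types = {t for t, n in type_counts.items() if n > 0}
    if len(types) == 1:
        return "HomC", next(iter(types))
    if types == {"BG", "GLA", "WMA"}:
        return "HetC", "BG+GLA+WMA"
    if types == {"BG", "GLA"}:
        return "HetC", "BG+GLA"
    return "HetC", "other"


def _empirical_p30_counts(clones: Sequence[Clone]) -> tuple[dict, dict, list]:
    """Clone-subtype counts, cell-type counts and sizes with CNA cells
    removed (they are excluded from all simulation comparisons)."""
    subtype_counts: dict[str, int] = {}
    cell_counts: dict[str, int] = {t: 0 for t in ASTRO_TYPES}
    sizes = []
    for clone in clones:
        counts = {
            t: n for t, n in clone.type_counts.items() if t in ASTRO_TYPES and n > 0
        }
        if not counts:
            continue  # CNA-only clone
        cat, sub = _clone_subtype_p30(counts)
        key = f"{cat}:{sub}"
        subtype_counts[key] = subtype_counts.get(key, 0) + 1
        for t, n in counts.items():
            cell_counts[t] += n
        sizes.append(sum(counts.values()))
    return subtype_counts, cell_counts, sizes


def _simulated_p30_counts(cohort: SimulatedCohort) -> tuple[dict, dict, list]:
    type_counts = cohort.final_type_counts()
    subtype_counts: dict[str, int] = {}
    cell_counts = {t: int(type_counts[:, i].sum()) for i, t in enumerate(ASTRO_TYPES)}
    sizes = []
    for i in range(cohort.n_clones):
        counts = {
            t: int(type_counts[i, j])
            for j, t in enumerate(ASTRO_TYPES)
            if type_counts[i, j] > 0
        }
        if not counts:
            continue  # non-terminal clone with no differentiated cells
        cat, sub = _clone_subtype_p30(counts)
        key = f"{cat}:{sub}"
        subtype_counts[key] = subtype_counts.get(key, 0) + 1
        sizes.append(sum(counts.values()))
    return subtype_counts, cell_counts, sizes


def _chi2_on_counts(sim: dict[str, int], emp: dict[str, int]) -> tuple[float, float]:
    cats = sorted(set(sim) | set(emp))
    table = np.array(
        [[sim.get(c, 0) for c in cats], [emp.get(c, 0) for c in cats]], dtype=float
    )
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return float("nan"), 1.0
    chi2, p, _, _ = sps.chi2_contingency(table)
    return float(chi2), float(p)


def compare_to_empirical(
    cohort: SimulatedCohort,
    empirical_clones: Sequence[Clone],
    level: str = "P30",
    snapshot_generation: Optional[int] = None,
    mp_handling: str = "pwm",
) -> dict:
    """Side-by-side simulated-vs-observed fractions with chi-squared tests.

    ``level="P30"`` compares final clone subtypes, astrocyte-type
    proportions and clone-size distributions; ``level="P0"`` compares
    snapshot clone classes at ``snapshot_generation``.
    """
    if level == "P30":
        sim_sub, sim_cells, sim_sizes = _simulated_p30_counts(cohort)
        emp_sub, emp_cells, emp_sizes = _empirical_p30_counts(empirical_clones)
    elif level == "P0":
        if snapshot_generation is None:
            raise ValueError("P0 comparison needs snapshot_generation")
        sim_classes = snapshot_at_generation(cohort, snapshot_generation, mp_handling)
        sim_sub = {}
        for c in sim_classes:
            if c is None:
                continue
            key = f"{c.category}:{c.subtype}"
            sim_sub[key] = sim_sub.get(key, 0) + 1
        emp_sub = {}
        for clone in empirical_clones:
            from .model import classify_clone

            c = classify_clone(clone, "P0")
            key = f"{c.category}:{c.subtype}"
            emp_sub[key] = emp_sub.get(key, 0) + 1
        sim_cells = emp_cells = None
        sim_sizes = list(cohort.sizes_at(snapshot_generation))
        emp_sizes = [c.size for c in empirical_clones]
    else:
        raise ValueError("level must be 'P30' or 'P0'")

    def _fraction_frame(sim: dict, emp: dict) -> pd.DataFrame:
        cats = sorted(set(sim) | set(emp))
        s_tot = max(sum(sim.values()), 1)
        e_tot = max(sum(emp.values()), 1)
        return pd.DataFrame(
            {
                "category": cats,
                "simulated_count": [sim.get(c, 0) for c in cats],
                "observed_count": [emp.get(c, 0) for c in cats],
                "simulated_fraction": [sim.get(c, 0) / s_tot for c in cats],
                "observed_fraction": [emp.get(c, 0) / e_tot for c in cats],
            }
        )

    report: dict = {"level": level}
    report["clone_subtypes"] = _fraction_frame(sim_sub, emp_sub)
    chi2, p = _chi2_on_counts(sim_sub, emp_sub)
    report["clone_subtype_chi2"] = chi2
    report["clone_subtype_p"] = p
    if sim_cells is not None:
        report["cell_types"] = _fraction_frame(sim_cells, emp_cells)
        chi2, p = _chi2_on_counts(sim_cells, emp_cells)
        report["cell_type_chi2"] = chi2
        report["cell_type_p"] = p
    # size distributions on shared unit bins
    edges = _size_bin_edges(np.asarray(emp_sizes, dtype=float), 0.99)
    sim_h, _ = np.histogram(sim_sizes, bins=edges)
    emp_h, _ = np.histogram(emp_sizes, bins=edges)
    keep = (sim_h + emp_h) > 0
    if keep.sum() >= 2:
        chi2, p, _, _ = sps.chi2_contingency(np.array([sim_h[keep], emp_h[keep]]))
    else:
        chi2, p = float("nan"), 1.0
    report["size_chi2"] = float(chi2)
    report["size_p"] = float(p)
    report["mean_size_simulated"] = float(np.mean(sim_sizes)) if sim_sizes else 0.0
    report["mean_size_observed"] = float(np.mean(emp_sizes)) if emp_sizes else 0.0
    return report
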