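"""Clone-level quantitative statistics.

Covers medio-lateral dispersion (section-span convention), antero-posterior
spread over lobules, clone-wise cell-type stoichiometry aggregated in the
natural-log domain, size-dispersion correlation, population composition by
clone class, and cleavage-plane angle binning.

Ratios of cell-type counts are skewed and bounded below by 0; the pipeline
therefore log-transforms them (natural log), aggregates in log units, and
back-transforms means, so a ratio of 2 and a ratio of 1/2 are symmetric
around 0.  A printed mean ratio of 1.772 corresponds to 0.572 log units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import Clone, CloneClass, classify_clone

__all__ = [
    "RatioStatConfig",
    "ml_dispersion",
    "ml_dispersion_coords",
    "ap_spread",
    "ratio_to_log",
    "log_to_ratio",
    "stoichiometry_clonewise",
    "size_dispersion_correlation",
    "population_composition",
    "cleavage_angle_classify",
    "bca_ci",
]


@dataclass(frozen=True)
class RatioStatConfig:
    """How ratio statistics are aggregated.

    Natural-log transform, bootstrap CIs by the bias-corrected and
    accelerated (BCa) percentile method with N = 1,000 resamples.
    """

    bootstrap_n: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_n < 100:
            raise ValueError("bootstrap_n must be >= 100")


def ratio_to_log(ratio: float) -> float:
    """Natural log of a positive ratio (log units)."""
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    return math.log(ratio)


def log_to_ratio(log_units: float) -> float:
    """Inverse of :func:`ratio_to_log`."""
    return math.exp(log_units)


def ml_dispersion(clone: Clone, thickness: float = 50.0) -> float:
    """Medio-lateral clone extent from the parasagittal section span, in um.

    Inclusive span convention: ``(max_section - min_section + 1) * thickness``,
    so a single-section clone spans one section thickness.
    """
    sections = clone.sections
    return (max(sections) - min(sections) + 1) * thickness


def ml_dispersion_coords(clone: Clone) -> float:
    """Alternative metric: max pairwise M-L (first-axis) coordinate difference."""
    ml = clone.coords_array()[:, 0]
    return float(ml.max() - ml.min())


def ap_spread(clone: Clone) -> tuple[int, bool]:
    """Antero-posterior spread: (number of distinct lobules, wall consistency).

    Wall consistency considers cortical cells only (types BG, GLA and their
    P0 precursors); a clone is wall-consistent when all its cortical cells
    with a known wall share one lobular wall.
    """
    n_lobules = len({c.lobule for c in clone.cells})
    cortical = ("BG", "GLA", "PCLp", "GLAp")
    walls = {
        c.wall
        for c in clone.cells
        if c.cell_type in cortical and c.wall != "unknown"
    }
    return n_lobules, len(walls) <= 1


def bca_ci(
    sample: np.ndarray,
    statistic=np.mean,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval of a statistic of one sample."""
    sample = np.asarray(sample, dtype=float)
    rng = np.random.default_rng(seed)
    res = sps.bootstrap(
        (sample,),
        statistic,
        n_resamples=n_boot,
        confidence_level=level,
        method="BCa",
        vectorized=False,
        random_state=rng,
    )
    return float(res.confidence_interval.low), float(res.confidence_interval.high)


def stoichiometry_clonewise(
    clones: Sequence[Clone],
    numerators: Sequence[str],
    denominator: str,
    config: RatioStatConfig | None = None,
) -> pd.DataFrame:
    """Per-clone cell-type ratios aggregated in the log domain.

    For each clone, ``count(numerator) / count(denominator)`` is computed;
    clones lacking the denominator type are excluded with a warning.  The
    per-type mean is the back-transformed mean of natural-log ratios (the
    geometric mean); uncertainty is reported both as the log-domain SEM
    (back-transformed into an interval) and the linear-domain SEM, plus a
    BCa bootstrap CI of the back-transformed mean.
    """
    config = config or RatioStatConfig()
    rows = []
    for num in numerators:
        ratios = []
        n_excluded = 0
        for clone in clones:
            counts = clone.type_counts
            denom = counts.get(denominator, 0)
            if denom == 0:
                n_excluded += 1
                continue
            n = counts.get(num, 0)
            if n == 0:
                n_excluded += 1  # log-ratio undefined
                continue
            ratios.append(n / denom)
        if n_excluded:
            warnings.warn(
                f"{n_excluded} clone(s) excluded from {num}:{denominator} ratio "
                f"(missing {denominator!r} or {num!r} cells)",
                stacklevel=2,
            )
        if not ratios:
            raise ValueError(f"no clone has both {num!r} and {denominator!r} cells")
        logs = np.log(np.asarray(ratios, dtype=float))
        mean_log = float(logs.mean())
        sem_log = float(sps.sem(logs)) if len(logs) > 1 else float("nan")
        sem_linear = float(sps.sem(ratios)) if len(ratios) > 1 else float("nan")

        def _geo_mean(x):
            return np.exp(np.mean(np.log(x)))

        if len(ratios) > 4:
            ci_lo, ci_hi = bca_ci(
                np.asarray(ratios),
                _geo_mean,
                n_boot=config.bootstrap_n,
                level=config.ci_level,
                seed=config.seed,
            )
        else:
            ci_lo = ci_hi = float("nan")
        rows.append(
            {
                "numerator": num,
                "denominator": denominator,
                "n_clones": len(ratios),
                "n_excluded": n_excluded,
                "mean_ratio": math.exp(mean_log),
                "mean_log": mean_log,
                "sem_log": sem_log,
                "sem_linear": sem_linear,
                "ratio_lo": math.exp(mean_log - sem_log) if len(logs) > 1 else float("nan"),
                "ratio_hi": math.exp(mean_log + sem_log) if len(logs) > 1 else float("nan"),
                "ci_lo": ci_lo,
                "ci_hi": ci_hi,
            }
        )
    return pd.DataFrame(rows)


def size_dispersion_correlation(
    clones: Sequence[Clone], thickness: float = 50.0
) -> tuple[float, float]:
    """Pearson correlation between clone size and M-L dispersion."""
    if len(clones) < 3:
        raise ValueError("need at least 3 clones for a correlation")
    sizes = np.array([c.size for c in clones], dtype=float)
    disp = np.array([ml_dispersion(c, thickness) for c in clones])
    if sizes.std() == 0 or disp.std() == 0:
        raise ValueError("correlation undefined: zero variance in size or dispersion")
    r, p = sps.pearsonr(sizes, disp)
    return float(r), float(p)


def population_composition(
    clones: Sequence[Clone], timepoint: str = "P30"
) -> pd.DataFrame:
    """Per cell type: fraction of cells residing in HetCs vs HomCs, and the
    fraction of single-cell clones among that type's HomCs.

    HetC + HomC cell fractions sum to 1 for every type.
    """
    het_cells: dict[str, int] = {}
    hom_cells: dict[str, int] = {}
    hom_clones: dict[str, int] = {}
    hom_singletons: dict[str, int] = {}
    for clone in clones:
        cls = classify_clone(clone, timepoint)
        target = hom_cells if cls.is_homogeneous else het_cells
        for t, n in clone.type_counts.items():
            target[t] = target.get(t, 0) + n
        if cls.is_homogeneous:
            (t,) = set(clone.type_counts)
            hom_clones[t] = hom_clones.get(t, 0) + 1
            if clone.size == 1:
                hom_singletons[t] = hom_singletons.get(t, 0) + 1
    rows = []
    for t in sorted(set(het_cells) | set(hom_cells)):
        het = het_cells.get(t, 0)
        hom = hom_cells.get(t, 0)
        total = het + hom
        n_homc = hom_clones.get(t, 0)
        rows.append(
            {
                "cell_type": t,
                "n_cells": total,
                "hetc_cell_fraction": het / total,
                "homc_cell_fraction": hom / total,
                "n_homc_clones": n_homc,
                "homc_singleton_fraction": (
                    hom_singletons.get(t, 0) / n_homc if n_homc else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def cleavage_angle_classify(angle: float) -> str:
    """Bin a cleavage-plane angle (degrees from the layer trajectory).

    Left-closed bins: [0, 30) horizontal, [30, 60) oblique, [60, 90] vertical.
    """
    if not 0 <= angle <= 90:
        raise ValueError(f"angle must be in [0, 90] degrees, got {angle}")
    if angle < 30:
        return "horizontal"
    if angle < 60:
        return "oblique"
    return "vertical"
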