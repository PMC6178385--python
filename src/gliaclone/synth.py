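"""Synthetic clone-table generators with known ground truth.

The study's own clone tables are microscopy-derived supplementary
spreadsheets without a public accession, so every pipeline stage is tested
against synthetic datasets that emulate their statistical structure:

* **StarTrack-like** data: a mixture of homogeneous and heterogeneous clone
  classes, branching-process clone sizes, clone-wise cell-type stoichiometry
  with log-normal clone-to-clone variation, spatially clustered subclones
  (isotropic Gaussian scatter around spaced-out centers), and 12-mark color
  combinations with a configurable repeat probability.
* **Confetti-like** data: sparse progenitors with 4 reporter colors,
  developmental growth scaling between induction and analysis, and planted
  clones separated by more than the minimal clone distance.

Ground truth (true memberships, subclone assignments, planted repeats) is
emitted as a sidecar table keyed by ``cell_id`` so synthetic and real data
share the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .confetti import CONFETTI_COLORS
from .lineage import FateSchedule, simulate_final_sizes
from .model import Cell, Clone, SampleDataset

__all__ = [
    "ConfigError",
    "SubcloneModel",
    "Geometry",
    "SynthConfig",
    "GroundTruth",
    "generate_startrack_dataset",
    "generate_confetti_dataset",
    "generate_fate_schedule",
]


class ConfigError(ValueError):
    """Infeasible or inconsistent generator configuration."""


@dataclass(frozen=True)
class SubcloneModel:
    """Spatial subclone structure of heterogeneous clones.

    Cells scatter isotropically (Gaussian, per-axis ``sigma_um``) around
    subclone centers placed uniformly within the clone's lobule-wall box
    subject to a minimum ``spacing_um`` between centers.  ``mixed_fraction``
    is the planted probability that a subclone contains both BG and GLAs.
    """

    n_subclones: Mapping[str, int] = field(
        default_factory=lambda: {"BG+GLA": 2, "BG+GLA+WMA": 3}
    )
    sigma_um: float = 50.0
    spacing_um: float = 600.0
    mixed_fraction: float = 0.85

    def __post_init__(self) -> None:
        if self.sigma_um <= 0 or self.spacing_um <= 0:
            raise ConfigError("spatial scales must be positive")
        if not 0 <= self.mixed_fraction <= 1:
            raise ConfigError("mixed_fraction must be a probability")


@dataclass(frozen=True)
class Geometry:
    """Tissue geometry for synthetic samples (lengths in um)."""

    lobules: tuple[str, ...] = ("I-III", "IV-V", "VI-VII", "VIII", "IX", "X")
    walls: tuple[str, ...] = ("wall_A", "wall_B")
    section_thickness: float = 50.0
    box: tuple[float, float, float] = (2000.0, 1500.0, 800.0)

    def __post_init__(self) -> None:
        if self.section_thickness <= 0 or any(b <= 0 for b in self.box):
            raise ConfigError("geometry lengths must be positive")


#: Default clone-class mixture: early-electroporation-like conditions with a
#: roughly even homogeneous/heterogeneous split and triple clones near 18%.
_DEFAULT_MIXTURE = {
    "BG": 0.25,
    "GLA": 0.15,
    "WMA": 0.13,
    "BG+GLA": 0.294,
    "BG+GLA+WMA": 0.176,
}

_HOMC_CLASSES = ("BG", "GLA", "WMA")
_HETC_CLASSES = ("BG+GLA", "BG+GLA+WMA")


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults emulate the study conditions."""

    seed: int = 0
    n_clones: int = 275
    clone_class_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIXTURE)
    )
    #: ("branching", pMP) draws heterogeneous-clone sizes from the lineage
    #: branching process; ("explicit", sizes) resamples a given list.
    size_model: tuple = ("branching", 0.465)
    #: target WMA:GLA:BG per-clone ratios in triple clones
    stoichiometry: tuple[float, float, float] = (1.0, 4.0, 4.0)
    #: target BG per GLA in double clones
    double_bg_per_gla: float = 1.5
    #: clone-to-clone log-normal spread of planted ratios (log units)
    ratio_sigma_log: float = 0.3
    #: mean extra cells of a homogeneous clone beyond the first (Poisson)
    homc_extra_mean: float = 0.8
    subclone_model: SubcloneModel = field(default_factory=SubcloneModel)
    n_marks: int = 12
    mark_repeat_probability: float = 0.0
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        mix = dict(self.clone_class_mixture)
        if not mix:
            raise ConfigError("clone_class_mixture must be non-empty")
        if any(not 0 <= p <= 1 for p in mix.values()):
            raise ConfigError("mixture probabilities must be in [0, 1]")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigError("clone_class_mixture must sum to 1")
        unknown = set(mix) - set(_HOMC_CLASSES) - set(_HETC_CLASSES)
        if unknown:
            raise ConfigError(f"unknown clone classes in mixture: {sorted(unknown)}")
        if not 0 <= self.mark_repeat_probability <= 1:
            raise ConfigError("mark_repeat_probability must be a probability")
        if self.size_model[0] not in ("branching", "explicit"):
            raise ConfigError(f"unknown size model {self.size_model[0]!r}")

    def echo(self) -> dict:
        d = asdict(self)
        d["clone_class_mixture"] = dict(self.clone_class_mixture)
        d["subclone_model"] = asdict(self.subclone_model)
        d["geometry"] = asdict(self.geometry)
        return d


@dataclass
class GroundTruth:
    """Sidecar ground truth for a generated dataset."""

    frame: pd.DataFrame  # cell_id, clone_id, subclone_index
    clone_classes: dict[str, str]
    repeated_combinations: list[str]
    config_echo: dict
    induction_positions: Optional[pd.DataFrame] = None

    def write(self, csv_path, config_path=None) -> None:
        self.frame.to_csv(Path(csv_path), index=False)
        if config_path is not None:
            Path(config_path).write_text(
                yaml.safe_dump(self.config_echo, sort_keys=True)
            )


def _min_required_size(clone_class: str) -> int:
    # triple clones are the biggest clone type in the study; 9 cells is the
    # smallest count that can carry >= 1 WMA plus a 1:4:4 stoichiometry
    if clone_class == "BG+GLA+WMA":
        return 9
    if clone_class == "BG+GLA":
        return 2
    return 1


def _draw_hetc_size(
    config: SynthConfig, clone_class: str, rng: np.random.Generator
) -> int:
    min_size = _min_required_size(clone_class)
    kind = config.size_model[0]
    if kind == "explicit":
        sizes = np.asarray(config.size_model[1], dtype=int)
        if np.all(sizes < min_size):
            raise ConfigError(
                f"{clone_class} clone requires >= {min_size} cells but the "
                "explicit size distribution offers none"
            )
        for _ in range(10000):
            s = int(rng.choice(sizes))
            if s >= min_size:
                return s
        raise ConfigError("could not draw a feasible clone size")
    pmp = float(config.size_model[1])
    while True:
        s = int(simulate_final_sizes(pmp, 1, root_mp_fraction=1.0, rng=rng)[0])
        if s >= max(min_size, 2):
            return s


def _draw_composition(
    config: SynthConfig, clone_class: str, size: int, rng: np.random.Generator
) -> dict[str, int]:
    """Type counts of one clone honoring the planted stoichiometry."""
    if clone_class in _HOMC_CLASSES:
        return {clone_class: size}
    if clone_class == "BG+GLA":
        # split size so that BG/GLA ~ double_bg_per_gla (log-normal spread)
        r = config.double_bg_per_gla * float(
            np.exp(rng.normal(0.0, config.ratio_sigma_log))
        )
        bg = int(np.clip(round(size * r / (1 + r)), 1, size - 1))
        return {"BG": bg, "GLA": size - bg}
    # triple: WMA-anchored counts so each clone-wise log ratio is centered
    # on the planted stoichiometry (stochastic rounding keeps the rounded
    # counts unbiased; totals track `size` approximately)
    w_s, g_s, b_s = config.stoichiometry
    denom = w_s + g_s + b_s
    wma = max(1, int(round(size * w_s / denom)))

    def _anchored(target_per_wma: float) -> int:
        x = wma * target_per_wma * float(
            np.exp(rng.normal(0.0, config.ratio_sigma_log))
        )
        lo = int(np.floor(x))
        n = lo + int(rng.random() < (x - lo))
        return max(1, n)

    return {
        "WMA": wma,
        "GLA": _anchored(g_s / w_s),
        "BG": _anchored(b_s / w_s),
    }


def _place_centers(
    k: int,
    box: np.ndarray,
    spacing: float,
    rng: np.random.Generator,
    max_tries_per_center: int = 5000,
) -> np.ndarray:
    """Sequential dart-throwing: each center is retried against the ones
    already placed, which packs far denser than all-at-once rejection."""
    centers: list[np.ndarray] = []
    for _ in range(k):
        for _ in range(max_tries_per_center):
            cand = rng.random(3) * box
            if all(np.linalg.norm(cand - c) >= spacing for c in centers):
                centers.append(cand)
                break
        else:
            raise ConfigError(
                f"could not place {k} centers with spacing {spacing} um in "
                f"box {box}: density too high"
            )
    return np.array(centers)


def _allocate_to_subclones(
    counts: dict[str, int], k: int, mixed_fraction: float, rng: np.random.Generator
) -> list[dict[str, int]]:
    """Deal a clone's cells to k subclones.

    Cortical cells (BG, GLA) are dealt round-robin so subclones come out
    mixed; with probability ``1 - mixed_fraction`` a subclone is made
    single-type by handing its minority cortical type to a neighbor.  WMA
    cells all join subclone 0 (white-matter cells cluster separately from
    the cortical scatter in real clones, but a single planted spatial
    cluster keeps the ground-truth subclone count unambiguous).
    """
    per = [dict.fromkeys(counts, 0) for _ in range(k)]
    for t, n in counts.items():
        if t == "WMA":
            per[0][t] += n
            continue
        start = int(rng.integers(k))
        for i in range(n):
            per[(start + i) % k][t] += 1
    if k > 1:
        for idx in range(k):
            if per[idx].get("BG", 0) > 0 and per[idx].get("GLA", 0) > 0:
                if rng.random() < 1.0 - mixed_fraction:
                    minority = (
                        "BG" if per[idx]["BG"] <= per[idx]["GLA"] else "GLA"
                    )
                    moved = per[idx][minority]
                    per[idx][minority] = 0
                    per[(idx + 1) % k][minority] += moved
        # keep planted subclones at >= 3 cells (the detection minimum), so
        # the ground truth stays recoverable on well-separated geometry
        def total(i: int) -> int:
            return sum(per[i].values())

        for _ in range(1000):
            small = min(range(k), key=total)
            if total(small) >= 3:
                break
            donor = max(range(k), key=total)
            move_type = max(per[donor], key=lambda t: per[donor][t])
            per[donor][move_type] -= 1
            per[small][move_type] = per[small].get(move_type, 0) + 1
    return per


def _new_combination(
    used: set[int], n_marks: int, rng: np.random.Generator
) -> int:
    space = 2**n_marks
    if len(used) >= space - 1:
        raise ConfigError("combination space exhausted")
    while True:
        c = int(rng.integers(1, space))  # never the all-absent combination
        if c not in used:
            return c


def generate_startrack_dataset(
    config: SynthConfig | None = None,
) -> tuple[SampleDataset, GroundTruth]:
    """Generate a StarTrack-like sample with known ground truth.

    Deterministic given ``config.seed``; ground truth records true clone
    memberships, true subclone assignments, per-clone classes, and which
    combinations were planted as repeats.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    geom = config.geometry
    box = np.asarray(geom.box, dtype=float)
    classes = list(config.clone_class_mixture)
    probs = np.array([config.clone_class_mixture[c] for c in classes])
    sub = config.subclone_model

    from .model import ColorCombination

    used_combos: set[int] = set()
    combo_of_clone: list[int] = []
    clones: list[Clone] = []
    gt_rows = []
    clone_classes: dict[str, str] = {}
    cell_counter = 0
    for ci in range(config.n_clones):
        clone_class = classes[int(rng.choice(len(classes), p=probs))]
        if clone_class in _HOMC_CLASSES:
            size = 1 + int(rng.poisson(config.homc_extra_mean))
        else:
            size = _draw_hetc_size(config, clone_class, rng)
        counts = _draw_composition(config, clone_class, size, rng)

        if (
            config.mark_repeat_probability > 0
            and used_combos
            and rng.random() < config.mark_repeat_probability
        ):
            combo = int(rng.choice(sorted(used_combos)))
        else:
            combo = _new_combination(used_combos, config.n_marks, rng)
        used_combos.add(combo)
        combo_of_clone.append(combo)
        key = ColorCombination.from_index(combo).to_string()

        lobule = str(rng.choice(geom.lobules))
        wall = str(rng.choice(geom.walls))
        total = sum(counts.values())
        k = (
            dict(sub.n_subclones).get(clone_class, 1)
            if clone_class in _HETC_CLASSES
            else 1
        )
        k = max(1, min(k, total // 3 if total >= 6 else 1))
        margin = 4 * sub.sigma_um
        inner = np.maximum(box - 2 * margin, 1.0)
        centers = _place_centers(k, inner, sub.spacing_um, rng) + margin
        allocation = _allocate_to_subclones(counts, k, sub.mixed_fraction, rng)

        clone_id = f"clone{ci:04d}"
        clone_classes[clone_id] = clone_class
        cells = []
        for sc_idx, sc_counts in enumerate(allocation):
            for cell_type, n in sc_counts.items():
                for _ in range(n):
                    pos = centers[sc_idx] + rng.normal(0.0, sub.sigma_um, 3)
                    pos = np.clip(pos, 0.0, box - 1e-6)
                    section = int(pos[0] // geom.section_thickness) + 1
                    cell_id = f"cell{cell_counter:06d}"
                    cell_counter += 1
                    cells.append(
                        Cell(
                            cell_id=cell_id,
                            clone_key=key,
                            cell_type=cell_type,
                            lobule=lobule,
                            wall=wall,
                            section_index=section,
                            coords=tuple(pos),
                        )
                    )
                    gt_rows.append(
                        {
                            "cell_id": cell_id,
                            "clone_id": clone_id,
                            "subclone_index": sc_idx,
                            "clone_class": clone_class,
                            "combination": key,
                        }
                    )
        clones.append(Clone(cells=cells, sample_id="synth1"))

    combo_counts = pd.Series(combo_of_clone).value_counts()
    repeated = [
        ColorCombination.from_index(int(c)).to_string()
        for c in combo_counts[combo_counts >= 2].index
    ]
    dataset = SampleDataset(
        sample_id="synth1",
        eporation_age="E12",
        analysis_age="P30",
        clones=clones,
        section_thickness=geom.section_thickness,
        region_volume=tuple(box),
    )
    truth = GroundTruth(
        frame=pd.DataFrame(gt_rows),
        clone_classes=clone_classes,
        repeated_combinations=repeated,
        config_echo=config.echo(),
    )
    return dataset, truth


@dataclass(frozen=True)
class ConfettiSynthConfig:
    """Confetti generator settings; defaults emulate the induction protocol
    (sparse Purkinje-layer progenitors tagged at P6, analyzed at P30)."""

    seed: int = 0
    n_clones: int = 40
    minimal_clone_distance_um: float = 317.0
    clone_type_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"BG-only": 0.45, "BG+GLA": 0.45, "GLA-only": 0.10}
    )
    double_mean_size: float = 4.5
    single_mean_size: float = 2.0
    double_bg_per_gla: float = 1.2
    ratio_sigma_log: float = 0.3
    geometry: Geometry = field(
        default_factory=lambda: Geometry(lobules=("IV-V",), box=(3000.0, 2500.0, 1200.0))
    )

    def __post_init__(self) -> None:
        mix = dict(self.clone_type_mixture)
        if abs(sum(mix.values()) - 1.0) > 1e-9 or any(p < 0 for p in mix.values()):
            raise ConfigError("clone_type_mixture must be probabilities summing to 1")
        if self.minimal_clone_distance_um <= 0:
            raise ConfigError("minimal clone distance must be positive")


def generate_confetti_dataset(
    config: ConfettiSynthConfig | None = None,
    n_colors: int = 4,
    growth_factor: float = 2.3,
) -> tuple[SampleDataset, GroundTruth]:
    """Generate a Confetti-like sample with known ground truth.

    Cells are planted at induction (progenitor positions, emitted in the
    ground truth) and mapped to analysis age by uniform growth scaling:
    ``p30 = induction * growth_factor``.  Planted clones are separated by
    more than the minimal clone distance while within-clone extents stay
    below half of it, so single-linkage clone calling at the default cutoff
    recovers them exactly.
    """
    config = config or ConfettiSynthConfig()
    if n_colors < 2:
        raise ConfigError("n_colors must be >= 2")
    if growth_factor <= 0:
        raise ConfigError("growth_factor must be positive")
    rng = np.random.default_rng(config.seed)
    geom = config.geometry
    box = np.asarray(geom.box, dtype=float)
    colors = list(CONFETTI_COLORS[:n_colors])
    min_dist = config.minimal_clone_distance_um
    # centers live at analysis scale; scatter radius keeps intra-clone links
    # strictly below half the minimal distance
    scatter_radius = 0.2 * min_dist
    margin = scatter_radius + 1.0
    inner = box - 2 * margin
    if np.any(inner <= 0):
        raise ConfigError("geometry box too small for the clone separation")
    centers = (
        _place_centers(config.n_clones, inner, min_dist + 2 * scatter_radius, rng)
        + margin
    )

    types = list(config.clone_type_mixture)
    type_p = np.array([config.clone_type_mixture[t] for t in types])
    clones: list[Clone] = []
    gt_rows = []
    induction_rows = []
    clone_classes: dict[str, str] = {}
    cell_counter = 0
    for ci in range(config.n_clones):
        clone_type = types[int(rng.choice(len(types), p=type_p))]
        color = str(rng.choice(colors))
        if clone_type == "BG+GLA":
            size = max(2, int(rng.poisson(config.double_mean_size)))
            r = config.double_bg_per_gla * float(
                np.exp(rng.normal(0.0, config.ratio_sigma_log))
            )
            bg = int(np.clip(round(size * r / (1 + r)), 1, size - 1))
            counts = {"BG": bg, "GLA": size - bg}
        else:
            size = max(1, int(rng.poisson(config.single_mean_size)))
            counts = {("BG" if clone_type == "BG-only" else "GLA"): size}
        clone_id = f"cclone{ci:03d}"
        clone_classes[clone_id] = clone_type
        lobule = str(rng.choice(geom.lobules))
        wall = str(rng.choice(geom.walls))
        cells = []
        for cell_type, n in counts.items():
            for _ in range(n):
                # uniform offset inside a ball of scatter_radius (analysis scale)
                while True:
                    off = rng.uniform(-scatter_radius, scatter_radius, 3)
                    if np.linalg.norm(off) <= scatter_radius:
                        break
                p30 = centers[ci] + off
                induction = p30 / growth_factor
                section = int(p30[0] // geom.section_thickness) + 1
                cell_id = f"ccell{cell_counter:05d}"
                cell_counter += 1
                cells.append(
                    Cell(
                        cell_id=cell_id,
                        clone_key=color,
                        cell_type=cell_type,
                        lobule=lobule,
                        wall=wall,
                        section_index=section,
                        coords=tuple(p30),
                    )
                )
                gt_rows.append(
                    {
                        "cell_id": cell_id,
                        "clone_id": clone_id,
                        "subclone_index": 0,
                        "clone_class": clone_type,
                        "combination": color,
                    }
                )
                induction_rows.append(
                    {
                        "cell_id": cell_id,
                        "x_um": induction[0],
                        "y_um": induction[1],
                        "z_um": induction[2],
                    }
                )
        clones.append(Clone(cells=cells, sample_id="confetti1"))
    dataset = SampleDataset(
        sample_id="confetti1",
        eporation_age="P6",
        analysis_age="P30",
        clones=clones,
        section_thickness=geom.section_thickness,
        region_volume=tuple(box),
    )
    echo = asdict(config)
    echo["clone_type_mixture"] = dict(config.clone_type_mixture)
    echo["geometry"] = asdict(geom)
    echo["n_colors"] = n_colors
    echo["growth_factor"] = growth_factor
    truth = GroundTruth(
        frame=pd.DataFrame(gt_rows),
        clone_classes=clone_classes,
        repeated_combinations=[],
        config_echo=echo,
        induction_positions=pd.DataFrame(induction_rows),
    )
    return dataset, truth


def generate_fate_schedule(
    anchor_fractions: Mapping[str, Sequence[float]],
    age_to_generation: Mapping[str, int],
    n_generations: Optional[int] = None,
) -> FateSchedule:
    """Build a generation-indexed fate schedule from birthdating anchors.

    ``anchor_fractions`` maps ages (e.g. ``"P1"``) to (BG, GLA, WMA)
    differentiation fractions (normalized here); ``age_to_generation`` maps
    each age to its lineage generation.  Interpolation is piecewise-constant:
    row ``g`` takes the anchor at the nearest generation <= ``g`` (rows
    before the first anchor take the first anchor).
    """
    if not anchor_fractions:
        raise ConfigError("anchor_fractions must be non-empty")
    missing = set(anchor_fractions) - set(age_to_generation)
    if missing:
        raise ConfigError(f"ages without a generation mapping: {sorted(missing)}")
    anchors = []
    for age, fr in anchor_fractions.items():
        fr = np.asarray(fr, dtype=float)
        if fr.shape != (3,) or np.any(fr < 0) or fr.sum() <= 0:
            raise ConfigError(f"invalid fractions for age {age!r}")
        anchors.append((int(age_to_generation[age]), fr / fr.sum()))
    anchors.sort(key=lambda a: a[0])
    top = max(g for g, _ in anchors)
    n_rows = (n_generations if n_generations is not None else top) + 1
    rows = np.empty((n_rows, 3))
    for g in range(n_rows):
        current = anchors[0][1]
        for gen, fr in anchors:
            if gen <= g:
                current = fr
            else:
                break
        rows[g] = current
    return FateSchedule(rows)
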