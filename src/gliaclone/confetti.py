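"""Clone identification for 4-color sparse-labeling (Confetti) data.

With only 4 stochastic reporter colors, color alone cannot define a clone;
clone calling additionally requires location in the same lobule and lobular
wall and spatial contiguity of cells.  The contiguity scale is anchored by
the mean nearest-neighbor distance between labeled progenitors shortly after
induction, scaled by subsequent tissue growth (ratio of geometric means of
3D lobule measurements): 137.62 um x 2.3 = 317 um is the minimal distance
separating distinct clones at maturity.  Cells closer than the linkage
cutoff (default: half the minimal clone distance) with the same color,
lobule and wall are linked; clones are the connected components
(single linkage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin

from .model import Cell, Clone
from .stats import RatioStatConfig, stoichiometry_clonewise

__all__ = [
    "CONFETTI_COLORS",
    "GrowthModel",
    "ConfettiCloneConfig",
    "minimal_clone_distance",
    "ConfettiCloneCaller",
    "identify_clones",
    "confetti_stats",
    "validate_against_induction",
]

#: The four reporter colors (nuclear GFP cells are excluded upstream).
CONFETTI_COLORS = ("RFP", "YFP", "CFP", "mGFP")


@dataclass(frozen=True)
class GrowthModel:
    """Tissue growth between induction and analysis.

    ``factor`` is the ratio of geometric means of 3D lobule measurements at
    the two ages (dimensionless); pass explicit dims via :meth:`from_dims`.
    """

    factor: float
    dims_t0: Optional[tuple[float, float, float]] = None
    dims_t1: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("growth factor must be positive")

    @classmethod
    def from_dims(
        cls, dims_t0: Sequence[float], dims_t1: Sequence[float]
    ) -> "GrowthModel":
        t0 = np.asarray(dims_t0, dtype=float)
        t1 = np.asarray(dims_t1, dtype=float)
        if t0.shape != (3,) or t1.shape != (3,) or np.any(t0 <= 0) or np.any(t1 <= 0):
            raise ValueError("growth dims must be 3 positive lengths (um)")
        factor = float(sps.gmean(t1) / sps.gmean(t0))
        return cls(factor=factor, dims_t0=tuple(t0), dims_t1=tuple(t1))


def minimal_clone_distance(mean_nnd_at_induction: float, growth: GrowthModel) -> float:
    """Minimal inter-clone distance at analysis age, in um.

    The mean NND between same-color progenitors at induction, scaled by the
    tissue growth factor.
    """
    if mean_nnd_at_induction <= 0:
        raise ValueError("mean NND must be positive")
    return mean_nnd_at_induction * growth.factor


@dataclass(frozen=True)
class ConfettiCloneConfig:
    """Clone-calling rules for sparse color labeling."""

    linkage_cutoff: float = 317.0 * 0.5  # um; half the minimal clone distance
    require_same_lobule: bool = True
    require_same_wall: bool = True
    colors: tuple[str, ...] = CONFETTI_COLORS

    def __post_init__(self) -> None:
        if self.linkage_cutoff <= 0:
            raise ValueError("linkage_cutoff must be positive")

    @classmethod
    def from_minimal_distance(
        cls, minimal_distance: float, cutoff_factor: float = 0.5, **kwargs
    ) -> "ConfettiCloneConfig":
        return cls(linkage_cutoff=minimal_distance * cutoff_factor, **kwargs)


class ConfettiCloneCaller(BaseEstimator, ClusterMixin):
    """Single-linkage clone caller over (color, lobule, wall) groups.

    ``fit(X)`` takes an (n, 3) coordinate array together with per-cell
    ``groups`` (color/lobule/wall tokens, combined upstream); cells of the
    same group closer than ``linkage_cutoff`` are linked and clones are the
    connected components.  Fitted attribute: ``labels_`` (clone index per
    cell).  Raising the cutoff never increases the number of clones.
    """

    def __init__(self, linkage_cutoff: float = 317.0 * 0.5):
        self.linkage_cutoff = linkage_cutoff

    def fit(self, X, y=None, groups=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        if groups is None:
            groups = np.zeros(n, dtype=int)
        groups = np.asarray(groups)
        if groups.shape[0] != n:
            raise ValueError("groups must align with X rows")
        rows, cols = [], []
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            if idx.size < 2:
                continue
            tree = cKDTree(X[idx])
            for i, j in tree.query_pairs(r=self.linkage_cutoff):
                rows.append(idx[i])
                cols.append(idx[j])
        adj = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        n_comp, labels = connected_components(adj, directed=False)
        # relabel components so labels are deterministic in input order but
        # group-disjoint: cells of different groups never share a clone
        # (singleton groups already form their own components)
        combined = np.empty(n, dtype=object)
        for i in range(n):
            combined[i] = (labels[i], groups[i])
        _, self.labels_ = np.unique(combined, return_inverse=True)
        self.n_clones_ = int(self.labels_.max()) + 1 if n else 0
        return self


def identify_clones(
    cells: Sequence[Cell],
    config: ConfettiCloneConfig | None = None,
    sample_id: str = "confetti",
) -> tuple[list[Clone], list[Cell]]:
    """Group Confetti-labeled cells into clones.

    Returns ``(clones, held_out)``: cells lacking a lobule/wall while the
    corresponding requirement is on are held out rather than clustered.
    Each remaining cell belongs to exactly one clone.  Cells without 3D
    coordinates fall back to section adjacency: their M-L coordinate is
    ``section_index * 50`` and in-plane coordinates 0.
    """
    config = config or ConfettiCloneConfig()
    eligible: list[Cell] = []
    held_out: list[Cell] = []
    for c in cells:
        if config.require_same_wall and c.wall == "unknown":
            held_out.append(c)
        elif config.require_same_lobule and not c.lobule:
            held_out.append(c)
        else:
            eligible.append(c)
    if not eligible:
        return [], held_out
    coords = np.array(
        [
            c.coords
            if c.coords is not None
            else (c.section_index * 50.0, 0.0, 0.0)
            for c in eligible
        ],
        dtype=float,
    )
    group_keys = [
        "|".join(
            (
                c.clone_key,
                c.lobule if config.require_same_lobule else "",
                c.wall if config.require_same_wall else "",
            )
        )
        for c in eligible
    ]
    groups = pd.factorize(np.asarray(group_keys, dtype=object))[0]
    caller = ConfettiCloneCaller(linkage_cutoff=config.linkage_cutoff).fit(
        coords, groups=groups
    )
    clones: dict[int, list[Cell]] = {}
    for cell, label in zip(eligible, caller.labels_):
        clones.setdefault(int(label), []).append(cell)
    out = [Clone(cells=members, sample_id=sample_id) for _, members in sorted(clones.items())]
    return out, held_out


def _confetti_clone_type(clone: Clone) -> str:
    types = {t for t, n in clone.type_counts.items() if n > 0}
    if types == {"BG"}:
        return "BG-only"
    if types == {"GLA"}:
        return "GLA-only"
    if types == {"BG", "GLA"}:
        return "BG+GLA"
    return "other"


def _mean_and_max_intercell(clone: Clone) -> tuple[float, float]:
    if clone.size < 2 or not clone.has_coords:
        return 0.0, 0.0
    pts = clone.coords_array()
    diffs = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diffs**2).sum(axis=-1))
    iu = np.triu_indices(clone.size, k=1)
    return float(d[iu].mean()), float(d[iu].max())


def _mean_sister_nnd(clone: Clone) -> float:
    if clone.size < 2 or not clone.has_coords:
        return float("nan")
    pts = clone.coords_array()
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    return float(dists[:, 1].mean())


def confetti_stats(
    clones: Sequence[Clone], config: RatioStatConfig | None = None
) -> dict:
    """Summary statistics of called Confetti clones.

    Clone-type fractions (BG-only / BG+GLA / GLA-only), sizes by type, the
    clone-wise BG:GLA ratio aggregated in the log domain, mean sister-cell
    NND, and mean/max intraclone intercell distance.
    """
    if not clones:
        raise ValueError("confetti_stats requires clones")
    config = config or RatioStatConfig()
    types = [_confetti_clone_type(c) for c in clones]
    counts = pd.Series(types).value_counts()
    fractions = (counts / counts.sum()).to_dict()
    sizes_by_type = (
        pd.DataFrame({"clone_type": types, "size": [c.size for c in clones]})
        .groupby("clone_type")["size"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "mean_size", "count": "n_clones"})
        .reset_index()
    )
    doubles = [c for c in clones if _confetti_clone_type(c) == "BG+GLA"]
    if doubles:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ratio = stoichiometry_clonewise(doubles, ["BG"], "GLA", config)
        ratio_row = ratio.iloc[0].to_dict()
    else:
        ratio_row = None
    nnds = [v for c in clones if (v := _mean_sister_nnd(c)) == v]  # drop NaN
    pair_stats = [_mean_and_max_intercell(c) for c in clones if c.size >= 2]
    return {
        "clone_type_fractions": fractions,
        "sizes_by_type": sizes_by_type,
        "bg_gla_ratio": ratio_row,
        "mean_sister_nnd_um": float(np.mean(nnds)) if nnds else float("nan"),
        "mean_intercell_distance_um": (
            float(np.mean([m for m, _ in pair_stats])) if pair_stats else float("nan")
        ),
        "max_intercell_distance_um": (
            float(np.max([mx for _, mx in pair_stats])) if pair_stats else float("nan")
        ),
        "n_clones": len(clones),
    }


def validate_against_induction(
    induction_counts: dict[str, Sequence[float]],
    clone_counts: dict[str, Sequence[float]],
) -> dict:
    """Compare per-color progenitor counts at induction with per-color clone
    counts at analysis (two-sample t test).

    If clone calling is accurate and each progenitor founds one clone, the
    two per-color count distributions should be indistinguishable.
    """
    colors = sorted(set(induction_counts) & set(clone_counts))
    if not colors:
        raise ValueError("no shared colors between induction and clone counts")
    ind = np.concatenate([np.asarray(induction_counts[c], dtype=float) for c in colors])
    clo = np.concatenate([np.asarray(clone_counts[c], dtype=float) for c in colors])
    degenerate = bool(
        ind.size == clo.size and np.allclose(np.sort(ind), np.sort(clo))
    ) or (ind.std() == 0 and clo.std() == 0)
    if degenerate and ind.mean() == clo.mean():
        p = 1.0
        t = 0.0
    else:
        t, p = sps.ttest_ind(ind, clo)
    per_color = {
        c: {
            "induction_mean": float(np.mean(induction_counts[c])),
            "induction_sem": float(sps.sem(induction_counts[c]))
            if len(induction_counts[c]) > 1
            else float("nan"),
            "clone_mean": float(np.mean(clone_counts[c])),
            "clone_sem": float(sps.sem(clone_counts[c]))
            if len(clone_counts[c]) > 1
            else float("nan"),
        }
        for c in colors
    }
    return {
        "per_color": per_color,
        "t_statistic": float(t),
        "p_value": float(p),
        "degenerate": degenerate,
    }
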