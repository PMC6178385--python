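"""Monte-Carlo estimators of label-collision errors for combination clonality.

Two error modes threaten combination-based clone calling:

* **splitting** — one progenitor's combination recurs by chance in an
  unrelated lineage, so one clone is read as several.  Estimated by a
  birthday-problem Monte Carlo over equiprobable theoretical combinations,
  cross-checkable against the closed form ``(n - K(1 - (1 - 1/K)^n)) / n``.
* **lumping** — cells sharing a combination actually derive from different
  progenitors.  Estimated by resampling fixed-size samples from a reference
  multiset of observed combinations (repeated combinations carry more weight)
  and scoring within-sample collisions of the repeated combinations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import Clone

__all__ = [
    "ErrorSimConfig",
    "theoretical_combinations",
    "combination_frequencies",
    "splitting_error",
    "splitting_error_expected",
    "lumping_error",
]


@dataclass
class ErrorSimConfig:
    """Configuration of the collision Monte Carlos.

    ``reference_multiset`` (lumping only) lists observed combinations with
    their repeat counts; ``per_sample_n`` gives the clone count of each
    animal whose lumping risk is evaluated.
    """

    reps: int = 300_000
    n_theoretical: int = 4096
    reference_multiset: dict[str, int] = field(default_factory=dict)
    per_sample_n: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    mode: str = "within_draw"  # or "reference"

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.n_theoretical < 2:
            raise ValueError("n_theoretical must be >= 2")
        if any(n < 1 for n in self.per_sample_n.values()):
            raise ValueError("per-sample clone counts must all be >= 1")
        if self.mode not in ("within_draw", "reference"):
            raise ValueError(f"unknown lumping mode {self.mode!r}")


def theoretical_combinations(n_marks: int) -> int:
    """Number of theoretical combinations of ``n_marks`` binary marks.

    ``2**n_marks``; includes the all-absent (unlabeled) combination, which
    is what makes 12 marks yield 4,096.
    """
    if n_marks < 1:
        raise ValueError("n_marks must be >= 1")
    return 2**n_marks


def combination_frequencies(
    clones: Sequence[Clone], cutoff: float = 8e-3
) -> pd.DataFrame:
    """Relative frequency of each combination among clones, with flags.

    Frequencies sum to 1; ``flagged`` marks combinations whose frequency
    exceeds ``cutoff`` (default 8e-3, the screen used for a 12-mark system).
    """
    if not clones:
        raise ValueError("combination_frequencies requires clones")
    counts = Counter(c.clone_key for c in clones)
    total = sum(counts.values())
    frame = pd.DataFrame(
        {
            "combination": list(counts),
            "count": list(counts.values()),
        }
    ).sort_values("count", ascending=False, ignore_index=True)
    frame["frequency"] = frame["count"] / total
    frame["flagged"] = frame["frequency"] > cutoff
    return frame


def splitting_error_expected(n_clones: int, n_theoretical: int) -> float:
    """Closed-form expected splitting error (birthday-problem expectation).

    Expected fraction of ``n_clones`` uniform draws from ``n_theoretical``
    labels that duplicate an earlier draw:
    ``(n - K(1 - (1 - 1/K)^n)) / n``.
    """
    n, k = n_clones, n_theoretical
    return (n - k * (1.0 - (1.0 - 1.0 / k) ** n)) / n


def splitting_error(
    n_clones: int,
    config: ErrorSimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Monte-Carlo splitting-error probability.

    Per repetition: draw ``n_clones`` labels uniformly with replacement from
    ``n_theoretical`` equiprobable combinations, count draws duplicating an
    earlier draw, divide by ``n_clones``.  Returns the mean over repetitions
    with its Monte-Carlo standard error.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    config = config or ErrorSimConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    k = config.n_theoretical
    reps = config.reps
    # duplicates per repetition = n - (number of distinct labels drawn)
    chunk = max(1, min(reps, 20_000_000 // max(n_clones, 1)))
    per_rep = np.empty(reps, dtype=float)
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        draws = rng.integers(0, k, size=(m, n_clones))
        draws.sort(axis=1)
        n_unique = 1 + np.count_nonzero(np.diff(draws, axis=1), axis=1)
        per_rep[done : done + m] = (n_clones - n_unique) / n_clones
        done += m
    mean = float(per_rep.mean())
    se = float(per_rep.std(ddof=1) / np.sqrt(reps)) if reps > 1 else float("nan")
    return {
        "probability": mean,
        "se": se,
        "expected": splitting_error_expected(n_clones, k),
        "n_clones": n_clones,
        "n_theoretical": k,
        "reps": reps,
    }


def lumping_error(config: ErrorSimConfig) -> dict:
    """Monte-Carlo lumping-error probability per sample and pooled.

    A weighted reference vector is built from ``reference_multiset`` (each
    combination appears as many times as observed, so repeated combinations
    are proportionally more likely to be drawn).  Per repetition and per
    sample, ``per_sample_n[sample]`` elements are drawn with replacement;
    the event probability is the fraction of drawn elements whose
    combination (i) is one of the repeated combinations and (ii) collides
    within the draw (mode ``"within_draw"``, default) or simply (i) alone
    (mode ``"reference"``).  Returns per-sample mean and SD over repetitions
    and the pooled mean over samples.
    """
    if not config.reference_multiset:
        raise ValueError("lumping_error requires a non-empty reference multiset")
    if not config.per_sample_n:
        raise ValueError("lumping_error requires per-sample clone counts")
    combos = list(config.reference_multiset)
    weights = np.array(
        [config.reference_multiset[c] for c in combos], dtype=float
    )
    if np.any(weights < 1):
        raise ValueError("reference multiset counts must be >= 1")
    n_ref = len(combos)
    probs = weights / weights.sum()
    repeated = weights >= 2  # per-combination flag
    rng = np.random.default_rng(config.seed)
    per_sample = {}
    for sample, n in config.per_sample_n.items():
        reps = config.reps
        chunk = max(1, min(reps, 20_000_000 // max(n, 1)))
        vals = np.empty(reps, dtype=float)
        done = 0
        while done < reps:
            m = min(chunk, reps - done)
            draws = rng.choice(n_ref, size=(m, n), p=probs)
            is_rep = repeated[draws]
            if config.mode == "reference":
                vals[done : done + m] = is_rep.mean(axis=1)
            else:
                # within-draw collision: combination drawn more than once
                order = np.argsort(draws, axis=1)
                sorted_draws = np.take_along_axis(draws, order, axis=1)
                dup_next = np.zeros((m, n), dtype=bool)
                eq = sorted_draws[:, 1:] == sorted_draws[:, :-1]
                dup_next[:, 1:] = eq
                dup_next[:, :-1] |= eq
                collides_sorted = dup_next
                collides = np.zeros_like(collides_sorted)
                np.put_along_axis(collides, order, collides_sorted, axis=1)
                vals[done : done + m] = (collides & is_rep).mean(axis=1)
            done += m
        per_sample[sample] = {
            "n_clones": n,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if reps > 1 else float("nan"),
        }
    pooled = float(np.mean([s["mean"] for s in per_sample.values()]))
    return {
        "per_sample": per_sample,
        "pooled_mean": pooled,
        "mode": config.mode,
        "reps": config.reps,
        "seed": config.seed,
    }
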