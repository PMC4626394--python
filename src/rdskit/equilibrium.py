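"""Equilibrium diagnostics for recruitment chains.

Two complementary views of convergence:

* the empirical one — the trait proportion in the *accumulated* sample up to
  each wave, with the working rule that equilibrium is reached at the first
  wave from which every adjacent-wave change stays below a tolerance
  (default 2%, the stricter of the two conventional cutoffs; 5% is the other
  common default);
* the model one — the number of Markov-recursion steps the estimated
  transition matrix needs to carry the seed composition to within the
  tolerance of its stationary distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, NonConvergenceError
from .estimator import TransitionMatrix, equilibrium_distribution
from .forest import RecruitmentForest
from .records import TraitPartition

DEFAULT_TOLERANCE = 0.02


@dataclass
class EquilibriumTrace:
    """Cumulative per-wave proportions of one trait group."""

    trait_name: str
    group: str
    waves: np.ndarray  # 0..W
    n_cumulative: np.ndarray
    cumulative_proportion: np.ndarray
    tolerance: float = DEFAULT_TOLERANCE
    converged_at: int | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.n_cumulative) < 0):
            raise ValueError("cumulative counts must be non-decreasing")
        p = self.cumulative_proportion
        if np.any((p < 0) | (p > 1)):
            raise ValueError("proportions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": self.trait_name,
                "group": self.group,
                "wave": self.waves,
                "n_cum": self.n_cumulative,
                "proportion": self.cumulative_proportion,
                "converged_at": self.converged_at,
            }
        )


def cumulative_wave_proportions(
    forest: RecruitmentForest,
    partition: TraitPartition,
    trait_group: str,
    tolerance: float = DEFAULT_TOLERANCE,
) -> EquilibriumTrace:
    """Trait proportion among all participants of wave <= w, for each wave.

    Seeds are wave 0.  Waves with no members (impossible in a well-formed
    forest, but tolerated) carry the previous cumulative value forward.
    """
    if not forest.nodes:
        raise InsufficientDataError("empty forest")
    W = forest.max_wave
    counts = np.zeros(W + 1)
    hits = np.zeros(W + 1)
    for r in forest.nodes.values():
        counts[r.wave] += 1
        if partition.group_of(r.pid) == trait_group:
            hits[r.wave] += 1
    n_cum = np.cumsum(counts)
    h_cum = np.cumsum(hits)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_cum > 0, h_cum / np.maximum(n_cum, 1), 0.0)
    trace = EquilibriumTrace(
        trait_name=partition.trait_name,
        group=trait_group,
        waves=np.arange(W + 1),
        n_cumulative=n_cum.astype(int),
        cumulative_proportion=p,
        tolerance=tolerance,
    )
    trace.converged_at = detect_equilibrium(p, tolerance)
    return trace


def detect_equilibrium(
    proportions: np.ndarray | list[float], tolerance: float = DEFAULT_TOLERANCE
) -> int | None:
    """First wave from which every adjacent-wave change is below tolerance.

    "Consistently" below: the returned wave w is the smallest such that
    |p_{w'+1} - p_{w'}| < tolerance for *every* w' >= w, not merely the first
    crossing.  Returns None if the final step still exceeds the tolerance.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size < 2:
        raise InsufficientDataError("need at least two waves to assess equilibrium")
    diffs = np.abs(np.diff(p))
    bad = np.nonzero(diffs >= tolerance)[0]
    if bad.size == 0:
        return 0
    if bad[-1] == diffs.size - 1:  # the final step still moves too much
        return None
    return int(bad[-1]) + 1


def waves_to_equilibrium(
    T: TransitionMatrix,
    seed_composition: np.ndarray | list[float],
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = 1000,
) -> int:
    """Markov-recursion steps from the seed composition to the stationary pi.

    The smallest t with ``max_g |(v S^t)_g - pi_g| < tolerance`` where v is
    the seed group composition.

    Raises
    ------
    NonConvergenceError
        ``max_iter`` steps were not enough (e.g. a periodic chain).
    """
    v = np.asarray(seed_composition, dtype=float)
    if v.shape != (T.k,) or abs(v.sum() - 1.0) > 1e-9 or np.any(v < 0):
        raise ValueError("seed composition must be a probability vector over groups")
    pi = equilibrium_distribution(T)
    for t in range(max_iter + 1):
        if np.max(np.abs(v - pi)) < tolerance:
            return t
        v = v @ T.S
    raise NonConvergenceError(
        f"seed composition did not reach equilibrium within {max_iter} steps"
    )


def seed_composition(
    forest: RecruitmentForest, partition: TraitPartition
) -> np.ndarray:
    """Group composition of the seeds (wave-0 participants)."""
    counts = np.zeros(len(partition.groups))
    idx = {g: i for i, g in enumerate(partition.groups)}
    for pid in forest.roots:
        counts[idx[partition.group_of(pid)]] += 1
    if counts.sum() == 0:
        raise InsufficientDataError("forest has no seeds")
    return counts / counts.sum()


def traces_to_frame(traces: list[EquilibriumTrace]) -> pd.DataFrame:
    """Stack traces into one tidy table suitable for re-plotting."""
    return pd.concat([t.to_frame() for t in traces], ignore_index=True)


def plot_traces(traces: list[EquilibriumTrace], path=None):
    """Minimal convergence figure: one panel per trait, cumulative proportion
    by wave with a dashed line at the detected equilibrium wave."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(traces)
    ncol = min(3, n)
    nrow = -(-n // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax, tr in zip(axes.ravel(), traces):
        ax.plot(tr.waves, tr.cumulative_proportion, marker="o", ms=3)
        if tr.converged_at is not None:
            ax.axvline(tr.converged_at, ls="--", color="grey")
        ax.set_title(tr.trait_name, fontsize=9)
        ax.set_xlabel("wave")
        ax.set_ylabel("cumulative proportion")
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
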