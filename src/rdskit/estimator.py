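"""Prevalence estimation for chain-referral (RDS) samples.

The estimator family implemented here is the classical reciprocity (RDS-I)
estimator: recruitment is modelled as a Markov chain on trait groups, whose
transition matrix is estimated from recruiter -> recruit pairs.  Three
estimates are produced per trait:

* **crude** - the raw sample proportion;
* **equilibrium** - the stationary distribution pi of the recruitment chain
  (what the sample composition converges to, regardless of seeds);
* **RDS-adjusted** - pi corrected for differential network degree with the
  harmonic ("multiplicity") mean degree per group:

  .. math:: \\hat P_g = \\frac{\\pi_g / \\hat D_g}{\\sum_h \\pi_h / \\hat D_h},
            \\qquad \\hat D_g = \\frac{n_g}{\\sum_{i \\in g} 1/d_i}.

  For two groups this reduces to
  :math:`\\hat P_A = S_{BA}\\hat D_B / (S_{AB}\\hat D_A + S_{BA}\\hat D_B)`.

Standard errors come from a dependent (chain) bootstrap: each replicate
regrows a pseudo-sample of the original size by Markov draws from the
observed recruit pools conditional on recruiter group, and the chosen
estimator is recomputed on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np
from scipy import stats

from .errors import (
    DegenerateChainError,
    InsufficientDataError,
    UndefinedRatioError,
    UndefinedTestError,
)
from .forest import RecruitmentForest
from .records import ParticipantRecord, TraitPartition

logger = logging.getLogger(__name__)

_ROW_TOL = 1e-12
_STATIONARY_TOL = 1e-10


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupEstimate:
    """A prevalence estimate for one group of a trait partition."""

    trait_name: str
    group: str
    kind: str  # crude | equilibrium | rds_adjusted
    proportion: float
    n_contributing: int
    se: float | None = None
    ci95: tuple[float, float] | None = None

    def with_uncertainty(self, se: float, ci95: tuple[float, float]) -> "GroupEstimate":
        return GroupEstimate(
            self.trait_name, self.group, self.kind, self.proportion,
            self.n_contributing, se, ci95,
        )


@dataclass
class TransitionMatrix:
    """Row-stochastic group -> group recruitment probabilities.

    ``counts[a, b]`` is the number of observed recruitments of a group-``b``
    member by a group-``a`` recruiter; seeds contribute as recruiters only.
    ``S`` is counts row-normalised, with zero-count rows filled per policy
    (``uniform`` or ``self_loop``) and remembered in ``zero_rows``.
    """

    groups: tuple[str, ...]
    S: np.ndarray
    counts: np.ndarray
    zero_rows: list[str] = field(default_factory=list)
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        k = len(self.groups)
        if self.S.shape != (k, k):
            raise ValueError(f"S must be {k}x{k}, got {self.S.shape}")
        if np.any(self.S < -_ROW_TOL):
            raise ValueError("transition probabilities must be non-negative")
        if np.max(np.abs(self.S.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transition-matrix rows must sum to 1")

    @property
    def k(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class DegreeSummary:
    """Harmonic-mean degrees per group, with exclusion bookkeeping."""

    groups: tuple[str, ...]
    harmonic_mean: dict[str, float]
    n: dict[str, int]
    n_excluded: dict[str, int]

    def as_array(self) -> np.ndarray:
        return np.array([self.harmonic_mean[g] for g in self.groups])


@dataclass
class BootstrapResult:
    groups: tuple[str, ...]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    replicates: np.ndarray  # B x k
    n_restarts: int = 0


@dataclass(frozen=True)
class WaldResult:
    z: float
    p_value: float


# ---------------------------------------------------------------------------
# Point estimators
# ---------------------------------------------------------------------------


def crude_proportion(
    records: list[ParticipantRecord], partition: TraitPartition
) -> dict[str, GroupEstimate]:
    """Raw sample proportions per group (includes seeds)."""
    if not records:
        raise InsufficientDataError("cannot estimate proportions from zero records")
    n = len(records)
    counts = {g: 0 for g in partition.groups}
    for r in records:
        counts[partition.group_of(r.pid)] += 1
    return {
        g: GroupEstimate(partition.trait_name, g, "crude", counts[g] / n, n)
        for g in partition.groups
    }


def estimate_transition_matrix(
    forest: RecruitmentForest,
    partition: TraitPartition,
    zero_row_policy: str = "uniform",
    smoothing: bool = False,
) -> TransitionMatrix:
    """Estimate the recruitment Markov chain from recruiter -> recruit pairs.

    ``smoothing=True`` applies reciprocity smoothing (symmetrises the count
    matrix, ``(C + C.T) / 2``) before row-normalising; off by default.
    """
    edges = forest.edges()
    if not edges:
        raise InsufficientDataError("transition matrix needs at least one edge")
    k = len(partition.groups)
    idx = {g: i for i, g in enumerate(partition.groups)}
    counts = np.zeros((k, k))
    for a, b in edges:
        counts[idx[partition.group_of(a)], idx[partition.group_of(b)]] += 1
    return transition_matrix_from_counts(
        counts, partition.groups, zero_row_policy=zero_row_policy, smoothing=smoothing
    )


def transition_matrix_from_counts(
    counts: np.ndarray,
    groups: tuple[str, ...],
    zero_row_policy: str = "uniform",
    smoothing: bool = False,
) -> TransitionMatrix:
    counts = np.asarray(counts, dtype=float)
    work = (counts + counts.T) / 2.0 if smoothing else counts.copy()
    k = len(groups)
    row_sums = work.sum(axis=1)
    S = np.zeros((k, k))
    zero_rows = []
    for i in range(k):
        if row_sums[i] > 0:
            S[i] = work[i] / row_sums[i]
        else:
            zero_rows.append(groups[i])
            if zero_row_policy == "uniform":
                S[i] = 1.0 / k
            elif zero_row_policy == "self_loop":
                S[i, i] = 1.0
            else:
                raise ValueError(f"unknown zero_row_policy {zero_row_policy!r}")
    if zero_rows:
        logger.warning(
            "groups with no recruiters %s: rows filled with %s policy",
            zero_rows, zero_row_policy,
        )
    return TransitionMatrix(tuple(groups), S, counts, zero_rows, smoothing)


def equilibrium_distribution(T: TransitionMatrix) -> np.ndarray:
    """Stationary distribution pi with pi S = pi, sum(pi) = 1, pi >= 0.

    Raises
    ------
    DegenerateChainError
        The chain is reducible with more than one closed class (e.g. the
        identity matrix), so no unique stationary distribution exists.  The
        error names the absorbing classes.
    """
    S = T.S
    k = T.k
    # Reducibility check: more than one sink in the condensation of the
    # positive-transition digraph means multiple stationary distributions.
    g = nx.DiGraph(
        (i, j) for i in range(k) for j in range(k) if S[i, j] > _ROW_TOL and i != j
    )
    g.add_nodes_from(range(k))
    cond = nx.condensation(g)
    sinks = [c for c in cond.nodes if cond.out_degree(c) == 0]
    if len(sinks) > 1:
        classes = [
            sorted(T.groups[i] for i in cond.nodes[c]["members"]) for c in sinks
        ]
        raise DegenerateChainError(
            "recruitment chain is reducible: no unique equilibrium; absorbing "
            f"classes {classes}",
            absorbing_classes=classes,
        )
    # Solve (S^T - I) pi = 0 with the normalisation row appended.
    A = np.vstack([S.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    residual = np.max(np.abs(pi @ S - pi))
    if residual > _STATIONARY_TOL:
        raise DegenerateChainError(
            f"stationary solve failed: residual {residual:.2e} exceeds "
            f"{_STATIONARY_TOL:.0e}"
        )
    return pi


def equilibrium_proportion(
    T: TransitionMatrix, n_contributing: int, trait_name: str | None = None
) -> dict[str, GroupEstimate]:
    """The stationary distribution packaged as per-group estimates."""
    pi = equilibrium_distribution(T)
    name = trait_name or ""
    return {
        g: GroupEstimate(name, g, "equilibrium", float(pi[i]), n_contributing)
        for i, g in enumerate(T.groups)
    }


def harmonic_mean_degrees(
    records: list[ParticipantRecord], partition: TraitPartition
) -> DegreeSummary:
    """Harmonic-mean degree per group; degrees < 1 are excluded and counted."""
    inv = {g: 0.0 for g in partition.groups}
    n = {g: 0 for g in partition.groups}
    excl = {g: 0 for g in partition.groups}
    for r in records:
        g = partition.group_of(r.pid)
        if r.degree >= 1:
            inv[g] += 1.0 / r.degree
            n[g] += 1
        else:
            excl[g] += 1
    hm = {}
    for g in partition.groups:
        if n[g] == 0:
            raise InsufficientDataError(
                f"group {g!r} has no member with a valid (>=1) degree"
            )
        hm[g] = n[g] / inv[g]
    total_excluded = sum(excl.values())
    if total_excluded:
        logger.warning(
            "%d record(s) with degree < 1 excluded from degree weighting",
            total_excluded,
        )
    return DegreeSummary(partition.groups, hm, n, excl)


def rds_adjusted_proportion(
    T: TransitionMatrix,
    degrees: DegreeSummary,
    n_contributing: int | None = None,
    trait_name: str | None = None,
) -> dict[str, GroupEstimate]:
    """Degree-corrected equilibrium proportions (the RDS-I estimator)."""
    if tuple(degrees.groups) != tuple(T.groups):
        raise ValueError("degree summary and transition matrix group order differ")
    pi = equilibrium_distribution(T)
    D = degrees.as_array()
    w = pi / D
    P = w / w.sum()
    n = n_contributing if n_contributing is not None else sum(degrees.n.values())
    name = trait_name or ""
    return {
        g: GroupEstimate(name, g, "rds_adjusted", float(P[i]), n)
        for i, g in enumerate(T.groups)
    }


# ---------------------------------------------------------------------------
# Dependent bootstrap
# ---------------------------------------------------------------------------


def _stationary_vectorised(counts: np.ndarray, k: int) -> np.ndarray:
    """Stationary distributions for a batch of count matrices (B, k, k).

    Zero rows get the uniform policy.  k = 2 uses the closed form; larger k
    falls back to a per-replicate linear solve.
    """
    B = counts.shape[0]
    row = counts.sum(axis=2, keepdims=True)
    S = np.where(row > 0, counts / np.where(row > 0, row, 1.0), 1.0 / k)
    if k == 2:
        denom = S[:, 0, 1] + S[:, 1, 0]
        piA = np.where(denom > 0, S[:, 1, 0] / np.where(denom > 0, denom, 1.0), 0.5)
        return np.stack([piA, 1.0 - piA], axis=1)
    out = np.empty((B, k))
    A_bottom = np.ones((1, k))
    b = np.zeros(k + 1)
    b[-1] = 1.0
    eye = np.eye(k)
    for r in range(B):
        A = np.vstack([S[r].T - eye, A_bottom])
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        out[r] = pi / pi.sum()
    return out


def bootstrap_se(
    forest: RecruitmentForest,
    partition: TraitPartition,
    estimator_kind: str = "rds_adjusted",
    B: int = 1000,
    rng_seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Dependent (chain) bootstrap SEs and percentile 95% CIs.

    Each of the ``B`` replicates regrows a pseudo-sample of the original size:
    the first member is drawn uniformly from the observed sample, and each
    subsequent member is drawn uniformly from the pool of observed recruits
    whose recruiter belonged to the current member's group.  If that pool is
    empty the chain restarts from a uniformly chosen observed recruit (logged,
    never silent).  The chosen estimator is then recomputed on each replicate;
    ``se`` is the standard deviation over replicates and ``ci95`` the
    2.5/97.5 percentiles.  Deterministic given ``rng_seed``.
    """
    if B < 2:
        raise InsufficientDataError("bootstrap needs B >= 2 replicates")
    if estimator_kind not in {"crude", "equilibrium", "rds_adjusted"}:
        raise ValueError(f"unknown estimator_kind {estimator_kind!r}")
    if rng is None:
        rng = np.random.default_rng(rng_seed)

    records = forest.records
    n = len(records)
    if n < 2 or not forest.edges():
        raise InsufficientDataError("bootstrap needs a forest with edges")
    groups = partition.groups
    k = len(groups)
    gidx = {g: i for i, g in enumerate(groups)}

    all_groups = np.array([gidx[partition.group_of(r.pid)] for r in records])
    all_degrees = np.array([r.degree for r in records], dtype=float)

    # Pools: recruits indexed by their recruiter's group.
    pool_groups: list[np.ndarray] = []
    pool_degrees: list[np.ndarray] = []
    recruit_rows = []
    pid_to_row = {r.pid: i for i, r in enumerate(records)}
    for a in range(k):
        rows = []
        for rec_pid, kid_pid in forest.edges():
            if gidx[partition.group_of(rec_pid)] == a:
                rows.append(pid_to_row[kid_pid])
        rows = np.array(rows, dtype=int)
        pool_groups.append(all_groups[rows] if rows.size else rows)
        pool_degrees.append(all_degrees[rows] if rows.size else rows.astype(float))
        recruit_rows.extend(rows.tolist())
    recruit_rows = np.array(sorted(set(recruit_rows)), dtype=int)

    # State across the B replicates, advanced one chain step at a time.
    start = rng.integers(0, n, size=B)
    cur_group = all_groups[start]
    cur_deg = all_degrees[start]

    group_counts = np.zeros((B, k))
    trans_counts = np.zeros((B, k, k))
    inv_deg = np.zeros((B, k))
    n_valid = np.zeros((B, k))
    n_restarts = 0

    def _accumulate(gr: np.ndarray, dg: np.ndarray) -> None:
        np.add.at(group_counts, (np.arange(B), gr), 1.0)
        valid = dg >= 1
        np.add.at(inv_deg, (np.arange(B)[valid], gr[valid]), 1.0 / dg[valid])
        np.add.at(n_valid, (np.arange(B)[valid], gr[valid]), 1.0)

    _accumulate(cur_group, cur_deg)
    empty_pool = np.array([pool_groups[a].size == 0 for a in range(k)])
    for _ in range(n - 1):
        nxt_group = np.empty(B, dtype=int)
        nxt_deg = np.empty(B)
        restarted = np.zeros(B, dtype=bool)
        for a in range(k):
            mask = cur_group == a
            m = int(mask.sum())
            if m == 0:
                continue
            if empty_pool[a]:
                rows = recruit_rows[rng.integers(0, recruit_rows.size, size=m)]
                nxt_group[mask] = all_groups[rows]
                nxt_deg[mask] = all_degrees[rows]
                restarted[mask] = True
                n_restarts += m
            else:
                picks = rng.integers(0, pool_groups[a].size, size=m)
                nxt_group[mask] = pool_groups[a][picks]
                nxt_deg[mask] = pool_degrees[a][picks]
        # Restart draws are not recruitments; only true draws count as
        # transitions from the current group.
        real = ~restarted
        if real.any():
            np.add.at(
                trans_counts,
                (np.arange(B)[real], cur_group[real], nxt_group[real]),
                1.0,
            )
        _accumulate(nxt_group, nxt_deg)
        cur_group, cur_deg = nxt_group, nxt_deg
    if n_restarts:
        logger.warning(
            "bootstrap restarted %d chain step(s) on empty recruiter pools",
            n_restarts,
        )

    if estimator_kind == "crude":
        reps = group_counts / n
    else:
        pi = _stationary_vectorised(trans_counts, k)
        if estimator_kind == "equilibrium":
            reps = pi
        else:
            # Harmonic-mean degree per replicate/group; a group unseen in a
            # replicate falls back to the replicate-wide harmonic mean.
            overall = group_counts.sum(axis=1) / np.maximum(
                inv_deg.sum(axis=1), 1e-300
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                D = np.where(n_valid > 0, n_valid / np.where(inv_deg > 0, inv_deg, 1.0),
                             overall[:, None])
            w = pi / D
            reps = w / w.sum(axis=1, keepdims=True)

    se = reps.std(axis=0, ddof=1)
    lo = np.percentile(reps, 2.5, axis=0)
    hi = np.percentile(reps, 97.5, axis=0)
    return BootstrapResult(
        groups=groups,
        se={g: float(se[i]) for i, g in enumerate(groups)},
        ci95={g: (float(lo[i]), float(hi[i])) for i, g in enumerate(groups)},
        replicates=reps,
        n_restarts=n_restarts,
    )


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------


def wald_test(p1: float, se1: float, p2: float, se2: float) -> WaldResult:
    """Two-sided Wald z-test for a difference of two proportions."""
    if se1 <= 0 or se2 <= 0:
        raise UndefinedTestError("Wald test undefined with a zero standard error")
    z = (p1 - p2) / float(np.hypot(se1, se2))
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return WaldResult(z=float(z), p_value=float(p))


def prevalence_ratio(p_early: float, p_late: float, decimals: int = 1) -> float:
    """Ratio of two prevalences, rounded half away from zero.

    Inputs are taken at their shortest decimal representation (``repr``) so
    that ratios of printed one-decimal percentages round exactly as a reader
    would compute them by hand (6.1 / 2.0 = 3.05 -> 3.1), immune to binary
    float noise.
    """
    if p_late == 0:
        raise UndefinedRatioError("prevalence ratio undefined: denominator is zero")
    ratio = Decimal(repr(float(p_early))) / Decimal(repr(float(p_late)))
    q = Decimal(1).scaleb(-decimals)
    return float(ratio.quantize(q, rounding=ROUND_HALF_UP))
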