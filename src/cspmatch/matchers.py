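"""Peak-matching algorithms for assignment transfer between two spectra.

Four algorithms match the free-protein peak list P to the protein:ligand
peak list P', one-to-one, until the shorter list is exhausted:

``sd``  (sorting distances)
    Greedy: repeatedly take the globally smallest remaining entry of the CSP
    distance matrix, emulating how a spectroscopist assigns the least-shifted
    peaks first.
``sds`` (sorting distances, smart)
    Greedy on the score ``|d_ij - avg_csp(i, k)|``: a candidate pair is good
    when its CSP resembles the average CSP of residue i's sequence neighbors,
    exploiting the empirical clustering of CSPs along the sequence.  The
    neighborhood profile is updated after every accepted pair; whole passes
    are iterated to convergence, the first pass seeded with an all-zero
    profile.
``ra``  (resource allocation)
    Minimum-cost bipartite assignment: the matching minimizing the total CSP.
``ras`` (resource allocation, smart)
    Iterated RA where each row i of the distance matrix is rescaled by
    ``1 / avg_csp(i, k)`` between rounds, penalizing assignments that deviate
    from the local CSP level.  Reported CSPs always come from the unscaled
    distances.

A brute-force enumerator over all injections of the shorter list serves as an
independent optimality oracle for small instances.

Everywhere a "smallest" element is selected, exact ties are broken by lowest
reference row index, then lowest target column index (SDS first compares the
raw distance).  All pairings are invariant under a global positive rescaling
of the distance matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

from .csp_core import CspProfile, avg_csp, build_cost_matrix, neighborhood_averages
from .errors import AssignmentsRequiredError, OracleSizeError
from .peaks_io import MatchConfig, Peak, PeakList, drop_unassigned

ALGORITHMS = ("sd", "sds", "ra", "ras", "brute")
SMART_ALGORITHMS = ("sds", "ras")

_BRUTE_MAX = 8


@dataclass(frozen=True)
class MatchedPair:
    """One matched (reference, target) peak pair and its CSP in ppm."""

    ref: Peak
    tgt: Peak
    csp: float


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of one matching run.

    ``pairs`` covers the shorter list exactly once; ``unmatched_ref`` /
    ``unmatched_tgt`` hold the surplus peaks of the longer list (plus, for
    Smart algorithms, any unassigned reference peaks that were neglected).
    Together they partition both input lists.
    """

    pairs: tuple[MatchedPair, ...]
    unmatched_ref: tuple[Peak, ...]
    unmatched_tgt: tuple[Peak, ...]
    algorithm: str
    iterations_used: int = 1
    converged: bool = True

    @property
    def total_cost(self) -> float:
        return float(sum(p.csp for p in self.pairs))

    def pair_ids(self) -> set[tuple[str, str]]:
        return {(p.ref.peak_id, p.tgt.peak_id) for p in self.pairs}

    def csp_profile(self) -> CspProfile:
        """Per-residue CSPs for the assigned reference peaks in the matching."""
        return {
            p.ref.residue_index: p.csp
            for p in self.pairs
            if p.ref.residue_index is not None
        }


# ---------------------------------------------------------------------------
# Matrix-level solvers.  These operate on an abstract nonnegative cost matrix
# and return (pairs, total_cost); the peak-list API wraps them.
# ---------------------------------------------------------------------------

def solve_sd(cost: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Greedy smallest-entry matching (row-then-column tie rule)."""
    work = np.array(cost, dtype=float, copy=True)
    if work.ndim != 2 or work.size == 0:
        raise ValueError("cost matrix must be 2-D and non-empty")
    n, m = work.shape
    pairs: list[tuple[int, int]] = []
    for _ in range(min(n, m)):
        # np.argmin returns the first (row-major) occurrence of the minimum,
        # which is exactly the lowest-row-then-lowest-column tie rule.
        i, j = divmod(int(np.argmin(work)), m)
        pairs.append((i, j))
        work[i, :] = np.inf
        work[:, j] = np.inf
    total = float(sum(cost[i, j] for i, j in pairs))
    return pairs, total


def solve_ra(cost: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Minimum-total-cost one-to-one matching covering the shorter side."""
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.size == 0:
        raise ValueError("cost matrix must be 2-D and non-empty")
    rows, cols = linear_sum_assignment(cost)
    pairs = sorted(zip(rows.tolist(), cols.tolist()))
    total = float(cost[rows, cols].sum())
    return pairs, total


def solve_brute_force(cost: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Exhaustive minimum over all injections of the shorter side into the longer.

    Refuses instances with min(n, m) > 8.  The first injection (in the
    row-then-column lexicographic order) achieving the minimum is returned,
    matching the global tie rule.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.size == 0:
        raise ValueError("cost matrix must be 2-D and non-empty")
    n, m = cost.shape
    if min(n, m) > _BRUTE_MAX:
        raise OracleSizeError(
            f"brute-force oracle limited to {_BRUTE_MAX} peaks on the shorter side"
        )
    best_pairs: list[tuple[int, int]] | None = None
    best_total = np.inf
    if n <= m:
        for cols in itertools.permutations(range(m), n):
            total = float(sum(cost[i, j] for i, j in enumerate(cols)))
            if total < best_total:
                best_total = total
                best_pairs = list(enumerate(cols))
    else:
        for rows in itertools.permutations(range(n), m):
            total = float(sum(cost[i, j] for j, i in enumerate(rows)))
            if total < best_total:
                best_total = total
                best_pairs = sorted((i, j) for j, i in enumerate(rows))
    assert best_pairs is not None
    return best_pairs, best_total


def _sds_pass(
    cost: np.ndarray,
    residue_indices: list[int],
    seed_profile: CspProfile,
    window_k: int,
) -> tuple[list[tuple[int, int]], CspProfile]:
    """One greedy SDS pass; returns the pairing and the end-of-pass profile.

    The profile starts from ``seed_profile`` and is overwritten in place as
    pairs are accepted, so neighborhood averages within the pass mix fresh
    values with the previous pass's.
    """
    n, m = cost.shape
    profile: CspProfile = dict(seed_profile)
    row_active = np.ones(n, dtype=bool)
    col_active = np.ones(m, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for _ in range(min(n, m)):
        averages = np.array(
            [avg_csp(profile, residue_indices[i], window_k) if row_active[i] else 0.0
             for i in range(n)]
        )
        scores = np.abs(cost - averages[:, None])
        scores[~row_active, :] = np.inf
        scores[:, ~col_active] = np.inf
        smin = scores.min()
        ties = np.argwhere(scores == smin)
        # score ties -> smaller raw distance, then lower row, then lower column
        i, j = min(ties, key=lambda rc: (cost[rc[0], rc[1]], rc[0], rc[1]))
        i, j = int(i), int(j)
        pairs.append((i, j))
        profile[residue_indices[i]] = float(cost[i, j])
        row_active[i] = False
        col_active[j] = False
    return sorted(pairs), profile


def solve_sds(
    cost: np.ndarray,
    residue_indices: list[int],
    window_k: int = 7,
    max_iterations: int = 50,
) -> tuple[list[tuple[int, int]], float, int, bool]:
    """Iterated SDS on an explicit cost matrix.

    Returns (pairs, total_cost, passes_used, converged).  Convergence is an
    identical pairing between two consecutive passes; the first pass is seeded
    with an all-zero profile.
    """
    cost = np.asarray(cost, dtype=float)
    seed: CspProfile = {r: 0.0 for r in residue_indices}
    prev: list[tuple[int, int]] | None = None
    converged = False
    pairs: list[tuple[int, int]] = []
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        pairs, final_profile = _sds_pass(cost, residue_indices, seed, window_k)
        if prev is not None and pairs == prev:
            converged = True
            break
        prev = pairs
        seed = final_profile
    total = float(sum(cost[i, j] for i, j in pairs))
    return pairs, total, iterations, converged


def solve_ras(
    cost: np.ndarray,
    residue_indices: list[int],
    window_k: int = 7,
    max_iterations: int = 50,
    epsilon: float = 1e-6,
) -> tuple[list[tuple[int, int]], float, int, bool]:
    """Iterated row-rescaled RA on an explicit cost matrix.

    Round 1 is plain RA.  Each later round rescales row i by
    ``1 / max(avg_csp(i, k), epsilon)`` computed from the previous round's
    CSP profile and re-solves; the loop stops when the pairing is stable.
    The returned total cost is measured on the *unscaled* matrix.
    """
    cost = np.asarray(cost, dtype=float)
    pairs, _ = solve_ra(cost)
    converged = False
    iterations = 1
    for iterations in range(2, max_iterations + 1):
        profile: CspProfile = {
            residue_indices[i]: float(cost[i, j]) for i, j in pairs
        }
        averages = neighborhood_averages(profile, residue_indices, window_k)
        scale = 1.0 / np.maximum(averages, epsilon)
        new_pairs, _ = solve_ra(cost * scale[:, None])
        if set(new_pairs) == set(pairs):
            converged = True
            break
        pairs = new_pairs
    total = float(sum(cost[i, j] for i, j in pairs))
    return sorted(pairs), total, iterations, converged


# ---------------------------------------------------------------------------
# Estimator API
# ---------------------------------------------------------------------------

class PeakMatcher(BaseEstimator):
    """Transfer peak assignments from a reference spectrum to a target spectrum.

    Scikit-learn style estimator: ``fit`` stores the free-protein reference
    peak list, ``predict`` matches a target (protein:ligand) peak list against
    it and returns an :class:`AssignmentResult`.

    Parameters
    ----------
    algorithm : {"sd", "sds", "ra", "ras", "brute"}, default "ras"
        Matching algorithm.  The Smart algorithms ("sds", "ras") require an
        assigned reference list; unassigned reference peaks are neglected.
    het_scale : float, default 5.0
        Weight divisor for the heteronuclear shift difference.
    window_k : int, default 7
        Sequence window width for the neighborhood CSP average.
    max_iterations : int, default 50
        Cap on SDS passes / RAS refinement rounds.
    epsilon : float, default 1e-6
        Floor for neighborhood averages used as RAS divisors.

    Examples
    --------
    >>> matcher = PeakMatcher(algorithm="ra").fit(free_protein)
    >>> result = matcher.predict(ligand_mixture)
    >>> result.total_cost  # doctest: +SKIP
    """

    def __init__(
        self,
        algorithm: str = "ras",
        het_scale: float = 5.0,
        window_k: int = 7,
        max_iterations: int = 50,
        epsilon: float = 1e-6,
    ):
        self.algorithm = algorithm
        self.het_scale = het_scale
        self.window_k = window_k
        self.max_iterations = max_iterations
        self.epsilon = epsilon

    def _config(self) -> MatchConfig:
        return MatchConfig(
            het_scale=self.het_scale,
            window_k=self.window_k,
            max_iterations=self.max_iterations,
            epsilon=self.epsilon,
        )

    def fit(self, X: PeakList, y=None) -> "PeakMatcher":
        """Validate parameters and store the reference peak list."""
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )
        self._config()  # parameter validation
        if not isinstance(X, PeakList):
            raise TypeError("X must be a PeakList (the free-protein reference)")
        if len(X) == 0:
            raise ValueError("reference peak list must be non-empty")
        if self.algorithm in SMART_ALGORITHMS:
            if not any(p.is_assigned for p in X):
                raise AssignmentsRequiredError(
                    f"algorithm {self.algorithm!r} requires residue assignments "
                    "on the reference peak list"
                )
        self.reference_ = X
        return self

    def predict(self, X: PeakList) -> AssignmentResult:
        """Match the target peak list ``X`` against the fitted reference."""
        if not hasattr(self, "reference_"):
            raise AttributeError("PeakMatcher must be fitted before predict()")
        if not isinstance(X, PeakList) or len(X) == 0:
            raise ValueError("X must be a non-empty PeakList (the target spectrum)")
        config = self._config()
        ref = self.reference_
        neglected: tuple[Peak, ...] = ()
        if self.algorithm in SMART_ALGORITHMS:
            assigned = drop_unassigned(ref)
            neglected = tuple(p for p in ref if not p.is_assigned)
            ref = assigned
        cost = build_cost_matrix(ref, X, config)
        residues = [p.residue_index for p in ref]
        iterations, converged = 1, True
        if self.algorithm == "sd":
            pairs, _ = solve_sd(cost)
        elif self.algorithm == "ra":
            pairs, _ = solve_ra(cost)
        elif self.algorithm == "brute":
            pairs, _ = solve_brute_force(cost)
        elif self.algorithm == "sds":
            pairs, _, iterations, converged = solve_sds(
                cost, residues, config.window_k, config.max_iterations
            )
        else:  # ras
            pairs, _, iterations, converged = solve_ras(
                cost, residues, config.window_k, config.max_iterations, config.epsilon
            )
        matched = tuple(
            MatchedPair(ref.peaks[i], X.peaks[j], float(cost[i, j])) for i, j in pairs
        )
        used_rows = {i for i, _ in pairs}
        used_cols = {j for _, j in pairs}
        unmatched_ref = neglected + tuple(
            p for i, p in enumerate(ref.peaks) if i not in used_rows
        )
        unmatched_tgt = tuple(p for j, p in enumerate(X.peaks) if j not in used_cols)
        return AssignmentResult(
            pairs=matched,
            unmatched_ref=unmatched_ref,
            unmatched_tgt=unmatched_tgt,
            algorithm=self.algorithm,
            iterations_used=iterations,
            converged=converged,
        )

    def fit_predict(self, ref: PeakList, tgt: PeakList) -> AssignmentResult:
        return self.fit(ref).predict(tgt)


def _run(algorithm: str, ref: PeakList, tgt: PeakList, config: MatchConfig | None):
    config = config or MatchConfig()
    matcher = PeakMatcher(
        algorithm=algorithm,
        het_scale=config.het_scale,
        window_k=config.window_k,
        max_iterations=config.max_iterations,
        epsilon=config.epsilon,
    )
    return matcher.fit_predict(ref, tgt)


def assign_sd(ref: PeakList, tgt: PeakList, config: MatchConfig | None = None) -> AssignmentResult:
    """Greedy sorting-distances matching."""
    return _run("sd", ref, tgt, config)


def assign_sds(ref: PeakList, tgt: PeakList, config: MatchConfig | None = None) -> AssignmentResult:
    """Smart greedy matching using sequence-neighborhood CSP averages."""
    return _run("sds", ref, tgt, config)


def assign_ra(ref: PeakList, tgt: PeakList, config: MatchConfig | None = None) -> AssignmentResult:
    """Minimum-total-CSP bipartite assignment."""
    return _run("ra", ref, tgt, config)


def assign_ras(ref: PeakList, tgt: PeakList, config: MatchConfig | None = None) -> AssignmentResult:
    """Iterated row-rescaled assignment using neighborhood CSP averages."""
    return _run("ras", ref, tgt, config)


def assign_brute_force(ref: PeakList, tgt: PeakList, config: MatchConfig | None = None) -> AssignmentResult:
    """Exhaustive optimal matching (test oracle; shorter list must have <= 8 peaks)."""
    return _run("brute", ref, tgt, config)
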