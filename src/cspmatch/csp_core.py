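"""The chemical shift perturbation distance, cost matrices, and the
sequence-neighborhood CSP average used by the Smart algorithms.

The CSP of a residue is the weighted Euclidean distance between its peak
positions in the free-protein and protein:ligand spectra::

    CSP = sqrt(dH**2 + (dHet / het_scale)**2)        [ppm]

where ``het_scale`` (default 5.0) compensates for the larger ppm dispersion of
¹⁵N (or ¹³C) relative to ¹H.  No global normalization constant (such as the
1/sqrt(2) prefactor some authors apply) is included: every matching algorithm
in this package is invariant to a global positive rescaling of the distance
matrix, so pairings and accuracies are unaffected, and only the absolute
magnitude of reported CSPs would change.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .errors import IncompatibleSpectraError, InvalidShiftError
from .peaks_io import MatchConfig, PeakList

#: Per-residue CSP values along the sequence (residue index -> ppm).
CspProfile = dict[int, float]


def compute_csp(delta_h: float, delta_het: float, het_scale: float = 5.0) -> float:
    """Weighted peak distance (ppm) for shift differences ``delta_h``, ``delta_het``.

    Symmetric in the sign of both inputs and homogeneous of degree 1.
    """
    if not (math.isfinite(delta_h) and math.isfinite(delta_het)):
        raise InvalidShiftError(
            f"shift differences must be finite, got ({delta_h}, {delta_het})"
        )
    if not (het_scale > 0 and math.isfinite(het_scale)):
        raise ValueError("het_scale must be a positive finite number")
    return math.hypot(delta_h, delta_het / het_scale)


def build_cost_matrix(
    ref: PeakList, tgt: PeakList, config: MatchConfig | None = None
) -> np.ndarray:
    """All-pairs CSP distance matrix between two peak lists.

    Entry ``(i, j)`` is the CSP distance between reference peak ``i`` and
    target peak ``j``.  Both lists must be non-empty and record the same
    heteronucleus.
    """
    config = config or MatchConfig()
    if len(ref) == 0 or len(tgt) == 0:
        raise ValueError("both peak lists must be non-empty")
    if ref.het_nucleus != tgt.het_nucleus:
        raise IncompatibleSpectraError(
            f"reference records {ref.het_nucleus} but target records {tgt.het_nucleus}"
        )
    ref_h = np.array([p.shift_h for p in ref])
    ref_het = np.array([p.shift_het for p in ref])
    tgt_h = np.array([p.shift_h for p in tgt])
    tgt_het = np.array([p.shift_het for p in tgt])
    if not (np.isfinite(ref_h).all() and np.isfinite(tgt_h).all()
            and np.isfinite(ref_het).all() and np.isfinite(tgt_het).all()):
        raise InvalidShiftError("peak lists contain non-finite shifts")
    dh = ref_h[:, None] - tgt_h[None, :]
    dhet = (ref_het[:, None] - tgt_het[None, :]) / config.het_scale
    return np.hypot(dh, dhet)


def avg_csp(profile: Mapping[int, float], residue_index: int, window_k: int = 7) -> float:
    """Average CSP over the sequence window centered at ``residue_index``.

    The window spans ``window_k`` positions centered on the residue; the
    residue itself is excluded so a candidate assignment cannot vote for
    itself.  Positions absent from the profile are skipped; with no informative
    neighbor the average is 0 (which is also the all-zero first-iteration
    seed of the Smart algorithms).
    """
    if window_k < 1:
        raise ValueError("window_k must be >= 1")
    half = window_k // 2
    values = [
        profile[pos]
        for pos in range(residue_index - half, residue_index + half + 1)
        if pos != residue_index and pos in profile
    ]
    if not values:
        return 0.0
    return float(sum(values) / len(values))


def neighborhood_averages(
    profile: Mapping[int, float], residue_indices, window_k: int = 7
) -> np.ndarray:
    """Vector of :func:`avg_csp` values for a sequence of residue indices."""
    return np.array([avg_csp(profile, r, window_k) for r in residue_indices])
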