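"""Accuracy scoring against curated assignments and per-residue CSP export.

Accuracy is the percentage of predicted pairs whose target peak carries the
same curated residue assignment as the matched reference peak — i.e. the
fraction of transferred assignments a human assignment effort would agree
with.  Predicted pairs whose target (or reference) peak carries no curated
assignment cannot be scored and are excluded from the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .csp_core import CspProfile
from .errors import AssignmentsRequiredError
from .matchers import AssignmentResult
from .peaks_io import PeakList


@dataclass(frozen=True)
class Mismatch:
    """A wrongly transferred assignment for one reference residue."""

    residue_index: int | None
    predicted_target_peak: str
    true_target_peak: str | None


@dataclass(frozen=True)
class AccuracyReport:
    n_scored: int
    n_correct: int
    accuracy_pct: float
    mismatches: tuple[Mismatch, ...] = ()
    n_excluded_unlabeled: int = 0

    @property
    def rounded_pct(self) -> int:
        """Integer percentage, half-up, for comparison with published tables."""
        return int(math.floor(self.accuracy_pct + 0.5))


def score_accuracy(
    predicted: AssignmentResult, ref: PeakList, tgt: PeakList
) -> AccuracyReport:
    """Score a predicted matching against the target list's curated assignments.

    A pair is correct iff the curated residue index of the target peak equals
    the residue index of the reference peak it was matched to.  Pairs whose
    target or reference peak is uncurated are excluded from ``n_scored`` and
    counted in ``n_excluded_unlabeled``.
    """
    if not any(p.is_assigned for p in tgt):
        raise AssignmentsRequiredError(
            "accuracy scoring requires curated residue assignments on the target list"
        )
    true_peak_by_residue = {
        p.residue_index: p.peak_id for p in tgt if p.residue_index is not None
    }
    n_scored = 0
    n_correct = 0
    excluded = 0
    mismatches: list[Mismatch] = []
    for pair in predicted.pairs:
        if pair.tgt.residue_index is None or pair.ref.residue_index is None:
            excluded += 1
            continue
        n_scored += 1
        if pair.tgt.residue_index == pair.ref.residue_index:
            n_correct += 1
        else:
            mismatches.append(
                Mismatch(
                    residue_index=pair.ref.residue_index,
                    predicted_target_peak=pair.tgt.peak_id,
                    true_target_peak=true_peak_by_residue.get(pair.ref.residue_index),
                )
            )
    if n_scored == 0:
        raise AssignmentsRequiredError(
            "no predicted pair could be scored: the reference peaks in the "
            "matching carry no assignments"
        )
    return AccuracyReport(
        n_scored=n_scored,
        n_correct=n_correct,
        accuracy_pct=100.0 * n_correct / n_scored,
        mismatches=tuple(mismatches),
        n_excluded_unlabeled=excluded,
    )


def compare_labeled(
    predicted: AssignmentResult, ref: PeakList, tgt: PeakList
) -> AccuracyReport:
    """Labeled-input comparison: accuracy scoring with the mismatch table.

    Identical scoring to :func:`score_accuracy`, but additionally requires the
    reference list to be fully curated (the "input labeled" workflow, where
    both spectra were assigned independently).
    """
    if not any(p.is_assigned for p in ref):
        raise AssignmentsRequiredError(
            "labeled comparison requires residue assignments on the reference list"
        )
    return score_accuracy(predicted, ref, tgt)


def export_csp_profile(
    result: AssignmentResult, ref: PeakList, path: str | Path
) -> None:
    """Write the per-residue CSPs of a matching as csv, sorted by residue.

    Columns: residue_index, residue_label, csp_ppm (full float precision, so
    reading the file back reproduces the profile used for classification).
    """
    if not any(p.is_assigned for p in ref):
        raise AssignmentsRequiredError(
            "per-residue export requires residue assignments on the reference list"
        )
    label_by_residue = {
        p.residue_index: (p.residue_label or str(p.residue_index))
        for p in ref
        if p.residue_index is not None
    }
    rows = [
        {
            "residue_index": res,
            "residue_label": label_by_residue.get(res, str(res)),
            "csp_ppm": repr(csp),
        }
        for res, csp in sorted(result.csp_profile().items())
    ]
    pd.DataFrame(rows, columns=["residue_index", "residue_label", "csp_ppm"]).to_csv(
        path, index=False
    )


def read_csp_profile(path: str | Path) -> CspProfile:
    """Read a per-residue CSP csv back into a profile mapping."""
    # csp_ppm is parsed via float() so repr-written values round-trip exactly
    frame = pd.read_csv(path, dtype={"csp_ppm": str})
    return {
        int(r): float(c) for r, c in zip(frame["residue_index"], frame["csp_ppm"])
    }
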