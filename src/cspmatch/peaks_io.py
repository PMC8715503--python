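"""Peak and peak-list domain types plus csv readers/writers.

A peak list is the output of peak picking on one 2D heteronuclear spectrum
(typically a ¹H–¹⁵N HSQC): one row per resonance, giving the ¹H shift and the
heteronuclear shift in ppm, optionally preceded by a residue assignment label
such as ``G23`` or ``Gly23``.  The csv dialect is deliberately liberal about
header names because peak lists come from many different NMR programs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import (
    DuplicateAssignmentError,
    EmptyAfterFilterError,
    MalformedInputError,
)

HET_NUCLEI = ("N15", "C13")

# Accepted (lower-cased, stripped) header synonyms for each logical column.
_H_COLUMNS = {"w_h", "h", "1h", "h_ppm", "w1", "hn", "proton", "w_1h"}
_HET_COLUMNS = {
    "w_het", "het", "n", "15n", "n15", "n_ppm", "13c", "c13", "c_ppm",
    "w2", "nitrogen", "carbon", "w_15n", "w_13c",
}
_ASSIGN_COLUMNS = {"assignment", "residue", "label", "assign", "res", "residue_label"}

_LABEL_RE = re.compile(r"^([A-Za-z]{0,3})\.?\s*(\d+)$")


def parse_residue_label(label: str) -> int | None:
    """Parse a residue assignment label into a sequence position.

    Accepts ``G23``, ``Gly23`` and bare ``23``; returns ``None`` when the
    label carries no recognizable sequence number.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        return None
    return int(m.group(2))


@dataclass(frozen=True)
class Peak:
    """One resonance: a position in the 2D spectrum, optionally assigned.

    Parameters
    ----------
    peak_id : str
        Opaque identifier, unique within the containing list.
    shift_h : float
        ¹H chemical shift in ppm.
    shift_het : float
        Heteronuclear (¹⁵N or ¹³C) chemical shift in ppm.
    het_nucleus : {"N15", "C13"}
    residue_index : int, optional
        Sequence position (1-based) when the peak is assigned.
    residue_label : str, optional
        Human-readable assignment label, e.g. ``"G23"``.
    """

    peak_id: str
    shift_h: float
    shift_het: float
    het_nucleus: str = "N15"
    residue_index: int | None = None
    residue_label: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.shift_h) and math.isfinite(self.shift_het)):
            raise MalformedInputError(
                f"peak {self.peak_id!r}: chemical shifts must be finite, got "
                f"({self.shift_h}, {self.shift_het})"
            )
        if self.het_nucleus not in HET_NUCLEI:
            raise MalformedInputError(
                f"peak {self.peak_id!r}: het_nucleus must be one of {HET_NUCLEI}"
            )
        if self.residue_index is not None and self.residue_index < 1:
            raise MalformedInputError(
                f"peak {self.peak_id!r}: residue_index must be >= 1"
            )

    @property
    def is_assigned(self) -> bool:
        return self.residue_index is not None


@dataclass(frozen=True)
class PeakList:
    """An ordered collection of peaks from a single spectrum."""

    name: str
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        seen_ids: set[str] = set()
        seen_res: dict[int, str] = {}
        for p in self.peaks:
            if p.peak_id in seen_ids:
                raise DuplicateAssignmentError(
                    f"peak list {self.name!r}: duplicate peak_id {p.peak_id!r}"
                )
            seen_ids.add(p.peak_id)
            if p.residue_index is not None:
                if p.residue_index in seen_res:
                    raise DuplicateAssignmentError(
                        f"peak list {self.name!r}: residue {p.residue_index} assigned "
                        f"to both {seen_res[p.residue_index]!r} and {p.peak_id!r}"
                    )
                seen_res[p.residue_index] = p.peak_id

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    @property
    def is_assigned(self) -> bool:
        """True iff the list is non-empty and every peak carries a residue index."""
        return len(self.peaks) > 0 and all(p.is_assigned for p in self.peaks)

    @property
    def het_nucleus(self) -> str:
        return self.peaks[0].het_nucleus if self.peaks else "N15"

    def residue_indices(self) -> tuple[int, ...]:
        return tuple(p.residue_index for p in self.peaks if p.residue_index is not None)

    def by_id(self, peak_id: str) -> Peak:
        for p in self.peaks:
            if p.peak_id == peak_id:
                return p
        raise KeyError(peak_id)


@dataclass(frozen=True)
class MatchConfig:
    """Parameters shared by all matching algorithms.

    het_scale
        Divisor applied to the heteronuclear shift difference before it is
        combined with the ¹H difference (default 5.0, the conventional
        ¹⁵N weighting).
    window_k
        Width (odd) of the sequence window used by the Smart algorithms'
        neighborhood CSP average; default 7 (the residue ±3 neighbors).
    max_iterations
        Cap on SDS passes / RAS refinement rounds; guarantees termination
        when the stability criterion is never met.
    epsilon
        Floor (ppm) for neighborhood averages used as divisors in RAS.
    """

    het_scale: float = 5.0
    window_k: int = 7
    max_iterations: int = 50
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.het_scale > 0 and math.isfinite(self.het_scale)):
            raise ValueError("het_scale must be a positive finite number")
        if self.window_k < 1 or self.window_k % 2 == 0:
            raise ValueError("window_k must be a positive odd integer")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")


def _resolve_columns(columns: Iterable[str]) -> tuple[str, str, str | None]:
    """Map actual csv headers onto (h, het, assignment) columns."""
    lookup = {str(c).strip().lower(): c for c in columns}
    h_col = next((lookup[c] for c in lookup if c in _H_COLUMNS), None)
    het_col = next((lookup[c] for c in lookup if c in _HET_COLUMNS), None)
    assign_col = next((lookup[c] for c in lookup if c in _ASSIGN_COLUMNS), None)
    if h_col is None or het_col is None:
        raise MalformedInputError(
            "peak list must contain a 1H shift column and a heteronuclear shift "
            f"column (recognized names e.g. 'w_h'/'h' and 'w_het'/'n'); got {sorted(lookup)}"
        )
    return h_col, het_col, assign_col


def read_peaklist_csv(
    path: str | Path,
    het_nucleus: str = "N15",
    name: str | None = None,
) -> PeakList:
    """Read a peak list from a header-bearing csv file.

    One :class:`Peak` is produced per data row, in file order.  When an
    assignment column is present, residue labels are parsed into sequence
    positions; rows with an empty assignment cell stay unassigned.

    Raises
    ------
    MalformedInputError
        On unreadable shift values (the message cites the file row number,
        where the header is row 1).
    DuplicateAssignmentError
        When two rows claim the same residue.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MalformedInputError(f"{path}: cannot parse csv: {exc}") from exc
    if frame.empty:
        raise MalformedInputError(f"{path}: no data rows")
    h_col, het_col, assign_col = _resolve_columns(frame.columns)

    peaks: list[Peak] = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        file_row = pos + 2  # header occupies row 1
        try:
            shift_h = float(row[h_col])
            shift_het = float(row[het_col])
        except (TypeError, ValueError) as exc:
            raise MalformedInputError(
                f"{path}: row {file_row}: unparsable chemical shift "
                f"({row[h_col]!r}, {row[het_col]!r})"
            ) from exc
        if not (math.isfinite(shift_h) and math.isfinite(shift_het)):
            raise MalformedInputError(
                f"{path}: row {file_row}: non-finite chemical shift"
            )
        residue_label = None
        residue_index = None
        if assign_col is not None:
            raw = row[assign_col]
            if isinstance(raw, str) and raw.strip():
                residue_label = raw.strip()
                residue_index = parse_residue_label(residue_label)
        peaks.append(
            Peak(
                peak_id=f"p{pos + 1}",
                shift_h=shift_h,
                shift_het=shift_het,
                het_nucleus=het_nucleus,
                residue_index=residue_index,
                residue_label=residue_label,
            )
        )
    return PeakList(name=name or path.stem, peaks=tuple(peaks))


def write_peaklist_csv(peaklist: PeakList, path: str | Path) -> None:
    """Write a peak list in the canonical dialect (assignment, w_h, w_het)."""
    rows = []
    for p in peaklist:
        rows.append(
            {
                "assignment": p.residue_label or "",
                "w_h": f"{p.shift_h:.4f}",
                "w_het": f"{p.shift_het:.4f}",
            }
        )
    pd.DataFrame(rows, columns=["assignment", "w_h", "w_het"]).to_csv(path, index=False)


def drop_unassigned(peaklist: PeakList) -> PeakList:
    """Return a copy containing only assigned peaks, order preserved.

    The Smart algorithms neglect unassigned reference peaks; this is the
    filter that realizes that rule.  Idempotent.
    """
    kept = tuple(p for p in peaklist if p.is_assigned)
    if not kept:
        raise EmptyAfterFilterError(
            f"peak list {peaklist.name!r}: no assigned peaks remain after filtering"
        )
    return replace(peaklist, peaks=kept)


def write_assignment_csv(result, path: str | Path) -> None:
    """Write matched pairs and unmatched peaks as a csv result table.

    Columns: ref_peak_id, ref_assignment, tgt_peak_id, csp_ppm, status.
    Matched rows come first, then unmatched reference peaks, then unmatched
    target peaks.  CSPs are printed to 4 decimals.
    """
    rows = []
    for pair in result.pairs:
        rows.append(
            {
                "ref_peak_id": pair.ref.peak_id,
                "ref_assignment": pair.ref.residue_label or "",
                "tgt_peak_id": pair.tgt.peak_id,
                "csp_ppm": f"{pair.csp:.4f}",
                "status": "matched",
            }
        )
    for p in result.unmatched_ref:
        rows.append(
            {
                "ref_peak_id": p.peak_id,
                "ref_assignment": p.residue_label or "",
                "tgt_peak_id": "",
                "csp_ppm": "",
                "status": "unmatched_ref",
            }
        )
    for p in result.unmatched_tgt:
        rows.append(
            {
                "ref_peak_id": "",
                "ref_assignment": "",
                "tgt_peak_id": p.peak_id,
                "csp_ppm": "",
                "status": "unmatched_tgt",
            }
        )
    if not rows:
        raise ValueError("cannot write an empty assignment result")
    pd.DataFrame(
        rows, columns=["ref_peak_id", "ref_assignment", "tgt_peak_id", "csp_ppm", "status"]
    ).to_csv(path, index=False)


def read_assignment_csv(path: str | Path) -> pd.DataFrame:
    """Read back an assignment table written by :func:`write_assignment_csv`."""
    frame = pd.read_csv(path, dtype={"ref_peak_id": str, "tgt_peak_id": str, "status": str})
    return frame
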