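"""Crest detection and the four shape descriptors of each Raman band.

A crest (peak) on the background-subtracted difference trace is described by
four numbers:

* ``prominence`` — topographic height of the apex above the higher of the two
  bounding valleys (the valleys are searched up to the nearest strictly
  higher sample on each side, or the trace end);
* ``width`` — horizontal extent, in cm^-1, of the crest at an evaluation line
  drawn a fraction ``rel_height`` of the prominence below the apex, with the
  crossings located by linear interpolation;
* ``width_height`` — the vertical apex-to-line distance,
  ``rel_height * prominence`` (a configuration switch yields the alternative
  absolute-line-height convention instead);
* ``peak_dif`` — signed offset (cm^-1) of the detected apex from the nominal
  reference shift it is matched to.

Detected crests are matched to the seven reference shifts within a tolerance
window; each sample then contributes 7 crests x 4 descriptors = 28 features,
which together with three metadata columns form the N x 31 feature table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import REFERENCE_SHIFTS, RamanSpectrum
from .preprocessing import CorrectedSpectrum

__all__ = [
    "DetectedPeak",
    "CrestFeature",
    "DESCRIPTOR_CODES",
    "feature_column_names",
    "METADATA_COLUMNS",
    "peak_prominence",
    "peak_width",
    "detect_peaks",
    "match_reference_crests",
    "build_feature_table",
    "feature_columns",
]

#: short descriptor codes used in column names and selection tables
DESCRIPTOR_CODES = ("p", "w", "wh", "pd")
METADATA_COLUMNS = ("sample_name", "variety_label", "sample_number")


def feature_column_names(reference_shifts: Sequence[float] = REFERENCE_SHIFTS) -> list[str]:
    """Column names in fixed crest-then-descriptor order, e.g. ``480_p``."""
    return [f"{int(round(s))}_{code}" for s in reference_shifts for code in DESCRIPTOR_CODES]


@dataclass(frozen=True)
class DetectedPeak:
    index: int
    shift: float
    height: float
    prominence: float
    left_base: int
    right_base: int
    width: float
    width_height: float
    left_crossing: float  # cm^-1
    right_crossing: float  # cm^-1


@dataclass(frozen=True)
class CrestFeature:
    """One reference crest's descriptors; unmatched crests are all-zero."""

    reference_shift: float
    prominence: float
    width: float
    width_height: float
    peak_dif: float
    matched: bool

    @classmethod
    def sentinel(cls, reference_shift: float) -> "CrestFeature":
        return cls(reference_shift, 0.0, 0.0, 0.0, 0.0, False)


def peak_prominence(trace: np.ndarray, apex: int) -> tuple[float, int, int]:
    """Topographic prominence of a strict local maximum.

    Each side's search interval runs from the apex to the nearest strictly
    higher sample (exclusive) or to the trace end; the side's base is the
    interval minimum closest to the apex.  Prominence is the apex height
    minus the higher of the two side minima.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if not 0 <= apex < n:
        raise ValueError("apex index out of range")
    h = trace[apex]
    if (apex > 0 and trace[apex - 1] >= h) or (apex < n - 1 and trace[apex + 1] >= h):
        raise ValueError("apex is not a strict local maximum")

    def side_base(step: int) -> int:
        base = apex
        best = h
        i = apex + step
        while 0 <= i < n and trace[i] <= h:
            if trace[i] < best:
                best = trace[i]
                base = i
            i += step
        return base

    left_base = side_base(-1)
    right_base = side_base(+1)
    prominence = h - max(trace[left_base], trace[right_base])
    return float(prominence), left_base, right_base


def peak_width(
    trace: np.ndarray,
    shifts: np.ndarray,
    apex: int,
    prominence: float,
    left_base: int,
    right_base: int,
    rel_height: float = 0.5,
    height_convention: str = "relative",
) -> tuple[float, float, float, float]:
    """Width at an evaluation line ``rel_height * prominence`` below the apex.

    Returns ``(width, width_height, left_crossing, right_crossing)``; the
    crossings are linearly interpolated in index space and mapped onto the
    shift grid, and the width is their distance in cm^-1 (grid-resolution
    independent).  Where the trace never drops below the line inside the
    prominence interval, the base position bounds the crossing (as in the
    standard contract).

    ``height_convention='relative'`` reports the apex-to-line distance;
    ``'absolute'`` reports the evaluation line's absolute intensity.
    """
    if not 0.0 < rel_height <= 1.0:
        raise ValueError("rel_height must lie in (0, 1]")
    if height_convention not in ("relative", "absolute"):
        raise ValueError("height_convention must be 'relative' or 'absolute'")
    trace = np.asarray(trace, dtype=float)
    shifts = np.asarray(shifts, dtype=float)
    eval_height = trace[apex] - rel_height * prominence

    # The line sits at or above both base minima, so a crossing exists on
    # each side within the prominence interval; walk outward to the first
    # sample at or below the line and interpolate.
    def crossing(step: int, base: int) -> float:
        i = apex
        while i != base and trace[i + step] > eval_height:
            i += step
        nxt = i + step if i != base else base
        if i == base or trace[nxt] == trace[i]:
            return float(i)
        frac = (trace[i] - eval_height) / (trace[i] - trace[nxt])
        return i + step * frac

    left_pos = crossing(-1, left_base)
    right_pos = crossing(+1, right_base)

    idx = np.arange(trace.size, dtype=float)
    left_x = float(np.interp(left_pos, idx, shifts))
    right_x = float(np.interp(right_pos, idx, shifts))
    width = right_x - left_x
    if height_convention == "relative":
        width_height = rel_height * prominence
    else:
        width_height = eval_height
    return width, float(width_height), left_x, right_x


def detect_peaks(
    corrected: CorrectedSpectrum,
    min_prominence: float = 10.0,
    rel_height: float = 0.5,
    height_convention: str = "relative",
) -> list[DetectedPeak]:
    """All strict local maxima of the difference trace with prominence >=
    ``min_prominence``, ordered by shift, with widths filled in."""
    trace = np.asarray(corrected.difference, dtype=float)
    shifts = np.asarray(corrected.shifts, dtype=float)
    if trace.size < 3:
        raise ValueError("difference trace must contain at least 3 samples")
    interior = np.arange(1, trace.size - 1)
    apexes = interior[(trace[interior] > trace[interior - 1]) & (trace[interior] > trace[interior + 1])]
    peaks: list[DetectedPeak] = []
    for apex in apexes:
        prom, lb, rb = peak_prominence(trace, int(apex))
        if prom < min_prominence:
            continue
        width, wh, lx, rx = peak_width(
            trace, shifts, int(apex), prom, lb, rb, rel_height, height_convention
        )
        peaks.append(
            DetectedPeak(
                index=int(apex),
                shift=float(shifts[apex]),
                height=float(trace[apex]),
                prominence=prom,
                left_base=lb,
                right_base=rb,
                width=width,
                width_height=wh,
                left_crossing=lx,
                right_crossing=rx,
            )
        )
    return peaks


def match_reference_crests(
    peaks: Sequence[DetectedPeak],
    reference_shifts: Sequence[float] = REFERENCE_SHIFTS,
    tolerance: float = 30.0,
) -> list[CrestFeature]:
    """Assign detected peaks to the reference shifts.

    For each reference shift (ascending) the unassigned peak within
    ±``tolerance`` cm^-1 with the largest prominence wins; prominence ties go
    to the smallest |peak_dif|.  Each peak serves at most one reference;
    references with no candidate get the all-zero sentinel.
    """
    if list(reference_shifts) != sorted(reference_shifts):
        raise ValueError("reference shifts must be sorted ascending")
    assigned: set[int] = set()
    features: list[CrestFeature] = []
    for ref in reference_shifts:
        candidates = [
            (i, p)
            for i, p in enumerate(peaks)
            if i not in assigned and abs(p.shift - ref) <= tolerance
        ]
        if not candidates:
            features.append(CrestFeature.sentinel(ref))
            continue
        i, best = max(candidates, key=lambda ip: (ip[1].prominence, -abs(ip[1].shift - ref)))
        assigned.add(i)
        features.append(
            CrestFeature(
                reference_shift=float(ref),
                prominence=best.prominence,
                width=best.width,
                width_height=best.width_height,
                peak_dif=float(best.shift - ref),
                matched=True,
            )
        )
    return features


def build_feature_table(
    samples: Iterable[tuple[RamanSpectrum, Sequence[CrestFeature]]],
    reference_shifts: Sequence[float] = REFERENCE_SHIFTS,
) -> pd.DataFrame:
    """Assemble the N x 31 feature table (3 metadata + 28 descriptor columns).

    Row order follows the input; column order is fixed crest-then-descriptor
    (``480_p, 480_w, 480_wh, 480_pd, 865_p, ...``).
    """
    names = feature_column_names(reference_shifts)
    rows = []
    for spectrum, crests in samples:
        if len(crests) != len(reference_shifts):
            raise ValueError(
                f"sample {spectrum.sample_name!r}: expected {len(reference_shifts)} "
                f"crest features, got {len(crests)}"
            )
        row: dict[str, object] = {
            "sample_name": spectrum.sample_name,
            "variety_label": spectrum.variety_label,
            "sample_number": spectrum.sample_number,
        }
        for ref, cf in zip(reference_shifts, crests):
            if cf.reference_shift != ref:
                raise ValueError("crest features out of order with reference shifts")
            key = str(int(round(ref)))
            row[f"{key}_p"] = cf.prominence
            row[f"{key}_w"] = cf.width
            row[f"{key}_wh"] = cf.width_height
            row[f"{key}_pd"] = cf.peak_dif
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + names)
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The numeric descriptor columns of a feature table (metadata excluded)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]
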