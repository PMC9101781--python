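"""Biochemical attribution of the seven rice Raman crests.

Each reference shift is assigned to the grain constituent whose vibrational
mode produces it: the starch skeleton and CH2/NH2 stretches (amylum), the
amylopectin ring and C-O-C modes, and the sugar C-O / C-O-H / C-H modes.
Given a feature-selection result, the report lists, per covered crest, the
substance, its vibration mode and the kept descriptor codes, and ranks
substances by how many selected descriptors point at them — the basis for
reading which constituent drives the tolerant/sensitive discrimination.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .crests import DESCRIPTOR_CODES
from .selection import SelectionResult

__all__ = ["AttributionEntry", "ATTRIBUTION", "attribute_features", "rank_substances"]


@dataclass(frozen=True)
class AttributionEntry:
    reference_shift: float
    substances: tuple[str, ...]
    pattern_of_manifestation: str


#: Fixed attribution of the seven reference crests.
ATTRIBUTION: dict[int, AttributionEntry] = {
    480: AttributionEntry(480.0, ("amylum",), "Skeleton vibration"),
    865: AttributionEntry(
        865.0,
        ("amylopectin", "sugar ring"),
        "The vibration of C-H deformation and C-O ring",
    ),
    941: AttributionEntry(941.0, ("amylopectin",), "Symmetric stretching vibration of C-O-C"),
    1129: AttributionEntry(
        1129.0, ("sugar",), "The vibration of C-O stretching and C-O-H bending deformation"
    ),
    1339: AttributionEntry(
        1339.0, ("sugar",), "C-O-H bending and the vibration of C-C stretching"
    ),
    1461: AttributionEntry(1461.0, ("sugar",), "C-H bending vibration in-plane"),
    2910: AttributionEntry(2910.0, ("amylum",), "Stretching vibration of CH2 and NH2"),
}


def lookup(reference_shift: float) -> AttributionEntry:
    key = int(round(reference_shift))
    if key not in ATTRIBUTION:
        raise KeyError(f"no attribution for Raman shift {reference_shift}")
    return ATTRIBUTION[key]


def attribute_features(selection: SelectionResult) -> pd.DataFrame:
    """Table-style attribution report for one selection result.

    One row per covered crest: shift, substance(s), vibration mode, and the
    kept descriptor codes; empty selection gives an empty report.
    """
    rows = []
    for crest, covered in selection.crest_coverage.items():
        if not covered:
            continue
        entry = lookup(float(crest))
        codes = [c for c in DESCRIPTOR_CODES if f"{crest}_{c}" in selection.selected_columns]
        rows.append(
            {
                "Raman Shift/cm-1": int(float(crest)),
                "Spectral Attribution": " / ".join(entry.substances),
                "Pattern of Manifestation": entry.pattern_of_manifestation,
                "Selected Features": "\\".join(codes),
                "n_selected": len(codes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Raman Shift/cm-1",
            "Spectral Attribution",
            "Pattern of Manifestation",
            "Selected Features",
            "n_selected",
        ],
    )


def rank_substances(selection: SelectionResult) -> list[tuple[str, int]]:
    """Substances ordered by the number of selected descriptors on their crests.

    Ties are broken alphabetically; this operationalises "which constituent
    matters most" as a descriptor count over the attribution map.
    """
    counts: Counter[str] = Counter()
    for col in selection.selected_columns:
        crest = col.rsplit("_", 1)[0]
        for substance in lookup(float(crest)).substances:
            counts[substance] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
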