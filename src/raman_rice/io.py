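"""Reading and writing two-column ASCII (PRN) spectra and dataset manifests.

PRN here is the loose ASCII export dialect of desktop Raman spectrometer
software: one "shift intensity" pair per line, whitespace- or
comma-delimited, optionally preceded by non-numeric header lines.  The
reader autodetects the delimiter, skips headers, normalises the shift order
to ascending, and reports format problems with the offending line number.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import RamanSpectrum

__all__ = ["PRNFormatError", "read_prn", "write_prn", "write_dataset", "read_manifest"]


class PRNFormatError(ValueError):
    """A PRN file that cannot be parsed; the message names the line."""


_NUMERIC_LINE = re.compile(r"^\s*[-+0-9.]")


def read_prn(
    path: str | Path,
    variety_label: int = 0,
    sample_number: int = 0,
) -> RamanSpectrum:
    """Parse a two-column ASCII spectrum; the sample name is the file stem.

    The variety label and sample number are not stored in PRN files, so they
    are supplied by the caller (typically from a manifest).
    """
    path = Path(path)
    shifts: list[float] = []
    intensities: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not _NUMERIC_LINE.match(stripped):
                if shifts:
                    raise PRNFormatError(f"{path.name}:{lineno}: non-numeric line in data body")
                continue  # header line
            fields = [f for f in re.split(r"[,\s]+", stripped) if f]
            if len(fields) < 2:
                raise PRNFormatError(f"{path.name}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                shifts.append(float(fields[0]))
                intensities.append(float(fields[1]))
            except ValueError as exc:
                raise PRNFormatError(f"{path.name}:{lineno}: non-numeric value") from exc
    if len(shifts) < 2:
        raise PRNFormatError(f"{path.name}: fewer than 2 data rows")
    s = np.asarray(shifts)
    v = np.asarray(intensities)
    order = np.argsort(s, kind="stable")
    s, v = s[order], v[order]
    if np.any(np.diff(s) == 0):
        dup = float(s[np.nonzero(np.diff(s) == 0)[0][0]])
        raise PRNFormatError(f"{path.name}: duplicate Raman shift {dup}")
    return RamanSpectrum(
        shifts=s,
        intensity=v,
        sample_name=path.stem,
        variety_label=variety_label,
        sample_number=sample_number,
    )


def write_prn(spectrum: RamanSpectrum, path: str | Path) -> Path:
    """Write a spectrum as whitespace-delimited "shift intensity" lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for s, v in zip(spectrum.shifts, spectrum.intensity):
            fh.write(f"{s:.6f} {v:.6f}\n")
    return path


def write_dataset(spectra: list[RamanSpectrum], out_dir: str | Path) -> Path:
    """Write one PRN file per spectrum plus a ``manifest.csv``.

    The manifest records sample_name, variety_label, sample_number and the
    relative path of each PRN file; returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for sp in spectra:
        fname = f"{sp.sample_name}.prn"
        write_prn(sp, out_dir / fname)
        records.append(
            {
                "sample_name": sp.sample_name,
                "variety_label": sp.variety_label,
                "sample_number": sp.sample_number,
                "path": fname,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path: str | Path) -> list[RamanSpectrum]:
    """Load every spectrum listed in a dataset manifest."""
    manifest_path = Path(manifest_path)
    frame = pd.read_csv(manifest_path)
    base = manifest_path.parent
    spectra = []
    for rec in frame.itertuples(index=False):
        sp = read_prn(
            base / rec.path,
            variety_label=int(rec.variety_label),
            sample_number=int(rec.sample_number),
        )
        spectra.append(sp)
    return spectra
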