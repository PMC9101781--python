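"""Synthetic Raman spectra of rice grains.

The real study spectra (156 grains of four rice varieties, two
saline-alkali-tolerant and two sensitive) are not publicly deposited, so this
module emulates their structure: a 200-3400 cm^-1 grid at 1.4 cm^-1
resolution, narrow Raman lines at the seven reference shifts attributed to
starch and sugar bands, a broad smooth fluorescence background that dwarfs the
lines, and additive detector noise.  Tolerant varieties carry stronger amylum
(starch) bands at 480 and 2910 cm^-1, the spectral correlate of their higher
starch-accumulation capacity during grain filling.

Every random draw goes through one explicitly threaded
``numpy.random.Generator``; identical (config, seed) pairs give bit-identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "REFERENCE_SHIFTS",
    "SyntheticConfig",
    "RamanSpectrum",
    "generate_spectrum",
    "generate_dataset",
    "default_config",
    "amylum_only_config",
]

#: The seven reference Raman shifts (cm^-1) of the rice crests, in ascending
#: order: starch skeleton (480), amylopectin/sugar-ring (865), amylopectin
#: C-O-C (941), sugar C-O (1129), sugar C-O-H/C-C (1339), sugar C-H (1461)
#: and the CH2/NH2 stretch of starch (2910).
REFERENCE_SHIFTS: tuple[float, ...] = (480.0, 865.0, 941.0, 1129.0, 1339.0, 1461.0, 2910.0)

# Baseline mean line amplitudes (arbitrary intensity units), one per crest.
_BASE_AMPLITUDES = np.array([120.0, 60.0, 70.0, 55.0, 50.0, 45.0, 110.0])

# Amylum crest indices (480 and 2910 cm^-1) boosted in tolerant varieties.
_AMYLUM_CRESTS = (0, 6)


def _variety_amplitudes(boost: float, crests: Sequence[int] = _AMYLUM_CRESTS) -> tuple[float, ...]:
    amps = _BASE_AMPLITUDES.copy()
    amps[list(crests)] *= 1.0 + boost
    return tuple(amps)


class ConfigurationError(ValueError):
    """Raised when a synthetic-data configuration violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic rice-spectrum generator.

    Defaults mirror the study design: 39 grains for each of four varieties
    (156 spectra), acquisition range 200-3400 cm^-1 at 1.4 cm^-1 steps, and a
    +30% amylum-band boost for the tolerant varieties.
    """

    shift_min: float = 200.0
    shift_max: float = 3400.0
    step: float = 1.4
    reference_shifts: tuple[float, ...] = REFERENCE_SHIFTS
    line_width: float = 25.0  # FWHM, cm^-1
    #: variety name -> per-crest mean line amplitude (same length as
    #: reference_shifts).
    class_amplitudes: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "BD6": _variety_amplitudes(0.30),
            "DF132": _variety_amplitudes(0.25),
            "KD42": _variety_amplitudes(0.0),
            "LD12": _variety_amplitudes(-0.05),
        }
    )
    #: variety name -> binary tolerance label (1 tolerant, 0 sensitive).
    variety_labels: Mapping[str, int] = field(
        default_factory=lambda: {"BD6": 1, "DF132": 1, "KD42": 0, "LD12": 0}
    )
    amplitude_cv: float = 0.10
    #: fluorescence background polynomial c0 + c1*s + c2*s^2 (+ ...), evaluated
    #: on the Raman shift s; large compared with the line amplitudes.
    baseline_coeffs: tuple[float, ...] = (2500.0, -1.2, 1.8e-4)
    noise_sd: float = 5.0
    n_per_class: int = 39
    seed: int = 0
    #: pseudo-Voigt mixing: 0 = pure Gaussian, 1 = pure Lorentzian.
    voigt_eta: float = 0.0

    def __post_init__(self) -> None:
        if not self.shift_min < self.shift_max:
            raise ConfigurationError("shift_min must be < shift_max")
        if self.step <= 0:
            raise ConfigurationError("step must be positive")
        if self.line_width <= 0:
            raise ConfigurationError("line_width must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.amplitude_cv < 0:
            raise ConfigurationError("amplitude_cv must be non-negative")
        if not 0.0 <= self.voigt_eta <= 1.0:
            raise ConfigurationError("voigt_eta must lie in [0, 1]")
        for c in self.reference_shifts:
            if not self.shift_min <= c <= self.shift_max:
                raise ConfigurationError(f"reference shift {c} outside the grid range")
        n_crests = len(self.reference_shifts)
        for name, amps in self.class_amplitudes.items():
            if len(amps) != n_crests:
                raise ConfigurationError(
                    f"class {name!r}: expected {n_crests} amplitudes, got {len(amps)}"
                )
            if any(a < 0 for a in amps):
                raise ConfigurationError(f"class {name!r}: amplitudes must be non-negative")
            if name not in self.variety_labels:
                raise ConfigurationError(f"class {name!r} has no variety label")
        for name, lab in self.variety_labels.items():
            if lab not in (0, 1):
                raise ConfigurationError(f"variety label for {name!r} must be 0 or 1")

    def grid(self) -> np.ndarray:
        """The ascending Raman-shift grid, ``arange(shift_min, shift_max, step)``."""
        return np.arange(self.shift_min, self.shift_max, self.step)


@dataclass(frozen=True)
class RamanSpectrum:
    """One sample's Raman trace: shift grid, raw intensity and metadata."""

    shifts: np.ndarray
    intensity: np.ndarray
    sample_name: str
    variety_label: int  # 1 = saline-alkali-tolerant, 0 = sensitive
    sample_number: int

    def __post_init__(self) -> None:
        shifts = np.asarray(self.shifts, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "shifts", shifts)
        object.__setattr__(self, "intensity", intensity)
        if shifts.ndim != 1 or intensity.shape != shifts.shape:
            raise ValueError("shifts and intensity must be 1-D arrays of equal length")
        if shifts.size >= 2 and not np.all(np.diff(shifts) > 0):
            raise ValueError("shifts must be strictly increasing")
        if self.variety_label not in (0, 1):
            raise ValueError("variety_label must be 0 or 1")


def _line_profile(grid: np.ndarray, center: float, fwhm: float, eta: float) -> np.ndarray:
    """Unit-height pseudo-Voigt profile: eta*Lorentzian + (1-eta)*Gaussian."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gauss = np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    if eta == 0.0:
        return gauss
    gamma = fwhm / 2.0
    lorentz = 1.0 / (1.0 + ((grid - center) / gamma) ** 2)
    return eta * lorentz + (1.0 - eta) * gauss


def generate_spectrum(
    config: SyntheticConfig,
    class_label: str,
    rng: np.random.Generator,
    sample_name: str | None = None,
    sample_number: int = 1,
) -> RamanSpectrum:
    """Draw one synthetic spectrum of the given variety.

    The intensity trace is the fluorescence-background polynomial plus one
    pseudo-Voigt line per reference crest (amplitude drawn per class with
    relative spread ``amplitude_cv``, clipped at zero) plus Gaussian noise.
    """
    if class_label not in config.class_amplitudes:
        raise ConfigurationError(f"unknown class label {class_label!r}")
    grid = config.grid()
    intensity = np.polynomial.polynomial.polyval(grid, config.baseline_coeffs)
    intensity = np.broadcast_to(intensity, grid.shape).astype(float).copy()
    means = np.asarray(config.class_amplitudes[class_label], dtype=float)
    amplitudes = means.copy()
    if config.amplitude_cv > 0:
        amplitudes = rng.normal(means, config.amplitude_cv * means)
        amplitudes = np.clip(amplitudes, 0.0, None)
    for center, amp in zip(config.reference_shifts, amplitudes):
        if amp > 0:
            intensity += amp * _line_profile(grid, center, config.line_width, config.voigt_eta)
    if config.noise_sd > 0:
        intensity += rng.normal(0.0, config.noise_sd, size=grid.size)
    return RamanSpectrum(
        shifts=grid,
        intensity=intensity,
        sample_name=sample_name or class_label,
        variety_label=config.variety_labels[class_label],
        sample_number=sample_number,
    )


def generate_dataset(config: SyntheticConfig) -> list[RamanSpectrum]:
    """Generate ``n_per_class`` spectra per configured variety.

    With the default four varieties and 39 grains each this yields 156
    labelled spectra.  Sample numbering is sequential across the dataset and
    the output is deterministic for a given config (the seed lives in it).
    """
    if config.n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    rng = np.random.default_rng(config.seed)
    spectra: list[RamanSpectrum] = []
    number = 1
    for variety in config.class_amplitudes:
        for i in range(config.n_per_class):
            spectra.append(
                generate_spectrum(
                    config,
                    variety,
                    rng,
                    sample_name=f"{variety}_{i + 1:02d}",
                    sample_number=number,
                )
            )
            number += 1
    return spectra


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The study-design configuration (4 varieties x 39 grains)."""
    return replace(SyntheticConfig(seed=seed), **overrides) if overrides else SyntheticConfig(seed=seed)


def amylum_only_config(
    seed: int = 0,
    boost: float = 0.5,
    n_per_class: int = 39,
    noise_sd: float = 5.0,
) -> SyntheticConfig:
    """A two-variety design whose only class signal sits on the amylum crests.

    Both varieties share the baseline amplitudes on every crest except 480 and
    2910 cm^-1, where the tolerant variety is boosted by ``boost``.  Used for
    parameter-recovery checks: any sound selection or importance ranking must
    point back at the amylum bands.
    """
    return SyntheticConfig(
        class_amplitudes={
            "TOL": _variety_amplitudes(boost),
            "SEN": _variety_amplitudes(0.0),
        },
        variety_labels={"TOL": 1, "SEN": 0},
        n_per_class=n_per_class,
        noise_sd=noise_sd,
        seed=seed,
    )
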