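"""Core data containers shared across the analysis modules.

The containers are plain frozen-ish dataclasses holding numpy arrays plus
the metadata each analysis needs (control intensity, concentration unit,
instrument G factor, ...).  Validation happens at construction time so the
estimators can assume well-formed inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

#: multiplier taking the declared concentration unit to molar
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class TitrationSeries:
    """A quenching titration: ligand concentration vs fluorescence.

    Parameters
    ----------
    quencher_conc
        Ligand (quencher) concentrations, strictly positive, in the unit
        declared by ``unit``.
    F
        Fluorescence intensities at each concentration (arbitrary units).
    F0
        Control intensity without ligand.
    unit
        Concentration unit tag, one of ``M``, ``mM``, ``uM``, ``nM``.
    replicate_id
        Optional replicate label per row; rows sharing a label belong to
        one titration repeat.
    lip_conc
        Optional lipid concentration (mg/mL) for membrane partition fits.
    """

    quencher_conc: np.ndarray
    F: np.ndarray
    F0: float
    unit: str = "uM"
    replicate_id: np.ndarray | None = None
    lip_conc: float | None = None

    def __post_init__(self):
        self.quencher_conc = _as_float_array(self.quencher_conc, "quencher_conc")
        self.F = _as_float_array(self.F, "F")
        if self.quencher_conc.shape != self.F.shape:
            raise ValidationError("quencher_conc and F must have equal length")
        if np.any(self.quencher_conc <= 0):
            raise ValidationError("quencher concentrations must be positive")
        if not np.all(np.isfinite(self.F)) or np.any(self.F <= 0):
            raise ValidationError("fluorescence intensities must be positive")
        if not (np.isfinite(self.F0) and self.F0 > 0):
            raise ValidationError("F0 must be positive")
        if self.unit not in _UNIT_TO_MOLAR:
            raise ValidationError(f"unknown concentration unit {self.unit!r}")
        if self.replicate_id is not None:
            self.replicate_id = np.asarray(self.replicate_id)
            if self.replicate_id.shape != self.F.shape:
                raise ValidationError("replicate_id length mismatch")

    @property
    def conc_molar(self) -> np.ndarray:
        """Concentrations converted to molar."""
        return self.quencher_conc * _UNIT_TO_MOLAR[self.unit]

    def averaged(self) -> "TitrationSeries":
        """Collapse replicates to per-concentration mean intensities."""
        if self.replicate_id is None:
            return self
        conc = np.unique(self.quencher_conc)
        fmean = np.array([self.F[self.quencher_conc == c].mean() for c in conc])
        return TitrationSeries(conc, fmean, self.F0, unit=self.unit,
                               lip_conc=self.lip_conc)

    def replicates(self) -> list["TitrationSeries"]:
        """Split into one series per replicate label."""
        if self.replicate_id is None:
            return [self]
        out = []
        for rid in np.unique(self.replicate_id):
            m = self.replicate_id == rid
            out.append(TitrationSeries(self.quencher_conc[m], self.F[m],
                                       self.F0, unit=self.unit,
                                       lip_conc=self.lip_conc))
        return out


@dataclass(frozen=True)
class PolarizedReading:
    """One polarized fluorescence measurement: (I_par, I_perp, G)."""

    I_par: float
    I_perp: float
    G: float = 1.0

    def __post_init__(self):
        if self.I_par < 0 or self.I_perp < 0:
            raise ValidationError("polarized intensities must be nonnegative")
        if self.G <= 0:
            raise ValidationError("G factor must be positive")


@dataclass(frozen=True)
class AbsorbancePair:
    """Absorbances at the excitation and emission wavelengths."""

    A_ex: float
    A_em: float

    def __post_init__(self):
        if self.A_ex < 0 or self.A_em < 0:
            raise ValidationError("absorbances must be nonnegative")


@dataclass
class EmissionSpectrum:
    """Emission spectrum on a strictly increasing wavelength grid (nm)."""

    wavelength: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.wavelength = _as_float_array(self.wavelength, "wavelength")
        self.intensity = _as_float_array(self.intensity, "intensity")
        if self.wavelength.shape != self.intensity.shape:
            raise ValidationError("wavelength/intensity length mismatch")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValidationError("intensities must be nonnegative")


@dataclass
class Spectrum:
    """Infrared (or generic) spectrum on a strictly increasing abscissa."""

    wavenumber: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.wavenumber = _as_float_array(self.wavenumber, "wavenumber")
        self.absorbance = _as_float_array(self.absorbance, "absorbance")
        if self.wavenumber.shape != self.absorbance.shape:
            raise ValidationError("wavenumber/absorbance length mismatch")
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValidationError("wavenumbers must be strictly increasing")


@dataclass
class PhotonStream:
    """Time-tagged time-resolved photon records.

    Each photon carries a macro-time (seconds since measurement start)
    and a micro-time (nanoseconds since the previous laser pulse).
    """

    macro_times: np.ndarray
    micro_times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.macro_times = _as_float_array(self.macro_times, "macro_times")
        self.micro_times = _as_float_array(self.micro_times, "micro_times")
        if self.macro_times.shape != self.micro_times.shape:
            raise ValidationError("macro/micro time length mismatch")
        if self.macro_times.size and np.any(np.diff(self.macro_times) < 0):
            raise ValidationError("macro_times must be nondecreasing")
        period = self.meta.get("pulse_period_ns")
        if period is not None and self.micro_times.size:
            if self.micro_times.min() < 0 or self.micro_times.max() >= period:
                raise ValidationError("micro_times outside [0, pulse period)")

    @property
    def duration(self) -> float:
        d = self.meta.get("duration")
        if d is not None:
            return float(d)
        return float(self.macro_times[-1]) if self.macro_times.size else 0.0

    def __len__(self) -> int:
        return self.macro_times.size


@dataclass
class CorrelationCurve:
    """Normalized intensity autocorrelation G(tau) on increasing lags."""

    lags: np.ndarray
    G: np.ndarray
    stderr: np.ndarray | None = None

    def __post_init__(self):
        self.lags = _as_float_array(self.lags, "lags")
        self.G = _as_float_array(self.G, "G")
        if self.lags.shape != self.G.shape:
            raise ValidationError("lags and G must have equal length")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValidationError("lags must be positive and strictly increasing")
        if self.stderr is not None:
            self.stderr = _as_float_array(self.stderr, "stderr")
            if self.stderr.shape != self.G.shape:
                raise ValidationError("stderr length mismatch")
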