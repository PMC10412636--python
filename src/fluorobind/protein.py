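"""Protein (HSA) quenching analysis.

Inner-filter correction, Stern-Volmer quenching constants and double-log
binding parameters for ligand titrations against the intrinsic
tryptophan fluorescence of serum albumin:

    F_corr = F_obs * 10^((A_ex + A_em)/2)
    F0/F   = 1 + K_SV [Q],            K_SV = K_q * tau0
    log10((F0 - F)/F) = log10 K_b + n log10 [Q]

Concentrations enter the Stern-Volmer and double-log fits in molar, so
the fitted constants come out in 1/M (and 1/M^n).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError
from .types import AbsorbancePair, EmissionSpectrum, TitrationSeries

#: default unquenched biopolymer fluorescence lifetime (s)
DEFAULT_TAU0 = 5e-9


def correct_inner_filter(F_obs: float, absorbance: AbsorbancePair) -> float:
    """Correct an observed intensity for the inner-filter effect.

    Multiplies by 10^((A_ex + A_em)/2); always >= the observed value.
    Accepts scalars or arrays of intensities.
    """
    F_obs = np.asarray(F_obs, dtype=float)
    if np.any(F_obs <= 0):
        raise ValidationError("observed intensity must be positive")
    out = F_obs * 10.0 ** ((absorbance.A_ex + absorbance.A_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def apply_inner_filter_correction(series: TitrationSeries,
                                  absorbances: list[AbsorbancePair],
                                  control: AbsorbancePair | None = None
                                  ) -> TitrationSeries:
    """Return a titration with every intensity inner-filter corrected.

    ``absorbances`` has one pair per titration point; ``control`` (if
    given) corrects F0 as well.
    """
    if len(absorbances) != len(series.F):
        raise ValidationError("need one absorbance pair per titration point")
    f = np.array([correct_inner_filter(fi, ab)
                  for fi, ab in zip(series.F, absorbances)])
    f0 = correct_inner_filter(series.F0, control) if control else series.F0
    return TitrationSeries(series.quencher_conc, f, f0, unit=series.unit,
                           replicate_id=series.replicate_id,
                           lip_conc=series.lip_conc)


@dataclass
class SternVolmerFit:
    K_SV: float              # 1/M
    K_q: float               # 1/(M s)
    tau0: float              # s
    intercept: float         # fitted freely; 1 under the ideal model
    r_squared: float
    se_K_SV: float


@dataclass
class BindingFit:
    K_b: float               # effective 1/M^n
    n: float                 # binding sites
    r_squared: float
    se_log_Kb: float
    se_n: float
    excluded_points: list = field(default_factory=list)


def fit_stern_volmer(series: TitrationSeries, tau0: float = DEFAULT_TAU0,
                     force_unit_intercept: bool = False) -> SternVolmerFit:
    """Fit the Stern-Volmer constant from a quenching titration.

    OLS of F0/F against [Q] (molar); K_SV is the slope and
    K_q = K_SV / tau0.  The intercept is fitted freely by default — its
    deviation from 1 is a diagnostic of static quenching or calibration
    error; ``force_unit_intercept`` constrains it to 1 instead.
    """
    series = series.averaged()
    if len(series.F) < 3:
        raise InsufficientDataError("need >= 3 titration points")
    q = series.conc_molar
    y = series.F0 / series.F
    if force_unit_intercept:
        slope = float(np.dot(q, y - 1.0) / np.dot(q, q))
        resid = y - 1.0 - slope * q
        dof = max(len(q) - 1, 1)
        se = float(np.sqrt(resid @ resid / dof / (q @ q)))
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        intercept = 1.0
    else:
        res = stats.linregress(q, y)
        slope, intercept, se = res.slope, res.intercept, res.stderr
        r2 = res.rvalue ** 2
    if slope <= 0:
        warnings.warn("non-positive Stern-Volmer slope: no quenching detected",
                      stacklevel=2)
        slope = max(slope, 0.0)
    return SternVolmerFit(K_SV=slope, K_q=slope / tau0, tau0=tau0,
                          intercept=intercept, r_squared=r2, se_K_SV=se)


def fit_binding_double_log(series: TitrationSeries) -> BindingFit:
    """Fit the apparent binding constant and site number (double-log plot).

    OLS of log10((F0 - F)/F) against log10([Q] in molar): the slope is
    the number of binding sites n and 10^intercept the binding constant
    K_b.  Points with F >= F0 carry no binding signal and are excluded
    (reported in ``excluded_points``).
    """
    series = series.averaged()
    usable = series.F < series.F0
    excluded = list(np.nonzero(~usable)[0])
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 points with F < F0, found {int(usable.sum())}")
    q = series.conc_molar[usable]
    f = series.F[usable]
    x = np.log10(q)
    y = np.log10((series.F0 - f) / f)
    res = stats.linregress(x, y)
    return BindingFit(K_b=10.0 ** res.intercept, n=res.slope,
                      r_squared=res.rvalue ** 2,
                      se_log_Kb=res.intercept_stderr, se_n=res.stderr,
                      excluded_points=excluded)


def emission_summary(spectrum: EmissionSpectrum,
                     read_at: float = 345.0) -> tuple[float, float]:
    """Locate the emission maximum and read the intensity at a wavelength.

    Returns ``(lambda_max, F_at_read)``: the argmax refined by 3-point
    parabolic interpolation, and the linearly interpolated intensity at
    ``read_at`` nm.
    """
    wl, inten = spectrum.wavelength, spectrum.intensity
    if not (wl[0] <= read_at <= wl[-1]):
        raise ValidationError("read_at outside the measured wavelength range")
    i = int(np.argmax(inten))
    lam = wl[i]
    if 0 < i < len(wl) - 1:
        y0, y1, y2 = inten[i - 1], inten[i], inten[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # genuine maximum
            lam = wl[i] + 0.5 * (y0 - y2) / denom * (wl[i + 1] - wl[i])
    f_read = float(np.interp(read_at, wl, inten))
    return float(lam), f_read
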