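"""Membrane-probe analysis: anisotropy, percent changes, partition constant.

Steady-state anisotropy A = (I_par - G I_perp) / (I_par + 2 G I_perp)
reports the rotational mobility of a membrane-embedded probe (DPH,
TMA-DPH); lower values mean a more fluid environment.  The
ligand-membrane dissociation constant K_d comes from probe-quenching
titrations via the double-reciprocal regression

    1 / ((F0/F) - 1) = (K_d / L) * (1/[Q]) + 1/L

so K_d = slope / intercept, independent of the lipid concentration L.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (DegenerateInputError, InsufficientDataError,
                         NonPhysicalFitError, ValidationError)
from .types import PolarizedReading, TitrationSeries


def compute_anisotropy(reading: PolarizedReading) -> float:
    """Steady-state fluorescence anisotropy of one polarized reading.

    Returns A in [-0.5, 1.0]; raises :class:`DegenerateInputError` when
    the total intensity I_par + 2 G I_perp vanishes.
    """
    denom = reading.I_par + 2.0 * reading.G * reading.I_perp
    if denom <= 0:
        raise DegenerateInputError("total intensity is zero; anisotropy undefined")
    return (reading.I_par - reading.G * reading.I_perp) / denom


def percent_change(value: float, control: float, direction: str = "decrease") -> float:
    """Percent change of ``value`` relative to ``control``.

    ``direction='decrease'`` returns 100 (control - value)/control (how
    much intensity was lost); ``'increase'`` returns the signed gain
    100 (value - control)/control.
    """
    if control <= 0:
        raise ValidationError("control must be positive")
    if direction == "decrease":
        return 100.0 * (control - value) / control
    if direction == "increase":
        return 100.0 * (value - control) / control
    raise ValidationError("direction must be 'decrease' or 'increase'")


@dataclass
class PartitionFit:
    """Result of the double-reciprocal partition regression."""

    K_d: float               # in the unit of the titration's concentrations
    slope: float
    intercept: float
    r_squared: float
    n_points_used: int
    excluded_points: list = field(default_factory=list)
    se_K_d: float | None = None  # delta-method SE from the fit covariance


def fit_partition(series: TitrationSeries, per_replicate: bool = False):
    """Fit the membrane partition (dissociation) constant K_d.

    Ordinary least squares of y = 1/((F0/F) - 1) against x = 1/[Q] over
    points with F < F0; K_d = slope/intercept in the series'
    concentration unit.  Points with F >= F0 (possible under noise,
    impossible under the model) are excluded and listed in
    ``excluded_points``, never silently dropped.

    With ``per_replicate=True`` and a replicated series, returns a list
    of per-replicate :class:`PartitionFit` objects (for SD estimation);
    otherwise replicates are averaged per concentration first.
    """
    if per_replicate and series.replicate_id is not None:
        return [fit_partition(rep) for rep in series.replicates()]
    series = series.averaged()

    usable = series.F < series.F0
    excluded = list(np.nonzero(~usable)[0])
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 points with F < F0, found {int(usable.sum())}")
    q = series.quencher_conc[usable]
    f = series.F[usable]
    x = 1.0 / q
    y = 1.0 / (series.F0 / f - 1.0)
    res = stats.linregress(x, y)
    if res.intercept <= 0 or res.slope <= 0:
        # slope = K_d/L and intercept = 1/L are both positive under the
        # model; either sign flipping means the data contradict it
        raise NonPhysicalFitError(
            "non-physical double-reciprocal fit (K_d would be <= 0)",
            slope=res.slope, intercept=res.intercept)
    kd = res.slope / res.intercept
    # delta method for K_d = slope/intercept using OLS standard errors
    se = abs(kd) * np.sqrt((res.stderr / res.slope) ** 2
                           + (res.intercept_stderr / res.intercept) ** 2) \
        if res.slope != 0 else None
    return PartitionFit(K_d=kd, slope=res.slope, intercept=res.intercept,
                        r_squared=res.rvalue ** 2,
                        n_points_used=int(usable.sum()),
                        excluded_points=excluded, se_K_d=se)
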