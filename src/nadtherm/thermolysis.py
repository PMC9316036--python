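"""Arrhenius analysis of non-enzymatic pyridine-nucleotide hydrolysis.

Glycohydrolysis of the pyridine glycosidic bond is first order in the
substrate and strongly temperature dependent.  Given a small table of
measured hydrolysis rates (percent substrate lost per minute at a few
incubation temperatures), this module fits the Arrhenius law

    k(T) = A * exp(-Ea / (R * T))

by nonlinear least squares on the rate scale and provides temperature
scaling of any rate constant anchored at a base temperature.

Unit conventions matter here: the activation energy ``Ea`` from a
least-squares fit is invariant under a rescaling of the rate unit, but
the prefactor ``A`` scales linearly with it.  Every fitted parameter set
therefore carries a ``rate_unit`` tag and prefactors must never be
compared across conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import R
from .errors import ConfigurationError, InsufficientDataError, InvalidMeasurementError

__all__ = [
    "RATE_UNIT_DIVISOR",
    "RateMeasurement",
    "ArrheniusParams",
    "ArrheniusFit",
    "convert_rate",
    "arrhenius_rate",
    "arrhenius_scale",
    "rescale_to_base",
    "compute_q10",
    "fit_arrhenius",
    "fit_all_compounds",
]

#: Divisor converting a rate expressed in percent per minute into each unit.
#: percent/min -> fraction/min is /100; -> fraction/s a further /60;
#: -> fraction/ms a further /1000.
RATE_UNIT_DIVISOR = {
    "percent_per_min": 1.0,
    "fraction_per_s": 6000.0,
    "fraction_per_ms": 6.0e6,
}


@dataclass(frozen=True)
class RateMeasurement:
    """One compound x temperature hydrolysis observation.

    Parameters
    ----------
    compound : str
        Pyridine species identifier (NR, NMN, NAD, NAR, NAMN, NAAD).
    temperature : float
        Incubation temperature in kelvin (> 273.15).
    rate : float
        Hydrolysis rate in percent per minute, >= 0.
    rate_sd : float
        Standard deviation of the rate, same unit, >= 0.
    """

    compound: str
    temperature: float
    rate: float
    rate_sd: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate) or self.rate < 0:
            raise InvalidMeasurementError(
                f"{self.compound}: rate must be finite and >= 0, got {self.rate}"
            )
        if self.temperature <= 273.15:
            raise InvalidMeasurementError(
                f"{self.compound}: temperature must exceed 273.15 K, got {self.temperature}"
            )
        if self.rate_sd < 0:
            raise InvalidMeasurementError(f"{self.compound}: rate_sd must be >= 0")


@dataclass(frozen=True)
class ArrheniusParams:
    """Arrhenius prefactor and activation energy for one first-order process.

    ``prefactor_A`` is expressed in the unit recorded in ``rate_unit``;
    ``activation_energy_Ea`` is in kJ/mol and unit-independent.
    """

    prefactor_A: float
    activation_energy_Ea: float
    rate_unit: str = "fraction_per_s"
    gas_constant_R: float = field(default=R, repr=False)

    def k(self, T: float | np.ndarray) -> float | np.ndarray:
        """Rate constant at temperature ``T`` (kelvin), in ``rate_unit``."""
        return arrhenius_rate(self, T)


@dataclass(frozen=True)
class ArrheniusFit:
    """Fit result: parameters plus diagnostics on the fitted rate scale."""

    params: ArrheniusParams
    residuals: np.ndarray
    sse: float
    n_points: int
    weighting: str = "none"
    flag: str | None = None

    @property
    def degenerate(self) -> bool:
        return self.flag == "no detectable hydrolysis"


def convert_rate(rate, unit: str, from_unit: str = "percent_per_min"):
    """Convert a hydrolysis rate between unit conventions.

    The conversion is linear (and therefore invertible for ``rate > 0``):
    percent/min -> fraction/s divides by 6000, -> fraction/ms by 6e6.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise InvalidMeasurementError("hydrolysis rates must be >= 0")
    for tag in (unit, from_unit):
        if tag not in RATE_UNIT_DIVISOR:
            raise ConfigurationError(
                f"unknown rate unit {tag!r}; expected one of {sorted(RATE_UNIT_DIVISOR)}"
            )
    out = rate * (RATE_UNIT_DIVISOR[from_unit] / RATE_UNIT_DIVISOR[unit])
    return float(out) if out.ndim == 0 else out


def arrhenius_rate(params: ArrheniusParams, T):
    """Evaluate ``A * exp(-Ea/(R*T))`` at temperature ``T`` in kelvin.

    ``Ea`` is taken in kJ/mol and converted to J/mol internally.  Strictly
    increasing in ``T`` whenever ``Ea > 0``.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    out = params.prefactor_A * np.exp(
        -params.activation_energy_Ea * 1e3 / (params.gas_constant_R * T)
    )
    return float(out) if out.ndim == 0 else out


def arrhenius_scale(Ea_kJ: float, T, T0: float):
    """Dimensionless Arrhenius factor ``k(T)/k(T0)`` for activation energy
    ``Ea_kJ`` (kJ/mol).  Equals 1 exactly at ``T == T0``."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0) or T0 <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    out = np.exp(-(Ea_kJ * 1e3 / R) * (1.0 / T - 1.0 / T0))
    return float(out) if out.ndim == 0 else out


def rescale_to_base(params: ArrheniusParams, k0: float, T0: float):
    """Return ``k(T) = k0 * exp(-(Ea/R) * (1/T - 1/T0))``.

    Anchors a process with the fitted activation energy to a known rate
    constant ``k0`` at base temperature ``T0``; ``k(T0) == k0`` exactly.
    """
    if k0 <= 0:
        raise ValueError("k0 must be positive")
    Ea = params.activation_energy_Ea

    def k(T):
        return k0 * arrhenius_scale(Ea, T, T0)

    return k


def compute_q10(Ea_kJ: float, T: float) -> float:
    """Factor by which a rate constant with activation energy ``Ea_kJ``
    increases between ``T`` and ``T + 10`` kelvin."""
    return float(arrhenius_scale(Ea_kJ, T + 10.0, T))


def _multistart_fit(T: np.ndarray, k: np.ndarray, sd: np.ndarray | None):
    """Multistart nonlinear least squares of (A, Ea) on the rate scale.

    Internally parameterized as (ln k_ref, Ea) with 1/T centred at the
    harmonic-mean temperature; this decorrelates the two parameters, which
    are otherwise collinear enough to stall the optimizer.  The start grid
    spans Ea = 20..200 kJ/mol; the best-SSE solution is returned.
    """
    scale = float(k.max())
    Tref = 1.0 / np.mean(1.0 / T)
    x = 1.0 / T - 1.0 / Tref
    w = np.ones_like(k) if sd is None else 1.0 / np.where(sd > 0, sd, sd[sd > 0].min())

    def residuals(p):
        lnk, Ea = p
        return w * (np.exp(lnk - (Ea * 1e3 / R) * x) - k) / scale

    best = None
    for Ea0 in np.linspace(20.0, 200.0, 19):
        e = np.exp(-(Ea0 * 1e3 / R) * x)
        kref0 = max(float((e * w**2) @ k / ((e * w) @ (e * w))), scale * 1e-12)
        sol = least_squares(
            residuals,
            x0=[np.log(kref0), Ea0],
            method="lm",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-14,
            max_nfev=2000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    lnk, Ea = best.x
    A = float(np.exp(lnk + Ea * 1e3 / (R * Tref)))
    resid = best.fun * scale / w
    return A, float(Ea), resid


def fit_arrhenius(
    measurements: list[RateMeasurement],
    unit: str = "fraction_per_ms",
    weighting: str = "none",
    scale: str = "rate",
) -> ArrheniusFit:
    """Fit Arrhenius parameters to one compound's hydrolysis series.

    Parameters
    ----------
    measurements
        Observations of a single compound at >= 2 distinct temperatures.
    unit
        Rate unit the fit is performed in (recorded in the result; the
        fitted ``Ea`` is unit-invariant, ``A`` scales with the unit).
    weighting
        ``"none"`` (default) for unweighted least squares on the rate
        scale, including zero-rate points; ``"inverse_variance"`` to
        weight residuals by 1/sd.
    scale
        ``"rate"`` (default) fits on the rate scale; ``"log"`` performs a
        log-linear regression excluding zero rates.  The rate-scale fit is
        the default because the log variant down-weights the fastest,
        best-determined rates and lands far from the rate-scale optimum on
        typical three-point series.

    Returns
    -------
    ArrheniusFit
        Parameters plus residuals and SSE on the fitted scale.  An
        all-zero series returns the degenerate ``A = 0`` result flagged
        ``"no detectable hydrolysis"`` with ``Ea`` undefined (NaN).
    """
    if weighting not in ("none", "inverse_variance"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    if scale not in ("rate", "log"):
        raise ConfigurationError(f"unknown fit scale {scale!r}")
    if unit not in RATE_UNIT_DIVISOR:
        raise ConfigurationError(f"unknown rate unit {unit!r}")

    compounds = {m.compound for m in measurements}
    if len(compounds) > 1:
        raise InvalidMeasurementError(f"mixed compounds in one fit: {sorted(compounds)}")

    T = np.array([m.temperature for m in measurements], dtype=float)
    rate = np.array([m.rate for m in measurements], dtype=float)
    sd = np.array([m.rate_sd for m in measurements], dtype=float)
    if len(np.unique(T)) < 2:
        raise InsufficientDataError("need measurements at >= 2 distinct temperatures")

    k = convert_rate(rate, unit)
    if np.all(k == 0):
        params = ArrheniusParams(0.0, float("nan"), rate_unit=unit)
        return ArrheniusFit(params, np.zeros_like(k), 0.0, len(k),
                            weighting, flag="no detectable hydrolysis")

    sd_k = convert_rate(sd, unit) if weighting == "inverse_variance" else None
    if scale == "log":
        mask = k > 0
        if mask.sum() < 2:
            raise InsufficientDataError("log-scale fit needs >= 2 nonzero rates")
        w = None
        if sd_k is not None:
            # delta method: sd(ln k) = sd_k / k
            w = k[mask] / np.where(sd_k[mask] > 0, sd_k[mask], sd_k[mask].max())
        slope, intercept = np.polyfit(1.0 / T[mask], np.log(k[mask]), 1, w=w)
        A, Ea = float(np.exp(intercept)), float(-slope * R / 1e3)
        resid = np.exp(intercept + slope / T) - k
    else:
        A, Ea, resid = _multistart_fit(T, k, sd_k)

    params = ArrheniusParams(A, Ea, rate_unit=unit)
    return ArrheniusFit(params, resid, float(resid @ resid), len(k), weighting)


def fit_all_compounds(measurements, unit="fraction_per_ms", weighting="none"):
    """Fit each compound in a mixed measurement list; returns a dict
    compound -> ArrheniusFit, in first-appearance order."""
    order: list[str] = []
    groups: dict[str, list[RateMeasurement]] = {}
    for m in measurements:
        groups.setdefault(m.compound, []).append(m)
        if m.compound not in order:
            order.append(m.compound)
    return {c: fit_arrhenius(groups[c], unit=unit, weighting=weighting) for c in order}
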