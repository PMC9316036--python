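"""Metabolic control analysis: concentration control coefficients.

The scaled concentration control coefficient of a rate process p (an
enzyme abundance or a hydrolysis rate constant) over a steady-state
concentration S is

    C^S_p = (p / S) * dS/dp = d ln S / d ln p.

Coefficients are estimated by central finite differences on
multiplicatively perturbed process magnitudes (p -> p * exp(+-h)), with
each coefficient recomputed at half the step and flagged when the two
estimates disagree (a Richardson-style reliability check, substituting
for the closed-form Jacobian algebra that the conserved pyridine moiety
would make singular).

Because every reaction rate is proportional to exactly one process
magnitude (enzymes enter the Michaelis-Menten laws linearly; hydrolysis
constants are the first-order rates themselves), scaling all 14 processes
together rescales time only and leaves the steady state unchanged - so
the coefficients of each species sum to zero over all processes, which
the test suite uses as the summation-theorem oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ENZYMES, SPECIES, EnzymeProfile, NetworkModel
from .steady_state import FastSolver

__all__ = ["ControlMatrix", "control_coefficients", "summation_residual"]

_HYD_IDS = ("hyd_NAD", "hyd_NMN", "hyd_NR", "hyd_NAR", "hyd_NAMN")


@dataclass
class ControlMatrix:
    """Species x process matrix of scaled concentration control coefficients.

    ``reliable`` is False where the half-step re-estimate disagreed with
    the full-step one by more than ``richardson_tol`` (relative) - the
    half-step value is retained but flagged - and where a perturbed steady
    state failed to converge, in which case the entry is NaN.
    """

    coefficients: pd.DataFrame  # index: species, columns: processes
    reliable: pd.DataFrame
    rel_step: float
    richardson_tol: float

    def coefficient(self, species: str, process: str) -> float:
        return float(self.coefficients.loc[species, process])


def _steady_concentrations(solver: FastSolver, E: np.ndarray, kT: np.ndarray,
                           warm: np.ndarray | None):
    y, converged, _fn, _nit = solver.solve(E, y0=warm, kT=kT)
    return solver.concentrations(y), converged, y


def control_coefficients(model: NetworkModel, E, T: float, rel_step: float = 5e-3,
                         richardson_tol: float = 1e-3) -> ControlMatrix:
    """Concentration control coefficients of all 14 rate processes.

    Processes are the nine enzyme abundances plus the five hydrolysis rate
    constants.  ``rel_step`` is the log-perturbation h (each process is
    scaled by exp(+-h)); it must lie in (0, 0.1].  The default step keeps
    the O(h^2) truncation error small enough that the per-species
    summation over all processes closes to well below 1e-4.  Requires an interior
    steady state: species held exactly at zero get zero coefficients, and
    perturbing a zero-magnitude process trivially yields zero control.
    """
    if not 0 < rel_step <= 0.1:
        raise ValueError("rel_step must lie in (0, 0.1]")
    E_arr = (E.abundances if isinstance(E, EnzymeProfile) else np.asarray(E, dtype=float)).copy()
    solver = FastSolver(model, T, tol_rel=1e-12)
    kT0 = solver.kT.copy()
    C0, converged, y0 = _steady_concentrations(solver, E_arr, kT0, None)
    if not converged:
        raise RuntimeError("base steady state did not converge")

    processes = list(ENZYMES) + [p for p in _HYD_IDS if p in model.reaction_ids]
    coef = np.full((len(SPECIES), len(processes)), np.nan)
    ok = np.zeros((len(SPECIES), len(processes)), dtype=bool)

    tiny = 1e-30
    for ip, proc in enumerate(processes):
        estimates = []
        usable = True
        for h in (rel_step, rel_step / 2.0):
            Cs = []
            for sign in (+1.0, -1.0):
                factor = float(np.exp(sign * h))
                E_p, kT_p = E_arr, kT0
                if proc in ENZYMES:
                    if E_arr[ENZYMES.index(proc)] == 0.0:
                        # multiplicative perturbation of a zero magnitude
                        Cs.append(C0)
                        continue
                    E_p = E_arr.copy()
                    E_p[ENZYMES.index(proc)] *= factor
                else:
                    kT_p = kT0.copy()
                    kT_p[model.reaction_index(proc)] *= factor
                C_pert, conv, _ = _steady_concentrations(solver, E_p, kT_p, y0)
                if not conv:
                    usable = False
                    break
                Cs.append(C_pert)
            if not usable:
                break
            with np.errstate(divide="ignore", invalid="ignore"):
                est = (Cs[0] - Cs[1]) / (2.0 * h * np.where(C0 > tiny, C0, np.nan))
            est = np.where(C0 > tiny, est, 0.0)
            estimates.append(est)
        if not usable:
            continue
        full_h, half_h = estimates
        coef[:, ip] = half_h
        disc = np.abs(half_h - full_h) / np.maximum(np.abs(half_h), 1e-6)
        ok[:, ip] = disc < richardson_tol

    coefficients = pd.DataFrame(coef, index=list(SPECIES), columns=processes)
    reliable = pd.DataFrame(ok, index=list(SPECIES), columns=processes)
    return ControlMatrix(coefficients, reliable, rel_step, richardson_tol)


def summation_residual(cm: ControlMatrix) -> pd.Series:
    """Per-species sum of coefficients over all processes (zero in theory)."""
    return cm.coefficients.sum(axis=1)
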