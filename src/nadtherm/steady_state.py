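"""Steady states of the NAD biosynthesis network.

The closed system conserves the pyridine moiety, which makes the full
Jacobian structurally singular.  The solver therefore works on the reduced
system in which Nam is eliminated through the conservation relation
(Nam = total - sum of the other seven species), and the steady state is
found by a damped Newton iteration embedded in pseudo-transient
continuation: each step solves (I/dt - J) d = f, with the pseudo-timestep
dt adapted to the residual decrease so that the iteration degenerates into
plain implicit-Euler time stepping far from the solution and into full
Newton (dt -> infinity) near it.  The inner loop is JIT-compiled.

A reference path integrates the ODEs with a stiff-capable scipy integrator
over geometrically growing horizons before the Newton refinement; the two
routes must agree and are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .network import SPECIES, EnzymeProfile, NetworkModel

__all__ = ["SteadyStateResult", "Trajectory", "integrate", "solve_steady_state", "FastSolver"]


@dataclass
class SteadyStateResult:
    """Converged concentrations, per-reaction fluxes and diagnostics."""

    concentrations: np.ndarray  # mM, SPECIES order
    fluxes: np.ndarray  # mM/s, model reaction order
    species: tuple
    reaction_ids: tuple
    converged: bool
    residual_norm: float  # max |dC/dt| over species, mM/s
    method: str
    t_integrated: float  # integration time reached before refinement, s
    n_iter: int

    def conc(self, species: str) -> float:
        return float(self.concentrations[self.species.index(species)])

    def flux(self, rid: str) -> float:
        return float(self.fluxes[self.reaction_ids.index(rid)])

    @property
    def total(self) -> float:
        return float(self.concentrations.sum())

    def as_dict(self) -> dict:
        return {
            "concentrations_mM": {s: float(c) for s, c in zip(self.species, self.concentrations)},
            "fluxes_mM_per_s": {r: float(v) for r, v in zip(self.reaction_ids, self.fluxes)},
            "converged": bool(self.converged),
            "residual_norm_mM_per_s": float(self.residual_norm),
            "method": self.method,
            "t_integrated_s": float(self.t_integrated),
            "n_iter": int(self.n_iter),
        }


@dataclass
class Trajectory:
    t: np.ndarray  # s
    states: np.ndarray  # (n_times, n_species), mM

    @property
    def totals(self) -> np.ndarray:
        return self.states.sum(axis=1)


# ---------------------------------------------------------------------------
# JIT inner loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def _eval_rhs(N, sub, is_mm, Km, enz, kT, Emm, total, y, C, v, dv, f):
    """Fill C, per-reaction fluxes v, flux derivatives dv and species
    derivatives f for reduced state y; returns the largest |flux|."""
    ns = N.shape[0]
    nr = N.shape[1]
    s = 0.0
    for i in range(ns - 1):
        s += y[i]
    C[0] = total - s
    for i in range(1, ns):
        C[i] = y[i - 1]
    vmax = 0.0
    for j in range(nr):
        S = C[sub[j]]
        if S < 0.0:
            S = 0.0
        if is_mm[j]:
            E = Emm[enz[j]] if enz[j] >= 0 else 0.0
            denom = Km[j] + S
            v[j] = kT[j] * E * S / denom
            dv[j] = kT[j] * E * Km[j] / (denom * denom)
        else:
            v[j] = kT[j] * S
            dv[j] = kT[j]
        av = abs(v[j])
        if av > vmax:
            vmax = av
    for i in range(ns):
        acc = 0.0
        for j in range(nr):
            nij = N[i, j]
            if nij != 0.0:
                acc += nij * v[j]
        f[i] = acc
    return vmax


@njit(cache=True)
def _gauss(A, b, x):
    """Solve A x = b in place (partial pivoting); returns False if singular."""
    n = A.shape[0]
    for col in range(n):
        piv = col
        amax = abs(A[col, col])
        for r in range(col + 1, n):
            if abs(A[r, col]) > amax:
                amax = abs(A[r, col])
                piv = r
        if amax < 1e-300:
            return False
        if piv != col:
            for c in range(n):
                tmp = A[col, c]
                A[col, c] = A[piv, c]
                A[piv, c] = tmp
            tmp = b[col]
            b[col] = b[piv]
            b[piv] = tmp
        inv = 1.0 / A[col, col]
        for r in range(col + 1, n):
            fac = A[r, col] * inv
            if fac != 0.0:
                for c in range(col, n):
                    A[r, c] -= fac * A[col, c]
                b[r] -= fac * b[col]
    for r in range(n - 1, -1, -1):
        acc = b[r]
        for c in range(r + 1, n):
            acc -= A[r, c] * x[c]
        x[r] = acc / A[r, r]
    return True


@njit(cache=True)
def _steady_core(N, sub, is_mm, Km, enz, kT, Emm, total, y0, tol_rel, tol_abs, max_iter):
    """Pseudo-transient Newton on the reduced (Nam-eliminated) system.

    Returns (y, converged, residual_inf_norm, iterations)."""
    ns = N.shape[0]
    m = ns - 1
    nr = N.shape[1]
    y = y0.copy()
    for i in range(m):
        if y[i] < 0.0:
            y[i] = 0.0
    s = 0.0
    for i in range(m):
        s += y[i]
    if s > total:
        sc = total / s
        for i in range(m):
            y[i] *= sc

    C = np.empty(ns)
    v = np.empty(nr)
    dv = np.empty(nr)
    f = np.empty(ns)
    C_t = np.empty(ns)
    v_t = np.empty(nr)
    dv_t = np.empty(nr)
    f_t = np.empty(ns)
    Jfull = np.empty((ns, ns))
    A = np.empty((m, m))
    b = np.empty(m)
    d = np.empty(m)
    ytrial = np.empty(m)

    vmax = _eval_rhs(N, sub, is_mm, Km, enz, kT, Emm, total, y, C, v, dv, f)
    fn = 0.0
    for i in range(1, ns):
        if abs(f[i]) > fn:
            fn = abs(f[i])
    best_y = y.copy()
    best_fn = fn
    # pseudo-timestep started at a tenth of the characteristic turnover time
    dt = 1e2 if vmax <= 0.0 else 0.1 * total / vmax
    nit = 0
    for it in range(max_iter):
        nit = it
        if fn <= tol_abs + tol_rel * vmax:
            return y, True, fn, it
        for i in range(ns):
            for k in range(ns):
                Jfull[i, k] = 0.0
        for j in range(nr):
            k = sub[j]
            for i in range(ns):
                nij = N[i, j]
                if nij != 0.0:
                    Jfull[i, k] += nij * dv[j]
        accepted = False
        for _attempt in range(40):
            for a in range(m):
                for c in range(m):
                    A[a, c] = -(Jfull[a + 1, c + 1] - Jfull[a + 1, 0])
                A[a, a] += 1.0 / dt
                b[a] = f[a + 1]
            if _gauss(A, b, d):
                for a in range(m):
                    yt = y[a] + d[a]
                    if yt < 0.0:
                        yt = 0.0
                    ytrial[a] = yt
                st = 0.0
                for a in range(m):
                    st += ytrial[a]
                if st > total:
                    sc = total / st
                    for a in range(m):
                        ytrial[a] *= sc
                vmax_t = _eval_rhs(N, sub, is_mm, Km, enz, kT, Emm, total,
                                   ytrial, C_t, v_t, dv_t, f_t)
                fn_t = 0.0
                bad = False
                for i in range(1, ns):
                    af = abs(f_t[i])
                    if not np.isfinite(af):
                        bad = True
                        break
                    if af > fn_t:
                        fn_t = af
                if not bad and fn_t <= 1.5 * fn + tol_abs:
                    if fn_t > 0.0:
                        ratio = fn / fn_t
                        if ratio > 1e3:
                            ratio = 1e3
                        elif ratio < 1e-2:
                            ratio = 1e-2
                        dt *= ratio
                        if dt > 1e30:
                            dt = 1e30
                        elif dt < 1e-12:
                            dt = 1e-12
                    else:
                        dt = 1e30
                    for a in range(m):
                        y[a] = ytrial[a]
                    for i in range(ns):
                        f[i] = f_t[i]
                    for j in range(nr):
                        v[j] = v_t[j]
                        dv[j] = dv_t[j]
                    vmax = vmax_t
                    fn = fn_t
                    accepted = True
                    break
            dt *= 0.25
            if dt < 1e-15:
                break
        if not accepted:
            break
        if fn < best_fn:
            best_fn = fn
            for a in range(m):
                best_y[a] = y[a]
    vmax = _eval_rhs(N, sub, is_mm, Km, enz, kT, Emm, total, best_y, C, v, dv, f)
    fn = 0.0
    for i in range(1, ns):
        if abs(f[i]) > fn:
            fn = abs(f[i])
    return best_y, fn <= tol_abs + tol_rel * vmax, fn, nit


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _as_abundances(E) -> np.ndarray:
    return E.abundances if isinstance(E, EnzymeProfile) else np.asarray(E, dtype=float)


class FastSolver:
    """Repeated steady-state solves at one temperature with minimal overhead.

    Precomputes the model arrays and temperature-scaled rate constants once;
    intended for the inner loops of the optimizer and of the control-
    coefficient finite differences, where thousands of solves with warm
    starts are needed.
    """

    def __init__(self, model: NetworkModel, T: float, tol_rel: float = 1e-10,
                 tol_abs: float = 1e-16, max_iter: int = 500):
        self.model = model
        self.T = float(T)
        self.kT = model.k_at(T)
        self.tol_rel = tol_rel
        self.tol_abs = tol_abs
        self.max_iter = max_iter
        self._default_y0 = np.zeros(len(SPECIES) - 1)
        self._default_y0[SPECIES.index("NAD") - 1] = model.pyridine_total

    def solve(self, E_nM: np.ndarray, y0: np.ndarray | None = None,
              kT: np.ndarray | None = None):
        """Returns (y_reduced, converged, residual_norm, iterations)."""
        m = self.model
        return _steady_core(
            m._N, m._sub, m._is_mm, m._Km, m._enz,
            self.kT if kT is None else kT,
            _as_abundances(E_nM) * 1e-6, m.pyridine_total,
            self._default_y0 if y0 is None else np.asarray(y0, dtype=float),
            self.tol_rel, self.tol_abs, self.max_iter,
        )

    def concentrations(self, y: np.ndarray) -> np.ndarray:
        C = np.empty(len(SPECIES))
        C[1:] = y
        C[0] = self.model.pyridine_total - y.sum()
        return C

    def result(self, E_nM, y, converged, fn, nit, method="newton") -> SteadyStateResult:
        C = self.concentrations(y)
        fluxes = self.model.reaction_rates(C, _as_abundances(E_nM), self.T, kT=self.kT)
        return SteadyStateResult(
            concentrations=C, fluxes=fluxes, species=SPECIES,
            reaction_ids=self.model.reaction_ids, converged=bool(converged),
            residual_norm=float(fn), method=method, t_integrated=0.0, n_iter=int(nit),
        )


def _default_initial(model: NetworkModel) -> np.ndarray:
    C0 = np.zeros(len(SPECIES))
    C0[SPECIES.index("NAD")] = model.pyridine_total
    return C0


def integrate(model: NetworkModel, E, T: float, initial=None, t_end: float = 1e6,
              rtol: float = 1e-8, atol: float = 1e-12, method: str = "LSODA",
              t_eval=None) -> Trajectory:
    """Integrate the network ODEs with a stiff-capable scipy integrator.

    The analytic Jacobian is supplied; concentrations are clamped at zero
    inside the rate laws, so trajectories started in the non-negative
    orthant stay there up to integrator tolerance, and the pyridine total
    is conserved by construction of the stoichiometry.
    """
    E_arr = _as_abundances(E)
    C0 = _default_initial(model) if initial is None else np.asarray(initial, dtype=float)
    if np.any(C0 < 0):
        raise ValueError("initial state must be non-negative")
    kT = model.k_at(T)
    N = model._N
    sub, is_mm, Km, enz = model._sub, model._is_mm, model._Km, model._enz
    E_mM = E_arr[np.where(enz >= 0, enz, 0)] * 1e-6
    M = np.zeros((len(sub), N.shape[0]))
    M[np.arange(len(sub)), sub] = 1.0

    def rhs(_t, C):
        S = np.maximum(C[sub], 0.0)
        v = np.where(is_mm, kT * E_mM * S / (Km + S), kT * S)
        return N @ v

    def jac(_t, C):
        S = np.maximum(C[sub], 0.0)
        dv = np.where(is_mm, kT * E_mM * Km / (Km + S) ** 2, kT)
        return N @ (dv[:, None] * M)

    sol = solve_ivp(rhs, (0.0, t_end), C0, method=method, jac=jac,
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1]:.3g}: {sol.message}")
    return Trajectory(t=sol.t, states=sol.y.T)


def solve_steady_state(model: NetworkModel, E, T: float, initial=None,
                       method: str = "hybrid", tol_rel: float = 1e-10,
                       tol_abs: float = 1e-16, t_max: float = 1e6,
                       max_iter: int = 500) -> SteadyStateResult:
    """Steady state for an enzyme profile at temperature ``T``.

    ``method="hybrid"`` (default) integrates over geometrically growing
    horizons until the relative derivative norm falls below ``tol_rel``
    (or the horizon ``t_max`` is exhausted) and then applies Newton
    refinement on the reduced system; ``method="newton"`` starts the
    damped Newton/pseudo-transient iteration directly from ``initial``.
    A non-converged outcome is reported explicitly in the result, never
    silently.
    """
    E_arr = _as_abundances(E)
    C0 = _default_initial(model) if initial is None else np.asarray(initial, dtype=float)
    if np.any(C0 < 0):
        raise ValueError("initial state must be non-negative")
    fast = FastSolver(model, T, tol_rel=tol_rel, tol_abs=tol_abs, max_iter=max_iter)
    t_reached = 0.0
    state = C0.copy()
    if method in ("hybrid", "integrate_newton"):
        kT = fast.kT
        for horizon in 10.0 ** np.arange(1, int(np.ceil(np.log10(max(t_max, 10.0)))) + 1):
            horizon = min(horizon, t_max)
            traj = integrate(model, E_arr, T, initial=state, t_end=horizon - t_reached)
            # integrator tolerance can leave O(atol) negative components
            state = np.maximum(traj.states[-1], 0.0)
            t_reached = horizon
            rhs_now = model.ode_rhs(state, E_arr, T, kT=kT)
            vmax = np.abs(model.reaction_rates(state, E_arr, T, kT=kT)).max()
            if np.abs(rhs_now[1:]).max() <= tol_abs + tol_rel * vmax or horizon >= t_max:
                break
        label = "integrate+newton"
    elif method == "newton":
        label = "newton"
    else:
        raise ValueError(f"unknown method {method!r}")
    y, converged, fn, nit = fast.solve(E_arr, y0=state[1:])
    res = fast.result(E_arr, y, converged, fn, nit, method=label)
    res.t_integrated = t_reached
    return res
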