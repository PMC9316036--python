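"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators, all pure functions of (specification, seed):

* thermolysis rate tables drawn from known Arrhenius parameters with
  multiplicative Gaussian noise truncated at zero, in the same TSV schema
  as the bundled measurement table (three temperatures, small relative
  scatter) - used for parameter-recovery studies of the fitting code;
* enzyme abundance profiles, log-uniform within the allocation bounds and
  rejection-sampled to the total budget - used to probe steady states and
  flux accounting away from optimized corners;
* perturbed model configurations with kcat/Km jittered log-uniformly
  within a fold range - a robustness harness for the parameter-dependent
  qualitative claims (pathway mutual exclusivity, efficiency ordering).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import R
from .errors import ConfigurationError
from .network import ENZYMES, SUBSET_A, validate_config
from .thermolysis import ArrheniusParams

__all__ = ["SyntheticSpec", "gen_rate_table", "gen_enzyme_profiles", "gen_perturbed_configs"]

#: Measurement design of the bundled thermolysis table: 50/75/90 degC.
DEFAULT_TEMPERATURES_K = (323.15, 348.15, 363.15)

#: Typical relative scatter of the bundled table's nonzero rates
#: (sd/mean clusters around a few percent).
DEFAULT_REL_SD = 0.05


@dataclass(frozen=True)
class SyntheticSpec:
    """True Arrhenius parameters per compound plus the measurement design.

    ``true_params`` maps compound name -> ArrheniusParams whose
    ``rate_unit`` must be ``percent_per_min`` (the unit of the emitted
    table).  ``rel_sd`` is the relative SD of the multiplicative Gaussian
    noise, either a scalar or a per-compound mapping.
    """

    true_params: dict
    temperatures_K: tuple = DEFAULT_TEMPERATURES_K
    rel_sd: float | dict = DEFAULT_REL_SD
    seed: int = 0

    def __post_init__(self):
        for name, p in self.true_params.items():
            if p.rate_unit != "percent_per_min":
                raise ConfigurationError(
                    f"{name}: synthetic tables are emitted in percent_per_min; "
                    f"got params in {p.rate_unit!r}"
                )
        sds = (self.rel_sd.values() if isinstance(self.rel_sd, dict) else [self.rel_sd])
        if any(s < 0 for s in sds):
            raise ConfigurationError("relative noise SD must be >= 0")


def gen_rate_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw one noisy rate table in the bundled fixture schema.

    rate = A*exp(-Ea/(R*T)) * (1 + N(0, rel_sd)), truncated at zero (the
    bundled table prints 0.00 for rates below detection).  The sd column
    records rel_sd * true rate.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for compound, params in spec.true_params.items():
        sd_rel = (spec.rel_sd[compound] if isinstance(spec.rel_sd, dict) else spec.rel_sd)
        for T in spec.temperatures_K:
            true = params.prefactor_A * np.exp(
                -params.activation_energy_Ea * 1e3 / (R * T))
            noisy = max(0.0, float(true * (1.0 + sd_rel * rng.standard_normal())))
            rows.append({
                "compound": compound,
                "temperature_C": round(T - 273.15, 2),
                "rate_pct_per_min": noisy,
                "sd_pct_per_min": float(sd_rel * true),
            })
    return pd.DataFrame(rows)


def gen_enzyme_profiles(n: int, bounds_A=(1e-10, 100.0), bounds_B=(0.01, 100.0),
                        budget: float = 1000.0, seed: int = 0) -> np.ndarray:
    """Log-uniform enzyme profiles (nM) within the allocation box,
    rejection-sampled so every profile respects the total budget.

    Returns an (n, 9) array in ``ENZYMES`` order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo = np.full(len(ENZYMES), np.log10(bounds_B[0]))
    hi = np.full(len(ENZYMES), np.log10(bounds_B[1]))
    for e in SUBSET_A:
        lo[ENZYMES.index(e)] = np.log10(bounds_A[0])
        hi[ENZYMES.index(e)] = np.log10(bounds_A[1])
    out = np.empty((n, len(ENZYMES)))
    filled = 0
    while filled < n:
        draw = 10.0 ** rng.uniform(lo, hi, size=(2 * (n - filled), len(ENZYMES)))
        good = draw[draw.sum(axis=1) <= budget]
        take = min(len(good), n - filled)
        out[filled:filled + take] = good[:take]
        filled += take
    return out


def gen_perturbed_configs(base_config: dict, fold_range: float, n: int,
                          seed: int = 0) -> list[dict]:
    """Jitter every enzymatic kcat and Km log-uniformly within the fold range.

    ``fold_range = 1`` returns copies identical to the base.  Each returned
    configuration passes schema validation.
    """
    if fold_range < 1:
        raise ValueError("fold_range must be >= 1")
    validate_config(base_config)
    rng = np.random.default_rng(seed)
    log_f = np.log(fold_range)
    configs = []
    for _ in range(n):
        cfg = copy.deepcopy(base_config)
        for r in cfg["reactions"].values():
            r["kcat"] = float(r["kcat"] * np.exp(rng.uniform(-log_f, log_f)))
            r["Km"] = float(r["Km"] * np.exp(rng.uniform(-log_f, log_f)))
        validate_config(cfg)
        configs.append(cfg)
    return configs
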