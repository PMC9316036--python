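"""The bacterial NAD biosynthesis reaction network and its ODE right-hand side.

Eight pyridine-moiety species (Nam, NA, NR, NAR, NMN, NAMN, NAD, NAAD) are
interconverted by 13 enzyme-catalysed steps carried by 9 enzymes plus 5
non-enzymatic hydrolysis reactions.  The system is closed: every reaction
moves exactly one pyridine moiety, so the summed concentration of the eight
species is a conserved total (0.3 mM by default, the measured free-NAD pool).

Two routes regenerate NAD from the nicotinamide released by NAD-consuming
signalling enzymes (lumped as NCE):

* the two-step route: Nampt (Nam -> NMN, 1 ATP) then NadD (NMN -> NAD, 1 ATP);
* the four-step Preiss-Handler route: PncA (Nam -> NA), PncB (NA -> NAMN,
  1 ATP), NadD (NAMN -> NAAD, 1 ATP) and NadE (NAAD -> NAD, ATP -> AMP,
  counted as 2 ATP equivalents).

Salvage of the ribosides runs through NadR, SurE and PNP.  Enzymatic steps
are irreversible Michaelis-Menten in the pyridine substrate only (ATP, PRPP,
phosphate and ribose cosubstrates are held constant and absorbed into kcat);
hydrolysis is first order.  Every rate constant is Arrhenius-scaled from the
base temperature T0 = 310.65 K with the reaction's activation energy.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .constants import PYRIDINE_TOTAL_DEFAULT, R, T0_DEFAULT
from .errors import ConfigurationError
from .thermolysis import compute_q10 as _q10

__all__ = [
    "SPECIES",
    "ENZYMES",
    "SUBSET_A",
    "SUBSET_B",
    "Reaction",
    "EnzymeProfile",
    "NetworkModel",
    "default_config",
    "validate_config",
    "build_default_model",
    "build_model",
    "reaction_rate",
    "ode_rhs",
    "compute_q10",
]

SPECIES = ("Nam", "NA", "NR", "NAR", "NMN", "NAMN", "NAD", "NAAD")
ENZYMES = ("PncA", "Nampt", "PncB", "NadD", "NadR", "PNP", "NadE", "NCE", "SurE")
#: The two committed entry enzymes whose abundance is allowed to collapse to
#: effectively zero in the allocation problem.
SUBSET_A = ("PncA", "Nampt")
SUBSET_B = tuple(e for e in ENZYMES if e not in SUBSET_A)

_SP_IDX = {s: i for i, s in enumerate(SPECIES)}
_ENZ_IDX = {e: i for i, e in enumerate(ENZYMES)}

#: Hydrolysis products: amidated compounds release Nam, deamidated release NA.
#: NAAD shows no detectable hydrolysis and has no such reaction.
HYDROLYSIS_PRODUCT = {"NAD": "Nam", "NMN": "Nam", "NR": "Nam", "NAR": "NA", "NAMN": "NA"}


@dataclass(frozen=True)
class Reaction:
    """One reaction: a single pyridine substrate converted to a single product.

    ``kcat`` is the turnover number in 1/s at T0 for Michaelis-Menten steps,
    or the first-order hydrolysis constant at T0 (1/s) when ``enzyme`` is
    None.  ``atp_cost`` counts ATP equivalents consumed per turnover (2 for
    NadE, whose ATP -> AMP cleavage takes two phosphorylations to reverse).
    """

    id: str
    substrate: str
    product: str
    enzyme: str | None
    rate_law: str  # "michaelis_menten" | "first_order"
    kcat: float
    Km: float | None
    Ea: float
    atp_cost: int = 0


@dataclass
class EnzymeProfile:
    """Abundances (nM) of the nine enzymes, in ``ENZYMES`` order."""

    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(ENZYMES),):
            raise ConfigurationError(
                f"enzyme profile must have {len(ENZYMES)} entries in order {ENZYMES}"
            )
        if np.any(self.abundances < 0):
            raise ConfigurationError("enzyme abundances must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "EnzymeProfile":
        unknown = set(d) - set(ENZYMES)
        if unknown:
            raise ConfigurationError(f"unknown enzymes: {sorted(unknown)}")
        return cls(np.array([float(d.get(e, 0.0)) for e in ENZYMES]))

    @classmethod
    def uniform(cls, abundance_nM: float = 100.0) -> "EnzymeProfile":
        return cls(np.full(len(ENZYMES), float(abundance_nM)))

    def as_dict(self) -> dict:
        return {e: float(a) for e, a in zip(ENZYMES, self.abundances)}

    def __getitem__(self, enzyme: str) -> float:
        return float(self.abundances[_ENZ_IDX[enzyme]])

    @property
    def total(self) -> float:
        return float(self.abundances.sum())


_DEFAULT_ENZYMATIC = {
    # kcat 1/s at T0, Km mM, Ea kJ/mol, atp ATP equivalents per turnover.
    # Values sit in the documented default bands kcat in [1, 50] 1/s and
    # Km in [0.005, 1] mM; Ea = 65 kJ/mol puts every Q10 near 2.2 at T0.
    "PncA":      dict(substrate="Nam",  product="NA",   enzyme="PncA",  kcat=10.0, Km=0.05, Ea=65.0, atp_cost=0),
    "Nampt":     dict(substrate="Nam",  product="NMN",  enzyme="Nampt", kcat=5.0,  Km=0.01, Ea=65.0, atp_cost=1),
    "PncB":      dict(substrate="NA",   product="NAMN", enzyme="PncB",  kcat=10.0, Km=0.02, Ea=65.0, atp_cost=1),
    "NadD_NMN":  dict(substrate="NMN",  product="NAD",  enzyme="NadD",  kcat=20.0, Km=0.05, Ea=65.0, atp_cost=1),
    "NadD_NAMN": dict(substrate="NAMN", product="NAAD", enzyme="NadD",  kcat=20.0, Km=0.05, Ea=65.0, atp_cost=1),
    "NadE":      dict(substrate="NAAD", product="NAD",  enzyme="NadE",  kcat=10.0, Km=0.02, Ea=65.0, atp_cost=2),
    "NadR_NR":   dict(substrate="NR",   product="NMN",  enzyme="NadR",  kcat=15.0, Km=0.05, Ea=65.0, atp_cost=1),
    "NadR_NAR":  dict(substrate="NAR",  product="NAMN", enzyme="NadR",  kcat=15.0, Km=0.05, Ea=65.0, atp_cost=1),
    "SurE_NMN":  dict(substrate="NMN",  product="NR",   enzyme="SurE",  kcat=5.0,  Km=0.10, Ea=65.0, atp_cost=0),
    "SurE_NAMN": dict(substrate="NAMN", product="NAR",  enzyme="SurE",  kcat=5.0,  Km=0.10, Ea=65.0, atp_cost=0),
    "PNP_NR":    dict(substrate="NR",   product="Nam",  enzyme="PNP",   kcat=10.0, Km=0.10, Ea=65.0, atp_cost=0),
    "PNP_NAR":   dict(substrate="NAR",  product="NA",   enzyme="PNP",   kcat=10.0, Km=0.10, Ea=65.0, atp_cost=0),
    "NCE":       dict(substrate="NAD",  product="Nam",  enzyme="NCE",   kcat=30.0, Km=0.10, Ea=65.0, atp_cost=0),
}


def default_config() -> dict:
    """A fresh copy of the bundled default model configuration.

    ``hydrolysis: "fitted"`` means the five hydrolysis reactions take their
    rate constant at T0 and activation energy from the Arrhenius fits to the
    bundled thermolysis measurement table.  Explicit values may be supplied
    instead as ``{compound: {"k0_per_s": ..., "Ea": ...}}``.
    """
    return {
        "pyridine_total_mM": PYRIDINE_TOTAL_DEFAULT,
        "base_temperature_K": T0_DEFAULT,
        "reactions": copy.deepcopy(_DEFAULT_ENZYMATIC),
        "hydrolysis": "fitted",
    }


@lru_cache(maxsize=1)
def _fitted_hydrolysis_params() -> dict:
    """Hydrolysis (k0 at T0 in 1/s, Ea kJ/mol) from the bundled rate table."""
    from .io import fixture_path, read_rate_table, to_measurements
    from .thermolysis import arrhenius_rate, fit_all_compounds

    meas = to_measurements(read_rate_table(fixture_path()))
    fits = fit_all_compounds(meas, unit="fraction_per_s")
    out = {}
    for compound, fit in fits.items():
        out[compound] = {
            "k0_per_s": float(arrhenius_rate(fit.params, T0_DEFAULT)),
            "Ea": float(fit.params.activation_energy_Ea),
        }
    return out


_REQUIRED_RXN_KEYS = {"substrate", "product", "enzyme", "kcat", "Km", "Ea", "atp_cost"}


def validate_config(config: dict) -> None:
    """Schema check; raises ConfigurationError naming the offending entry."""
    for key in ("pyridine_total_mM", "base_temperature_K", "reactions", "hydrolysis"):
        if key not in config:
            raise ConfigurationError(f"model config missing key {key!r}")
    if config["pyridine_total_mM"] <= 0:
        raise ConfigurationError("pyridine_total_mM must be positive")
    if config["base_temperature_K"] <= 0:
        raise ConfigurationError("base_temperature_K must be positive")
    for rid, r in config["reactions"].items():
        missing = _REQUIRED_RXN_KEYS - set(r)
        if missing:
            raise ConfigurationError(f"reaction {rid!r} missing fields {sorted(missing)}")
        for side in ("substrate", "product"):
            if r[side] not in SPECIES:
                raise ConfigurationError(f"reaction {rid!r}: unknown species {r[side]!r}")
        if r["enzyme"] not in ENZYMES:
            raise ConfigurationError(f"reaction {rid!r}: unknown enzyme {r['enzyme']!r}")
        if r["kcat"] < 0 or r["Km"] <= 0 or r["Ea"] < 0:
            raise ConfigurationError(f"reaction {rid!r}: kcat/Km/Ea out of range")
        if r["atp_cost"] not in (0, 1, 2):
            raise ConfigurationError(f"reaction {rid!r}: atp_cost must be 0, 1 or 2")
    hyd = config["hydrolysis"]
    if hyd != "fitted":
        if not isinstance(hyd, dict):
            raise ConfigurationError("hydrolysis must be 'fitted' or a mapping")
        for compound, h in hyd.items():
            if compound not in HYDROLYSIS_PRODUCT:
                raise ConfigurationError(
                    f"hydrolysis declared for {compound!r}; allowed: "
                    f"{sorted(HYDROLYSIS_PRODUCT)} (NAAD shows no detectable hydrolysis)"
                )
            if "k0_per_s" not in h or "Ea" not in h:
                raise ConfigurationError(f"hydrolysis {compound!r} needs k0_per_s and Ea")
            if h["k0_per_s"] < 0 or h["Ea"] < 0:
                raise ConfigurationError(f"hydrolysis {compound!r}: negative k0 or Ea")


class NetworkModel:
    """The reaction network with precomputed numeric arrays.

    Attributes with a leading underscore are flat numpy views used by the
    steady-state solver: ``_N`` (species x reactions stoichiometry),
    ``_sub`` (substrate index per reaction), ``_is_mm``, ``_k0``, ``_Km``,
    ``_Ea``, ``_enz`` (enzyme index, -1 for hydrolysis) and ``_atp``.
    """

    def __init__(self, reactions: list[Reaction], pyridine_total: float = PYRIDINE_TOTAL_DEFAULT,
                 T0: float = T0_DEFAULT):
        self.reactions = list(reactions)
        self.pyridine_total = float(pyridine_total)
        self.T0 = float(T0)
        nr = len(self.reactions)
        self._N = np.zeros((len(SPECIES), nr))
        self._sub = np.empty(nr, dtype=np.int64)
        self._is_mm = np.empty(nr, dtype=np.bool_)
        self._k0 = np.empty(nr)
        self._Km = np.ones(nr)
        self._Ea = np.empty(nr)
        self._enz = np.full(nr, -1, dtype=np.int64)
        self._atp = np.zeros(nr)
        for j, r in enumerate(self.reactions):
            self._N[_SP_IDX[r.substrate], j] = -1.0
            self._N[_SP_IDX[r.product], j] = 1.0
            self._sub[j] = _SP_IDX[r.substrate]
            self._is_mm[j] = r.rate_law == "michaelis_menten"
            self._k0[j] = r.kcat
            if r.Km is not None:
                self._Km[j] = r.Km
            self._Ea[j] = r.Ea
            if r.enzyme is not None:
                self._enz[j] = _ENZ_IDX[r.enzyme]
            self._atp[j] = r.atp_cost
        self.reaction_ids = tuple(r.id for r in self.reactions)
        self._rxn_idx = {r.id: j for j, r in enumerate(self.reactions)}

    # -- structural queries -------------------------------------------------
    @property
    def stoichiometry(self) -> np.ndarray:
        return self._N.copy()

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_idx[rid]]

    def reaction_index(self, rid: str) -> int:
        return self._rxn_idx[rid]

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    # -- kinetics -----------------------------------------------------------
    def k_at(self, T: float) -> np.ndarray:
        """Per-reaction rate constants at temperature ``T``, Arrhenius-scaled
        from T0 (kcat in 1/s for enzymatic steps, k_hyd in 1/s otherwise)."""
        if T <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        return self._k0 * np.exp(-(self._Ea * 1e3 / R) * (1.0 / T - 1.0 / self.T0))

    def reaction_rates(self, state, E: EnzymeProfile | np.ndarray, T: float,
                       kT: np.ndarray | None = None) -> np.ndarray:
        """Flux of every reaction (mM/s) at concentrations ``state`` (mM).

        Michaelis-Menten: v = kcat(T) * E * S / (Km + S), with the enzyme
        abundance converted nM -> mM; first order: v = k_hyd(T) * S.
        Concentrations are clamped at zero so that trajectories grazing the
        orthant boundary never produce outward flux.
        """
        C = np.asarray(state, dtype=float)
        if C.shape != (len(SPECIES),):
            raise ValueError(f"state must have {len(SPECIES)} entries in order {SPECIES}")
        E_arr = E.abundances if isinstance(E, EnzymeProfile) else np.asarray(E, dtype=float)
        if kT is None:
            kT = self.k_at(T)
        S = np.maximum(C[self._sub], 0.0)
        E_mM = E_arr[np.where(self._enz >= 0, self._enz, 0)] * 1e-6
        return np.where(self._is_mm, kT * E_mM * S / (self._Km + S), kT * S)

    def ode_rhs(self, state, E, T: float, kT: np.ndarray | None = None) -> np.ndarray:
        """Time derivatives dC/dt (mM/s); sums to zero across species."""
        return self._N @ self.reaction_rates(state, E, T, kT=kT)

    def q10(self, rid: str, T: float | None = None) -> float:
        """k(T+10)/k(T) for one reaction from its activation energy."""
        return _q10(self.reaction(rid).Ea, self.T0 if T is None else T)


def build_model(config: dict) -> NetworkModel:
    """Construct a NetworkModel from a validated configuration mapping."""
    validate_config(config)
    reactions = [
        Reaction(id=rid, substrate=r["substrate"], product=r["product"], enzyme=r["enzyme"],
                 rate_law="michaelis_menten", kcat=float(r["kcat"]), Km=float(r["Km"]),
                 Ea=float(r["Ea"]), atp_cost=int(r["atp_cost"]))
        for rid, r in config["reactions"].items()
    ]
    hyd = config["hydrolysis"]
    if hyd == "fitted":
        hyd = _fitted_hydrolysis_params()
    for compound, h in hyd.items():
        reactions.append(
            Reaction(id=f"hyd_{compound}", substrate=compound,
                     product=HYDROLYSIS_PRODUCT[compound], enzyme=None,
                     rate_law="first_order", kcat=float(h["k0_per_s"]), Km=None,
                     Ea=float(h["Ea"]), atp_cost=0)
        )
    return NetworkModel(reactions, pyridine_total=float(config["pyridine_total_mM"]),
                        T0=float(config["base_temperature_K"]))


def build_default_model(config: dict | None = None) -> NetworkModel:
    """The bundled default network (13 enzymatic + 5 hydrolysis reactions).

    ``config`` may override any subset of the default configuration; keys it
    omits fall back to the documented defaults.
    """
    base = default_config()
    if config:
        for key, value in config.items():
            if key == "reactions":
                for rid, r in value.items():
                    base["reactions"].setdefault(rid, {}).update(r)
            else:
                base[key] = value
    return build_model(base)


# -- thin functional wrappers over the model methods -------------------------

def reaction_rate(model: NetworkModel, rid: str, state, E, T: float) -> float:
    """Flux (mM/s) of a single named reaction."""
    return float(model.reaction_rates(state, E, T)[model.reaction_index(rid)])


def ode_rhs(state, E, T: float, model: NetworkModel) -> np.ndarray:
    return model.ode_rhs(state, E, T)


def compute_q10(model: NetworkModel, rid: str, T: float | None = None) -> float:
    return model.q10(rid, T)
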