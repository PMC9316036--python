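"""ATP-cost accounting of NAD biosynthesis at steady state.

ATP is consumed by Nampt, PncB, NadD (both branches) and NadR (both
branches) at one equivalent per turnover, and by NadE at two equivalents
(its ATP -> AMP cleavage takes two phosphorylations to reverse):

    J_ATP = J_Nampt + J_PncB + 2*J_NadE + J_NadD + J_NadR

NAD is produced by NadE (four-step route) and by the NMN-adenylylation
branch of NadD (two-step route):

    J_NAD = J_NadE + J_NadD,NMN

Note the asymmetry: both NadD branches consume ATP, but only the NMN
branch produces NAD (the NAMN branch produces NAAD).  The energy demand
of a pathway configuration is the ratio J_ATP / J_NAD, i.e. ATP
equivalents spent per NAD made.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import NotConvergedError
from .steady_state import SteadyStateResult

__all__ = ["EnergyAccount", "atp_flux", "nad_flux", "efficiency", "account"]

#: Reactions consuming one ATP equivalent per turnover.
_ONE_ATP = ("Nampt", "PncB", "NadD_NMN", "NadD_NAMN", "NadR_NR", "NadR_NAR")


@dataclass(frozen=True)
class EnergyAccount:
    """Named steady-state fluxes (mM/s) entering the ATP/NAD balance.

    ``j_nadd_nmn`` and ``j_nadd_namn`` are kept separate because the two
    NadD branches enter the accounting asymmetrically (see module docs).
    """

    j_nampt: float
    j_pncb: float
    j_nade: float
    j_nadd_nmn: float
    j_nadd_namn: float
    j_nadr: float
    j_atp: float
    j_nad: float

    @property
    def ratio(self) -> float:
        """ATP equivalents consumed per NAD produced; requires J_NAD > 0."""
        if self.j_nad <= 0:
            raise ZeroDivisionError("efficiency undefined: J_NAD is zero")
        return self.j_atp / self.j_nad


def _require_converged(result: SteadyStateResult) -> None:
    if not result.converged:
        raise NotConvergedError(
            "energy accounting requires a converged steady state "
            f"(residual {result.residual_norm:.3g} mM/s)"
        )


def account(result: SteadyStateResult) -> EnergyAccount:
    """Build the full energy account from a converged steady state."""
    _require_converged(result)
    j = {rid: result.flux(rid) for rid in
         ("Nampt", "PncB", "NadE", "NadD_NMN", "NadD_NAMN", "NadR_NR", "NadR_NAR")}
    j_nadr = j["NadR_NR"] + j["NadR_NAR"]
    j_atp = sum(result.flux(r) for r in _ONE_ATP) + 2.0 * j["NadE"]
    j_nad = j["NadE"] + j["NadD_NMN"]
    return EnergyAccount(
        j_nampt=j["Nampt"], j_pncb=j["PncB"], j_nade=j["NadE"],
        j_nadd_nmn=j["NadD_NMN"], j_nadd_namn=j["NadD_NAMN"], j_nadr=j_nadr,
        j_atp=j_atp, j_nad=j_nad,
    )


def atp_flux(result: SteadyStateResult) -> float:
    """Total flux of ATP-consuming reactions, mM/s."""
    return account(result).j_atp


def nad_flux(result: SteadyStateResult) -> float:
    """Total NAD production flux (NadE plus NadD acting on NMN), mM/s."""
    return account(result).j_nad


def efficiency(result: SteadyStateResult) -> float:
    """J_ATP / J_NAD; raises if J_NAD is zero."""
    return account(result).ratio
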