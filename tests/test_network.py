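"""Network structure, rate laws, conservation and temperature scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nadtherm.errors import ConfigurationError
from nadtherm.network import (
    ENZYMES,
    SPECIES,
    EnzymeProfile,
    build_default_model,
    default_config,
)
from nadtherm.thermolysis import convert_rate


class TestStructure:
    def test_default_counts(self, model):
        assert len(SPECIES) == 8
        assert model.n_reactions == 18
        enzymatic = [r for r in model.reactions if r.enzyme is not None]
        hydrolysis = [r for r in model.reactions if r.enzyme is None]
        assert len(enzymatic) == 13
        assert len(hydrolysis) == 5

    def test_pyridine_vector_in_left_null_space(self, model):
        # every reaction moves exactly one pyridine moiety
        assert np.allclose(np.ones(8) @ model.stoichiometry, 0.0, atol=1e-14)

    def test_no_naad_hydrolysis(self, model):
        # no detectable NAAD hydrolysis: the reaction does not exist, so
        # temperature cannot create a NAAD degradation flux
        assert "hyd_NAAD" not in model.reaction_ids
        hyd_subs = {r.substrate for r in model.reactions if r.enzyme is None}
        assert hyd_subs == {"NAD", "NMN", "NR", "NAR", "NAMN"}

    def test_atp_costs(self, model):
        assert model.reaction("NadE").atp_cost == 2
        for rid in ("Nampt", "PncB", "NadD_NMN", "NadD_NAMN", "NadR_NR", "NadR_NAR"):
            assert model.reaction(rid).atp_cost == 1
        for rid in ("PncA", "NCE", "SurE_NMN", "SurE_NAMN", "PNP_NR", "PNP_NAR"):
            assert model.reaction(rid).atp_cost == 0

    def test_unknown_enzyme_rejected(self):
        cfg = default_config()
        cfg["reactions"]["PncA"]["enzyme"] = "NotAnEnzyme"
        with pytest.raises(ConfigurationError):
            build_default_model(cfg)

    def test_unknown_species_rejected(self):
        cfg = default_config()
        cfg["reactions"]["PncA"]["substrate"] = "NADH"
        with pytest.raises(ConfigurationError):
            build_default_model(cfg)

    def test_naad_hydrolysis_config_rejected(self):
        cfg = default_config()
        cfg["hydrolysis"] = {"NAAD": {"k0_per_s": 1e-6, "Ea": 100.0}}
        with pytest.raises(ConfigurationError):
            build_default_model(cfg)


class TestRates:
    def test_zero_substrate_zero_flux(self, model, uniform_profile):
        state = np.zeros(8)
        assert np.all(model.reaction_rates(state, uniform_profile, 310.65) == 0.0)

    def test_saturation_plateau(self, model, uniform_profile):
        state = np.zeros(8)
        state[SPECIES.index("Nam")] = 1e4  # far above any Km
        v = model.reaction_rates(state, uniform_profile, 310.65)
        r = model.reaction("PncA")
        vmax = r.kcat * 100.0 * 1e-6  # kcat * E(mM)
        assert v[model.reaction_index("PncA")] == pytest.approx(vmax, rel=1e-3)

    def test_nad_hydrolysis_matches_measured_rate(self, model, uniform_profile):
        # at 90 degC with 0.3 mM NAD the fitted first-order flux must
        # reproduce the measured 1.60 %/min within the fit residual
        state = np.zeros(8)
        state[SPECIES.index("NAD")] = 0.3
        v = model.reaction_rates(state, uniform_profile, 363.15)
        expected = convert_rate(1.60, "fraction_per_s") * 0.3
        assert v[model.reaction_index("hyd_NAD")] == pytest.approx(expected, rel=0.05)

    def test_zero_hydrolysis_config(self, uniform_profile, rng):
        cfg = default_config()
        cfg["hydrolysis"] = {c: {"k0_per_s": 0.0, "Ea": 0.0}
                             for c in ("NAD", "NMN", "NR", "NAR", "NAMN")}
        m = build_default_model(cfg)
        state = rng.uniform(0, 0.1, 8)
        v = m.reaction_rates(state, uniform_profile, 350.0)
        for rid in m.reaction_ids:
            if rid.startswith("hyd_"):
                assert v[m.reaction_index(rid)] == 0.0

    def test_rate_monotone_in_temperature(self, model):
        k1, k2 = model.k_at(310.65), model.k_at(320.65)
        assert np.all(k2 >= k1)

    def test_negative_state_rejected_by_rhs_wrapper(self, model, uniform_profile):
        with pytest.raises(ValueError):
            model.reaction_rates(np.zeros(7), uniform_profile, 310.65)


class TestOdeRhs:
    def test_all_rates_zero_gives_zero_derivative(self):
        cfg = default_config()
        cfg["hydrolysis"] = {c: {"k0_per_s": 0.0, "Ea": 0.0}
                             for c in ("NAD", "NMN", "NR", "NAR", "NAMN")}
        m = build_default_model(cfg)
        E = EnzymeProfile(np.zeros(9))
        state = np.full(8, 0.3 / 8)
        assert np.all(m.ode_rhs(state, E, 310.65) == 0.0)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_conservation_for_random_states(self, model, seed):
        r = np.random.default_rng(seed)
        state = r.uniform(0, 0.3, 8)
        E = EnzymeProfile(10.0 ** r.uniform(-2, 2, 9))
        dC = model.ode_rhs(state, E, r.uniform(300, 363))
        assert abs(dC.sum()) <= 1e-12 * max(np.abs(dC).max(), 1e-300)

    def test_single_reaction_balance(self, model):
        # only NCE active: NAD falls, Nam rises, one-for-one
        E = EnzymeProfile.from_dict({"NCE": 50.0})
        state = np.zeros(8)
        state[SPECIES.index("NAD")] = 0.3
        dC = model.ode_rhs(state, E, 310.65)
        i_nad, i_nam = SPECIES.index("NAD"), SPECIES.index("Nam")
        assert dC[i_nad] < 0 < dC[i_nam]
        assert dC[i_nad] == pytest.approx(-dC[i_nam], rel=1e-12)


class TestQ10:
    def test_band_for_every_enzymatic_reaction(self, model):
        # the default activation energies must keep all catalysed steps
        # inside the physiological Q10 band of 2-3 at base temperature
        for r in model.reactions:
            if r.enzyme is not None:
                assert 2.0 <= model.q10(r.id) <= 3.0

    def test_zero_activation_energy(self, model):
        cfg = default_config()
        cfg["reactions"]["PncA"]["Ea"] = 0.0
        m = build_default_model(cfg)
        assert m.q10("PncA") == pytest.approx(1.0)


class TestEnzymeProfile:
    def test_from_dict_defaults_to_zero(self):
        p = EnzymeProfile.from_dict({"PncA": 5.0})
        assert p["PncA"] == 5.0
        assert p["Nampt"] == 0.0
        assert p.total == 5.0

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(ConfigurationError):
            EnzymeProfile.from_dict({"PncZ": 1.0})

    def test_negative_abundance_rejected(self):
        with pytest.raises(ConfigurationError):
            EnzymeProfile(np.array([-1.0] + [0.0] * 8))

    def test_order_matches_enzyme_tuple(self):
        p = EnzymeProfile(np.arange(9, dtype=float))
        assert [p[e] for e in ENZYMES] == list(range(9))
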