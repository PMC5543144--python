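"""Network construction, drift evaluation and variant factory."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mescgrn import (
    MediumInputs,
    build_full_network,
    default_params,
    evaluate_drift,
    make_variant,
)
from mescgrn.network import (
    CompiledDrift,
    ConfigError,
    DomainError,
    ModelValidationError,
    SPECIES_ORDER,
    model_from_dict,
    model_to_dict,
)


class TestBuild:
    def test_full_network_species_and_edges(self, serum):
        assert serum.names == SPECIES_ORDER
        counts = serum.edge_summary()
        # Fig-1 topology: 14 transcriptional Hill terms, 4 non-transcriptional
        # regulations (Tcf3 gate, Erk gate, Chiron->Bcat, Bcat->Tcf3) and the
        # PD/Prdm14 attenuators acting on the Erk gate itself.
        assert counts == {"transcriptional": 14, "non_transcriptional": 4, "attenuators": 2}

    def test_two_i_preset_same_topology_different_inputs(self, serum, twoi):
        # topology identical; only inputs and Nanog noise differ
        d_serum, d_twoi = model_to_dict(serum), model_to_dict(twoi)
        n_serum = d_serum["species"]["NANOG"].pop("noise")
        n_twoi = d_twoi["species"]["NANOG"].pop("noise")
        assert n_twoi == pytest.approx(0.8 * n_serum)
        assert d_serum["species"] == d_twoi["species"]
        assert twoi.inputs == MediumInputs(2.0, 2.0)
        assert serum.inputs == MediumInputs(0.0, 0.0)

    def test_missing_edge_parameters_name_the_edge(self):
        cfg = copy.deepcopy(default_params())
        cfg["species"]["NANOG"]["terms"] = [
            t for t in cfg["species"]["NANOG"]["terms"] if t["regulator"] != "REST"
        ]
        with pytest.raises(ConfigError, match="REST->NANOG"):
            build_full_network(cfg)

    def test_unknown_regulator_rejected(self):
        cfg = copy.deepcopy(default_params())
        cfg["species"]["NANOG"]["terms"][0]["regulator"] = "KLF4"
        with pytest.raises(ModelValidationError, match="KLF4"):
            build_full_network(cfg)


class TestDrift:
    def test_half_saturation_identity(self, serum):
        """An activation Hill term with x = K and n = 1 contributes s/2."""
        term = serum.find_term("FGF_ERK", "OS")
        i_os, i_f = serum.index("OS"), serum.index("FGF_ERK")
        x = np.zeros(serum.n_species)
        x[i_os] = term.K
        d = evaluate_drift(serum, x)
        assert d[i_f] == pytest.approx(term.s / 2.0)

    def test_limit_cases_of_hill_terms(self, serum):
        """Repression at zero regulator gives full s; activation gives 0."""
        x = np.zeros(serum.n_species)
        d = evaluate_drift(serum, x)
        i_m = serum.index("MYCN")
        total_s = sum(t.s for t in serum.equations["MYCN"].terms)  # all repressors
        assert d[i_m] == pytest.approx(total_s)
        i_f = serum.index("FGF_ERK")
        assert d[i_f] == pytest.approx(0.0)  # lone activator at zero

    def test_negative_state_rejected(self, serum):
        x = np.zeros(serum.n_species)
        x[0] = -0.1
        with pytest.raises(DomainError):
            evaluate_drift(serum, x)

    def test_drift_vanishes_at_equilibria(self, serum, serum_equilibria):
        for eq in serum_equilibria:
            assert np.max(np.abs(evaluate_drift(serum, eq.state))) < 1e-8

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 10.0), min_size=8, max_size=8))
    def test_production_bounded_by_sum_of_rates(self, state):
        """Total production never exceeds basal + sum of maximal rates."""
        model = build_full_network()
        x = np.asarray(state)
        d = CompiledDrift(model)(x)
        for i, name in enumerate(model.names):
            eq = model.equations[name]
            cap = eq.basal + sum(t.s for t in eq.terms)
            assert d[i] <= cap + 1e-12  # degradation only subtracts

    def test_serialisation_round_trip_bit_equal_drift(self, serum, rng):
        rebuilt = model_from_dict(model_to_dict(serum))
        f0, f1 = CompiledDrift(serum), CompiledDrift(rebuilt)
        probe = rng.uniform(0.0, 3.0, size=(50, serum.n_species))
        assert np.array_equal(f0(probe), f1(probe))


class TestVariants:
    def test_deleting_an_input_is_rejected(self, serum):
        with pytest.raises(ModelValidationError, match="MediumInputs"):
            make_variant(serum, "delete:PD")

    def test_deletion_clamps_species_to_zero(self, serum):
        m = make_variant(serum, "delete:TCF3")
        i_t = m.index("TCF3")
        eq = m.equations["TCF3"]
        assert eq.terms == () and eq.basal == 0.0
        x = m.initial_state()
        assert x[i_t] == 0.0
        assert evaluate_drift(m, x)[i_t] == 0.0

    def test_deletion_variant_locality(self, serum, rng):
        """Drift changes only through terms involving the deleted species:
        on states where that species is 0 the drift is unchanged."""
        m = make_variant(serum, "delete:PRDM14")
        i_p = serum.index("PRDM14")
        probe = rng.uniform(0.0, 2.0, size=(20, serum.n_species))
        probe[:, i_p] = 0.0
        d0 = CompiledDrift(serum)(probe)
        d1 = CompiledDrift(m)(probe)
        keep = [i for i in range(serum.n_species) if i != i_p]
        assert np.allclose(d0[:, keep], d1[:, keep], atol=1e-14)

    def test_reduced_core_species_set(self, serum):
        m = make_variant(serum, "reduced_core")
        assert set(m.names) == {"OS", "NANOG", "FGF_ERK", "BCAT", "TCF3"}

    def test_mycn_bcat_rewiring(self, serum):
        none = make_variant(serum, "mycn_bcat:none")
        assert all(t.regulator != "BCAT" for t in none.equations["MYCN"].terms)
        act = make_variant(serum, "mycn_bcat:activation")
        t = act.find_term("MYCN", "BCAT")
        assert t.mode == "activation"

    def test_nanog_activates_bcat_adds_one_edge(self, serum):
        m = make_variant(serum, "nanog_activates_bcat")
        t = m.find_term("BCAT", "NANOG")
        assert t.mode == "activation"
        base_counts = serum.edge_summary()
        assert m.edge_summary()["transcriptional"] == base_counts["transcriptional"] + 1

    def test_autoinhibition_variants_flip_the_auto_loop(self, serum):
        for desc in ("nanog_autoinhibition:via_bcat_tcf3", "nanog_autoinhibition:via_rest"):
            m = make_variant(serum, desc)
            assert m.find_term("NANOG", "NANOG").mode == "repression"
        via_rest = make_variant(serum, "nanog_autoinhibition:via_rest")
        assert "REST" in via_rest.names
        via_bcat = make_variant(serum, "nanog_autoinhibition:via_bcat_tcf3")
        assert via_bcat.find_term("BCAT", "NANOG").mode == "activation"

    def test_unknown_variant_rejected(self, serum):
        with pytest.raises(ModelValidationError):
            make_variant(serum, "delete:NOTAGENE")
        with pytest.raises(ModelValidationError):
            make_variant(serum, "frobnicate")
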