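"""Circuit description, validation, built-ins, and config round-trips."""

import math
from importlib import resources

import pytest

from txtlkit.circuits import (CircuitConfigError, ParameterSet, apply_parameters,
                              builtin_circuit, free_parameter_names, load_circuit,
                              serialize_circuit, validate_circuit)

MINIMAL_CONFIG = """
name: toy
genes:
  - {name: gfp, gene_conc: 5.0, gene_length: 700, protein_length: 230}
promoters:
  gfp:
    - {label: RNAP, gibbs_energy: 10.0, expressing: true}
"""

C1_PARAM_NAMES = {
    "K_L", "tau_L_half", "tau_X_deGFP", "tau_L_deGFP", "theta_m_deGFP",
    "theta_p_deGFP", "theta_p_sigma70", "dG_deGFP_RNAP", "dG_deGFP_sigma70",
    "n_deGFP_sigma70", "K_deGFP_sigma70",
}

C2_PARAM_NAMES = {
    "K_L", "tau_L_half",
    "tau_X_cI_ssrA", "tau_X_deGFP_ssrA", "tau_X_sigma28",
    "tau_L_cI_ssrA", "tau_L_deGFP_ssrA", "tau_L_sigma28",
    "theta_m_cI_ssrA", "theta_m_deGFP_ssrA", "theta_m_sigma28",
    "theta_p_cI_ssrA", "theta_p_deGFP_ssrA", "theta_p_sigma28",
    "theta_p_sigma70",
    "dG_cI_ssrA_RNAP", "dG_cI_ssrA_sigma28", "dG_deGFP_ssrA_RNAP",
    "dG_deGFP_ssrA_sigma70", "dG_deGFP_ssrA_cI", "dG_sigma28_RNAP",
    "dG_sigma28_sigma70", "dG_sigma28_cI",
    "n_cI_ssrA_sigma28", "n_deGFP_ssrA_sigma70", "n_deGFP_ssrA_cI",
    "n_sigma28_sigma70", "n_sigma28_cI",
    "K_cI_ssrA_sigma28", "K_deGFP_ssrA_sigma70", "K_deGFP_ssrA_cI",
    "K_sigma28_sigma70", "K_sigma28_cI",
}


class TestBuiltins:
    def test_c1_exposes_eleven_free_parameters(self, c1):
        _, params = c1
        assert len(params) == 11
        assert set(params.names()) == C1_PARAM_NAMES

    def test_c2_exposes_thirtythree_free_parameters(self, c2):
        _, params = c2
        assert len(params) == 33
        assert set(params.names()) == C2_PARAM_NAMES

    def test_unknown_circuit_name_rejected(self):
        with pytest.raises(ValueError, match="C3"):
            builtin_circuit("C3")

    @pytest.mark.parametrize("name", ["C1", "C2"])
    def test_builtins_validate_clean(self, name):
        spec, _ = builtin_circuit(name)
        assert validate_circuit(spec) == []

    def test_c1_structure(self, c1):
        spec, _ = c1
        assert [g.name for g in spec.genes] == ["deGFP"]
        g = spec.gene("deGFP")
        assert (g.gene_conc, g.gene_length, g.protein_length) == (5.0, 782, 237)
        labels = [c.label for c in spec.promoters["deGFP"].configurations]
        assert labels == ["ground", "RNAP", "RNAP_sigma70"]
        assert spec.constitutive_species[0].name == "sigma70"
        assert spec.constitutive_species[0].initial_conc == 35.0

    def test_c2_structure(self, c2):
        spec, _ = c2
        assert {g.name for g in spec.genes} == {"sigma28", "cI_ssrA", "deGFP_ssrA"}
        # both P70a promoters carry a repressing cI-bound configuration
        for gene in ("sigma28", "deGFP_ssrA"):
            conf = spec.promoters[gene].configuration("cI")
            assert not conf.expressing
            assert conf.binding.sense == "repressor"
            assert conf.binding.regulator == "cI_ssrA"
        # the P28 promoter is sigma28-activated and carries no repressor
        labels = [c.label for c in spec.promoters["cI_ssrA"].configurations]
        assert labels == ["ground", "RNAP", "RNAP_sigma28"]

    def test_free_parameter_enumeration_covers_builtin_names(self, c1, c2):
        for spec, params in (c1, c2):
            assert set(free_parameter_names(spec)) == set(params.names())

    def test_degradation_rates_follow_printed_halflives(self, c1):
        _, params = c1
        # 13.5 min mRNA half-life and 10.86 day protein half-life
        assert params["theta_m_deGFP"] == pytest.approx(math.log(2) / 0.225)
        assert params["theta_p_deGFP"] == pytest.approx(
            math.log(2) / (10.86 * 24.0))


class TestConfigIO:
    def test_minimal_config_gains_implicit_ground(self):
        spec = load_circuit(MINIMAL_CONFIG)
        assert len(spec.genes) == 1
        confs = spec.promoters["gfp"].configurations
        assert len(confs) == 2
        assert confs[0].is_ground and not confs[0].expressing
        assert confs[1].expressing

    def test_omitted_temperature_defaults_to_reaction_conditions(self):
        spec = load_circuit(MINIMAL_CONFIG)
        assert spec.constants.temperature == pytest.approx(302.15)

    def test_omitted_time_constants_are_seeded(self):
        spec = load_circuit(MINIMAL_CONFIG)
        g = spec.gene("gfp")
        # initiation time over elongation time, seconds
        assert g.tx_time_constant == pytest.approx(22.0 / (700 / 30.0))
        assert g.tl_time_constant == pytest.approx(1.5 / (230 / 1.5))

    def test_undeclared_regulator_is_named_in_error(self):
        bad = MINIMAL_CONFIG + """\
    - label: RNAP_act
      gibbs_energy: -5.0
      expressing: true
      binding: {regulator: ghost, dissociation_constant: 10.0, hill_coefficient: 1.0}
"""
        with pytest.raises(CircuitConfigError, match="ghost"):
            load_circuit(bad)

    def test_non_positive_quantity_rejected(self):
        bad = MINIMAL_CONFIG.replace("gene_length: 700", "gene_length: -700")
        with pytest.raises(CircuitConfigError, match="gene_length"):
            load_circuit(bad)

    def test_unparsable_text_reports_parse_error(self):
        with pytest.raises(CircuitConfigError, match="YAML"):
            load_circuit("genes: [unclosed")

    @pytest.mark.parametrize("name", ["C1", "C2"])
    def test_serialize_load_round_trip(self, name):
        spec, _ = builtin_circuit(name)
        assert load_circuit(serialize_circuit(spec)) == spec

    @pytest.mark.parametrize("name", ["C1", "C2"])
    def test_shipped_configs_match_builtins(self, name):
        text = (resources.files("txtlkit") / "data" / f"{name}.yaml").read_text()
        spec, _ = builtin_circuit(name)
        assert load_circuit(text) == spec


class TestValidationDiagnostics:
    def test_negative_gene_conc_cited(self, c1):
        spec, _ = c1
        import copy

        bad = copy.deepcopy(spec)
        bad.genes[0].gene_conc = -1.0
        diags = validate_circuit(bad)
        assert len(diags) == 1 and "gene_conc" in diags[0]

    def test_promoter_without_expressing_configuration_cited(self, c1):
        spec, _ = c1
        import copy

        bad = copy.deepcopy(spec)
        for conf in bad.promoters["deGFP"].configurations:
            conf.expressing = False
        diags = validate_circuit(bad)
        assert len(diags) == 1 and "expressing" in diags[0]

    def test_ground_state_weight_must_be_unity(self, c1):
        spec, _ = c1
        import copy

        bad = copy.deepcopy(spec)
        bad.promoters["deGFP"].configuration("ground").gibbs_energy = 3.0
        assert any("gibbs_energy = 0" in d for d in validate_circuit(bad))


class TestApplyParameters:
    def test_values_land_on_the_right_fields(self, c1):
        spec, params = c1
        updated = apply_parameters(spec, params.replace(tau_X_deGFP=0.9))
        assert updated.gene("deGFP").tx_time_constant == pytest.approx(0.9)
        conf = updated.promoters["deGFP"].configuration("RNAP_sigma70")
        assert conf.gibbs_energy == pytest.approx(params["dG_deGFP_sigma70"])
        assert updated.constants.tl_saturation == pytest.approx(params["K_L"])

    def test_degradation_applied_through_modifier(self, c1):
        spec, params = c1
        updated = apply_parameters(spec, params.replace(theta_m_deGFP=7.5))
        g = updated.gene("deGFP")
        eff = g.mrna_deg_modifier * updated.constants.mrna_deg_default
        assert eff == pytest.approx(7.5)

    def test_unknown_parameter_is_named(self, c1):
        spec, _ = c1
        with pytest.raises(KeyError, match="tau_X_nonexistent"):
            apply_parameters(spec, ParameterSet({"tau_X_nonexistent": 1.0}))
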