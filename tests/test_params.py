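import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from pbpkddi.params import (
    DoseEvent,
    DrugParameters,
    IonizationGroup,
    Regimen,
    default_physiology,
    fraction_unionized,
    load_drug_parameters,
    serialize_drug_parameters,
)


def _minimal_doc(**overrides):
    doc = {
        "name": "testdrug",
        "molecular_weight": 400.0,
        "logP": 2.0,
        "fu_plasma": 0.5,
        "blood_plasma_ratio": 1.0,
        "permeability": {"peff_human": 2.0},
        "absorption_model": "first_order",
        "distribution_model": "minimal",
        "elimination_pathways": [
            {"route": "renal", "kinetics": {"systemic_renal": 1.0}}
        ],
    }
    doc.update(overrides)
    return doc


class TestLoadDrugParameters:
    def test_zanubrutinib_fixture_values(self, drugs):
        z = drugs["zanubrutinib"]
        assert z.fu_plasma == 0.0582
        assert z.logP == 4.2
        assert z.blood_plasma_ratio == 0.804

    def test_fluconazole_fixture_values(self, drugs):
        f = drugs["fluconazole"]
        assert f.blood_plasma_ratio == 1.0
        assert f.fu_plasma == 0.89

    def test_missing_mandatory_field_names_it(self):
        doc = _minimal_doc()
        del doc["molecular_weight"]
        with pytest.raises(ValidationError, match="molecular_weight"):
            DrugParameters.model_validate(doc)

    def test_non_positive_fraction_rejected(self):
        with pytest.raises(ValidationError):
            DrugParameters.model_validate(_minimal_doc(fu_plasma=0.0))
        with pytest.raises(ValidationError):
            DrugParameters.model_validate(_minimal_doc(fu_plasma=1.2))

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValidationError):
            DrugParameters.model_validate(_minimal_doc(not_a_field=1))

    def test_both_permeabilities_rejected(self):
        with pytest.raises(ValidationError):
            DrugParameters.model_validate(
                _minimal_doc(permeability={"peff_human": 1.0, "papp_caco2": 10.0})
            )

    def test_segmented_requires_solubility(self):
        with pytest.raises(ValidationError, match="solubility"):
            DrugParameters.model_validate(_minimal_doc(absorption_model="segmented_gi"))

    @pytest.mark.parametrize(
        "name",
        ["zanubrutinib", "acalabrutinib", "voriconazole", "fluconazole", "itraconazole"],
    )
    def test_round_trip_full_precision(self, name, drugs, tmp_path):
        original = drugs[name]
        path = tmp_path / f"{name}.yaml"
        serialize_drug_parameters(original, path)
        reloaded = load_drug_parameters(path)
        assert reloaded == original


# every published parameter-table cell for the five compounds, checked
# against exactly one fixture field
TABLE_CELLS = {
    "zanubrutinib": {
        "pKa": [3.3], "molecular_weight": 471.55, "blood_plasma_ratio": 0.804,
        "peff": 0.9, "logP": 4.2, "fu_plasma": 0.0582,
        "clint_hlm_cyp3a4": 120.0, "clint_hlm_additional": 60.0, "clr": 0.5,
    },
    "acalabrutinib": {
        "pKa": [3.54, 5.77], "molecular_weight": 465.5, "blood_plasma_ratio": 0.787,
        "peff": 4.0, "logP": 2.03, "fu_gut": 0.026, "fu_plasma": 0.026,
        "clint_rcyp_cyp3a4": 9.63, "clint_hlm_additional": 289.5, "clr": 1.33,
    },
    "voriconazole": {
        "pKa": [1.6], "molecular_weight": 349.3, "solubility": 3.2,
        "blood_plasma_ratio": 1.0, "peff": 3.8, "logP": 1.8, "fu_plasma": 0.42,
        "clint_hlm_additional": 4.3, "clr": 0.096, "ki": 0.66,
    },
    "fluconazole": {
        "pKa": [1.76], "molecular_weight": 306.3, "solubility": 1.39,
        "blood_plasma_ratio": 1.0, "papp": 29.8, "logP": 0.2,
        "fu_gut": 0.89, "fu_plasma": 0.89, "clr": 0.86, "ki": 10.7,
    },
    "itraconazole": {
        "pKa": [4.28], "molecular_weight": 705.6, "solubility": 0.00964,
        "blood_plasma_ratio": 0.58, "peff": 0.28, "logP": 4.47,
        "fu_gut": 0.016, "fu_plasma": 0.016, "km": 0.004, "vmax": 0.065,
        "ki": 0.001,
    },
}


class TestFixtureCompleteness:
    @pytest.mark.parametrize("name", sorted(TABLE_CELLS))
    def test_every_table_cell_present(self, name, drugs):
        d = drugs[name]
        cells = TABLE_CELLS[name]
        assert [g.pKa for g in d.ionization] == cells["pKa"]
        assert d.molecular_weight == cells["molecular_weight"]
        assert d.blood_plasma_ratio == cells["blood_plasma_ratio"]
        assert d.logP == cells["logP"]
        assert d.fu_plasma == cells["fu_plasma"]
        if "solubility" in cells:
            assert d.solubility_mg_ml == cells["solubility"]
        if "fu_gut" in cells:
            assert d.fu_gut == cells["fu_gut"]
        if "peff" in cells:
            assert d.permeability.peff_human == cells["peff"]
        if "papp" in cells:
            assert d.permeability.papp_caco2 == cells["papp"]
        kin = {
            (p.route, type(p.kinetics).__name__): p.kinetics
            for p in d.elimination_pathways
        }
        if "clint_hlm_cyp3a4" in cells:
            assert kin[("hepatic_CYP3A4", "LinearClintHLM")].linear_clint_hlm == cells[
                "clint_hlm_cyp3a4"
            ]
        if "clint_rcyp_cyp3a4" in cells:
            assert kin[("hepatic_CYP3A4", "LinearClintRCYP")].linear_clint_rcyp == cells[
                "clint_rcyp_cyp3a4"
            ]
        if "clint_hlm_additional" in cells:
            assert kin[
                ("hepatic_additional", "LinearClintHLM")
            ].linear_clint_hlm == cells["clint_hlm_additional"]
        if "clr" in cells:
            assert kin[("renal", "SystemicRenal")].systemic_renal == cells["clr"]
        if "km" in cells:
            sat = kin[("hepatic_CYP3A4", "SaturableRCYP")]
            assert sat.km_um == cells["km"]
            assert sat.vmax_pmol_min_pmol == cells["vmax"]
        if "ki" in cells:
            assert d.interaction.ki_um == cells["ki"]
        else:
            assert d.interaction is None


class TestFractionUnionized:
    def test_monoprotic_base_hand_value(self):
        f = fraction_unionized([IonizationGroup(type="base", pKa=3.3)], 7.4)
        assert f == pytest.approx(1.0 / (1.0 + 10 ** (3.3 - 7.4)), rel=1e-12)
        assert f == pytest.approx(0.99992, abs=1e-5)

    def test_ph_equal_pka_gives_half(self):
        assert fraction_unionized(
            [IonizationGroup(type="base", pKa=5.0)], 5.0
        ) == pytest.approx(0.5)

    def test_neutral_compound_is_one(self):
        for ph in (1.0, 7.4, 13.0):
            assert fraction_unionized([], ph) == 1.0

    def test_ph_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fraction_unionized([], -1.0)

    @given(
        ph1=st.floats(0.0, 14.0),
        ph2=st.floats(0.0, 14.0),
        pka=st.floats(1.0, 12.0),
    )
    @settings(derandomize=True, max_examples=60)
    def test_monotone_in_ph_for_base_and_bounded(self, ph1, ph2, pka):
        grp = [IonizationGroup(type="base", pKa=pka)]
        f1 = fraction_unionized(grp, ph1)
        f2 = fraction_unionized(grp, ph2)
        assert 0.0 < f1 <= 1.0
        if ph1 < ph2:
            assert f1 <= f2


class TestPhysiologyDefaults:
    def test_pinned_hepatic_flow(self, physiology):
        assert physiology.hepatic_blood_flow_l_h == 87.0

    def test_invariants_hold(self, physiology):
        assert physiology.liver_weight_g > 0
        assert all(t.volume_l > 0 and t.blood_flow_l_h > 0 for t in physiology.tissue_compartments)
        assert all(s.transit_time_h > 0 for s in physiology.gi_segments)

    def test_tissue_flows_within_cardiac_output(self, physiology):
        total = sum(
            t.blood_flow_l_h for t in physiology.tissue_compartments if t.name != "lung"
        )
        assert total <= physiology.cardiac_output_l_h + 1e-9


class TestRegimen:
    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValidationError):
            Regimen(
                compound="x",
                doses=[DoseEvent(dose_mg=1, time_h=2), DoseEvent(dose_mg=1, time_h=2)],
            )

    def test_repeating_with_loading_day(self):
        # 400 mg twice daily on day 1 then 200 mg twice daily, 14 days total
        reg = Regimen.repeating(
            "voriconazole", 200.0, 12.0, 26, loading=[(400.0, 0.0), (400.0, 12.0)]
        )
        assert len(reg.doses) == 28
        assert reg.doses[0].dose_mg == 400.0
        assert reg.doses[2].dose_mg == 200.0
        assert reg.doses[2].time_h == 24.0
        assert reg.last_dose_time_h == pytest.approx(324.0)
        assert reg.dosing_interval_h() == pytest.approx(12.0)
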