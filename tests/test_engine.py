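import numpy as np
import pytest

from pbpkddi.cohort import bateman
from pbpkddi.engine import (
    Scenario,
    SolverSettings,
    build_system,
    simulate,
    steady_state_metrics,
)
from pbpkddi.params import DrugParameters, Regimen
from pbpkddi.pk_metrics import auc_trapezoid, cmax_tmax


def _drug(**overrides):
    doc = {
        "name": "probe",
        "molecular_weight": 400.0,
        "logP": 1.0,
        "ionization": [],
        "fu_plasma": 0.5,
        "blood_plasma_ratio": 1.0,
        "permeability": {"peff_human": 2.0},
        "absorption_model": "first_order",
        "distribution_model": "minimal",
        "elimination_pathways": [
            {"route": "renal", "kinetics": {"systemic_renal": 3.0}}
        ],
    }
    doc.update(overrides)
    return DrugParameters.model_validate(doc)


def _one_compartment_drug(v_l=35.0, ka=1.2, clr=3.0):
    """Reduces to the oral one-compartment model: renal-only elimination,
    vanishing liver partition (no hepatic hold-up), pinned volume."""
    return _drug(
        absorption={"ka_override_per_h": ka},
        distribution={"kp_scalar": 1e-4, "vss_override_l": v_l},
        elimination_pathways=[{"route": "renal", "kinetics": {"systemic_renal": clr}}],
    )


class TestSimulate:
    def test_one_compartment_matches_bateman_closed_form(self):
        v, ka, clr, dose = 35.0, 1.2, 3.0, 100.0
        d = _one_compartment_drug(v, ka, clr)
        sc = Scenario(
            substrate=d,
            substrate_regimen=Regimen.single("probe", dose),
            horizon_h=48.0,
            solver=SolverSettings().tightened(100.0),
        )
        p = simulate(sc)["probe"]
        ke = clr / v
        expected = bateman(p.times_h, dose / v, ka, ke) * 1000.0  # ng/mL
        scale = expected.max()
        err = np.abs(p.conc_ng_ml - expected) / scale
        assert np.max(err) < 1e-3

    def test_zero_dose_gives_zero_profile(self):
        sc = Scenario(
            substrate=_drug(),
            substrate_regimen=Regimen.single("probe", 0.0),
            horizon_h=24.0,
        )
        p = simulate(sc)["probe"]
        assert np.all(p.conc_ng_ml == 0.0)

    def test_superposition_doubling_dose(self):
        profiles = []
        for dose in (50.0, 100.0):
            sc = Scenario(
                substrate=_drug(),
                substrate_regimen=Regimen.single("probe", dose),
                horizon_h=24.0,
            )
            profiles.append(simulate(sc)["probe"].conc_ng_ml)
        ref = np.max(profiles[1])
        assert np.max(np.abs(2.0 * profiles[0] - profiles[1])) < 1e-4 * ref

    def test_mass_balance_within_tolerance(self):
        sc = Scenario(
            substrate=_drug(),
            substrate_regimen=Regimen.repeating("probe", 50.0, 12.0, 4),
            horizon_h=72.0,
        )
        log = simulate(sc)["probe"].log
        assert log["mass_balance_rel_error"] < 5e-3

    def test_convergence_under_tighter_tolerances(self, drugs):
        metrics = {}
        for label, solver in (
            ("default", SolverSettings()),
            ("tight", SolverSettings().tightened(2.0)),
        ):
            sc = Scenario(
                substrate=drugs["acalabrutinib"],
                substrate_regimen=Regimen.single("acalabrutinib", 100.0),
                horizon_h=24.0,
                solver=solver,
            )
            p = simulate(sc)["acalabrutinib"]
            cmax, _ = cmax_tmax(p.times_h, p.conc_ng_ml)
            metrics[label] = (cmax, auc_trapezoid(p.times_h, p.conc_ng_ml))
        for a, b in zip(metrics["default"], metrics["tight"]):
            assert abs(a - b) / b < 1e-3

    def test_horizon_must_cover_doses(self):
        with pytest.raises(ValueError, match="horizon"):
            Scenario(
                substrate=_drug(),
                substrate_regimen=Regimen.repeating("probe", 50.0, 12.0, 10),
                horizon_h=24.0,
            )


class TestBuildSystem:
    def test_bid_14_days_yields_28_events(self, drugs):
        sc = Scenario(
            substrate=drugs["zanubrutinib"],
            substrate_regimen=Regimen.repeating("zanubrutinib", 160.0, 12.0, 28),
            horizon_h=14 * 24.0,
        )
        system = build_system(sc)
        assert len(system.dose_events) == 28

    def test_substrate_layout_identical_with_and_without_inhibitor(self, drugs):
        alone = build_system(
            Scenario(
                substrate=drugs["zanubrutinib"],
                substrate_regimen=Regimen.single("zanubrutinib", 160.0),
                horizon_h=24.0,
            )
        )
        combined = build_system(
            Scenario(
                substrate=drugs["zanubrutinib"],
                substrate_regimen=Regimen.single("zanubrutinib", 160.0),
                inhibitor=drugs["voriconazole"],
                inhibitor_regimen=Regimen.single("voriconazole", 200.0),
                horizon_h=24.0,
            )
        )
        a, b = alone.compounds[0], combined.compounds[0]
        assert (a.abs_slice, a.dist_slice, a.n_states) == (
            b.abs_slice,
            b.dist_slice,
            b.n_states,
        )

    def test_duplicate_compound_names_rejected(self, drugs):
        with pytest.raises(ValueError, match="overlapping"):
            Scenario(
                substrate=drugs["zanubrutinib"],
                substrate_regimen=Regimen.single("zanubrutinib", 160.0),
                inhibitor=drugs["zanubrutinib"],
                inhibitor_regimen=Regimen.single("zanubrutinib", 160.0),
                horizon_h=24.0,
            )


class TestInteractionNullCases:
    def test_zero_dose_inhibitor_leaves_substrate_unchanged(self, drugs):
        alone = simulate(
            Scenario(
                substrate=drugs["acalabrutinib"],
                substrate_regimen=Regimen.single("acalabrutinib", 100.0),
                horizon_h=24.0,
            )
        )["acalabrutinib"]
        with_null = simulate(
            Scenario(
                substrate=drugs["acalabrutinib"],
                substrate_regimen=Regimen.single("acalabrutinib", 100.0),
                inhibitor=drugs["voriconazole"],
                inhibitor_regimen=Regimen.single("voriconazole", 0.0),
                horizon_h=24.0,
            )
        )["acalabrutinib"]
        ref = np.max(alone.conc_ng_ml)
        assert np.max(np.abs(alone.conc_ng_ml - with_null.conc_ng_ml)) < 1e-6 * ref

    def test_infinite_ki_sentinel_is_noop(self, drugs):
        import math

        inert = drugs["voriconazole"].model_copy(deep=True)
        inert.interaction.ki_um = math.inf
        alone = simulate(
            Scenario(
                substrate=drugs["acalabrutinib"],
                substrate_regimen=Regimen.single("acalabrutinib", 100.0),
                horizon_h=24.0,
            )
        )["acalabrutinib"]
        combined = simulate(
            Scenario(
                substrate=drugs["acalabrutinib"],
                substrate_regimen=Regimen.single("acalabrutinib", 100.0),
                inhibitor=inert,
                inhibitor_regimen=Regimen.single("voriconazole", 200.0),
                horizon_h=24.0,
            )
        )["acalabrutinib"]
        ref = np.max(alone.conc_ng_ml)
        assert np.max(np.abs(alone.conc_ng_ml - combined.conc_ng_ml)) < 1e-4 * ref


class TestSteadyStateMetrics:
    def test_short_half_life_has_no_accumulation(self):
        # t1/2 ~ 0.7 h << 12 h interval
        d = _one_compartment_drug(v_l=20.0, ka=3.0, clr=20.0)
        reg = Regimen.repeating("probe", 50.0, 12.0, 6)
        sc = Scenario(substrate=d, substrate_regimen=reg, horizon_h=84.0)
        p = simulate(sc)["probe"]
        m = steady_state_metrics(p, reg)
        assert m.accumulation_index == pytest.approx(1.0, abs=0.01)

    def test_window_endpoints_align_with_final_dose(self):
        d = _one_compartment_drug()
        reg = Regimen.repeating("probe", 50.0, 12.0, 4)
        sc = Scenario(substrate=d, substrate_regimen=reg, horizon_h=60.0)
        p = simulate(sc)["probe"]
        m = steady_state_metrics(p, reg)
        assert m.interval == (36.0, 48.0)

    def test_single_dose_rejected(self):
        d = _one_compartment_drug()
        reg = Regimen.single("probe", 50.0)
        sc = Scenario(substrate=d, substrate_regimen=reg, horizon_h=24.0)
        p = simulate(sc)["probe"]
        with pytest.raises(ValueError, match="two doses"):
            steady_state_metrics(p, reg)
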