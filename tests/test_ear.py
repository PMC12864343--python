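"""rEAR statistic, EAR curves, classification and the virtual-drug sweep."""

import numpy as np
import pytest

from pgpear import (
    ClassifyThresholds,
    Condition,
    DrugParams,
    EarResult,
    classify_ear,
    compute_rear,
    ear_curve,
    efflux_efficiency,
    get_drug,
    make_virtual_drug,
    sweep_rear50,
)


def synthetic_ear(r50: float) -> EarResult:
    """Hand-built EarResult carrying a chosen rEAR_50% (no simulation)."""
    return EarResult(
        drug="synthetic",
        reference_condition=Condition.from_micromolar(1, 1000),
        fractions=(50.0, 100.0),
        rear=(r50, 100.0),
    )


class TestComputeRear:
    def test_reference_fraction_is_exactly_100(self, verapamil, reference_condition):
        assert compute_rear(verapamil, reference_condition, 100.0) == 100.0

    def test_quadrature_reuse_matches_fresh_computation(self, verapamil, reference_condition):
        curve = ear_curve(verapamil, reference_condition, (50, 100))
        direct = compute_rear(verapamil, reference_condition, 50)
        assert curve.rear_at(50) == pytest.approx(direct, rel=1e-12)

    def test_undefined_without_efflux(self, reference_condition):
        no_efflux = DrugParams("null", k_off=1e4, k_e=0.0, P_AC=3e-6, P_BC=3e-6,
                               K_AO=300, K_BO=300, K_IL=300)
        with pytest.raises(ValueError, match="undefined"):
            compute_rear(no_efflux, reference_condition, 50)

    def test_undefined_without_pgp(self, verapamil):
        cond = Condition(dose=1e-6, C_Pgp_tot=0.0)
        with pytest.raises(ValueError, match="undefined"):
            compute_rear(verapamil, cond, 50)

    def test_invalid_fraction(self, verapamil, reference_condition):
        with pytest.raises(ValueError):
            compute_rear(verapamil, reference_condition, 0)


class TestEarCurve:
    def test_single_reference_fraction(self, verapamil, reference_condition):
        curve = ear_curve(verapamil, reference_condition, (100,))
        assert curve.fractions == (100.0,)
        assert curve.rear == (100.0,)

    def test_empty_fractions_rejected(self, verapamil, reference_condition):
        with pytest.raises(ValueError):
            ear_curve(verapamil, reference_condition, ())

    def test_nonpositive_fraction_rejected(self, verapamil, reference_condition):
        with pytest.raises(ValueError):
            ear_curve(verapamil, reference_condition, (50, -10))

    def test_tidy_frame(self, verapamil, reference_condition):
        curve = ear_curve(verapamil, reference_condition, (50, 100))
        frame = curve.to_frame()
        assert list(frame.columns) == ["drug", "fraction_pct", "rEAR_pct"]
        assert len(frame) == 2
        assert (frame["drug"] == "verapamil").all()

    def test_missing_fraction_lookup(self, verapamil, reference_condition):
        curve = ear_curve(verapamil, reference_condition, (100,))
        with pytest.raises(KeyError):
            curve.rear_at(50)


class TestEffluxEfficiency:
    def test_amprenavir(self, amprenavir):
        assert efflux_efficiency(amprenavir) == pytest.approx(7e4 / 30, rel=1e-12)

    def test_unity_when_rates_equal(self):
        drug = DrugParams("even", k_off=5.0, k_e=5.0, P_AC=3e-6, P_BC=3e-6,
                          K_AO=300, K_BO=300, K_IL=300)
        assert efflux_efficiency(drug) == 1.0

    def test_undefined_without_efflux(self):
        drug = DrugParams("null", k_off=5.0, k_e=0.0, P_AC=3e-6, P_BC=3e-6,
                          K_AO=300, K_BO=300, K_IL=300)
        with pytest.raises(ValueError):
            efflux_efficiency(drug)


class TestClassification:
    @pytest.mark.parametrize(
        "r50,label",
        [(53.0, "linear"), (60.0, "linear"), (79.0, "intermediate"),
         (85.0, "non-linear"), (93.0, "non-linear")],
    )
    def test_default_thresholds(self, r50, label):
        assert classify_ear(synthetic_ear(r50)) == label

    def test_custom_thresholds(self):
        strict = ClassifyThresholds(linear_max=55.0, nonlinear_min=90.0)
        assert classify_ear(synthetic_ear(79.0), strict) == "intermediate"
        assert classify_ear(synthetic_ear(89.0), strict) == "intermediate"

    def test_requires_r50(self, verapamil, reference_condition):
        curve = EarResult(
            drug="x", reference_condition=reference_condition,
            fractions=(100.0,), rear=(100.0,),
        )
        with pytest.raises(KeyError):
            classify_ear(curve)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            ClassifyThresholds(linear_max=90.0, nonlinear_min=85.0)


class TestSweep:
    def test_single_point_consistent_with_compute_rear(self):
        drug = make_virtual_drug(2e4, 0.1, P_nm_s=300.0, K=300.0)
        cond = Condition.from_micromolar(1.0, 1000.0)
        expected = compute_rear(drug, cond, 50)
        sweep = sweep_rear50([2e4], [0.1], [1.0], [1000.0])
        assert len(sweep.frame) == 1
        assert sweep.frame["rEAR_50_pct"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert sweep.n_failed == 0

    def test_grid_cardinality(self):
        sweep = sweep_rear50([1e4, 1e5], [0.1, 1.0], [1.0], [1000.0])
        assert len(sweep.frame) == 4
        assert set(sweep.frame.columns) == {
            "k_off_per_s", "k_e_per_s", "dose_um", "pgp_um", "rEAR_50_pct",
        }

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_rear50([], [0.1], [1.0], [1000.0])

    def test_higher_permeability_shifts_linear_region_to_larger_ke(self):
        """Raising passive permeability extends the linear region: on a
        fixed k_off slice, the smallest k_e reaching a non-linear
        rEAR_50% (>= 85%) increases."""
        k_es = np.logspace(np.log10(0.03), np.log10(30), 5)

        def smallest_nonlinear_ke(p_nm_s: float) -> float:
            sweep = sweep_rear50([1e4], k_es, [1.0], [1000.0], P_nm_s=p_nm_s)
            frame = sweep.frame
            hits = frame[frame["rEAR_50_pct"] >= 85.0]
            return hits["k_e_per_s"].min() if len(hits) else np.inf

        assert smallest_nonlinear_ke(700.0) >= smallest_nonlinear_ke(300.0)

    def test_higher_partitioning_moves_towards_nonlinear(self):
        """Raising the inner-leaflet partition coefficient strengthens
        binding flux and pushes the same kinetic point towards a
        non-linear expression-activity relationship."""
        drug_lo = make_virtual_drug(1e4, 0.3, P_nm_s=300.0, K=300.0)
        drug_hi = DrugParams(
            "highKIL", k_off=1e4, k_e=0.3, P_AC=3e-6, P_BC=3e-6,
            K_AO=300.0, K_BO=300.0, K_IL=900.0,
        )
        cond = Condition.from_micromolar(1.0, 1000.0)
        assert compute_rear(drug_hi, cond, 50) >= compute_rear(drug_lo, cond, 50)
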