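"""Activation signal, MTX pharmacodynamics, and the coupled immune ODE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adaqsp.config import (
    ImmuneRates,
    MtxParameters,
    MtxRegimen,
    PhysiologyParameters,
    Regimen,
)
from adaqsp.immune import (
    ActivationInputs,
    CalibrationResult,
    calibrate_k_ag_n,
    epitope_activation_signal,
    mtx_proliferation_factor,
    simulate_subject,
)
from adaqsp.pbpk import simulate_pk_only

GRID = np.array(sorted({336.0 * k for k in range(7)} | {100.0, 500.0}))[1:]


def activation(**kw):
    defaults = dict(
        id_m=100.0, t_tot=300.0, dc_uptake=1.0, ag_vs_nM=1.0,
        elution_ranks=(10.0,), k_ag_n=81.0,
    )
    defaults.update(kw)
    return epitope_activation_signal(ActivationInputs(**defaults))


class TestActivationSignal:
    def test_hand_arithmetic_example(self):
        # DC fraction 100/400 = 0.25; S = (100/10 - 1)^2 = 81; 81/162 = 0.5
        assert activation() == pytest.approx(0.125, abs=1e-15)

    def test_zero_antigen_gives_zero(self):
        assert activation(ag_vs_nM=0.0) == 0.0

    def test_rank_100_gives_zero(self):
        assert activation(elution_ranks=(100.0, 100.0)) == 0.0

    def test_no_cells_defined_as_zero(self):
        assert activation(id_m=0.0, t_tot=0.0) == 0.0

    @pytest.mark.parametrize("bad_rank", [0.0, -1.0, 101.0])
    def test_invalid_rank_rejected(self, bad_rank):
        with pytest.raises(ValueError):
            activation(elution_ranks=(bad_rank,))

    @given(
        ag=st.floats(0.0, 1e4),
        ag2=st.floats(0.0, 1e4),
        uptake=st.floats(0.0, 10.0),
        ranks=st.lists(st.floats(0.01, 100.0), min_size=1, max_size=6),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_bounds_and_monotonicity(self, ag, ag2, uptake, ranks):
        d1 = activation(ag_vs_nM=ag, dc_uptake=uptake, elution_ranks=ranks)
        assert 0.0 <= d1 <= 1.0
        d2 = activation(ag_vs_nM=ag2, dc_uptake=uptake, elution_ranks=ranks)
        if ag2 >= ag:
            assert d2 >= d1 - 1e-12
        # weakening every rank can only lower the signal
        weaker = [min(100.0, r * 2) for r in ranks]
        d3 = activation(ag_vs_nM=ag, dc_uptake=uptake, elution_ranks=weaker)
        assert d3 <= d1 + 1e-12


class TestMtxInhibition:
    def test_no_drug_no_inhibition(self):
        assert mtx_proliferation_factor(0.0, MtxParameters()) == 1.0

    def test_half_maximal_at_ic50(self):
        params = MtxParameters()  # imax = 1, IC50 = 283 nM
        assert mtx_proliferation_factor(283.0, params) == pytest.approx(0.5)

    def test_three_ic50(self):
        assert mtx_proliferation_factor(
            3 * 283.0, MtxParameters()
        ) == pytest.approx(0.25)

    def test_strictly_decreasing_with_floor(self):
        params = MtxParameters(imax=0.8)
        c = np.linspace(0, 1e5, 50)
        f = np.array([mtx_proliferation_factor(x, params) for x in c])
        assert np.all(np.diff(f) < 0)
        assert f[-1] > 1 - params.imax

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            mtx_proliferation_factor(-1.0, MtxParameters())


class TestCoupledSystem:
    def test_no_epitopes_equals_pk_only(self, physiology, high_risk_scenario):
        drug = high_risk_scenario.drug.model_copy(update={"epitopes": []})
        regimen = high_risk_scenario.regimen
        full = simulate_subject(
            drug, physiology, regimen, GRID, alleles=("DRB1*01:01",)
        )
        pk = simulate_pk_only(drug, physiology, regimen, GRID)
        assert full.mode == "full"
        np.testing.assert_allclose(
            full.drug_nM["plasma"], pk.drug_nM["plasma"], rtol=1e-9
        )
        assert np.all(full.ada_total_nM == 0.0)
        # immune states stay at initial conditions
        assert np.all(full.cells["NB"] == full.cells["NB"][0])

    def test_zero_dc_uptake_never_raises_ada(self, physiology, high_risk_scenario):
        sc = high_risk_scenario
        drug = sc.drug.model_copy(update={"dc_uptake": 0.0})
        alleles = tuple(sc.drug.epitopes[0].ranks)[:6]
        full = simulate_subject(drug, physiology, sc.regimen, GRID, alleles=alleles)
        assert np.all(full.ada_total_nM == 0.0)

    def test_huge_k_ag_n_suppresses_ada(self, physiology, high_risk_scenario):
        sc = high_risk_scenario
        alleles = tuple(sc.drug.epitopes[0].ranks)[:6]
        rates = ImmuneRates(k_ag_n=1e12)
        full = simulate_subject(
            sc.drug, physiology, sc.regimen, GRID, rates=rates, alleles=alleles
        )
        pk = simulate_pk_only(sc.drug, physiology, sc.regimen, GRID)
        np.testing.assert_allclose(
            full.drug_nM["plasma"], pk.drug_nM["plasma"], rtol=1e-3
        )
        assert np.max(full.ada_total_nM) < 1e-3

    def test_immune_off_bit_identical_to_pk_only(self, physiology, high_risk_scenario):
        sc = high_risk_scenario
        alleles = tuple(sc.drug.epitopes[0].ranks)[:6]
        off = simulate_subject(
            sc.drug, physiology, sc.regimen, GRID,
            alleles=alleles, immune_enabled=False,
        )
        pk = simulate_pk_only(sc.drug, physiology, sc.regimen, GRID)
        for name in pk.drug_nM:
            np.testing.assert_array_equal(off.drug_nM[name], pk.drug_nM[name])
        assert off.mode == "pk_only"

    def test_drug_complex_mass_balance(self, high_risk_scenario):
        """With zero clearance and no complex elimination, free drug summed
        over compartments plus complexed drug is conserved."""
        sc = high_risk_scenario
        phys = PhysiologyParameters()
        alleles = tuple(sc.drug.epitopes[0].ranks)[:6]
        rates = ImmuneRates(k_ic=0.0)
        grid = np.linspace(50.0, 1000.0, 12)
        full = simulate_subject(
            sc.drug, phys, sc.regimen, grid,
            rates=rates, alleles=alleles, clearance_L_per_h=0.0,
        )
        total = full.total_drug_nmol(phys)
        # doses at 0, 336, 672 have all entered the system by t >= 672 + eps
        from adaqsp.units import mg_to_nmol

        dosed = 3 * sc.drug.bioavailability * mg_to_nmol(100.0, 150_000.0)
        late = total[grid >= 900.0]
        assert np.all(np.abs(late - dosed) / dosed <= 1e-6)
        assert np.max(full.complex_nM) > 0  # binding actually occurred

    def test_all_states_non_negative(self, physiology, high_risk_scenario):
        sc = high_risk_scenario
        alleles = tuple(sc.drug.epitopes[0].ranks)[:6]
        full = simulate_subject(sc.drug, physiology, sc.regimen, GRID, alleles=alleles)
        for series in (*full.drug_nM.values(), *full.cells.values(),
                       full.ada_free_nM, full.complex_nM):
            assert np.all(series >= 0.0)

    def test_mtx_never_increases_ada(self, physiology, high_risk_scenario):
        # moderate DC uptake: the response is well clear of saturation, so
        # the proliferation block is the only pathway MTX can act through
        sc = high_risk_scenario
        drug = sc.drug.model_copy(update={"dc_uptake": 3e-4})
        alleles = tuple(sc.drug.epitopes[0].ranks)[:6]
        mtx_regimen = MtxRegimen(dose_mg=20.0, interval_h=168.0, n_doses=12)
        regimen_mtx = sc.regimen.model_copy(update={"mtx": mtx_regimen})
        ctrl = simulate_subject(drug, physiology, sc.regimen, GRID, alleles=alleles)
        mtx = simulate_subject(
            drug, physiology, regimen_mtx, GRID,
            alleles=alleles, mtx_params=MtxParameters(),
        )
        assert np.max(ctrl.ada_total_nM) > 1.0  # a real response to suppress
        assert np.all(mtx.ada_total_nM <= ctrl.ada_total_nM * (1 + 1e-9) + 1e-12)
        assert np.max(mtx.ada_total_nM) < np.max(ctrl.ada_total_nM)


class TestCalibration:
    @staticmethod
    def _toy_incidence(cfg, k):
        # smooth strictly decreasing toy response
        return 80.0 / (1.0 + k / 5e3)

    def test_target_at_lower_bound_returns_lower_bound(self):
        lo = 1e3
        target = self._toy_incidence(None, lo)
        res = calibrate_k_ag_n(
            [(None, target)], self._toy_incidence, bounds=(lo, 1e5)
        )
        assert isinstance(res, CalibrationResult)
        assert res.k_ag_n == pytest.approx(lo)
        assert res.rmse == pytest.approx(0.0, abs=1e-9)
        assert not res.insensitive

    def test_recovers_interior_optimum(self):
        target = self._toy_incidence(None, 7.3e3)
        res = calibrate_k_ag_n(
            [(None, target)], self._toy_incidence, bounds=(1e3, 1e5)
        )
        assert res.k_ag_n == pytest.approx(7.3e3, rel=0.01)

    def test_insensitive_flag(self):
        res = calibrate_k_ag_n(
            [(None, 10.0)], lambda cfg, k: 42.0, bounds=(1e3, 1e5)
        )
        assert res.insensitive

    def test_rejects_bad_bounds_and_empty_targets(self):
        with pytest.raises(ValueError):
            calibrate_k_ag_n([], self._toy_incidence, bounds=(1.0, 10.0))
        with pytest.raises(ValueError):
            calibrate_k_ag_n(
                [(None, 1.0)], self._toy_incidence, bounds=(10.0, 1.0)
            )
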