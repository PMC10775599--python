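"""Mito-Stress extraction and ATP-budget stoichiometry."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acidflux import bioenergetics as be
from acidflux import synth
from acidflux.assays import flux_normalize
from acidflux.design import ExperimentDesign, GroundTruth


def make_trace(levels, cycles=3):
    phases = [p for p in be.PHASES for _ in range(cycles)]
    ocr = [lv for lv in levels for _ in range(cycles)]
    t = np.arange(1, len(ocr) + 1) * 6.5
    return be.OCRTrace(time_min=t, ocr=np.array(ocr, float), phase=np.array(phases))


class TestExtractMitoParams:
    def test_reference_phase_levels(self):
        """Plateaus (100, 40, 180, 20) force the textbook parameter set."""
        p = be.extract_mito_params(make_trace([100, 40, 180, 20]))
        assert p.non_mito == 20
        assert p.basal == 80
        assert p.proton_leak == 20
        assert p.atp_linked == 60
        assert p.maximal == 160
        assert p.spare == 80
        assert p.coupling_efficiency == pytest.approx(0.75)

    def test_flat_trace_undefined_coupling(self):
        p = be.extract_mito_params(make_trace([50, 50, 50, 50]))
        assert p.basal == 0 and p.spare == 0
        assert math.isnan(p.coupling_efficiency)
        assert "undefined_coupling" in p.flags

    def test_missing_phase_rejected(self):
        t = make_trace([100, 40, 180, 20])
        with pytest.raises(ValueError, match="order"):
            be.OCRTrace(time_min=t.time_min[:9], ocr=t.ocr[:9], phase=t.phase[:9])

    def test_negative_corrected_rate_flagged_not_clamped(self):
        p = be.extract_mito_params(make_trace([100, 40, 30, 20]))  # FCCP below baseline
        assert p.spare == pytest.approx(-70)
        assert "negative_rate" in p.flags

    def test_phase_stat_override(self):
        trace = make_trace([100, 40, 180, 20])
        trace.ocr[2] = 130.0  # last baseline cycle raised
        p_last = be.extract_mito_params(trace)
        p_mean = be.extract_mito_params(trace, {"baseline": "mean"})
        assert p_last.basal == pytest.approx(110)
        assert p_mean.basal == pytest.approx(90)

    def test_monte_carlo_recovery_within_3se(self):
        """Means over 500 single-cycle noisy traces recover the true parameters."""
        design = ExperimentDesign(replicates_per_condition=500, conditions=("ctrl",), seed=42)
        truth = GroundTruth()
        table = synth.generate_ocr_trace(design, truth, cycles_per_phase=1, noise_cv=0.03)
        params = [be.extract_mito_params(t) for t in be.traces_from_table(table)]
        b0, o0, f0, r0 = truth.ocr_levels["ctrl"]
        expected = {"basal": b0 - r0, "atp_linked": b0 - o0,
                    "maximal": f0 - r0, "proton_leak": o0 - r0}
        for name, true_val in expected.items():
            values = np.array([getattr(p, name) for p in params])
            se = values.std(ddof=1) / np.sqrt(len(values))
            assert abs(values.mean() - true_val) < 3 * se, name

    @given(
        levels=st.tuples(
            st.floats(1, 500), st.floats(1, 500), st.floats(1, 500), st.floats(0.5, 100)
        )
    )
    def test_internal_identities_hold_exactly(self, levels):
        """basal = atp_linked + proton_leak and spare = maximal - basal, always."""
        p = be.extract_mito_params(make_trace(list(levels)))
        assert p.basal == pytest.approx(p.atp_linked + p.proton_leak, rel=1e-12, abs=1e-12)
        assert p.spare == pytest.approx(p.maximal - p.basal, rel=1e-12, abs=1e-12)


class TestYields:
    K = be.StoichiometryConstants()

    def test_printed_stoichiometric_yields(self):
        assert be.glycolytic_atp(1.0, self.K) == 2.0
        assert be.max_oxidative_atp_from_glucose(1.0, self.K) == 30.0
        assert be.max_atp_from_glutamine(1.0, self.K) == 10.0
        assert self.K.atp_per_o2 == 5.0

    def test_zero_and_scaling(self):
        assert be.glycolytic_atp(0.0) == 0.0
        assert be.glycolytic_atp(3.25) == pytest.approx(6.5)
        assert be.max_oxidative_atp_from_glucose(0.5) == pytest.approx(15.0)
        assert be.max_atp_from_glutamine(2.3) == pytest.approx(23.0)

    def test_mito_atp_from_ocr(self):
        assert be.mito_atp_from_ocr(1.0) == pytest.approx(5.0)
        assert be.mito_atp_from_ocr(0.0) == 0.0
        with pytest.raises(ValueError):
            be.mito_atp_from_ocr(-1.0)

    @given(g=st.floats(0, 1e6))
    def test_glucose_and_glutamine_stoichiometries_consistent(self, g):
        """6 O2 per fully oxidized glucose: ATP-from-O2 at 6g O2 equals the
        30-ATP glucose yield at g."""
        assert be.mito_atp_from_ocr(6 * g) == pytest.approx(
            be.max_oxidative_atp_from_glucose(g), rel=1e-12
        )

    @given(x=st.floats(0, 1e6), a=st.floats(0, 100))
    def test_yields_linear_homogeneous(self, x, a):
        for f in (be.glycolytic_atp, be.max_oxidative_atp_from_glucose,
                  be.max_atp_from_glutamine, be.mito_atp_from_ocr):
            assert f(a * x) == pytest.approx(a * f(x), rel=1e-9, abs=1e-9)

    def test_glutamine_required(self):
        req = be.glutamine_required(10.0)
        assert req.glutamine_flux == pytest.approx(1.0)
        assert req.o2_flux == pytest.approx(2.0)
        req = be.glutamine_required(5.0, measured_glutamine_flux=0.4)
        assert req.glutamine_flux == pytest.approx(0.5)
        assert req.o2_flux == pytest.approx(1.0)
        assert req.sufficient is False
        assert be.glutamine_required(0.0).glutamine_flux == 0.0


class TestATPBudget:
    def _params(self, atp_linked=0.8, leak=0.2, non_mito=0.5, maximal=4.0):
        basal = atp_linked + leak
        return be.MitoParams(non_mito=non_mito, basal=basal, atp_linked=atp_linked,
                             proton_leak=leak, maximal=maximal, spare=maximal - basal,
                             coupling_efficiency=atp_linked / basal)

    def test_equal_proportions(self):
        # glycolytic 4 needs glucose flux 2 (delta 0.2 mmol/l here);
        # mito 4 needs atp_linked 0.8 at 5 ATP per O2
        g = flux_normalize(0.2, 1e-3, 1000.0, 1e5, substrate="glucose")
        assert g.flux == pytest.approx(2.0)
        budget = be.build_atp_budget(
            g, flux_normalize(0.0, 1e-3, 1000.0, 1e5, substrate="glutamine"),
            self._params(atp_linked=0.8), atp_content=1.0,
        )
        assert budget.glycolytic_atp == pytest.approx(4.0)
        assert budget.mito_atp_from_ocr == pytest.approx(4.0)
        assert budget.fraction_glycolysis == pytest.approx(0.5)
        assert budget.fraction_oxphos == pytest.approx(0.5)

    def test_pure_oxphos(self):
        g = flux_normalize(0.0, 1e-3, 1000.0, 1e5, substrate="glucose")
        gln = flux_normalize(0.0, 1e-3, 1000.0, 1e5, substrate="glutamine")
        budget = be.build_atp_budget(g, gln, self._params(atp_linked=1.2),
                                     atp_content=1.0)
        assert budget.glycolytic_atp == 0.0
        assert budget.mito_atp_from_ocr == pytest.approx(6.0)
        assert budget.fraction_glycolysis == 0.0
        assert budget.fraction_oxphos == 1.0

    def test_missing_inputs_name_the_panel(self):
        g = flux_normalize(1.0, 1e-3, 1000.0, 1e5, substrate="glucose")
        gln = flux_normalize(1.0, 1e-3, 1000.0, 1e5, substrate="glutamine")
        with pytest.raises(ValueError, match="panels 1-3"):
            be.build_atp_budget(None, gln, self._params(), 1.0)
        with pytest.raises(ValueError, match="panels 5-6"):
            be.build_atp_budget(g, None, self._params(), 1.0)
        with pytest.raises(ValueError, match="panel 4"):
            be.build_atp_budget(g, gln, None, 1.0)
        with pytest.raises(ValueError, match="panel 8"):
            be.build_atp_budget(g, gln, self._params(), math.nan)

    def test_budget_conservation(self):
        """total capacity = glycolytic + OCR-derived mitochondrial ATP."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = flux_normalize(rng.uniform(0, 2), 1e-3, 1000.0, 1e5, substrate="glucose")
            gln = flux_normalize(rng.uniform(0, 0.5), 1e-3, 1000.0, 1e5, substrate="glutamine")
            budget = be.build_atp_budget(
                g, gln, self._params(atp_linked=rng.uniform(0.1, 2)), atp_content=1.0
            )
            assert budget.total_atp_capacity == pytest.approx(
                budget.glycolytic_atp + budget.mito_atp_from_ocr, rel=1e-12
            )
            if budget.total_atp_capacity > 0:
                assert budget.fraction_glycolysis + budget.fraction_oxphos == pytest.approx(1.0)

    def test_la_like_condition_glutamine_insufficient(self):
        """Default LA truth: near-zero glucose flux and reduced glutamine leave
        OCR-derived mitochondrial ATP production unfueled."""
        design = ExperimentDesign(seed=0)
        truth = GroundTruth()
        b0, o0, f0, r0 = truth.ocr_levels["LA"]
        params = be.extract_mito_params(make_trace([b0, o0, f0, r0]))
        g = _flux_record(truth, design, "LA", "glucose")
        gln = _flux_record(truth, design, "LA", "glutamine")
        budget = be.build_atp_budget(g, gln, params, atp_content=1.2, condition="LA")
        assert budget.glutamine_sufficient is False
        ctrl_params = be.extract_mito_params(
            make_trace(list(truth.ocr_levels["ctrl"]))
        )
        ctrl_budget = be.build_atp_budget(
            _flux_record(truth, design, "ctrl", "glucose"),
            _flux_record(truth, design, "ctrl", "glutamine"),
            ctrl_params, atp_content=2.0, condition="ctrl",
        )
        assert ctrl_budget.glutamine_sufficient is True


def _flux_record(truth, design, condition, substrate):
    delta = truth.true_delta_mM(design, condition, substrate)
    return flux_normalize(delta, design.volume_l, design.duration_min,
                          design.cells_per_well, substrate=substrate, condition=condition)
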