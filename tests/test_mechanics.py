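import math

import numpy as np
import pytest

from filamech import synthetic, mechanics
from filamech.core_model import FilamentFrame, FilamentEnsemble
from filamech.mechanics import (HelixFit, fit_helix, estimate_twist_rise,
                                crossover_length, persistence_length,
                                flexural_rigidity, mechanics_report,
                                compare_filaments, EstimatorError, HelixFitError)
from filamech.synthetic import HelixParams, FlexParams
from conftest import random_rigid_motion


class TestFitHelix:
    def test_recovers_ideal_parameters(self, template):
        helix = HelixParams(rise_per_subunit=27.5, twist_per_subunit=-166.7,
                            radius=25.0)
        fit = fit_helix(synthetic.build_ideal_filament(template, helix))
        assert fit.twist_per_subunit == pytest.approx(-166.7, abs=1e-6)
        assert fit.rise_per_subunit == pytest.approx(27.5, abs=1e-6)
        assert fit.radius == pytest.approx(25.0, abs=1e-6)
        assert fit.rms_residual < 1e-6

    def test_rigid_motion_invariance(self, ideal_frame):
        rng = np.random.default_rng(31)
        for _ in range(3):
            rot, t = random_rigid_motion(rng)
            fit = fit_helix(ideal_frame.transformed(rot, t))
            assert fit.twist_per_subunit == pytest.approx(-166.7, abs=1e-6)
            assert fit.rise_per_subunit == pytest.approx(27.5, abs=1e-6)

    def test_subunit_order_reversal_preserves_chirality(self, ideal_frame):
        # handedness does not depend on which filament end is traversed first
        rev = FilamentFrame(ideal_frame.coords[::-1], ideal_frame.residue_ids)
        fwd = fit_helix(ideal_frame)
        bwd = fit_helix(rev)
        assert bwd.twist_per_subunit == pytest.approx(fwd.twist_per_subunit, abs=1e-6)
        assert bwd.rise_per_subunit == pytest.approx(fwd.rise_per_subunit, abs=1e-6)
        assert crossover_length(bwd) == pytest.approx(crossover_length(fwd), abs=1e-6)

    def test_too_few_subunits(self, ideal_frame):
        with pytest.raises(HelixFitError):
            fit_helix(FilamentFrame(ideal_frame.coords[:4], ideal_frame.residue_ids))

    def test_estimate_twist_rise_shortcut(self, ideal_frame):
        twist, rise = estimate_twist_rise(ideal_frame)
        assert (twist, rise) == (pytest.approx(-166.7, abs=1e-6),
                                 pytest.approx(27.5, abs=1e-6))


class TestCrossover:
    def test_hand_arithmetic(self):
        # wrap(2 * -166.7) = 26.6 deg; 180/26.6 * 55 = 372.18 A
        fit = HelixFit(np.zeros(3), np.array([0, 0, 1.0]), -166.7, 27.5, 25.0, 0.0)
        assert crossover_length(fit) == pytest.approx(180.0 / 26.6 * 55.0, abs=1e-9)

    def test_untwisted_strands_give_infinity(self):
        fit = HelixFit(np.zeros(3), np.array([0, 0, 1.0]), -180.0, 27.5, 25.0, 0.0)
        assert math.isinf(crossover_length(fit))

    def test_coordinate_estimate_equals_closed_form(self, template):
        for twist in (-170.0, -165.0, -160.0):
            for rise in (25.0, 27.5, 30.0):
                helix = HelixParams(rise_per_subunit=rise, twist_per_subunit=twist)
                frame = synthetic.build_ideal_filament(template, helix)
                measured = crossover_length(fit_helix(frame))
                strand = abs((2 * twist + 180.0) % 360.0 - 180.0)
                closed = 180.0 / strand * 2.0 * rise
                assert measured == pytest.approx(closed, abs=1e-6)


class TestPersistenceLength:
    def test_recovery_at_10um(self, template):
        flex = FlexParams(persistence_length=10.0, n_frames=2000, seed=21)
        ens = synthetic.sample_flexible_ensemble(template, None, flex)
        sv = persistence_length(ens)
        assert sv.mean == pytest.approx(10.0, rel=0.15)
        assert sv.units == "um"

    def test_estimates_ordered_in_stiffness(self, template):
        est = []
        for lp in (1.0, 20.0):
            flex = FlexParams(persistence_length=lp, n_frames=500, seed=22)
            est.append(persistence_length(
                synthetic.sample_flexible_ensemble(template, None, flex)).mean)
        assert est[0] < est[1]

    def test_rigid_ensemble_reports_infinite(self, ideal_frame):
        ens = FilamentEnsemble(np.array(np.broadcast_to(
            ideal_frame.coords, (150,) + ideal_frame.coords.shape)))
        sv = persistence_length(ens)
        assert math.isinf(sv.mean)

    def test_sd_shrinks_with_more_frames(self, template):
        sds = []
        for n_frames in (400, 1600):
            vals = []
            for seed in (40, 41, 42):
                flex = FlexParams(persistence_length=10.0, n_frames=n_frames, seed=seed)
                ens = synthetic.sample_flexible_ensemble(template, None, flex)
                vals.append(persistence_length(ens).sd)
            sds.append(np.median(vals))
        assert sds[1] < sds[0]

    def test_too_few_frames_rejected(self, jittered_ensemble):
        with pytest.raises(EstimatorError):
            persistence_length(jittered_ensemble)  # 60 frames < 100


class TestFlexuralRigidity:
    def test_reference_value(self):
        # Lp = 9.80 um at 310 K
        kappa = flexural_rigidity(9.80, 310.0)
        assert kappa == pytest.approx(9.80e-6 * 1.380649e-23 * 310.0, rel=1e-12)
        assert kappa == pytest.approx(4.194e-26, rel=1e-3)

    def test_linear_in_lp(self):
        assert flexural_rigidity(20.0) == pytest.approx(2 * flexural_rigidity(10.0))

    def test_zero_temperature(self):
        assert flexural_rigidity(10.0, 0.0) == 0.0


class TestCompareFilaments:
    @pytest.fixture(scope="class")
    def reports(self, template):
        out = {}
        for lp, seed in ((5.0, 51), (20.0, 52)):
            flex = FlexParams(persistence_length=lp, n_frames=600, seed=seed)
            ens = synthetic.sample_flexible_ensemble(template, None, flex)
            out[lp] = mechanics_report(ens, n_blocks=20)
        return out

    def test_identical_ensembles_not_significant(self, reports):
        gc = compare_filaments(reports[5.0], reports[5.0])
        assert gc.direction == "ns"

    def test_separated_stiffness_detected_with_direction(self, reports):
        gc = compare_filaments(reports[5.0], reports[20.0])
        assert gc.p_value < 0.01
        assert gc.direction == "a<b"

    def test_reference_record_carries_published_values(self):
        ref = mechanics.REFERENCE_VALUES["persistence_length_um"]
        assert ref["WT"] == (9.80, 0.14)
        assert ref["D286G"] == (17.2, 6.0)
        assert mechanics.REFERENCE_VALUES["crossover_length_A"]["D286G"] == (356.85, 0.71)

    def test_report_structure(self, reports):
        rep = reports[5.0]
        assert rep.n_frames == 600
        assert rep.crossover_length.mean > 0
        assert len(rep.lp_blocks) >= 3
        assert rep.flexural_rigidity == pytest.approx(
            flexural_rigidity(rep.persistence_length.mean), rel=1e-9)
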