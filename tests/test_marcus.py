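import math

import numpy as np
import pytest

from rfpfield.fieldsolver import VacuumChromophore
from rfpfield.fixtures import marcus_fit_inputs
from rfpfield.marcus import (
    DEFAULT_ETA_GRID,
    MarcusConstants,
    MarcusParameters,
    QuadraticFieldFit,
    coefficients_from_parameters,
    coupling_from_prefactor,
    design_surfaces,
    electrostatic_energy,
    eta_scan_fit,
    extract_tict_parameters,
    marcus_rate,
)
from rfpfield.synthetic import SyntheticSpec, synth_marcus_dataset

REF_PARAMS = MarcusParameters(lambda_reorg=21.9, dx=6.7, dy=-0.67, B=1.5e9,
                              eta=-0.1)
REF_CONST = MarcusConstants()


class TestElectrostaticEnergy:
    def test_zero_field_variable(self):
        assert electrostatic_energy(0.0, 0.0, 1.54e-10, 6.7, -0.1) == 0.0

    def test_dsred2_like_value(self):
        # Ex + eta*Ey = 9.9 - 0.1*57 = 4.2 MV/cm
        du = electrostatic_energy(9.9, 57.0, 1.54e-10, 6.7, -0.1)
        assert du == pytest.approx(-2.08, abs=0.01)

    def test_sign_stabilizes_ct_state(self):
        assert electrostatic_energy(10.0, 5.0, 1.54e-10, 6.7, -0.1) < 0


class TestMarcusRate:
    def test_activationless_maximum(self):
        assert marcus_rate(-21.9, 21.9, 1.5e9, 298.15) == pytest.approx(1.5e9)

    def test_dsred2_forward_prediction(self):
        """Reference parameters reproduce the measured nonradiative rate of
        the brightest protein to ~1%."""
        du = electrostatic_energy(9.9, 57.0, REF_CONST.q, REF_PARAMS.dx,
                                  REF_PARAMS.eta)
        k = marcus_rate(REF_CONST.dG_vac + du, REF_PARAMS.lambda_reorg,
                        REF_PARAMS.B, REF_CONST.T)
        assert k == pytest.approx(9.7e7, rel=0.02)
        assert k == pytest.approx(0.099e9, rel=0.05)  # measured kNR

    def test_inverted_region(self):
        lam = 21.9
        normal = marcus_rate(-lam, lam, 1e9, 298.15)
        inverted = marcus_rate(-lam - 10.0, lam, 1e9, 298.15)
        more_inverted = marcus_rate(-lam - 20.0, lam, 1e9, 298.15)
        assert normal > inverted > more_inverted

    @pytest.mark.parametrize("lam,b", [(0.0, 1e9), (-1.0, 1e9), (21.9, 0.0)])
    def test_invalid_inputs(self, lam, b):
        with pytest.raises(ValueError):
            marcus_rate(-7.9, lam, b, 298.15)


class TestEtaScan:
    def test_reference_dataset_selects_minus_point_one(self, fx):
        best, scan = eta_scan_fit(marcus_fit_inputs(fx))
        assert best.eta == pytest.approx(-0.1)
        assert len(scan) == len(DEFAULT_ETA_GRID)
        assert all(f.rss >= best.rss for f in scan)

    def test_coefficients_match_polyfit_oracle(self, fx):
        best, _ = eta_scan_fit(marcus_fit_inputs(fx))
        x = np.array([p[0] for p in best.points])
        y = np.array([p[1] for p in best.points])
        c2, c1, c0 = np.polyfit(x, y, 2)
        assert best.b0 == pytest.approx(c0, rel=1e-9)
        assert best.b1 == pytest.approx(c1, rel=1e-9)
        assert best.b2 == pytest.approx(c2, rel=1e-9)

    def test_refit_stored_points_reproduces_coefficients(self, fx):
        best, _ = eta_scan_fit(marcus_fit_inputs(fx))
        x = np.array([p[0] for p in best.points])
        y = np.array([p[1] for p in best.points])
        design = np.vstack([np.ones_like(x), x, x * x]).T
        coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
        np.testing.assert_allclose(coeffs, [best.b0, best.b1, best.b2],
                                   rtol=1e-12, atol=1e-12)

    def test_noiseless_synthetic_interpolated_exactly(self):
        spec = SyntheticSpec(seed=5, noise_ln_sigma=0.0)
        ex, ey, knr = synth_marcus_dataset(spec)
        best, _ = eta_scan_fit(list(zip(knr, ex, ey)))
        assert best.eta == pytest.approx(-0.1)
        assert best.rss < 1e-18
        b_true = coefficients_from_parameters(spec.true_params, spec.constants)
        assert best.b0 == pytest.approx(b_true[0], rel=1e-9)
        assert best.b1 == pytest.approx(b_true[1], rel=1e-9)
        assert best.b2 == pytest.approx(b_true[2], rel=1e-9)

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            eta_scan_fit([(0.1, 10, 30)] * 3)

    def test_degenerate_design_rejected(self):
        pts = [(0.1, 10.0, 30.0), (0.2, 10.0, 30.0),
               (0.3, 10.0, 30.0), (0.4, 10.0, 30.0)]
        with pytest.raises(ValueError, match="degenerate"):
            eta_scan_fit(pts)

    def test_nonpositive_rate_rejected(self):
        pts = [(0.1, 10, 30), (-0.2, 12, 40), (0.3, 14, 50), (0.4, 16, 55)]
        with pytest.raises(ValueError):
            eta_scan_fit(pts)


class TestExtraction:
    def test_reference_coefficients_recover_reference_parameters(self):
        """The published coefficient triple inverts to the published
        (lambda, dx, B)."""
        fit = QuadraticFieldFit(eta=-0.1, b0=17.35, b1=0.2673, b2=-0.004729,
                                rss=0.0, points=())
        p = extract_tict_parameters(fit, REF_CONST)
        assert p.lambda_reorg == pytest.approx(21.9, rel=0.01)
        assert p.dx == pytest.approx(6.7, rel=0.01)
        assert p.dy == pytest.approx(-0.67, rel=0.01)
        assert p.B == pytest.approx(1.5e9, rel=0.05)

    def test_round_trip_exact(self):
        b0, b1, b2 = coefficients_from_parameters(REF_PARAMS, REF_CONST)
        fit = QuadraticFieldFit(eta=-0.1, b0=b0, b1=b1, b2=b2, rss=0.0,
                                points=())
        p = extract_tict_parameters(fit, REF_CONST)
        assert p.lambda_reorg == pytest.approx(21.9, rel=1e-9)
        assert p.dx == pytest.approx(6.7, rel=1e-9)
        assert p.B == pytest.approx(1.5e9, rel=1e-9)

    def test_zero_vacuum_free_energy_closed_form(self):
        """With dG_vac = 0 the u-quadratic loses its constant term and
        dx = 2 kB T b1 / q exactly."""
        const = MarcusConstants(dG_vac=0.0)
        b0, b1, b2 = coefficients_from_parameters(
            MarcusParameters(lambda_reorg=20.0, dx=6.0, dy=-0.6, B=1e9,
                             eta=-0.1),
            const,
        )
        p = extract_tict_parameters(
            QuadraticFieldFit(eta=-0.1, b0=b0, b1=b1, b2=b2, rss=0.0,
                              points=()),
            const,
        )
        mvcm = 1e6 / 299.792458
        dx_closed = 2 * const.kBT_erg * b1 / (const.q * mvcm) * 1e8
        assert p.dx == pytest.approx(dx_closed, rel=1e-12)
        assert p.dx == pytest.approx(6.0, rel=1e-9)

    def test_positive_curvature_rejected(self):
        fit = QuadraticFieldFit(eta=-0.1, b0=17.0, b1=0.2, b2=0.001,
                                rss=0.0, points=())
        with pytest.raises(ValueError, match="unidentifiable"):
            extract_tict_parameters(fit, REF_CONST)

    def test_negative_discriminant_reports_roots(self):
        # an endergonic vacuum step with strong curvature has no real root
        fit = QuadraticFieldFit(eta=-0.1, b0=17.0, b1=0.01, b2=-0.05,
                                rss=0.0, points=())
        with pytest.raises(ValueError, match="discriminant"):
            extract_tict_parameters(fit, MarcusConstants(dG_vac=7.9))

    def test_negative_root_reported_in_diagnostics(self):
        fit = QuadraticFieldFit(eta=-0.1, b0=17.35, b1=0.2673, b2=-0.004729,
                                rss=0.0, points=())
        p = extract_tict_parameters(fit, REF_CONST)
        assert p.u_roots[0] > 0 > p.u_roots[1]


class TestCoupling:
    def test_inverse_pair(self):
        v_erg, _ = coupling_from_prefactor(1.5e9, 21.9, 298.15)
        # substitute back: B = 4 pi^2 V^2 / (h sqrt(4 pi kBT lambda))
        from rfpfield.units import CONSTANTS, thermal_energy
        lam_erg = 21.9 * CONSTANTS.kcal_per_mol_in_erg
        b_back = (4 * math.pi ** 2 / CONSTANTS.h) * v_erg ** 2 \
            / math.sqrt(4 * math.pi * thermal_energy(298.15).erg * lam_erg)
        assert b_back == pytest.approx(1.5e9, rel=1e-9)

    def test_sqrt_scaling(self):
        v1, _ = coupling_from_prefactor(1.5e9, 21.9, 298.15)
        v4, _ = coupling_from_prefactor(6.0e9, 21.9, 298.15)
        assert v4 == pytest.approx(2 * v1, rel=1e-12)

    def test_boundary(self):
        with pytest.raises(ValueError):
            coupling_from_prefactor(0.0, 21.9, 298.15)


class TestDesignSurfaces:
    KR_MEAN = 0.158e9

    def _surfaces(self, ex, ey):
        return design_surfaces(np.asarray(ex), np.asarray(ey), REF_PARAMS,
                               REF_CONST, self.KR_MEAN, VacuumChromophore())

    def test_dsred2_quantum_yield(self):
        grids = self._surfaces([9.9], [57.0])
        assert grids["phi"][0, 0] == pytest.approx(0.62, abs=0.02)

    def test_strong_negative_ex_saturates_quantum_yield(self):
        grids = self._surfaces([-60.0, -40.0], [0.0, 30.0, 57.0])
        assert np.all(grids["phi"] > 0.999)

    def test_phi_monotone_then_inverted_along_ex(self):
        ex = np.linspace(-20.0, 120.0, 141)
        grids = self._surfaces(ex, [40.0])
        phi = grids["phi"][0]
        imin = int(np.argmin(phi))
        assert 0 < imin < len(ex) - 1
        assert np.all(np.diff(phi[: imin + 1]) <= 1e-15)  # normal region
        assert np.all(np.diff(phi[imin:]) >= -1e-15)      # inverted region

    def test_nodes_are_pure_functions(self):
        big = self._surfaces([0.0, 10.0, 20.0], [30.0, 50.0])
        single = self._surfaces([10.0], [50.0])
        for key in ("phi", "nu_shift", "brightness2p"):
            assert big[key][1, 1] == pytest.approx(single[key][0, 0], rel=1e-12)

    def test_brightness_is_dmu2_times_phi(self):
        grids = self._surfaces([5.0, 15.0], [20.0, 40.0])
        np.testing.assert_allclose(grids["brightness2p"],
                                   grids["dmu2"] * grids["phi"], rtol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            self._surfaces([np.inf], [0.0])
        with pytest.raises(ValueError):
            design_surfaces(np.array([0.0]), np.array([0.0]), REF_PARAMS,
                            REF_CONST, 0.0, VacuumChromophore())
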