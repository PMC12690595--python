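import math

import numpy as np
import pytest

from ffcondense.energy import (
    ClassIAngleParam,
    ClassIBondParam,
    ClassITorsionParam,
    ClassIIBendParam,
    ClassIIStretchBendParam,
    ClassIIStretchParam,
    ClassIITorsionParam,
    DroppedInteraction,
    EngineConfig,
    EnergyBreakdown,
    OutOfPlaneParam,
    ParameterSet,
    total_energy,
    u_angle_I,
    u_bend_II,
    u_bond_I,
    u_buf_14_7,
    u_coulomb_I,
    u_coulomb_II,
    u_lj,
    u_oop,
    u_stretch_II,
    u_stretch_bend,
    u_torsion_I,
    u_torsion_II,
)
from ffcondense.errors import ConsistencyError
from ffcondense.topology import Conformer, InternalCoordinateIndex, enumerate_internals


class TestClassITerms:
    def test_bond_hand_values(self):
        p = ClassIBondParam(k_r=2.0, r0=1.5)
        assert u_bond_I(1.5, p) == 0.0
        assert u_bond_I(2.0, p) == pytest.approx(0.25)
        assert u_bond_I(1.5 + 0.3, p) == pytest.approx(u_bond_I(1.5 - 0.3, p))

    def test_angle_hand_values(self):
        p = ClassIAngleParam(k_theta=1.0, theta0=math.pi / 2)
        assert u_angle_I(math.pi / 2, p) == 0.0
        assert u_angle_I(math.pi, p) == pytest.approx(math.pi**2 / 8)

    def test_torsion_series(self):
        p = ClassITorsionParam(k_phi=(1.0,), phi0=0.3)
        assert u_torsion_I(0.3, p) == pytest.approx(2.0)
        assert u_torsion_I(0.3 + math.pi, p) == pytest.approx(0.0)

    def test_torsion_periodicity(self, rng):
        for _ in range(20):
            p = ClassITorsionParam(
                k_phi=tuple(rng.uniform(0, 3, size=int(rng.integers(1, 6)))),
                phi0=float(rng.uniform(-math.pi, math.pi)),
            )
            phi = float(rng.uniform(-math.pi, math.pi))
            assert u_torsion_I(phi, p) == pytest.approx(
                u_torsion_I(phi + 2 * math.pi, p), abs=1e-10
            )

    def test_coulomb(self):
        cfg = EngineConfig(coulomb_constant=1.0)
        assert u_coulomb_I(1.0, 0.0, 1.0, cfg) == 0.0
        assert u_coulomb_I(2.0, 1.0, 1.0, cfg) == pytest.approx(0.5)
        assert u_coulomb_I(2.0, -1.0, 1.0, cfg) == pytest.approx(-0.5)

    def test_lj_minimum_and_asymptotics(self):
        assert u_lj(3.4, 3.4, 0.5) == pytest.approx(0.0)
        rmin = 2 ** (1 / 6) * 3.4
        assert u_lj(rmin, 3.4, 0.5) == pytest.approx(-0.5)
        assert -1e-6 < u_lj(100.0, 3.4, 0.5) < 0.0


class TestClassIITerms:
    def test_stretch_hand_value(self):
        p = ClassIIStretchParam(k_r=2.0, r0=1.0, cs=-2.0)
        assert u_stretch_II(1.1, p) == pytest.approx(0.0082333333333333, rel=1e-12)
        assert u_stretch_II(1.0, p) == 0.0

    def test_stretch_literal_form_differs(self):
        p = ClassIIStretchParam(k_r=2.0, r0=1.0, cs=-2.0)
        assert u_stretch_II(1.1, p, form="literal") == pytest.approx(
            0.0046694444444444, rel=1e-12
        )

    def test_bend_hand_value(self):
        p = ClassIIBendParam(k_theta=1.0, theta0=2.0, cb=-0.4)
        assert u_bend_II(2.5, p) == pytest.approx(0.1)
        assert u_bend_II(2.0, p) == 0.0

    def test_stretch_bend_cancellations(self):
        p = ClassIIStretchBendParam(1.0, 1.0, 1.5, 1.5, 2.0)
        assert u_stretch_bend(1.5, 1.5, 2.7, p) == 0.0
        assert u_stretch_bend(1.9, 1.2, 2.0, p) == 0.0
        assert u_stretch_bend(1.6, 1.4, 2.5, p) == pytest.approx(0.0)  # +0.1/-0.1

    def test_torsion_hand_values(self):
        p = ClassIITorsionParam(k1=1.5, k2=0.0, k3=0.0, phi0=0.2)
        assert u_torsion_II(0.2 + math.pi, p) == pytest.approx(0.0)
        p2 = ClassIITorsionParam(k1=1.5, k2=0.7, k3=0.3, phi0=0.2)
        assert u_torsion_II(0.2, p2) == pytest.approx(2 * 1.5 + 2 * 0.3)

    def test_oop_hand_value(self):
        p = OutOfPlaneParam(k_oop=2.0)
        assert u_oop(0.0, p) == 0.0
        assert u_oop(0.1, p) == pytest.approx(0.01)
        assert u_oop(-0.1, p) == pytest.approx(0.01)

    def test_buffered_coulomb(self):
        cfg = EngineConfig(ff_class="II", coulomb_constant=1.0, delta=0.05,
                           scale14_coulomb=0.75, scale14_vdw=1.0)
        assert u_coulomb_II(1.0, 1.0, 1.0, cfg) == pytest.approx(1 / 1.05)

    def test_buf_14_7_minimum_and_hand_value(self):
        assert u_buf_14_7(1.0, 1.0, 1.0) == pytest.approx(-1.0)
        # frozen by exact rational substitution into the closed form
        assert u_buf_14_7(0.5, 1.0, 1.0) == pytest.approx(555.5092844233428, rel=1e-12)
        assert abs(u_buf_14_7(50.0, 1.0, 1.0)) < 1e-9

    def test_buf_14_7_dense_scan_confirms_minimum_location(self):
        # the buffered form (delta=0.07, gamma=0.12) is stationary at
        # rho = 0.9961827, not exactly at rho = 1: the "minimum at r*"
        # convention holds to ~0.4 %, with depth within 0.06 % of eps
        rs = np.linspace(0.8, 1.3, 20001)
        us = [u_buf_14_7(r, 2.0, 1.1) for r in rs]
        i = int(np.argmin(us))
        assert rs[i] == pytest.approx(0.996182687569541 * 1.1, abs=1e-4)
        assert rs[i] == pytest.approx(1.1, rel=4e-3)
        assert us[i] == pytest.approx(-2.0, rel=1e-3)
        assert u_buf_14_7(1.1, 2.0, 1.1) == pytest.approx(-2.0, rel=1e-14)


class TestReductionLimits:
    """Class II reduces term-by-term to Class I at cs = cb = delta = 0."""

    def test_stretch_bend_coulomb_reduce(self, rng):
        cfg1 = EngineConfig(ff_class="I", coulomb_constant=138.935458)
        cfg2 = EngineConfig(
            ff_class="II", coulomb_constant=138.935458, delta=0.0,
            scale14_coulomb=0.75, scale14_vdw=1.0,
        )
        for _ in range(1000):
            k, r0 = rng.uniform(100, 4000), rng.uniform(0.8, 2.0)
            r = r0 * rng.uniform(0.7, 1.4)
            assert u_stretch_II(r, ClassIIStretchParam(k, r0, cs=0.0)) == pytest.approx(
                u_bond_I(r, ClassIBondParam(k, r0)), abs=1e-12, rel=1e-12
            )
            kt, t0 = rng.uniform(50, 800), rng.uniform(1.0, math.pi)
            t = float(np.clip(t0 + rng.uniform(-0.5, 0.5), 0.05, math.pi))
            assert u_bend_II(t, ClassIIBendParam(kt, t0, cb=0.0)) == pytest.approx(
                u_angle_I(t, ClassIAngleParam(kt, t0)), abs=1e-12, rel=1e-12
            )
            q1, q2, rr = rng.uniform(-1, 1), rng.uniform(-1, 1), rng.uniform(1, 8)
            assert u_coulomb_II(rr, q1, q2, cfg2) == pytest.approx(
                u_coulomb_I(rr, q1, q2, cfg1), abs=1e-12, rel=1e-12
            )

    def test_torsion_reduces_for_single_cosine(self, rng):
        # k2 = k3 = 0 matches the n_max = 1 Class I series exactly
        for _ in range(100):
            k1 = float(rng.uniform(0, 5))
            phi0 = float(rng.uniform(-math.pi, math.pi))
            phi = float(rng.uniform(-math.pi, math.pi))
            assert u_torsion_II(phi, ClassIITorsionParam(k1, 0, 0, phi0)) == pytest.approx(
                u_torsion_I(phi, ClassITorsionParam((k1,), phi0)), abs=1e-12
            )


class TestTotalEnergy:
    def test_diatomic_at_equilibrium_is_zero(self, toy):
        mol, conf, internals, ps = toy("diatomic")
        e, bd = total_energy(conf, ps, internals)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_dropped_bond_contributes_nothing(self, toy):
        mol, conf, internals, ps = toy("diatomic")
        stretched = Conformer(conf.coords * 1.3)
        ps.dropped.append(DroppedInteraction("bond", (0, 1)))
        del ps.bond[(0, 1)]
        e, bd = total_energy(stretched, ps, internals)
        assert e == 0.0
        assert bd.n_dropped == 1

    def test_missing_parameter_is_consistency_error(self, toy):
        mol, conf, internals, ps = toy("diatomic")
        del ps.bond[(0, 1)]
        with pytest.raises(ConsistencyError):
            total_energy(conf, ps, internals)

    @pytest.mark.parametrize("ff", ["I", "II"])
    def test_breakdown_sums_to_total(self, toy, ff, rng):
        from ffcondense.fixtures import perturb_conformer

        mol, conf, internals, ps = toy("butane", ff)
        pc = perturb_conformer(conf, 0.1, 5)
        e, bd = total_energy(pc, ps, internals)
        assert e == bd.total()  # bitwise, same accumulation order
        assert set(bd.terms) == set(EnergyBreakdown.CATEGORIES)

    @pytest.mark.parametrize("ff", ["I", "II"])
    @pytest.mark.parametrize("kind", ["butane", "ethane", "trigonal_center"])
    def test_rigid_motion_invariance(self, toy, ff, kind, rng):
        from scipy.spatial.transform import Rotation

        mol, conf, internals, ps = toy(kind, ff)
        e0, _ = total_energy(conf, ps, internals)
        for _ in range(5):
            rot = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
            shift = rng.standard_normal(3) * 10
            moved = Conformer(conf.coords @ rot.T + shift)
            e1, _ = total_energy(moved, ps, internals)
            assert abs(e1 - e0) < 1e-9

    def test_total_matches_sum_of_term_functions_on_butane(self, toy):
        """Term-by-term oracle: independently evaluate each interaction."""
        from ffcondense.fixtures import perturb_conformer
        from ffcondense.topology import measure
        from ffcondense.energy import nonbonded_pairs

        mol, conf, internals, ps = toy("butane")
        pc = perturb_conformer(conf, 0.12, 9)
        expected = 0.0
        for t in internals.bonds:
            expected += u_bond_I(measure(pc, "distance", t), ps.bond[t])
        for t in internals.angles:
            expected += u_angle_I(measure(pc, "angle", t), ps.angle[t])
        for t in internals.propers:
            expected += u_torsion_I(measure(pc, "dihedral", t), ps.torsion[t])
        for i, j, sep in nonbonded_pairs(4, internals.bonds):
            s = ps.config.scale14_vdw if sep == 4 else 1.0
            sigma = 0.5 * (ps.sigma[i] + ps.sigma[j])
            eps = math.sqrt(ps.epsilon[i] * ps.epsilon[j])
            expected += s * u_lj(measure(pc, "distance", (i, j)), sigma, eps)
        e, _ = total_energy(pc, ps, internals)
        assert e == pytest.approx(expected, rel=1e-12)


class TestParameterSetIO:
    @pytest.mark.parametrize("ff", ["I", "II"])
    def test_json_roundtrip(self, toy, tmp_path, ff):
        mol, conf, internals, ps = toy("trigonal_center", ff)
        p = tmp_path / "ps.json"
        ps.to_json(str(p))
        ps2 = ParameterSet.from_json(str(p))
        assert ps2.bond == ps.bond
        assert ps2.angle == ps.angle
        assert ps2.torsion == ps.torsion
        assert ps2.oop == ps.oop
        assert ps2.config == ps.config
        np.testing.assert_array_equal(ps2.charges, ps.charges)
        e1, _ = total_energy(conf, ps, internals)
        e2, _ = total_energy(conf, ps2, internals)
        assert e1 == e2
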