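"""Beam solver: section geometry, elastic oracles, plasticity, load/unload
hysteresis, limiting-speed search and plastic-strain localization."""

import numpy as np
import pytest

from lodgesim import stemfe as fe
from lodgesim.morphotypes import Internode, Panicle, PlantMorphology
from lodgesim.windload import LoadSet, WindCase, build_loadset


def _tip_load_model(cards, L=300.0, r=1.5, t=0.5, P=2000.0, n_elem=12, **kw):
    pith, shell = cards["oat"]
    return fe.make_prismatic_model(
        L, r, t, shell, pith, n_elem=n_elem,
        loadset=LoadSet(W_u=0.0, F_w0=P, M_w0=0.0, G=0.0), **kw,
    )


def _section_EI(model):
    sec = model.sections[0]
    return float((sec.E_fib * sec.area_fib * sec.y**2).sum())


class TestSectionGeometry:
    def test_solid_section_area(self, cards):
        pith, shell = cards["oat"]
        sec = fe._build_section(1.3, 1.3, shell, None)
        assert sec.area == pytest.approx(np.pi * 1.3**2, rel=5e-3)

    def test_fiber_areas_tile_exactly(self, cards):
        pith, shell = cards["oat"]
        sec = fe._build_section(1.5, 0.5, shell, pith)
        assert sec.area == pytest.approx(np.pi * 1.5**2, rel=1e-12)

    def test_hollow_second_moment_closed_form(self, cards):
        # shell-annulus fiber I vs pi (r^4 - (r-t)^4) / 4 within 1%
        pith, shell = cards["oat"]
        r, t = 1.5, 0.5
        sec = fe._build_section(r, t, shell, pith)
        I_shell = float((sec.area_fib * sec.y**2)[sec.is_shell].sum())
        I_cf = np.pi / 4 * (r**4 - (r - t) ** 4)
        assert I_shell == pytest.approx(I_cf, rel=0.01)

    def test_hollow_needs_pith_card(self, cards):
        _, shell = cards["oat"]
        with pytest.raises(ValueError, match="pith card"):
            fe._build_section(1.5, 0.5, shell, None)

    def test_thickness_bounds(self, cards):
        pith, shell = cards["oat"]
        with pytest.raises(ValueError, match="t <= r"):
            fe._build_section(1.0, 1.2, shell, pith)


class TestElasticOracles:
    def test_tip_deflection_euler_bernoulli(self, cards):
        # slenderness L/r = 200 >> 20: PL^3 / 3EI within 1%
        model = _tip_load_model(cards)
        d, _, _ = fe.solve_quasistatic(model, [(0.0, 0.0), (1.0, 1.0)])
        w_cf = 2000.0 * 300.0**3 / (3.0 * _section_EI(model))
        assert d[-3] == pytest.approx(w_cf, rel=0.01)

    def test_tip_moment_oracle(self, cards):
        # pure tip moment M: rotation M L / EI, deflection M L^2 / 2EI
        pith, shell = cards["oat"]
        M = 5.0e4
        model = fe.make_prismatic_model(
            300.0, 1.5, 0.5, shell, pith, n_elem=12,
            loadset=LoadSet(W_u=0.0, F_w0=0.0, M_w0=M, G=0.0),
        )
        d, _, _ = fe.solve_quasistatic(model, [(0.0, 0.0), (1.0, 1.0)])
        EI = _section_EI(model)
        # applied tip moment is -M (downwind bending): deflection +x
        assert d[-3] == pytest.approx(M * 300.0**2 / (2 * EI), rel=0.01)
        assert abs(d[-1]) == pytest.approx(M * 300.0 / EI, rel=0.01)

    def test_uniform_load_oracle(self, cards):
        # self-weight bending of a horizontal beam is not modeled; check the
        # distributed-gravity axial shortening instead: q L^2 / 2EA
        pith, shell = cards["oat"]
        model = fe.make_prismatic_model(
            300.0, 1.5, 0.5, shell, pith, n_elem=12,
            loadset=LoadSet(W_u=0.0, F_w0=0.0, M_w0=0.0, G=3e-4 * 9810.0),
        )
        d, _, _ = fe.solve_quasistatic(model, [(0.0, 0.0), (1.0, 0.0)])
        sec = model.sections[0]
        EA = float((sec.E_fib * sec.area_fib).sum())
        q = 3e-4 * 9810.0 * np.pi * 1.5**2
        assert -d[-2] == pytest.approx(q * 300.0**2 / (2 * EA), rel=0.02)

    def test_mesh_convergence(self, cards):
        tips = []
        for n in (8, 16):
            model = _tip_load_model(cards, n_elem=n)
            d, _, _ = fe.solve_quasistatic(model, [(0.0, 0.0), (1.0, 1.0)])
            tips.append(d[-3])
        assert abs(tips[1] / tips[0] - 1.0) < 0.005

    def test_zero_load_zero_displacement(self, cards):
        model = _tip_load_model(cards, P=0.0)
        d, _, _ = fe.solve_quasistatic(model, [(0.0, 0.0), (1.0, 1.0)])
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_path_independence_elastic(self, cards):
        model = _tip_load_model(cards, P=5000.0)
        schedules = []
        for n in (5, 50):
            lam = np.linspace(0.0, 1.0, n + 1)
            schedules.append([(0.0, 0.0)] + [(1.0, l) for l in lam[1:]])
        d5, _, _ = fe.solve_quasistatic(model, schedules[0])
        d50, _, _ = fe.solve_quasistatic(model, schedules[1])
        assert np.linalg.norm(d5 - d50) <= 1e-6 * max(np.linalg.norm(d50), 1e-12)

    def test_tangent_consistency(self, cards):
        # finite-difference check of the assembled tangent at a bent state
        model = _tip_load_model(cards, n_elem=3)
        state = fe._State(model)
        rng = np.random.default_rng(0)
        d = np.zeros(3 * model.n_nodes)
        free = np.arange(3, len(d))
        d[free] = rng.normal(0.0, 2.0, len(free))
        F0, K0 = fe._assemble(model, d, state)
        eps = 1e-6
        for j in free[:6]:
            dp = d.copy()
            dp[j] += eps
            Fp, _ = fe._assemble(model, dp, state)
            fd = (Fp - F0) / eps
            assert np.allclose(fd, K0[:, j], atol=1e-4 * np.abs(K0).max())


class TestLoadUnload:
    def test_elastic_full_recovery(self, cards, mean_plants):
        # any speed below first yield: u_res < 1e-6 u_max and zero PEMAG
        pith, shell = cards["oat"]
        case = WindCase.from_m_s(4.0)
        model = fe.build_stem_model(
            mean_plants["oat"], pith, shell,
            loadset=build_loadset(mean_plants["oat"], case),
        )
        res = fe.simulate_load_unload(model, case)
        assert res.u_max > 0
        assert res.u_res < 1e-6 * res.u_max
        assert np.all(res.pemag == 0.0)

    def test_hysteresis_closes_elastically(self, cards, mean_plants):
        pith, shell = cards["oat"]
        case = WindCase.from_m_s(4.0)
        model = fe.build_stem_model(
            mean_plants["oat"], pith, shell,
            loadset=build_loadset(mean_plants["oat"], case),
        )
        res = fe.simulate_load_unload(model, case)
        gap = np.linalg.norm(res.tip_path[-1])
        assert gap < 1e-6 * res.u_max

    def test_plasticity_engaged_above_yield(self, cards, mean_plants):
        pith, shell = cards["oat"]
        case = WindCase.from_m_s(9.0)  # above the oat limiting speed
        model = fe.build_stem_model(
            mean_plants["oat"], pith, shell,
            loadset=build_loadset(mean_plants["oat"], case),
        )
        res = fe.simulate_load_unload(model, case)
        assert res.u_res > 0
        assert res.pemag.max() > 0
        assert res.u_res <= res.u_max + 1e-9

    def test_energy_balance(self, limit_results):
        # net external work = plastic work + residual stored energy (2%)
        for crop, res in limit_results.items():
            e = res.energy
            gap = abs(e["external_work"] - e["plastic_dissipation"]
                      - e["residual_elastic_energy"])
            assert gap <= 0.02 * e["external_work"], crop

    def test_schedule_must_start_at_zero(self, cards):
        model = _tip_load_model(cards)
        with pytest.raises(ValueError, match="zero load"):
            fe.solve_quasistatic(model, [(1.0, 0.0), (1.0, 1.0)])


class TestResidualRatio:
    def test_arithmetic(self, limit_results):
        res = limit_results["oat"]
        assert fe.residual_ratio(res) == pytest.approx(res.u_res / res.u_max)

    def test_undefined_at_zero_umax(self, limit_results):
        import dataclasses

        res = dataclasses.replace(limit_results["oat"], u_max=0.0, u_res=0.0)
        with pytest.raises(ValueError, match="u_max"):
            fe.residual_ratio(res)

    def test_elastic_sweep_identically_zero(self, sweeps):
        for crop in ("oat", "wheat"):
            curve = sweeps[crop].curve
            below = curve[curve[:, 0] <= 5.0]
            assert np.all(below[:, 1] < 1e-6)


class TestLimitingSpeed:
    def test_crop_limiting_speeds(self, sweeps):
        # oat fails near 8 m/s and wheat near 10 m/s at threshold 0.3
        assert sweeps["oat"].reached and sweeps["wheat"].reached
        assert sweeps["oat"].v_limit_m_s == pytest.approx(8.0, abs=0.5)
        assert sweeps["wheat"].v_limit_m_s == pytest.approx(10.0, abs=0.5)

    def test_crop_ordering(self, sweeps):
        assert sweeps["wheat"].v_limit_m_s > sweeps["oat"].v_limit_m_s

    def test_ratio_monotone_with_unique_crossing(self, sweeps):
        for crop in ("oat", "wheat"):
            curve = sweeps[crop].curve
            order = np.argsort(curve[:, 0])
            ratios = curve[order, 1]
            assert np.all(np.diff(ratios) >= -1e-6)
            crossings = np.sum(
                (ratios[:-1] < 0.3) & (ratios[1:] >= 0.3)
            )
            assert crossings == 1

    def test_wheat_recovers_better_at_common_speed(self, cards, mean_plants):
        u_res = {}
        for crop in ("oat", "wheat"):
            pith, shell = cards[crop]
            case = WindCase.from_m_s(8.5)
            model = fe.build_stem_model(
                mean_plants[crop], pith, shell,
                loadset=build_loadset(mean_plants[crop], case),
            )
            res = fe.simulate_load_unload(model, case, record_profiles=False)
            u_res[crop] = res.u_res
        assert u_res["wheat"] < u_res["oat"]

    def test_elastic_material_never_reaches_threshold(self, cards, mean_plants):
        # scale strengths far above any achievable stress: purely elastic
        import dataclasses

        pith, shell = cards["oat"]
        strong = lambda card: dataclasses.replace(
            card, strength=dataclasses.replace(
                card.strength,
                sigma11=card.strength.sigma11 * 1e4,
                sigma22=card.strength.sigma22 * 1e4,
                sigma33=card.strength.sigma33 * 1e4,
            )
        )
        res = fe.limiting_wind_speed(
            mean_plants["oat"], strong(pith), strong(shell),
            grid=2.0, v_max=10.0,
        )
        assert not res.reached
        assert res.v_limit_m_s is None

    def test_invalid_arguments(self, cards, mean_plants):
        pith, shell = cards["oat"]
        with pytest.raises(ValueError, match="threshold"):
            fe.limiting_wind_speed(mean_plants["oat"], pith, shell, threshold=1.5)


class TestLocalization:
    def _synthetic_result(self, diss, midheights, joint, length):
        return fe.SimResult(
            u_max=1.0, u_res=0.5, tip_path=np.zeros((1, 2)),
            deformed_profiles={}, pemag=np.zeros((len(diss), 2)),
            dissipation_per_element=np.asarray(diss, dtype=float),
            converged=True, element_midheights=np.asarray(midheights, dtype=float),
            joint_height=joint, model_length=length,
        )

    def test_all_dissipation_in_window(self):
        res = self._synthetic_result([0, 0, 1.0, 0], [10, 50, 95, 150], 100.0, 200.0)
        assert fe.localization_index(res, window=0.10) == pytest.approx(1.0)

    def test_uniform_dissipation_equals_window_fraction(self):
        n = 200
        mids = np.linspace(0.5, 199.5, n)
        res = self._synthetic_result(np.ones(n), mids, 100.0, 200.0)
        assert fe.localization_index(res, window=0.10) == pytest.approx(0.10, abs=0.01)

    def test_no_plasticity_zero_index(self):
        res = self._synthetic_result([0.0, 0.0], [50, 150], 100.0, 200.0)
        assert fe.localization_index(res) == 0.0

    def test_oat_localizes_more_than_wheat(self, limit_results):
        # hollow, soft-pith oat concentrates damage just below the node;
        # solid-pith wheat spreads it along the first internode
        li = {crop: fe.localization_index(res) for crop, res in limit_results.items()}
        assert li["oat"] > li["wheat"]


class TestExtendProfile:
    def test_straight_extension_along_tangent(self):
        prof = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        out = fe.extend_profile(prof, np.sqrt(2.0), n_points=1)
        assert np.allclose(out[-1], [3.0, 3.0])

    def test_zero_extension_is_identity(self):
        prof = np.array([[0.0, 0.0], [1.0, 2.0]])
        assert np.array_equal(fe.extend_profile(prof, 0.0), prof)
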