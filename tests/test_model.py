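"""Energy terms, relaxation, linker gradients and expansion dynamics."""

import math

import numpy as np
import pytest

import blebsim as bs
from blebsim.model import _energy, _grad


class TestInitialization:
    def test_cortex_is_inward_offset_circle(self, circle_contour, params):
        state = bs.initialize_model(circle_contour, params)
        radii = np.linalg.norm(state.cortex.nodes, axis=1)
        np.testing.assert_allclose(radii, 5.0 - 0.03, rtol=1e-4)
        np.testing.assert_allclose(state.linkers.lengths, 0.03, rtol=1e-9)
        assert state.membrane.n_nodes == state.cortex.n_nodes

    def test_initial_energy_is_bending_only(self, circle_contour, params):
        state = bs.initialize_model(circle_contour, params)
        terms = bs.energy_terms(state)
        assert terms["tension"] == pytest.approx(0.0, abs=1e-15)
        assert terms["coupling"] == pytest.approx(0.0, abs=1e-12)
        assert terms["pressure"] == 0.0
        assert terms["bending"] > 0

    def test_node_counts_match_on_any_shape(self, notched_contour, params):
        state = bs.initialize_model(notched_contour, params)
        assert state.membrane.n_nodes == state.cortex.n_nodes
        assert len(state.linkers.stiffness) == state.membrane.n_nodes
        assert not state.linkers.broken.any()


class TestEnergy:
    def test_doubling_stiffness_doubles_coupling(self, circle_contour, params):
        state = bs.initialize_model(circle_contour, params.replace(delta_p=0.01))
        relaxed = bs.relax_membrane(state)
        c1 = bs.energy_terms(relaxed)["coupling"]
        relaxed.linkers.stiffness = relaxed.linkers.stiffness * 2.0
        c2 = bs.energy_terms(relaxed)["coupling"]
        assert c2 == pytest.approx(2.0 * c1, rel=1e-12)

    def test_uniform_outward_displacement_coupling_closed_form(
        self, circle_contour, params
    ):
        state = bs.initialize_model(circle_contour, params)
        delta = 1e-3  # um, << r
        radial = state.membrane.nodes / np.linalg.norm(
            state.membrane.nodes, axis=1
        )[:, None]
        state.membrane.nodes += delta * radial
        coupling = bs.energy_terms(state)["coupling"]
        expected = 0.5 * float(state.linkers.stiffness.sum()) * delta**2
        assert coupling == pytest.approx(expected, rel=0.01)

    def test_gradient_matches_finite_differences(self, notched_contour, params):
        p = params.replace(delta_p=0.02)
        state = bs.initialize_model(notched_contour, p)
        x = state.membrane.nodes.copy()
        args = (state.cortex.nodes, state.linkers.stiffness,
                state.linkers.broken, state.x0, p)
        g = _grad(x, *args)
        rng = np.random.default_rng(0)
        eps = 1e-7
        for node in rng.integers(0, len(x), size=6):
            for dim in (0, 1):
                xp = x.copy()
                xp[node, dim] += eps
                xm = x.copy()
                xm[node, dim] -= eps
                fd = (_energy(xp, *args) - _energy(xm, *args)) / (2 * eps)
                assert g[node, dim] == pytest.approx(fd, rel=1e-4, abs=1e-9)

    def test_non_finite_state_raises(self, circle_contour, params):
        state = bs.initialize_model(circle_contour, params)
        state.membrane.nodes[0, 0] = np.nan
        with pytest.raises(bs.NumericalStateError):
            bs.total_energy(state)


class TestRelaxation:
    def test_zero_pressure_stays_at_initial_state(self, circle_contour, params):
        state = bs.initialize_model(circle_contour, params)
        relaxed = bs.relax_membrane(state)
        disp = np.linalg.norm(
            relaxed.membrane.nodes - state.membrane.nodes, axis=1
        ).max()
        assert relaxed.converged
        assert disp < 0.01 * params.L0

    def test_circle_extension_profile_uniform(self, circle_subcritical):
        _, relaxed = circle_subcritical
        ext = relaxed.extensions
        assert (ext.max() - ext.min()) / ext.mean() < 0.01

    def test_energy_never_above_start(self, notched_contour, params):
        state = bs.initialize_model(notched_contour, params.replace(delta_p=0.002))
        relaxed = bs.relax_membrane(state)
        assert relaxed.converged
        assert relaxed.energy <= state.energy + 1e-12

    def test_notch_hosts_maximum_extension(
        self, notched_subcritical, notch_center_node, node_distance
    ):
        _, relaxed = notched_subcritical
        peak = int(np.argmax(relaxed.extensions))
        assert node_distance(peak, notch_center_node, relaxed.n_nodes) <= 2

    def test_breaking_is_monotone_in_pressure(self, notched_contour, params):
        p_sub = bs.find_subcritical_pressure(notched_contour, params)
        state = bs.initialize_model(notched_contour, params)
        broken_sets = []
        for mult in (1.02, 1.08):
            s = state.copy()
            s.params = params.replace(delta_p=mult * p_sub)
            r = bs.relax_membrane(s, allow_breaking=True)
            broken_sets.append(set(np.nonzero(r.linkers.broken)[0]))
        low, high = broken_sets
        assert low
        assert low.issubset(high)


class TestLinkerGradient:
    def test_front_rear_and_midpoint_stiffness(self, params):
        spec = bs.FixtureSpec(shape="ellipse", semi_major=8.0, semi_minor=4.0)
        c = bs.make_contour(spec)
        state = bs.initialize_model(c, params)
        axis = bs.EllipseFit(np.zeros(2), 4.0, 8.0, 0.0, 1)  # front at +x
        graded = bs.apply_linker_gradient(state, axis, 0.60)
        k = graded.linkers.stiffness
        base = params.k * params.spacing
        front = int(np.argmax(c.nodes[:, 0]))
        rear = int(np.argmin(c.nodes[:, 0]))
        mid = int(np.argmin(np.abs(c.nodes[:, 0])))
        assert k[front] == pytest.approx(base, rel=1e-9)
        assert k[rear] == pytest.approx(1.60 * base, rel=1e-9)
        assert k[mid] == pytest.approx(math.sqrt(1.6) * base, rel=0.01)
        np.testing.assert_array_equal(
            graded.linkers.lengths, state.linkers.lengths
        )

    def test_zero_gradient_is_noop(self, circle_contour, params):
        state = bs.initialize_model(circle_contour, params)
        axis = bs.EllipseFit(np.zeros(2), 4.9, 5.0, 0.0, 1)
        graded = bs.apply_linker_gradient(state, axis, 0.0)
        np.testing.assert_allclose(
            graded.linkers.stiffness, state.linkers.stiffness, rtol=1e-12
        )

    def test_negative_gradient_rejected(self, circle_contour, params):
        state = bs.initialize_model(circle_contour, params)
        axis = bs.EllipseFit(np.zeros(2), 4.9, 5.0, 0.0, 1)
        with pytest.raises(ValueError):
            bs.apply_linker_gradient(state, axis, -0.1)


@pytest.fixture(scope="session")
def detached_state(notched_subcritical):
    """Sub-critical relaxed state with the rank-1 site's span detached."""
    p_sub, relaxed = notched_subcritical
    site = bs.rank_bleb_sites(relaxed)[0]
    s, e = site.width_span
    n = relaxed.n_nodes
    nodes = []
    i = s
    while True:
        nodes.append(i)
        if i == e:
            break
        i = (i + 1) % n
    state = relaxed.copy()
    state.params = relaxed.params.replace(delta_p=p_sub)
    state.linkers.broken[np.array(nodes)] = True
    return state, site.nucleation_node


class TestDynamics:
    def test_stokes_drag_arithmetic(self):
        assert bs.stokes_drag(1e-3, 1.0, 1.0) == pytest.approx(6 * math.pi * 1e-3)

    def test_requires_detached_span(self, circle_subcritical):
        _, relaxed = circle_subcritical
        with pytest.raises(ValueError, match="broken"):
            bs.expand_bleb_dynamics(relaxed, duration=0.1)

    def test_area_grows_during_expansion(self, detached_state):
        state, _ = detached_state
        traj = bs.expand_bleb_dynamics(state, duration=0.8, output_interval=0.1)
        areas = [abs(t.membrane.area) for t in traj]
        assert len(traj) >= 3
        assert areas[-1] > areas[0]
        assert all(b >= a - 1e-12 for a, b in zip(areas, areas[1:]))

    def test_doubling_viscosity_halves_apex_velocity(self, detached_state):
        state, apex = detached_state

        def early_speed(eta_mult):
            s = state.copy()
            s.params = state.params.replace(eta=state.params.eta * eta_mult)
            traj = bs.expand_bleb_dynamics(s, duration=0.4, output_interval=0.05)
            d = np.linalg.norm(
                traj[1].membrane.nodes[apex] - traj[0].membrane.nodes[apex]
            )
            return d / 0.05

        v1, v2 = early_speed(1.0), early_speed(2.0)
        assert v1 / v2 == pytest.approx(2.0, rel=0.05)


class TestParams:
    def test_default_file_round_trip(self, tmp_path, params):
        path = tmp_path / "p.txt"
        params.to_file(path)
        back = bs.ModelParams.from_file(path)
        assert back == params

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            bs.ModelParams(spacing=-1.0)
        with pytest.raises(ValueError):
            bs.ModelParams(delta_p=-0.1)
        with pytest.raises(ValueError):
            bs.ModelParams(x0_mode="bogus")
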