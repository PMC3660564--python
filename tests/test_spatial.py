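"""Reaction-diffusion model: scheme correctness, fronts, coverage, droplets."""

import numpy as np
import pytest

from colicomp import (
    IntegrationControl,
    SpatialState,
    State,
    coverage_fractions,
    detect_fronts,
    front_velocity,
    init_spatial,
    integrate_spatial,
    integrate_well_mixed,
    track_front,
)
from colicomp.spatial import FrontTrack, stable_dt


class TestInit:
    def test_half_split_constructive(self):
        st = init_spatial("half_split", 200, inoculum=0.5)
        assert (st.u_A[:100] == 0.5).all() and (st.u_A[100:] == 0.0).all()
        assert (st.u_B[100:] == 0.5).all() and (st.u_B[:100] == 0.0).all()
        assert (st.c_A == 0.0).all() and (st.c_B == 0.0).all()

    def test_droplets_reproducible_and_balanced(self):
        a = init_spatial("droplets", (64, 64), n_droplets=24, radius=3.0, rng=7)
        b = init_spatial("droplets", (64, 64), n_droplets=24, radius=3.0, rng=7)
        np.testing.assert_array_equal(a.u_A, b.u_A)
        np.testing.assert_array_equal(a.u_B, b.u_B)
        c = init_spatial("droplets", (64, 64), n_droplets=24, radius=3.0, rng=8)
        assert not np.array_equal(a.u_A, c.u_A)

    def test_droplets_split_evenly_between_strains(self):
        # non-overlapping discs would each cover ~pi*r^2 sites; just check
        # both strains received inoculated area of the same order
        st = init_spatial("droplets", (128, 128), n_droplets=24, radius=3.0, rng=0)
        n_a, n_b = (st.u_A > 0).sum(), (st.u_B > 0).sum()
        assert n_a > 0 and n_b > 0
        assert 0.5 < n_a / n_b < 2.0

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(pattern="droplets", shape=64), "2D"),
            (dict(pattern="droplets", shape=(64, 64), radius=0.5), "radius"),
            (dict(pattern="droplets", shape=(8, 8), radius=6.0), "fit"),
            (dict(pattern="spots", shape=64), "unknown pattern"),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            init_spatial(rng=0, **kwargs)


class TestScheme:
    def test_stability_bound_enforced_with_max_dt_in_message(
        self, spatial_asym_params
    ):
        st = init_spatial("half_split", 64)
        dt_max = stable_dt(spatial_asym_params, st.h, st.ndim)
        with pytest.raises(ValueError, match=f"{dt_max:g}"):
            integrate_spatial(spatial_asym_params, st, horizon=10.0,
                              dt=1.1 * dt_max)

    def test_mass_conserved_without_reactions(self, spatial_asym_params):
        rng = np.random.default_rng(0)
        fields = [rng.uniform(0, 1, size=(32, 32)) for _ in range(4)]
        st = SpatialState(*fields, h=1.0)
        run = integrate_spatial(spatial_asym_params, st, horizon=5.0,
                                reactions=False, snap_every=1.0)
        n_steps = round(5.0 / run.meta["dt"])
        for name in ("u_A", "u_B", "c_A", "c_B"):
            m0 = getattr(run.states[0], name).sum()
            m1 = getattr(run.final, name).sum()
            assert abs(m1 - m0) < 1e-10 * n_steps

    def test_decoupled_sites_match_well_mixed(self, generic_params):
        p = generic_params.replace(D_u=0.0, D_c=0.0)
        n = 6
        st = SpatialState(np.full(n, 0.3), np.full(n, 0.2),
                          np.full(n, 0.1), np.full(n, 0.25), h=1.0)
        run = integrate_spatial(p, st, horizon=5.0, dt=0.01, snap_every=1.0,
                                time_scheme="rk4")
        ctrl = IntegrationControl(rtol=1e-11, atol=1e-14, n_samples=6)
        traj = integrate_well_mixed(p, State(0.3, 0.2, 0.1, 0.25), 5.0, ctrl)
        for snap, y in zip(run.states, traj.states):
            for i, name in enumerate(("u_A", "u_B", "c_A", "c_B")):
                assert np.abs(getattr(snap, name) - y[i]).max() < 1e-8

    def test_mirror_symmetry_preserved(self, spatial_sym_params):
        st = init_spatial("half_split", 100, inoculum=0.5)
        run = integrate_spatial(spatial_sym_params, st, horizon=50.0, dt=0.25)
        final = run.final
        np.testing.assert_allclose(final.u_A, final.u_B[::-1], atol=1e-9)
        np.testing.assert_allclose(final.c_A, final.c_B[::-1], atol=1e-9)

    def test_periodic_boundaries_available(self, spatial_sym_params):
        st = init_spatial("blocks", 64, n_blocks=4, inoculum=0.5)
        run = integrate_spatial(spatial_sym_params, st, horizon=5.0,
                                dt=0.25, periodic=True)
        assert run.meta["periodic"] is True


class TestFronts:
    def test_half_split_front_at_midpoint(self):
        st = init_spatial("half_split", 200, inoculum=0.5)
        fronts = detect_fronts(st)
        assert fronts.size == 1
        assert fronts[0] == pytest.approx(99.5)

    def test_single_territory_has_no_front(self):
        st = init_spatial("half_split", 100, inoculum=0.5)
        st.u_B[:] = 0.0
        assert detect_fronts(st).size == 0

    def test_empty_grid_has_no_front(self):
        st = SpatialState(*(np.zeros(50) for _ in range(4)), h=1.0)
        assert detect_fronts(st).size == 0

    def test_toxin_peaks_near_front(self, spatial_asym_params):
        st = init_spatial("half_split", 200, inoculum=0.5)
        run = integrate_spatial(spatial_asym_params, st, horizon=150.0, dt=0.25)
        snap = run.final
        fronts = detect_fronts(snap)
        assert fronts.size == 1
        i0 = int(round(fronts[0] / snap.h))
        c_tot = snap.c_A + snap.c_B
        near_front = c_tot[max(0, i0 - 5): i0 + 6].max()
        interior = np.median(c_tot[(snap.u_A + snap.u_B) > 0.5])
        assert near_front > interior

    def test_velocity_sign_follows_potency(self, spatial_asym_params):
        # strain A is the more potent: the front advances into B's territory
        st = init_spatial("half_split", 200, inoculum=0.5)
        run = integrate_spatial(spatial_asym_params, st, horizon=300.0,
                                dt=0.25, snap_every=10.0)
        fit = front_velocity(track_front(run), discard_fraction=0.2)
        assert fit.velocity > 0

    def test_symmetric_velocity_is_zero_within_residual(self, spatial_sym_params):
        st = init_spatial("half_split", 200, inoculum=0.5)
        run = integrate_spatial(spatial_sym_params, st, horizon=300.0,
                                dt=0.25, snap_every=10.0)
        fit = front_velocity(track_front(run), discard_fraction=0.2)
        assert abs(fit.velocity) * (fit.times[-1] - fit.times[0]) <= max(
            fit.residual, 1e-9
        )

    def test_velocity_converges_under_grid_refinement(self, spatial_asym_params):
        fits = []
        for h, n, dt in [(1.0, 400, 0.25), (0.5, 800, 0.06)]:
            st = init_spatial("half_split", n, h=h, inoculum=0.5)
            run = integrate_spatial(spatial_asym_params, st, horizon=400.0,
                                    dt=dt, snap_every=10.0)
            fits.append(front_velocity(track_front(run), 0.2).velocity)
        assert abs(fits[1] - fits[0]) / abs(fits[1]) < 0.05

    def test_velocity_needs_five_points(self):
        track = FrontTrack(times=np.arange(4.0), positions=np.arange(4.0))
        with pytest.raises(ValueError, match="5"):
            front_velocity(track, discard_fraction=0.0)


class TestCoverage:
    def test_counting_single_droplet(self):
        st = init_spatial("droplets", (64, 64), n_droplets=1, radius=4.0, rng=3)
        k = int((st.u_A > 0).sum() + (st.u_B > 0).sum())
        cov = coverage_fractions(st, occupancy_threshold=0.01)
        assert cov["A"] + cov["B"] == pytest.approx(k / 64**2)

    def test_empty_grid_fully_unoccupied(self):
        st = SpatialState(*(np.zeros((16, 16)) for _ in range(4)), h=1.0)
        cov = coverage_fractions(st)
        assert cov == {"A": 0.0, "B": 0.0, "unoccupied": 1.0}

    def test_fractions_sum_to_one(self, spatial_asym_params):
        st = init_spatial("droplets", (48, 48), n_droplets=8, radius=3.0, rng=1)
        run = integrate_spatial(spatial_asym_params, st, horizon=30.0, dt=0.2)
        cov = coverage_fractions(run.final)
        assert cov["A"] + cov["B"] + cov["unoccupied"] == pytest.approx(1.0)


class TestCurvature:
    def test_convex_patch_of_dominant_strain_locally_excluded(self):
        """A mildly dominant strain advances on a planar front but is
        eliminated when confined to a small convex island: its boundary
        cells sit in a bath of the surrounding competitor's toxin (the
        curvature disadvantage of convex territories)."""
        from colicomp.model import CommunityParams

        p = CommunityParams(beta_A=1.0, beta_B=1.0, delta=0.1, s=0.05, d=1.0,
                            kill_AonB=1.2, kill_BonA=1.0,
                            induce_AonB=2.0, induce_BonA=2.0,
                            D_u=0.1, D_c=1.0)
        # planar geometry: A's front advances into B
        st1 = init_spatial("half_split", 128, inoculum=0.5)
        run1 = integrate_spatial(p, st1, horizon=400.0, dt=0.25, snap_every=20.0)
        fit = front_velocity(track_front(run1), discard_fraction=0.2)
        assert fit.velocity > 0

        # convex island of radius ~4 h: the same dominant strain dies out
        n = 64
        yy, xx = np.mgrid[0:n, 0:n]
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 4**2
        st2 = SpatialState(np.where(disc, 0.5, 0.0), np.where(disc, 0.0, 0.5),
                           np.zeros((n, n)), np.zeros((n, n)), h=1.0)
        run2 = integrate_spatial(p, st2, horizon=300.0, dt=0.2)
        assert coverage_fractions(run2.final)["A"] == 0.0
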