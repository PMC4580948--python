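"""Continuum rod model: quadrature, topology classification, bifurcation."""

import numpy as np
import pytest
from scipy.integrate import quad

from oostream.nucleation import SeedingDensityParams
from oostream.polymer import target_length_cdf
from oostream.rod import (
    RodModelParams,
    axis_profile,
    classify_topology,
    monte_carlo_orientation,
    net_orientation,
    normal_form_field,
    normal_form_fixed_points,
    phase_diagram,
)


def _params(kP=3.0, h0P=0.0, epsilon=0.28, **kw):
    return RodModelParams(
        seeding=SeedingDensityParams(h0P=h0P, kP=kP), epsilon=epsilon, **kw
    )


class TestConditionalDensityNormalization:
    def test_fixed_length_rod_density_integrates_to_one(self):
        """For rods of fixed length l the conditional density
        N (2 pi r^2)^-1 [1 - Phi(r)] integrates to 1 over the half space."""
        l = 0.7
        # radial integral of (2 pi r^2)^-1 Theta(l - r) over the half space
        # (solid angle 2 pi) times N = 1/l
        val, _ = quad(lambda r: (1.0 / l) * (r < l), 0, 2 * l)
        assert val == pytest.approx(1.0, rel=1e-8)

    def test_gamma_length_density_integrates_to_one(self):
        Lambda = 0.2
        val, _ = quad(
            lambda r: (1 - target_length_cdf(r, Lambda)) / (2 * Lambda), 0, 50 * Lambda
        )
        assert val == pytest.approx(1.0, rel=1e-6)


class TestNetOrientation:
    def test_rotational_symmetry_on_axis(self, geom1):
        o, pv = net_orientation(np.array([0.0, 0.0, 0.84]), _params(), geom1)
        assert pv > 0
        assert abs(o[0]) < 1e-12 and abs(o[1]) < 1e-12

    def test_wildtype_points_posterior_at_midpoint(self, geom1):
        o, pv = net_orientation(np.array([0.0, 0.0, 0.84]), _params(), geom1)
        assert o[2] * pv > 0

    def test_outside_point_rejected(self, geom1):
        with pytest.raises(ValueError):
            net_orientation(np.array([0.0, 0.0, 2.0]), _params(), geom1)

    def test_monte_carlo_oracle_agreement(self, geom1):
        """Surface quadrature agrees with brute-force rod sampling."""
        x = np.array([0.35, 0.0, 0.8])
        params = _params(epsilon=0.4)
        o_quad, _ = net_orientation(x, params, geom1)
        o_mc, hits = monte_carlo_orientation(
            x, params, geom1, n_rods=2_000_000, ball_radius=0.07, rng=13
        )
        assert hits > 800
        # the MC estimate is ball-averaged; compare direction and magnitude
        assert o_mc[2] == pytest.approx(o_quad[2], abs=0.08)
        assert o_mc[0] == pytest.approx(o_quad[0], abs=0.08)
        cos = o_mc @ o_quad / (np.linalg.norm(o_mc) * np.linalg.norm(o_quad))
        assert cos > 0.97


class TestAxisProfileAndClassification:
    def test_wildtype_no_sign_change(self, geom1):
        z, prof = axis_profile(_params(), geom1)
        assert np.all(prof > 0)
        assert classify_topology(z, prof).label == "wildtype"

    def test_uniform_posterior_seeding_negative_at_pole(self, geom1):
        z, prof = axis_profile(_params(kP=0.02), geom1)
        assert prof[-1] < 0
        topo = classify_topology(z, prof, _params(kP=0.02), geom1)
        assert topo.label == "strong_hypomorph"
        assert [s for _, s in topo.fixed_points] == ["stable"]

    def test_intermediate_split_with_fixed_point_pair(self, geom1):
        params = _params(kP=0.35)
        z, prof = axis_profile(params, geom1)
        topo = classify_topology(z, prof, params, geom1)
        assert topo.label == "split"
        assert [s for _, s in topo.fixed_points] == ["stable", "unstable"]
        # refined positions bracket the sign changes
        for pos, _ in topo.fixed_points:
            assert z[0] < pos < z[-1]

    def test_synthetic_sign_logic(self):
        z = np.linspace(0.2, 1.4, 7)
        assert classify_topology(z, np.ones(7)).label == "wildtype"
        prof = np.array([1, 1, -1, -1, 1, 1, 1.0])
        t = classify_topology(z, prof)
        assert t.label == "split" and len(t.fixed_points) == 2
        with pytest.raises(ValueError):
            classify_topology(z, np.zeros(7))

    def test_profile_continuity_in_kP(self, geom1):
        _, a = axis_profile(_params(kP=0.35), geom1)
        _, b = axis_profile(_params(kP=0.35 * 1.01), geom1)
        assert np.max(np.abs(a - b)) / np.max(np.abs(a)) < 0.05

    def test_classification_invariant_under_refinement(self, geom1):
        for kP, expect in ((3.0, "wildtype"), (0.35, "split"), (0.02, "strong_hypomorph")):
            coarse = _params(kP=kP, n_rho=64)
            fine = _params(kP=kP, n_rho=256)
            zc, pc = axis_profile(coarse, geom1, n_points=100)
            zf, pf = axis_profile(fine, geom1, n_points=200)
            assert classify_topology(zc, pc).label == expect
            assert classify_topology(zf, pf).label == expect


class TestPhaseDiagram:
    def test_three_regions_at_zero_floor(self, geom1):
        df = phase_diagram(
            geom1,
            epsilons=np.linspace(0.08, 0.55, 8),
            kPs=np.geomspace(0.02, 3.0, 9),
            h0P=0.0,
            n_axis=100,
            n_rho=64,
        )
        labels = set(df["label"])
        assert labels == {"wildtype", "split", "strong_hypomorph"}
        # wild type occupies the large-epsilon, large-kP corner
        corner = df[(df.epsilon > 0.4) & (df.kP > 1.0)]
        assert (corner["label"] == "wildtype").all()
        # for long MTs the single-attractor topology needs near-uniform
        # seeding (small kP); short rods widen it (pole-local cortex wins)
        strong = df[df.label == "strong_hypomorph"]
        assert np.isclose(strong["kP"], 0.02).any()
        assert strong[strong.epsilon > 0.3]["kP"].max() < 0.1

    def test_posterior_floor_expands_hypomorph_and_keeps_wildtype(self, geom1):
        """With nucleation allowed at the pole the single-attractor region
        grows, but long MTs still restore wild-type topology."""
        kw = dict(
            epsilons=np.linspace(0.08, 0.55, 8),
            kPs=np.geomspace(0.02, 3.0, 9),
            n_axis=100,
            n_rho=64,
        )
        df0 = phase_diagram(geom1, h0P=0.0, **kw)
        df10 = phase_diagram(geom1, h0P=0.1, **kw)
        n0 = (df0.label == "strong_hypomorph").sum()
        n10 = (df10.label == "strong_hypomorph").sum()
        assert n10 > n0
        assert (df10[df10.epsilon > 0.5].label == "wildtype").any()


class TestSaddleNode:
    def test_normal_form_fixed_points(self):
        v = normal_form_field(-1.0, np.linspace(-2, 2, 41), np.linspace(-1, 1, 21))
        ix = np.argmin(np.abs(np.linspace(-2, 2, 41) - 1.0))
        iy = 10  # y = 0
        assert np.allclose(v[ix, iy], [0.0, 0.0], atol=1e-12)
        assert normal_form_fixed_points(-1.0) == [(-1.0, "stable"), (1.0, "unstable")]
        assert normal_form_fixed_points(0.0) == [(0.0, "degenerate")]
        assert normal_form_fixed_points(0.5) == []

    def test_fixed_point_separation_scales_as_sqrt(self, geom1):
        """Near the wildtype/split boundary the stable-unstable pair
        separation grows as the square root of the distance to the
        boundary (saddle-node signature)."""

        def separation(eps):
            params = _params(kP=0.35, epsilon=eps, n_rho=64)
            z, prof = axis_profile(params, geom1, n_points=400)
            topo = classify_topology(z, prof, refine=False)
            if topo.label != "split" or len(topo.fixed_points) != 2:
                return None
            return topo.fixed_points[1][0] - topo.fixed_points[0][0]

        # locate the bifurcation epsilon* by bisection on pair existence
        lo, hi = 0.28, 0.60  # split at 0.28 (has pair), wildtype at 0.6
        assert separation(lo) is not None and separation(hi) is None
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if separation(mid) is None:
                hi = mid
            else:
                lo = mid
        eps_star = 0.5 * (lo + hi)
        d1, d2 = 0.02, 0.08  # distances below the boundary
        s1, s2 = separation(eps_star - d1), separation(eps_star - d2)
        assert s1 is not None and s2 is not None
        assert s2 / s1 == pytest.approx(np.sqrt(d2 / d1), rel=0.25)
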