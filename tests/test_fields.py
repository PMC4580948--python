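"""Coarse-graining, directional bias and temporal autocorrelation."""

import numpy as np
import pytest

from oostream.fields import (
    CoarseGrid,
    autocorrelation,
    bias_vs_depth,
    coarse_grain,
    directional_bias,
    ensemble_average,
)
from oostream.geometry import CapId
from oostream.nucleation import SeedingDensityParams, sample_seeds
from oostream.polymer import PolymerParams, grow_cytoskeleton


def _toy_realization(geom, midpoints, orientations):
    """Wrap explicit segment lists in a realization-shaped object."""
    from oostream.polymer import CytoskeletonRealization
    from oostream.nucleation import SeedSet

    n = len(midpoints)
    seeds = SeedSet(
        geometry=geom,
        params=SeedingDensityParams(),
        cap=np.zeros(1, dtype=bool),
        rho=np.zeros(1),
        phi=np.zeros(1),
        position=np.zeros((1, 3)),
        normal=np.tile([0.0, 0.0, 1.0], (1, 1)),
    )
    return CytoskeletonRealization(
        geometry=geom,
        seeds=seeds,
        params=PolymerParams(),
        offsets=np.array([0, n]),
        orientations=np.asarray(orientations, dtype=np.float32),
        midpoints=np.asarray(midpoints, dtype=np.float32),
        target_length=np.zeros(1),
        terminated_by=np.zeros(1, dtype=np.int8),
    )


class TestCoarseGrain:
    def test_single_segment_cell(self, geom1):
        r = _toy_realization(geom1, [[0.0, 0.0, 0.8]], [[0.0, 0.0, 1.0]])
        f = coarse_grain(r, CoarseGrid(geom1, dG=0.1))
        occ = np.argwhere(f.counts > 0)
        assert len(occ) == 1
        assert np.allclose(f.vectors[tuple(occ[0])], [0, 0, 1.0])
        assert f.mean_speed() == pytest.approx(1.0)

    def test_antiparallel_cancellation(self, geom1):
        mids = [[0.0, 0.0, 0.8], [0.0, 0.0, 0.81], [0.3, 0.0, 0.8]]
        oris = [[0, 0, 1.0], [0, 0, -1.0], [1.0, 0, 0]]
        f = coarse_grain(_toy_realization(geom1, mids, oris), CoarseGrid(geom1, dG=0.1))
        cancelled = f.sums[f.counts == 2]
        assert np.allclose(cancelled, 0.0)

    def test_counts_sum_and_linearity(self, geom1, small_realization):
        grid = CoarseGrid(geom1, dG=0.1)
        f = coarse_grain(small_realization, grid)
        assert f.counts.sum() == small_realization.n_segments
        # linearity of raw sums in the segment set: first half + second half
        half = small_realization.n_polymers // 2
        cut = small_realization.offsets[half]
        a = _toy_realization(
            geom1,
            small_realization.midpoints[:cut],
            small_realization.orientations[:cut],
        )
        b = _toy_realization(
            geom1,
            small_realization.midpoints[cut:],
            small_realization.orientations[cut:],
        )
        fa, fb = coarse_grain(a, grid), coarse_grain(b, grid)
        assert np.allclose(fa.sums + fb.sums, f.sums, atol=1e-4)

    def test_cortical_density_gradient(self, geom1):
        """Ensemble MT density along the posterior-lateral cortex decays
        toward the pole (highest near the anterior corners)."""
        grid = CoarseGrid(geom1, dG=0.1)
        counts = np.zeros(grid.shape, dtype=np.int64)
        for s in range(4):
            seeds = sample_seeds(geom1, SeedingDensityParams(N_A=4000), rng=40 + s)
            r = grow_cytoskeleton(seeds, PolymerParams(), rng=50 + s)
            counts += coarse_grain(r, grid).counts
        centers = grid.centers()
        # cortical shell: within one cell of the posterior surface
        rho2 = centers[..., 0] ** 2 + centers[..., 1] ** 2
        z_post = geom1.z0P * (1.0 - rho2)
        shell = grid.interior_mask() & (z_post - centers[..., 2] < 0.1)
        s0 = geom1.max_arclength(CapId.posterior)
        s = geom1.arclength(CapId.posterior, np.sqrt(np.clip(rho2, 0, 1)))
        near_pole = shell & (np.abs(s - 0.1 * s0) < 0.1)
        near_corner = shell & (np.abs(s - 0.9 * s0) < 0.1)
        assert counts[near_corner].mean() > counts[near_pole].mean()


class TestDirectionalBias:
    def test_all_posterior(self, geom1):
        r = _toy_realization(geom1, [[0, 0, 0.8]] * 4, [[0, 0, 1.0]] * 4)
        b = directional_bias(r)
        assert b.posterior_share == 100.0 and b.anterior_share == 0.0

    def test_zero_axial_split_evenly(self, geom1):
        r = _toy_realization(geom1, [[0, 0, 0.8]] * 2, [[1.0, 0, 0], [0, 1.0, 0]])
        b = directional_bias(r)
        assert b.posterior_share == 50.0
        assert b.excess_over_parity == 0.0
        assert b.posterior_share + b.anterior_share == 100.0

    def test_slice_mode_and_depth_sweep(self, small_realization):
        mid = directional_bias(small_realization, "slice", depth=1.0)
        assert 0 < mid.posterior_share < 100
        depths, shares = bias_vs_depth(small_realization, np.array([0.3, 1.0]))
        assert shares.shape == (2,)
        with pytest.raises(ValueError):
            directional_bias(small_realization, "slice")  # depth missing


class TestEnsembleAverage:
    def test_identical_fields_unchanged(self, small_motor):
        avg = ensemble_average([small_motor, small_motor])
        assert np.allclose(avg.vectors, small_motor.vectors)
        assert np.array_equal(avg.counts, 2 * small_motor.counts)

    def test_grid_mismatch_raises(self, geom1, small_motor, small_realization):
        other = coarse_grain(small_realization, CoarseGrid(geom1, dG=0.2))
        with pytest.raises(ValueError):
            ensemble_average([small_motor, other])


def test_ensemble_mean_orientation_converges(geom1):
    """Cell-wise direction of the ensemble-mean field stabilizes with
    ensemble size in well-populated cells (cosine similarity between a
    half and the full ensemble > 0.9 where >= 100 segments pooled)."""
    grid = CoarseGrid(geom1, dG=0.1)
    fields = []
    for s in range(20):
        seeds = sample_seeds(geom1, SeedingDensityParams(N_A=1000), rng=700 + s)
        fields.append(coarse_grain(grow_cytoskeleton(seeds, PolymerParams(), rng=800 + s), grid))
    half = ensemble_average(fields[:10])
    full = ensemble_average(fields)
    good = full.counts >= 100
    a, b = half.sums[good], full.sums[good]
    cos = np.einsum("ij,ij->i", a, b) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )
    assert good.sum() > 100
    assert np.median(cos) > 0.9


class TestAutocorrelation:
    def test_constant_sequence(self):
        u = [np.ones((4, 4, 2))] * 6
        c = autocorrelation(u)
        assert np.allclose(c, 1.0)

    def test_iid_sequence_decorrelates(self):
        rng = np.random.default_rng(6)
        u = [rng.normal(size=(20, 20, 2)) for _ in range(40)]
        c = autocorrelation(u, max_lag=5)
        assert c[0] == pytest.approx(1.0)
        assert np.max(np.abs(c[1:])) < 0.1

    def test_ar1_decay_recovery(self):
        """Fitted exponential decay of C(k) recovers the AR(1) time scale."""
        rng = np.random.default_rng(7)
        phi = np.exp(-1.0 / 5.0)  # tau = 5 steps
        u = [rng.normal(size=(30, 30, 2))]
        for _ in range(399):
            u.append(phi * u[-1] + np.sqrt(1 - phi**2) * rng.normal(size=(30, 30, 2)))
        c = autocorrelation(u, max_lag=6)
        lags = np.arange(1, 7)
        tau_fit = -1.0 / np.polyfit(lags, np.log(c[1:7]), 1)[0]
        assert tau_fit == pytest.approx(5.0, rel=0.10)

    def test_lag_bounds(self):
        with pytest.raises(ValueError):
            autocorrelation([np.ones((2, 2))] * 3, max_lag=3)
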