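"""Coarse-grained motor-velocity fields and directional statistics.

A cytoskeleton realization is reduced to a *motor-velocity field* ``v_m`` on
a regular cubic grid: segment orientations (unit vectors) are vectorially
summed per cell by segment midpoint, and the resulting field is scaled so
that the mean vector magnitude over occupied cells is one.  ``v_m``
represents the local direction of Kinesin-driven (plus-end directed)
transport and later both advects bound cargo and, scaled by the coupling
``a'``, forces the cytoplasmic Stokes flow.

Directional bias statistics quantify the anterior-posterior asymmetry of
segment orientations.  Conventions (both are reported): ``posterior_share``
is the percentage of segments with positive AP-axis component among those
with nonzero axial component; ``excess_over_parity = posterior_share - 50``
is the headline "x% more posterior than anterior" number; ``pp_difference``
is posterior minus anterior percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import OocyteGeometry
from .polymer import CytoskeletonRealization

__all__ = [
    "CoarseGrid",
    "MotorVelocityField",
    "BiasReport",
    "coarse_grain",
    "directional_bias",
    "bias_vs_depth",
    "ensemble_average",
    "autocorrelation",
]


@dataclass(frozen=True)
class CoarseGrid:
    """Regular cubic grid of cell centers covering the oocyte bounding box.

    Cell size ``dG`` (default 0.04 nondimensional); centers range over
    ``[-1 + dG/2, 1 - dG/2]`` in x and y.  Along the AP axis the box spans
    the full domain, ``[dG/2, z0P - dG/2]``: for an inward-curved anterior
    (z0A > 0) the oocyte extends below the anterior apex plane down to
    z = 0 at the equatorial ring, and that wedge (which holds the
    high-density anterior corners) must be gridded too.
    """

    geometry: OocyteGeometry
    dG: float = 0.04

    @property
    def shape(self) -> tuple[int, int, int]:
        n_xy = int(round(2.0 / self.dG))
        n_z = int(round(self.geometry.z0P / self.dG))
        return n_xy, n_xy, n_z

    @property
    def origin(self) -> tuple[float, float, float]:
        """Lower corner of the grid box (cell edge, not center)."""
        return -1.0, -1.0, 0.0

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.shape
        x = -1.0 + self.dG * (np.arange(nx) + 0.5)
        y = -1.0 + self.dG * (np.arange(ny) + 0.5)
        z = self.dG * (np.arange(nz) + 0.5)
        return x, y, z

    def centers(self) -> np.ndarray:
        """All cell centers, shape (nx, ny, nz, 3)."""
        x, y, z = self.axes()
        xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)

    def interior_mask(self) -> np.ndarray:
        """Boolean (nx, ny, nz): cell center lies inside the oocyte."""
        return self.geometry.contains(self.centers())

    def cell_index(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map points (N, 3) to integer cell indices; returns (idx, valid).

        ``idx`` has shape (N, 3); ``valid`` flags points inside the box.
        """
        p = np.asarray(points, dtype=float)
        ox, oy, oz = self.origin
        idx = np.empty((p.shape[0], 3), dtype=np.int64)
        idx[:, 0] = np.floor((p[:, 0] - ox) / self.dG)
        idx[:, 1] = np.floor((p[:, 1] - oy) / self.dG)
        idx[:, 2] = np.floor((p[:, 2] - oz) / self.dG)
        shape = np.array(self.shape)
        valid = np.all((idx >= 0) & (idx < shape), axis=1)
        return idx, valid

    def compatible(self, other: "CoarseGrid") -> bool:
        return self.shape == other.shape and abs(self.dG - other.dG) < 1e-12


@dataclass
class MotorVelocityField:
    """Per-cell vector sum of MT segment orientations, normalized so the
    mean magnitude over occupied cells is 1.

    ``sums`` keeps the raw (unnormalized) per-cell vector sums for ensemble
    averaging; ``counts`` the per-cell segment counts (the density map).
    """

    grid: CoarseGrid
    vectors: np.ndarray  # (nx, ny, nz, 3), normalized
    sums: np.ndarray  # (nx, ny, nz, 3), raw vector sums
    counts: np.ndarray  # (nx, ny, nz) int64

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def mean_speed(self) -> float:
        """Mean |v| over occupied cells (1.0 after normalization)."""
        mags = np.linalg.norm(self.vectors[self.occupied], axis=-1)
        return float(mags.mean())


def _normalize(sums: np.ndarray, counts: np.ndarray) -> np.ndarray:
    occ = counts > 0
    mags = np.linalg.norm(sums[occ], axis=-1)
    mean_mag = mags.mean()
    if mean_mag == 0.0:
        raise ValueError("all per-cell vector sums vanish; cannot normalize")
    return sums / mean_mag


def coarse_grain(
    realization: CytoskeletonRealization, grid: CoarseGrid | None = None
) -> MotorVelocityField:
    """Bin segment orientations by midpoint into grid cells and normalize."""
    if realization.n_segments == 0:
        raise ValueError("realization has no segments")
    if grid is None:
        grid = CoarseGrid(realization.geometry)
    idx, valid = grid.cell_index(realization.midpoints)
    shape = grid.shape
    flat = np.ravel_multi_index(
        (idx[valid, 0], idx[valid, 1], idx[valid, 2]), shape
    )
    sums = np.zeros(shape + (3,), dtype=np.float64)
    counts = np.zeros(shape, dtype=np.int64)
    ori = realization.orientations[valid].astype(np.float64)
    for c in range(3):
        np.add.at(sums.reshape(-1, 3)[:, c], flat, ori[:, c])
    np.add.at(counts.reshape(-1), flat, 1)
    return MotorVelocityField(
        grid=grid, vectors=_normalize(sums, counts), sums=sums, counts=counts
    )


@dataclass
class BiasReport:
    """Anterior-posterior orientation bias of a segment set (percentages).

    Segments with exactly zero axial component are split evenly between the
    two classes, so ``posterior_share + anterior_share = 100``.
    """

    n_segments: int
    posterior_share: float
    anterior_share: float

    @property
    def excess_over_parity(self) -> float:
        """posterior_share - 50: the "x% more posterior" convention."""
        return self.posterior_share - 50.0

    @property
    def pp_difference(self) -> float:
        """posterior_share - anterior_share in percentage points."""
        return self.posterior_share - self.anterior_share

    def to_dict(self) -> dict:
        return {
            "n_segments": self.n_segments,
            "posterior_share": self.posterior_share,
            "anterior_share": self.anterior_share,
            "excess_over_parity": self.excess_over_parity,
            "pp_difference": self.pp_difference,
        }


def _bias_of(axial: np.ndarray) -> BiasReport:
    n = axial.size
    if n == 0:
        raise ValueError("empty segment set")
    n_pos = np.count_nonzero(axial > 0)
    n_neg = np.count_nonzero(axial < 0)
    n_zero = n - n_pos - n_neg
    post = (n_pos + 0.5 * n_zero) / n * 100.0
    return BiasReport(n_segments=n, posterior_share=post, anterior_share=100.0 - post)


def directional_bias(
    realization: CytoskeletonRealization,
    mode: str = "3D",
    depth: float | None = None,
    slab_thickness: float = 0.04,
) -> BiasReport:
    """Posterior/anterior orientation bias of MT segments.

    ``mode='3D'``: all segments.  ``mode='slice'``: only segments whose
    midpoints lie in a slab of the given thickness whose center plane sits a
    distance ``depth`` from the lateral cortex along y (``depth=1`` is the
    mid plane y=0).
    """
    axial = realization.orientations[:, 2].astype(np.float64)
    if mode == "3D":
        return _bias_of(axial)
    if mode == "slice":
        if depth is None:
            raise ValueError("slice mode requires a depth")
        y0 = 1.0 - depth
        sel = np.abs(realization.midpoints[:, 1] - y0) <= slab_thickness / 2.0
        if not np.any(sel):
            raise ValueError(f"empty slab at depth {depth}")
        return _bias_of(axial[sel])
    raise ValueError("mode must be '3D' or 'slice'")


def bias_vs_depth(
    realization: CytoskeletonRealization,
    depths: np.ndarray | None = None,
    slab_thickness: float = 0.04,
):
    """Posterior share of 2D slabs as a function of depth from the lateral
    cortex; returns (depths, posterior_share_percent)."""
    if depths is None:
        depths = np.linspace(0.1, 1.0, 10)
    shares = [
        directional_bias(realization, "slice", d, slab_thickness).posterior_share
        for d in depths
    ]
    return np.asarray(depths), np.asarray(shares)


def ensemble_average(fields: list[MotorVelocityField]) -> MotorVelocityField:
    """Mean orientation field of an ensemble.

    Per-cell raw vector sums are added across realizations *before* any
    normalization, then the pooled field is normalized; counts are pooled.
    """
    if len(fields) < 1:
        raise ValueError("need at least one field")
    grid = fields[0].grid
    for f in fields[1:]:
        if not grid.compatible(f.grid):
            raise ValueError("ensemble fields live on incompatible grids")
    sums = np.sum([f.sums for f in fields], axis=0)
    counts = np.sum([f.counts for f in fields], axis=0)
    return MotorVelocityField(
        grid=grid, vectors=_normalize(sums, counts), sums=sums, counts=counts
    )


def autocorrelation(sequence: list[np.ndarray], max_lag: int | None = None) -> np.ndarray:
    """Unbiased discrete vector autocorrelation of a field time series.

    ``C(k) = < (N-k)^-1 sum_n u(n+k) . u(n) >`` averaged over grid points,
    normalized so the peak value is one.  ``sequence`` is a list of arrays
    of identical shape (..., ncomp); returns C for lags 0..max_lag.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("need at least two fields in the sequence")
    if max_lag is None:
        max_lag = n - 1
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the sequence length")
    u = np.stack([np.asarray(f, dtype=float) for f in sequence])  # (n, ..., c)
    c = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        prod = np.sum(u[k:] * u[: n - k], axis=(0, -1)) / (n - k)
        c[k] = prod.mean()
    peak = np.max(np.abs(c))
    if peak == 0.0:
        raise ValueError("zero autocorrelation sequence")
    return c / peak
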