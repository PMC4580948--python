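"""Cortical microtubule seeding densities and seed-point sampling.

MTs nucleate at the oocyte cortex with a density that is high at the anterior
corners and decays toward the posterior pole.  Along the arclength ``s`` of
each cap the (unnormalized) density is

    p~(s | h0, k) = h0 + (1 - h0) * (1 + (k/s0)**2) * s**2 / (k**2 + s**2),

where ``s0`` is the cap's maximal arclength (corner ring).  By construction
``p~(s0) = 1`` on every cap, which makes the seed density continuous across
the anterior/posterior contact ring.  ``h0`` in [0, 1] raises the floor of
the density at the pole (``h0 = 1`` is uniform-by-area); ``k`` controls the
lateral width of the depleted zone.  For ``k >> s0`` the density approaches
the parabola ``h0 + (1-h0)(s/s0)**2``, for ``k << s0`` a Hill function of
coefficient 2.

Sampling is by per-cap inverse-transform: the cap CDF over ``rho`` is
tabulated and inverted numerically; the posterior seed count is fixed by
matching ring densities at the contact line,

    N_P = N_A * A(h0P, kP) / A(h0A, kA),

with ``A`` the integral of ``p~`` over one cap.  This is distributionally
identical to sampling from the globally normalized density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator

from .geometry import CapId, OocyteGeometry

__all__ = [
    "SeedingDensityParams",
    "SeedSet",
    "seeding_preset",
    "density_value",
    "cap_density_integral",
    "posterior_count",
    "sample_seeds",
    "empirical_density_check",
    "alt_density_sample",
    "alt_posterior_count",
]

#: Number of tabulation nodes for numerical CDF inversion.
_CDF_NODES = 4096


@dataclass(frozen=True)
class SeedingDensityParams:
    """Parameters of the cortical seeding density on both caps.

    ``kA``/``kP`` are nondimensional (dimensional width = L*k).  ``N_A`` is
    the prescribed number of anterior seeds; the posterior count follows
    from density matching.
    """

    h0A: float = 0.8
    kA: float = 20.0
    h0P: float = 0.0
    kP: float = 3.0
    N_A: int = 25000

    def __post_init__(self) -> None:
        for name, h in (("h0A", self.h0A), ("h0P", self.h0P)):
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name, k in (("kA", self.kA), ("kP", self.kP)):
            if k <= 0:
                raise ValueError(f"{name} must be positive")
        if self.N_A < 1:
            raise ValueError("N_A must be a positive integer")

    def for_cap(self, cap: CapId) -> tuple[float, float]:
        if CapId(cap) is CapId.anterior:
            return self.h0A, self.kA
        return self.h0P, self.kP

    def to_dict(self) -> dict:
        return {
            "h0A": self.h0A,
            "kA": self.kA,
            "h0P": self.h0P,
            "kP": self.kP,
            "N_A": self.N_A,
        }


_SEEDING_PRESETS = {
    # wild type: shallow anterior gradient, steep parabolic posterior gradient
    "wildtype": dict(h0A=0.8, kA=20.0, h0P=0.0, kP=3.0),
    # par-1 hypomorph series: progressively more uniform posterior seeding
    "par1-intermediate": dict(h0A=0.8, kA=20.0, h0P=0.0, kP=0.35),
    "par1-strong": dict(h0A=0.8, kA=20.0, h0P=0.0, kP=0.02),
    "par1-shallow": dict(h0A=0.8, kA=20.0, h0P=0.7, kP=0.8),
}


def seeding_preset(name: str, N_A: int = 25000) -> SeedingDensityParams:
    """Named seeding-density presets (wild type and *par-1* hypomorph series)."""
    try:
        return SeedingDensityParams(N_A=N_A, **_SEEDING_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown seeding preset {name!r}; choose from {sorted(_SEEDING_PRESETS)}"
        ) from None


def density_value(s, s0: float, h0: float, k: float):
    """Unnormalized arclength density ``p~(s | h0, k)``; ``p~(s0) = 1``."""
    if k <= 0:
        raise ValueError("k must be positive")
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > s0 * (1 + 1e-12))):
        raise ValueError("s must lie in [0, s0]")
    return h0 + (1.0 - h0) * (1.0 + (k / s0) ** 2) * s**2 / (k**2 + s**2)


def _cap_integrand(geom: OocyteGeometry, cap: CapId, params: SeedingDensityParams):
    h0, k = params.for_cap(cap)
    s0 = geom.max_arclength(cap)

    def integrand(rho):
        s = geom.arclength(cap, rho)
        return 2.0 * np.pi * rho * geom.line_element(cap, rho) * density_value(s, s0, h0, k)

    return integrand


def cap_density_integral(
    geom: OocyteGeometry, cap: CapId, params: SeedingDensityParams
) -> float:
    """A(h0, k) = integral of p~ over one cap surface (adaptive quadrature)."""
    val, _ = quad(_cap_integrand(geom, cap, params), 0.0, 1.0, epsabs=1e-12, epsrel=1e-12)
    return val


def posterior_count(geom: OocyteGeometry, params: SeedingDensityParams) -> int:
    """N_P from contact-ring density matching, rounded to nearest integer."""
    A_ant = cap_density_integral(geom, CapId.anterior, params)
    A_post = cap_density_integral(geom, CapId.posterior, params)
    return int(round(params.N_A * A_post / A_ant))


@dataclass
class SeedSet:
    """Sampled cortical seed points with surface coordinates and normals."""

    geometry: OocyteGeometry
    params: SeedingDensityParams
    cap: np.ndarray  # bool, True = posterior
    rho: np.ndarray
    phi: np.ndarray
    position: np.ndarray  # (N, 3)
    normal: np.ndarray  # (N, 3) inward unit normals
    seed: int | None = None

    @property
    def n_total(self) -> int:
        return self.rho.size

    @property
    def n_anterior(self) -> int:
        return int(np.count_nonzero(~self.cap))

    @property
    def n_posterior(self) -> int:
        return int(np.count_nonzero(self.cap))

    def arclength(self) -> np.ndarray:
        s = np.empty_like(self.rho)
        for flag, cap in ((False, CapId.anterior), (True, CapId.posterior)):
            m = self.cap == flag
            s[m] = self.geometry.arclength(cap, self.rho[m])
        return s

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cap": np.where(self.cap, "posterior", "anterior"),
                "rho": self.rho,
                "phi": self.phi,
                "x": self.position[:, 0],
                "y": self.position[:, 1],
                "z": self.position[:, 2],
                "nx": self.normal[:, 0],
                "ny": self.normal[:, 1],
                "nz": self.normal[:, 2],
            }
        )


def _cdf_inverter(geom: OocyteGeometry, cap: CapId, params: SeedingDensityParams):
    """Monotone interpolant of the inverse per-cap CDF u -> rho.

    The CDF is tabulated on Chebyshev-spaced rho nodes by cumulative
    trapezoidal integration of the surface density and inverted with a
    monotone (PCHIP) cubic.
    """
    j = np.arange(_CDF_NODES, dtype=float)
    rho = 0.5 * (1.0 - np.cos(np.pi * j / (_CDF_NODES - 1)))  # Chebyshev in [0,1]
    f = _cap_integrand(geom, cap, params)(rho)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(rho))])
    cdf /= cdf[-1]
    # guard against flat stretches (h0=0 makes the density ~s^2 near rho=0)
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    return PchipInterpolator(cdf[keep], rho[keep])


def sample_seeds(
    geom: OocyteGeometry,
    params: SeedingDensityParams,
    rng: np.random.Generator | int | None = None,
) -> SeedSet:
    """Draw all seed points for one cytoskeleton realization.

    Per-cap inverse-transform sampling of ``rho``; ``phi`` uniform on
    [0, 2*pi).  N_P is fixed by :func:`posterior_count`.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    n_post = posterior_count(geom, params)
    counts = {CapId.anterior: params.N_A, CapId.posterior: n_post}

    caps, rhos, phis, positions, normals = [], [], [], [], []
    for cap in (CapId.anterior, CapId.posterior):
        n = counts[cap]
        inv = _cdf_inverter(geom, cap, params)
        u = rng.random(n)
        rho = np.clip(inv(u), 0.0, 1.0)
        phi = rng.random(n) * 2.0 * np.pi
        caps.append(np.full(n, cap is CapId.posterior))
        rhos.append(rho)
        phis.append(phi)
        positions.append(geom.surface_point(cap, rho, phi))
        normals.append(geom.inward_normal(cap, rho, phi))

    return SeedSet(
        geometry=geom,
        params=params,
        cap=np.concatenate(caps),
        rho=np.concatenate(rhos),
        phi=np.concatenate(phis),
        position=np.concatenate(positions),
        normal=np.concatenate(normals),
        seed=int(seed) if seed is not None else None,
    )


def empirical_density_check(seeds: SeedSet, cap: CapId = CapId.posterior) -> float:
    """Kolmogorov-Smirnov distance between sampled arclengths on one cap and
    the analytic target CDF.  Small values validate the sampler."""
    mask = seeds.cap == (CapId(cap) is CapId.posterior)
    if np.count_nonzero(mask) < 10:
        raise ValueError("too few seeds on the requested cap for a KS check")
    rho = np.sort(seeds.rho[mask])
    inv = _cdf_inverter(seeds.geometry, cap, seeds.params)
    # analytic CDF at the sampled rho by inverting the tabulated inverse
    grid_u = np.linspace(0.0, 1.0, _CDF_NODES)
    grid_rho = inv(grid_u)
    cdf_at = np.interp(rho, grid_rho, grid_u)
    n = rho.size
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(emp_hi - cdf_at)), np.max(np.abs(cdf_at - emp_lo))))


# -- closed-form alternative densities ------------------------------------


def alt_density_sample(
    kind: str,
    geom: OocyteGeometry,
    cap: CapId,
    n_points: int,
    rng: np.random.Generator | int | None = None,
    n: int = 2,
) -> SeedSet:
    """Sample from the analytically invertible alternative seeding densities.

    ``kind='gradient_n'``: density ~ rho**(n-1) along the cap with CDF
    ``rho**(n+1)`` and inverse ``u**(1/(n+1))``.  ``kind='uniform_arc'``:
    uniform by surface area, with closed-form inverse CDF on a parabolic cap
    and ``rho = sqrt(u)`` on a flat disc.
    """
    rng = np.random.default_rng(rng)
    z0 = geom.cap_height(cap)
    u = rng.random(n_points)
    if kind == "gradient_n":
        if n < 1:
            raise ValueError("gradient exponent n must be >= 1")
        rho = u ** (1.0 / (n + 1.0))
    elif kind == "uniform_arc":
        rho = uniform_cap_inverse_cdf(u, z0)
    else:
        raise ValueError(f"unknown alternative density kind {kind!r}")
    phi = rng.random(n_points) * 2.0 * np.pi
    dummy = SeedingDensityParams()
    is_post = CapId(cap) is CapId.posterior
    return SeedSet(
        geometry=geom,
        params=dummy,
        cap=np.full(n_points, is_post),
        rho=rho,
        phi=phi,
        position=geom.surface_point(cap, rho, phi),
        normal=geom.inward_normal(cap, rho, phi),
    )


def uniform_cap_cdf(rho, z0: float):
    """CDF of the uniform-by-area density on a parabolic cap (disc: rho**2)."""
    rho = np.asarray(rho, dtype=float)
    if z0 == 0.0:
        return rho**2
    a = (1.0 + (2.0 * z0 * rho) ** 2) ** 1.5 - 1.0
    b = (1.0 + (2.0 * z0) ** 2) ** 1.5 - 1.0
    return a / b


def uniform_cap_inverse_cdf(u, z0: float):
    """Closed-form inverse of :func:`uniform_cap_cdf`."""
    u = np.asarray(u, dtype=float)
    if z0 == 0.0:
        return np.sqrt(u)
    b = (1.0 + (2.0 * z0) ** 2) ** 1.5 - 1.0
    return np.sqrt((u * b + 1.0) ** (2.0 / 3.0) - 1.0) / (2.0 * z0)


def alt_posterior_count(geom: OocyteGeometry, N_A: int, n: int = 2) -> int:
    """Posterior count matching a uniform anterior density to a gradient
    posterior density of exponent ``n`` at the contact ring.

    Parabolic anterior cap:
    ``N_P = 3 (2 z0A)^2 N_A / (n+1) * sqrt(1+(2 z0P)^2) / ((1+(2 z0A)^2)^{3/2} - 1)``;
    flat-disc anterior: ``N_P = 2 N_A / (n+1) * sqrt(1+(2 z0P)^2)``.
    """
    z0A, z0P = geom.z0A, geom.z0P
    root = np.sqrt(1.0 + (2.0 * z0P) ** 2)
    if z0A == 0.0:
        return int(round(2.0 * N_A / (n + 1.0) * root))
    denom = (1.0 + (2.0 * z0A) ** 2) ** 1.5 - 1.0
    return int(round(3.0 * (2.0 * z0A) ** 2 * N_A / (n + 1.0) * root / denom))
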