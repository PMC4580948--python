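"""Oocyte geometry: two rotationally symmetric parabolic caps.

The stage 9 *Drosophila* oocyte is modelled as the closed volume between an
anterior and a posterior parabolic cap, both surfaces of revolution about the
anterior-posterior (AP) axis.  Internally the AP axis is the ``z`` axis; all
coordinates are nondimensional with length scale ``L`` (50 um by default), so
``x, y`` range over [-1, 1] and ``z`` over the band between the two caps.

Each cap is parameterized in cylindrical coordinates ``(rho, phi)`` as

    sigma_i(rho, phi) = rho * e_rho + z0_i * (1 - rho**2) * e_z,

with cap heights ``z0_A < z0_P``.  The anterior cap curves *into* the volume
(the oocyte is concave at the anterior for ``z0_A > 0``); the special case
``z0_A = 0`` is a flat disc.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.integrate import quad

__all__ = [
    "CapId",
    "OocyteGeometry",
    "geometry_preset",
    "revolve_volume",
]

#: Tolerance used for boundary-inclusive membership tests.  Seed points lie
#: exactly on the surface; floating-point round-off must not expel them.
CONTAINS_TOL = 1e-12


class CapId(str, Enum):
    """Selects one of the two parabolic caps."""

    anterior = "anterior"
    posterior = "posterior"


@dataclass(frozen=True)
class OocyteGeometry:
    """Closed oocyte domain bounded by two parabolic caps.

    Parameters
    ----------
    z0A : float
        Nondimensional anterior cap height, ``>= 0``.  ``0`` gives a flat
        anterior disc.
    z0P : float
        Nondimensional posterior cap height, ``> z0A``.
    L : float
        Length scale in micrometres used to dimensionalize coordinates.
    """

    z0A: float = 0.2
    z0P: float = 1.48
    L: float = 50.0

    def __post_init__(self) -> None:
        if self.z0A < 0:
            raise ValueError("z0A must be >= 0")
        if self.z0P <= self.z0A:
            raise ValueError("z0P must exceed z0A (positive AP-axis length)")

    # -- basic scalars -----------------------------------------------------

    @property
    def ap_length(self) -> float:
        """Nondimensional length of the AP axis, ``z0P - z0A``."""
        return self.z0P - self.z0A

    @property
    def aspect_ratio(self) -> float:
        """Width (2) over AP-axis length."""
        return 2.0 / self.ap_length

    def cap_height(self, cap: CapId) -> float:
        return self.z0A if CapId(cap) is CapId.anterior else self.z0P

    # -- surface parameterization -----------------------------------------

    def surface_point(self, cap: CapId, rho, phi) -> np.ndarray:
        """Point(s) on a cap surface, shape (..., 3).

        ``sigma_i(rho, phi) = rho*e_rho + z0_i*(1 - rho**2)*e_z`` with
        ``e_rho = (cos phi, sin phi, 0)``.
        """
        rho = np.asarray(rho, dtype=float)
        phi = np.asarray(phi, dtype=float)
        if np.any((rho < 0) | (rho > 1)):
            raise ValueError("rho must lie in [0, 1]")
        if np.any((phi < 0) | (phi >= 2 * np.pi)):
            raise ValueError("phi must lie in [0, 2*pi)")
        z0 = self.cap_height(cap)
        return np.stack(
            np.broadcast_arrays(
                rho * np.cos(phi), rho * np.sin(phi), z0 * (1.0 - rho**2)
            ),
            axis=-1,
        )

    def arclength(self, cap: CapId, rho) -> np.ndarray:
        """Arclength s_i(rho) from the cap tip (rho=0) along the parabola.

        Closed form: ``s = rho/2 * sqrt(1 + (2 z0 rho)^2)
        + asinh(2 z0 rho) / (4 z0)``; the flat disc limit is ``s = rho``.
        """
        rho = np.asarray(rho, dtype=float)
        if np.any((rho < 0) | (rho > 1)):
            raise ValueError("rho must lie in [0, 1]")
        z0 = self.cap_height(cap)
        if z0 == 0.0:
            return rho + 0.0
        a = 2.0 * z0 * rho
        return 0.5 * rho * np.sqrt(1.0 + a**2) + np.arcsinh(a) / (4.0 * z0)

    def max_arclength(self, cap: CapId) -> float:
        """s0_i: arclength from the cap tip to the equatorial corner ring."""
        return float(self.arclength(cap, 1.0))

    def line_element(self, cap: CapId, rho) -> np.ndarray:
        """ds/drho = sqrt(1 + (2 z0 rho)^2)."""
        z0 = self.cap_height(cap)
        rho = np.asarray(rho, dtype=float)
        return np.sqrt(1.0 + (2.0 * z0 * rho) ** 2)

    def surface_area(self, cap: CapId) -> float:
        """Total cap area ``pi/(6 z0^2) * ([1+(2 z0)^2]^(3/2) - 1)``.

        The flat-disc limit (z0 -> 0) is ``pi``.
        """
        z0 = self.cap_height(cap)
        if z0 == 0.0:
            return float(np.pi)
        # expm1/log1p form stays accurate in the flat-disc limit z0 -> 0
        a = (2.0 * z0) ** 2
        return float(np.pi / (6.0 * z0**2) * np.expm1(1.5 * np.log1p(a)))

    def inward_normal(self, cap: CapId, rho, phi) -> np.ndarray:
        """Unit normal(s) pointing into the oocyte volume, shape (..., 3).

        With the volume lying between the caps, ``z0A(1-rho^2) <= z <=
        z0P(1-rho^2)``, the inward normals are

            anterior:  (+2 z0A rho e_rho + e_z) / sqrt(1 + (2 z0A rho)^2)
            posterior: -(2 z0P rho e_rho + e_z) / sqrt(1 + (2 z0P rho)^2)

        (``e_z`` for the flat anterior disc; ``-e_z`` at the posterior pole).
        """
        rho = np.asarray(rho, dtype=float)
        phi = np.asarray(phi, dtype=float)
        z0 = self.cap_height(cap)
        sign = -1.0 if CapId(cap) is CapId.posterior else 1.0
        a = 2.0 * z0 * rho
        norm = np.sqrt(1.0 + a**2)
        return np.stack(
            np.broadcast_arrays(
                sign * a * np.cos(phi) / norm,
                sign * a * np.sin(phi) / norm,
                sign / norm,
            ),
            axis=-1,
        )

    # -- membership --------------------------------------------------------

    def contains(self, points, tol: float = CONTAINS_TOL):
        """Boundary-inclusive membership test for point(s) of shape (..., 3)."""
        p = np.asarray(points, dtype=float)
        rho2 = p[..., 0] ** 2 + p[..., 1] ** 2
        z = p[..., 2]
        inside = rho2 <= 1.0 + tol
        lower = self.z0A * (1.0 - rho2)
        upper = self.z0P * (1.0 - rho2)
        return inside & (z >= lower - tol) & (z <= upper + tol)

    # -- volumes -----------------------------------------------------------

    def cap_volume(self, cap: CapId) -> float:
        """Nondimensional volume of the solid of revolution under one cap:
        ``pi * z0 / 2``."""
        return float(np.pi * self.cap_height(cap) / 2.0)

    def total_volume(self) -> float:
        """Nondimensional oocyte volume.

        The anterior cap curves inward, so the volume is the difference of
        the two cap solids: ``pi * (z0P - z0A) / 2``.
        """
        return float(np.pi * self.ap_length / 2.0)

    def nucleus_ratio(self, r: float) -> float:
        """Volume fraction occupied by a spherical nucleus of radius ``r``
        (nondimensional units)."""
        if r <= 0:
            raise ValueError("nucleus radius must be positive")
        return (4.0 / 3.0) * np.pi * r**3 / self.total_volume()

    def to_dict(self) -> dict:
        return {"z0A": self.z0A, "z0P": self.z0P, "L": self.L}


_PRESETS = {
    "geometry1": dict(z0A=0.2, z0P=1.48, L=50.0),
    "geometry2": dict(z0A=0.0, z0P=1.0, L=50.0),
}


def geometry_preset(name: str) -> OocyteGeometry:
    """Named oocyte geometries.

    ``geometry1``: standard stage 9 shape (z0A=0.2, z0P=1.48, AP length 1.28,
    aspect ratio 1.56).  ``geometry2``: flat anterior disc (z0A=0, z0P=1).
    """
    try:
        return OocyteGeometry(**_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown geometry preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None


def revolve_volume(x, y, warn_self_intersect: bool = True) -> float:
    """Volume of the solid of revolution of a sampled planar curve.

    The curve ``(x(t), y(t))`` is rotated about the x axis and the enclosed
    volume computed as ``V = pi * integral y(t)^2 dx/dt dt`` by trapezoidal
    quadrature.  ``t`` is the sample index; ``x`` should be sampled
    monotonically for the result to be a geometric volume.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1D arrays, length >= 2")
    dx = np.diff(x)
    if warn_self_intersect and np.any(dx > 0) and np.any(dx < 0):
        import warnings

        warnings.warn(
            "curve is not monotone in x; revolved volume may be signed/overlapping",
            stacklevel=2,
        )
    return float(np.pi * np.trapezoid(y**2, x))


def cap_profile_curve(geom: OocyteGeometry, cap: CapId, n: int = 2001):
    """Planar profile (z(rho), rho) of a cap for use with revolve_volume.

    Returned with the AP coordinate first so that revolving about the AP
    axis reproduces ``cap_volume``.
    """
    rho = np.linspace(0.0, 1.0, n)
    z0 = geom.cap_height(cap)
    return z0 * (1.0 - rho**2), rho


def surface_area_quadrature(geom: OocyteGeometry, cap: CapId) -> float:
    """Cap area by adaptive quadrature of the surface element (cross-check
    for the closed form)."""
    z0 = geom.cap_height(cap)
    val, _ = quad(lambda r: 2 * np.pi * r * np.sqrt(1 + (2 * z0 * r) ** 2), 0, 1)
    return val
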