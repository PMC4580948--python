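"""Microtubule polymers as persistent random walks.

Each cortical seed nucleates one MT, modelled as a chain of straight
segments of constant nondimensional length ``lambda_seg``.  The orientation
of segment *i* is drawn from a von Mises-Fisher (vMF) distribution on the
sphere concentrated around the previous segment's orientation with
concentration ``kappa``; the first orientation is uniform on the inward
hemisphere at the seed.  A polymer stops growing when a new segment's
endpoint would leave the oocyte (the exiting segment is discarded), when its
cumulative length reaches a stochastic target length, or at ``Ns_max``
segments.

Target lengths follow the length distribution of a growing MT population
whose catastrophe lengths are Gamma-distributed with ``n = 3`` aging steps
(step scale ``Lambda``); its CDF is

    Phi(l) = 1 - exp(-l/Lambda) * (6 Lambda^2 + 4 l Lambda + l^2) / (6 Lambda^2),

with mean ``2 Lambda``.  ``Lambda`` is set from ``epsilon``, the mean target
length as a fraction of the AP-axis length.  An exponential length law with
the same mean is available as an alternative.

Closed-form chain statistics: the vMF mean resultant is
``sigma = coth(kappa) - 1/kappa``, the mean end-to-end vector has magnitude
``lambda (1 - sigma^Ns) / (1 - sigma)``, and the persistence length is
``P = -lambda / ln(sigma)`` (``~ lambda * kappa`` for stiff chains).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import OocyteGeometry
from .nucleation import SeedSet

__all__ = [
    "PolymerParams",
    "CytoskeletonRealization",
    "sample_vmf",
    "sample_target_length",
    "target_length_cdf",
    "grow_cytoskeleton",
    "sigma_of_kappa",
    "mean_end_to_end",
    "persistence_length",
]

# termination codes
TERM_TARGET = 0
TERM_BOUNDARY = 1
TERM_NSMAX = 2
TERMINATION_LABELS = {TERM_TARGET: "target_length", TERM_BOUNDARY: "boundary", TERM_NSMAX: "Ns_max"}


@dataclass(frozen=True)
class PolymerParams:
    """MT growth parameters.

    ``lambda_seg`` is the nondimensional segment length (0.015, i.e. 0.75 um
    at L = 50 um); ``kappa`` the vMF concentration (18, an effective
    persistence length of ~13.5 um); ``epsilon`` the mean target length as a
    fraction of the AP-axis length.
    """

    lambda_seg: float = 0.015
    kappa: float = 18.0
    Ns_max: int = 200
    epsilon: float = 0.5
    length_law: str = "gamma3"

    def __post_init__(self) -> None:
        if self.lambda_seg <= 0:
            raise ValueError("lambda_seg must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.Ns_max < 1:
            raise ValueError("Ns_max must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.length_law not in ("gamma3", "exponential"):
            raise ValueError("length_law must be 'gamma3' or 'exponential'")

    def length_scale(self, ap_length: float) -> float:
        """Lambda such that the mean target length is epsilon * AP length."""
        mean = self.epsilon * ap_length
        return mean / 2.0 if self.length_law == "gamma3" else mean

    def to_dict(self) -> dict:
        return {
            "lambda_seg": self.lambda_seg,
            "kappa": self.kappa,
            "Ns_max": self.Ns_max,
            "epsilon": self.epsilon,
            "length_law": self.length_law,
        }


# -- closed-form chain statistics -----------------------------------------


def sigma_of_kappa(kappa: float) -> float:
    """Mean resultant length of the vMF distribution, coth(k) - 1/k.

    This is the expected projection of a drawn direction onto the mean
    direction; sigma(0) = 0 (uniform sphere), sigma -> 1 as kappa -> inf.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0.0:
        return 0.0
    if kappa < 1e-4:  # series: k/3 - k^3/45 + ...
        return kappa / 3.0 - kappa**3 / 45.0
    return float(1.0 / np.tanh(kappa) - 1.0 / kappa)


def mean_end_to_end(Ns: int, kappa: float, lambda_seg: float) -> float:
    """Magnitude of the mean end-to-end vector of an Ns-segment chain:
    ``lambda * (1 - sigma^Ns) / (1 - sigma)``."""
    if Ns < 1:
        raise ValueError("Ns must be >= 1")
    s = sigma_of_kappa(kappa)
    if s == 1.0:
        return lambda_seg * Ns
    return lambda_seg * (1.0 - s**Ns) / (1.0 - s)


def persistence_length(kappa: float, lambda_seg: float, approx: str | None = None) -> float:
    """Tangent-correlation decay length of the chain.

    Exact: ``P = -lambda / ln(sigma)``.  ``approx='stiff'`` returns the
    large-kappa form ``lambda * kappa``; ``approx='floppy'`` the small-kappa
    form ``lambda / ln(3/kappa)``.
    """
    if approx == "stiff":
        return lambda_seg * kappa
    if approx == "floppy":
        return lambda_seg / np.log(3.0 / kappa)
    if approx is not None:
        raise ValueError("approx must be None, 'stiff' or 'floppy'")
    s = sigma_of_kappa(kappa)
    if s <= 0.0:
        return 0.0
    return float(-lambda_seg / np.log(s))


# -- sampling primitives ---------------------------------------------------


def sample_vmf(
    mu_prev: np.ndarray, kappa: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw unit vectors from vMF(mu_prev, kappa); vectorized over rows.

    Polar cosine by inverse CDF, ``w = 1 + ln(u + (1-u) e^(-2k)) / k``,
    uniform azimuth in the plane orthogonal to ``mu_prev``.  ``kappa = 0``
    reduces to the uniform sphere.
    """
    rng = np.random.default_rng(rng)
    mu = np.atleast_2d(np.asarray(mu_prev, dtype=float))
    n = mu.shape[0]
    u = rng.random(n)
    if kappa == 0.0:
        w = 2.0 * u - 1.0
    else:
        # log1p formulation avoids overflow for large kappa
        w = 1.0 + np.log1p(-(1.0 - np.exp(-2.0 * kappa)) * (1.0 - u)) / kappa
    w = np.clip(w, -1.0, 1.0)
    alpha = rng.random(n) * 2.0 * np.pi

    # orthonormal frame (e1, e2) perpendicular to each mu
    helper = np.zeros_like(mu)
    smallest = np.argmin(np.abs(mu), axis=1)
    helper[np.arange(n), smallest] = 1.0
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(mu, e1)

    r = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    out = (
        w[:, None] * mu
        + (r * np.cos(alpha))[:, None] * e1
        + (r * np.sin(alpha))[:, None] * e2
    )
    return out if np.asarray(mu_prev).ndim == 2 else out[0]


def target_length_cdf(l, Lambda: float):
    """CDF of the gamma3 growing-population length law (mean 2*Lambda)."""
    l = np.asarray(l, dtype=float)
    x = l / Lambda
    return 1.0 - np.exp(-x) * (6.0 + 4.0 * x + x**2) / 6.0


def sample_target_length(
    n: int,
    Lambda: float,
    rng: np.random.Generator | int | None = None,
    law: str = "gamma3",
) -> np.ndarray:
    """Draw target lengths.

    The gamma3 law is sampled exactly through its mixture representation:
    the growing-population length distribution for Erlang(3) catastrophe
    lengths is an equal-weight mixture of Erlang(1), Erlang(2) and Erlang(3),
    so ``l = Lambda * Gamma(K, 1)`` with ``K`` uniform on {1, 2, 3}.  This
    coincides with inverse-transform sampling of the stated CDF.
    """
    if Lambda <= 0:
        raise ValueError("Lambda must be positive")
    rng = np.random.default_rng(rng)
    if law == "gamma3":
        k = rng.integers(1, 4, size=n)
        return Lambda * rng.gamma(k)
    if law == "exponential":
        return rng.exponential(Lambda, size=n)
    raise ValueError("law must be 'gamma3' or 'exponential'")


# -- growth ---------------------------------------------------------------


@dataclass
class CytoskeletonRealization:
    """One stochastic MT cytoskeleton: all polymers grown from one seed set.

    Segments are stored flat, grouped per polymer: polymer ``i`` owns
    segments ``offsets[i]:offsets[i+1]``.  ``orientations`` are unit
    seed-to-tip segment directions; ``midpoints`` their centre points.
    """

    geometry: OocyteGeometry
    seeds: SeedSet
    params: PolymerParams
    offsets: np.ndarray  # (N+1,) int64
    orientations: np.ndarray  # (M, 3) float32
    midpoints: np.ndarray  # (M, 3) float32
    target_length: np.ndarray  # (N,) float
    terminated_by: np.ndarray  # (N,) int8 codes
    seed: int | None = None

    @property
    def n_polymers(self) -> int:
        return self.offsets.size - 1

    @property
    def n_segments(self) -> int:
        return int(self.offsets[-1])

    def segments_per_polymer(self) -> np.ndarray:
        return np.diff(self.offsets)

    def termination_fractions(self) -> dict[str, float]:
        n = self.n_polymers
        return {
            label: float(np.count_nonzero(self.terminated_by == code)) / n
            for code, label in TERMINATION_LABELS.items()
        }


def grow_cytoskeleton(
    seeds: SeedSet,
    params: PolymerParams,
    rng: np.random.Generator | int | None = None,
) -> CytoskeletonRealization:
    """Grow one MT polymer from every seed point (vectorized over polymers).

    All polymers advance one segment per iteration.  The first orientation
    is uniform on the inward hemisphere (a uniform sphere draw reflected
    through the tangent plane when pointing outward, which realizes the same
    rejection law); later orientations follow vMF around the previous one.
    """
    seed_int = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    geom = seeds.geometry
    n = seeds.n_total
    lam = params.lambda_seg
    Lambda = params.length_scale(geom.ap_length)
    target = sample_target_length(n, Lambda, rng, law=params.length_law)

    orient_store = np.zeros((n, params.Ns_max, 3), dtype=np.float32)
    mid_store = np.zeros((n, params.Ns_max, 3), dtype=np.float32)
    n_seg = np.zeros(n, dtype=np.int64)
    terminated = np.full(n, TERM_NSMAX, dtype=np.int8)

    active = np.arange(n)
    pos = seeds.position.copy()
    mu = np.empty((n, 3))

    for step in range(params.Ns_max):
        if active.size == 0:
            break
        if step == 0:
            d = sample_vmf(np.tile([0.0, 0.0, 1.0], (n, 1)), 0.0, rng)
            # reflect outward draws into the inward hemisphere
            proj = np.einsum("ij,ij->i", d, seeds.normal)
            flip = proj < 0.0
            d[flip] -= 2.0 * proj[flip, None] * seeds.normal[flip]
            mu_new = d
        else:
            mu_new = sample_vmf(mu[active], params.kappa, rng)
        tip = pos[active] + lam * mu_new
        ok = geom.contains(tip)

        hit = active[~ok]
        terminated[hit] = TERM_BOUNDARY
        keep = ok
        act = active[keep]
        orient_store[act, n_seg[act]] = mu_new[keep]
        mid_store[act, n_seg[act]] = pos[act] + 0.5 * lam * mu_new[keep]
        n_seg[act] += 1
        pos[act] = tip[keep]
        mu[act] = mu_new[keep]

        reached = n_seg[act] * lam >= target[act]
        terminated[act[reached]] = TERM_TARGET
        active = act[~reached]

    # flatten, grouped per polymer
    offsets = np.concatenate([[0], np.cumsum(n_seg)])
    m = int(offsets[-1])
    orientations = np.empty((m, 3), dtype=np.float32)
    midpoints = np.empty((m, 3), dtype=np.float32)
    mask = np.arange(params.Ns_max)[None, :] < n_seg[:, None]
    orientations[:] = orient_store[mask]
    midpoints[:] = mid_store[mask]

    return CytoskeletonRealization(
        geometry=geom,
        seeds=seeds,
        params=params,
        offsets=offsets,
        orientations=orientations,
        midpoints=midpoints,
        target_length=target,
        terminated_by=terminated,
        seed=int(seed_int) if seed_int is not None else None,
    )
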