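"""Spherical geometry primitives.

All public functions take latitude/longitude in decimal degrees and work
internally on the unit sphere in 3D Cartesian coordinates, which avoids
date-line and polar artifacts that plague naive lat/lon arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


@dataclass(frozen=True)
class GeoPoint:
    """A point on the Earth's surface in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 < self.lon <= 180.0 + 1e-12:
            raise ValueError(f"longitude {self.lon} outside (-180, 180]")


def normalize_lon(lon: float) -> float:
    """Wrap a longitude into the canonical (-180, 180] interval."""
    wrapped = (float(lon) + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


def sphere_to_cartesian(p: GeoPoint) -> np.ndarray:
    """Map (lat, lon) to a unit 3-vector; (0, 0) -> (1, 0, 0), poles -> ±z."""
    lat = np.deg2rad(p.lat)
    lon = np.deg2rad(p.lon)
    return np.array(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def cartesian_to_sphere(v: np.ndarray) -> GeoPoint:
    """Map a (not necessarily unit) 3-vector back to (lat, lon) degrees."""
    v = np.asarray(v, dtype=float)
    norm = float(np.linalg.norm(v))
    if norm < 1e-9:
        raise ValueError("cannot project a (near-)zero vector to the sphere")
    x, y, z = v / norm
    lat = np.rad2deg(np.arcsin(np.clip(z, -1.0, 1.0)))
    lon = np.rad2deg(np.arctan2(y, x))
    return GeoPoint(float(lat), normalize_lon(float(lon)))


def points_to_matrix(points) -> np.ndarray:
    """Stack GeoPoints into an (n, 3) array of unit vectors."""
    return np.array([sphere_to_cartesian(p) for p in points])


def geographic_midpoint(points) -> GeoPoint:
    """Geographic midpoint of a set of points.

    Each point is mapped to a unit 3-vector, the arithmetic mean of the
    vectors is taken, and the mean is projected back to the sphere.  This is
    the classic Cartesian-mean midpoint respecting the curvature of the
    Earth.  Raises for an (anti-)symmetric configuration whose mean vector
    vanishes, where the midpoint is undefined.
    """
    points = list(points)
    if not points:
        raise ValueError("geographic_midpoint needs at least one point")
    mean = points_to_matrix(points).mean(axis=0)
    if np.linalg.norm(mean) < 1e-9:
        raise ValueError("midpoint undefined: mean vector is (near) zero "
                         "(antipodal/degenerate configuration)")
    return cartesian_to_sphere(mean)


def great_circle_km(a: GeoPoint, b: GeoPoint, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle (haversine) distance between two points in kilometres."""
    lat1, lon1 = np.deg2rad([a.lat, a.lon])
    lat2, lon2 = np.deg2rad([b.lat, b.lon])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def angular_distance_deg(a: GeoPoint, b: GeoPoint) -> float:
    """Central angle between two points in degrees."""
    cosang = float(np.dot(sphere_to_cartesian(a), sphere_to_cartesian(b)))
    return float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random 3x3 rotation (for equivariance property tests)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def sample_vmf(mu: np.ndarray, kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n unit vectors from a von Mises–Fisher distribution on S².

    Uses the closed-form inverse-CDF for the cosine of the polar angle that
    exists in three dimensions: w = 1 + log(u + (1-u) e^{-2κ}) / κ.
    """
    if kappa <= 0:
        raise ValueError("vMF concentration kappa must be > 0")
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    u = rng.uniform(size=n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    # orthonormal basis (e1, e2) perpendicular to mu
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, mu)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    sin_ang = np.sqrt(np.clip(1.0 - w**2, 0.0, 1.0))
    return (
        w[:, None] * mu[None, :]
        + (sin_ang * np.cos(theta))[:, None] * e1[None, :]
        + (sin_ang * np.sin(theta))[:, None] * e2[None, :]
    )
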