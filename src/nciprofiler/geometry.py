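"""Vector and plane geometry shared by all interaction detectors.

All distances are in Angstrom and all angles in degrees. Plane normals
follow a fixed sign convention (positive z component, ties broken by
positive y then positive x) so that serialized geometry is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateGeometryError(ValueError):
    """Raised for undefined geometric queries (zero-length arms, collinear planes)."""


@dataclass(frozen=True)
class Plane:
    """Least-squares plane through a set of points."""

    centroid: np.ndarray
    normal: np.ndarray
    planarity_rmsd: float


def distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two points."""
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def angle(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    """Interior angle at ``vertex`` between ``a`` and ``c``, in [0, 180] degrees."""
    v1 = np.asarray(a, float) - np.asarray(vertex, float)
    v2 = np.asarray(c, float) - np.asarray(vertex, float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise DegenerateGeometryError("angle undefined: zero-length arm at vertex")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _orient_normal(n: np.ndarray) -> np.ndarray:
    # fixed sign convention: positive z, ties by positive y then x
    for i in (2, 1, 0):
        if abs(n[i]) > 1e-12:
            return n if n[i] > 0 else -n
    return n


def fit_plane(points) -> Plane:
    """Least-squares plane through >= 3 non-collinear points (SVD)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise DegenerateGeometryError("fit_plane needs >= 3 points in 3D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear: second singular value ~ 0 means no unique plane
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("fit_plane: points are collinear")
    normal = _orient_normal(vt[2])
    normal = normal / np.linalg.norm(normal)
    dists = centered @ normal
    rmsd = float(np.sqrt(np.mean(dists**2)))
    return Plane(centroid=centroid, normal=normal, planarity_rmsd=rmsd)


def plane_angle(p1: Plane, p2: Plane) -> float:
    """Acute angle between two plane normals, folded into [0, 90] degrees."""
    cosang = abs(np.clip(np.dot(p1.normal, p2.normal), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def projected_offset(p: Plane, point: np.ndarray) -> float:
    """In-plane distance from the plane centroid to the projection of ``point``."""
    v = np.asarray(point, float) - p.centroid
    proj = v - np.dot(v, p.normal) * p.normal
    return float(np.linalg.norm(proj))


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``angle_deg`` (Rodrigues)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)
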