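"""Small 3D geometry helpers: dihedrals, axis rotations, rigid alignment."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in [-180, 180).

    IUPAC sign convention: looking down the p1->p2 axis, a clockwise
    rotation of the far bond relative to the near bond is positive.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return wrap_angle(ang)


def wrap_angle(a) -> float:
    """Wrap an angle in degrees to [-180, 180)."""
    return float((np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a unit axis."""
    u = unit(np.asarray(axis, dtype=float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    K = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(u, u)


def rotate_about_line(coords: np.ndarray, point: np.ndarray,
                      axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate points about the line through `point` with direction `axis`."""
    R = rotation_about_axis(axis, angle_deg)
    return (coords - point) @ R.T + point


def align_vector_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking direction a onto direction b."""
    a = unit(np.asarray(a, dtype=float))
    b = unit(np.asarray(b, dtype=float))
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular
        p = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(p) < 1e-6:
            p = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_about_axis(p, 180.0)
    K = np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])
    return np.eye(3) + K + K @ K * (1.0 / (1.0 + c))


def set_dihedral(coords: np.ndarray, moved: np.ndarray,
                 p0: int, p1: int, p2: int, p3: int,
                 target_deg: float) -> np.ndarray:
    """Rotate the `moved` atoms about the p1-p2 axis so that the dihedral
    p0-p1-p2-p3 equals `target_deg`.  Sign-robust: the rotation sense is
    verified by re-measurement.  Returns a new coordinate array."""
    cur = dihedral(coords[p0], coords[p1], coords[p2], coords[p3])
    delta = wrap_angle(target_deg - cur)
    axis = coords[p2] - coords[p1]
    out = coords.copy()
    out[moved] = rotate_about_line(coords[moved], coords[p1], axis, delta)
    new = dihedral(out[p0], out[p1], out[p2], out[p3])
    if abs(wrap_angle(new - target_deg)) > 1e-9:
        out = coords.copy()
        out[moved] = rotate_about_line(coords[moved], coords[p1], axis, -delta)
    return out


def angle_between_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Unsigned angle between two direction vectors in degrees."""
    ca = float(np.clip(np.dot(unit(a), unit(b)), -1.0, 1.0))
    return float(np.degrees(np.arccos(ca)))
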