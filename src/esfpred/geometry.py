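"""Backbone and virtual conformational angles, local helix axes, kinks.

Angle conventions
-----------------
* ``phi``/``psi``: IUPAC backbone dihedrals in degrees, range (-180, 180],
  right-handed positive.
* ``kappa``: bend angle at residue i, the angle between the successive
  2-residue virtual bonds CA(i-2)->CA(i) and CA(i)->CA(i+2). A straight
  trace gives 0 deg; an ideal alpha-helix about 110 deg.
* ``alpha``: virtual torsion over CA(i-1), CA(i), CA(i+1), CA(i+2);
  about +50 deg for a right-handed alpha-helix.
* Kink angle: angle between local helix axes fitted (HELANAL-style) to the
  four residues preceding and the four following a position, i.e. a
  9-residue running window; undefined near segment ends.

Undefined values are returned as NaN and propagate silently.
"""

from __future__ import annotations

import numpy as np

from .io import Chain, SegmentAnnotation

_EPS = 1e-10


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, range (-180, 180].

    Returns NaN when the central bond is degenerate (zero length or
    collinear flanking bonds).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 < _EPS:
        return np.nan
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < _EPS or np.linalg.norm(w) < _EPS:
        return np.nan
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def vector_angle(u, v) -> float:
    """Angle between two vectors in degrees, [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        return np.nan
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _backbone(chain: Chain, name: str) -> np.ndarray:
    out = np.full((len(chain), 3), np.nan)
    for i, res in enumerate(chain.residues):
        xyz = res.coord(name)
        if xyz is not None:
            out[i] = xyz
    return out


def phi_psi(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Backbone phi/psi per residue (degrees); NaN at termini and gaps.

    phi(i) = dihedral C(i-1), N(i), CA(i), C(i);
    psi(i) = dihedral N(i), CA(i), C(i), N(i+1).
    """
    L = len(chain)
    N, CA, C = _backbone(chain, "N"), _backbone(chain, "CA"), _backbone(chain, "C")
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    for i in range(L):
        if i > 0 and np.all(np.isfinite([C[i - 1], N[i], CA[i], C[i]])):
            phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
        if i < L - 1 and np.all(np.isfinite([N[i], CA[i], C[i], N[i + 1]])):
            psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
    return phi, psi


def kappa_alpha(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Bend angle kappa and virtual torsion alpha per residue (degrees).

    kappa(i) needs CA at i-2, i, i+2; alpha(i) needs CA at i-1 .. i+2.
    """
    ca = chain.ca_coords()
    L = len(chain)
    kappa = np.full(L, np.nan)
    alpha = np.full(L, np.nan)
    for i in range(L):
        if 2 <= i < L - 2 and np.all(np.isfinite(ca[[i - 2, i, i + 2]])):
            kappa[i] = vector_angle(ca[i] - ca[i - 2], ca[i + 2] - ca[i])
        if 1 <= i < L - 2 and np.all(np.isfinite(ca[i - 1:i + 3])):
            alpha[i] = dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
    return kappa, alpha


def local_helix_axis(calphas) -> np.ndarray:
    """Local helix axis through 4 consecutive C-alpha positions.

    Uses the HELANAL/Kahn bisector construction: at each of the two interior
    points the bisector of the flanking virtual bonds points toward the
    helix axis; the axis direction is the cross product of the two
    bisectors, oriented N->C. Returns a unit 3-vector, or NaNs when the
    points are (near-)collinear.
    """
    p = np.asarray(calphas, dtype=float)
    if p.shape != (4, 3):
        raise ValueError("local_helix_axis expects exactly 4 points")
    nan = np.full(3, np.nan)
    b1 = (p[0] - p[1]) + (p[2] - p[1])
    b2 = (p[1] - p[2]) + (p[3] - p[2])
    axis = np.cross(b1, b2)
    n = np.linalg.norm(axis)
    chord = p[3] - p[0]
    if n < 1e-6 * max(np.linalg.norm(b1) * np.linalg.norm(b2), _EPS) or n < _EPS:
        return nan
    axis = axis / n
    if np.dot(axis, chord) < 0:
        axis = -axis
    return axis


def kink_angle(chain: Chain, segments: SegmentAnnotation) -> dict[str, np.ndarray]:
    """Kink angle per residue from the two flanking 4-residue helix axes.

    For residue i inside a TM segment with at least 4 helical residues on
    each side, the kink is the angle (degrees, >= 0) between the local axis
    of residues [i-4, i-1] and that of [i+1, i+4]. The central residue is
    excluded from both half-windows so the two axes are independent.

    Returns arrays ``kink`` (L,), ``axis_pre`` and ``axis_post`` (L, 3),
    NaN where undefined.
    """
    ca = chain.ca_coords()
    L = len(chain)
    kink = np.full(L, np.nan)
    axis_pre = np.full((L, 3), np.nan)
    axis_post = np.full((L, 3), np.nan)
    for s, e in segments.helix_segments:
        for i in range(s + 4, e - 4):
            pre = ca[i - 4:i]
            post = ca[i + 1:i + 5]
            if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
                continue
            a1 = local_helix_axis(pre)
            a2 = local_helix_axis(post)
            if np.any(np.isnan(a1)) or np.any(np.isnan(a2)):
                continue
            axis_pre[i] = a1
            axis_post[i] = a2
            kink[i] = vector_angle(a1, a2)
    return {"kink": kink, "axis_pre": axis_pre, "axis_post": axis_post}


def fit_axis_tls(points) -> np.ndarray:
    """Total-least-squares line direction through points (unit vector, N->C).

    Cross-check oracle for :func:`local_helix_axis`; a plain SVD principal
    direction of the centered points.
    """
    p = np.asarray(points, dtype=float)
    centered = p - p.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if np.dot(axis, p[-1] - p[0]) < 0:
        axis = -axis
    return axis
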