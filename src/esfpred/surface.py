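"""Solvent-accessible surface area with a lipid-sized probe.

ASA is computed Shrake-Rupley style with a deterministic golden-spiral
(Fibonacci) point set, so results are bit-stable. The default probe radius
is 1.9 A, the customary size of a hypothetical lipid probe for membrane
proteins (a water probe would be 1.4 A).

Three residue-level groupings are reported, each normalized by the ASA of
the same residue as the central X of an extended Ala-X-Ala tripeptide
(phi = psi = 180 deg) computed with the same probe:

* tASA  — all heavy atoms of the residue;
* scASA — side-chain atoms (everything outside N, CA, C, O, OXT; for Gly
  the CA counts as the side chain);
* npASA — non-polar atoms (carbon and sulfur).

Relative values are percentages and are not clamped at 100%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import Chain, BACKBONE_ATOMS

#: Heavy-atom radii in Angstrom (NACCESS default set).
DEFAULT_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85}
DEFAULT_RADIUS = 1.80

DEFAULT_PROBE = 1.9
DEFAULT_N_POINTS = 960

_reference_cache: dict = {}


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Quasi-uniform deterministic points on the unit sphere (golden spiral)."""
    i = np.arange(n_points, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_points)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.c_[np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]


def element_radius(element: str, radii: dict | None = None) -> float:
    table = DEFAULT_RADII if radii is None else radii
    return table.get(element.upper(), DEFAULT_RADIUS)


def atomic_asa(coords, radii_per_atom, probe: float = DEFAULT_PROBE,
               n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom accessible surface area in A^2 (Shrake-Rupley).

    For each atom, the fraction of ``n_points`` quasi-uniform points on its
    expanded sphere (radius r + probe) that fall inside no neighbor's
    expanded sphere, times 4 pi (r + probe)^2.
    """
    coords = np.asarray(coords, dtype=float)
    radii_per_atom = np.asarray(radii_per_atom, dtype=float)
    if np.any(radii_per_atom <= 0):
        raise ValueError("atom radii must be positive")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    if n_points < 100:
        raise ValueError("n_points must be at least 100")
    expanded = radii_per_atom + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        neighbors = tree.query_ball_point(coords[i], expanded[i] + max_r)
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas


def _group_areas(residue, atom_areas_by_name: list[tuple[str, str, float]],
                 res_name: str) -> tuple[float, float, float]:
    """Sum atomic areas into (total, side-chain, non-polar)."""
    total = sc = nonpolar = 0.0
    for name, element, area in atom_areas_by_name:
        total += area
        is_backbone = name in BACKBONE_ATOMS
        if res_name == "GLY" and name == "CA":
            is_backbone = False
        if not is_backbone:
            sc += area
        if element.upper() in ("C", "S"):
            nonpolar += area
    return total, sc, nonpolar


def chain_atomic_asa(chain: Chain, probe: float = DEFAULT_PROBE,
                     n_points: int = DEFAULT_N_POINTS,
                     radii: dict | None = None) -> list[list[float]]:
    """Atomic ASA for every atom of the chain, nested per residue."""
    coords, res_idx, elements = chain.all_atoms()
    if len(coords) == 0:
        raise ValueError("chain has no atoms")
    atom_radii = np.array([
        a.radius if a.radius is not None else element_radius(a.element, radii)
        for res in chain.residues for a in res.atoms
    ])
    areas = atomic_asa(coords, atom_radii, probe=probe, n_points=n_points)
    nested: list[list[float]] = [[] for _ in chain.residues]
    for a, i in zip(areas, res_idx):
        nested[i].append(float(a))
    return nested


def extended_reference(res_name: str, probe: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_N_POINTS,
                       radii: dict | None = None) -> dict[str, float]:
    """Reference absolute ASA of residue X in an extended Ala-X-Ala tripeptide.

    Returns the central residue's absolute area per grouping
    (``total``, ``sidechain``, ``nonpolar``), cached per configuration.
    """
    from .io import AA3_TO_1
    from .synthetic import build_peptide

    if res_name not in AA3_TO_1:
        raise ValueError(f"unknown residue {res_name!r}")
    key = (res_name, round(probe, 6), n_points, None if radii is None else tuple(sorted(radii.items())))
    if key in _reference_cache:
        return _reference_cache[key]
    seq = "A" + AA3_TO_1[res_name] + "A"
    tri = build_peptide(seq, phi=[180.0] * 3, psi=[180.0] * 3)
    areas = chain_atomic_asa(tri, probe=probe, n_points=n_points, radii=radii)
    res = tri.residues[1]
    triples = [(a.name, a.element, area) for a, area in zip(res.atoms, areas[1])]
    t, sc, npol = _group_areas(res, triples, res_name)
    ref = {"total": t, "sidechain": sc, "nonpolar": npol}
    _reference_cache[key] = ref
    return ref


def residue_asa(chain: Chain, probe: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS,
                radii: dict | None = None) -> pd.DataFrame:
    """Relative (%) and absolute (A^2) per-residue ASA groupings.

    Columns: tASA, scASA, npASA (relative %, NaN where the reference
    grouping area is zero) and tASA_abs, scASA_abs, npASA_abs.
    """
    nested = chain_atomic_asa(chain, probe=probe, n_points=n_points, radii=radii)
    rows = []
    for res, areas in zip(chain.residues, nested):
        if not res.atoms:
            rows.append([np.nan] * 6)
            continue
        triples = [(a.name, a.element, area) for a, area in zip(res.atoms, areas)]
        t, sc, npol = _group_areas(res, triples, res.res_name)
        try:
            ref = extended_reference(res.res_name, probe=probe, n_points=n_points, radii=radii)
        except ValueError:
            rows.append([np.nan, np.nan, np.nan, t, sc, npol])
            continue
        rel = [
            100.0 * t / ref["total"] if ref["total"] > 0 else np.nan,
            100.0 * sc / ref["sidechain"] if ref["sidechain"] > 0 else np.nan,
            100.0 * npol / ref["nonpolar"] if ref["nonpolar"] > 0 else np.nan,
        ]
        rows.append(rel + [t, sc, npol])
    return pd.DataFrame(
        rows, columns=["tASA", "scASA", "npASA", "tASA_abs", "scASA_abs", "npASA_abs"]
    )
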