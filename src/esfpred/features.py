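"""Assembly of the eight-dimensional ESF target vector and its scaling.

The eight equilibrium structural features (ESFs) per residue are, in fixed
order: tASA, scASA, npASA (relative %), HHC (binary), phi, psi (deg),
kappa (deg) and alpha (deg). Undefined components are NaN ("masked") and
are excluded from training losses and error averages downstream.

Scaling to [0, 1] uses fixed, dataset-independent linear ranges so trained
models transfer across datasets:

==========  ================
feature     native range
==========  ================
ASA (all)   [0, 150] %
kappa       [0, 180] deg
phi/psi/alpha  [-180, 180] deg
HHC         already {0, 1}
==========  ================

Angle periodicity is ignored by the linear map — a known limitation for
phi values near +-180 deg.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import contacts, geometry, surface
from .io import Chain, SegmentAnnotation

#: The eight ESF names in canonical order.
ESF_NAMES = ["tASA", "scASA", "npASA", "hhc", "phi", "psi", "kappa", "alpha"]

#: Fixed (lo, hi) scaling ranges per feature.
SCALING_RANGES = {
    "tASA": (0.0, 150.0),
    "scASA": (0.0, 150.0),
    "npASA": (0.0, 150.0),
    "hhc": (0.0, 1.0),
    "phi": (-180.0, 180.0),
    "psi": (-180.0, 180.0),
    "kappa": (0.0, 180.0),
    "alpha": (-180.0, 180.0),
}


def compute_esf(chain: Chain, segments: SegmentAnnotation,
                probe: float = surface.DEFAULT_PROBE,
                contact_cutoff: float = contacts.DEFAULT_CUTOFF,
                n_points: int = surface.DEFAULT_N_POINTS,
                radii: dict | None = None) -> pd.DataFrame:
    """Per-residue feature table with all eight ESFs plus kink, z and tm.

    Delegates to :mod:`surface`, :mod:`contacts` and :mod:`geometry`;
    undefined constituents stay NaN. Deterministic: repeated calls yield
    identical tables.
    """
    asa = surface.residue_asa(chain, probe=probe, n_points=n_points, radii=radii)
    hhc = contacts.hhc_labels(chain, segments, cutoff=contact_cutoff)
    phi, psi = geometry.phi_psi(chain)
    kappa, alpha = geometry.kappa_alpha(chain)
    kink = geometry.kink_angle(chain, segments)["kink"]
    table = pd.DataFrame({
        "res_index": np.arange(len(chain)),
        "res_number": [r.res_number for r in chain.residues],
        "res_name": [r.res_name for r in chain.residues],
        "tASA": asa["tASA"].to_numpy(),
        "scASA": asa["scASA"].to_numpy(),
        "npASA": asa["npASA"].to_numpy(),
        "hhc": hhc["hhc"].to_numpy(),
        "phi": phi,
        "psi": psi,
        "kappa": kappa,
        "alpha": alpha,
        "kink": kink,
        "d_interhelix": hhc["d_interhelix"].to_numpy(),
        "z": segments.z_coord,
        "tm": segments.tm_flag,
        "tASA_abs": asa["tASA_abs"].to_numpy(),
        "scASA_abs": asa["scASA_abs"].to_numpy(),
        "npASA_abs": asa["npASA_abs"].to_numpy(),
    })
    return table


def scale(values, feature: str | None = None) -> np.ndarray:
    """Map native-unit ESF values onto [0, 1] with the fixed linear ranges.

    ``values`` may be a (L, 8) array/DataFrame in :data:`ESF_NAMES` order,
    or a 1-D vector with ``feature`` naming its ESF. Out-of-range inputs
    are clamped with a warning; NaN passes through.
    """
    if feature is not None:
        lo, hi = SCALING_RANGES[feature]
        v = np.asarray(values, dtype=float)
        return _scale_one(v, lo, hi, feature)
    if isinstance(values, pd.DataFrame):
        values = values[ESF_NAMES].to_numpy(dtype=float)
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    for j, name in enumerate(ESF_NAMES):
        lo, hi = SCALING_RANGES[name]
        out[..., j] = _scale_one(v[..., j], lo, hi, name)
    return out


def _scale_one(v, lo, hi, name):
    with np.errstate(invalid="ignore"):
        if np.any((v < lo) | (v > hi)):
            warnings.warn(f"{name}: values outside [{lo}, {hi}] clamped before scaling")
        v = np.clip(v, lo, hi)
    return (v - lo) / (hi - lo)


def unscale(values, feature: str | None = None) -> np.ndarray:
    """Inverse of :func:`scale`: [0, 1] back to native units."""
    if feature is not None:
        lo, hi = SCALING_RANGES[feature]
        return np.asarray(values, dtype=float) * (hi - lo) + lo
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    for j, name in enumerate(ESF_NAMES):
        lo, hi = SCALING_RANGES[name]
        out[..., j] = v[..., j] * (hi - lo) + lo
    return out


def esf_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Scaled (L, 8) target matrix and boolean mask (True = defined)."""
    native = table[ESF_NAMES].to_numpy(dtype=float)
    mask = np.isfinite(native)
    scaled = scale(native)
    return scaled, mask
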