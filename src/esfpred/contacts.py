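"""Helix-helix contacts within a single chain.

A TM residue is in helix-helix contact (HHC = 1) when any of its heavy
atoms lies within a cutoff (default 3.5 A) of any heavy atom of a residue
in a *different* TM helix of the same chain. Residues outside TM segments
have no HHC label (NaN); hydrogens are never present in the input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import Chain, SegmentAnnotation

DEFAULT_CUTOFF = 3.5


def _atom_table(chain: Chain, segments: SegmentAnnotation):
    coords, res_idx, _ = chain.all_atoms()
    seg_idx = np.array([segments.segment_of(int(i)) for i in res_idx])
    return coords, res_idx, seg_idx


def closest_interhelix_distance(chain: Chain, segments: SegmentAnnotation,
                                residue_index: int) -> float:
    """Minimum heavy-atom distance from a TM residue to any other TM helix.

    NaN for non-TM residues and for chains with a single TM segment
    (no partner helix).
    """
    own_seg = segments.segment_of(residue_index)
    if own_seg < 0:
        return np.nan
    coords, res_idx, seg_idx = _atom_table(chain, segments)
    own = coords[res_idx == residue_index]
    other = coords[(seg_idx >= 0) & (seg_idx != own_seg)]
    if len(own) == 0 or len(other) == 0:
        return np.nan
    d = np.sqrt(((own[:, None, :] - other[None, :, :]) ** 2).sum(axis=2))
    return float(d.min())


def hhc_labels(chain: Chain, segments: SegmentAnnotation,
               cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Per-residue contact labels and closest inter-helical distances.

    Returns a DataFrame with ``hhc`` (0/1 for TM residues, NaN otherwise)
    and ``d_interhelix`` (A, NaN where undefined). The distance column is
    the per-residue minimum, the basis of the closest-distance histogram
    from which the 3.5 A cutoff was chosen.
    """
    L = len(chain)
    hhc = np.full(L, np.nan)
    dmin = np.full(L, np.nan)
    coords, res_idx, seg_idx = _atom_table(chain, segments)
    tm_mask = seg_idx >= 0
    if tm_mask.sum() == 0:
        return pd.DataFrame({"hhc": hhc, "d_interhelix": dmin})
    tm_coords = coords[tm_mask]
    tm_res = res_idx[tm_mask]
    tm_seg = seg_idx[tm_mask]
    tree = cKDTree(tm_coords)
    n_segments = len(segments.helix_segments)
    for i in range(L):
        seg = segments.segment_of(i)
        if seg < 0:
            continue
        if n_segments < 2:
            continue  # no partner helix: HHC undefined
        own = coords[(res_idx == i)]
        best = np.inf
        for xyz in own:
            # expand the search radius until a foreign-segment atom is found
            r = max(cutoff, 4.0)
            while True:
                idx = tree.query_ball_point(xyz, r)
                foreign = [j for j in idx if tm_seg[j] != seg]
                if foreign:
                    d = np.sqrt(((tm_coords[foreign] - xyz) ** 2).sum(axis=1)).min()
                    best = min(best, float(d))
                    break
                if r > 1e6:
                    break
                r *= 4.0
        if np.isfinite(best):
            dmin[i] = best
            hhc[i] = 1.0 if best <= cutoff else 0.0
        else:
            hhc[i] = 0.0
    return pd.DataFrame({"hhc": hhc, "d_interhelix": dmin})
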