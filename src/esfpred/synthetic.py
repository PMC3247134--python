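"""Synthetic helical membrane proteins for end-to-end testing.

This module generates everything the pipeline consumes, with known ground
truth recorded in metadata:

* ideal-to-perturbed alpha-helices and kinked helices built from internal
  coordinates (NeRF construction), with full backbone, C-beta and a single
  side-chain centroid pseudo-atom per residue;
* multi-helix bundles on a circle with alternating antiparallel packing,
  short loops, TM segment annotation and per-residue membrane z;
* PSSM profiles whose columns carry a tunable linear signal about the
  residue's scaled ESF vector (signal_strength 0 = pure noise, 1 = pure
  signal), integer-rounded to the PSI-BLAST log-odds range [-10, 10];
* Gaussian network model (GNM) fluctuation profiles standing in for
  normal-mode B-factors, with chain ends more mobile than the core.

Everything is reproducible from integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Atom, Chain, PSSMProfile, Residue, SegmentAnnotation, AA1_TO_3, PSSM_ALPHABET

# Ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_CA_CB = 110.6
TORSION_N_C_CA_CB = 122.6  # L-amino-acid improper

#: Distance (A) from CA to the side-chain centroid pseudo-atom, and its radius.
SIDECHAIN_CENTROID = {
    "SER": (1.9, 1.7), "CYS": (2.0, 1.8), "THR": (1.9, 1.9), "VAL": (2.0, 2.0),
    "PRO": (1.9, 1.9), "LEU": (2.6, 2.2), "ILE": (2.3, 2.2), "MET": (2.9, 2.3),
    "ASN": (2.5, 2.0), "ASP": (2.5, 2.0), "GLN": (3.1, 2.2), "GLU": (3.1, 2.2),
    "LYS": (3.5, 2.3), "ARG": (4.1, 2.4), "HIS": (3.2, 2.2), "PHE": (3.4, 2.4),
    "TYR": (3.8, 2.5), "TRP": (3.9, 2.6),
}

# membrane-biased residue pools for random sequences
_HYDROPHOBIC = "AVLIFMGWT"
_POLAR = "STNQKRDEGP"


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d) given."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_peptide(sequence: str, phi, psi, omega: float = 180.0) -> Chain:
    """Build a peptide chain from phi/psi lists with ideal bond geometry.

    Backbone N, CA, C, O plus C-beta and a residue-specific side-chain
    centroid pseudo-atom (element C). phi[0] and psi[-1] are unused
    (undefined at the termini but must be supplied for alignment).
    """
    sequence = sequence.upper()
    L = len(sequence)
    if not (len(phi) == len(psi) == L):
        raise ValueError("phi/psi lists must match sequence length")
    for aa in sequence:
        if aa not in AA1_TO_3:
            raise ValueError(f"unknown residue {aa!r}")
    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    # first residue in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, L):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, omega)
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi[i])
    chain = Chain(chain_id="A")
    for i, aa in enumerate(sequence):
        res_name = AA1_TO_3[aa]
        res = Residue(res_number=i + 1, res_name=res_name)
        res.atoms.append(Atom("N", "N", N[i].copy()))
        res.atoms.append(Atom("CA", "C", CA[i].copy()))
        res.atoms.append(Atom("C", "C", C[i].copy()))
        # carbonyl O anti to the next N (torsion psi - 180)
        psi_eff = psi[i] if i < L - 1 else -40.0
        O = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi_eff - 180.0)
        res.atoms.append(Atom("O", "O", O))
        if res_name != "GLY":
            CB = place_atom(N[i], C[i], CA[i], BOND_CA_CB, ANGLE_C_CA_CB, TORSION_N_C_CA_CB)
            res.atoms.append(Atom("CB", "C", CB))
            if res_name in SIDECHAIN_CENTROID:
                dist, radius = SIDECHAIN_CENTROID[res_name]
                direction = CB - CA[i]
                direction /= np.linalg.norm(direction)
                res.atoms.append(Atom("SC1", "C", CA[i] + dist * direction,
                                      radius=radius))
        chain.residues.append(res)
    return chain


def _rotation_between(a, b) -> np.ndarray:
    """Rotation matrix sending unit vector a onto unit vector b (Rodrigues)."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 deg about any axis perpendicular to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_rotation(axis, 180.0)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_rotation(axis, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def transform_chain(chain: Chain, R=None, t=None, pivot=None, residue_slice=None) -> Chain:
    """Apply ``x -> R (x - pivot) + pivot + t`` in place; returns the chain."""
    R = np.eye(3) if R is None else np.asarray(R, float)
    t = np.zeros(3) if t is None else np.asarray(t, float)
    pivot = np.zeros(3) if pivot is None else np.asarray(pivot, float)
    residues = chain.residues if residue_slice is None else chain.residues[residue_slice]
    for res in residues:
        for a in res.atoms:
            a.xyz = R @ (a.xyz - pivot) + pivot + t
    return chain


def _align_to_z(chain: Chain) -> Chain:
    """Rotate so the CA screw axis lies along +z, centered at the origin.

    The axis of a periodic discrete helix is exactly parallel to the cross
    product of successive second differences of the CA trace (a TLS line
    fit would be biased by partial-turn coverage).
    """
    ca = chain.ca_coords()
    center = ca.mean(axis=0)
    d = np.diff(ca, axis=0)
    sd = np.diff(d, axis=0)
    axes = np.cross(sd[:-1], sd[1:])
    norms = np.linalg.norm(axes, axis=1, keepdims=True)
    axes = axes[norms[:, 0] > 1e-9] / norms[norms[:, 0] > 1e-9]
    chord = ca[-1] - ca[0]
    axes[axes @ chord < 0] *= -1
    axis = axes.mean(axis=0)
    axis /= np.linalg.norm(axis)
    R = _rotation_between(axis, [0.0, 0.0, 1.0])
    return transform_chain(chain, R=R, t=-center, pivot=center)


def build_helix(n_res: int, phi: float = -66.0, psi: float = -40.0,
                noise_sd: float = 0.0, seed: int | None = None,
                sequence: str | None = None) -> Chain:
    """Polyalanine (or given-sequence) alpha-helix aligned to the z-axis.

    phi/psi defaults are the observed means for TM helices (-66/-40 deg).
    Gaussian coordinate noise of ``noise_sd`` A is added when requested.
    """
    if n_res < 9:
        raise ValueError("build_helix needs n_res >= 9")
    seq = sequence if sequence is not None else "A" * n_res
    if len(seq) != n_res:
        raise ValueError("sequence length must equal n_res")
    chain = build_peptide(seq, [phi] * n_res, [psi] * n_res)
    chain = _align_to_z(chain)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for res in chain.residues:
            for a in res.atoms:
                a.xyz = a.xyz + rng.normal(0.0, noise_sd, 3)
    return chain


def build_kinked_helix(n_res: int, kink_pos: int, kink_deg: float,
                       seed: int | None = None, noise_sd: float = 0.0,
                       sequence: str | None = None) -> Chain:
    """Helix whose two arms meet at ``kink_pos`` with axis angle ``kink_deg``.

    Built by rigidly rotating the C-terminal arm about the hinge CA; the
    backbone stays connected (the single hinge peptide bond is distorted by
    up to ~1 A at 30 deg, the price of exact axis-angle control).
    """
    if not (0.0 <= kink_deg <= 90.0):
        raise ValueError("kink_deg must lie in [0, 90]")
    if not (4 < kink_pos < n_res - 4):
        raise ValueError("kink_pos must leave > 4 residues on each side")
    chain = build_helix(n_res, noise_sd=0.0, sequence=sequence)
    hinge = chain.residues[kink_pos].coord("CA").copy()
    # rotate about a horizontal axis through the hinge
    R = _axis_rotation([1.0, 0.0, 0.0], kink_deg)
    transform_chain(chain, R=R, pivot=hinge, residue_slice=slice(kink_pos + 1, None))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for res in chain.residues:
            for a in res.atoms:
                a.xyz = a.xyz + rng.normal(0.0, noise_sd, 3)
    return chain


@dataclass
class HelixSpec:
    n_res: int
    kink_pos: int | None = None  # position within the helix
    kink_deg: float = 0.0
    sequence: str | None = None


def build_bundle(helices: list[HelixSpec], spacing: float = 9.5,
                 loop_length: int = 4, noise_sd: float = 0.0,
                 seed: int | None = None,
                 loop_sequences: list[str] | None = None):
    """Helix bundle: helices on a circle, alternating antiparallel, short loops.

    Adjacent helix axes are ``spacing`` A apart; each helix is centered at
    z = 0 so membrane z-coordinates come directly from the construction.
    Returns ``(chain, segments, metadata)`` where metadata records every
    construction parameter (ground truth for recovery tests).
    """
    if not helices:
        raise ValueError("need at least one helix")
    rng = np.random.default_rng(seed)
    n_h = len(helices)
    if n_h == 1:
        centers = [np.zeros(2)]
    else:
        radius = spacing / (2.0 * np.sin(np.pi / n_h)) if n_h > 2 else spacing / 2.0
        angles = 2.0 * np.pi * np.arange(n_h) / n_h
        centers = [radius * np.array([np.cos(a), np.sin(a)]) for a in angles]
    chain = Chain(chain_id="A")
    segments: list[tuple[int, int]] = []
    metadata = {"spacing": spacing, "helices": []}
    prev_end_ca = None
    for k, spec in enumerate(helices):
        if spec.kink_pos is not None and spec.kink_deg > 0:
            helix = build_kinked_helix(spec.n_res, spec.kink_pos, spec.kink_deg,
                                       sequence=spec.sequence)
        else:
            helix = build_helix(spec.n_res, sequence=spec.sequence)
        if k % 2 == 1:  # antiparallel: flip about the x-axis
            transform_chain(helix, R=_axis_rotation([1.0, 0.0, 0.0], 180.0))
        transform_chain(helix, t=np.array([centers[k][0], centers[k][1], 0.0]))
        start_ca = helix.residues[0].coord("CA")
        if prev_end_ca is not None:
            _append_loop(chain, prev_end_ca, start_ca, loop_length, rng,
                         sequence=None if loop_sequences is None else loop_sequences[k - 1])
        seg_start = len(chain.residues)
        chain.residues.extend(helix.residues)
        segments.append((seg_start, seg_start + spec.n_res))
        prev_end_ca = helix.residues[-1].coord("CA")
        kink_chain_pos = None if spec.kink_pos is None else seg_start + spec.kink_pos
        metadata["helices"].append({
            "segment": (seg_start, seg_start + spec.n_res),
            "antiparallel": k % 2 == 1,
            "kink_pos": kink_chain_pos,
            "kink_deg": spec.kink_deg if spec.kink_pos is not None else 0.0,
        })
    for i, res in enumerate(chain.residues):
        res.res_number = i + 1
    if noise_sd > 0:
        for res in chain.residues:
            for a in res.atoms:
                a.xyz = a.xyz + rng.normal(0.0, noise_sd, 3)
    z = chain.ca_coords()[:, 2].copy()
    seg = SegmentAnnotation(helix_segments=segments, n_residues=len(chain.residues),
                            z_coord=z)
    z_masked = np.where(seg.tm_flag, z, np.nan)
    seg.z_coord = z_masked
    return chain, seg, metadata


def _append_loop(chain: Chain, p_from: np.ndarray, p_to: np.ndarray,
                 n_loop: int, rng, sequence: str | None = None) -> None:
    """Crude connecting loop: CA path interpolated with an outward bow."""
    if n_loop <= 0:
        return
    if sequence is None:
        sequence = "".join(rng.choice(list(_POLAR), size=n_loop))
    direction = p_to - p_from
    mid_out = (p_from + p_to) / 2.0
    radial = mid_out[:2]
    nrm = np.linalg.norm(radial)
    bow = np.zeros(3)
    if nrm > 1e-6:
        bow[:2] = radial / nrm * 3.0
    bow[2] = 3.0 * np.sign(mid_out[2]) if abs(mid_out[2]) > 1e-6 else 3.0
    start = len(chain.residues)
    for j in range(n_loop):
        f = (j + 1) / (n_loop + 1)
        ca = p_from + f * direction + np.sin(np.pi * f) * bow
        tangent = direction / max(np.linalg.norm(direction), 1e-6)
        res_name = AA1_TO_3[sequence[j]]
        res = Residue(res_number=start + j + 1, res_name=res_name)
        res.atoms.append(Atom("N", "N", ca - 1.2 * tangent + np.array([0.3, 0.0, 0.3])))
        res.atoms.append(Atom("CA", "C", ca.copy()))
        res.atoms.append(Atom("C", "C", ca + 1.2 * tangent))
        res.atoms.append(Atom("O", "O", ca + 1.2 * tangent + np.array([0.0, 1.0, 0.5])))
        if res_name != "GLY":
            # side chain pointing along the outward bow, away from the path
            side = bow / max(np.linalg.norm(bow), 1e-6)
            res.atoms.append(Atom("CB", "C", ca + 1.53 * side))
            if res_name in SIDECHAIN_CENTROID:
                dist, radius = SIDECHAIN_CENTROID[res_name]
                res.atoms.append(Atom("SC1", "C", ca + dist * side, radius=radius))
        chain.residues.append(res)


# ---------------------------------------------------------------------------
# Coupled PSSMs

#: Seed of the fixed ESF-to-log-odds projection (shared across a corpus so
#: the mapping is learnable between proteins).
PROJECTION_SEED = 20105330

SIGNAL_GAIN = 8.0
NOISE_SD = 3.0


def esf_projection(projection_seed: int = PROJECTION_SEED) -> np.ndarray:
    """Fixed (20, 8) unit-row projection from scaled ESFs to log-odds space."""
    rng = np.random.default_rng(projection_seed)
    P = rng.normal(size=(20, 8))
    P /= np.linalg.norm(P, axis=1, keepdims=True)
    return P


def synth_pssm(chain: Chain, esf_scaled: np.ndarray, signal_strength: float,
               seed: int | None = None,
               projection_seed: int = PROJECTION_SEED) -> PSSMProfile:
    """PSSM whose columns carry a tunable linear signal about the ESFs.

    ``esf_scaled`` is the (L, 8) scaled ESF matrix (NaN allowed; treated as
    neutral 0.5). Each row of log-odds is
    ``signal * gain * P @ (2 esf - 1) + (1 - signal) * noise``, rounded to
    integers and clipped to the PSI-BLAST-like range [-10, 10].
    """
    if not (0.0 <= signal_strength <= 1.0):
        raise ValueError("signal_strength must lie in [0, 1]")
    esf = np.asarray(esf_scaled, dtype=float)
    if esf.shape != (len(chain), 8):
        raise ValueError("esf_scaled must be (L, 8)")
    z = 2.0 * (np.nan_to_num(esf, nan=0.5) - 0.5)
    P = esf_projection(projection_seed)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, NOISE_SD, size=(len(chain), 20))
    raw = signal_strength * SIGNAL_GAIN * (z @ P.T) + (1.0 - signal_strength) * noise
    logodds = np.clip(np.round(raw), -10, 10)
    seq = chain.sequence
    counts = np.array([seq.count(a) for a in PSSM_ALPHABET], dtype=float)
    if counts.sum() == 0:
        counts = np.ones(20)
    return PSSMProfile(logodds=logodds, composition=counts / counts.sum(), sequence=seq)


# ---------------------------------------------------------------------------
# GNM fluctuations

def gnm_bfactors(chain: Chain, cutoff: float = 7.0) -> np.ndarray:
    """Per-residue fluctuation profile from a C-alpha Gaussian network model.

    Diagonal of the pseudoinverse of the Kirchhoff (connectivity) matrix at
    the given CA-CA cutoff, scaled to mean 1. Raises on a disconnected
    contact graph (the pseudoinverse diagonal is meaningless then).
    """
    ca = chain.ca_coords()
    if len(ca) < 3 or not np.all(np.isfinite(ca)):
        raise ValueError("gnm_bfactors needs >= 3 residues with CA coordinates")
    d = np.sqrt(((ca[:, None, :] - ca[None, :, :]) ** 2).sum(axis=2))
    contact = (d <= cutoff) & ~np.eye(len(ca), dtype=bool)
    from scipy.sparse.csgraph import connected_components
    n_comp, _ = connected_components(contact.astype(int), directed=False)
    if n_comp > 1:
        raise ValueError(f"contact graph disconnected ({n_comp} components) at cutoff {cutoff}")
    kirchhoff = -contact.astype(float)
    np.fill_diagonal(kirchhoff, contact.sum(axis=1))
    diag = np.diag(np.linalg.pinv(kirchhoff, hermitian=True)).copy()
    return diag / diag.mean()


# ---------------------------------------------------------------------------
# Corpus

@dataclass
class CorpusSpec:
    """Conditions under which a synthetic corpus is generated."""

    n_proteins: int = 12
    helices_per_protein: tuple[int, int] = (2, 4)  # inclusive range
    helix_length: tuple[int, int] = (16, 24)
    kink_prob: float = 0.3
    kink_angle_range: tuple[float, float] = (15.0, 45.0)
    coord_noise_sd: float = 0.15
    pssm_signal_strength: float = 1.0
    spacing: float = 9.5
    loop_length: int = 4
    asa_n_points: int = 960
    gnm_cutoff: float = 7.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.pssm_signal_strength <= 1.0):
            raise ValueError("pssm_signal_strength must lie in [0, 1]")
        for rng_ in (self.helices_per_protein, self.helix_length, self.kink_angle_range):
            if rng_[1] < rng_[0]:
                raise ValueError(f"empty range {rng_}")


@dataclass
class SyntheticProtein:
    protein_id: str
    chain: Chain
    segments: SegmentAnnotation
    pssm: PSSMProfile
    flex: np.ndarray
    esf_table: "object"  # pandas DataFrame; avoided at import time
    metadata: dict = field(default_factory=dict)


def save_corpus(corpus: list[SyntheticProtein], directory) -> None:
    """Write a corpus as plain-text files (PDB, TSVs, PSSM, JSON metadata)."""
    import json
    from pathlib import Path
    from . import io as eio

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    index = []
    for prot in corpus:
        stem = d / prot.protein_id
        eio.write_pdb_chain(prot.chain, f"{stem}.pdb")
        eio.write_segments(prot.segments, f"{stem}.segments.tsv")
        eio.write_residue_scalar(prot.segments.z_coord, f"{stem}.z.tsv")
        eio.write_pssm(prot.pssm, f"{stem}.pssm")
        eio.write_residue_scalar(prot.flex, f"{stem}.flex.tsv")
        eio.write_feature_table(prot.esf_table, f"{stem}.esf.tsv")
        index.append({"id": prot.protein_id, "metadata": _jsonable(prot.metadata)})
    with open(d / "corpus.json", "w") as fh:
        json.dump({"proteins": index}, fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_corpus(directory) -> list[SyntheticProtein]:
    """Read back a corpus written by :func:`save_corpus`."""
    import json
    from pathlib import Path
    from . import io as eio

    d = Path(directory)
    with open(d / "corpus.json") as fh:
        index = json.load(fh)["proteins"]
    corpus = []
    for entry in index:
        stem = d / entry["id"]
        chain = eio.read_pdb_chain(f"{stem}.pdb", chain_id="A")
        segments = eio.read_segments(f"{stem}.segments.tsv", n_residues=len(chain),
                                     z_path=f"{stem}.z.tsv")
        pssm = eio.read_pssm(f"{stem}.pssm")
        flex = eio.read_residue_scalar(f"{stem}.flex.tsv", n_residues=len(chain))
        table = eio.read_feature_table(f"{stem}.esf.tsv")
        corpus.append(SyntheticProtein(
            protein_id=entry["id"], chain=chain, segments=segments, pssm=pssm,
            flex=flex, esf_table=table, metadata=entry.get("metadata", {})))
    return corpus


def make_corpus(spec: CorpusSpec) -> list[SyntheticProtein]:
    """Fully reproducible corpus of synthetic membrane proteins.

    Each protein carries its chain, TM segments with membrane z, a coupled
    PSSM, a GNM fluctuation profile and the observed ESF table; metadata
    records all construction parameters.
    """
    from . import features  # deferred: features imports surface which builds peptides

    proteins = []
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(spec.n_proteins)
    for p in range(spec.n_proteins):
        rng = np.random.default_rng(child_seeds[p])
        n_h = int(rng.integers(spec.helices_per_protein[0], spec.helices_per_protein[1] + 1))
        helix_specs = []
        for _h in range(n_h):
            n_res = int(rng.integers(spec.helix_length[0], spec.helix_length[1] + 1))
            seq = "".join(rng.choice(list(_HYDROPHOBIC), size=n_res))
            kink_pos = None
            kink_deg = 0.0
            if rng.random() < spec.kink_prob and n_res >= 12:
                kink_pos = int(rng.integers(5, n_res - 5))
                kink_deg = float(rng.uniform(*spec.kink_angle_range))
            helix_specs.append(HelixSpec(n_res=n_res, kink_pos=kink_pos,
                                         kink_deg=kink_deg, sequence=seq))
        bundle_seed = int(rng.integers(2 ** 31))
        chain, segments, meta = build_bundle(
            helix_specs, spacing=spec.spacing, loop_length=spec.loop_length,
            noise_sd=spec.coord_noise_sd, seed=bundle_seed)
        table = features.compute_esf(chain, segments, n_points=spec.asa_n_points)
        scaled, _mask = features.esf_matrix(table)
        pssm_seed = int(rng.integers(2 ** 31))
        pssm = synth_pssm(chain, scaled, spec.pssm_signal_strength, seed=pssm_seed)
        flex = gnm_bfactors(chain, cutoff=spec.gnm_cutoff)
        meta.update({"seed": spec.seed, "protein_index": p,
                     "signal_strength": spec.pssm_signal_strength})
        proteins.append(SyntheticProtein(
            protein_id=f"syn{p:03d}", chain=chain, segments=segments,
            pssm=pssm, flex=flex, esf_table=table, metadata=meta))
    return proteins
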