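"""Readers and writers for structures, PSSM profiles and feature tables.

Internal residue indexing is 0-based and positional (file order), decoupled
from PDB residue numbers; the original author-assigned number is carried
along in ``res_number``. Hydrogens are always discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: PSI-BLAST column order for the 20 log-odds columns.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    bfactor: float = 0.0
    #: explicit radius override in Angstrom (side-chain centroid pseudo-atoms);
    #: None = use the element-based radii table
    radius: float | None = None


@dataclass
class Residue:
    res_number: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.xyz


@dataclass
class Chain:
    """A single protein chain: ordered residues with heavy-atom coordinates."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(AA3_TO_1.get(r.res_name, "X") for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(L, 3) array of C-alpha coordinates; NaN rows where CA is missing."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, res in enumerate(self.residues):
            xyz = res.coord("CA")
            if xyz is not None:
                out[i] = xyz
        return out

    def all_atoms(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Flat arrays of (coords, residue indices, element symbols)."""
        coords, res_idx, elements = [], [], []
        for i, res in enumerate(self.residues):
            for a in res.atoms:
                coords.append(a.xyz)
                res_idx.append(i)
                elements.append(a.element)
        return np.asarray(coords, dtype=float), np.asarray(res_idx), elements


@dataclass
class SegmentAnnotation:
    """TM helix segments as half-open [start, end) 0-based residue ranges.

    ``z_coord`` holds the per-residue distance from the membrane mid-plane
    in Angstrom (NaN where unknown); ``tm_flag`` marks membrane-spanning
    residues and is true exactly for residues covered by a segment.
    """

    helix_segments: list[tuple[int, int]]
    n_residues: int
    z_coord: np.ndarray | None = None

    def __post_init__(self):
        segs = sorted(self.helix_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping segments ({s1},{e1}) and ({s2},{e2})")
        for s, e in segs:
            if not (0 <= s < e <= self.n_residues):
                raise ValueError(f"segment ({s},{e}) outside chain of length {self.n_residues}")
        self.helix_segments = segs
        if self.z_coord is None:
            self.z_coord = np.full(self.n_residues, np.nan)
        else:
            self.z_coord = np.asarray(self.z_coord, dtype=float)

    @property
    def tm_flag(self) -> np.ndarray:
        flag = np.zeros(self.n_residues, dtype=bool)
        for s, e in self.helix_segments:
            flag[s:e] = True
        return flag

    def segment_of(self, i: int) -> int:
        """Index of the segment containing residue i, or -1."""
        for k, (s, e) in enumerate(self.helix_segments):
            if s <= i < e:
                return k
        return -1


@dataclass
class PSSMProfile:
    """PSI-BLAST position-specific scoring matrix plus sequence composition."""

    logodds: np.ndarray  # (L, 20) in PSSM_ALPHABET order
    composition: np.ndarray  # (20,) fractions summing to 1
    sequence: str = ""

    def __post_init__(self):
        self.logodds = np.asarray(self.logodds, dtype=float)
        self.composition = np.asarray(self.composition, dtype=float)
        if self.logodds.ndim != 2 or self.logodds.shape[1] != 20:
            raise ValueError("logodds must be (L, 20)")
        if self.composition.shape != (20,):
            raise ValueError("composition must have 20 entries")
        if np.any(self.composition < 0) or abs(self.composition.sum() - 1.0) > 1e-9:
            raise ValueError("composition must be non-negative and sum to 1")

    def __len__(self) -> int:
        return self.logodds.shape[0]


# ---------------------------------------------------------------------------
# PDB

def read_pdb_chain(path, chain_id: str, model: int = 1) -> Chain:
    """Read one chain from a PDB file into a :class:`Chain`.

    Heavy atoms only; for alternate locations the highest-occupancy variant
    is kept; HETATM records are ignored. Residues with insertion codes are
    kept in file order.
    """
    pdb_file = pdb.PDBFile.read(str(path))
    arr = pdb_file.get_structure(
        model=model, altloc="occupancy", extra_fields=["b_factor"]
    )
    mask = (arr.chain_id == chain_id) & ~arr.hetero
    mask &= ~np.isin(arr.element, ("H", "D"))
    arr = arr[mask]
    if arr.array_length() == 0:
        available = sorted(set(pdb_file.get_structure(model=model).chain_id))
        raise ValueError(
            f"no ATOM records for chain {chain_id!r} in {path} "
            f"(available chains: {available})"
        )
    chain = Chain(chain_id=chain_id)
    current_key = None
    for i in range(arr.array_length()):
        key = (arr.res_id[i], arr.ins_code[i])
        if key != current_key:
            chain.residues.append(Residue(int(arr.res_id[i]), str(arr.res_name[i])))
            current_key = key
        chain.residues[-1].atoms.append(
            Atom(
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                xyz=np.array(arr.coord[i], dtype=float),
                bfactor=float(arr.b_factor[i]),
            )
        )
    for res in chain.residues:
        if not np.all(np.isfinite([a.xyz for a in res.atoms])):
            raise ValueError(f"non-finite coordinates in residue {res.res_number}")
    return chain


def write_pdb_chain(chain: Chain, path) -> None:
    """Serialize a :class:`Chain` back to a single-model PDB file."""
    n = sum(len(r.atoms) for r in chain.residues)
    arr = struc.AtomArray(n)
    arr.set_annotation("b_factor", np.zeros(n))
    k = 0
    for res in chain.residues:
        for a in res.atoms:
            arr.chain_id[k] = chain.chain_id
            arr.res_id[k] = res.res_number
            arr.res_name[k] = res.res_name
            arr.atom_name[k] = a.name
            arr.element[k] = a.element
            arr.coord[k] = a.xyz
            arr.b_factor[k] = a.bfactor
            arr.hetero[k] = False
            k += 1
    out = pdb.PDBFile()
    out.set_structure(arr)
    out.write(str(path))


# ---------------------------------------------------------------------------
# PSSM

def read_pssm(path) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM file.

    Only the 20 log-odds columns are used; the sequence column yields the
    amino acid composition. Raises ``ValueError`` with a line number on
    malformed input.
    """
    lines = Path(path).read_text().splitlines()
    alphabet = None
    rows, seq = [], []
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if alphabet is None:
            if len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens[:20]):
                alphabet = "".join(tokens[:20])
            continue
        if len(tokens) < 22:
            if rows:
                break  # footer reached
            continue
        try:
            int(tokens[0])
        except ValueError:
            if rows:
                break
            continue
        aa = tokens[1]
        try:
            values = [float(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric PSSM cell ({exc})") from None
        seq.append(aa)
        rows.append(values)
    if alphabet is None or not rows:
        raise ValueError(f"{path}: no PSSM matrix found (truncated or empty file)")
    logodds = np.asarray(rows, dtype=float)
    # reorder columns into the canonical PSSM_ALPHABET order if needed
    if alphabet != PSSM_ALPHABET:
        order = [alphabet.index(a) for a in PSSM_ALPHABET]
        logodds = logodds[:, order]
    sequence = "".join(seq)
    counts = np.array([sequence.count(a) for a in PSSM_ALPHABET], dtype=float)
    if counts.sum() == 0:
        raise ValueError(f"{path}: sequence column contains no standard residues")
    composition = counts / counts.sum()
    return PSSMProfile(logodds=logodds, composition=composition, sequence=sequence)


def write_pssm(profile: PSSMProfile, path) -> None:
    """Write a PSSM in PSI-BLAST-like ASCII layout (round-trips via read_pssm)."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("    " + "  ".join(PSSM_ALPHABET) + "   " + "  ".join(PSSM_ALPHABET) + "\n")
        for i in range(len(profile)):
            aa = profile.sequence[i] if i < len(profile.sequence) else "X"
            cells = " ".join(f"{v:6.0f}" for v in profile.logodds[i])
            # dummy percentage block + info/weight columns, as PSI-BLAST prints
            pct = " ".join("0" for _ in range(20))
            fh.write(f"{i + 1:5d} {aa} {cells}  {pct}  0.00 0.00\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# Per-residue scalars and segments

def read_residue_scalar(path, n_residues: int | None = None) -> np.ndarray:
    """Read a two-column TSV (0-based residue index, value) into a vector.

    Missing indices become NaN. Duplicate indices are an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["index", "value"])
    idx = df["index"].to_numpy(dtype=int)
    if len(np.unique(idx)) != len(idx):
        dup = idx[pd.Series(idx).duplicated()][0]
        raise ValueError(f"{path}: duplicate residue index {dup}")
    length = n_residues if n_residues is not None else (idx.max() + 1 if len(idx) else 0)
    out = np.full(length, np.nan)
    out[idx] = df["value"].to_numpy(dtype=float)
    return out


def write_residue_scalar(values: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if np.isfinite(v):
                fh.write(f"{i}\t{v:.10g}\n")


def read_segments(path, n_residues: int, z_path=None) -> SegmentAnnotation:
    """Read TM segments from a TSV with columns start, end (half-open, 0-based)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    unknown = set(df.columns) - {"start", "end"}
    if unknown:
        raise ValueError(f"{path}: unknown segment columns {sorted(unknown)}")
    segments = [(int(s), int(e)) for s, e in zip(df["start"], df["end"])]
    z = read_residue_scalar(z_path, n_residues) if z_path is not None else None
    return SegmentAnnotation(helix_segments=segments, n_residues=n_residues, z_coord=z)


def write_segments(segments: SegmentAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\n")
        for s, e in segments.helix_segments:
            fh.write(f"{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Feature tables

#: Canonical feature-table columns, in stable output order.
FEATURE_COLUMNS = [
    "res_index", "res_number", "res_name",
    "tASA", "scASA", "npASA", "hhc",
    "phi", "psi", "kappa", "alpha",
    "kink", "d_interhelix", "z", "tm",
    "tASA_abs", "scASA_abs", "npASA_abs",
]

_FLOAT_COLUMNS = [c for c in FEATURE_COLUMNS if c not in ("res_index", "res_number", "res_name", "tm")]


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a per-residue feature table as TSV (empty cell = undefined)."""
    unknown = set(table.columns) - set(FEATURE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown feature columns {sorted(unknown)}")
    cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    out = table[cols].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    unknown = set(df.columns) - set(FEATURE_COLUMNS)
    if unknown:
        raise ValueError(f"{path}: unknown feature columns {sorted(unknown)}")
    for c in df.columns:
        if c in _FLOAT_COLUMNS:
            df[c] = df[c].astype(float)
    if "tm" in df.columns:
        df["tm"] = df["tm"].astype(bool)
    return df
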