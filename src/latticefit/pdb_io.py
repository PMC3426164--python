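"""Extraction of fitting targets from PDB files and output writers.

The fitting target of a residue is its Cα position and, in side-chain mode,
the geometric centre of its non-hydrogen side-chain atoms (backbone atoms
N, CA, C, O and the terminal OXT are excluded).  Glycine has no heavy
side-chain atom; its Cα position doubles as the side-chain target so every
residue keeps the two-monomer layout the side-chain model requires.

Experimental structures are often fragmented (unresolved loops); residues
are grouped into contiguous fragments, broken wherever the author numbering
jumps or consecutive Cα atoms are further apart than ``MAX_CA_CA`` (4.5 Å —
loose enough for cis-proline linkages at ~2.9 Å and trans at ~3.8 Å, tight
enough to reject non-bonded neighbours).  Each fragment is fitted
independently.

Parsing and PDB writing are delegated to :mod:`gemmi`; only the first MODEL
is read and alternate locations other than blank/'A' are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import gemmi
import numpy as np

from .errors import (
    ChainNotFoundError,
    EmptyStructureError,
    PDBError,
    UnsupportedInputError,
)

__all__ = [
    "Residue",
    "Fragment",
    "TargetStructure",
    "parse_pdb",
    "load_pdb",
    "write_model_pdb",
    "write_xyz",
    "fetch_pdb",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
MAX_CA_CA = 4.5  # Å; consecutive-Cα distance beyond which a chain break is assumed

BACKBONE = "backbone"
SIDE_CHAIN = "side-chain"


@dataclass(frozen=True)
class Residue:
    """One residue's fitting target."""

    name: str
    number: int
    icode: str
    ca: np.ndarray
    centroid: Optional[np.ndarray]
    has_side_chain_atoms: bool = False

    @property
    def label(self) -> str:
        return f"{self.number}{self.icode}".strip()


@dataclass
class Fragment:
    """A contiguous stretch of resolved residues."""

    residues: list[Residue]
    chain_id: str = "A"

    def __len__(self) -> int:
        return len(self.residues)

    def ca_array(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    def centroid_array(self) -> np.ndarray:
        if any(r.centroid is None for r in self.residues):
            raise PDBError("fragment parsed in backbone-only mode has no centroids")
        return np.array([r.centroid for r in self.residues], dtype=float)

    def points(self, mode: str) -> np.ndarray:
        """Target points in fitting order: Cα only, or (Cα, centroid) per residue."""
        ca = self.ca_array()
        if mode == BACKBONE:
            return ca
        cen = self.centroid_array()
        out = np.empty((2 * len(self), 3), dtype=float)
        out[0::2] = ca
        out[1::2] = cen
        return out


@dataclass
class TargetStructure:
    """All fragments of one chain, ready for fitting."""

    fragments: list[Fragment]
    chain_id: str = "A"
    mode: str = BACKBONE
    source: str = ""

    @property
    def n_residues(self) -> int:
        return sum(len(f) for f in self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)


def _residue_target(res: gemmi.Residue, mode: str) -> Optional[Residue]:
    """Extract Cα and side-chain centroid from one gemmi residue, or None."""
    ca = None
    side = []
    for atom in res:
        if atom.altloc not in ("\0", "A"):
            continue
        if atom.element.is_hydrogen:
            continue
        if atom.name == "CA":
            if ca is None or atom.occ > ca.occ:
                ca = atom
        elif atom.name not in BACKBONE_ATOMS:
            side.append(atom.pos)
    if ca is None:
        return None
    ca_xyz = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
    centroid = None
    if mode == SIDE_CHAIN:
        if side:
            centroid = np.array([[p.x, p.y, p.z] for p in side]).mean(axis=0)
        else:
            centroid = ca_xyz.copy()  # Gly (or stripped residue): reuse Cα
    return Residue(res.name, res.seqid.num, res.seqid.icode.strip(), ca_xyz,
                   centroid, has_side_chain_atoms=bool(side))


def parse_pdb(source: str, chain: Optional[str] = None, mode: str = BACKBONE) -> TargetStructure:
    """Parse PDB-format text into a :class:`TargetStructure`.

    Parameters
    ----------
    source:
        PDB-format text (use :func:`load_pdb` for files).
    chain:
        Chain identifier; ``None`` selects the first chain containing a Cα.
    mode:
        ``"backbone"`` or ``"side-chain"``.

    Raises
    ------
    ChainNotFoundError
        The requested chain is absent.
    EmptyStructureError
        No residue with a Cα coordinate.
    UnsupportedInputError
        Side-chain mode requested but the chain is Cα-only.
    """
    if mode not in (BACKBONE, SIDE_CHAIN):
        raise ValueError(f"mode must be {BACKBONE!r} or {SIDE_CHAIN!r}, got {mode!r}")
    try:
        st = gemmi.read_pdb_string(source)
    except (RuntimeError, ValueError) as exc:
        raise PDBError(f"cannot parse PDB input: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError("no MODEL/coordinates in input")
    model = st[0]

    gchain = None
    if chain is None:
        for ch in model:
            if any(a.name == "CA" for res in ch for a in res):
                gchain = ch
                break
        if gchain is None:
            raise EmptyStructureError("no chain with Cα atoms found")
    else:
        gchain = model.find_chain(chain)
        if gchain is None:
            names = ", ".join(ch.name for ch in model) or "none"
            raise ChainNotFoundError(f"chain {chain!r} not found (available: {names})")

    residues = [r for r in (_residue_target(res, mode) for res in gchain) if r is not None]
    if not residues:
        raise EmptyStructureError(f"chain {gchain.name!r} has no residue with a Cα atom")
    if mode == SIDE_CHAIN and not any(r.has_side_chain_atoms for r in residues):
        raise UnsupportedInputError(
            f"chain {gchain.name!r} is Cα-only; side-chain mode needs side-chain atoms"
        )

    fragments: list[Fragment] = []
    current: list[Residue] = []
    for res in residues:
        if current:
            prev = current[-1]
            num_ok = 0 <= res.number - prev.number <= 1
            dist_ok = float(np.linalg.norm(res.ca - prev.ca)) <= MAX_CA_CA
            if not (num_ok and dist_ok):
                fragments.append(Fragment(current, gchain.name))
                current = []
        current.append(res)
    if current:
        fragments.append(Fragment(current, gchain.name))
    return TargetStructure(fragments, gchain.name, mode)


def load_pdb(path, chain: Optional[str] = None, mode: str = BACKBONE) -> TargetStructure:
    """Read a PDB file from disk; see :func:`parse_pdb`."""
    with open(path) as fh:
        target = parse_pdb(fh.read(), chain, mode)
    target.source = str(path)
    return target


def fetch_pdb(pdb_id: str) -> str:
    """Download PDB-format text for a 4-character identifier (convenience only)."""
    from urllib.request import urlopen

    if len(pdb_id) != 4:
        raise ValueError(f"PDB identifiers have 4 characters, got {pdb_id!r}")
    with urlopen(f"https://files.rcsb.org/download/{pdb_id.lower()}.pdb") as resp:
        return resp.read().decode()


def _results_list(fit) -> list:
    return list(fit) if isinstance(fit, (list, tuple)) else [fit]


def write_model_pdb(fit, conect: bool = False) -> str:
    """Render fitted model(s) as PDB text.

    One ``ATOM`` record per backbone monomer (atom name ``CA``) and, for
    side-chain models, one per side-chain monomer (``CB``), carrying the
    original residue names and author numbering.  Fragments of the same
    target become separate gemmi "chains" internally but share the original
    chain identifier, which yields TER-separated segments.  ``conect`` adds
    CONECT records for backbone and side-chain bonds.
    """
    results = _results_list(fit)
    st = gemmi.Structure()
    st.name = "lattice model"
    gmodel = gemmi.Model("1")
    serial = 0
    bonds: list[tuple[int, int]] = []
    for fi, res_fit in enumerate(results):
        frag = res_fit.fragment
        real = res_fit.superposed
        ch = gemmi.Chain(frag.chain_id or "A")
        prev_ca_serial = None
        for i, res in enumerate(frag.residues):
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            serial += 1
            ca = gemmi.Atom()
            ca.name = "CA"
            ca.element = gemmi.Element("C")
            ca.occ = 1.0
            ca.serial = serial
            ca.pos = gemmi.Position(*real.backbone[i])
            gres.add_atom(ca)
            if prev_ca_serial is not None:
                bonds.append((prev_ca_serial, serial))
            prev_ca_serial = serial
            if real.side_chains is not None:
                serial += 1
                cb = gemmi.Atom()
                cb.name = "CB"
                cb.element = gemmi.Element("C")
                cb.occ = 1.0
                cb.serial = serial
                cb.pos = gemmi.Position(*real.side_chains[i])
                gres.add_atom(cb)
                bonds.append((prev_ca_serial, serial))
            ch.add_residue(gres)
        gmodel.add_chain(ch)
    st.add_model(gmodel)
    text = st.make_pdb_string()
    if conect:
        lines = [ln for ln in text.splitlines() if not ln.startswith("END")]
        for a, b in bonds:
            lines.append(f"CONECT{a:5d}{b:5d}")
            lines.append(f"CONECT{b:5d}{a:5d}")
        lines.append("END")
        text = "\n".join(lines) + "\n"
    return text


def write_xyz(fit, comment: str = "") -> str:
    """Render fitted model(s) in XYZ format.

    Backbone monomers are labelled ``C``, side-chain monomers ``S``; the
    per-residue interleaving matches the fitting order.
    """
    results = _results_list(fit)
    rows: list[str] = []
    for res_fit in results:
        real = res_fit.superposed
        pts = real.interleaved()
        labels = (["C"] if real.side_chains is None else ["C", "S"]) * len(real)
        for lab, p in zip(labels, pts):
            rows.append(f"{lab} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    if not rows:
        raise ValueError("nothing to write: empty model")
    head = comment or "lattice protein model"
    return f"{len(rows)}\n{head}\n" + "\n".join(rows) + "\n"
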