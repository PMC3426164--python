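"""Lattice protein models and their validity rules.

A model of length ``l`` is a backbone node sequence, plus — in side-chain
mode — one side-chain node per residue (the Bromberg–Dill two-monomer
representation).  A model is *valid* when

* consecutive backbone nodes differ by a neighbour vector,
* each side-chain node is adjacent to its backbone node, and
* all occupied nodes are pairwise distinct (self-avoidance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InvalidStructureError
from .lattices import LatticeSpec, PointGroup, point_group as _point_group

__all__ = ["LatticeModel", "RealModel", "ValidityReport", "canonical_form"]


@dataclass(frozen=True)
class ValidityReport:
    """Outcome of a validity check: ``ok`` or the first violated constraint.

    ``kind`` is one of ``backbone-break``, ``side-chain-break``,
    ``collision`` (with the offending indices into the interleaved node
    sequence) or ``None`` when valid.
    """

    ok: bool
    kind: Optional[str] = None
    indices: Optional[tuple[int, ...]] = None

    def __bool__(self) -> bool:
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "valid"
        return f"{self.kind} at {self.indices}"


class LatticeModel:
    """A (possibly invalid) lattice protein structure.

    Parameters
    ----------
    backbone:
        (l, 3) integer array of backbone nodes.
    side_chains:
        Optional (l, 3) integer array of side-chain nodes; all-or-none.
    lattice:
        The lattice the model lives on.
    """

    __slots__ = ("backbone", "side_chains", "lattice")

    def __init__(
        self,
        backbone: np.ndarray,
        side_chains: Optional[np.ndarray],
        lattice: LatticeSpec,
    ):
        bb = np.asarray(backbone, dtype=np.int64).reshape(-1, 3)
        if len(bb) == 0:
            raise ValueError("model must contain at least one residue")
        sc = None
        if side_chains is not None:
            sc = np.asarray(side_chains, dtype=np.int64).reshape(-1, 3)
            if sc.shape != bb.shape:
                raise ValueError("side-chain and backbone sequences must match in length")
        self.backbone = bb
        self.side_chains = sc
        self.lattice = lattice

    def __len__(self) -> int:
        return len(self.backbone)

    @property
    def has_side_chains(self) -> bool:
        return self.side_chains is not None

    def backbone_array(self) -> np.ndarray:
        return self.backbone

    def side_chain_array(self) -> np.ndarray:
        if self.side_chains is None:
            raise ValueError("backbone-only model has no side chains")
        return self.side_chains

    def interleaved(self) -> np.ndarray:
        """All nodes in per-residue order b1, s1, b2, s2, … (or b1, b2, …)."""
        if self.side_chains is None:
            return self.backbone
        out = np.empty((2 * len(self), 3), dtype=np.int64)
        out[0::2] = self.backbone
        out[1::2] = self.side_chains
        return out

    def node_key(self) -> tuple:
        """Hashable form of the interleaved node sequence."""
        return tuple(map(tuple, self.interleaved().tolist()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, LatticeModel):
            return NotImplemented
        return (
            self.lattice.name == other.lattice.name
            and self.has_side_chains == other.has_side_chains
            and self.node_key() == other.node_key()
        )

    def __hash__(self) -> int:
        return hash((self.lattice.name, self.node_key()))

    def __repr__(self) -> str:
        mode = "side-chain" if self.has_side_chains else "backbone"
        return f"<LatticeModel {self.lattice.name} {mode} l={len(self)}>"

    def validate(self) -> ValidityReport:
        """Check connectivity and self-avoidance; report the first violation.

        Indices in the report refer to the interleaved node sequence
        (1-based), matching the order used by :func:`canonical_form`.
        """
        lat = self.lattice
        bb, sc = self.backbone, self.side_chains
        for i in range(len(bb) - 1):
            if not lat.contains_step(bb[i + 1] - bb[i]):
                return ValidityReport(False, "backbone-break", (i + 1,))
        if sc is not None:
            for i in range(len(bb)):
                if not lat.contains_step(bb[i] - sc[i]):
                    return ValidityReport(False, "side-chain-break", (i + 1,))
        seen: dict[tuple, int] = {}
        for idx, node in enumerate(map(tuple, self.interleaved().tolist()), start=1):
            if node in seen:
                return ValidityReport(False, "collision", (seen[node], idx))
            seen[node] = idx
        return ValidityReport(True)

    def translated(self, offset: np.ndarray) -> "LatticeModel":
        off = np.asarray(offset, dtype=np.int64)
        sc = None if self.side_chains is None else self.side_chains + off
        return LatticeModel(self.backbone + off, sc, self.lattice)

    def transformed(self, matrix: np.ndarray) -> "LatticeModel":
        m = np.asarray(matrix, dtype=np.int64)
        sc = None if self.side_chains is None else self.side_chains @ m.T
        return LatticeModel(self.backbone @ m.T, sc, self.lattice)

    def to_real(self, bond_length: float | None = None) -> "RealModel":
        """Scale lattice nodes to real coordinates with the given bond length (Å).

        Raises :class:`InvalidStructureError` if the model is invalid.
        """
        report = self.validate()
        if not report.ok:
            raise InvalidStructureError(f"cannot scale invalid model: {report}")
        if bond_length is None:
            bond_length = self.lattice.scale
        f = bond_length / self.lattice.step_length
        sc = None if self.side_chains is None else self.side_chains * f
        return RealModel(self.backbone * f, sc, bond_length)


@dataclass(frozen=True)
class RealModel:
    """Real-space (Å) coordinates of a lattice model, same layout."""

    backbone: np.ndarray
    side_chains: Optional[np.ndarray]
    bond_length: float

    def __len__(self) -> int:
        return len(self.backbone)

    @property
    def has_side_chains(self) -> bool:
        return self.side_chains is not None

    def interleaved(self) -> np.ndarray:
        if self.side_chains is None:
            return self.backbone
        out = np.empty((2 * len(self), 3), dtype=float)
        out[0::2] = self.backbone
        out[1::2] = self.side_chains
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "RealModel":
        sc = None
        if self.side_chains is not None:
            sc = self.side_chains @ rotation.T + translation
        return RealModel(self.backbone @ rotation.T + translation, sc, self.bond_length)


def canonical_form(m: LatticeModel, group: PointGroup | None = None) -> LatticeModel:
    """Canonical representative of a model's symmetry-and-translation orbit.

    The image with the lexicographically smallest interleaved node sequence,
    over all point-group transforms followed by translating the first node to
    the origin.  Two models related by a lattice symmetry (including mirror
    images) and/or a translation map to the identical canonical form, which
    is what lets the dRMSD beam search discard symmetric duplicates.
    """
    group = group or _point_group(m.lattice)
    nodes = m.interleaved()
    best_key = None
    best_nodes = None
    for g in group.as_array():
        img = nodes @ g.T
        img = img - img[0]
        tup = tuple(map(tuple, img.tolist()))
        if best_key is None or tup < best_key:
            best_key = tup
            best_nodes = img
    if m.side_chains is None:
        return LatticeModel(best_nodes, None, m.lattice)
    return LatticeModel(best_nodes[0::2], best_nodes[1::2], m.lattice)
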