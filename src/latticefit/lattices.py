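"""Lattice definitions: neighbourhood vectors, point groups and move strings.

A lattice is described by its neighbourhood ``N`` — a set of equal-length
integer vectors closed under negation.  Every lattice node reachable along a
chain is an integer combination of these vectors.  The built-in registry
provides the four standard choices:

========  ====================================  ====
name      neighbourhood                          |N|
========  ====================================  ====
``SQR``   (±1, 0, 0), (0, ±1, 0)                  4
``CUB``   signed unit axis vectors (100)          6
``FCC``   signed permutations of (1, 1, 0)       12
``210``   signed permutations of (2, 1, 0)       24
========  ====================================  ====

2D lattices are embedded in 3D with z = 0 so that a single code path serves
all of them.  One neighbour vector corresponds to ``scale`` ångström in real
space (3.8 Å by default, the mean consecutive Cα–Cα distance in proteins).

The *move-string* encoding labels the neighbour vectors, in lexicographic
order of their integer components, with letters ``A``, ``B``, ``C``, … ; a
chain of ``l`` nodes becomes a string of ``l − 1`` tokens.  Side-chain bonds
are encoded as a second, parallel string (one token per residue), keeping the
backbone string compatible with HP-model tool chains.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .errors import InvalidStructureError, MoveStringError, UnsupportedLatticeError

if TYPE_CHECKING:  # pragma: no cover
    from .model import LatticeModel

__all__ = [
    "LatticeSpec",
    "PointGroup",
    "MoveStrings",
    "make_lattice",
    "register_lattice",
    "available_lattices",
    "scaled_neighbors",
    "point_group",
    "encode_move_string",
    "decode_move_string",
]

DEFAULT_BOND_LENGTH = 3.8  # Å per neighbour vector

_TOKENS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class LatticeSpec:
    """A named lattice neighbourhood with an ångström scale.

    Parameters
    ----------
    name:
        Registry identifier (e.g. ``"FCC"``).
    neighbors:
        Tuple of integer 3-vectors, stored in canonical (lexicographic)
        order.  All vectors share one Euclidean length, the set is closed
        under negation and contains no zero vector or duplicate.
    scale:
        Real-space length in Å assigned to one neighbour vector.
    """

    name: str
    neighbors: tuple[tuple[int, int, int], ...]
    scale: float = DEFAULT_BOND_LENGTH

    def __post_init__(self) -> None:
        vecs = [tuple(int(c) for c in v) for v in self.neighbors]
        if not vecs:
            raise ValueError("neighbourhood must not be empty")
        if len(set(vecs)) != len(vecs):
            raise ValueError("duplicate neighbour vectors")
        if any(v == (0, 0, 0) for v in vecs):
            raise ValueError("zero vector is not a valid neighbour")
        sq = {vx * vx + vy * vy + vz * vz for vx, vy, vz in vecs}
        if len(sq) != 1:
            raise ValueError("neighbour vectors must have identical length")
        vset = set(vecs)
        if any((-vx, -vy, -vz) not in vset for vx, vy, vz in vecs):
            raise ValueError("neighbourhood must be closed under negation")
        object.__setattr__(self, "neighbors", tuple(sorted(vecs)))

    @property
    def coordination(self) -> int:
        """Number of neighbour vectors |N|."""
        return len(self.neighbors)

    @property
    def step_length(self) -> float:
        """Unscaled Euclidean length of one neighbour vector."""
        v = self.neighbors[0]
        return float(np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2))

    @property
    def is_planar(self) -> bool:
        return all(v[2] == 0 for v in self.neighbors)

    def neighbor_array(self) -> np.ndarray:
        """Neighbour vectors as an (|N|, 3) int array in canonical order."""
        return np.array(self.neighbors, dtype=np.int64)

    def alphabet(self) -> dict[tuple[int, int, int], str]:
        """Token assigned to each neighbour vector (canonical order → A, B, …)."""
        return {v: _TOKENS[i] for i, v in enumerate(self.neighbors)}

    def contains_step(self, v: Sequence[int]) -> bool:
        return tuple(int(c) for c in v) in set(self.neighbors)


@dataclass(frozen=True)
class PointGroup:
    """The integer orthogonal matrices mapping a neighbourhood onto itself."""

    matrices: tuple[tuple[tuple[int, int, int], ...], ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.matrices)

    def as_array(self) -> np.ndarray:
        """All matrices stacked as a (g, 3, 3) int array; identity first."""
        return np.array(self.matrices, dtype=np.int64)


_REGISTRY: dict[str, tuple[tuple[int, int, int], ...]] = {}


def register_lattice(name: str, neighbors: Iterable[Sequence[int]]) -> None:
    """Add a lattice to the registry by listing its neighbour vectors.

    Validation (equal lengths, negation closure, …) happens on construction,
    so a bad neighbourhood is rejected here rather than at first use.
    """
    spec = LatticeSpec(name.upper(), tuple(tuple(int(c) for c in v) for v in neighbors))
    _REGISTRY[name.upper()] = spec.neighbors


def available_lattices() -> list[str]:
    return sorted(_REGISTRY)


def _signed_permutations(base: Sequence[int]) -> list[tuple[int, int, int]]:
    out = set()
    for perm in itertools.permutations(base):
        for signs in itertools.product((1, -1), repeat=3):
            v = tuple(p * s for p, s in zip(perm, signs))
            if v != (0, 0, 0):
                out.add(v)
    return sorted(out)


register_lattice("SQR", [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)])
register_lattice("CUB", _signed_permutations((1, 0, 0)))
register_lattice("FCC", _signed_permutations((1, 1, 0)))
register_lattice("210", _signed_permutations((2, 1, 0)))


def make_lattice(name: str, scale: float = DEFAULT_BOND_LENGTH) -> LatticeSpec:
    """Look up a lattice by (case-insensitive) name.

    Raises
    ------
    UnsupportedLatticeError
        If the name is not registered.
    """
    key = name.upper()
    if key not in _REGISTRY:
        raise UnsupportedLatticeError(
            f"unknown lattice {name!r}; available: {', '.join(available_lattices())}"
        )
    return LatticeSpec(key, _REGISTRY[key], scale)


def scaled_neighbors(lat: LatticeSpec, bond_length: float | None = None) -> np.ndarray:
    """Neighbour vectors rescaled so each has Euclidean length ``bond_length`` Å."""
    if bond_length is None:
        bond_length = lat.scale
    if bond_length <= 0:
        raise ValueError(f"bond length must be positive, got {bond_length}")
    return lat.neighbor_array() * (bond_length / lat.step_length)


def _candidate_matrices(planar: bool) -> list[np.ndarray]:
    """Signed permutation matrices: 48 in 3D, the 8 fixing z in 2D."""
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=np.int64)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if planar and not (m[2, 2] == 1 and m[2, 0] == m[2, 1] == 0):
                continue
            mats.append(m)
    return mats


def point_group(lat: LatticeSpec) -> PointGroup:
    """All signed-permutation matrices that permute the neighbourhood.

    For the cubic-family lattices (CUB, FCC, 210) this is the full cubic
    point group of order 48; for the square lattice the dihedral group of
    order 8 acting in the z = 0 plane.
    """
    nset = {tuple(v) for v in lat.neighbors}
    keep = []
    for m in _candidate_matrices(lat.is_planar):
        imgs = {tuple(m @ np.array(v)) for v in lat.neighbors}
        if imgs == nset:
            keep.append(m)
    # identity first, then a deterministic order
    keep.sort(key=lambda m: (not np.array_equal(m, np.eye(3, dtype=np.int64)),
                             m.flatten().tolist()))
    return PointGroup(tuple(tuple(tuple(int(x) for x in row) for row in m) for m in keep))


@dataclass(frozen=True)
class MoveStrings:
    """Move-string encoding of a lattice model.

    ``backbone`` holds one token per backbone step (length l − 1);
    ``side_chains`` one token per backbone→side-chain bond (length l), or
    ``None`` for backbone-only models.  The two strings are kept separate so
    the backbone string stays usable with HP-model tools.
    """

    backbone: str
    side_chains: str | None = None

    def __str__(self) -> str:
        if self.side_chains is None:
            return self.backbone
        return f"{self.backbone}|{self.side_chains}"


def encode_move_string(model: "LatticeModel", lat: LatticeSpec | None = None) -> MoveStrings:
    """Encode a valid lattice model as absolute move strings.

    Raises :class:`InvalidStructureError` if any step is not a neighbour
    vector of the lattice.
    """
    lat = lat or model.lattice
    alpha = lat.alphabet()
    bb = model.backbone_array()
    tokens = []
    for i in range(len(bb) - 1):
        step = tuple(int(c) for c in bb[i + 1] - bb[i])
        if step not in alpha:
            raise InvalidStructureError(f"backbone step {i}→{i + 1} {step} not in N")
        tokens.append(alpha[step])
    side = None
    if model.side_chains is not None:
        sc = model.side_chain_array()
        stoks = []
        for i in range(len(bb)):
            step = tuple(int(c) for c in sc[i] - bb[i])
            if step not in alpha:
                raise InvalidStructureError(f"side-chain bond {i} {step} not in N")
            stoks.append(alpha[step])
        side = "".join(stoks)
    return MoveStrings("".join(tokens), side)


def decode_move_string(
    s: str | MoveStrings,
    lat: LatticeSpec,
    side_chains: str | None = None,
) -> "LatticeModel":
    """Decode absolute move strings into a lattice model anchored at the origin.

    Accepts either a backbone token string (with the side-chain string as a
    separate argument) or a :class:`MoveStrings` pair.  Self-avoidance of the
    decoded path is checked; a colliding path raises
    :class:`InvalidStructureError` (distinct from :class:`MoveStringError`
    for unknown tokens).
    """
    from .model import LatticeModel

    if isinstance(s, MoveStrings):
        side_chains = s.side_chains
        s = s.backbone
    rev = {tok: np.array(v, dtype=np.int64) for v, tok in lat.alphabet().items()}

    def steps(text: str, what: str) -> list[np.ndarray]:
        out = []
        for tok in text:
            if tok not in rev:
                raise MoveStringError(f"unknown {what} token {tok!r} for lattice {lat.name}")
            out.append(rev[tok])
        return out

    pos = np.zeros(3, dtype=np.int64)
    backbone = [pos.copy()]
    for step in steps(s, "backbone"):
        pos = pos + step
        backbone.append(pos.copy())
    sc = None
    if side_chains is not None:
        bonds = steps(side_chains, "side-chain")
        if len(bonds) != len(backbone):
            raise MoveStringError(
                f"side-chain string length {len(bonds)} != chain length {len(backbone)}"
            )
        sc = [b + d for b, d in zip(backbone, bonds)]
    model = LatticeModel(np.array(backbone), None if sc is None else np.array(sc), lat)
    report = model.validate()
    if not report.ok:
        raise InvalidStructureError(f"decoded path is invalid: {report}")
    return model
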