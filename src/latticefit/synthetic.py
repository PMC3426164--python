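"""Synthetic fixtures and brute-force oracles.

Everything here exists so the fitting machinery can be exercised and
verified without downloading real structures:

* seeded self-avoiding random structures on any registered lattice,
* perturbed real-space targets with a controllable noise floor
  (rigid motion + isotropic Gaussian displacement per monomer),
* exhaustive enumeration of all lattice structures of small length,
  used as ground truth for the beam-search optimisers,
* synthetic PDB text so the parse → fit → write path runs end to end.

The generator makes no attempt to mimic real protein geometry (no
Ramachandran statistics, no realistic radius of gyration); it produces
uniform-restart self-avoiding walks, which is exactly what the validity
rules and optimisers need and nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import LatticeFitError
from .lattices import LatticeSpec, make_lattice, point_group
from .metrics import drmsd as _drmsd
from .model import LatticeModel, canonical_form
from .pdb_io import BACKBONE, SIDE_CHAIN, Fragment, Residue, TargetStructure

__all__ = [
    "FixtureSpec",
    "random_structure",
    "perturb",
    "make_target",
    "enumerate_structures",
    "exhaustive_oracle",
    "write_fixture_pdb",
]

MAX_RANDOM_LENGTH = 500
MAX_ENUM_BACKBONE = 6
MAX_ENUM_SIDE_CHAIN = 3


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one synthetic fitting target."""

    lattice: str = "FCC"
    length: int = 10
    mode: str = BACKBONE
    seed: int = 0
    sigma: float = 0.0
    fragment_lengths: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        if self.fragment_lengths is not None:
            if sum(self.fragment_lengths) != self.length:
                raise ValueError("fragment lengths must sum to the chain length")
            if any(fl < 1 for fl in self.fragment_lengths):
                raise ValueError("fragment lengths must be positive")


def random_structure(spec: FixtureSpec, lat: LatticeSpec | None = None) -> LatticeModel:
    """Seeded self-avoiding random structure (uniform-restart growth).

    At each step a uniformly random valid extension is chosen (backbone
    node, then side-chain node in side-chain mode); dead ends restart the
    whole chain.  No uniformity over the set of walks is claimed.
    """
    if spec.length < 1:
        raise ValueError("length must be >= 1")
    if spec.length > MAX_RANDOM_LENGTH:
        raise ValueError(f"length {spec.length} exceeds the bound {MAX_RANDOM_LENGTH}")
    lat = lat or make_lattice(spec.lattice)
    sc_mode = spec.mode == SIDE_CHAIN
    N = [tuple(v) for v in lat.neighbors]
    rng = np.random.default_rng(spec.seed)

    for _attempt in range(100_000):
        bb = [(0, 0, 0)]
        sc: list[tuple] = []
        occupied = {bb[0]}
        ok = True
        if sc_mode:
            s = N[rng.integers(len(N))]
            sc.append(s)
            occupied.add(s)
        while len(bb) < spec.length:
            last = bb[-1]
            opts = [tuple(last[d] + v[d] for d in range(3)) for v in N]
            opts = [o for o in opts if o not in occupied]
            if not opts:
                ok = False
                break
            b = opts[rng.integers(len(opts))]
            if sc_mode:
                sopts = [tuple(b[d] + v[d] for d in range(3)) for v in N]
                sopts = [o for o in sopts if o not in occupied and o != b]
                if not sopts:
                    ok = False
                    break
                s = sopts[rng.integers(len(sopts))]
                occupied.update((b, s))
                bb.append(b)
                sc.append(s)
            else:
                occupied.add(b)
                bb.append(b)
        if ok:
            return LatticeModel(np.array(bb), np.array(sc) if sc_mode else None, lat)
    raise LatticeFitError("random growth failed to complete (too many restarts)")


def perturb(
    m: LatticeModel,
    sigma: float = 0.0,
    seed: int = 0,
    rigid_motion: bool = True,
    fragment_lengths: Optional[Sequence[int]] = None,
) -> TargetStructure:
    """Turn a lattice model into an off-lattice fitting target.

    Scales to real coordinates, optionally applies a seeded random rigid
    motion, adds isotropic Gaussian noise of scale ``sigma`` Å per monomer
    and packages the result as a :class:`TargetStructure` (one fragment, or
    split according to ``fragment_lengths``).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    real = m.to_real()
    rng = np.random.default_rng(seed)
    bb = real.backbone.copy()
    sc = None if real.side_chains is None else real.side_chains.copy()
    if rigid_motion:
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(0.0, 10.0, 3)
        bb = bb @ R.T + t
        if sc is not None:
            sc = sc @ R.T + t
    if sigma > 0:
        bb = bb + rng.normal(0.0, sigma, bb.shape)
        if sc is not None:
            sc = sc + rng.normal(0.0, sigma, sc.shape)

    mode = SIDE_CHAIN if sc is not None else BACKBONE
    lengths = list(fragment_lengths) if fragment_lengths else [len(m)]
    if sum(lengths) != len(m):
        raise ValueError("fragment lengths must sum to the chain length")
    fragments = []
    start, number = 0, 1
    for fl in lengths:
        residues = []
        for i in range(start, start + fl):
            residues.append(
                Residue("ALA", number, "", bb[i],
                        None if sc is None else sc[i], has_side_chain_atoms=sc is not None)
            )
            number += 1
        number += 1  # numbering gap marks the chain break
        fragments.append(Fragment(residues, "A"))
        start += fl
    return TargetStructure(fragments, "A", mode, source="synthetic")


def make_target(spec: FixtureSpec) -> tuple[LatticeModel, TargetStructure]:
    """Generate a random structure and its perturbed target in one call."""
    m = random_structure(spec)
    t = perturb(m, spec.sigma, spec.seed + 1, rigid_motion=spec.sigma > 0,
                fragment_lengths=spec.fragment_lengths)
    return m, t


# ---------------------------------------------------------------------------
# exhaustive enumeration
# ---------------------------------------------------------------------------

def enumerate_structures(
    lat: LatticeSpec,
    length: int,
    mode: str = BACKBONE,
    symmetry_distinct: bool = True,
) -> Iterator[LatticeModel]:
    """Enumerate every valid structure of the given length anchored at the origin.

    With ``symmetry_distinct`` one canonical representative per point-group
    orbit is yielded; otherwise every origin-anchored structure (the frame
    needed by coordinate-space comparisons).
    """
    sc_mode = mode == SIDE_CHAIN
    N = [tuple(v) for v in lat.neighbors]
    group = point_group(lat)
    seen: set = set()

    bb: list[tuple] = [(0, 0, 0)]
    sc: list[tuple] = []
    occupied = {bb[0]}

    def emit() -> Iterator[LatticeModel]:
        m = LatticeModel(np.array(bb), np.array(sc) if sc_mode else None, lat)
        if symmetry_distinct:
            can = canonical_form(m, group)
            key = can.node_key()
            if key in seen:
                return
            seen.add(key)
            yield can
        else:
            yield m

    def grow(i: int) -> Iterator[LatticeModel]:
        if i == length:
            yield from emit()
            return
        last = bb[-1]
        for v in N:
            b = (last[0] + v[0], last[1] + v[1], last[2] + v[2])
            if b in occupied:
                continue
            bb.append(b)
            occupied.add(b)
            if sc_mode:
                for w in N:
                    s = (b[0] + w[0], b[1] + w[1], b[2] + w[2])
                    if s in occupied:
                        continue
                    sc.append(s)
                    occupied.add(s)
                    yield from grow(i + 1)
                    occupied.remove(s)
                    sc.pop()
            else:
                yield from grow(i + 1)
            occupied.remove(b)
            bb.pop()

    if sc_mode:
        for w in N:
            sc.append(w)
            occupied.add(w)
            yield from grow(1)
            occupied.remove(w)
            sc.pop()
    else:
        yield from grow(1)


def exhaustive_oracle(
    fragment: Fragment,
    lat: LatticeSpec,
    mode: str = BACKBONE,
    objective: str = "drmsd",
    rotations: Optional[Sequence[np.ndarray]] = None,
) -> tuple[LatticeModel, float]:
    """Ground-truth optimum by exhaustive enumeration (tiny instances only).

    ``objective="drmsd"`` scores every symmetry-distinct structure against
    the fragment and returns the global dRMSD minimum.
    ``objective="crmsd"`` anchors the fragment's first Cα at the origin,
    evaluates every origin-anchored structure under each supplied rotation
    matrix and returns the minimal coordinate RMSD (the frame convention of
    the rotation-screen fitter).

    Raises a refusal error when the instance exceeds the enumeration bounds
    (backbone length ≤ 6, side-chain length ≤ 3).
    """
    sc_mode = mode == SIDE_CHAIN
    l = len(fragment)
    bound = MAX_ENUM_SIDE_CHAIN if sc_mode else MAX_ENUM_BACKBONE
    if l > bound:
        raise LatticeFitError(
            f"instance too large for exhaustive enumeration: length {l} > bound {bound}"
        )
    pts = fragment.points(mode)

    if objective == "drmsd":
        best = None
        for m in enumerate_structures(lat, l, mode, symmetry_distinct=True):
            real = m.to_real().interleaved()
            score = _drmsd(pts, real) if len(pts) >= 2 else 0.0
            key = (score, m.node_key())
            if best is None or key < best[0]:
                best = (key, m)
        return best[1], best[0][0]

    if objective == "crmsd":
        if rotations is None:
            raise ValueError("crmsd objective needs an explicit rotation list")
        anchored = pts - pts[0]
        models = list(enumerate_structures(lat, l, mode, symmetry_distinct=False))
        reals = [m.to_real().interleaved() for m in models]
        best = None
        for Rm in rotations:
            tgt = anchored @ np.asarray(Rm).T
            for m, real in zip(models, reals):
                score = float(np.sqrt(np.mean(np.sum((tgt - real) ** 2, axis=1))))
                key = (score, m.node_key())
                if best is None or key < best[0]:
                    best = (key, m)
        return best[1], best[0][0]

    raise ValueError(f"unknown objective {objective!r}")


# ---------------------------------------------------------------------------
# synthetic PDB output
# ---------------------------------------------------------------------------

def write_fixture_pdb(target: TargetStructure) -> str:
    """Render a synthetic target as PDB text (CA plus a CB pseudo side chain).

    Backbone-only targets become Gly traces; side-chain targets carry a
    single CB atom at the centroid position so the parser reconstructs the
    same coordinates.  Fragment numbering gaps survive a parse round trip.
    """
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic fixture"
    gmodel = gemmi.Model("1")
    ch = gemmi.Chain(target.chain_id or "A")
    serial = 0
    for frag in target.fragments:
        for res in frag.residues:
            gres = gemmi.Residue()
            gres.name = "ALA" if res.centroid is not None else "GLY"
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            serial += 1
            ca = gemmi.Atom()
            ca.name = "CA"
            ca.element = gemmi.Element("C")
            ca.occ = 1.0
            ca.serial = serial
            ca.pos = gemmi.Position(*res.ca)
            gres.add_atom(ca)
            if res.centroid is not None:
                serial += 1
                cb = gemmi.Atom()
                cb.name = "CB"
                cb.element = gemmi.Element("C")
                cb.occ = 1.0
                cb.serial = serial
                cb.pos = gemmi.Position(*res.centroid)
                gres.add_atom(cb)
            ch.add_residue(gres)
    gmodel.add_chain(ch)
    st.add_model(gmodel)
    return st.make_pdb_string()
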