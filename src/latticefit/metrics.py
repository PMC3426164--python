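"""Similarity measures between a model and its target: dRMSD, cRMSD, Kabsch.

Both measures operate on matched point sets.  For side-chain models the
point set interleaves backbone and side-chain monomers per residue, so a
chain of ``l`` residues contributes ``2l`` points; the denominators below
then reduce to the side-chain-model forms (``l·(2l−1)`` pairs for dRMSD,
``2l`` points for cRMSD) while backbone-only models get the natural
``l(l−1)/2`` and ``l``.

dRMSD compares intramolecular distances and is therefore invariant under
any rigid motion *or reflection* of either argument; cRMSD compares matched
coordinates in a common frame and needs a superposition first.  Because a
dRMSD-optimal model is only determined up to reflection, the final
superposition tries both the model and its mirror image and keeps the
better one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = ["Superposition", "drmsd", "crmsd", "kabsch", "best_superposition"]


def _as_points(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) coordinate array, got {a.shape}")
    return a


def drmsd(P, M) -> float:
    """Root-mean-square deviation of all pairwise intramolecular distances.

    ``sqrt( Σ_{i<j} (|P_i−P_j| − |M_i−M_j|)² / n_pairs )`` with
    ``n_pairs = n(n−1)/2`` for ``n`` matched points.  A pseudo-metric:
    zero on congruent sets (including mirror images).
    """
    P, M = _as_points(P, "P"), _as_points(M, "M")
    if P.shape != M.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {M.shape}")
    if len(P) < 2:
        raise ValueError("dRMSD needs at least two points")
    diff = pdist(P) - pdist(M)
    return float(np.sqrt(np.mean(diff**2)))


def crmsd(P, M) -> float:
    """Coordinate RMSD of matched points in a common frame:
    ``sqrt( Σ_i |P_i−M_i|² / n )``."""
    P, M = _as_points(P, "P"), _as_points(M, "M")
    if P.shape != M.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {M.shape}")
    return float(np.sqrt(np.mean(np.sum((P - M) ** 2, axis=1))))


@dataclass(frozen=True)
class Superposition:
    """A rigid placement ``x ↦ R·(s·x) + t`` minimising cRMSD onto a target.

    ``rotation`` is a proper rotation (det +1); ``reflected`` records whether
    the mirror image (``s = −1``, point reflection through the origin) was
    superposed instead of the model itself.
    """

    rotation: np.ndarray
    translation: np.ndarray
    reflected: bool = False

    def apply(self, coords) -> np.ndarray:
        x = _as_points(coords, "coords")
        if self.reflected:
            x = -x
        return x @ self.rotation.T + self.translation


def kabsch(P, M) -> Superposition:
    """Optimal proper-rotation superposition of ``M`` onto ``P`` (Kabsch).

    Returns the rigid motion minimising ``crmsd(P, R·M + t)`` over all
    rotations and translations, via SVD of the covariance matrix with a
    determinant correction that forbids improper rotations.  Degenerate
    inputs (e.g. a single point, or all points coincident) fall back to the
    identity rotation with a pure centroid translation.
    """
    P, M = _as_points(P, "P"), _as_points(M, "M")
    if P.shape != M.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {M.shape}")
    cP, cM = P.mean(axis=0), M.mean(axis=0)
    H = (M - cM).T @ (P - cP)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cP - R @ cM
    return Superposition(R, t, reflected=False)


def best_superposition(P, M) -> tuple[Superposition, float]:
    """Superpose ``M`` and its point reflection onto ``P``; keep the better.

    A distance-optimised model matches its target only up to reflection, so
    the mirror copy ``M′ = −M`` is superposed as well and the branch with
    the lower cRMSD wins (ties go to the non-reflected branch).  Returns the
    chosen :class:`Superposition` and its cRMSD in Å.
    """
    P, M = _as_points(P, "P"), _as_points(M, "M")
    plain = kabsch(P, M)
    mirrored = kabsch(P, -M)
    c_plain = crmsd(P, plain.apply(M))
    sup_mirr = Superposition(mirrored.rotation, mirrored.translation, reflected=True)
    c_mirr = crmsd(P, sup_mirr.apply(M))
    if c_mirr < c_plain - 1e-12:
        return sup_mirr, c_mirr
    return plain, c_plain
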