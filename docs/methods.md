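# Methods

## Problem and representation

The package solves the protein chain lattice fitting problem: given
per-residue target coordinates extracted from a PDB file — the Cα position
`P^b_i` and, for side-chain models, the centroid `P^s_i` of the residue's
non-hydrogen side-chain atoms — find a valid self-avoiding lattice structure
minimising dRMSD or cRMSD. A lattice is specified purely by its
neighbourhood `N` (equal-length integer vectors, closed under negation);
the registry is open, so a new lattice is added by listing its vectors.
2D lattices are embedded in 3D with z = 0 so that a single code path serves
all of them.

All neighbour vectors are scaled to one bond length, 3.8 Å by default: the
mean distance between consecutive Cα atoms, and close to the mean Cα–side
chain-centroid distance. This makes every reported RMSD directly
interpretable in ångström. The scaling deliberately ignores the shorter
cis-proline Cα linkage and glycine's missing side chain; both are accepted
distortions of the representation, not of the optimiser.

## dRMSD strategy

Chain growth from the amino terminus. The first backbone node sits at the
origin; in side-chain mode the first side-chain monomer occupies one
canonical adjacent node (all choices are a single symmetry orbit). At each
iteration every beam entry is extended by all valid placements of the next
backbone node (and side-chain node), scored by the partial sum of squared
pairwise-distance deviations, and the best `n_keep` symmetry-distinct
partial models survive. Scores are kept as raw sums: within an iteration all
partials cover the same prefix, so raw sums rank identically to normalised
partial RMSDs while remaining exactly additive (a new monomer contributes
only its distances to already-placed monomers). After the last residue the
winner is superposed onto the target with the Kabsch algorithm; because
dRMSD determines a structure only up to reflection, the point-mirrored copy
is superposed too and the lower-cRMSD branch is returned (ties go to the
non-reflected branch).

**Symmetry filtering.** dRMSD cannot distinguish models related by a
point-group operation of the lattice, so an unfiltered beam fills with
redundant images. Partial models are therefore deduplicated at every
iteration by canonical form: the lexicographically smallest node sequence
over all point-group transforms after translating the first node to the
origin. The node sequence is compared in per-residue interleaved order
(b1, s1, b2, s2, …). That order is prefix-monotone under chain growth,
which enables an incremental scheme: each beam entry is stored as its
canonical representative together with its stabilizer (the matrices fixing
it pointwise). Children of distinct canonical parents can never be
symmetric images of one another — the mapping would have to map one parent
onto the other — so duplicates arise only among children of one parent via
its stabilizer, which almost always collapses to the identity within two or
three residues. The scheme is exactly equivalent to canonicalising every
partial model per iteration and is tested against the direct computation.

**Determinism and beam nesting.** Candidates are ordered by
(partial score, node sequence), a total order. Hence results are
reproducible, and the beam of width k is a prefix of the beam of width
k′ > k at every iteration, which gives the tested monotonicity: final dRMSD
is non-increasing in `n_keep`.

## cRMSD strategy

cRMSD depends on the relative orientation of target and lattice, so the
target is rotated through a grid of `r` uniform steps per XYZ axis. The
grid spans [0, π/2) per axis by default: for the built-in 3D lattices the
cubic point group makes wider scans redundant; a `full_range` flag scans
[0, 2π) for lattices without that symmetry. Per rotation, the first Cα is
anchored on the origin node (translation fixed), the first side-chain
monomer goes to the adjacent node nearest its centroid, and chain growth
keeps the `n_keep` best partials by additive coordinate score. No symmetry
filtering is applied — with the frame fixed, symmetric images score
differently. The best rotation is then refined with `r_ref` sub-steps per
axis within ± half a coarse step (the identity offset is always included,
so refinement never loses to the coarse screen; `r_ref = 0` disables it).
The final model is Kabsch-superposed onto the original target, which can
only improve on the anchored-frame score; the anchored screen value is
retained in `params["screen_crmsd"]` for exact comparison against
enumeration oracles.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `bond_length` | 3.8 Å | real-space length of one lattice bond |
| `n_keep` | 1000 | beam width; 1 = greedy. Exact on-lattice targets are recovered already at small widths; noisy targets benefit up to a few hundred |
| `r` | 10 | rotation steps per axis (cRMSD strategy); cost grows as r³ |
| `r_ref` | 5 | refinement sub-steps per axis around the best coarse rotation |

Defaults favour quality over speed (FCC fits complete in seconds to minutes
at these settings); tests and the acceptance script use smaller beams and
grids where exactness is already guaranteed at that scale.

## PDB extraction rules

* Only the first MODEL is read; alternate locations other than blank/'A'
  are dropped (highest occupancy on duplicate names).
* Side-chain centroids exclude hydrogens and the backbone atoms N, CA, C,
  O, OXT. Glycine (or any residue stripped to its backbone) reuses the Cα
  position as side-chain target, keeping two monomers per residue.
* A chain with no side-chain atoms at all is rejected in side-chain mode
  (Cα-only traces carry no centroid information).
* Fragments break where author numbering is non-consecutive (insertion
  codes count as consecutive) or where consecutive Cα atoms are more than
  4.5 Å apart — tolerant of cis-proline (~2.9 Å) and trans (~3.8 Å)
  linkages, rejecting non-bonded neighbours. Fragments are fitted
  independently, each in its own lattice frame; overall report metrics are
  weighted by point count (cRMSD) and pair count (dRMSD).

## Synthetic data

The generator produces seeded uniform-restart self-avoiding walks (a dead
end restarts the chain; no uniformity over walk space is claimed), scales
them to real coordinates, optionally applies a random rigid motion, and
adds isotropic Gaussian noise per monomer. This emulates exactly the
features the optimiser consumes — bond geometry, fragmentation, noise
level, pose — and none of real protein geometry (no Ramachandran
statistics, no native-like compactness, no heteroatoms). Passing tests
therefore demonstrate correctness of the optimisation and I/O machinery,
not fitting accuracy on real proteins; accuracy on real structures is
measured with `latticefit benchmark` on user-supplied PDB files.

Noise defaults used by the acceptance script: σ = 0.5 Å per monomer
(comparable to the coordinate error a good lattice fit itself introduces)
on chains of length 10–25, with σ = 1.0 Å for the beam-width comparison
where greedy growth starts to fail.

## Numerical choices and degenerate inputs

* Kabsch via SVD of the 3×3 covariance with determinant correction; the
  improper branch is handled exclusively by explicitly mirroring the model.
  Degenerate point sets fall back to identity rotation + centroid shift.
* Ties in beam ordering are broken lexicographically on the node sequence;
  ties between reflection branches go to the non-reflected one.
* Single-residue fragments have no pairwise distances; their dRMSD is
  reported as 0 and the superposition reduces to a translation.
* Scores are exact raw sums, so reported metrics equal a from-scratch
  recomputation to 1e-9.

## Exhaustive oracles and their bounds

For small instances every valid structure is enumerated (backbone length
≤ 6, side-chain length ≤ 3; larger instances are refused). For the dRMSD
objective one canonical representative per symmetry orbit suffices; for the
cRMSD objective orientation matters, so all origin-anchored structures are
enumerated under an explicit rotation list, mirroring the fitter's
anchoring convention. The test suite sweeps every symmetry-distinct walk on
SQR and CUB at these lengths, perturbs each with σ = 0.5 Å to make the
optimum non-trivial, and requires the saturating-beam search to match the
enumeration optimum exactly.

## Known limitations

* Chain growth is heuristic for realistic lengths: optimality is only
  guaranteed (and only tested) where enumeration is feasible.
* The cRMSD rotation screen scales as r³; the 210 lattice in side-chain
  mode is the slowest combination by an order of magnitude.
* No structure repair: missing side chains reuse Cα, missing residues split
  fragments. mmCIF input and CML output are not supported.
* Fragments are fitted in independent lattice frames; a shared frame across
  fragments is not attempted.
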