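# Methods

## Model

`enmflex` implements coarse-grained normal-mode analysis of protein
structures with a Tirion elastic network: every pair of nodes closer than a
connectivity cutoff R_c is joined by a Hookean spring of identical force
constant k at its native distance, so the input conformation is the energy
minimum by construction. The 3N x 3N Hessian of this potential has, for
spring (i, j) with native separation d = r_i - r_j, the off-diagonal
super-element -(k/d0^2) d d^T, and diagonal super-elements that make every
row-block sum vanish (exact translation invariance). A connected free
molecule therefore has exactly six zero-frequency rigid-body modes; mode
numbering follows the convention that these are modes 1-6 and the first
internal mode is mode 7.

All computations use reduced units: k = 1, k_B T = 1, unit node masses.
Physical masses and k_B T are accepted as options but nothing downstream
depends on them; frequencies are reported relative to the first internal
mode (omega_j / omega_7), with an optional physical scale that anchors the
slowest internal mode at 2.5 cm^-1.

## Node schemes

`calpha_plus_hetero` (the reference scheme) places one node per residue at
its C-alpha plus one node per hetero heavy atom, so prosthetic groups (heme)
and bound ligands enter the network with all their heavy atoms. Per-atom
hetero inclusion was chosen over a single centroid so that hetero regions
contribute several nodes to region averages. `all_heavy` uses every heavy
atom; residue-level statistics then average over backbone atoms (N, CA, C,
O) instead of reading the C-alpha value.

## RTB projection

The rotation-translation-block projection groups runs of consecutive
residues (never across chains; hetero residues always form their own block)
into rigid blocks with up to six degrees of freedom: three translations and
three rotations about the block centroid, orthonormalized per block by QR.
Blocks with degenerate geometry contribute only their well-defined rigid
degrees (one node: 3 columns; collinear: 5). The projected matrix P^T H P
is solved densely and eigenvectors are back-projected to atomic space;
because P has orthonormal columns the back-projected modes remain
orthonormal. With one residue per block the projection spans the full
C-alpha space and the spectrum equals the unprojected one to round-off; with
coarser blocks eigenvalues are Rayleigh-Ritz upper bounds of the true ones.
The default block size is 1 up to 2000 residues, then ceil(N_res/2000).

## Fluctuations and B-factors

MSF_i = (k_B T / m_i) sum_j |U_ij|^2 / omega_j^2 over the n_v = 100 slowest
internal modes (all of them when fewer exist; rigid modes never enter).
With every internal mode the sum equals the 3x3-trace of the Hessian
pseudo-inverse, which serves as the oracle in the tests. B-factors follow
B = (8 pi^2 / 3) MSF, and are rescaled onto experimental values by ordinary
least squares, b_exp ~ s b_calc + b0: the intercept absorbs the rigid-body
and lattice-disorder contribution present in X-ray B-factors but absent
from internal-mode fluctuations. A configurable number of terminal residues
per chain (default 2 in the pipeline) is excluded from the fit, since chain
termini are dominated by effects the network does not model. Total least
squares was considered and rejected: the error budget is dominated by the
model, not the experimental B's, and OLS keeps the intercept interpretable.

Flexibility is reported as relative RMSF: sqrt(MSF) normalized so that the
mean over the reporting node set is exactly 1. The reporting set defaults
to the whole system of study — for a membrane-embedded run that includes
the lipid surrogate nodes. This matters for cross-system comparisons: a
soft environment raises the system mean and thereby lowers every protein
node's relative value, which is precisely the convention under which
membrane-contacting residues come out damped relative to the free monomer.

## Regions and layers

Region membership is resolved from residue-number / residue-name selectors.
Radial layers are assigned from each node's distance to the centroid of the
substrate heavy atoms with the boundary convention r <= 15 A inner core,
15 < r <= 20 A middle layer, r > 20 A outer layer; layer assignment uses
the node position itself (the C-alpha in C-alpha mode) and partitions the
node set exactly. Region means are unweighted arithmetic means over
residue-level values. Two region lists are not fixed by any published
enumeration and are therefore declared approximations, overridable in the
config: the catalytic cleft defaults to residues with any heavy atom within
4.5 A of the bound substrate, and the shipped proximal-cavity list
(examples/aromatase_regions.yaml) was assembled from the K''-L loop span and
the named heme-coordinating and proximal-surface residues.

## Crystallographic oligomers

Symmetry expansion applies operators in fractional coordinates using the
standard crystallographic orthogonalization matrix; operator tables come
from gemmi's space-group database (P3221 included), and arbitrary operator
lists — including lattice-translated ones — are accepted. Each copy's
chains are relabeled. Exact identity operators bypass the fractional round
trip so that an identity-only "oligomer" is bit-identical to the monomer
run. Default cutoffs are 10 A for a monomer and 8 A for oligomers, both
overridable.

## Bilayer-slab surrogate

The membrane is a two-leaflet square lattice of elastic-network nodes
(default 80 x 80 A lateral, 5 A spacing, leaflets at +/-15 A), merged with
a pre-oriented protein (membrane normal = z is an input contract) by
removing lipid nodes within a clash radius (default 3 A) of any protein
heavy atom. Lipid nodes are ordinary network nodes with unit mass and the
common force constant, one RTB block each.

A perfectly planar central-force lattice is a mechanism — every node can
leave the plane at zero energy cost — so the slab supports an optional
checkerboard pucker (+/- pucker/2 along z). The geometric default is 0
(nodes exactly on the leaflet planes); the membrane pipeline uses 0.5 A so
the embedded complex has exactly six zero modes. What the surrogate
reproduces is the qualitative membrane effect: added connectivity damps the
contact surface and reorders slow modes. It does not reproduce lipid
chemistry, leaflet fluidity, or the specific mode indices obtained with an
all-atom membrane model, and quantitative membrane-dependent RMSF ratios
are deliberately not asserted anywhere — only their direction.

## Synthetic test systems

The generators produce legal PDB records so tests exercise the real I/O
path. The zigzag chain has exact nearest-neighbor spacing and, at a cutoff
just above it, a spring per consecutive pair — its spectrum is deliberately
mechanism-rich (rank = spring count) and is checked against a dense
eigensolve, not against a rigid-body count. The two-domain dumbbell uses
compact jittered-lattice clusters (internally rigid at an 8 A cutoff for
every seed) with domain B an exact mirror image of domain A, bridged by a
double-stranded off-axis linker: single-strand and on-axis variants were
rejected because they leave zero-energy mechanisms or make torsion the
slowest mode, whereas this geometry makes mode 7 the anti-phase hinge bend
with the linker at the motion's node. Ring oligomers place rotated copies
on a circle and refuse geometries whose copies come closer than a clearance.
Pseudo-experimental B-factor vectors are a planted affine transform of a
computed MSF profile plus seeded Gaussian noise.

All generators are bit-reproducible under a fixed seed.

## Numerical choices

- Eigensolves are dense (`scipy.linalg.eigh`) up to dimension 3000, sparse
  shifted Lanczos beyond; the RTB reduction keeps practical problems small.
- Zero modes are eigenvalues below 1e-8 x lambda_max; detected zeros are
  clamped to exactly 0 and never enter MSF sums.
- Hessians are dense below 1000 nodes and CSR above.
- Altloc resolution: highest occupancy wins, ties to the first listed.
- Degenerate-mode pairs are handled by summing over modes, never by
  comparing individual eigenvectors of a degenerate subspace.

## Problem sizes and what the tests show

The test suite and the acceptance script run on synthetic systems of 2-200
nodes — sizes chosen so every oracle (finite differences, dense eigensolve,
pseudo-inverse, closed-form OLS) is exact and cheap. Passing them
establishes the correctness of the machinery (Hessian, RTB, Eq.-level
statistics, symmetry handling), not the biological conclusions for any
particular protein: real-structure results additionally depend on the
region lists and on the membrane model, whose approximations are documented
above.
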