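# Methods

## Model and procedure

The package treats CoA bound to an ANL-superfamily enzyme as a rigid
"flag on a mast": the 4'-phosphopantetheine arm (mast) is extended and
largely rigid in crystal structures, while the adenosine
3',5'-bisphosphate head group (flag) has one dominant degree of freedom —
rotation about the arm.  The steric question "can a FAAL accommodate
CoA?" is therefore answered by an exhaustive rigid sweep: place a
crystallographic CoA conformation in the target's frame, rotate the flag
about the mast axis in 1° steps, and at each step count van der Waals
clashes against the protein.

### Ligand partition

CoA is split at the pyrophosphate.  Bonds are perceived by the covalent
criterion `d ≤ r_i + r_j + 0.45 Å`; the bridging oxygen is the unique
oxygen bonded to two phosphorus atoms.  Cutting it leaves two connected
components: the mast (contains the terminal thiol sulfur, keeps the
pantetheine-side 4'-phosphate) and the flag (contains the adenine ring,
keeps the ribose 3'-phosphate and the 5'-α-phosphate).  The bridging
oxygen belongs to neither set for clash counting and serves as the
rotation anchor.  Working on the molecular graph instead of a hard-coded
name list makes the split independent of non-standard atom naming; a
2-column name map is still accepted for exotic dialects.

### Mast axis

The rotation axis is the first principal component of the mast
heavy-atom coordinates (SVD of the centred coordinates), sign-oriented
from the bridge anchor toward the thiol.  A principal axis rather than a
two-atom vector degrades gracefully for bent arms.  All mast atoms
coincident is the only degenerate case and raises an error.

### Sweep

Frames are generated at angles `0, s, 2s, …, 360 − s` with `s` required
to divide 360 exactly (default 1°, i.e. 360 conformers); frame 0 is the
crystallographic pose, so reported angles are directly comparable across
runs.  Rotation is an axis–angle (Rodrigues) map about the anchored axis;
bond geometry at the pivot is deliberately *not* re-idealised — the
object of the computation is clash counting, not chemistry.

### Clash counting and ranked score

With Bondi-type radii (C 1.70, N 1.55, O 1.52, P 1.80, S 1.80 Å; shipped
as an editable TSV and echoed into every report), a clash is overlap
`r_i + r_j − d` strictly greater than 0.25 Å between a flag atom and a
protein atom from the main-chain + Cβ selection (N, CA, C, O, CB).  The
per-angle statistic is the number of **distinct protein atoms** in clash,
not the number of pairs; pair detail is retained in the contact records.
The ranked score is the step function `≥30 → 3, ≥10 → 2, ≥2 → 1, <2 → 0`.
Mast and bridge atoms are excluded from clash counting: the question is
whether the *head group* fits.

Summaries report both per-configuration means and the grand mean over all
angles × donors × targets × states, since an "average clash count" can be
reduced over either universe; reports always state which number is which.

### Superposition and state models

All superpositions are least-squares rigid (Kabsch via SVD, reflections
excluded) on paired domain Cα atoms.  Residue pairing comes either from
curated 2-column TSVs (the reliable route at low sequence identity) or
from global sequence alignment of the domain-range sequences (match 2,
mismatch −1, gap open −5, extend −0.5; a fixed, logged convenience
default).  Ligand transplants anchor on the N-terminal domain by default
because the CoA pocket is framed by N-domain elements; the domain is a
config switch.  The T-state hybrid keeps the target's N-domain fixed and
rebuilds the C-domain by composing the target-C→template-C fit with the
template→target N-domain fit, so the rebuilt C-domain adopts the
template's relative domain orientation.  The default T-state template is
the CoA-bound FACL reference (3EQ6), exposed as config since no canonical
choice exists.

### Short-contact census

Protein/ligand atom pairs at distance strictly below 2.5 Å, evaluated
against the whole ligand, per conformation and as a union over
conformations (closest observation kept per pair).  Distinct-atom and
distinct-residue reductions and a per-residue table (contact-atom count,
closest approach) are derived from the pair list.  A "≤ 2.5 Å" reading
differs from the strict "<" only on measure-zero boundary distances; the
strict inequality is used and recorded.

### Cavity detection

One simple grid method stands in for the five published pocket tools the
analysis was originally cross-checked with; the claim being tested is
that the pocket is recovered by any reasonable detector.  Voxels (spacing
1.0 Å) inside any atom's vdW sphere are protein; bulk solvent is the
probe-accessible region (binary dilation of the protein by the probe
radius, flood-fill from the box boundary, dilation back); remaining empty
voxels are candidates; a candidate is buried if ≥ 60% of a fixed
14-direction ray set (6 axes + 8 cube diagonals) hits protein before
leaving the grid.  Buried voxels are clustered by 26-connectivity,
clusters under 50 Å³ dropped, and pockets reported by decreasing volume
(= voxel count × spacing³).  Pocket length is the extent along the first
principal axis of the cluster's points.  The angle between two pockets is
the unsigned axis angle `arccos |a·b| ∈ [0°, 90°]`; the canonical-pocket
axis is operationalised as the mast axis of a transplanted CoA, its
physical occupant.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| angular step | 1 | deg | exhaustive sweep; must divide 360 |
| clash threshold | 0.25 | Å overlap | severe-contact criterion on heavy atoms |
| census cutoff | 2.5 | Å | short-contact definition |
| vdW radii | Bondi-type TSV | Å | standard element radii; editable data |
| bond tolerance | 0.45 | Å | covalent-radius slack for bond perception |
| grid spacing | 1.0 | Å | cavity discretisation |
| probe radius | 3.0 | Å | bulk-solvent reachability |
| burial fraction | 0.6 | — | ray-burial criterion |
| min pocket volume | 50 | Å³ | noise-cluster suppression |
| alignment scores | 2/−1/−5/−0.5 | — | fixed convenience defaults |

Domain boundaries (author numbering) are **required configuration** per
structure and are never inferred: published analyses do not print them,
and guessing would silently shift every downstream count.

## Synthetic fixtures: what they emulate, and what they do not

* **Tunnel fixture** — a cylindrical lining (R = 10 Å) with a planted
  wall arc at a known azimuth and a toy CoA on the axis.  The angular
  window in which the rotating flag must clash is computed in closed
  form, per flag atom, from circle-circle geometry
  (`cos Δφ = (ρ² + r_wall² − d²)/(2ρ·r_wall)`), inside the generator and
  never via the production clash code — the oracle stays independent.
* **Hinge fixture** — a seeded two-domain point cloud whose C-domain is
  moved by an exactly recorded rigid transform; T-state reconstruction
  must invert it to machine precision.
* **Toy CoA** — 20 atoms with exact hand-set coordinates: an 11-atom
  collinear mast (15.0 Å extent, thiol on top), a real pyrophosphate
  bridge oxygen, and an 8-atom planar flag reaching 4 Å off-axis, named
  in the standard CoA style so the file round-trips through the
  connectivity splitter.
* **Cavity fixtures** — hollow sphere and capped cylinder shells with
  analytic volume, axis and extent.

These fixtures validate geometry, counting and numerics.  They do not
emulate real protein chemistry: no side-chain diversity, no low-identity
correspondence problems, no bent 4'-PPant arms, no crystallographic
disorder.  Passing fixture tests therefore demonstrates the machinery is
correct, not that any particular enzyme rejects CoA; conclusions about
real structures require running the pipeline on the actual coordinate
files (config template in `configs/paper_run.yaml`).  With the published
inputs, the expected real-structure values are a 15–16 Å extended arm, a
grand mean near 28 clashes, ≥ 7 close N-domain atoms for a FAAL versus 1
for a FACL, a 17–18 Å alternative pocket, and ~25° between the two pocket
axes; the fixture suite reproduces the analogous quantities at their
constructed truths.

## Numerical choices and degenerate inputs

* Kabsch refuses < 3 pairs (underdetermined) and collinear/coincident
  sets (second singular value ≤ 1e-8 of the first); rotations are proper
  (det +1) by construction and validated at 1e-6.
* Altloc resolution keeps the highest occupancy, ties to the
  alphabetically first identifier; only model 1 of multi-model files is
  read; hydrogens and waters are dropped.
* Strict inequalities at both thresholds (clash `> 0.25`, census
  `< 2.5`): boundary-exact values do not count.
* All thresholds and breakpoints are compared on raw floats; report
  files round to 3 decimals (Å) and 1 decimal (degrees) only at
  serialisation, so re-runs are bit-identical.
* Multiple ligand instances: the first in file order is used and logged.
* Pocket clusters are re-labelled deterministically by volume rank; grid
  axes derive from the atom bounding box, so equal inputs give equal
  grids.

## Problem sizes

The shipped fixture runs use a ~735-atom tunnel, 360-frame sweeps,
60-atom hinge clouds and ~25³–35³ voxel grids; the full fixture test
suite and the acceptance script each complete in seconds on one CPU.
Real-structure runs (two targets × two states × four donors at 1°) are
minutes-scale.

## Known limitations

* Single-axis sweep only: secondary torsional freedom around the
  4'-phosphate (which distinguishes extended from bent CoA conformations)
  is not sampled, matching the original procedure.
* No energetics: no Lennard-Jones or electrostatic scoring, no
  hydrogen-bond detection, no positive-selection (Arg/Lys patch)
  modelling — the analysis is purely steric.
* The cavity detector is a stand-in for dedicated pocket software; its
  volumes carry O(spacing) discretisation error and its burial criterion
  is cruder than channel-following algorithms.
* Sequence-alignment correspondence is unreliable below ~25% identity;
  curated pair lists should be used for cross-family superpositions.
* Published-number reproduction requires the six wwPDB entries and
  curated domain boundaries; neither ships with the package.
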