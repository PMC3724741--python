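# Methods

This note records the models, conventions and numerical choices behind
cgagg, in the spirit of a simulation package's methods documentation.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Geometry and units

Lengths are nm, times ns, diffusion coefficients are reported in the
conventional 10⁻⁸ cm²/s (1 unit = 10⁻³ nm²/ns; the conversion is a named
constant and is tested against a from-scratch unit computation).  Boxes are
orthorhombic only; triclinic GRO boxes are rejected rather than silently
approximated, because every distance in the package goes through the
component-wise minimum-image convention (each displacement component mapped
into (−L/2, +L/2]).  Coordinates are treated as wrapped on input.

Neighbor searches (contact detection, SASA occlusion) use a periodic k-d
tree (`scipy.spatial.cKDTree` with `boxsize`), which provides the same
near-linear scaling as a cell list.  The contact interval is closed: a pair
exactly at the cutoff is in contact ("within" a distance includes the
boundary).

## File formats

Trajectories are fixed-column GRO files, single- or multi-frame
(concatenated); frame times are read from `t=` markers in title lines.  The
reader is wrap-aware: the GRO residue and atom-serial fields overflow at
100000, so a running residue counter that advances on every change of the
raw field recovers correct molecule numbering for systems beyond that size
(exercised at 267476 beads in the tests).  Bead roles and radii are not
inferred from GRO atom names — coarse-grained naming is ambiguous — but
supplied in a separate TSV topology table (bead_id, molecule_id,
molecule_type, residue_index, bead_role, bead_radius) validated on load:
one backbone bead per residue per protein, contiguous 1-based residue
ranges, positive radii.  The canonical protein sizes (186 residues
full-length, 166 for the isolated catalytic domain) are enforced only under
`validate(strict_sizes=True)`; the analysis operations themselves accept
any homogeneous protein size so that reduced test systems remain
first-class inputs.

## Cluster detection

Two proteins are in contact when any two of their backbone beads lie within
the cutoff (default 0.75 nm).  Side-chain beads are deliberately excluded
even where including them would detect more contacts — the criterion is a
backbone-bead criterion.  Clusters are connected components of the contact
graph (scipy's csgraph; an independent depth-first-search oracle backs this
in the tests), with labels canonicalized to the smallest member id.
Monomers count as size-1 clusters; the per-frame size histogram is reported
so either counting convention is recoverable.  Labels are not tracked
across frames: the observables used here need only per-frame partitions.

Aggregation "completion" is operationalized as the first time the cluster
count holds at or below a target (default 1) for a dwell number of
consecutive frames (default 5).  The dwell guards against transient touches
being read as completed aggregation; both parameters are configurable.

## Contact-probability map

Contacts between residue i of one protein and residue j of another are
counted per frame per unordered molecule pair, binary (each residue carries
exactly one backbone bead, and a pair in contact through both orientations
still counts once).  The count matrix C is stored symmetrically.  The map

    P_ij = C_ij / (F · C(M,2) · N_r²)

normalizes by the number of frames F, the number of molecule pairs C(M,2)
(= 496 for M = 32), and the N_r² equally likely residue pairings
(N_r² = 34596 for N_r = 186), so P_ij is the probability that randomly
choosing two distinct molecules and one residue on each lands on the pair
(i, j) in contact.  P_ij is bounded by 1/N_r² ≈ 2.9×10⁻⁵, comfortably above
the 10×10⁻⁹ high-contact threshold; this normalization is a documented
reconstruction from the prose definition of the normalization term (the
source's rendered formula is not machine-readable), and the implementation
treats it as the definition.

The ensemble ratio R divides the per-frame total pairwise contacts of one
accumulator by another's, making windows of unequal length comparable;
R(a,a) = 1 and R(a,b)·R(b,a) = 1 are tested invariants.

## Lateral diffusion

Center-of-mass tracks are built per molecule (beads unwrapped around the
molecule's first bead within each frame, then inter-frame minimum-image
displacements accumulated).  Whether to use the center of mass or a single
reference bead was an open choice; center of mass was adopted as the less
noisy estimator and is documented here.  A per-frame displacement component
above `max_step_fraction` (default 0.45) of the box edge raises an
undersampling error naming the molecule and frame — a minimum-image
displacement can never mathematically reach L/2, so the guard is a
near-aliasing threshold rather than an exact criterion.

The MSD is averaged over all molecules in the selection and all time
origins within the window, xy components only (d = 2).  D = slope/(2d) from
an ordinary least-squares fit over a lag window; the default window spans
10–50% of the maximum lag, the usual compromise between the short-lag
regime and the poorly averaged tail, and is user-configurable (analyses of
real data should choose it from the MSD curve).  Uncertainty comes from
block averaging over molecules, not time, because aggregated proteins are
strongly time-correlated: molecules are split into 5 blocks, D refit per
block, and the standard deviation of block estimates reported (not divided
by √n_blocks — it is the spread of block estimates, a conservative
convention).

## SASA and ΔSASA

Shrake–Rupley on beads: each bead's accessible sphere (bead radius + probe)
is discretized with a deterministic golden-spiral lattice (no RNG, so
results are bit-reproducible at fixed point count); a point is accessible
if outside every neighbor's expanded sphere, with neighbors found
periodically so images occlude.  The probe radius defaults to 0.56 nm.
Bead radii default to 0.26 nm (half the standard 0.52 nm coarse-grained
bead interaction diameter) and are explicit topology inputs, never
hard-coded in the computation; because the radii used in the original
analyses are not published, no acceptance quantity depends on absolute
SASA values.  Lipid beads occlude by default (a membrane-facing residue is
genuinely inaccessible); explicit solvent is excluded by leaving it out of
the occluder set.  At 960 points the isolated-bead area is exact to the
closed form and two-sphere fixtures agree with the analytic lens-overlap
expression to well under 2%; agreement with an established reference
implementation (biotite) on non-periodic fixtures is under 1%.

ΔSASA is signed, late-window minus early-window per residue, averaged over
frames sampled every `spacing` ns (default 4) and pooled across proteins.
Burial is the magnitude of negative ΔSASA: the text convention makes buried
surface negative while interface extraction thresholds the positive burial
magnitude (default 0.75 nm²), reconciling the two sign conventions in
circulation without guessing intent; both the signed value and the burial
magnitude are reported.

## Lipid-domain statistics

Protein–lipid contacts count lipid beads of any role within the same
0.75 nm cutoff of any bead of the selected protein residues; a lipid bead
touching several proteins counts once, globally.  The domain-preference
ratio is DPPC count / DLiPC count averaged over a window (≥2 frames), with
a block-averaged standard error over frames; if no DLiPC bead is ever in
contact the ratio is reported as undefined (NaN) alongside the raw counts.
The de-mixing ratio is, per frame and leaflet, the fraction of DPPC
bead-contacts (to DPPC or DLiPC) that are hetero; for an ideally mixed
field it approaches n_DLiPC/(n_DPPC + n_DLiPC − 1), and it decays toward a
stripe-boundary floor as domains form.  Leaflets are assigned by z relative
to the median lipid z per frame — adequate for the flat synthetic bilayers
this package generates; undulating membranes would need a local midplane.

## Synthetic generator

`simulate_sticky_brownian` emulates the statistical structure of
membrane-anchored protein aggregation: n proteins (default 32, matching the
reference bilayer system in its 44×46 nm plane) are rigid blobs of one
backbone bead per residue (default 186, blob radius 1 nm, deterministic
ball-filling offsets) whose centers perform 2D Gaussian steps with
per-cluster D = d_free·size⁻ᵅ.  Defaults: d_free = 10.5×10⁻⁸ cm²/s (the
monomeric-protein reference value), dt = 4 ns (the one frame interval the
reference analyses state), α = 1 (Stokes-like; loosely consistent with the
reported ~10-fold slow-down on aggregation and configurable).  Two clusters
merge irreversibly as soon as any two member centers come within
`bind_radius`; no unbinding is modeled because the emulated system forms a
single, stable aggregate.  Merged clusters translate rigidly, so their
internal geometry freezes at merge time — which is exactly why, with
single-bead proteins and bind_radius equal to the contact cutoff, the
analysis-side cluster detector must reproduce the ground-truth labels frame
by frame (a tested invariant).  For multi-bead blobs the pipeline default
bind_radius is 2.3 nm, the center separation at which two 1-nm discrete
bead shells are reliably within the 0.75 nm bead criterion.  Frames are
emitted wrapped; the ground-truth record keeps unwrapped centers, merge
events and input parameters, so unwrapping logic is genuinely exercised.

The generator is a kinetic stand-in, not a force field: there is no
energetic realism, no protein–lipid coupling, no membrane undulation, and
no quantitative aggregation rate law is claimed.  Tests that pass on it
demonstrate the correctness of the estimators (parameter recovery, oracle
equivalence), not the realism of any particular trajectory.

`generate_domain_field` emits a one-bead-per-lipid ternary field (defaults
3480 DPPC / 2304 DLiPC / 1536 CHOL, the reference 5:3:2 composition) split
over two leaflets, interpolating between uniform mixing and a DLiPC stripe
of configurable width; positional jitter is bounded-uniform so domain
membership stays auditable.  `make_sasa_fixture` provides the three
analytically solvable SASA geometries (isolated sphere, two spheres, buried
core).

Randomness: every generator takes one integer seed; subsystem streams (the
pipeline's per-frame lipid fields) are derived deterministically from it.

## Pipeline

`run_pipeline` chains load/generate → clusters → contacts → diffusion →
SASA → domains, writing TSV artifacts, a MANIFEST with per-stage status,
and a JSON report validated against the packaged `report.schema.json` (a
small structural checker; the schema file is the contract).  Reports
contain no timestamps, so same-seed runs are byte-identical.  Default
problem sizes are CI-scale — 8 proteins × 186 residues, 2000 lipid beads,
200 frames in a 22×23 nm box, SASA on 2 frames per window at 240 sphere
points — chosen so the whole pipeline runs in seconds while every stage
has non-trivial signal (the smaller box lets aggregation actually proceed
within 800 ns at the default monomer D).  The `paper_scale` fixture profile
reproduces the reference composition (32 proteins, 7320 lipid beads,
44×46 nm).

## Known limitations

* The generator's aggregation kinetics are qualitative; no comparison of
  cluster-count decay shapes against real trajectories is made or implied.
* Leaflet assignment and the quasi-2D protein model assume flat membranes.
* SASA ignores solvent structure entirely (geometric probe only), and
  absolute values depend on the chosen bead radii.
* Cluster identity is per-frame; no tracking across frames, no cluster
  shape metrics.
* GRO is the only trajectory format; binary formats (XTC/TRR) would need an
  adapter.
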