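# Methods

## Rigid-body segmentation

The segmentation metric is the population (divide-by-N) standard deviation
of every Cα–Cα distance over the analyzed frames. The population convention
is fixed so that the matrix is fully determined by the frame set; at
hundreds of frames the N vs N−1 difference is far below the clustering
threshold, but exact tests require one choice. Frames are sampled at times
t₀, t₀+stride, … (stride 100 ps default); if the stride is not a multiple of
the frame interval the nearest earlier frame is taken and a warning logged.

DBSCAN runs on this matrix as a precomputed metric with cluster radius
`clr` = 2.5 Å and neighbor count `cln` = 5. Two conventions exist for
whether a point counts among its own neighbors; the default here is
`exclude_self` (a residue needs `cln` *other* residues within `clr`), read
off the plain meaning of "neighbor count", with `include_self` available as
a switch because several library implementations use it. DBSCAN's border
points are order-dependent in the textbook algorithm; for determinism a
border residue always attaches to the lowest-indexed core residue within
`clr`, and segment ids are renumbered 0..K−1 by each segment's first
residue. This makes identical inputs give identical labelings, which the
test suite verifies label-for-label against an independently coded naive
DBSCAN and (for the shared convention) against scikit-learn's cluster
partition.

By default all residues of the trajectory enter the segmentation and no
equilibration prefix is discarded; chain subsets and a discard fraction are
configuration options.

## Synthetic hinge trajectories

The generator emulates the statistical signature that RBS consumes: small
within-body distance fluctuations, large between-body fluctuations, and
freely moving flexible residues. It is not a physical simulation — no force
field, no excluded volume, no solvent — and its Cα-only chains have
idealized geometry.

Design of the motion model, and why:

- **Template.** Body residues lie on an ideal α-helical Cα trace (1.5 Å
  rise, 100°/residue, 2.3 Å radius); chain steps across flexible regions are
  extended (3.5 Å). The template is statically kinked by 90° at each joint
  between consecutive bodies. A collinear resting arrangement would make
  hinge bending invisible to internal distances at first order (the motion
  is perpendicular to the separation vectors), which no real multi-domain
  system exhibits; the kink gives the bodies the non-collinear resting
  geometry of real domain arrangements.
- **Hinge axes.** Each joint's bending axis is drawn uniformly in the plane
  perpendicular to the inter-body direction (orientation random per seed).
  A random 3-D axis will occasionally lie near the inter-body vector, where
  the rotation degenerates into a twist that leaves distances unchanged to
  first order. A second, perpendicular bending axis with its own independent
  angle makes the hinge conical, so no residue pair is blind to the motion.
  Angles are drawn per frame from N(0, hinge_amplitude).
- **Flexible linkers.** Residues in a hinge gap do not ride rigidly with
  the downstream body: each draws its own independent bending angles every
  frame (a melted hinge whose residues move freely), and their template
  positions detour 6 Å off the inter-body axis, as disordered loops bulge.
  Without these two features a linker residue adjacent to a rigid body sits
  ~3.5 Å from a core residue, and an isotropic 3 Å jitter alone produces a
  distance fluctuation of only ≈2.4 Å — right at the 2.5 Å cluster radius —
  making the linker's "unassigned" ground truth unrecoverable in principle.
- **Jitter.** Per-atom isotropic Gaussian noise with each range's σ is
  added last. All draws come from one seeded generator in fixed order, so
  identical spec + seed gives bit-identical output.

Default study conditions for the recovery tests: K = 1..4 bodies of 30
residues, 8-residue flexible linkers (σ = 3 Å), body jitter 0.2 Å, hinge
amplitude 30°, 200 frames at 100 ps. With these geometries the worst-case
between-body distance fluctuation is ≈4.5 Å (vs clr = 2.5 Å) and the
worst linker-body fluctuation ≈2.9–3.0 Å, giving robust margins; recovery
was exact over 80 independent seeds when the defaults were frozen. Shorter
gaps (4–5 residues) put near-pivot residue pairs at ≈2.4–2.9 Å fluctuation
— a knife edge against clr — which is the physical reason the default
linker is 8 residues.

What passing these tests shows: the segmentation correctly inverts the
generator's statistical model. What it does not show: performance on real
MD, where fluctuations are anharmonic, hinges are partial, and bodies
exchange residues; on such data the clr/cln defaults matter and gray
(unassigned) regions are expected to be broader.

## Trajectory descriptors

- Ring-centroid distances use unweighted atom means. Distribution summaries
  report the median (midpoint rule for even n) and the histogram mode with
  0.1 Å default bins, centered on the series minimum, ties resolving to the
  lowest bin — fine enough to resolve reported distances at 0.1 Å
  granularity.
- Torsions follow the standard signed convention on (−180°, 180°], computed
  from the perpendicular components of the outer bonds around the central
  bond; frames with collinear defining atoms yield NaN and are logged.
  Rotamer classes are fixed 120° sectors centered at −60°/+60°/180°
  (boundaries half-open: gauche(−) = [−120°, 0°)), since class names alone
  do not fix boundaries.
- Contact criteria default to heavy-atom donor–acceptor ≤ 3.5 Å plus
  D–H···A ≥ 120° for hydrogen bonds (distance-only, with a logged
  downgrade, when no H is present) and N–O ≤ 4.0 Å for salt bridges —
  common MD-analysis conventions, overridable per spec. Occupancy is the
  fraction of retained frames where *any* listed pair qualifies; the
  equilibration discard defaults to 0.
- Segment RMSD against a reference ensemble reduces the reference to its
  average structure after superposing all reference frames onto the first
  on the fit selection; each trajectory frame is then least-squares fitted
  on the fit selection and measured on the measure selection. The
  mean-structure reference is deterministic and cheap; a per-frame-minimum
  alternative would report systematically lower values.
- Conformer counting is gromos-style leader clustering on pairwise fitted
  Cα RMSD (most-neighbors frame becomes a center, ties to the lowest frame
  index); the result is the minimal number of clusters, largest first,
  covering 95% of frames.

## SCS fold descriptors and melting normalization

SCS = δ_obs − δ_rc per proton; protons present in only one table are
dropped with a log message. SCS_helix sums |SCS| of Hα protons over
residues 16–27 (Ex4 numbering; identical to residues 2–13 of the truncated
25-mers under the +14 offset). SCS_Tc sums over the nine unique
ring-current-sensitive protons (W25 Hε1, L21 Hα, G30 Hα2, P31 Hβ2, R35 Hα,
P37 Hα, P37 Hβ2, P38 Hδ1, P38 Hδ2); the summation is absolute by default,
matching the SCS_helix convention, with a signed mode exposed — after
normalization the two modes coincide whenever the signs are homogeneous.

Melting series are normalized per method: each descriptor kind divides by
the reference variant's value at that method's own lowest temperature
(4 °C grids for NMR, 5 °C for CD), recorded in the result's metadata. The
crossing temperature is the lowest temperature where linear interpolation
between grid points reaches the target level (exact grid hits returned
as-is); on a strictly monotone series it is unique and bracketed by
adjacent grid temperatures. Raw-ellipticity conversion uses
[Θ]_MR = θ/(10·c·l·N).

## NOE calibration

V_ref is the arithmetic mean of the volumes in the list being calibrated
(per variant, per temperature); a geometric-mean switch exists because
processing software conventions differ. Distances follow
d = d_ref·(V_ref/V)^(1/6) with d_ref = 3.2 Å, clipped into [1.72, 8.00] Å;
clip events are counted. The conversion is invariant to rescaling all
volumes by a constant (V_ref scales identically), and larger volumes never
give longer distances.

The round-trip self check generates volumes from known distances and
recovers them through calibration. Because calibration anchors d_ref at the
*mean* volume, exact inversion requires the reference distance to be the
distance the d⁻⁶ model assigns to that mean; the check computes it from its
own ground truth ("mean-volume consistency"). At zero noise recovery is
then exact to floating point inside the open clipping interval; under
multiplicative volume noise ε the first-order propagation |Δd/d| ≈ |ε|/6
holds, and the measured median error sits within ~5% of that bound.

Duplicate listings of the same unordered proton pair are merged by volume
summation with a warning (symmetric-peak exports do this), or rejected in
strict mode. Long-range means sequence separation |i − j| ≥ 5; intra-residue
peaks count toward totals but are never long-range.

## Numerical and interface choices

- Multi-model PDB is the portable trajectory format (Biopython parser; all
  MODELs must share one topology, mismatches rejected naming the MODEL).
  Segment labels are written into the B-factor column of the first frame,
  with −1.00 as the documented unassigned sentinel.
- Tables are TSV/CSV with a declarable dialect; missing columns are rejected
  by name, non-numeric cells by row number, non-positive peak volumes
  always. Melting series are sorted ascending on load.
- Author (Ex4) residue numbering is canonical everywhere; an offset helper
  converts to sequential numbering of truncated constructs.
- Every CLI run logs the package version and sha256 checksums of file
  inputs.

## Known limitations

- No binary trajectory readers (XTC/DCD); no mmCIF writing; no NMR-STAR
  ingestion.
- Random-coil shift prediction and CD spectrum deconvolution are upstream
  of this package; their outputs are inputs here.
- Occupancy defaults (cutoffs, discard fraction) are conventions, not
  fitted; comparisons across force fields or trajectory lengths should fix
  them explicitly.
- The pairwise-RMSD clustering is O(n²) in frames and is intended for
  ensembles up to a few thousand frames.
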