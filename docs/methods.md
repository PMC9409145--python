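# Methods

This note documents the models, conventions and numerical choices behind
`apjbias`, and what its synthetic tests do and do not demonstrate about
real receptor data.

## Structure model and I/O

Atoms carry name, residue name, author residue number (preserved verbatim,
because the diagnostic residues — Arg127, Tyr221, Tyr309, Tyr356 — are
author-numbered), chain, element and a Bondi van-der-Waals radius
(fallback 1.70 Å for unknown elements). Elements come from the PDB element
column when present, otherwise from the atom name's leading letters
(two-letter symbols only when the full stripped name matches one, so `CA`
is carbon). Alternate locations other than `''`/`'A'` are dropped. PDB
coordinates are fixed-width with three decimals, so round trips are exact
to 0.001 Å. Multi-model files become trajectories whose topology is model
1; models with differing atom counts are rejected. Frame times (ns) ride
in `REMARK 250 TIME_NS=` records so trajectories round-trip losslessly; a
tidy `frame,time_ns,atom_index,x,y,z` table is supported as a lightweight
trajectory dialect. No mmCIF or binary trajectory formats.

## Superposition and RMSD

Optimal rigid superposition uses the Kabsch solution (via
`scipy.spatial.transform.Rotation.align_vectors` on centred coordinates);
the returned rotation is always proper. The reported RMSD is recomputed
from the applied transform, which is more accurate than the solver's
residual for near-exact matches. Fewer than 3 pairs, or pairs whose second
singular value vanishes (collinear sets), raise a degenerate-geometry
error rather than returning an arbitrary axis. RMSD traces fit each frame
to frame 1 on a fit selection (default Cα) and measure on the same or a
separate selection; frame 1 is exactly 0.

Pairwise frame–frame RMSDs for clustering use the closed-form SVD identity
`rmsd² = (‖P‖² + ‖Q‖² − 2(σ₁+σ₂±σ₃))/N`, batched over pairs. The identity
cancels two large sums, so "identical" frames show machine noise around
1e-7 nm; tests use tolerances above that floor.

## Hydrogen bonds and the tyrosine-pair diagnostic

A donor–acceptor pair is bonded when d(D···A) ≤ 3.5 Å and, when the donor
carries a hydrogen, the smallest H–D–A angle is ≤ 30° (the common MD
convention). Hydrogens are associated with their donor geometrically (same
residue, within 1.25 Å), which matches the usual naming conventions
without a bonded topology; donors without hydrogens degrade to the
distance criterion alone and the bond is flagged `distance_only`.

The Tyr221/Tyr309 report measures the phenolic acceptor-oxygen to
donor-hydrogen distance in both donor directions (labelled
`Tyr309O-HTyr221` / `Tyr221O-HTyr309`); the two directions genuinely
differ, which is why the reference table prints two columns per ligand.
Window occupancy for the optimal 2.7–3.3 Å band is evaluated on the
donor–acceptor *heavy-atom* (O···O) distance, because that is the pair the
optimal-band rule is defined between; occupancy over a trajectory is the
hydrogen-bond persistence used for classification.

**Reporting convention.** Summary distances are *truncated*, not rounded,
to two decimals (`truncate_report`); this matches the tabulation
convention of the reference distance tables the package reproduces (their
printed column means, e.g. 6.116 → 6.11). Full-precision means are always
available programmatically.

## SASA and occupied volume

Shrake–Rupley with a deterministic golden-spiral point set (default 960
points per atom, probe 1.4 Å): a point on the probe-expanded sphere is
accessible when outside every neighbouring expanded sphere; per-atom areas
sum to the total by construction. The isolated-sphere result is exact at
any point count; overlapping-sphere accuracy is set by the point density
(≈1% at ~1000 points). The occupied volume of the union of expanded
spheres is estimated by seeded Monte-Carlo integration over the bounding
box and reported with its binomial standard error; sample count and seed
are caller-chosen (tests use 2×10⁵, the CLI default as well). There is no
cavity detection: areas and volumes refer to whatever atom set is passed
in.

## Clustering

GROMOS/Daura neighbour counting: the frame with the most neighbours within
the cutoff (default 0.2 nm, Cα atoms) becomes a centroid; it and its
neighbours form a cluster and are removed; repeat. Ties break to the
lowest frame index, making the partition deterministic. Cluster ids are
ordered by decreasing size (the greedy rule already yields non-increasing
sizes). The top centroid is the conformer passed to the G-protein clash
assessment.

The end-to-end pipeline clusters a strided subsample capped at 200 frames
(stride chosen as ⌈F/200⌉): the pairwise matrix is quadratic in frames,
and for trajectory-scale inputs a strided subsample characterises the
conformer population at a fraction of the cost. The tyrosine distance and
occupancy analysis always uses every frame.

## Clash assessment and classification

Steric clash between two named residues: any heavy-atom pair closer than
the sum of vdW radii minus a 0.4 Å tolerance (the standard soft-overlap
allowance). The G-protein assessment superposes the receptor conformer
onto the template's receptor chain by Cα pairs matched on residue number
(≥3 required; an explicit residue-number list can restrict the pairing; no
sequence alignment is attempted), discards the template receptor, and
evaluates the clash against the retained partner chain. The call is a pure
function of (occupancy, clash): persistent bond (occupancy ≥ 0.5 by
default) with a clash → β-arrestin-biased; neither → G-protein-competent;
otherwise indeterminate. The 0.5 threshold separates a bond that holds for
most of a run (the EC-like regime, ~0.7) from one that forms only
sporadically; it is configurable. Unlike a visual-inspection workflow, the
clash decision here is deterministic, and reports state that explicitly.

## Pharmacology

All three models are fitted by least squares with scale parameters
(Bmax, Kd, τ, K_A, IC50, slopes) in log10 space, which enforces positivity
without constraints. Optimisation is deterministic: a fixed multi-start
grid (5 points across the observed dose range for the midpoint parameter,
3–5 slope/efficacy values, 2–3 amplitude values) is screened by SSE and
the best five starts are refined with Levenberg–Marquardt at tight
tolerances. Replicates are pooled and unweighted.

Identifiability caveats worth knowing:

* at slope n = 1 the operational model collapses algebraically to a
  hyperbola — only Em·τ/(1+τ) and K_A/(1+τ) are identifiable; the fitter
  then reproduces the curve and those combinations, not the raw triplet;
* with Em free, τ and Em trade off strongly for shallow slopes
  (n ≈ 0.2–0.35) under realistic noise; τ is meaningfully estimated when
  Em is shared/fixed from the full agonist's curve (`Em_policy="shared"`),
  which is the standard operational-model protocol and what the noisy
  recovery simulations use.

Inhibition fits flag (but still fit) data that increase with dose. Bmax
normalisation divides each group's Bmax by the reference group's and
reports percentages rounded to one decimal; it is invariant under common
rescaling.

## Synthetic generators

The generators target *observables*, not physics. The toy receptor is an
idealised helical Cα trace (2.3 Å radius, 1.5 Å rise, 100° turn — Cα–Cα
≈ 3.8 Å) with the diagnostic residues at fixed fractional positions;
decorative residues are numbered from 400 so the author numbers 127, 221
and 309 stay unique at any size. The tyrosine hydroxyls are placed on a
straight O–H···O axis at the requested O···O distance, so the distance and
hydrogen-bond observables move together.

Trajectories drive the O···O distance with a discrete Ornstein–Uhlenbeck
process (`d ← d + (μ−d)/k + σ√(2/k)·ε`, defaults σ = 0.1 Å, k = 50
frames, 0.01 ns/frame), optionally switching regime at a chosen frame —
the EC-like scenario switches from 3.0 Å to 6.0 Å at 70% of the run,
giving a window occupancy of ≈ 0.70. Because the chain is autocorrelated,
the standard error of its mean uses the effective sample size n/(2k). All
other atoms receive 0.05 Å isotropic jitter (keeps RMSD traces and
clustering non-trivial but stable). The template complex reuses the same
helix as its receptor chain — so Cα pairing with a toy receptor is exact —
and places the partner Tyr356 hydroxyl exactly at the requested separation
from Arg127's NH1, the closest heavy-atom pair. Assay tables evaluate the
chosen model curve and add Gaussian noise scaled to the model's amplitude.
Everything is deterministic under its seed.

**What passing synthetic tests shows — and does not.** They verify the
analysis chain end to end: geometry extraction, occupancy, clustering,
superposition, clash logic, classification, and fitter correctness against
known truth. They do not validate force-field physics, solvent effects,
docking poses, the choice of the 2.7–3.3 Å band, or the biological claim
that the tyrosine bond/Arg–Tyr clash pair predicts transducer bias in real
receptors; on real trajectories the diagnostic inherits whatever
limitations the simulation setup has.

## Known limitations

No periodic-boundary imaging, electrostatics or energetics; no
bond-topology perception beyond naming conventions; no mmCIF/DCD/XTC; no
automatic sequence alignment for template pairing; cluster RMSD assumes a
sensible fit selection (default Cα); the Monte-Carlo volume is a
union-of-expanded-spheres volume, not a cavity volume.
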