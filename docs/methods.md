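# Methods

## Scope and data model

`surfchannel` analyses multi-frame coordinate trajectories of a protein
plus freely diffusing substrate molecules. The on-disk interchange
format is multi-model PDB (one `MODEL` block per frame) with a CSV
dialect (`frame,molecule_tag,substrate_type,x,y,z`, 6-decimal
coordinates) for centroid tables. Binary MD formats are deliberately out
of scope: text PDB keeps the core dependency-light and every output
byte-checkable. Coordinates are always Å; residue numbering is 1-based
and preserved verbatim. Substrate instances are identified by a
`molecule_tag` synthesised from (residue name, chain, residue number),
since PDB has no molecule-instance concept; residue names `AHA` and
`HMD` are registered by default as the two substrate types.

## Trajectory conditioning

Conditioning mirrors standard MD post-processing: translate each frame
so the geometric centroid of an anchor selection (e.g. `resid 138-140`)
is at the origin; superpose every frame onto frame 0 by a least-squares
rigid fit (Kabsch via SVD with determinant correction, so reflections
are never introduced); re-center; strip to substrate atoms. Centroids
are geometric, never mass-weighted — the pipeline treats a molecule's
"position" as a spatial average throughout, and no masses enter
anywhere. The fit selection defaults to all protein atoms, with any
selection expression accepted; collinear fit sets (rotation
underdetermined) are rejected. **Periodic-boundary re-imaging is not
performed**: inputs must be re-imaged upstream by the MD engine's
tooling, or centroids of molecules crossing the box boundary will be
meaningless.

## Centroid reduction

Each substrate molecule in each frame becomes one point: the unweighted
arithmetic mean over all its atoms, hydrogens included ("spatially
averaged" admits no weighting scheme, and retaining hydrogens keeps the
reduction factor honest — 22–24 atoms per molecule gives the ~23-fold
reduction the pipeline is designed around). A series with exactly one
entry per (frame, molecule) pair is *complete*; series filtered
downstream (e.g. arriving molecules only) are incomplete and cardinality
contracts relax to per-frame counts.

## Iterative cutoff clustering

Parameters: `cutoff` (Å, default 10.0, comparison strictly `<`),
`max_iterations` (64), `unmatched` (carry/drop), `weighted_average`
(off by default). Each iteration: enumerate all pairs under the cutoff
sorted by distance (k-d tree, ties broken lexicographically by index —
required for determinism); drop isolated points; greedily match disjoint
pairs in ascending order; replace each pair by its unweighted midpoint
with summed weight and concatenated origin lists.

Design choices that were genuinely open:

* **Carry vs drop.** Points that have neighbours but end an iteration
  unpaired are carried forward by default: the cutoff's stated job is to
  remove *isolated* points, and dropping the unpaired would discard
  density signal in odd-sized clusters. `unmatched="drop"` gives the
  stricter pairs-only behaviour.
* **Midpoint vs weighted mean.** The merged point is the plain midpoint
  of the two coordinates, ignoring accumulated weights; a
  weight-proportional mean is available behind `weighted_average=True`.
  Midpoints bias the survivors toward regions that stay dense over many
  scales, which is the intended filtering effect.
* **Termination.** `cluster_to_convergence` stops when no pair remains
  under the cutoff, when one point remains, or at `max_iterations`. The
  no-pair check happens *before* the iteration executes, so a final
  handful of mutually distant survivors is returned rather than deleted
  wholesale as "isolated" — a single extra iteration on such a cloud
  would otherwise erase the result. `cluster_iteration` called directly
  keeps the literal semantics (two mutually isolated points → empty).

Input to convergence clustering must be a single substrate type (like
pairs only with like); a `CentroidSeries` is pooled across all frames
into the iteration-0 cloud. Per-iteration clouds are exported as
`<run>_iter<k>.pdb` point files, and the merge history as JSON lines.

## Per-residue scoring

`contact_population_score` is the headline scalar: for each residue, the
number of (frame, centroid) events with the centroid within
`contact_cutoff` (default 5.0 Å — a generous first-shell contact
distance for a centroid-to-atom measure) of any atom of the residue,
divided by the frame count. One substrate can score several residues in
a frame. Scores from replicate simulations are averaged per residue;
the accumulated frame count is retained. A textbook `g(r)`
(`radial_distribution`) is provided for users wanting the conventional
curve: distance is centroid to *nearest* reference atom, normalised by
spherical shell volume and bulk density (supplied exactly, or estimated
as molecules / bounding-box volume and flagged as estimated). The
scalar-per-residue score, not `g(r)`, drives structure colouring because
colouring needs one number per residue.

B-factor export min-max rescales scored residues to [0, 99.99] by
default (`linear_0_99`); a constant score map writes 0.00 everywhere
(degenerate range); `raw` writes scores verbatim. Only columns 61–66
change relative to a plain structure write.

## Arrival detection

A molecule *arrives* at a site in the first frame its centroid comes
within `arrival_cutoff` of the site's nearest anchor atom.
`arrival_cutoff` defaults to 3.5 Å — the canonical donor–acceptor
heavy-atom distance for a hydrogen bond — and is flag-adjustable, since
"hydrogen-bonding distance" on a centroid measure is a modelling choice,
not a physical constant. Retention is the fraction of frames from first
arrival onward spent within `site_region_cutoff` (default 6.0 Å);
a molecule is called *retained* at ≥ 0.95. The "empty" vs "occupied"
site distinction is purely two `SiteDefinition`s with different anchor
selections (bare cofactor vs cofactor–ligand adduct); no chemistry is
modelled. Replicate counting reports, per site, how many replicate
simulations saw ≥ 1 arrival of a given substrate type, plus the overall
fraction of replicates with any arrival.

## Synthetic systems

The generator produces controls with known answers, **not** a physical
model of solvated MD:

* **Protein**: `n_protein_residues` (default 200) single-residue sites
  on a triaxial ellipsoid shell (semi-axes `protein_radius`×(1.0, 0.9,
  0.8), default radius 30 Å), `atoms_per_residue` (5) atoms each.
* **Sites**: two cofactor anchors (`PLP`, `PLX`) just above the surface
  on near-opposite faces.
* **Substrates**: 20 type-A (22-atom) + 20 type-B (24-atom) rigid
  dummy-atom clusters with zero-mean offsets, so centroid extraction
  recovers walker paths exactly and exercises the ~23-fold reduction.
  Defaults mirror the 20+20, 10,000-frame study design; tests and the
  acceptance script pass smaller explicit `n_frames`.
* **Free walkers**: reflected Gaussian random walks, per-axis step
  `step_sigma` = 1.4 Å/frame (a small molecule with D ≈ 1e-5 cm²/s
  sampled every 10 ps: σ = √(2·D·Δt) ≈ 1.4 Å), reflecting box walls at
  `box_half_width` (60 Å) and hard-sphere reflection off the protein
  ellipsoid.
* **Channeled walkers**: the first `n_channel_walkers` (3) type-A
  molecules follow a planted surface polyline (~3 Å above the surface)
  with noise clamped to 2.5 Å, enter their target site *exactly* at a
  scripted frame, and then wobble mean-revertingly within 4 Å of the
  anchor (retention 1.0 by construction). Targets alternate between the
  two sites.
* **Keep-out**: all *pre-arrival* motion (free walkers included) is
  excluded from a 5 Å sphere around each anchor, so the scripted
  arrivals are the fixture's exact and exhaustive ground truth — a free
  walker can approach but never cross the arrival threshold.
* **Ground truth** (`PlantedTruth`): the polyline, per-walker roles,
  scripted arrival frames and target sites, and the channel-lining
  residues (within 8 Å of the polyline, brute-force verified).

What passing tests on these fixtures shows: the pipeline recovers
planted channels, arrivals and lining residues from data with the right
shape, scale and bookkeeping, deterministically. What it does not show:
behaviour under force-field physics, solvent structure, periodic-image
artefacts, conformational change, or substrate flexibility — none of
which the generator emulates.

## Numerical choices

* Pair cutoff comparison is strict `<`; k-d-tree results are re-filtered
  to enforce it and sorted with lexicographic tie-breaks, making every
  stage byte-deterministic under a fixed seed.
* Kabsch uses SVD with the determinant-sign correction; fit sets with
  rank < 2 (collinear) raise.
* Coordinates written to PDB carry 3 decimals (%8.3f); values ≥ 10⁵ Å
  overflow the column and raise rather than truncate. Centroid CSVs
  carry 6 decimals.
* Empty inputs: clustering an empty cloud raises; an empty centroid
  table is valid and yields zero-filled scores/histograms.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run synthetic systems of
120–200 protein residues and 100–300 frames with the full 20+20
substrate complement, 3 replicates in the acceptance ensemble, 200-seed
oracle sweeps at ≤ 60 points, and 20-seed sweeps for the polyline and
ideal-gas checks — sizes chosen so the complete battery runs in well
under a minute while every contract is exercised at full molecular
complement.

## Known limitations

* No periodic-boundary handling anywhere; re-image upstream.
* Clustering output order (merges before carries) is a convention, not
  a physical statement; comparisons should be set-wise unless
  reproducing byte-level runs.
* The per-residue score is centroid-based; ligands whose interacting
  atoms sit far from their centroid will be under-counted (atom-level
  scoring is not implemented).
* `g(r)` normalisation assumes full spherical shells; near a large
  reference body or box edge the ideal-gas limit will not be reached.
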