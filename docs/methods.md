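# Methods

## Structure representation

A protein conformation is reduced to its heavy atoms (hydrogens, waters and
monatomic ions are removed; of alternate locations the highest-occupancy one
is kept, ties broken by altloc letter). Each atom is deposited on a cubic
voxel grid as a truncated Gaussian density `rho(r) = exp(-r^2/2)` for
`r <= r_cutoff`, exactly zero beyond. Atoms at exactly the cutoff radius
contribute (the comparison is `<=`). Voxel centers sit at
`origin + (i + 0.5) * v_size` with 0-based indices.

Defaults: `v_size = 1.0` Å, `r_cutoff = 4.0` Å, tile edge 64 voxels,
tiling stride 48 voxels. Tiles anchor at the bounding-box minimum and
advance per axis until the box maximum lies inside the last tile, so every
atom is in at least one tile; atoms outside a tile still contribute density
within `r_cutoff` of its boundary, which makes padding of the box
unnecessary. Tiles whose mean density over all voxels and channels is below
1e-4 are treated as empty and skipped.

### Channels

Eleven channels: four element channels (C, N, O, S), six property channels
(hydrophobic = carbon atoms; aromatic ring atoms of Phe/Tyr/Trp/His;
hydrogen-bond donors and acceptors from a bundled residue/atom-name table;
formally positive Arg/Lys side-chain nitrogens; formally negative Asp/Glu
carboxylate oxygens and OXT), and one total-occupancy channel covering
every heavy atom. Atoms of unrecognized elements enter only the occupancy
channel (with a logged warning). The assignment table is deliberately
simple — membership is by residue and atom name, not by computed chemistry —
and the scheme is pluggable; the channel count is the contract, the exact
table is a design choice.

## Detection network

The detector follows the single-shot cell-grid scheme of image object
detectors: a tile of `64^3 x 11` densities maps to `8^3` cells of 8 voxels
per edge, each predicting four sigmoid outputs — a probability score
`s_hat` that the cell contains a binding-site center, and the center's
fractional coordinates within the cell. The default trunk is ten 3x3x3
convolutions (32,32,32,32,32,64,64,64,128,4 filters) with batch
normalization and ReLU on all but the last layer and stride-2 max pooling
after layers 2, 5 and 8. Cartesian decoding:
`X = c_size * v_size * (i_cell + x_hat) + O_x`, and likewise for Y, Z.

Target encoding is the exact inverse: the cell containing a true center
(cells are half-open; boundary centers go to the lower-index cell) gets
`s = 1` and the fractional position. A cell can encode only one center;
when two true centers share a cell the site whose ligand has more heavy
atoms wins, ties broken by lower ligand residue id.

### Loss

```
Loss = sum_cells (s - s_hat)^2
     + lambda * sum_cells s * ((x - x_hat)^2 + (y - y_hat)^2 + (z - z_hat)^2)
     + gamma * L2
```

summed over the 512 cells of a tile. The coordinate term is gated by the
binary target score, so coordinates are only penalized where a site truly
is. `lambda = 5` and `gamma = 1e-5` by default; the L2 term covers
convolution weights only (not batch-norm parameters). No weighting is
applied to the many negative cells. Targets are strictly binary (no label
smoothing).

### Training

Adam with the standard moments, minibatch 16, learning rate decaying
exponentially from 1e-3 to 1e-5 over 400 epochs (full profile). Optional
data augmentation re-voxelizes each structure in a random orientation every
epoch via a dataset-provider hook. All randomness is driven by the config
seed; two runs with the same seed produce identical loss histories.

The squared-error score term has a well-defined poor local optimum: with
one positive cell among 512, a network that scores every cell near zero is
a stable attractor (per-sample score loss ~1.0, versus < 0.3 once the
positives are learned). Whether a run falls into it depends on the weight
initialization. `train()` therefore supports deterministic multi-start: a
run whose per-sample score loss still exceeds 0.8 at epoch 12 (or at the
end) is abandoned and restarted from a re-derived weight seed, the same
strategy non-convex fitters like k-means use. The end-to-end benchmark
allows up to four restarts.

Because no deep-learning framework is assumed, the network engine
(convolution as a shift-and-add over kernel offsets, batch norm, max
pooling, sigmoid, Adam) is written in numpy with hand-derived backprop,
verified in the test suite against float64 finite differences. The sigmoid
output is clipped to [1e-6, 1 - 1e-6] so scores and coordinates stay
strictly inside (0, 1) where float32 would saturate.

### Reduced CPU profile

The full 64-voxel profile trains far too slowly on one CPU for routine
testing, so a toy profile is provided and used by the benchmark: 32-voxel
tiles (still 1 Å voxels), filters (16, 32, 32, 4) with one max-pool on the
raw densities and one after the first convolution (32 -> 8 cells, cell edge
4 voxels), 25 epochs, learning rate 3e-3 -> 3e-4. The pool-first layout
halves the working resolution and keeps an epoch over 200 tiles at a few
seconds. Depth matters here: a three-convolution trunk falls into the
all-background optimum far more often than the four-convolution one.

## Post-processing

Predictions scoring below `s_threshold` are discarded (0.1 for training
diagnostics, 0.01 for benchmarking so AP sweeps the entire ranking). The
rest undergo greedy non-maximum suppression: the best remaining prediction
seeds a cluster and absorbs everything within `d_threshold = 8` Å
(absorption uses `<=`, so kept seeds are pairwise strictly farther apart
than the radius); ties in score break deterministically on center
coordinates. Optionally only the `N_top` best seeds are kept. Overlapping
tiles need no separate deduplication — their decoded predictions enter the
same global suppression. A 4 Å variant of `d_threshold` is exposed for
structures with adjacent distinct sites. Binding-site residues are all
protein residues with at least one heavy atom within 6 Å (inclusive) of
the predicted center.

### Rotation replicas

The network is not rotation-invariant. To damp this, a structure can be
predicted in 50 replicas: rotations by pi/3, 2pi/3, pi, 4pi/3, 5pi/3 about
the ten axes through opposite facet centroids of a regular icosahedron,
centered on the structure centroid. Per-replica predictions are mapped back
by the inverse rotation, pooled, grouped by the same greedy clustering at
`d_threshold`, and each group is replaced by its mean center with score
`sum(member scores) / n_replicas`. A site detected in every orientation
keeps its score; a single-orientation artifact is divided down by the
replica count. (The grouping-then-averaging rule is fixed here; pooling
before suppression is one consistent reading of "average the obtained
results", and it is what the unit tests pin down.)

## Ensembles

Frames of a conformational ensemble are assumed pre-aligned (MD tools
export aligned trajectories; no superposition is attempted). The per-frame
pipeline produces a prediction cloud that is grouped by one of three
clustering algorithms (scikit-learn implementations): mean shift
(bandwidth = `d_threshold`), DBSCAN (eps = `d_threshold`/2,
min_samples = 5; noise points become singleton clusters flagged as noise),
or agglomerative clustering (average linkage, distance threshold
`d_threshold`; alternatively on binding-site residue sets with 1 - Jaccard
distance and threshold 0.5).

Each cluster gets two scores over the F frames:

* **score 1** — per-frame maximum member score (zero where absent), summed
  and divided by F. For a site present in a window of W frames at constant
  score s this equals `s * W / F`.
* **score 2** — per-frame sum of member scores strictly above the 0.1 step
  threshold, averaged over the frames where that sum is positive. The
  phrase "mean sum over the corresponding frames" is ambiguous; this
  implementation averages only over frames where the cluster is present
  above threshold, so a persistent weak cluster is not diluted by its
  absent frames.

A windowed-mean RMSD utility supports mobility analysis of an arbitrary
atom selection: for frame f, the RMSD to the selection's mean conformation
over frames [f - w, f + w] (w = 100 by default), low values flagging a
molecule locked in place.

## Evaluation protocol

True sites are defined by the curation rules below; the site center is the
mass-weighted center of all heavy atoms of the residues contacting the
ligand. A prediction is correct if its center is within 4.0 Å of the true
center (`<=`), or — the ligand criterion — strictly closer than 4.0 Å to the
nearest ligand heavy atom. Predictions are scanned in descending score
order and matched one-to-one to the nearest still-unmatched correct site,
so per site the top-scored correct prediction is the TP; everything else is
FP and unmatched sites are FN. Precision and recall are the exact ratios,
with 0/0 defined as 0 so empty outputs stay well-defined. AP is the
interpolation-free step sum (each TP at rank k contributes
`precision@k / n_sites`), which equals the integral of precision over
recall; the Top-N variant first truncates each structure's predictions to
its number of true sites. Per-family breakdowns take a user-supplied label
per structure and report AP for families with at least 20 structures.

## Corpus curation and splitting

A complex enters the training corpus if: resolution better than 3.0 Å
(strict; the filter is skipped with a warning when metadata is missing),
fewer than four protein chains, chains shorter than 50 residues dropped,
and no principal-axis extent above 250 Å (extents measured as max - min of
coordinates projected on the eigenvectors of the coordinate covariance).
Ligands are HETATM groups with more than 14 heavy atoms whose residue name
is not in a bundled exclusion list of common crystallization additives
(glycerol, PEG fragments, MES/HEPES, sulfate, phosphate, DMSO, cryoprotectant
sugars, detergents, ...; user-extensible — the list is a pragmatic default,
not an authority). A site is accepted if at least 20 protein heavy atoms lie
within 4.0 Å of a ligand atom. A generic coordinate-diff counter supports
the "refinement moved >= 3 site atoms, discard" rule for users who refine
structures with external tools.

Train/validation splitting must respect structural similarity: chains are
grouped into the connected components of the graph joining pairs with
similarity >= 0.5 (the single-linkage clusters at that cut — the only
linkage for which "no cross-cluster pair reaches the threshold" is a
theorem rather than a hope), and components are assigned whole to
validation, largest first, while they fit the requested fraction. A
component too large for the training budget raises a warning and goes to
train. The similarity matrix itself (e.g. TM-scores) is an input.

## Synthetic fixtures

The generator emulates what the pipeline actually consumes: a compact
heavy-atom cloud at protein-interior density (jittered cubic lattice,
spacing 2.4 Å, ~0.07 atoms/Å^3) organized into pseudo-residues with real
residue and atom names, a concave pocket carved as a spherical cavity
(radius 4.5 Å) with a lining shell guaranteeing the 20-contact-atom rule,
and a 16-heavy-atom ligand placed inside. Ground truth is computed by the
same curation rules applied to real structures, so fixtures are
in-distribution for every stage by construction. Defaults: 440 atoms,
24 Å box (one 32-voxel tile), one pocket, noise 0.4 Å. Trajectory fixtures
perturb the base structure with per-atom displacements clipped to drift/2
(bounding consecutive-frame RMSD by the drift) and can open the pocket only
within a frame window, plugging the cavity elsewhere.

What the fixtures do **not** emulate: real backbone connectivity and
rotamer geometry, chemically coherent pockets (polarity complementary to a
ligand), crystallographic noise, or the enormous shape diversity of real
binding sites. Passing the end-to-end benchmark therefore shows that the
implementation is correct and the pipeline learnable, not that the toy
network would rival a fully trained model on real proteins — reaching the
published level requires the full-size profile, the curated corpus and GPU
training, which are outside this package's desk-scale scope.

## Problem sizes and numerical choices

The end-to-end benchmark trains on 200 fixtures and evaluates 50 held-out
ones (about two minutes on one CPU); the figures in the README come from
`scripts/acceptance.py`, which recomputes them from scratch at a given
seed. Degenerate inputs are handled explicitly: empty structures raise,
an all-zero tile is "empty", 0/0 precision is 0, AP requires at least one
true site. Boundary conventions are inclusive where the science says
"within" (density cutoff, residue radius, center criterion, site distance,
20-contact minimum) and strict where it says "more than" / "less than"
(ligand heavy atoms > 14, resolution < 3.0, similarity < 0.5, ligand-mode
distance). Known limitations: batch-norm statistics are per-minibatch with
running averages (small batches make inference mildly dependent on
minibatch size used in training); the numpy engine is single-threaded and
not meant for full-profile training; multi-model PDB input assumes
identical atom ordering across frames.
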