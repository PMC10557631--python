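# Methods

This note documents the models, parameters, and numerical conventions
behind `lesionmap`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Hex lattice and subspots

Spots live on a triangular lattice in Visium array coordinates: integer
`(row, col)` with `row + col` even; physical centers at
`x = col·s/2`, `y = row·s·√3/2` for spacing `s` (default 100 µm), which
makes every neighbor pair exactly `s` apart. The neighbor relation is the
array-coordinate rule `(r±1, c±1)` and `(r, c±2)`; graph distance is
breadth-first search over that relation, and is validated in the tests
against the closed-form axial-coordinate hex distance.

Each spot subdivides into **6 subspots** on a circle of radius `s/5`
(20 µm at default spacing) at 60° steps, so adjacent subspots within a
spot are ~20 µm apart. The subspot count is a convention of this package
(hexagonal subdivision); the Bayesian expression-enhancement model that
motivates subspot analysis is deliberately *not* implemented — subspot
expression is either supplied externally or inherited from the parent
spot, and the source is recorded in output metadata.

## Histology mask transfer

Colour deconvolution is plain optical-density unmixing: `OD = −log10(I/255)`
(intensities clipped below at 1), concentrations `C = OD · S⁻¹` for a 3×3
matrix `S` of unit-length stain OD row vectors. The shipped "H DAB" preset
uses the published Ruifrok–Johnston vectors with the residual third vector
as the normalized cross product; any invertible 3×3 matrix is accepted.
The SB channel is binarized by Otsu's threshold by default (a fixed
threshold is accepted), dilated `rounds` times (default 5) with a 3×3
8-neighbor structuring element, and transferred to spots by the
**center-pixel rule**: a spot is SB⁺ iff the dilated mask is foreground at
the pixel nearest its center. The membership rule is a design choice —
deterministic and scale-independent; an any-pixel-in-footprint alternative
is available via `rule="footprint"`. Spots whose center falls outside the
image are flagged, never silently dropped.

## Module scores, masks, and the filter chains

Counts are log-normalized (per-unit scaling to 10,000 counts, then
`log1p`). The module score of a gene set is the mean log-normalized
expression over the set minus the mean over control genes drawn from the
same average-expression bins (**24 bins, 100 controls per set gene**,
seeded; both configurable). Scores are exactly zero for constant matrices
and for the whole-genome set, and invariant to adding a constant to all
values. Region masks use strict inequalities: GM = {score > 0.01},
Lesion = {score > 0.1}; values exactly at a threshold are excluded.

The DEG chain runs a two-sided Wilcoxon rank-sum test per gene (midranks,
normal approximation with continuity correction), **Bonferroni** adjustment,
and keeps genes with adjusted p < 0.05, average logFC > 0.25 (log of the
ratio of mean un-logged expression + 1), and detection in < 10% of the
other population (pct.2 < 0.1). Bonferroni is used here because the filter
is a conservative screen; the cluster-proportion test uses
**Benjamini–Hochberg** because its cutoff is stated as an FDR. The
proportion test statistic is the log2 ratio of cluster proportions with a
0.5 pseudocount on cluster counts (keeps clusters empty in one condition
finite); the null is label permutation and p = (1 + hits)/(1 + n_perm),
slightly conservative by construction.

Cross-group z-scores standardize group means by the sample SD (ddof = 1)
of the group means; with two groups this is ±√2/2 by construction.

## Rims and subregions

The lesion core is SB⁻ ∧ Lesion⁺. Outward rims +1…+n (default n = 10) are
multi-source BFS shells from the core; centripetal rims −k mark core spots
at distance k from the nearest non-core spot, so −1 is the outermost core
ring and the depth is unbounded. With several lesions the union core is
used (min-distance semantics); per-lesion analysis can be had by passing
connected components separately. Subregion labels are a total function:
core → `SB-WM_-rim.k`; outward rims in the GM mask → `SB-notWM_rims`,
otherwise `SB+WM_rim.k`; SB⁺ beyond the rims → `SB+WM_NA.Ctrl`
(normal-appearing WM); everything else → `SB-notWM_EAE`. Healthy bundles
emit only `SB+WM_He.Ctrl` / `SB-notWM_He`. Rim profiles report one row per
signed rim index with mean and count; empty rims carry count 0 and a
missing (never zero) mean.

## Subspot cell typing and LR encounters

Expression is rescaled per gene to unit maximum (0/0 → 0); gene-set scores
are plain means of rescaled values, so they live in [0, 1] and are
invariant to per-gene linear rescaling. Assignment is a hierarchical
argmax — L1 class first, then L2 within the winning class — with exact
ties broken to the lexicographically smallest label and flagged. Only the
winning labels are emitted (no soft posterior), but the full score table
is retained so soft analyses remain possible.

An LR encounter requires *every* component — ligand(s), all receptor
subunits, and cofactors — above 0.15 rescaled expression (strict `>`).
Requiring cofactors is the default and can be switched off
(`require_cofactors=False`), in which case they are still reported.
Protein/complex aliases (e.g. VEGFR1 → FLT1, VEGFR2 → KDR) are resolved
before counting, and results are identical whether a pair is stated via
aliases or gene symbols.

## M3Q MRI pipeline

PDw volumes are divided by the median over cortical-GM voxels (output GM
median exactly 1; invariant to global rescaling). The lesion mask is
{terminal − baseline > δ} on normalized PD with **δ = 0.2** by default —
the binarization level is a design choice of this package (Otsu on the
positive difference is available with `delta=None`). The subtraction runs
terminal − baseline, the direction that yields positive signal where
lesions raised PD. T1 > 1250 ms (strict) splits lesion voxels into core
and edge; the partition is asserted disjoint and exhaustive. Voxel rims
are in-plane 8-connected dilations of the core restricted to WM — slice
thickness (1 mm) dwarfs the in-plane voxel (0.15 mm), so through-plane
rims would be physically inconsistent; a 3D mode exists but is off by
default. Five one-voxel rims at 0.15 mm put the outer rim boundary 750 µm
from the core. The PD/T1 ratio masks voxels with T1 ≤ 0 to NaN rather than
failing. Lesion ages are bracketed by scan gaps: first detection at day t
after a clean scan at day s gives age ∈ (0, t − s]; presence at baseline
is left-censored; present→absent→present sequences produce one flagged
record per episode. Registration is an input contract, not an operation.

## Synthetic generator: what it emulates, and what it does not

The spatial generator plants a 40×40 lattice (800 spots) with a
gray-matter band on the right 30% of columns and one hex-radius-3 lesion
(37 spots) in the WM; the pixel-space myelin mask is rasterized so each
pixel takes the SB status of its nearest spot, which makes the zero-round
center-pixel transfer reproduce the spot truth exactly — that property is
a *consistency check of the transfer machinery*, not evidence about real
histology. Counts are negative-binomial (gamma–Poisson) with baseline
mean 3 per gene and dispersion 8 over a compact 1,200-gene genome
(≈3,600 counts/spot, a realistic total Visium depth concentrated on
detected genes); the count distribution is an assumption, as no
distributional form is implied by the masks themselves. Region programs
(WM / GM / lesion) use 40 markers at 6× fold; the cell-type panel is 4 L1
classes × 2 L2 subtypes × 10 markers at 4× fold, with region-dependent L1
composition (immune-heavy core, oligodendrocyte-heavy WM, neuron-heavy
GM). One master seed with fixed per-layer offsets keeps layers
independently regenerable and byte-identical across calls.

The MRI generator uses 48×48×3 volumes at 0.15×0.15×1 mm with axis-aligned
atlas blocks (background, cortical GM 1000±20 PD / 1500±60 ms T1,
subcortical GM, two WM tracts at 700±15 / 900±40 ms), scans at days 0, 23,
30, 37, 44, and one lesion appearing day 37 (in-plane radius 4 voxels,
growing 1 voxel per scan, T1 2000±80 ms, PD ×1.5 — a +50% rise).
**PD leads T1 per voxel**: a voxel's PD rises one lead interval (7 days =
one scan gap) before its T1 does, so the PD extent at day d equals the T1
extent at day d + lead. This is the mechanism that makes the PD/T1
early-warning property testable; the capture statistic is therefore
evaluated against the lesion extent at the first post-warning scan.
Registration is perfect by construction, atlas blocks are rectangles, and
gadolinium enhancement is not simulated — passing tests show the pipeline
arithmetic is correct under the stated model, not that the thresholds are
optimal for any particular scanner.

Problem sizes in the test-suite and acceptance runs (20 recovery seeds on
the 800-spot bundle, 10 seeds for subspot recovery on a 20×20 lattice,
50 DEG null replicates of 1,000 genes × 120 units, 12 permutation-test
replicates at 2,000 permutations, 200 null gene sets) were chosen as the
smallest sizes at which the Monte-Carlo standard errors are well below the
margins being asserted.

## Known limitations

* Subspot expression is parent-inherited unless supplied; no spatial
  smoothing or deconvolution model is fitted.
* Microenvironment (ME) clustering is out of scope; ME labels are inputs.
* The DEG p-value is asymptotic; for groups of a few units the permutation
  test is the better tool.
* The lesion-mask δ and the module-score thresholds are fixed conventions;
  real data may need recalibration, which the config exposes.
* `compare_interaction_tables` assumes upstream significance filtering;
  it applies the probability/p-value filter only when those columns exist.
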