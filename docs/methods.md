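# Methods

## Radial enrichment model

The analysis treats spot-level spatial transcriptomics data as a genes ×
spots integer count matrix with one planar coordinate per spot. Around a
chosen center (a spot barcode or an explicit position), spots are binned
into concentric annuli by Euclidean distance with half-open boundaries:
annulus *k* holds spots with r\_{k−1} ≤ d < r\_k, and the outermost bin is
open beyond the last breakpoint. The default breakpoints
(500, 775, 1050, 1325, 1600, 1825) give seven bins. Coordinates are
deliberately unitless — breakpoints are interpreted in whatever units the
coordinates arrive in (pixels or µm), since distances in array units and
image units differ only by a scale that the user controls; synthetic data
uses µm throughout.

Per annulus the gene-set fraction (set counts over total counts) is
computed and divided by its mean over annuli, so the profile averages to 1
by construction. Using within-annulus fractions makes the statistic
invariant to any per-spot capture multiplier that is constant within an
annulus, and approximately invariant to smooth capture fields — the reason
this normalization is appropriate for data with strongly inhomogeneous
capture. Annuli with zero total counts are excluded from the normalizing
mean and flagged rather than treated as zeros, avoiding division artifacts
on sparse grids.

Two resampling nulls give one-sided exact p-values per annulus (is the
observed enrichment larger than under the null?):

* **center null** — the center is re-drawn uniformly (with replacement)
  from all spots; an `exhaustive=True` mode enumerates every spot once,
  which is what small-grid oracle tests compare against;
* **gene-set null** — |S| genes are re-drawn uniformly without replacement
  from the measured panel. Uniform sampling is the minimal reading of
  "random gene sets" and may include observed-set genes; an optional
  abundance-matched sampler (genes binned by mean expression, controls
  drawn within each observed gene's bin) is provided for users who want a
  composition-matched null.

The default p-value is the add-one permutation estimate
(1 + #{null ≥ obs}) / (N + 1). This is a valid exact test under ties and
never returns 0; the plain strict-exceedance fraction #{null > obs}/N —
the convention some analyses report — is exposed as `tie_policy="strict"`.
On perfectly uniform data every null profile ties the observed one and the
add-one p is exactly 1 in every bin.

Two robustness views accompany the binned profile: `scan_bins` recomputes
the profile for 6–9 bins using equal-width annuli inside the default outer
breakpoint (the reference 7-bin layout is not equally spaced, so this is an
approximation and is documented as such), and `cumulative_profile` drops
binning entirely, reporting the cumulative set fraction over spots ordered
by distance, normalized to end at exactly 1.

## Distance-to-source statistics

In segmented single-molecule data a cell is "positive" for a transcript at
≥ 5 molecules (threshold configurable). Each target-positive cell is
matched to its nearest source-positive cell (default source transcript
SHH) by Euclidean centroid distance via a k-d tree; an independent
brute-force pairwise-matrix oracle verifies the lookup in tests. A cell
positive for both target and source contributes distance 0 — it is its own
nearest source — which is the behaviour that makes source-confined genes
show near-zero distance distributions; `include_self=False` matches such
cells to the nearest *other* source cell instead (and drops them when no
other source exists). Summaries are median / quartiles with 1.5 × IQR
whisker bounds, the standard boxplot convention.

## QC, normalization and module scores

QC keeps cells with total counts strictly above 800 and mitochondrial
fraction strictly below 5% (both cutoffs configurable; mitochondrial genes
recognized by the `MT-` prefix or an explicit list — a panel without
mitochondrial genes simply has mito fraction 0). Counts are then
depth-normalized to 10,000 per cell and log1p-transformed.

Module scores use the binned-control scheme standard in single-cell
toolkits: panel genes are ranked by dataset-average normalized expression
and split into 25 equal-frequency bins (ties broken by gene id for
determinism); for each module gene, up to 100 control genes are sampled
without replacement from its bin; the per-cell score is the mean of the
module genes minus the mean of the pooled controls. The 25/100 defaults
are the scheme's conventional values, not quantities estimated from data.
A consequence of pooling is that a module spanning the whole panel has
controls covering the panel too, so its score is exactly zero — the
symmetry property the tests assert. The bundled modules are the curated
dorsoventral neural-tube marker lists (SHH module, floor plate, p3, pMN,
p0-2, dp1-6, roof plate) plus the SHH-and-targets set used as the radial
enrichment readout; the lists are frozen in `resources/gene_sets.json` and
checked token-for-token by the test suite.

## Stimulation DSL

The LED firmware runs 1 Hz programs of four one-byte instructions: ON for
(byte+1) s over 0x00–0x7E, OFF for (byte−0x80+1) s over 0x80–0xFE, REPEAT
(0x7F), HALT (0xFF). The value+1 duration mapping is the only one that
covers exactly 1–127 s with 127 opcodes. REPEAT loops the whole step list
from the first instruction (nesting is disallowed; a bare REPEAT is an
empty loop, i.e. dark); HALT leaves the LED off for the remainder.
Programs are canonicalized at construction by appending an implicit HALT
when no terminator is given, which makes decode∘encode the identity — a
property tested exhaustively over all 256 single bytes and on random
programs. Duty cycle and cumulative dose (power × on-seconds) summarize a
program; `amplitude_from_dose` maps dose to an induction amplitude through
a saturating curve (half-saturation at 3600 power-seconds, capped at 3) as
a modelling convenience linking stimulation schedules to the synthetic
generator — it is not a calibrated photobiology response.

## Synthetic data generator

`generate_spot_dataset` emulates the data regime the radial analysis is
designed for. Spots sit on a square lattice (hex topology is irrelevant
here because the analysis only uses Euclidean distances). Expected counts
are

μ\_{gs} = μ0 · c\_s · (1 + A · exp(−d(s, center)/λ) · 1[g ∈ S])

with defaults μ0 = 0.5 counts/gene/spot (giving ~100 UMIs per spot over a
200-gene panel, matching the low-count regime where induced-set molecules
number in the tens to hundreds globally), induction increment A = 3 at the
source (4× total at d = 0) decaying over λ = 300 µm, on a 30 × 30 lattice
at 100 µm pitch so the field spans all seven annuli. The exponential
kernel is the canonical single-parameter morphogen-gradient form; it is a
generator choice, not a mechanistic claim. The capture multiplier c\_s is a
smoothed Gaussian log-field rescaled to log-SD 0.6 and exponentiated,
producing severalfold spot-to-spot total-count differences (total-count CV
≈ 0.8, far above the Poisson-only level) — the "vastly different UMI
counts" regime. Counts are negative-binomial via gamma–Poisson mixing with
shared dispersion 2 (nb\_dispersion = ∞ recovers Poisson). Everything is
drawn from one `numpy` Generator seeded by `rng_seed`, so identical
configs give bit-identical datasets.

`generate_cell_table` scatters cells uniformly in a disc (default radius
250 µm, an organoid-section scale), concentrates a source-cell fraction
(default 10%, Gaussian spread 30 µm) at a pole with high source-gene
counts (Poisson mean 20 vs 0.2 background), and elevates each ring gene
(Poisson mean 15) in cells whose pole distance falls within its ring.
Rings therefore reproduce ordered median distances in the
distance-to-source analysis, with near-pole rings compressed toward zero
by the source-pole spread.

What the generator does **not** emulate: lattice-registered tissue
morphology, spatial gene–gene correlation beyond the single induction
kernel, segmentation errors, molecule misassignment between adjacent
cells, cell migration or proliferation. Passing tests therefore
demonstrate correctness of the statistics under the stated generative
model, not robustness to those real-data artifacts.

## Numerical and design choices

* Breakpoint boundaries are strict "less than", so a spot exactly on a
  breakpoint belongs to the outer neighbour — asserted explicitly in tests.
* Gene-id matching is exact and case-sensitive, with an opt-in
  case-insensitive fallback, to avoid silent mis-mapping.
* Permutation tests and generators take explicit seeds (no global RNG);
  multi-null and multi-module runs spawn independent `SeedSequence`
  children so adding one analysis never perturbs another.
* The module-score expression bins use equal-frequency quantiles with
  gene-id tie-breaking, making scores reproducible across platforms.
* Desk-scale problem sizes used by the test suite and the acceptance
  script (a 30 × 30 lattice, 200 genes, 1,000 permutations per null; 200
  datasets × 199 permutations for the type-I calibration check) were fixed
  once as the package's reference conditions and complete in seconds to a
  few minutes on one CPU.

## Known limitations

* The center null resamples centers uniformly over spots; on small or
  irregular fields the observed (typically central) position has more
  close-by spots than a random edge position, which makes the test mildly
  conservative rather than anti-conservative — the calibration test bounds
  the type-I error empirically.
* The gene-set null is uniform by default; for panels with extreme
  abundance skew the abundance-matched sampler is the better-calibrated
  choice, at the cost of a composition assumption.
* `scan_bins` uses equal-width annuli, an approximation of the unequal
  reference layout (flagged in its docstring).
* Geodesic (tissue-masked) distances are out of scope; all distances are
  Euclidean in the plane.
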