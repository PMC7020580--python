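# Methods

## Data model

A run images one field of view (reference setup: 2048 × 2048 pixels, 117 nm
pixel pitch, 63× objective) once per marker.  After preprocessing, each of the
n = 13 markers contributes an aligned binary mask; the per-pixel stack of bits
is the pixel's combinatorial molecular phenotype (CMP).  Conventions used
throughout:

- code strings are positional: character *i* is marker *i*; internally codes
  are integers with bit *i* = marker *i*;
- the all-zero code is background, excluded from every table but reported as a
  count, so `Σ frequencies + background = total pixels` is an exact invariant;
- frequency tables rank codes from 0 (most abundant), ties broken by code
  string ascending — the reference software is silent on ties, and a total
  order is required for reproducible ranks;
- a 15-pixel border band is excluded from all counting (`margin=15` default).

## Image preparation

**Registration.** Stage drift between staining cycles is corrected by integer
translation only: the goal is that a pixel address the same physical spot in
every image, and sub-pixel resampling would smear the binary decision.  The
estimate is the argmax of normalized cross-correlation over |dy|,|dx| ≤
`max_shift`, computed with FFT sliding sums; the brute-force correlation scan
is kept in the test suite as the independent oracle.  Cross-channel
registration keys on structure shared between channels — in real data, cell
bodies and autofluorescence; in synthetic data, a sub-threshold shared
texture.  Input without shared structure (e.g. re-processing binarized masks)
must set `register=False`; a correlation estimate between independent granule
patterns is meaningless, and the chain is idempotent on its own output under
that setting.

**Background and thresholding.** The post-photobleach image of the same field
is subtracted pixelwise, clipped at zero.  Thresholds are per-marker and in
practice set manually; `binarize` compares inclusively (pixel ≥ threshold is
positive, matching the convention that staining *reaching* the threshold
counts).  An Otsu fallback exists for unattended synthetic runs and is flagged
in provenance.  Out-of-frame pixels after shifting are zero-filled; with
shifts ≤ margin this never affects counted pixels.

## Single-cell summaries

Cells are selected externally (no segmentation is attempted — the reference
workflow selects free-standing, morphologically normal cells by hand; for
synthetic data the ground-truth masks serve as regions).  A region is a pixel
list or a polygon rasterized with even-odd fill including boundary pixels;
both routes extract identical profiles for convex regions (tested).

Each cell is summarized by its k = 20 most abundant codes (k = 10 is a
first-class view: in practice the top 10 carry 70–85 % of the top-20 pixels).
The *signature* is the pair of 13-vectors (CMPs-containing-marker,
pixels-containing-marker) over those codes.  In segmented-bar displays every
member marker of a code gets a segment of height equal to the code's pixel
count, so a 3-marker code of 296 pixels draws an 888-pixel bar; the overlay
line keeps the true 296 visible.  Cells with fewer than k distinct codes yield
truncated tables.

## Group comparison

**Conservation (triplets / 2-of-3).**  For each marker, each subject
contributes the set of its 50 most abundant codes containing that marker.
Within a 3-subject group, a code present in all three sets is a *triplet*;
codes present in exactly two are *2-of-3*, split by which subject lacks them
(x-2-3, 1-x-3, 1-2-x) and never double-counted against triplets.  High totals
mean the group's subjects share their abundant phenotypes.  The strict API
enforces the 3-per-group design; a generalized n-sample mode exists but is not
the default.

**Aligned rank test.**  The 13 per-marker `triplet + 2-of-3` totals of the two
groups form a randomized complete block design with marker as block.  Each
block's mean is removed (alignment), the 26 aligned values are ranked jointly
with average ranks for ties, and the group rank sum is referred to the exact
sign-flip distribution over the 2¹³ within-block swaps (Monte Carlo above 13
blocks).  Identical groups give p = 1; a constant shift across all 13 markers
occupies the extreme orbit, p = 2/8192 ≈ 2.4 × 10⁻⁴ — the resolution limit of
this design.

**Pairwise similarity.**  The coefficient for a marker pair is the Jaccard
index of the two binary masks over non-margin pixels (0 when both masks are
empty).  Jaccard was chosen as the canonical presence/absence similarity; the
choice is isolated in one function so Dice or simple matching can be swapped
in.  Per pair, the two groups' three coefficients each are compared with a
Welch t-test by default: the exact 3-vs-3 permutation test has only 20 splits
and a two-sided floor of p = 0.1, so it cannot reach α = 0.05 and is provided
only for completeness.  No correction is applied across the 78 pairs (the
output records this).  The mean-profile test pairs the groups' per-pair means
across the 78 pairs and sign-flip permutes the differences (seeded Monte
Carlo, 20 000 draws).

## Gating

Per marker, the population limit is ⌊max/2⌋ of the per-cell CMP counts — this
single rule reproduces all documented cases (max 13 → 6, 15 → 7, 14 → 7).
"Hi" is count ≥ limit, "lo" is strictly below, so the two classes partition
the population exactly.  Sequential screens are conjunctive, hence
order-invariant and monotone (adding a criterion never enlarges the
selection).  Limits are computed once on the whole population and reused in
every screen, never re-derived inside sub-populations.  Markers not used as
criteria but hi (or lo) in ≥ 80 % of selected cells are reported as consensus
annotation; 0.8 operationalizes "most or all members" and is configurable.
The binomial enrichment p-value against the population's group share is a
convenience beyond raw counts.  An exhaustive 1–2-criterion scan
(`gating.scan_criteria`) is an optional extension; the reference workflow
chooses screens manually.

## Synthetic data

The generator's defaults encode the study conditions: 2 groups × 3 subjects ×
19 cells, one field of view per subject, 13 markers, integer stage shifts up
to ±5 px, flat background 10, marker signal 200, Gaussian camera noise
σ = 2, binarization threshold 150.  Tests run at 256 × 256 (512 × 512 default,
2048 × 2048 configurable); sizes were picked so the full planted-recovery
study runs in seconds on a laptop core while keeping ≥ 500 in-cell pixels per
cell.

**Cells** are random ellipses (radii 12–20 px) with low-order sinusoidal
boundary wobble, packed without overlap by rejection sampling, ≥ 20 px from
the border; an over-crowded field fails explicitly after bounded retries.

**Marker signal** is a Boolean (Poisson germ-grain) model of radius-2 disks:
granule centers form a Poisson process over the cell's disk-dilated bounding
box with intensity λ = −ln(1 − p)/A (A = disk area), so the marginal coverage
probability of every in-cell pixel is exactly the phenotype's marker
probability p, including at cell edges.  Granules mimic punctate organellar
staining and give codes realistic spatial clustering; the price is pixel-pixel
correlation, so the law-of-large-numbers check uses an effective sample size
of roughly area/A rather than the pixel count.  Markers in a co-expression
block share one granule pattern (drawn at the block's mean probability),
planting true within-pixel co-occurrence.

**Cross-channel texture.**  Every cell adds a dim base intensity (30) plus a
shared sub-threshold granular texture (40, 30 % coverage) to *all* channels,
emulating the cellular autofluorescence and morphology that real registration
locks onto.  Both sit safely below threshold, so ground truth is unaffected.

**Planted group difference.**  KO subjects share one mixture (A 0.6 / B 0.4)
and identical phenotype programs.  SP-A1 subjects get per-subject Dirichlet
mixtures over C/D/A *and* per-subject jitter of the programs themselves
(marker probabilities ± N(0, 0.25), clipped to [0.02, 0.95]).  The program
jitter is essential, and deliberate: varying only mixture weights leaves the
identity of each subject's abundant codes nearly unchanged (the same
phenotypes are present at all weights), so conservation counts barely move;
program drift is what the triplet analysis actually detects, and is the
natural model of treatment-induced diversification of expression programs.
Phenotype marker probabilities themselves (0.15 baseline / 0.75 hi) are free
parameters — no quantitative co-expression rates exist for the real cells —
chosen once to give each phenotype a distinct hi/lo pattern with every marker
detectable.

**What passing tests do and do not show.**  The generator reproduces the
*statistical* structure the analysis assumes (binarizable granular signal,
planted code mixtures, group contrasts) but not optics (PSF, illumination
fields), photobleaching kinetics, antibody chemistry, real macrophage
morphology, or marker-specific intensity distributions.  Green tests therefore
validate the correctness of the computations and the recoverability of
planted effects at study scale — not the biological calibration of thresholds
or effect sizes on real slides.

## Numerical and format choices

- Pseudocolor palette: rank r maps to 24-bit color ((r+1) · 0x9E3779B1)
  mod 2²⁴ — multiplication by an odd constant is a bijection on 24-bit values,
  so colors are unique per rank, never black (black is background), and
  composites decode losslessly back to the code map.
- Map files are UTF-8 text (`#width/#height/#markers` headers, then
  `row<TAB>col<TAB>code` for non-background pixels, row-major); parse errors
  report line numbers.  Tables are CSV with fixed column order for diffability.
- Registration tie-breaks: first argmax in row-major window order.
  Degenerate (constant-overlap) displacements score −inf; fully flat images
  raise.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical config + seed reproduces scenes, stacks
  and every downstream file bit-exactly.

## Known limitations

- The reference system's registration and similarity-coefficient algorithms
  are unpublished; cross-correlation and Jaccard are implementation choices,
  so inferential numbers on real data need not match the original software's.
- Whether the original pipeline counts all-zero pixels as a phenotype is
  unstated; here they are background by definition.
- Whole-image rank columns are 0-based everywhere; sources that mix 0- and
  1-based narration must be read accordingly.
- The aligned-rank permutation test's resolution is bounded by 2/2¹³ with 13
  blocks; the 3-vs-3 per-pair permutation test cannot reach α = 0.05 (hence
  the Welch default).
- No multiple-testing correction across the 78 similarity pairs, by design;
  downstream users comparing many screens should correct as appropriate.
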