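# Methods

## Consensus disorder annotation

Per-residue scores from at least two external predictor tracks are the
primary input; the package never re-implements the predictors. Each track is
binarized at a per-predictor threshold (default 0.5, the conventional cut
for probability-valued disorder predictors; tracks on other scales must be
pre-normalized by the caller), and a residue is disordered when strictly
more than half of the tracks agree. An exact tie on an even track count
resolves to ordered — the conservative call, and irrelevant for the typical
odd-sized panel. Ambiguous residues ('X') carry whatever score the track
supplies; no smoothing or gap-merging is applied to the resulting mask.

Whether the majority vote should run over individual tracks or over
predictor-level calls (several tracks of one predictor first combined among
themselves) is genuinely open when a predictor contributes multiple
flavours. The default votes over all supplied tracks;
`build_consensus(track_groups=...)` switches to a two-level vote when a
predictor-level reading is wanted.

Disordered domains are maximal consensus-disordered runs of at least 30
residues (`min_len`, configurable) — the length at which disordered regions
are conventionally treated as functional domains. Intervals are 0-based,
half-open everywhere.

## Group measures

Content quantiles (q10/q25/median/q75/q90, matching box-plot whiskers at the
10th/90th centiles) use linear interpolation between order statistics.
%DisProt uses an inclusive content cut at 0.4. %DisDom1K is pooled by
default — total domains over total residues × 1000 — because the measure is
defined on a protein *set* and pooling is robust to very short proteins; a
mean of per-protein rates is available (`disdom1k_mode="mean"`). The
moonlighting table keys proteins by compartment multiplicity 1–3; proteins
in more than three compartments are excluded as too rare to summarise.

## CH-CDF classification

Mean hydropathy uses the Kyte–Doolittle scale rescaled to [0, 1] via
(h + 4.5)/9, smoothed with a centred 5-residue window truncated at the
chain ends — the convention of the classical charge-hydropathy classifier.
Mean net charge is |Σq|/L with D/E = −1, K/R = +1, histidine and termini
neutral (pH-7 convention). 'X' contributes zero charge and the hydropathy
midpoint.

The boundary parameters are configuration, not code. The shipped CH default
(slope 2.785, intercept −1.151) is the classical literature boundary for
this coordinate system. The shipped 7-point CDF boundary is a clearly
labelled *synthetic* stand-in: the published CDF boundary belongs to a
proprietary predictor and is not reproduced here, so real analyses should
supply a calibrated boundary; the package's own tests never rely on the
shipped values. The score stream feeding the CDF is configurable
(`cdf_track`); the default is the per-residue mean over all tracks.

Points exactly on a boundary go to the ordered side of that axis (x = 0
counts as CDF-ordered, y = 0 as CH-compact): ties are measure-zero for real
data, and a deterministic partition matters for reproducibility.

## Hubs

The hub percentile (default 20) is converted to a degree threshold k* — the
degree at rank ⌈p/100·n⌉ in the descending degree ranking — and all nodes
with degree ≥ k* are hubs. Cutting at a degree value keeps the rule
order-independent; ties only ever add hubs, so the hub fraction is ≥ p/100.
Intra-compartment degree discards a protein's edges to nuclear proteins
sharing none of its compartments; edges to non-nuclear partners are kept.
Intra-compartment hubs reuse the *global* threshold k* so counts are
comparable across compartments; a per-compartment re-ranked percentile is
available (`method="rerank"`).

## Enrichment testing

Controls are length-matched because disorder content correlates with chain
length: each target draws a control uniformly, without replacement, among
pool proteins within ±10% of its length, falling back to the
nearest-length remaining control (logged) when the window is exhausted.
The test is a Welch t-test when the Anderson–Darling test (at 0.05) fails
to reject normality for *both* samples, otherwise the Wilcoxon rank sum
test, implemented as the tie-corrected Mann–Whitney U — the fraction-type
measures produce heavily tied (even binary) samples, for which an
uncorrected rank-sum normal approximation is wrong. Zero-variance samples
route directly to the rank test. Differences are called at p < 0.01,
two-sided, with no multiple-testing correction; the sign of the
target-minus-control measure gives '+' or '−'.

Two sample units are implemented. The default (`sample_unit="protein"`)
tests per-protein values of the full target set against one matched control
set. The alternative (`sample_unit="subset"`) follows the resampling
recipe literally: ten repeats, each drawing half the target set plus a
matched control sample, with the test run on the two vectors of ten
set-level summaries. The subset unit is *not* the default because it is
anticonservative by construction: the ten summaries share one fixed target
set, so their spread reflects only within-set resampling noise and omits
the target-set-level sampling variance. In a direct null simulation the
subset unit rejected at ≈ 0.21 at a nominal 0.01, while the per-protein
unit was calibrated (≈ 0.007, inside Monte-Carlo error). The subset mode
remains available for sensitivity analyses and comparability.

Compartments with fewer than 4 profiled proteins are skipped (a half-subset
of fewer than 2 proteins is meaningless). All randomness derives from one
seed through per-comparison substreams, so the full result table is
reproducible bit-for-bit.

## Synthetic data

The generator emulates the structure the analysis assumes, not any real
proteome:

- **Chains** alternate ordered/disordered segments with geometric lengths
  (memoryless, one parameter per state). The disordered-segment mean is 40
  residues; the ordered mean is set per protein so the expected disordered
  fraction equals the protein's target content. Protein lengths are
  lognormal (median ≈ 400, σ = 0.45, clipped to [50, 3000]).
- **Targets**: non-nuclear baseline 0.12; compartment targets between 0.12
  and 0.36 with six of eight compartments enriched over baseline and two
  (lamina, pore) programmed null — mirroring the qualitative structure of
  nuclear proteomes, where those two compartments show no clear disorder
  enrichment.
- **Sequences** draw residues from segment-specific compositions; the
  disordered composition is charge/polar-rich and hydrophobic-poor, so
  CH-CDF coordinates respond to the programmed disorder.
- **Tracks** (five by default, emulating a 3+2 predictor panel) score each
  residue from beta distributions with mean 0.25 (ordered) or 0.75
  (disordered) and per-track concentrations 8–12, making the vote
  informative but noisy.
- **Compartments**: multiplicity 1/2/3 with probabilities
  (0.785, 0.19, 0.025) (roughly one fifth of nuclear proteins co-localized
  in two compartments and a few percent in three); extra labels are drawn
  proportionally to compartment size. An optional coupling knob tilts
  multiplicity towards proteins with many disordered domains to emulate the
  moonlighting signal. Provenance is annotated with probability 0.45.
- **Network**: Chung–Lu expected-degree wiring with baseline expected
  degree 8 and node weight ∝ (1 + ρ·standardized true content), ρ = 0.8 by
  default, producing disorder-enriched hubs.

What the generator does *not* emulate: real amino-acid statistics,
homology, real compartment sizes, the empirical (heavy-tailed) PPI degree
distribution, correlated predictor errors, and annotation noise in
localization databases. Tests passing on this generator therefore establish
that the pipeline's bookkeeping, thresholds and inference behave as
specified under controlled conditions — not that any biological conclusion
transfers to a particular real proteome.

Per-protein content is right-skewed at low targets (few segments per
chain), so group *medians* sit somewhat below the programmed expected
content (e.g. ≈ 0.08 at target 0.12); recovery tests therefore compare
medians within ±0.05 of the target.

## Problem sizes and numerical choices in the test suite

The test suite exercises the statistics at deliberately modest sizes chosen
to make the checks sharp but quick: null calibration uses 18 independent
replicate proteomes of 8 × 30 compartment proteins against pools of 400
(1008 comparisons); power checks use +0.2 content shifts at 300 proteins
per compartment; parameter recovery uses 500 proteins per programmed
target. Oracle-equivalence checks run ≥ 200 randomized instances of ≤ 50
proteins/nodes against brute-force reimplementations.

## Known limitations

- The consensus is a hard vote on binarized tracks; no per-track confidence
  weighting.
- The CDF default boundary is a synthetic placeholder (see above).
- Degree is the only centrality; no community structure or weighted edges.
- The enrichment procedure treats proteins as exchangeable within length
  strata; phylogenetic or family structure is ignored.
- No multiple-testing correction is applied across the compartment × metric
  grid, by design.
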