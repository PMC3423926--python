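# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that affect results.

## Profile comparison and the d statistic

Samples are vectors of features — OTU read counts or gel lane
densitometric intensities. All comparisons go through the pairwise Pearson
correlation, expressed in percent (r × 100). Pearson correlation is
invariant to positive per-sample rescaling, so raw counts and relative
abundances give identical similarity matrices and unequal sequencing
depths do not bias the comparison (they do affect its *variance*: shallow
samples are noisier, which the permutation test absorbs but the point
estimates do not). A constant profile has no defined correlation and is
reported as an error naming the sample rather than silently propagating
NaN.

**UPGMA.** Clustering operates on the dissimilarity 100 − similarity with
size-weighted average linkage. Merge heights are half the merge
dissimilarity, so the tree is ultrametric and a node's height is the
leaf-to-node path length. Ties are broken by the lexicographically
smallest combined member list; this makes dendrograms reproducible across
platforms and is the only tie rule used anywhere in the package.

**Bootstrap supports.** Features (OTUs or gel positions) are resampled
with replacement; the support of an internal node is the percent of
replicate UPGMA trees containing *exactly* that node's sample set. The
resampling unit is the feature, not the read: fingerprint bootstrap
conventionally asks whether the clustering is stable against which
characters were measured. Replicates where a resampled profile becomes
constant are discarded but stay in the denominator, so support is, if
anything, understated. Default 500 replicates.

**Percent dissimilarity.** d = mean within-group pairwise similarity −
mean between-group pairwise similarity, in percent points. The
within-group mean pools the pairs of both groups (6 + 3 + 3 pairs in a
6-vs-6 design) rather than averaging per-group means; with equal group
sizes the two conventions coincide, and `pooled_within=False` switches to
the other reading.

**Permutation test.** One-sided (large d indicates a group effect). The
null reassigns samples to two groups of the original sizes; all distinct
unordered partitions are enumerated when there are at most 10,000,
otherwise Monte-Carlo reassignments are drawn, and
p = #(null d ≥ observed)/#(partitions evaluated) with the observed
partition always included, so p > 0. With `strata` given (normally the
soil), reassignments preserve per-stratum group sizes — the right null
when soils genuinely differ and only the treatment labels are
exchangeable. Attainability matters at these design sizes: 3-vs-3 gives
10 partitions (min p = 0.1), 4-vs-4 gives 35 (min p ≈ 0.029), and the
soil-stratified 6-vs-6 test gives 200, so only the latter two can reach
p ≤ 0.05. Results carry `min_attainable_p`, and the pipeline prints the
warning instead of reporting bare non-significance for 3-replicate soils.

## Diversity

Expected richness at depth k uses the exact hypergeometric formula with
binomial coefficients evaluated as log-gamma differences, so depths in the
thousands lose no precision. Chao1 defaults to the bias-corrected form
S + F1(F1−1)/(2(F2+1)), which is defined even without doubletons; the
classic form is available and falls back (with a warning) when F2 = 0.
Shannon uses the natural log (a `base` parameter exists); Pielou is
H/ln S and is reported as undefined — an explicit error, not NaN — when
fewer than two OTUs were observed. Rarefied indices subsample without
replacement (multivariate hypergeometric) n_iter = 100 times by default
and report mean ± sd; in richness mode this mean estimates exactly the
analytic value, which the tests exploit as an oracle.

The diversity-reduction summary compares mean per-sample rarefied richness
between control and treated groups at a common depth, default 400 reads —
the depth at which shallow amplicon groups can still be compared. Per-
sample rarefaction followed by within-group averaging is used (pooling
replicates first is available through pooled vectors); per-sample analytic
expectations make the summary deterministic. Samples below the depth are
excluded with a warning; an empty group is an error.

## Differential taxa

Each taxon at each rank (phylum … genus, then raw OTUs; "unclassified"
lineages form their own bins so reads are conserved) is modelled as
binomial: reads in the taxon out of the sample's total reads, with a
one-factor logistic GLM over soil × treatment groups, fitted per sample
(not on pooled counts), plain binomial with no overdispersion correction.
All pairwise group contrasts are tested on the logit scale.

*Multiplicity.* Unadjusted p-values drive the replication-oriented
enrichment rule; single-step adjusted p-values (the max-|z| law of the
joint normal distribution of the contrasts, the adjustment behind
Tukey-style all-pairs GLM comparisons) and per-rank Benjamini–Hochberg
q-values are reported alongside for modern use. The max-|z| distribution
is evaluated by a fixed-seed Monte-Carlo sample of 20,000 draws from the
joint normal (standard error ≈ 0.0015 near p = 0.05); adjusted values are
floored at the unadjusted ones.

*Separation.* Amplicon tables are full of groups with zero reads for a
taxon, where the Wald test is invalid. Any contrast touching a group with
zero (or all) pooled successes falls back to a two-sided Fisher exact test
on pooled counts, flagged `method="fisher"` with a Bonferroni-adjusted
companion value and a Haldane-corrected log-odds estimate.

*Calibration.* Under multinomial read sampling the Wald contrasts are well
calibrated for taxa with roughly ≥ 50 pooled reads (empirically 0.042–0.047
rejection at α = 0.05) and conservative below (0.016–0.026), as expected
from the normal approximation; the Fisher fallback is conservative by
discreteness. When replicate-level overdispersion is present the plain
binomial model is anti-conservative — that is a property of the model
choice, kept deliberately; a quasi-binomial correction is a natural
extension but is not applied on the default path.

*Decision rules.* Enriched = spiked > control with unadjusted p < α
(default 0.05) per soil; commonly enriched = intersection over soils.
Diminished (per soil): the "average detection" of an OTU is read as the
mean relative-abundance share of the OTUs detected in that soil's control
samples, i.e. 1/S_control (a reads-weighted average gives the same value;
a prevalence-based reading — fraction of control samples containing the
OTU — is implemented as an option). Rule 1: control share ≥ 5× average
and zero reads in every corresponding spiked sample. Rule 2: control
share ≥ 4× average and control > spiked with p < 0.05 in the OTU-level
contrast. Every reported entry carries the rule that fired. An OTU can
never be both enriched and diminished in the same soil because the two
rules require opposite directions.

Because relative abundances are compositional, planting a dominant
responder (20% of the community) mechanically depresses every other
taxon's share in the spiked groups. Two consequences are expected and
real, not artifacts: enrichment lists contain secondary hits beyond the
planted responders only where counts genuinely moved, while the
false-positive *enrichment* rate among unaffected taxa is pushed far below
α (the direction requirement cannot be met); and rule 2 legitimately
flags abundant unaffected OTUs whose share fell. Calibration checks on
enrichment are therefore one-sided (the rate must not exceed α's upper
binomial bound).

## Responder phylogeny

Distances from aligned sequences use pairwise deletion of gap/N columns —
short amplicon fragments lose too much under complete deletion — with
p-distance or the Jukes–Cantor correction d = −(3/4)ln(1 − 4p/3)
(default; the model choice is otherwise unconstrained). JC69 is undefined
at p ≥ 3/4 and raises an error naming the pair. Neighbor joining follows
the Saitou–Nei Q-criterion with lexicographic tie-breaks; negative branch
length estimates are clamped to zero with the total deficit warned. On
additive matrices the reconstruction is exact (path-length residual below
1e-9 in the tests). Bootstrap supports resample alignment columns and
count recovered bipartitions. Compression collapses every maximal subtree
whose leaf-to-subtree-root path lengths are all ≤ a threshold into a
single node labelled `"<representative> (+k)"` (representative =
lexicographically smallest member, k = members − 1); membership is
conserved and recorded on the node. The threshold semantics ("tight
clades by path length") is one defensible reading of compression "at
defined distances" and is fully parameterized. Trees are unrooted;
midpoint rooting is display-only.

## Synthetic communities

The generator emulates a two-soil spiking microcosm at the data level:

* 12 samples = 2 soils × {control, spiked} × 3 replicates; sample ids in
  the T63CA1/T63LP3 style.
* ~2000 species-level OTUs with lognormal baseline abundances
  (meanlog 0, sdlog 1.5 — a long tail where the top OTUs hold a few
  percent each), hierarchically consistent six-rank lineages, and 40% of
  OTUs unclassified at genus level.
* Between-soil divergence: 30% of OTU abundances independently redrawn
  per soil, giving control-vs-control dissimilarities of the few-tens-of-
  percent scale seen in real paired soils.
* Per-group read depths drawn from truncated normals floored at 200
  reads; the default group means ± sd (3272 ± 640, 1695 ± 2079,
  4420 ± 562, 1964 ± 1869) reproduce the uneven, occasionally very
  shallow depths typical of early pyrosequencing runs, with spiked
  samples systematically shallower.
* Replicate overdispersion: each sample's multinomial is drawn on a
  Dirichlet perturbation of the group profile with concentration 100,
  which yields between-replicate standard deviations of a few percent for
  a ~20% taxon — a realistic replicate scatter for such designs.
  `dirichlet_concentration=None` switches to exact multinomial
  sampling, the regime in which the binomial GLM's calibration statements
  hold.
* Planted effects: `CommunitySpec.study_emulation()` raises one responder
  OTU (with its own genus) to 20% and another to 5% of the spiked
  communities in both soils — the dominant/secondary responder pattern —
  and sets ten moderately abundant OTUs (1% control share each) to
  exactly zero in the spiked groups. Structural zeros survive sampling
  exactly, so absent-mode recovery is deterministic given detection in
  the controls.
* DGGE lanes: Gaussian band peaks over a 200-position gradient, 25 bands
  per soil (60% shared between soils), one band per planted responder
  multiplied ×5 in spiked lanes, additive clipped Gaussian noise. With
  zero noise replicate lanes are identical.

What it does **not** emulate: read-level artifacts (chimeras, sequencing
error, classifier confidence), taxon-correlated abundance structure,
environmental covariates, or gel-image processing. Passing recovery tests
therefore show the *statistics* behave correctly under the stated
sampling model, not that upstream bioinformatics is robust.

## Problem sizes and determinism

The calibration studies run 500 null datasets at 200 OTUs (type-I error of
a permutation test does not depend on table width, so the small width
keeps the study quick); recovery studies run at the full 2000-OTU,
realistic-depth configuration. All generator randomness flows from one
integer seed through named substreams (taxonomy/profiles/reads/gel), so
every artifact is reproducible from config + seed; the pipeline's run log
records seed and library versions and contains no timestamps, making
repeated runs byte-identical. Monte-Carlo oracles in the tests use
3-standard-error bands with a rule-of-three floor (3/n) where an event
can be too rare for the replicate sample to resolve.

## Known limitations

* The GLM treats reads as independent binomial trials; under replicate
  overdispersion its unadjusted p-values are anti-conservative (see
  above). The enrichment rule inherits this by design.
* Relative-abundance conclusions are compositional: a large responder
  depresses all other shares, and "diminished" means numerically reduced
  in share, not necessarily in absolute population size.
* The d statistic summarizes similarity differences in percent points;
  it has no absolute-scale interpretation across feature sets of very
  different dimension.
* With fewer than 4 replicates per group no within-group exhaustive
  permutation test can reach p ≤ 0.05; only the stratified pooled test
  can. The package reports attainability rather than fabricating power.
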