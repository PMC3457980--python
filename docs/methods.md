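# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, and the limits of what the synthetic-data tests
demonstrate.

## The experimental design being modelled

One Illumina HumanWG-6-class BeadChip carries six arrays; each condition
(siFUS, siEWS, siTAF15, the triple knockdown, and two controls matched to
the low and high total siRNA concentration) is measured once. Single
knockdowns are contrasted against the low-concentration control
(`controlPlus`), the triple knockdown against the high-concentration
control (`controlTriplePlus`), so every contrast compares equal total
siRNA amounts. With one array per condition no variance-based test is
possible; differential expression must rest on fold-change and detection
criteria. That constraint shapes everything below.

## Preprocessing

**Quantile normalization.** Each array's intensity distribution is forced
onto the across-array mean of order statistics; within-array ranks are
preserved. Ties receive the mean of the target values they map to, which
conserves column sums exactly. Normalization operates on the
regular-probe matrix only: negative-control probes inform the background
constant, not the rank structure, and including them would let their
random variation perturb otherwise identical arrays. On tie-free
matrices the transform is exactly idempotent; with ties the averaging
rule can shift values by a second application (ties are measure-zero for
continuous intensities).

**Detection filtering.** A regular probe is kept iff its detection
p-value is < α (default 0.05) on *at least one* array — "not expressed in
any array" is the removal condition. The removed count refers to regular
probes; negative controls are excluded from the expression matrix
unconditionally. An optional `drop_zero_variance` flag additionally
removes probes constant across all arrays (off by default, since a
constant probe is harmless to ratio calling and the on/off partition
invariant is easier to reason about).

**Background.** The arithmetic mean of negative-control intensities
pooled over all arrays, computed from *raw* signals (the controls define
an absolute background level; normalizing them first would couple the
estimate to the regular-probe distribution). Full precision is kept
internally; the integer-rounded value is the quotable constant. With the
default generator settings this recovers 28.

**Detection p-values.** Real arrays carry vendor-computed detection
p-values, used as-is. For synthetic data the rank-based empirical
analogue `p = (1 + #{controls ≥ x}) / (N + 1)` is computed per array
against that array's negative-control intensities; it lies in (0, 1] and
its 5% quantile sits near the 95th percentile of the control
distribution, mimicking the vendor definition.

## DEG calling

For each retained probe, `ratio = (treated − b) / (control − b)` with the
background constant `b`. Ratios are computed on quantile-normalized
signals (with the raw-derived `b`): with a single array per condition,
un-normalized ratios would confound chip-position brightness with
biology. A `use_raw` switch preserves the literal raw-intensity reading
for comparison runs. Probes with a non-positive background-subtracted
signal on either side are flagged invalid rather than clamped — a signal
at or below background carries no fold-change information, and clamping
would manufacture extreme ratios exactly where the data are least
informative.

Classification (strict inequalities, defaults): *up* iff ratio > 2 and
treated detection p < 0.05; *down* iff ratio < 0.5 and control detection
p < 0.05. The detection condition attaches to the array where the gene
is claimed expressed. The two rules are mutually exclusive (2 and 0.5
cannot both hold) and antisymmetric: swapping treated/control inverts the
ratio and exchanges up/down when the p-value roles are swapped too. The
counting unit is the probe throughout.

## Set analysis

Venn partitioning is exact membership enumeration; regions are pairwise
disjoint and cover the union, so region sizes sum to the union size.
Comparison against a combined (triple) knockdown reports, for each region
of the single-knockdown partition, how many of its members reappear in
the combined set, plus the count unique to the combined set.

Overlap significance uses the one-sided hypergeometric upper tail
(Fisher's exact test in the enrichment direction), the standard
formalization when the original analysis does not name its test. The
universe defaults to the number of probes surviving the detection filter
— only those could have been called — and is configurable for gene-level
comparisons, where the significance verdict can depend materially on the
universe chosen. Identifier matching is exact-string with an optional
case-folding flag; no ortholog or probe-to-symbol mapping is attempted.

## Multiscale-bootstrap clustering

**Gene selection.** Probes expressed near-identically in all arrays are
uninformative for inter-array structure and would dilute the correlation
signal; selection keeps probes with across-array SD above a threshold, or
the top-k by SD. No canonical cut-off exists; analyses here use
`top_k=300` on log2 intensities, chosen as a round number giving stable
correlations for six arrays. Clustering operates on `log2(x + 1)` so
that fold changes, not absolute intensities of the brightest probes,
drive the distances.

**Clustering.** Distance `d(x, y) = 1 − r(x, y)` (Pearson, over selected
probes) with average-linkage agglomeration — the conventional defaults
for expression-profile clustering when no settings are stated. Ties in
the merge distance are broken deterministically by the lexicographically
smallest merged member tuple. A zero-variance array column makes the
correlation undefined and is rejected with an error.

**Support values.** For each relative scale r in {0.5, …, 1.4} and B
replicates per scale (default 1000), probe rows are resampled with
replacement to size ⌈n·r⌉ and the arrays re-clustered; `BP_r` is the
fraction of replicate trees containing each original cluster. Fractions
are clipped to [1/(B+1), 1 − 1/(B+1)] so the probit transform stays
finite. The transformed values `z_r = Φ⁻¹(1 − BP_r)` are fitted by
weighted least squares to `z_r ≈ v√r + c/√r`, with per-scale weights
`B / (BP_r(1 − BP_r))` — the binomial-variance weighting, folding the
proportion's uncertainty into the fit. Then `AU = 1 − Φ(v − c)` and
`BP = 1 − Φ(v + c)`; v estimates the signed boundary distance and c its
curvature. Degenerate cases are snapped, not extrapolated: a cluster at
the ceiling at every scale gets AU = BP = 1 (flag `at_ceiling`), one
never observed gets AU = BP = 0 (flag `never_observed`). Replicates
whose resample produces an undefined correlation are discarded for all
clusters alike. Random streams are derived per (scale, replicate) from
the master seed, so supports are independent of evaluation order and of
array column order (cluster identity is the member *set*).

The fitted BP at r = 1 agrees with the raw appearance fraction within
binomial error (an internal consistency check exercised by the tests).
No external reference implementation of the multiscale bootstrap is
available in this environment, so validation rests on those internal
consistency properties and on planted-structure recovery rather than on a
numerical cross-check against another package.

## qPCR quantification

`X0 = E^(−Cq)` back-calculates the starting amount from the exponential
amplification model; E ∈ (1, 2] is the per-cycle efficiency from dilution
standard curves (default 2.0 = 100%). Technical replicates are averaged
on the linear X0 scale — X0, not Cq, is the quantity the method is built
around — and relative expression is the double ratio
`(X0_target/X0_ref)_sample / (X0_target/X0_ref)_control`. The reported
SD propagates the replicate X0 scatter (sample SD, ddof = 1) through the
double ratio in first order: relative variances add in quadrature. At
E = 2 with single replicates the value equals `2^(−ΔΔCq)` exactly, and a
global Cq shift (e.g. a threshold change affecting all wells equally)
cancels.

## Synthetic-data generator

Each regular probe draws a log-normal baseline
(`2^N(μ, σ)`, defaults μ = 6, σ = 2 in log2 units) shared by all six
arrays; per-array measurement noise is log-normal with σ = 0.15 (log2),
i.e. ~11% CV, an intermediate value covering technical plus
pooled-transfection variation. These defaults put roughly 40% of probes
below the detection threshold on every array, emulating the heavy
filtration typical of whole-genome BeadChips. Negative-control probes
(default 800 of 48,803; the true count on the chip is not public
knowledge, so this is a free parameter) are identically distributed in
every array, log-normal with log2-SD 0.5 and arithmetic mean equal to
`negctrl_mean` (default 28) — the mean *is* the intended background.

Effects: each knockdown perturbs `frac_deg_per_group` of regular probes
(default 0.006 ≈ 300 per group at chip scale, matching the order of
magnitude of the design being emulated) by a multiplicative fold with
magnitude log-uniform in `fold_range` (default 3–6) and sign down with
probability `down_fraction` (0.55). Sharing structure: a FUS∩TAF15
overlap (`frac_shared_fus_taf15`, default 0.14 of each group's DEGs)
containing an all-three core (`frac_shared_all`, 0.07); shared probes
reuse the identical effect across groups. The triple knockdown carries
the union of all single-group effects plus an independent triple-unique
block sized so that the unique fraction equals `frac_triple_unique`
(default 0.8). Note this "union plus unique" structure makes the triple
DEG set several times larger than any single set — a deliberate
simplification: it models additivity plus emergent combined effects, not
the sub-additivity real triple knockdowns can show.

Effects are planted only on probes bright enough to be observable:
up-effects require baseline ≥ 4× background, down-effects require
baseline ≥ 2 × background × fold_high, since dividing a dim probe by its
fold drops it to the background where the ratio is undefined. This is a
property of the measurement (background-subtracted ratios cannot see
changes in unexpressed genes), encoded in the truth so that recovery
metrics measure the pipeline, not the physics. Two control arrays are
drawn from the same null distribution; any divergence between them is
noise.

What passing tests show — and don't. Planted-effect recovery
(sensitivity ≥ 0.95, FPR ≤ 0.01 at low noise; FPR ≈ 1% at the default
noise, concentrated in dim probes where background subtraction amplifies
noise) demonstrates the rule's behaviour under the generator's
assumptions: independent log-normal noise, no batch or spatial effects,
no probe cross-hybridization, no annotation error. Real single-replicate
arrays violate several of these, which is precisely why fold-change DEG
lists from n = 1 designs need orthogonal (qPCR) confirmation.

## Problem sizes and numerical choices

The test suite runs at desk scale (hundreds to a few thousand probes,
B = 100–200 bootstrap replicates); the acceptance script runs the DEG
pipeline at full chip scale (48,803 probes) and the bootstrap at
B = 1000, which completes in seconds. Quantile normalization compares
exactly against a brute-force oracle at 1e-12; hypergeometric tails are
checked against exhaustive enumeration for all universes N ≤ 12.
Dendrogram branch lengths are merge-height differences; AU/BP labels are
rounded to integer percentages on export. All writers emit deterministic
bytes for a given object.

## Known limitations

- Gene-level collapsing of probes is not performed; counts are per probe.
- The multiscale-bootstrap weighting omits the probit-density factor some
  formulations include in the delta-method variance; at the support
  levels of interest (BP not extreme) the difference is small and the
  internal r = 1 consistency check bounds it.
- The generator does not model bead-level summarization, chip spatial
  artifacts, or sequence-dependent probe affinity.
- GEO SOFT/series-matrix parsing is out of scope; real deposits are
  ingested by exporting to the canonical TSV layout described in the
  README.
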