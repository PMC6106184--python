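# Methods

## The scoring model

A tow is an ordered sequence of fixed-duration video segments (default
5 s). Segments are the unit of observation; their intervals are half-open
`[k·d, (k+1)·d)` with 0-based contiguous indices, so annotation timestamps
map to exactly one segment and nothing is double-counted. A trailing
part-segment is kept when it is at least 1 s long, otherwise dropped — a
sub-second sliver carries no scoreable footage.

Per segment the analyst supplies: a quality flag, percentage cover in
[0, 100], and tube elevation in cm. Because the camera's field of view
drifts, cover is estimated once per *new field of view* and the sum is
divided by the number of new views (`normalize_cover`), clamped to [0, 100].
Two derived fields are never stored authoritatively but recomputed on every
read: **presence** (1 iff cover > 0, 0 iff cover = 0, missing when the
segment is unusable) and **status** from the reef structure matrix.

Scoring edge cases, decided here because the field protocol leaves them
open:

- A segment containing both obscured and usable footage is `ok` if any
  usable cover estimate exists; only segments with an explicit unusable
  flag or no cover estimate at all become `unusable`.
- Positive cover with no measurable tube elevation is scored at 0 cm. Via
  the <2 cm band this classifies as Not a reef — the conservative reading:
  visible worms without erect tubes are not reef structure.
- Zero cover clears the elevation field (there is no structure to measure).

## The reef structure matrix

Status is an ordinal scale NoReef < NotAReef < Low < Medium < High, with
Missing outside the ordering. The matrix maps four cover bands × four
elevation bands to a class; any cell with <10% cover or <2 cm elevation is
Not a reef. The printed band labels do not say which band owns a shared
edge, so bands are left-closed, right-open (`[10, 20)` etc.): contiguous,
deterministic, and conventional. The matrix ships as a YAML config
(`reefpatch/data/reef_matrix.yaml`) validated on load for partitioning,
legal classes, and ordinal monotonicity along both axes, so alternative
band schemes (e.g. the original Gubbay categories) can be swapped in
without code changes.

For broad-scale habitat segmentation, a habitat change is recorded only if
it persists ≥ 60 s; shorter runs are folded into the preceding section and
flagged as incidental patches. The first run of a tow is always kept (it
has no preceding section). A segment straddling a change carries the label
of the habitat occupying most of it, because labels arrive per segment.

## True patchiness

The presence sequence of a tow is cleaned by deleting missing values and
concatenating the remainder — so a missing observation between two presence
runs bridges them into one patch, and the randomization null operates on
the same cleaned string as the observed statistic. A patch is a maximal run
of 1s; a run ended by the end of the sequence still counts (this preserves
`sum(sizes) = number of 1s`).

With observed mean patch size `p_o`, the statistic is `K = p_o / p_r`,
where `p_r` is the mean of the mean patch sizes over 1,000 uniform random
permutations of the cleaned sequence. Permuting — rather than, say,
resampling Bernoulli draws — conditions on the observed prevalence: `K`
isolates the *arrangement* of presence from its abundance. The p-value is
the proportion of randomized means strictly greater than `p_o`; the number
of exact ties is reported alongside, and a Manly-style
`(greater + ties + 1)/(N + 1)` variant is available as an option (default
off, so the primary output matches the original strictly-greater
definition). One shared set of randomizations serves both `p_r` and the
p-value for a tow.

Implementation notes:

- Permutations are applied to the canonical sorted arrangement of the
  multiset, so any two sequences with the same 0/1 counts share an
  identical null sample for a given seed — the null depends on the multiset
  only, and permutation invariance holds exactly, not just in
  distribution.
- The per-permutation mean patch size is computed as
  `n_ones / (n_ones − #adjacent 11 pairs)` without run-length decoding;
  permutations are drawn in memory-bounded blocks.
- `exact_null` enumerates all `C(n, k)` position subsets of the 1s (each
  equally likely under uniform permutation), capped at 10⁶ arrangements,
  giving exact `p_r` and p-value as the oracle for the randomized path.
- Constant sequences (all 1s or all 0s) raise an error rather than return
  a default: every permutation is identical there, `K` is uninformative,
  and a silent `K = 1` would corrupt monitoring time series. Tow summaries
  still report the status percentages and patch counts for such tows, with
  the patchiness fields empty and a logged warning.
- Reproducibility: one run seed; per-tow sub-seeds are derived
  deterministically from `(seed, crc32(tow_id))` via numpy's SeedSequence,
  so adding or reordering tows does not perturb other tows' results.

Per-tow summaries report percentages of *valid* (non-missing) segments in
each status class (they sum to 100), patch count, mean/median patch length,
patch size range, `K` and p-value. The summary CSV is ordered by descending
largest patch by default, matching the published presentation; the mean
patch length and the percentage columns both use the same non-missing
denominator convention.

## Synthetic transects

The generator emulates what the scoring protocol would produce over
clustered reef. Presence follows a two-state Markov chain with
stay-probabilities `a = P(1→1)` and `b = P(0→0)`; mean presence-run length
is `1/(1−a)` and stationary prevalence `π = (1−b)/((1−a)+(1−b))`. Defaults,
chosen once: `n_segments = 120` (a 10-minute tow, the survey minimum, at
5 s), `a = 0.9` with `b` solved for `π = 0.3` — the strongly clustered,
moderate-prevalence regime the detection analyses use; `missing_rate =
0.05` i.i.d. (a typical obscured-seabed fraction; a burst mode generates
missing *runs*, as obscured footage occurs in practice, via a second Markov
chain matched to the same marginal rate). Given presence, cover ~
Uniform(0, 100] and elevation ~ Uniform(0, 15] cm: no distributional shape
is documented for real reef scores, so the flattest defensible choice is
used, and both families are pluggable (uniform, constant, lognormal,
truncated to their domains).

What the generator does *not* emulate: spatial autocorrelation of cover and
elevation within a patch (draws are i.i.d. given presence), analyst
scoring error, correlation between missingness and habitat, and tow-level
covariates. Passing tests therefore demonstrate the statistical machinery
is correct under the stated model, not that real tows satisfy that model.

## Calibration and power, at the sizes computed here

The test suite recomputes, at desk scale: agreement of the randomized null
with exact enumeration for every 0/1 composition of lengths ≤ 10 (10,000
randomizations, tolerance 0.05); null calibration over 500 i.i.d. sequences
(n = 200, prevalence 0.3) — mean K within [0.95, 1.05] and p-values
consistent with uniformity (KS, α = 0.01); and detection of genuine
clustering — chains with `a = 0.9`, `π = 0.3`, n = 500 yield K > 1 with
p < 0.05 in ≥ 95% of 200 replicates. The strictly-greater p-value is
discrete (mean patch size takes finitely many values), so its null
distribution is only approximately uniform; the tie-corrected option is
the remedy where exactness matters.

Station-level values from real surveys are not reproducible here: they
require the original per-segment scores, which are held in an external
archive. The summary CSV reproduces the published column structure, and
self-consistency is verified on synthetic tows instead.

## Known limitations

- `K` is strictly along-transect (1-D); it says nothing about 2-D patch
  geometry.
- The statistic's resolution is set by the segment duration: within-segment
  gaps are invisible, so shorter segments measure patchiness more finely.
- p-values are randomization p-values conditional on prevalence; tows with
  very few presence (or absence) segments have coarse, tie-heavy nulls.
- Patch statistics on sequences with heavy missingness inherit the
  bridging rule: missing-bridged patches may overstate patch length.
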