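# Methods

This note records the model behind each stage of the pipeline, the
parameters that matter, and the design choices made where the method
itself leaves the question open.

## Depletion model and per-peptide statistics

RBR-ID treats the ±4SU contrast as a per-peptide two-sample problem on
run-sum-normalized label-free intensities. Normalization divides each
intensity by its run's total, so any run-level multiplicative factor
(loading, ionization efficiency, instrument batch) cancels exactly; the
per-peptide score is therefore invariant to rescaling any single run.

Condition means are arithmetic means over that condition's runs, **zeros
included**: a zero is a measurement (below detection), not missing data.
Only when every replicate of a condition is zero is the mean undefined in a
useful sense; it is then imputed as

    imputation_floor_factor (default 0.5) × min over all peptides and both
    conditions of the strictly positive condition means.

The minimum is global, not per-condition — the floor should represent the
quantification limit of the dataset, which is a property of the experiment
rather than of one condition. Peptides all-zero in *both* conditions are
dropped with a warning: both means would impute to the same floor, giving
ratio 1 and score 0, an artifact rather than a measurement.

The t test is the classic pooled-variance (not Welch) unpaired two-sided
Student's t with n₁+n₂−2 df, computed on the same linear-scale normalized
intensities the ratio uses; a `test_scale="log"` switch tests log₂
intensities instead for users who prefer variance stabilization. Degenerate
zero-pooled-variance pairs give P = 1 when the group means are equal and
P = 1e-15 otherwise; independently, P is clamped to [1e-15, 1] before the
(log₁₀ P)² term, bounding any single peptide's score at 225·|log₂ ratio|
while preserving ranking.

Significance is P < α (strict; default α = 0.1) **and** log₂ ratio < 0 —
only depleted peptides can be RNA-contact evidence; enrichment is noise or
an indirect effect. No multiple-testing correction is applied: the score
track, not the significance list, is the primary readout, and the α = 0.1
filter is deliberately permissive. Note the direction filter means that on
null data the *significant* rate is ≈ α/2, while the P < α rate is ≈ α.

## Residue projection

Peptides are located by exact substring search against the target protein
(all occurrences, overlapping included; I/L distinct — the table is assumed
to come from a search engine that already resolved sequences). Each
residue's raw score is the sum of scores of all overlapping peptides.
Multimapped peptides default to policy `all` (add the full score at every
match): the alternative of discarding them loses signal silently, and the
multimap flag is visible downstream. `drop` and `split` are available.

Uncovered residues carry raw score 0 and participate in smoothing, so the
track is continuous along the full sequence; segment-calling quantiles are
computed over covered residues only, so coverage gaps do not deflate the
threshold.

## Supersmoother

The residue track is smoothed with a from-scratch implementation of
Friedman's variable-span supersmoother: running local linear fits over
nearest-neighbor windows at three primary spans (0.05, 0.2, 0.5 of n —
Friedman's published defaults; the window is `max(min_window, round(span·n))`
points, one-sided at the boundaries), leave-one-out absolute residuals via
the deletion formula r/(1−h), per-point span selection by the smallest
midrange-smoothed residual with optional bass enhancement toward the widest
span, smoothing of the chosen spans, and linear interpolation between the
two bracketing primary fits. All window statistics come from prefix sums
(O(n) per pass). By default a final fixed-span pass at the smallest span is
applied to the interpolated values, as in the original algorithm and R's
`stats::supsmu`; `SmootherConfig(final_pass=False)` yields the pure
interpolation, which is pointwise bounded by the three primary fits (the
envelope property used in testing). Comparison with R's supsmu on seeded
signals shows agreement within a few percent of the dynamic range away from
the boundaries; the first/last handful of points differ because the
implementations truncate boundary windows differently.

For residue smoothing x is the residue index 1…L, so x is always strictly
increasing and equally spaced; the smoother still validates general x for
standalone use. Defaults: spans (0.05, 0.2, 0.5), bass 0, min_window 5
(keeps leave-one-out leverages well below 1).

## Segment calling

Candidate RBRs are maximal runs of residues whose smoothed score exceeds
the `threshold_quantile` (default 0.85) of smoothed scores over covered
residues, merged across gaps ≤ `merge_gap` (5 aa) and filtered to
≥ `min_length` (10 aa), ranked by peak score. The quantile default reflects
the scale of the object being called: a major RBR of a large protein can
span ~10–15% of its sequence (ATRX's designated RBR is 351 aa of a 2492-aa
protein, ~14%), so the threshold must admit at least that fraction of
residues; a 0.95 quantile can never cover such a region. Users calling
narrow, sharp sites should raise the quantile.

## Synthetic experiments

The generator emulates an in vitro RBR-ID design on one purified protein:

- protein: i.i.d. residues at vertebrate average amino-acid frequencies
  (K+R ≈ 11%, so tryptic peptides average ~9 aa); tryptic digestion with
  the proline rule, 1 missed cleavage, peptide length 6–30 by default;
- design: 8 crosslinked + 8 control runs in 2 instrument batches;
- intensities: per-peptide base abundance LogNormal(ln-mean 16 ≈ 9×10⁶
  arbitrary units, ln-sd 1.5); a per-batch multiplicative factor
  (ln-sd 0.3), removed exactly by run-sum normalization; multiplicative
  log-normal measurement noise with CV 20%, typical of label-free
  quantification;
- depletion: peptides overlapping the planted RBR by ≥1 residue keep a
  fraction δ of their intensity in +4SU runs only (crosslinking at a single
  residue suffices to shift the whole peptide's mass);
  `proportional_depletion` scales the effect by the overlap fraction
  instead;
- dropout: detection probability expit(steepness · (ln I − midpoint)) with
  midpoint ln 13 (two abundance-sd below the mean) and steepness 1 — about
  5% missingness at median abundance, concentrated at low intensities,
  which is what produces the all-zero conditions the imputation rule
  exists for.

What the generator does *not* model: peptide-specific ionization
efficiencies beyond the static base abundance, retention-time or charge
effects, interference/co-isolation, peptide×batch interactions, or
proteome background (a single protein is simulated). Passing recovery tests
therefore demonstrates the statistical machinery, not robustness to every
artifact of real MS data.

Null calibration measured on this generator (20 seeds × ~1070 peptides,
δ = 1): the P < 0.1 fraction is ≈ 0.095 — slightly conservative because the
t test sees occasional zeros — within 3 binomial SE of 0.1; signed scores
split ~50/50 around 0. Recovery of a 300-aa planted region on a 2500-aa
protein at δ = 0.5, CV 20%, 8+8 runs is routine: across seeds the top
segment's Jaccard with truth is ~0.6–0.9 and its center lands within ~20
residues. Problem sizes used in the test suite and the acceptance script
(2500–7700-aa proteins, ~300–1100 peptides, 20 null seeds) keep any single
check under a couple of minutes on one core.

## Numerical and degenerate-input choices

- Empty intensity cells parse as 0 (not-detected convention of upstream
  quantification tools); malformed text errors.
- Ambiguous residue codes (B/Z/X/U/O) are rejected everywhere: they cannot
  be placed on a 20-letter protein string unambiguously.
- Contaminant filtering is substring matching on protein identifiers
  (default patterns `CON__`, `REV__`); the filter is idempotent.
- A peptide absent from the target protein is a warning, not an error — in
  re-analysis settings many table rows belong to other proteins.
- Segment calling on an uncovered profile returns no segments with a
  warning.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give byte-identical output
  files.
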