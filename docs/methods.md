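# Methods

## The combinatorial code registry

A color code is a triple (fluorescent combo, CAAR permutation, DNA
barcode). The six fluorescent combos are the single and pairwise positive
patterns over hmAG3, YFP and mChEY — the all-negative and triple-positive
patterns are reserved as rejection classes, which is what makes the
boolean fluorescent readout error-evident. The eight CAAR permutations are
the 2^3 antibody-binding states of HA, cMyc and Thy1.1 displayed on the
EGFRt anchor; EGFRt itself is positive on every code and serves as the
vector-bearing-cell pre-gate. Every (combo, permutation) pair is used
exactly once, so the 48 expected 7-channel signatures are distinct by
construction.

The published design does not print the full code-number-to-combination
table; it fixes only two anchors (codes 1–24 are cMyc-positive, and codes
1, 5, 9, 13, 17, 21 carry the fully antibody-binding array across the six
combos). The registry's numbering — blocks of four CAAR permutations per
fluorescent combo, fully-binding first, CAAR order within a block
(ha, thy) = (1,1), (1,0), (0,1), (0,0) — satisfies both anchors and is the
canonical convention of this package; every exported table carries the
explicit assignment, so downstream code never relies on the convention
implicitly.

DNA barcodes are random nucleotide strings (default length 30) drawn under
a pairwise Hamming distance ≥ 3 constraint, so any single substitution
still decodes uniquely. Construction is rejection sampling with a bounded
retry budget; an unsatisfiable combination of length and distance raises a
configuration error rather than looping.

## Clonal competition simulator

Time is discrete in passages (the 1:10 split every 2–3 days of routine
culture; `split_interval_days` is axis metadata only). Each passage
applies, in order:

1. **Selection** — the deterministic replicator update
   `f_i ← f_i·w_i / Σ_j f_j·w_j` on relative fitness `w_i`.
2. **Drift** — multinomial resampling of `n_cells_at_passage` cells
   (default 10^4), the bottleneck of the split. `None` disables drift and
   gives the infinite-population limit, for which closed forms exist
   (`f_1(T) = w^T/(w^T+1)` from a 50/50 start) and are used as test
   oracles.
3. **Mutation** — with per-clone probability `mutation_rate`, the clone's
   fitness is multiplied by a log-normal factor centered at 1.2
   (`mutation_log_sd` 0.05). The 1.2 default makes spontaneous dominance
   (> 10 % of the mix) appear within a few tens of passages at the default
   bottleneck, which is the qualitative phenomenology of long-term
   multiplexed cultures; there is no published per-passage mutation rate,
   so the default (0 in the library; an explicit parameter everywhere it
   matters) is always stated by the caller.

## Gene-marking dynamics and selection regimes

`simulate_marking` tracks the fraction of vector-expressing cells under
three regimes: *none* (unmarked cells persist — marking decays
geometrically at the silencing rate, `(1-s)^t` normalized to day 0),
*dhfr_addiction_noHT* (cells whose endogenous DHFR is knocked out die
without vector-encoded DHFR once hypoxanthine/thymidine supplementation is
withdrawn — unmarked cells have survival 0 and marking is driven to 1),
and *dhfr_addiction_HT* (the HT salvage pathway partially rescues unmarked
cells with per-passage survival `ht_rescue`, producing an intermediate,
monotone rise toward the fixed point `((1-s)-r)/((1-s)(1-r))`).

The dynamics are expectation (infinite-population) recursions rather than
per-cell sampling: the regime contrasts the package asserts — strict
monotone decline, monotone enrichment, and the rescued trajectory lying
strictly between the two — are properties of the expected dynamics, and
finite-cell noise would only blur them. The function returns both the raw
marked fraction (day 0 = `initial_marking`, default 0.4, a typical initial
transduction rate) and the day-0-normalized trajectory, because published
marking curves are conventionally normalized to day 0.

## Cytometry measurement model

All intensities are log10-normal. Marker channels share a negative
(autofluorescence) component at log-mean 2.0 and a positive component at
4.0, both sd 0.3 — roughly two decades of separation, i.e. a cleanly
compensated bright label. Scatter places intact cells at FSC-A log-mean
5.0 with a tight FSC-A/FSC-H ratio (sd 0.02 in log10); debris is low-FSC /
high-SSC; doublets are the channel-wise sum of two independently drawn
singlets with FSC-H inherited from one parent (sufficient to exercise the
singlet gate, not a pulse-shape model); dead cells are DAPI-bright
(log-mean 4.0 vs 2.0). Variegated (dim) cells express their positive
channels at an intermediate log-mean 3.0.

Contamination and dim fractions default to 0: the default model is the
clean acquisition, and contamination/variegation are switched on
explicitly where they are the object of study (the pre-gate and dim-loss
tests). A 3×3 spillover matrix over the fluorescent channels can be
applied after sampling to stress the gating; it is off by default since
routine analysis operates on compensated data.

What the generator does **not** emulate: spectral overlap beyond the
optional linear spillover, instrument drift between acquisitions,
autofluorescence heterogeneity across cell states, doublet pulse shapes,
or acquisition-order effects. Tests passing on this generator therefore
demonstrate the correctness of the decision logic and estimators under the
stated noise model, not instrument-level robustness.

## Threshold fitting

The published gating is manual; automation is this package's contribution.
Three methods fit the per-channel positive/negative cutoff on log10
intensity:

* `mixture2` (default): a two-component Gaussian mixture; the cutoff is
  the equal-posterior point between the components, solved on a grid
  between the component means. A channel is accepted as bimodal only if
  the two-component fit beats one component by BIC **and** the component
  means are separated by more than the sum of their standard deviations —
  without this guard the EM fit happily splits a single Gaussian in half
  and the "threshold" lands mid-population.
* `valley`: minimum of a Gaussian-KDE-smoothed density between the
  outermost modes.
* `percentile`: a stated quantile (default 99.9) of a negative control, or
  of the sample itself when no control is supplied.

Unimodal channels fall back deliberately: a unimodal *marker* channel
(EGFRt when every cell is vector-bearing, or an unused fluorochrome) takes
the pooled all-marker-channel mixture cutoff, since the autofluorescence
component is shared across channels; a unimodal *gate* channel (FSC-A with
no debris, DAPI with no dead cells) takes a tail percentile so that only
the stated tail (0.1 % by default) is sacrificed. Each fallback emits a
`ThresholdWarning` and is recorded in the fitted object's `method` map.

Positivity is a strict inequality (`log10 intensity > cutoff`); an event
exactly at the threshold is negative. Gates are axis-aligned by design —
reproducible and sufficient for a boolean code structure; polygon gating
is out of scope.

## Deconvolution

Gate order is fixed: debris (FSC-A floor) → singlet (relative deviation of
FSC-A/FSC-H from the median ratio, tolerance 0.35) → dead (DAPI ceiling) →
EGFRt (vector-negative below cutoff) → fluorescent combo (invalid patterns
→ `unassigned_fluor`) → CAAR permutation → registry lookup. Every event
receives exactly one label; the labels partition the input. The
implementation bit-packs the six boolean marker calls and maps them
through a 48-entry table; the test suite checks it event-by-event against
an independent exact-signature-lookup oracle, which must agree on every
event by construction.

Per-code fractions are reported with the coded events (assigned to any of
the 48 codes) as denominator; the all-live-singlets denominator is
exported alongside, since published "population sizes" are ambiguous
between the two. Dim (variegated) events fall below the positive cutoffs
and are counted as vector-negative or unassigned, mirroring bench practice
of excluding the dim population from the main gate — they are a known,
intentional loss channel, not an error.

## Barcode counting

Read layout: sample index + 5' flank + barcode + 3' flank. Demultiplexing
requires indices at pairwise Hamming distance > 2·`max_index_mismatch` so
assignment is unique. The barcode is located by matching the 5' flank at
its expected offset first (scanning only as a fallback), verifying the 3'
flank, then exact-dictionary lookup with a Hamming-distance-1 nearest-
neighbour fallback. A barcode within the mismatch budget of two registry
entries is ambiguous and never force-assigned — impossible for the built-in
distance-3 registry at budget 1, but the rule guards user-supplied
registries. Tallies (matched, unmatched index, unmatched flank, ambiguous,
unmatched barcode) partition the total read count exactly.

## Clone-fate analytics

Size classes use the printed cutoffs with strict inequalities: minor
≤ 2 %, large > 5 %, dominant > 10 %, intermediate otherwise; a fraction of
exactly 5 % is not large. Dominant is a subset of large by value, but the
reported classes partition the codes.

The four named trajectory patterns have no published numeric definition;
this package's operationalization (defaults in `TrajectoryParams`) is:
extinction — final ≤ 0.001 < initial; transient expansion and collapse —
peak ≥ 3× initial, final ≤ peak/3, final not itself expanded; delayed
expansion — final ≥ 3× initial with the series confined to a factor 2 of
the initial through the early half of the window; continuous expansion —
final ≥ 3× initial with the maximum at or adjacent to the end; persisting
— everything else. The rules are evaluated in that order: delayed must
precede continuous because a delayed riser also ends at its maximum. The
four archetype series and their labels are the behavioral contract
(tested). A fifth catch-all class exists because the observed taxonomy is
"at least four" patterns; persisting is never merged into the named four.
The extinction floor is the one absolute (non-ratio) parameter, so
scale-invariance of the classifier holds when the floor is scaled with the
series.

Paired-sample agreement is squared Pearson R² on untransformed fractions
(log-scale comparison can be done by transforming the inputs, but plain
fractions are the default because published population-size correlations
are on linear scale). Relative fitness is the exponentiated least-squares
slope of `log(f_i/f_ref)` against passage — exact under drift-free
replicator dynamics (recovered to ≥ 4 decimals in tests) and unbiased to
within 5 % in the mean over 100 drifting replicates at bottleneck 10^4
over 20 passages (tested). Perturbagen response is the per-code
treated/control fraction ratio at the final common timepoint — no
area-under-curve summarization; codes at zero in the control are flagged
NaN rather than dropped.

## Problem sizes and numerical choices

The test suite and the acceptance script use 10^5 events/reads for
distribution-level checks (binomial 5-SD bands), 10^4-cell bottlenecks
over 20 passages for fitness recovery, and 100 replicates for stochastic
means; these sizes put Monte-Carlo error well inside the asserted bands
while keeping a full run in the tens of seconds. Fraction conservation is
asserted at 1e-9 in the simulator and 1e-6 end-to-end. All randomness
flows through `numpy.random.default_rng` seeds; identical config + seed
gives bit-identical output (tested).

## Known limitations

* Event tables are CSV only; FCS ingestion is a config-level extension
  point, not implemented.
* The gating assumes compensated (or synthetic, spillover-free) data;
  compensation/unmixing estimation is out of scope.
* The measurement model is stationary; no drift between timepoints.
* Barcode counting models substitution errors only — no indels, chimeras,
  UMIs or PCR-duplicate structure.
* The registry numbering beyond the two published anchors is a declared
  convention; analyses that depend on the bench assignment must import the
  bench table via `CodeRegistry.from_tsv`.
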