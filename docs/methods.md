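# Methods

This note documents the models, statistics, parameter choices and known
limitations of the package. It is the design record; empirical claims below
are limited to what the test suite and `scripts/acceptance.py` actually
compute.

## Sequence model and scoring

DNA is handled over the fixed alphabet order (A, C, G, T). A motif is a
position probability matrix (PPM) of length L ≥ 4 whose columns sum to 1;
scoring uses the log-odds matrix `log2(p[i,b] / bg[b])` in bits against a
mononucleotide (Markov-0) background. The background defaults to uniform
0.25, to the background line of a motif file when present, or to the
strand-pooled mononucleotide frequencies of the input windows (pooling
forces A=T and C=G, as scanning is strand-symmetric; frequencies are floored
at 1e-3 and renormalized so log-odds stay finite on degenerate inputs).
Ambiguous bases (N) score 0 bits everywhere — background-neutral, neither
rewarded nor penalized. Probabilities of exactly zero are rejected at
scoring time with an instruction to apply a pseudocount; count matrices are
converted with `(c + a) / (rowsum + 4a)`, default pseudocount a = 0.1 per
cell — small enough not to distort strong motifs, large enough to avoid
infinite log-odds.

All interval arithmetic is 0-based half-open (narrowPeak's native
convention); the overlap of [x, y) and [y, z) is empty.

## Window extraction and primary anchoring

Peaks are ranked by the narrowPeak −log10 p column (ties broken by (chrom,
start) for reproducibility) and the top 1000 kept by default. Windows of
`width` (default 500 bp) centered on summits are the analysis unit; the
pipeline actually extracts `width + 2*recenter_slack` bp (slack default
100 bp) so that after the window is recentered on the primary-motif match —
which sits near, not at, the summit — the full target width is still
available. Windows whose recentered span would run off the extracted
sequence, or with more than 50% N, are dropped and counted.

The primary match threshold defaults to 60% of the motif's maximum
achievable log-odds. No threshold for this step is stated in the protocol
the pipeline follows; 60% of maximum is a common operating point for PWM
scanning that keeps one-mismatch sites of a 7-mer consensus while rejecting
background, and it is exposed in the config and echoed in the run manifest.
Score ties are broken by smallest offset, then + strand, making every scan
deterministic.

Recentering places the primary footprint at offset `(out_width - w) // 2`
(centered, rounding toward the lower offset) and reverse-complements the
sequence for minus-strand matches, so the primary always reads 5'→3' at the
window center. A consequence verified by tests: composite elements on the
reference minus strand yield identical (quadrant, gap) observations after
reorientation, while a primary-only strand flip mirrors both quadrant axes
(same-down ↔ opp-up).

## De novo discovery (ZOOPS EM)

Seeding: k-mers are counted on the forward strands with a k-mer and its
reverse complement collapsed into one candidate, and ranked by the Poisson
z-score of the observed pair count against its Markov-0 expectation. The
Poisson variance approximation is known to understate the variance of
self-overlapping words (their occurrences clump), so the z-scores are a
ranking heuristic, not calibrated p-values; the null-calibration test
asserts normal-bound behavior only for non-self-overlapping words. Seeds
become PPMs with 0.7 on the seed base and 0.1 elsewhere, padded with
background columns when the model width exceeds k.

EM fits the ZOOPS model: each window is background with probability 1−λ, or
background plus a single motif site at one of the 2·(W−w+1) offset×strand
placements (uniform prior over placements). Both strands live in the
placement space, keeping the at-most-one-site semantics exact. The M-step
uses a Dirichlet pseudocount (0.01 per cell) on the PPM and the MLE update
for λ. Because of the prior, the quantity EM maximizes — and the quantity
asserted non-decreasing at 1e-9 slack on every iteration — is the penalized
objective `loglik + 0.01·Σ log θ` (MAP-EM); the unpenalized data
log-likelihood is reported separately. Convergence: objective improvement
< 1e-4 or 200 iterations.

Model selection across widths and seeds maximizes
`(loglik − loglik_bg) − w · log(total scanned positions)` — a BIC-style
penalized log-likelihood ratio that plays the ordering role a discovery
E-value plays in standard motif tools (cloning any specific tool's E-value
is out of scope). A run in which no model scores above 0 raises "no primary
motif found" and the pipeline stops, which is the correct outcome on
background-only input (verified on null simulations). Discovery is fully
deterministic given (windows, widths, n_seeds, rng_seed).

## Spacing observations and the binomial test

For each secondary motif, each primary-centered window contributes at most
one observation: the best-scoring placement over both strands among those
that do not overlap the primary footprint and whose edge-to-edge gap is
≤ max_gap (default 150 bp, the largest gap that comfortably fits the flanks
of a 500 bp window; configurable). Spacing is edge-to-edge — gap 0 means
the footprints are adjacent, matching the natural reading of classic
composite elements with "0 bp" spacing. The secondary score floor is 0 bits
(better than background), i.e. best-match-wins; one observation per window
keeps the binomial trial count equal to the number of windows.

Observations are binned at 1 bp into B = 4·(max_gap+1) (quadrant, gap)
bins. The most occupied bin (ties → smaller gap, then quadrant order
same-down, same-up, opp-down, opp-up) is tested with the upper binomial
tail P(X ≥ k), X ~ Binomial(n, 1/B), Bonferroni-adjusted by B. The uniform
1/B null is the plain reading of "adjusted for the number of bins tested";
each bin corresponds to exactly one placement offset per strand/side, so
placement-uniformity and bin-uniformity coincide up to edge effects. The
smallest-offset tie-break induces a mild upstream excess in the null
best-placement distribution; measured over null replicates this stays well
inside the Bonferroni slack (the family-wise false-positive rate over a
4-motif database is ~4% at α = 0.01, see `null_false_positive_rate` in the
acceptance output). Dual optima (e.g. the 0 and 4 bp bins of an AP1-IRF
element) are preserved in the per-pair report, which lists every bin
individually passing p_adj < α.

E-values scale p_adj by the number of motifs in the secondary database
(uncapped, so ordering is preserved; the convention is recorded in the run
manifest since upstream tools differ on whether bins, motifs, or both enter
the scaling). The interaction matrix stores per-(library, motif) E-values;
the significance filter is E < 1e-10 and the heatmap shows −log10(E) with
primaries on x and secondaries on y.

Redundant secondaries are grouped by single-linkage clustering on PWM
similarity: the maximum over ungapped offsets and both orientations of the
mean column-wise Pearson correlation across ≥ 5 overlapping columns,
linking at ≥ 0.8. These values were chosen so same-family constructions
(shared-core ETS-like motifs) merge while unrelated consensi do not, and
both are configurable. Cluster tags in the motif file, when present on both
motifs, override similarity. Each cluster is represented by its member with
the smallest p_adj; clusters are ranked by that value.

## Synthetic data

The generator emulates what the pipeline consumes: summit-centered windows
over a Markov-0 background of configurable GC (default 0.41, human-like),
with a planted primary site near the window center and, in a configurable
fraction of windows, a planted secondary at an exact gap and quadrant
relative to it. Realism knobs and defaults:

- `summit_jitter_sd` (10 bp, clamped at ±3 sd): offset between summit and
  primary-site center, so recentering on the match — not the summit — is
  actually exercised.
- `mutation_rate` (0.1 per base on planted consensus sites): forces PWM
  scoring rather than string matching.
- `primary_fraction` (1.0) and `planted_fraction` (0.5): per-window
  occurrence probabilities of the primary and (conditional on it) the
  secondary.
- whole windows flip to the minus strand with probability 1/2, so
  reorientation is exercised; the planted quadrant is frame-invariant.
- The canonical demo fixture is AICE-style: primary TGACTCA, secondary
  TGAAAC (the IRF half-site core; a bare 4-mer GAAA is unrecoverable under
  best-match-per-window scanning because ~5 chance exact matches occur per
  300 bp of flank), gaps {0, 4}.

`make_fixture` writes a complete file set — one synthetic chromosome
concatenating the windows with 300 bp background pads, narrowPeak with
summits at window centers, MEME motif files (secondary plus column-shuffled
decoys), and a truth JSON — byte-reproducible from (spec, rng_seed) and
verified self-consistent by direct string inspection in tests.

What the generator does not emulate: higher-order sequence composition
(repeats, CpG islands), peak-strength-dependent site quality, multiple
sites per window, cofactor motifs beyond the one planted secondary, and
mapping artifacts. Passing recovery tests therefore demonstrates
correctness of the machinery and calibration under the stated model, not
performance on real chromatin.

## Problem sizes in the standard runs

The shipped study conditions are 200–400 windows of 200–500 bp, 20-seed
recovery panels, and 200 null replicates; the full-pipeline demo uses 300
peaks with single-width de novo discovery. These sizes give the recovery
and calibration statistics quoted by the acceptance script while keeping
any single run in the tens of seconds on one core; all are parameters, and
scale linearly in windows × width.

## Known limitations

- The binomial null ignores residual non-uniformity of best-placement
  positions (score ties, flank edge effects); Bonferroni conservativeness
  absorbs this in practice but the test is not exact.
- One observation per window discards secondary occupancy beyond the best
  placement; dense homotypic clusters are under-counted.
- Discovery fits a single motif; multi-motif peak sets resolve to the
  strongest, and the reported spacing is measured from the discovered
  footprint (a wider or reverse-oriented discovered motif shifts or mirrors
  the gap relative to the biological site, as the worked example notes).
- PWM similarity clustering is ungapped and correlation-based; motifs
  related through small indels will not merge without cluster tags.
- E-value calibration across databases of very different sizes is nominal
  (linear scaling), not empirical.
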