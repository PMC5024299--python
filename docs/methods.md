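# Methods

## Template model

Each library molecule is modelled as five fixed-order segments: adapter A
with the sequencing key at its 3' end (default 30 nt, the Ion Torrent A/key
sequence), a library barcode (default 6 nt), a random insert (default
12 nt), and the trP1 adapter (default 23 nt), for a 71-nt total. Only the
total length and segment order are constrained by the assay; the default
adapter sequences are the standard Ion Torrent ones and the barcode length
is a free design choice made to complete the 71-nt arithmetic. All segments
are configurable.

## Read filtering

Filters run in a fixed order — barcode, then `N`, then total length — and
each read is charged to the first filter it fails, so category counts always
partition the input and are reproducible run to run. The barcode is matched
at its fixed template position (immediately after adapter A); exact matching
is the default because the assay gives no mismatch tolerance, with an
optional `--barcode-mismatches` allowance for degraded data. With several
barcodes and a mismatch allowance a read can match more than one barcode;
such reads are counted as ambiguous and excluded everywhere. Quality
strings are parsed but never filtered on. Structurally corrupt FASTQ is a
hard error (the parser cannot realign mid-file); a structurally valid
record whose insert contains a non-`N` ambiguity code is counted in
`n_malformed` rather than silently dropped.

## k-mer scores

Counts are taken over every overlapping window of the insert on the forward
strand only; adapters and barcode never enter. For cycle *i*,
`f_i = count / total_windows`; `r_i = f_i / f_{i−1}`; `r_i0 = f_i / f_0`.
Ranks order k-mers by descending frequency with lexicographic tie-breaking,
so a rank table is always a permutation of 1..4^k.

**Zero denominators.** A k-mer unobserved in the denominator round gets a
single pseudocount there (count 1 over that round's window total), keeping
every ratio finite while leaving well-covered k-mers' ratios untouched;
affected k-mers are flagged in the score table.

**Markov background.** For k = 10 the 4^10 word space is undersampled at
round 0, so `f_0` is replaced by an order-5 Markov estimate: the
probability of a word is the probability of its first 5 bases (pseudocounted
window frequencies) times the product of conditional next-base
probabilities given the preceding 5 bases. Both tables are normalized, so
the estimates of all length-L words sum to 1 for any L > 5 by telescoping
(verified to 1e-6). The per-cell pseudocount defaults to 1. Words that
reuse one context repeatedly (homopolymers) raise the same estimated
conditional to a power, so their estimation error compounds relative to
typical words — visible in the uniform-corpus test tolerances.

**8-mer aggregation.** For comparison with double-stranded platforms, each
8-mer is identified with its reverse complement (32 896 classes; palindromes
are singletons). A class score is the read-count-weighted mean score of
every retained insert containing either orientation; an insert contributes
once per class it contains regardless of window multiplicity. Unweighted
(unique-insert) averaging is available behind a flag; read-weighted is the
default because retained read counts are the only abundance information the
data carries. Strand collapsing happens only here — f/r/r0 stay
strand-specific, since the counting convention upstream is single-stranded.

## Library-uniformity score

The QC score is the KL divergence of observed k-mer frequencies from the
uniform distribution, in bits, divided by k:
`(1/k) · Σ_w f(w) · log2(f(w) · 4^k)`, with `0·log 0 = 0`. The per-position
normalization pins the range to [0, 2]: 0 for a perfectly uniform library
and 2 for a point mass (un-normalized KL against uniform maxes at 2k bits).
The un-normalized variant is available via `per_position=False`. Inputs
must sum to 1 within 1e-9; tiny negative totals from floating-point
cancellation on near-uniform inputs are clamped to 0.

## PWM construction

The seed is the top-frequency k-mer of the last cycle (ties lexicographic).
Every k-mer at Hamming distance ≤ 1 from the seed with a nonzero count is
aligned ungapped in the seed frame; per-column base counts are accumulated
(count-weighted by default, presence/absence behind a flag) and normalized
to probabilities. At most 1 + 3k words contribute. Forward strand only, to
match the counting convention; for a reverse-complement-palindromic seed
with strand-symmetric counts the resulting PWM is itself
reverse-complement-palindromic. An empty neighbourhood raises an explicit
error rather than returning a degenerate matrix. Output formats: MEME
minimal and tabular TSV; logo rendering is out of scope.

## Comparison statistics

Pearson correlation is computed on score vectors joined over common
reverse-complement classes; tables listing both orientations contribute the
orientation mean. ΔΔG values (kcal/mol, relative to the consensus site)
map to binding probabilities as `p = 1/(1 + exp(ΔΔG · 0.592))`, exactly the
printed form of the transform; since 0.592 kcal/mol is RT at 298 K, the
dimensionally conventional variant `exp(ΔΔG / 0.592)` is provided behind
`mode="divide"` in case the printed form is a transcription slip — the
default follows the printed form. Two correlations sharing a variable are
compared with the Hotelling–Williams t-test on n − 3 degrees of freedom;
the implementation rejects non-positive-definite correlation triples.

## Simulator: the stated world and its limits

Round 0 draws insert bases i.i.d. from a composition vector, by default
mildly skewed (A/G 0.27, C/T 0.23) so the simulated library has a small
nonzero divergence like real syntheses. A selection round resamples reads
multinomially with probability ∝ frequency × affinity, collapsing capture,
PCR and sequencing into one sampling step — there is no PCR bias, no
sequencing error, and no oligo-specific synthesis artifact in this world,
so a green simulation test establishes algorithmic correctness, not
robustness to those real-data effects. The affinity model
`a(w) = λ^(−mismatches)`, best window per oligo, with λ = 5 and consensus
CACGTG as defaults, reproduces the qualitative enrichment course of real
runs: the consensus rises from mid-rank in the unselected pool to rank 1 by
round 2 and dominates the pool thereafter.

One intrinsic artifact of window-based counting does appear, as it does in
real enrichment data: single-base *shifts* of the consensus co-occur on
consensus-bearing inserts and acquire large cycle-ratios without own
affinity ("hitchhiking"). Consequently the linear correlation between
planted window affinity and r_2 over all 6-mers is low (~0.13), while
within the consensus's mutational neighbourhood — where no shifted words
intrude, and which is the regime low-affinity validation experiments
actually probe — it is high (~0.8). The low-affinity comparison test
therefore evaluates correlations over Hamming-distance ≤ 2 mutants of the
consensus, and emulates a stringently washed readout by clipping away the
low-affinity gradation of the score.

## Numerical and reproducibility choices

- 2-bit base encoding; a k-mer's code is its big-endian base-4 integer, so
  lexicographic string order equals numeric code order and dense arrays of
  length 4^k index every word.
- Counting is vectorized (sliding windows → codes → bincount) and verified
  against a naive sliding-window scan for k ∈ {1, 6, 8, 10, 12}.
- All randomness flows through `numpy.random.default_rng`; multi-round
  simulations derive per-round seeds from one `SeedSequence`, and identical
  seeds give byte-identical FASTQ and score tables.
- Pipeline outputs carry no timestamps; the manifest lists files per stage,
  and any stage failure aborts with the stage name and offending input.
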