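# Methods

`ptrmap` analyses post-transcriptional regulation (PTR) of mRNAs through the
joint action of RNA-binding proteins (RBPs) and microRNAs on 3'UTRs.  This
note documents the models and procedures each module implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Site mapping

A factor's binding preference is one or more of: a position frequency
matrix (PFM, k columns of A/C/G/U probabilities, 4 <= k <= 12), an IUPAC
consensus, or an explicit k-mer set.  PFMs are scanned through their top-10
most probable k-mers (product of column probabilities; probability ties
broken lexicographically so the scan is deterministic), which represents
motifs longer than the k-mers a binding assay measures directly.  Matching
is exact — no mismatches — and overlapping matches are all reported.  When
a factor owns several motif records their k-mer sets are pooled under one
factor id before scanning.

Sites are annotated with:

* **CLIP / gPAR-CLIP support** — overlap of >= 1 nt with a peak, after
  background regions have been subtracted from the peaks (peaks may split
  into fragments, which inherit the parent peak's rank percentile).  "In a
  peak" is deliberately the permissive >= 1 nt reading rather than full
  containment: background subtraction fragments peaks, so containment would
  drop genuinely supported sites.  The site's `clip_percentile` is the best
  (numerically smallest) percentile among overlapping peaks.
* **Conservation** — the arithmetic mean of per-base conservation scores
  (PhastCons-style, in [0, 1]) across the matched positions.  A missing
  track leaves the field unset, never zero.
* **miRNA prediction sources** — overlapping same-miRNA sites from
  different target predictors merge into one site spanning their union and
  carry one flag per source.  Database-validated interactions are pair
  level (miRNA x transcript) because such databases do not give positions;
  the flag is set on every site of that miRNA on that transcript.
  Ago-CLIP support again requires >= 1 nt peak overlap.

**Homotypic collapse.**  U-rich regions produce runs of overlapping
same-factor matches that would inflate co-occurrence counts.  Within each
(transcript, factor), sites are grouped by transitive overlap and only the
most upstream member of each group is kept.  The co-occurrence module
requires collapsed input.

## Secondary structure

The built-in folding engine is a Boltzmann-weighted Nussinov model over
nested structures: legal pairs are Watson-Crick plus GU wobble, every pair
contributes one stability unit, a structure with p pairs has weight
exp(p / T) (temperature weight T = 1 by default), and hairpin loops
enclose at least three unpaired bases.  Inside-outside dynamic programming
gives the exact partition function and per-base pair probabilities;
structures are drawn by stochastic traceback.  The model is intentionally
small — it is exactly verifiable against exhaustive enumeration on short
sequences — while behaving like a thermodynamic ensemble.  Full
nearest-neighbour (Turner) energies, pseudoknots and co-transcriptional
effects are out of scope; outputs of external engines (per-base unpaired
probabilities, dot-bracket structure samples) can be imported through the
`FoldBackend` adapters instead.

**Accessibility** of a site is the mean probability of being unpaired over
its bases.  Folding runs on the 3'UTR concatenated with its upstream
coding flank (target 200 nt) because flanking sequence alters local
structure.  Local folding uses windows of length W = 200 with base-pair
span <= L = 150 (the window/span combination reported to work best for
local accessibility); each base's value is the average over all length-W
windows containing it.  The per-window partition function is O(W^3), so
genome-scale profiles call for an external engine via the adapter; the
built-in backend is intended for desk-scale analyses and verification.  A
`window_step` parameter (default 1 = every window) strides the window
starts for long sequences, trading boundary resolution for speed; the
last window is always included so every base is covered.

**Stem-loop cooperation.**  Candidate cooperating site pairs are first
screened by ungapped reverse complementarity: the maximum number of legal
pairs (GU wobble included, consistent with the folding model) over all
antiparallel registers must be >= 5.  Each surviving pair is scored by the
average number of base pairs formed between the two sites across sampled
structures: for every length-W window containing both sites (for an
unclipped pair there are W - span + 1 such windows; windows truncated by
sequence boundaries are dropped), 1000 structures are sampled and the
inter-site pair count averaged, then averaged over windows.  The score is
an estimate of the Boltzmann-expected inter-site pair count; it is kept on
that raw scale (it can exceed 1) and the selection threshold 0.1 applies
to it directly — no normalisation is applied because none is defined for
the procedure.  Pairs scoring >= 0.1 are sorted (score descending, then
pair-count descending, then leftmost) and accepted greedily so that no
site joins two pairs; the selected set is a matching and is invariant to
input order.

## Co-occurrence permutation test

For an anchor factor, partner sites are counted in eight 50-nt windows:
four upstream of the anchor site start (offsets [-200,-150) ... [-50,0))
and four downstream of the anchor end ([0,50) ... [150,200)).  A partner
site is assigned by its start position; partners starting inside the
anchor body are uncounted (body overlap is the competition module's
concern, and counting it here would double-book the same geometry).

The null model shuffles factor identities with site positions fixed, 1000
times, under three stratifications: (i) within chromosomes; (ii) within
AU-content classes of the matched k-mer (counts of A/U bases: <3, 3-5,
>=6); (iii) within deciles of relative site position along the UTR
(floor(10 * midpoint / length), capped at 9).  Because positions never
move, the window geometry of every ordered site pair is precomputed once
and each permutation only relabels; counts come from a single bincount
pass, which keeps 3 x 1000 permutations on thousands of sites in seconds.
Per-stratum factor multisets are conserved by construction; a stratum with
one site permutes trivially (logged).

The empirical p-value is the add-one enrichment estimator
p = (1 + #{null >= observed}) / (1 + n), bounded below by 1/(n+1), which a
Benjamini-Hochberg step-up then converts to q-values (Storey's pi0 at
lambda = 0.5 is available behind a switch).  **BH scope:** q-values are
adjusted per (anchor, partner) across its eight windows, separately per
scheme.  With 1000 permutations the smallest achievable p is ~0.001; a
table-wide adjustment over all pairs x windows could therefore never reach
q < 0.01 for any single pair, making the protocol's calling rule ("at least
one window with q < 0.01 from all of the three permutation tests")
unattainable by construction.  The per-pair scope is the only reading
consistent with that rule at this permutation depth.  A pair is called
interacting when some window reaches q < 0.01 under all three schemes.
Only enrichment is tested; depletion appears in heatmaps as ratios < 1 but
is not significance-called.  The heatmap value is the log of the
min-over-schemes enrichment ratio, observed / mean-null count (0.5
pseudocount on both when the mean null is zero).

Factors with near-identical motifs would co-cluster trivially, so for each
anchor the partners whose motifs exceed 0.8 best-ungapped-offset mean
column Pearson correlation with the anchor's motif (consensus strings are
converted to PFMs with uniform-degenerate columns) are excluded, as are
explicitly listed pairs.

## Knockdown effect analyses

Transcripts are grouped per analysis and compared on log fold change (LFC)
with a one-tailed Mann-Whitney U test (exact by enumeration over rank
assignments when n_x + n_y <= 12, handling ties by midranks; otherwise the
normal approximation with tie and continuity corrections).  The test
direction is a required argument because it encodes factor biology:
knocking down a stabilizer destabilizes its targets (sites-more-negative),
a repressor the opposite.

* **CLIP grouping:** CLIP (>= 1 CLIP-supported site of the factor), other
  (sites but none supported), no_site.  Transcripts carrying sites outside
  the analysed region (e.g. intronic) can be excluded up front via the
  config.
* **Competition grouping:** overlap = sharing >= 1 UTR position with
  another factor's site.  no_competition = at least one CLIP-supported
  site of the factor overlapping nothing; competition = CLIP-supported
  sites present but every site of the factor overlapped; no_site = no
  sites.  Transcripts whose factor sites are all non-CLIP fall outside the
  three-group scheme and are emitted with label `excluded` for
  transparency (the same label covers the rare case where only a non-CLIP
  site escapes overlap).
* **Cooperation grouping:** five groups — None / OnlyA / OnlyB /
  Both_not_stemloop / Both_stemloop, where any selected stem pair on the
  transcript wins — or a two-group distance variant splitting
  both-factor transcripts by the minimal edge-to-edge gap (end of the left
  site to start of the right site) between an A and a B site relative to a
  cutoff (200 nt in the analyses here).  Edge-to-edge is the conservative
  reading of "within d nt"; start-to-start would differ only by site
  widths.

**Covariate adjustment.**  3'UTR length and baseline expression correlate
with LFC and with group membership, so contrasts are re-run on residuals
of OLS: lfc ~ 1 + utr_length + expression (covariates untransformed; the
procedure defines no transformation).  A second guard is covariate-matched
resampling: each repetition bootstrap-resamples the larger group, matches
every member of the smaller group to its nearest neighbour in the resample
on z-scored (length, expression) with random tie-breaking, and tests the
groups' LFCs; the empirical p is the fraction of repetitions that are NOT
significant at alpha = 0.05.  The bootstrap step supplies the sampling
variability that plain nearest-neighbour matching (deterministic up to
ties) would lack.

## Stability model

Transcripts (or fixed-length 3'UTR segments) are ranked by half-life or
abundance; ids without any RBP or miRNA site are removed; the top 500 are
labelled 1 (stable / highly expressed) and the bottom 500 labelled 0.
Features are the 16 overlapping dinucleotide counts plus site counts in
three factor groups — miRNAs, activators (HNRNPL, PABPC1/3/4/5, PABPN1,
RBFOX1, HuR, IGF2BP2/3) and repressors (CUGBP1, MBNL1, HNRNPC, KHSRP,
ZFP36, AUF1, TIA1, PUM1/2).  Variants replace the plain counts with
CLIP-supported-only counts, accessibility sums, or competition-aware
counts where an overlapped site contributes 0.5 instead of 1.

The classifier is L2-regularized (ridge) logistic regression.  Outer
evaluation is stratified 10-fold CV repeated 10 times (100 AUCs); within
each training fold an inner 3-fold CV picks the penalty maximizing
validation AUC from a 50-point log grid over [1e-4, 1e4] on standardized
features (standardization is fit on training folds only, so held-out rows
never leak into scaling or penalty choice).  AUC is the rank-based
U/(n1*n0) statistic; per-fold ROC curves are vertically interpolated onto
a 101-point FPR grid and averaged.  Models are compared by a two-sided
Wilcoxon signed-rank test on the 100 paired AUCs (zero differences
dropped).  A final full-data fit provides the coefficient vector for sign
inspection.  A length-only baseline (the same CV with 3'UTR length as the
single feature) checks that the features do not merely proxy length.

## Synthetic data

The generator emits the exact artefacts the pipeline consumes plus a
ground-truth record.  Defaults aim at realistic human-3'UTR statistics:
log-normal UTR lengths (median 1000 nt, sigma 0.5), AU fraction 0.55,
200-nt flanks, planted motif densities of 1.5-2 sites/kb/factor, CLIP
peaks (site +/- 10 nt, uniform rank percentiles) covering 50% of planted
sites plus decoy peaks on empty regions, and conservation elevated from a
Beta(1,3) baseline to Beta(8,2) at 70% of sites.  Planted instances are
exact k-mer copies (no mutation), non-overlapping within a factor, so
recovery by scanning is deterministic for sites whose sequence was not
later overwritten; the ground truth marks each site's intactness, and
chance background matches are expected and tolerated.  The five-factor
default roster uses 7-mers with mixed (3-5) A/U content so that
AU-stratified shuffling genuinely mixes factor identities.

Knockdown LFCs are drawn as
`base * (attenuation if all factor sites overlapped) + boosts + confounders
+ N(0, sigma)` where base is delta_clip (-1) for transcripts with a
CLIP-covered site of the knocked-down factor, delta_other (-0.5) with only
unsupported sites, and 0 without sites.  delta_other sits between the CLIP
effect and zero because partially supported sites show intermediate
knockdown response; it is what makes the CLIP < other < no-site ordering a
recoverable truth rather than an artefact.  The confounded preset adds
length and expression terms to LFC (a negative length correlation, as
seen in real knockdown array data) to exercise residualization.

Half-lives follow `h = b+*activators - b-*repressors - bm*mirnas +
sum_d g_d * dinuc_d + N(0, sigma_h)` with g_d drawn once per dataset from
N(0, 0.1); the stored half-life is exp(h / sd(h)), positive and
rank-preserving.  The stability experiment uses the `stability_config`
preset: near-fixed 300-nt segments and sigma_h = 3.  Fixed length mirrors
segment-based stability assays and matters statistically: under the
log-normal length default, dinucleotide counts track length so strongly
that the extreme classes become perfectly separable and no model
difference is measurable; at fixed length, composition and site counts
carry the signal and CV AUCs land in the 0.8-0.9 range typical of such
data.

**What passing tests show — and don't.**  Synthetic sequences are i.i.d.
draws: they lack real 3'UTR grammar (repeats, local composition structure,
phylogenetic conservation), sites are exact motif copies rather than
affinity-graded matches, CLIP coverage is independent of accessibility,
and effects are exactly additive with Gaussian noise.  Recovery of planted
structure therefore validates the estimators and their calibration — null
permutation p-values uniform, group contrasts and coefficient signs
recovered, planted co-localization called — not the biological accuracy of
any real-data conclusion.

## Numerical and reproducibility choices

* One global seed; every stochastic stage derives an independent stream
  from (seed, stage-name), so stages can rerun in any order with identical
  output and a whole run is byte-reproducible.
* Problem sizes in the test and acceptance suites: oracle equivalence uses
  <= 12-nt sequences (exhaustive enumeration is exact there); permutation
  calibration uses 5 factors x 200 transcripts x 1000 permutations; effect
  recovery 1500 transcripts; the stability experiment 2000 transcripts
  with the full 10 x 10 CV and a 20-seed sign-recovery sweep.
* Degenerate inputs: rank tests on constant data report p = 1 with a
  degenerate flag; an empty stem-window set scores 0 with a warning;
  conservation means are unset (not 0) without a track; single-site
  permutation strata shuffle trivially.
* Tie-breaks are deterministic: k-mer probability ties lexicographic,
  extreme-labelling boundary ties by id, greedy stem selection by score,
  pair count, then leftmost pair.

## Known limitations

The folding model's -1/pair energy exaggerates pairing of CG-poor regions
relative to a Turner model; accessibility values are comparable within a
run but not across engines.  The O(W^3)-per-window partition function
limits built-in accessibility profiling to desk scale.  The co-occurrence
test treats sites as points (start positions) and ignores site length
variation inside windows.  Competition grouping follows the protocol's
three-group scheme and so sets aside transcripts whose factor sites are
all unsupported.  The stability model's variants (CLIP-only,
accessibility-weighted, penalized) are implemented but their real-data
merit cannot be assessed on synthetic input.
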