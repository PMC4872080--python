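# ptrmap

Joint analysis of RNA-binding protein (RBP) and microRNA regulation on
3'UTRs: binding-site mapping, structural context, co-occurrence testing,
knockdown effect analyses and stability prediction — with a synthetic-data
generator that makes every stage testable against known ground truth.

## The problem

Post-transcriptional regulation is set by trans-factors — RBPs and miRNAs —
binding short cis-elements in 3'UTRs.  Most analyses treat one factor at a
time, but factors compete for overlapping sites and cooperate through
proximal or structurally coupled sites.  `ptrmap` is for computational
biologists who want to ask, on a compendium of 3'UTR sites: which sites are
functional (in vivo support, conservation, accessibility)?  Which factor
pairs co-localize more than chance?  Does competition blunt, and
cooperation amplify, the expression response to a knockdown?  How well do
site counts and sequence composition predict mRNA stability?

## What it computes

* **Site mapping** — exact-match scanning of PFM-derived top-10 k-mers,
  IUPAC consensus strings, or explicit k-mer sets on 3'UTRs; annotation
  with CLIP/gPAR-CLIP peak support (after background subtraction), peak
  rank percentiles, mean PhastCons-style conservation, and per-source
  miRNA prediction flags; homotypic clusters collapse to the most upstream
  site.
* **Structure** — a Boltzmann-weighted Nussinov folding backend (exact
  inside–outside unpaired probabilities, stochastic structure sampling;
  external folders pluggable) behind windowed accessibility profiles
  (W = 200 nt, pair span L <= 150 nt, flank included).  Stem-loop
  cooperation candidates are screened by ungapped reverse complementarity
  (>= 5 bp, GU wobble counted), scored by the mean inter-site base-pair
  count over 1000 sampled structures per window, and selected greedily at
  threshold 0.1 so each site joins at most one pair.
* **Co-occurrence** — counts of partner sites in eight 50-nt windows
  within 200 nt of each anchor site, compared against 1000 shuffles of
  factor identities stratified by chromosome, AU content and relative UTR
  position; add-one empirical p-values, BH q-values, and interaction calls
  requiring q < 0.01 under all three schemes in some window.
* **Effects** — CLIP / competition / cooperation / stem-loop transcript
  groupings compared on knockdown log fold changes with one-tailed
  Mann–Whitney U tests (exact at small n), plus residualization on 3'UTR
  length and expression and covariate-matched resampling.
* **Stability** — ridge (L2) logistic regression classifying top-500 vs
  bottom-500 transcripts by half-life or abundance from 16 dinucleotide
  counts + miRNA/activator/repressor site counts, 10x10-fold CV with
  inner-CV penalty selection, interpolated ROC averaging, and Wilcoxon
  signed-rank model comparison.
* **Synthetic data** — planted motif instances, CLIP coverage,
  conservation elevation, co-localized and stem-loop partner sites,
  knockdown LFC effects with competition attenuation and confounding, and
  half-lives from group counts + dinucleotide composition, all with a
  ground-truth record.

See `docs/methods.md` for models, parameters and design choices.

## Worked example

Generate a 300-transcript dataset with a planted co-localized pair
(partner sites of FACB within 50 nt downstream of FACA sites), then run
the co-occurrence test and a CLIP-group knockdown contrast:

```python
from ptrmap.config import RunConfig
from ptrmap.synth import SynthConfig, generate_dataset, ColocSpec
from ptrmap.sites import annotate_clip, collapse_homotypic
from ptrmap.cooccurrence import cooccurrence_analysis, interacting_pairs
from ptrmap.effects import classify_clip_groups, compare_groups, group_lfc_frame

cfg = SynthConfig(n_transcripts=300, seed=1,
                  coloc_pairs=[ColocSpec("FACA", "FACB", max_gap=50,
                                         prob_per_site=0.4)])
ds = generate_dataset(cfg)
sites = annotate_clip(ds.sites, ds.clip_peaks, "clip")

res = cooccurrence_analysis(collapse_homotypic(sites), ds.transcripts,
                            RunConfig(seed=1))
print(interacting_pairs(res))
# [('FACA', 'FACB'), ('FACB', 'FACA'), ('FACD', 'FACA')]

frame = group_lfc_frame(classify_clip_groups(ds.transcripts,
                        [s for s in sites if s.factor_id == "FACA"]),
                        {t.id: t.lfc for t in ds.transcripts})
r = compare_groups(frame, "CLIP", "other", "less")
print(f"CLIP vs other: U={r.statistic:.0f}, p={r.p:.2e} (n={r.n_x}/{r.n_y})")
# CLIP vs other: U=2703, p=4.70e-07 (n=212/47)
```

The planted pair is recovered in both anchor directions: the
first-downstream window holds 333 observed FACB sites against ~109
expected under shuffling (enrichment 3.0, q = 0.008 < 0.01 in all three
schemes).  `('FACD', 'FACA')` is also real structure: the default config
plants competitor sites overlapping FACA sites (competition), which is
itself co-localization; set `overlap_prob=0` for a clean null.  The CLIP
contrast recovers the planted ordering — median LFC −0.85 (CLIP) < −0.48
(other) < −0.05 (no site) under the default stabilizer-knockdown effects.

A CLI mirrors the library for shell use (`ptrmap --help`; subcommands
`synth`, `map-sites`, `accessibility`, `stem-pairs`, `cooccur`, `effects`,
`stability`), writing TSV/BED outputs and a provenance log per stage.

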