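# Methods

This note documents the models, defaults and numerical choices behind
`xescape`, and what the synthetic data do and do not establish.

## Coordinate and data conventions

All internal coordinates are 0-based, half-open; 1-based single-base
inputs (methylation probes, het sites) are converted on read. Only the
5′ end of a TSS is strand-aware; every window (±50 bp probe assignment,
±500 bp peak/motif flanks, ±5 kb depth profiles) is symmetric around
that point with inclusive boundaries. Strand "." is allowed for probes
and peaks; TSSs carry a strand. Every stochastic operation takes an
explicit seed.

## Sex classifier

A Random Forest (500 trees, √p features per split, bootstrap) over
X-non-PAR TSS expression. Out-of-bag (OOB) votes give the error rate and
balanced accuracy (mean per-class recall; undefined and an error when a
true class is empty). Outliers are samples whose *strict* OOB majority
vote disagrees with their label — ties are not outliers, since no margin
threshold is defensible without one being stated; they are reported
sorted by vote margin. The proximity of two samples is the fraction of
trees in which they share a terminal node, restricted to trees where
both are out of bag (falling back to all trees for pairs never jointly
OOB). The embedding is classical (Torgerson) MDS of `1 − proximity`:
double-centred squared dissimilarities, eigendecomposition, coordinates
scaled by √eigenvalue — chosen over stress-based MDS because it is
deterministic and exact for Euclidean inputs.

## Escapee-TSS calling

Expression is transformed as `y = log10(TPM + 5)`; the +5 pseudo-count
keeps zeros finite and compresses noise at very low TPM. Cell-category
structure is summarized by PCA of the binary sample × category
membership matrix — centred, unscaled by default (a `scale` switch
exists); the number of components is the smallest k whose cumulative
explained variance strictly exceeds the threshold (default 0.90), capped
at the matrix rank. Per TSS, ordinary least squares of `y` on
`[1, PC scores, sex]` with sex coded male = 1 / female = 0, so a
negative coefficient means higher female expression; the p-value is the
two-sided t test of that coefficient. The implementation solves the
normal equations once for the shared design and sweeps all TSSs
vectorized; tests pin it to an explicit normal-equation oracle at 1e-8.

Repeat-overlapping TSSs are removed *before* correction; Bonferroni uses
the retained X-non-PAR count. escTSS: corrected `p ≤ α` (boundary
inclusive) and negative coefficient; positive-coefficient significant
TSSs are male-biased; everything else is nonDT, and the subset with
corrected p exactly 1 forms the conservative nonDT background pool.

The benchmark truth rule: a gene is a true escapee when reported by at
least two of the four lists, counting the predicted list itself as one
approach — the only reading under which the canonical worked example
(31 predicted, 27 captured by ≥1 published list, 9 missed true genes)
yields precision 27/31 → 0.87 and recall 27/36 = 0.75. Reported values
are rounded half-up to 2 decimals; full precision is kept internally.

## Methylation similarity

`β = Meth/(Meth + Unmeth + 100)` (offset 100, the array default).
Per-sex probe means use all non-missing samples. `M = log2(β_m/β_f)`,
`A = log2((β_m + β_f)/2)`, both base 2; probes with a zero mean in
either sex are excluded rather than epsilon-padded, since the log is
undefined and the intensity offset makes exact zeros rare. The chrX fit
`M = d0 + d1·A` uses iteratively reweighted least squares with Tukey's
bisquare weights `w(u) = (1−u²)²·1{|u|<1}` at c = 4.685 (95% Gaussian
efficiency), scale re-estimated each iteration as `median(|r|)/0.6745`,
OLS initialization, convergence on parameter change < 1e-8 within 50
iterations (non-convergence returns the last iterate flagged). Gross
outliers get weight exactly 0. The per-probe residual is the similarity
score; statsmodels' RLM with the same norm serves as an independent
oracle in tests (agreement ≤ 1e-6), never as the implementation.

Probes within ±50 bp (inclusive) of a TSS 5′ end are averaged per TSS.
The escapee-vs-nonDT comparison is a one-sided rank-sum test (escapees
hypothesized higher), exact when untied. The autosomal test is a nested
OLS F test — reduced `β ~ 1 + age + stage`, full adds sex;
`F = (RSS_r − RSS_f) / (RSS_f/(n − p_f))` — Bonferroni over the
autosomal probes tested.

## Motif and peak over-representation

PFMs are regularized with pseudocount 0.8 spread by background
frequencies; information content is `Σ_j (2 + Σ_b p log2 p)` bits and
motifs below 8 bits are filtered. Scanning scores log2 odds on both
strands at every offset, N contributing zero; a hit requires relative
score `(s − s_min)/(s_max − s_min) ≥ 0.85`. Enrichment counts regions
with ≥1 hit (region-level, robust to merged-region length) in a
one-tailed Fisher exact test; the Fisher score is −ln p. GC/length
matching draws n (default 10) pool regions per target within ±0.05 GC
and ±10% length, without replacement. Top motifs are those strictly
above the 95th percentile of Fisher scores per background; percentile 0
returns all motifs.

Peak testing uses one TSS per escapee gene (smallest raw p, ties by
larger |coefficient| then tss_id). Backgrounds match the targets' 5-bin
expression-percentile distribution with largest-remainder quotas that
sum exactly to n (at full scale: 300 chrX / 3,000 autosomal); the chrX
pool additionally requires Bonferroni p = 1. A TSS "has a peak" when any
peak interval lies within ±500 bp of its 5′ point, inclusive. Bonferroni
runs across the datasets tested in the run. Non-finite log2
percent-overlap ratios are dropped (count logged) before the one-sample
signed-rank tests vs 0 (alternative: greater) and the one-sided
female > male rank-sum test. Depth ratios compare mean coverage within
±50 bp of the TSSs, windows clipped at contig ends.

## Allelic imbalance

Het sites become IUPAC degenerate codes in the personalized genome
(G/A → R etc.), so neither allele pays a mismatch. Mapability: every
36-bp window covering a het inside the merged peaks+100 bp regions is
instantiated for both alleles and strands (≤ 144 reads per interior
site) and mapped exactly against the degenerate genome (a read base
matches a symbol containing it; reads containing N are unmapped; unique
= exactly one match over both strands). Sites are kept when either
allele's unique-read fraction lies in [0.4, 0.6] inclusive — the two
readings coincide by complementarity. Phased counts assign the
Xi-parent allele (paternal by default, as in GM12878) to Ri; replicates
merge by (factor, lab) summing Ra/Ri.

Each (site, dataset) pair with Ra > 0 and Ri > 0 is tested with a
two-sided Fisher exact test on `[Ra, Ri; ΣRa−Ra, ΣRi−Ri]` — two-sided
because deviations both toward Xi (the headline class) and toward
extra-strong Xa are of interest against the Xa-biased norm — with BH
FDR across all tested pairs. The log2 odds ratio adds Haldane's 0.5 to
all four cells (never to the p-value) so zero-cell sites keep a defined
direction; positive means Xa-biased. Site summaries count sites
significant in >1 dataset and classify direction by the sign of the
log2 odds among significant pairs (all negative = Xi, all positive =
Xa, else mixed).

## Synthetic data: what it emulates, and what passing tests show

`generate_cohort` (defaults: 100 female / 100 male samples, 500 chrX +
200 autosomal TSSs, 20 escapees at 2× female fold, an XIST-like
female-only TSS, 10 overlapping cell categories with Gaussian per-TSS
effects of SD 0.3, log10 noise SD 0.2, 10% repeat flags). Per-sample
log10 TPM is baseline + category effects + sex effect + noise,
back-transformed; the model is exactly the caller's regression, so
recovery tests validate inference, not model robustness. The 2× escapee
fold encodes bi-allelic transcription; no per-gene Xi output
distribution is asserted because none is established, and the fold is
configurable. Repeat flags are drawn outside the escapee/XIST classes so
planted escapees lie in the retained testing universe. A
`xist_silenced_female_frac` option zeroes the XIST-like TSS in a female
subset, emulating cancer lines that lose the Xi; a
`category_sex_bias` option skews category membership by sex to create
the confounding that the PC covariates must absorb.

`generate_methylation` (defaults: 60/60 samples; chrX panel of 600
subject-promoter probes at male 0.05 / female 0.4, 100 escapee-promoter
probes at 0.05/0.05, 1,800 "body" background probes, one XIST-like
probe; 600 autosomal probes, 15 sex-differential; Beta noise at
concentration 50). The body class implements the chromosome-wide
inversion — Xi hypermethylated where Xa is unmethylated and
hypomethylated where Xa is methylated, the female beta averaging the two
copies — which is what produces the positive chrX M–A trend the robust
regression fits; escapee promoters then deviate above it. The
composition (escapee probes ≈ 4% of chrX) mirrors the array reality that
escapee-promoter probes are a small minority; with escapees as a large
fraction the trend correlation is not identifiable, which is a property
of the statistic, not of the implementation. Autosomal probes carry
small additive age/stage effects on the logit scale for the F test.

`generate_toy_genome` (6 kb, 8 phased hets, one 400 bp exact
duplication with one het inside) is sized so the exhaustive mapper runs
in seconds; the duplicated het fails the balance filter because only its
non-reference allele maps uniquely.

`simulate_allelic_counts` (defaults: 200 sites over 8 datasets,
negative-binomial totals of mean 60 and dispersion 5, 80% Xa-biased
sites at allele fraction 0.8, designated Xi sites at 0.97 toward Xi,
remainder balanced). The imbalance test's null is "site fraction equals
the dataset-wide norm"; with the default three-class mixture the pooled
norm (~0.74) lies between the classes, so *every* class genuinely
deviates and a class-label FDR would count real conditional deviations
as errors. FDR calibration therefore uses the clean recovery design —
5 designated Xi sites among 200 Xa-norm sites (`frac_xa_biased = 1.0`)
— where the Xa class is the null; observed pooled false-discovery
proportion over 20 seeds is ~8–10% at the 5% BH level, reflecting the
slight norm shift the Xi sites themselves induce. Replicate concordance
uses 65 sites + 2 designated Xi loci across two datasets sharing true
fractions, matching the scale at which per-site binomial noise still
permits r ≈ 0.85–0.9.

Problem sizes throughout (200-sample cohorts, ~2,500-probe panels,
6 kb genomes, 20-seed recovery loops) are chosen so the full suite and
the acceptance script each complete in about a minute while keeping
every statistical property measurably powered.

## Known limitations

Generated data are exchangeable draws from the stage models: passing
recovery tests demonstrates correct inference under those models, not
robustness to batch structure, probe cross-reactivity, mapping bias
beyond exact duplication, or TF-specific allele affinity (explicitly
unmodeled). Real-data preprocessing (RLE normalization, idat processing,
aligner behaviour) is upstream and out of scope; depth tracks are
ingested as text, not bigwig/BAM. Cohort-scale counts from FANTOM5/
TCGA/ENCODE-sized inputs are not reproducible at these problem sizes and
are not asserted anywhere.
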