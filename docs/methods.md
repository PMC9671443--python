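# Methods

## The estimands

For each gene we compare two closely related *Drosophila* species
(*D. simulans*, "sim", and *D. sechellia*, "sec") and their F1 hybrids in two
immune tissues under two conditions (unchallenged control vs immune
challenge).  On the natural-log scale of expected expression, three contrasts
are formed per condition:

* parental divergence `P` = log mean(sim parent) − log mean(sec parent);
* cis divergence `C` = log mean(sim allele in hybrids) − log mean(sec allele
  in hybrids).  Both hybrid alleles share one cellular (trans) environment,
  so any allelic imbalance is attributable to linked regulatory sequence;
* trans divergence `T = P − C`, the remainder attributable to diffusible
  factors.

A third "response" context is the interaction: each contrast evaluated on
the challenged-minus-control difference.  All fold changes are reported in
log2 units; `T = P − C` holds exactly (it is a linear identity of the fitted
coefficients, and `lfc_trans` is computed as that difference).

## Count model

Allele-specific read counts are modelled as negative binomial with gene-wise
dispersion φ in the mean–dispersion parameterisation `var = μ + φ μ²`
(φ → 0 recovers Poisson).  The design is a one-group-per-condition means
model with eight groups (sim parent, sec parent, hybrid sim allele, hybrid
sec allele × control, challenged) and per-sample offsets
`log(library_size × TMM factor)`.  Because the design matrix is one-hot, the
per-group coefficients solve decoupled one-dimensional score equations,
which we exploit to vectorise Newton fits across all genes simultaneously.

**Offsets for hybrid allele columns.**  The two allele columns of a hybrid
library are modelled as separate samples that share the *physical* library's
total assigned reads as offset, so allele proportions — not depths — drive
the cis estimates.  TMM normalisation factors (trimmed mean of M-values,
30 % log-ratio trim, 5 % abundance trim, inverse asymptotic-variance
weights, reference = sample with most typical upper-quartile CPM, factors
normalised to unit geometric mean) are likewise computed on physical
libraries — hybrid allele pairs summed — and the library's factor is shared
by both of its allele columns.  A shared offset cancels from the
within-library cis contrast.  The alternative, a TMM factor per allele
column, is biased whenever a large fraction of genes carries strong cis
effects: the factor then absorbs part of the allelic signal (on the
mixed-effect generator below the allele-pair factor gap reached ~0.2 log2
and inflated false cis calls several-fold).  Compositional normalisation of
any flavour cannot rescue the degenerate case where *every* gene shifts the
same way — such a shift is indistinguishable from a depth change — which is
why normalisation can be disabled (`normalize=False`) for simulations of
that kind.

**Dispersion.**  Per-gene φ maximises the Cox–Reid adjusted profile
likelihood (APL): the NB profile likelihood at the fitted means, penalised
by half the log-determinant of the observed information, which for the
one-hot design is the sum of log group-wise working-weight sums.  The APL is
evaluated on a 25-point log-spaced grid (10⁻⁴–16) with 3-point parabolic
refinement.  Estimates are shrunk toward an abundance trend: genes are
binned by mean log2 CPM (~20 quantile bins), the trend maximises each bin's
summed APL, and the shrunken estimate maximises
`APL_gene + (prior_df / df_residual) × mean-bin APL` (prior_df = 10 by
default), clipped between the raw and trend values so shrinkage never
overshoots.  Monte-Carlo checks: Poisson data give median φ̂ < 0.01; φ = 0.4
with 20 replicates is recovered within [0.3, 0.5].

**Testing.**  Each contrast `c'β = 0` is tested with a quasi-likelihood
F-test: the model is refit under the constraint (null-space
reparameterisation of the one-hot design; the iteratively reweighted least
squares is batched across genes) and the deviance difference is scaled by a
moderated quasi-likelihood dispersion, `s²_post = (d₀ s²₀ + df s²) /
(d₀ + df)` with `s² = deviance/df`, `s²₀` the mean scale across genes and
prior df `d₀ = 10`.  P-values come from F(1, df + d₀).  Under a global null
(2000 genes, n = 5, φ = 0.1) the p-values of all nine contrast families are
uniform (KS) and FDR < 0.05 call rates are ~0.  Benjamini–Hochberg FDR is
applied per contrast family (per component × context); a single pooled
family across components is a possible alternative but is not used.  Genes with an all-zero group
get a 0.5 pseudo-count for fold-change reporting only.

## Classification

Regulatory categories follow the standard inheritance-mode scheme, applied
to FDR calls at α = 0.05: **cis** (ASE significant, trans not), **trans**
(trans significant, ASE not), **cis + trans** / **cis × trans** (all of ASE,
parental and trans significant; same/opposite signs of C and T),
**compensatory** (ASE and trans significant, parents not diverged),
**conserved** (nothing significant), **ambiguous** (the rest — in practice
genes whose parental divergence crossed the threshold while neither
component did).  An ambiguous gene whose |C| or |T| explains at least half
of |P| is rescued to that component; when both qualify the larger magnitude
wins and an exact tie goes to cis (an arbitrary, documented choice).
`effective_category` folds the rescue in and is what parameter-recovery
checks score against ground truth.

Dominance uses hybrid *total* expression — the sum of the two allele columns
of a physical library, the only construction that yields a hybrid-level
expression from allele-resolved counts — contrasted against each parent in a
six-group means model.  The hybrid "differs" from a parent only if the
contrast is significant (FDR < α) *and* at least 1.25 log2 fold; differing
from both parents upward/downward gives over-/under-dominance, in opposite
directions additive, from one parent only dominance of the other parent,
from neither conserved.

Motif association is a Pearson χ² without continuity correction (configurable)
on 2 × 2 tables of {motif present in both species} × {trans-diverged,
FDR-based} and {motif in exactly one species} × {cis-diverged}; a zero
marginal reports the motif as untestable.

## Read assignment

The zero-mismatch criterion makes exact substring search equivalent to (and
simpler than) a heuristic aligner, so assignment uses a hash index of
read-length windows per genome, both strands.  A read's verdict is **sim**
iff it has exactly one location in at least one simulans-side genome (line
genome, plus the published reference when supplied) and none in any
sechellia-side genome — symmetrically **sec**; matches on both sides are
**ambiguous**, several matches within the own species **multi**, none
**unmapped**.  The aligner-style "up to k reportable alignments, keep
single-alignment reads" cap is configurable but equivalent to location
counting at the default.  Verdicts are validated against a brute-force scan
of every substring position (100 % agreement over 50 random genome pairs).

Counting is HTSeq-union-style: a read increments a gene iff its interval
overlaps the gene's conserved constitutive exons in its own coordinates
*and* its lifted interval overlaps an exon annotated in the partner genome;
reads touching two genes' exons are discarded as ambiguous features.
Constitutive exons are those with identical boundaries in every transcript
of a gene; conserved segments are their chain-mediated intersection with the
partner's constitutive exons, equal-length on both genomes by construction.
Chain files follow the UCSC format (single chain, + strands); positions in
alignment gaps do not lift, and lifting is exactly invertible inside blocks.
Genes with > 1 % wrong-species assignments in either parental species are
filtered; genes with CPM ≤ 3 in at least 3 (hemocyte) or 5 (fat body)
libraries are filtered.  Coordinates are 0-based half-open internally,
GFF3 1-based closed at I/O boundaries.

## Targeted panel

Amplicon allele counts at each gene's first (most 5′) SNP are modelled as
beta-binomial — mean `expit(logit)`, overdispersion ρ — which is the
likelihood analogue of the observation-level random intercept used with
mixed-model logistic fits; ρ = 0 reduces to binomial.  The treatment fixed
effect gives `logit_control` and `logit_wasp`; Wald CIs use the central
difference observed information and a t critical value on n − 2 df (the
normal quantile undercovers at the panel's ~10-sample replication: empirical
CI coverage rises from ~0.92 to ~0.95).  The allele × treatment p-value is
Bonferroni-adjusted over the panel (family size = number of genes, 13 in the
motivating design).  Hybrid gDNA, at a structural 50:50 ratio, is checked
with a Clopper–Pearson interval that must cover 0.5.  Multi-SNP amplicons
get a consistency report of per-SNP pooled proportions (flagged above 0.05
spread).

qPCR expression is `ΔCt = Ct_ref − Ct_gene` (reference gene Rpl32 in the
motivating design; higher ΔCt = higher expression, log2 scale).  Technical
replicates are averaged per biological sample.  Hybrid ΔCt is multiplied by
the amplicon allele proportion (and its complement) to give per-allele
values; parental ΔCt is divided by two (one chromosome per allele).  The
default follows this literal multiply-the-ΔCt rule; a linear-scale variant
(`2^ΔCt × proportion`, re-logged) is available behind a flag.  Allele
proportions enter as plug-in point estimates; their uncertainty is not
propagated into the qPCR CIs.  The per-allele values feed an ordinary linear
model with allele × species × treatment factorial structure (7 terms plus
intercept); the species:allele coefficient is the trans divergence at the
anchored condition, `trans_wasp = trans_control + threeway` exactly, the
three-way interaction is the trans effect on the immune response, and a 4-df
likelihood-ratio test against the nested species-free model
(allele, treatment, allele:treatment) tests for any trans divergence.

## Synthetic data: what it emulates, and what not

The count generator mirrors the study design: 3 hemocyte or 5 fat-body
replicate libraries per group, parents with allele = total, hybrid libraries
contributing sim/sec allele columns that share one physical library (~5
million assigned reads, log-normal 0.2 CV) and one trans environment.  Gene
baselines are N(5, 1.5) on the log2 CPM scale; hybrid allele columns use
half the baseline (one chromosome per allele — the reverse of the
divide-parents-by-two qPCR rule).  Per-gene effects are log2 fold changes:
`cis` separates the hybrid alleles, `cis + trans` separates the parents,
species-specific response effects act under challenge (a `cis_response`
term, default 0, lets the allelic imbalance itself change with treatment).
The mixed-truth generator places genes evenly across the six true
categories at ±2 log2 where active (cis × trans uses trans = −cis/2,
compensatory trans = −cis).

The genome-pair generator writes two FASTA genomes related by configurable
SNP and 1–3 bp indel rates, GFF3 annotations (1–3 exons per gene, a fraction
of genes with a transcript-specific exon and a fraction with an exon
annotated in one species only), the alignment chain implied by the edit
history, and FASTQ reads drawn uniformly within single exons of a 50:50
allele mixture, each carrying origin truth.  It errors out when the
requested divergence leaves no conserved exon of at least one read length.

Deliberately not emulated: spliced reads across exon junctions, sequencing
errors and quality-score realism, isoform switching, correlated biological
replicates, batch structure, and genome assembly errors.  Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under its own model, not robustness to those real-data features;
the mismap filter and the four-genome redundancy hooks exist precisely
because real alignments are messier than the generator.

## Numerical choices and problem sizes

Newton/IRLS iterations cap at 60/40 with 10⁻⁹–10⁻¹⁰ convergence tolerances
and linear predictors clipped to ±40; constrained fits add a 10⁻⁹ ridge.
Dispersion grids span 10⁻⁴–16.  The beta-binomial optimiser is L-BFGS-B with
ρ bounded in expit([−12, 4]).  Default simulation sizes in tests and the
acceptance script — 600-gene recovery runs, 2000-gene null calibrations,
50 oracle genome pairs of ~10 kb with 60 reads each, 500 gDNA panels — were
chosen so the whole suite completes in well under a minute of compute per
module while keeping Monte-Carlo error small relative to the asserted
margins.

## Known limitations

* Exact numerical agreement with any particular GLM library is not a goal;
  dispersion shrinkage and QL moderation follow the same ideas but differ in
  detail, so significant-gene counts on real data can differ at the margins.
* The trans component inherits the variances of both the parental and cis
  estimates; at n = 5 its median absolute error is ~√2 times that of cis.
* Power to separate cis × trans from pure cis is limited when the trans
  component is half the cis magnitude (the mixed-truth setting): those genes
  dominate the residual ~7–10 % category-recovery error.
* The qPCR decomposition multiplies a log-scale quantity by a linear
  proportion (the literal rule); the linear-scale alternative is provided
  but changes the estimand.
* One joint GLM is fit over all eight groups; fitting separate models per
  contrast family would change dispersion pooling.
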