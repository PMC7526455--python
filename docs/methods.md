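# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `regvar`, at the level of detail a maintainer or a
careful user needs. Empirical statements below are limited to what the test
suite and `scripts/acceptance.py` themselves compute.

## SNP universe construction

Tag SNPs (noncoding, genome-wide significant) seed three disjoint classes.
LD expansion keeps proxies with r² strictly above 0.8 within 1 Mb; disease
labels propagate as the union over all linked tags, so a proxy shared by two
tags carries both diseases. Loci are the merged ±1 Mb windows around tags
with any MHC intersection removed (default MHC chr6:25–35 Mb, hg19;
configurable — the region is conventionally named but not delimited in GWAS
resources). Class precedence is positive > background > negative; coding
SNPs, and out-of-locus SNPs with catalog r² ≥ 0.1, are `excluded` rather than
silently dropped so tallies always partition the input.

r² is computed from phased haplotypes by the standard haplotype-frequency
formula, D²/(p_A(1−p_A)p_B(1−p_B)); unphased genotypes are out of scope
(users supply precomputed LD tables), which avoids re-implementing EM
phasing. Monomorphic SNPs return NaN rather than 0: the quantity is
undefined, and a 0 would silently pass `r² < 0.1` filters.

## Epigenetic enrichment and scoring

The enrichment test is Pearson χ² without continuity correction; whenever any
expected cell falls below 5 the test falls back to the exact Fisher test and
records that in the result, so small fixtures and sparse features never ride
on an invalid asymptotic. The Bonferroni denominator is the total number of
features across all four categories, not the per-category count — one joint
family, mirroring how a practitioner would correct a single screen of several
hundred features. Selection requires both FC > 1 and adjusted p < 0.05.

By default the background universe for enrichment *includes* the positive
SNPs (they are, after all, noncoding SNPs inside the loci, and locus-wide
totals are tallied that way); `background_includes_positives=False` switches
to a strictly disjoint group. The class partition itself is unaffected.

The category score is the weighted sum S = Σ FC_j·B_j over selected features
of that category. Scores are additive and non-negative; the annotation step
streams negative SNPs in chunks (200k rows by default) so genome-scale null
sets never need to be resident all at once.

The support threshold is the nearest-rank 95th percentile of the negative
scores — the ceil(0.95·n)-th order statistic, no interpolation — and support
requires a *strictly* greater score. Nearest-rank guarantees that at most 5%
of the null itself exceeds the threshold for any distribution, including the
zero-inflated, tie-heavy distributions category scores actually have (most
negatives score exactly 0). Interpolating percentiles would break that
guarantee under ties.

## Allele-specific motif calls

The scanner computes log₂ odds against a background base composition
(uniform by default), discretized to 10⁻³-bit bins. The null score
distribution is built exactly by convolving the per-position binned score
distributions, giving Pr(score ≥ s) without simulation or asymptotics; window
scores are reported on the same grid, so p-values are reproducible
bit-for-bit given the configuration (bin width, pseudocount, background).
Matrix probabilities are floored at 10⁻⁹ before taking logs so one-hot
matrices with pseudocount 0 stay finite. Windows containing N are skipped.
Both strands are scanned; a reverse-strand hit is attributed to the forward
coordinates it covers, which makes calls invariant under reverse-complementing
the locus (tested).

A TF call is allele-specific when the best SNP-overlapping hit passes
p < 10⁻⁴ (the conventional motif-scan threshold) for exactly one allele:
`gain` when the alternative allele passes, `loss` when the reference does.
This presence/absence criterion — rather than a score delta — is the design
choice where the convention is genuinely open; the threshold is a parameter.
Retention requires the same TF name (uppercased) and direction from at least
two motif databases, plus TF expression (RPKM > 1 in ≥ 1 configured immune
cell type); with no expression table the filter is bypassed with a warning.

Molecular QTLs (bQTL/hQTL/caQTL/dsQTL) contribute evidence when the SNP lies
inside the molecular peak (local) at FDR < 0.1, with Benjamini–Hochberg
recomputed per dataset when only raw p-values are supplied. A SNP is
functional iff epigenetic support (≥ 1 category) and allelic evidence (motif
or QTL) are both present — a deliberate conjunction: either line of evidence
alone is too permissive.

## Colocalization

The ABF route uses Wakefield approximate Bayes factors per SNP,
lABF = ½[log(1−r) + r·z²] with r = W/(W+V), V the squared standard error and
√W the prior effect s.d. — 0.15 for quantitative traits, 0.2 for case-control,
the conventional defaults of this family of methods. The five hypothesis
masses are assembled in log space (logsumexp; the i≠j cross term via
log1p-difference) with per-SNP priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵, and
normalized to PP0–PP4. When only p-values are available, |z| is recovered
from the two-sided p (signed by beta if present — the per-SNP ABF is
sign-agnostic otherwise) and V approximated from sample size and allele
frequency. Fewer than two shared SNPs is an explicit error, not a silent
PP0.

The fine-mapping route assigns each SNP a causal probability given the lead
SNP's significance S = −log₁₀p: a Normal density at S with mean r²·S and s.d.
√(1−|r|^3.2)·√S/2. The constants 3.2 and ½ come from the published
description of the fine-mapping method this follows; they are isolated as
function arguments. Perfect proxies of the lead (s.d. → 0) are treated as a
point-mass class sharing probability equally — the correct degenerate limit,
and what makes a two-SNP perfect-LD locus return 0.5/0.5. The credible set is
the smallest set reaching cumulative 0.95.

Colocalization of two fine-mapping vectors g, q weighs the shared-causal mass
Σᵢgᵢqᵢ against the distinct-causal mass Σ_{i≠j}gᵢqⱼ with the same p12 versus
p1·p2 priors. PP0–PP2 are identically zero on this route: the probability
vectors exist only for loci where both traits already carry a
genome-wide-significant lead, so the no-association hypotheses are off the
table by construction. Disjoint SNP universes yield PP4 = 0 with a warning.

## Target genes, TF network, drugs

Pair prediction is a pure conjunction — functional SNP, ≥ 2 cis-QTL datasets
at FDR < 0.05, gene-level max PP4 > 0.8, and (local OR ≥ 2 contact
datasets) — so removing any evidence table can only shrink the output
(tested as a monotonicity property). "Local" means the SNP falls in the
±1 kb promoter window of any TSS of the gene; the half-width is configurable
0.5–10 kb since the published sensitivity analyses show the choice barely
matters. A gene is a *local gene* only when every predicted pair for it is
local; genes reached exclusively by distal SNPs are flagged separately.

TF enrichment compares functional SNPs with predicted targets against all
positive SNPs (Fisher exact, FC > 1, Bonferroni over the TFs actually
tested). Indirect regulation is limited to exactly one hop — TF → gene
encoding another enriched TF → that TF's direct targets — because deeper
chains have no support in the evidence model and would admit cycles. Both
deduplicated and raw indirect tallies are available (`dedup_indirect`). The
"TFs sharing all targets" summary uses greedy set cover with ties broken by
TF name; greedy is within the classical ln(n)+1 factor of optimal and is
verified against exhaustive enumeration on small instances in tests.

Drug-target prediction applies rules (a) strong PPI (> 0.9, strict) with an
autoimmune-indicated drug-target gene C, (b) both genes regulated by
functional SNPs for the same disease label — exact label equality, no
ontology expansion — and (c) candidate druggability (known target, or ≥ 2
druggability resources). Predictions are deduplicated per (candidate,
disease) with all qualifying partners listed; the repurposing flag marks
candidates already carrying a drug for another indication. Function tiers
are: *high* for pathway/IMPC/OMIM immune evidence, *suggestive* for blood
expression (RPKM > 1), tissue-specific expression (pSI < 0.01), disease-gene
databases, or Mendelian-randomization causality (FDR < 0.05 with
heterogeneity p > 0.05), else *none*; the three tiers partition any gene
list. The over-representation test is the one-sided hypergeometric with BH
correction, ties in the ordering broken by pathway id for bit-reproducible
output.

## Exact small-sample statistics

The two-sided Fisher p-value uses the point-probability rule (sum of outcome
probabilities no larger than the observed one). For table totals up to 2,000
the hypergeometric weights are integer-exact and tie comparisons are exact
integer comparisons, so the result equals rational enumeration to the last
float bit; beyond that, log-space computation with a 10⁻⁷ relative tie
tolerance (the same convention R uses) takes over. Directionality is not
built into the test — it is enforced separately by the FC > 1 filters, which
is how every "FC > 1, p < α" rule in the pipeline is phrased.

## The synthetic data generator

The generator emulates the *structure* of the real inputs — tag/LD tables,
BED peak sets per feature, MEME motif libraries in two databases, flank
FASTA, molecular- and cis-QTL tables, BEDPE contacts, per-locus summary
statistics, function/drug/PPI tables — on a 2 × 10 Mb genome with planted,
machine-readable truth. Default study conditions, chosen once: 12 tag SNPs
(three diseases) × 4 proxies = 60 positives, 1,500 background and 3,000
negative SNPs, 40 features of which 12 are enriched (positive coverage set to
target_fc × background coverage, realized by exact-count sampling), length-8
near-consensus PWMs whose matches the alternative allele destroys (one
mismatch pushes the best p-value above 10⁻⁴, so gain/loss calls are
deterministic), 24 planted functional SNPs of which 12 carry target genes (4
local, 8 distal, two of them doubling as drug-triple participants), coloc
scenarios with n = 5,000, 200-SNP-capable block-LD loci and causal effects of
0.5 phenotypic s.d., and decoy genes/triples that each violate exactly one
rule. Every output family draws from its own labelled substream of the master
seed, so bundles are byte-identical per seed and adding an output never
perturbs the others.

What the generator does *not* emulate: realistic human LD (block-uniform r
instead of recombination maps), allele-frequency spectra, overlapping peak
architectures, motif redundancy across TF families, trans effects, or any
correlation between evidence layers beyond the planted signals. Passing the
end-to-end tests therefore demonstrates that the machinery implements its
rules correctly and recovers strong planted signals — not that the thresholds
have a particular sensitivity/specificity on real cohort data.

## Problem sizes and runtime

The default test-suite and acceptance problem sizes — 60/1,500/3,000 SNP
classes, 50 colocalization replicates per scenario at 200 SNPs, Fisher
enumeration to total 60 (tests) / 40 (acceptance script), motif enumeration
to length 6 — run end to end in well under a minute on one CPU; they were
chosen as the smallest sizes at which every rule of the method is exercised
with planted-truth verification.

## Known limitations

- Indels, multi-allelic variants and dinucleotide background models are out
  of scope for the motif scanner.
- The single-causal-variant assumption of both colocalization routes is
  inherited from the methods they implement; multi-causal loci will split
  posterior mass.
- The fine-mapping constants (3.2, ½) are taken from the cited description
  rather than re-derived; they are parameters, not conclusions.
- Disease matching in drug rules is string equality; harmonizing disease
  vocabularies is the caller's responsibility.
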