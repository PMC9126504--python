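# Methods

## Model overview

The package models an allogeneic cancer-vaccine trial as a resampling
experiment over a tumor cohort. A trial draws `n_total = 33` tumors without
replacement, assigns a uniformly random 3 to the pooled vaccine and 30 to
the patient arm, and is repeated `n_iterations = 10` times from independent
draws of the same cohort (sample overlap between iterations is allowed).
All antigen accounting is per patient, per trial.

Three antigen classes are quantified:

1. **Shared neoantigens.** Variant identity is the triple (gene symbol,
   protein position, REF/ALT amino-acid string). Genomic coordinates do not
   participate in matching: two tumors share a neoantigen exactly when they
   produce the same altered amino-acid sequence. A shared identity counts
   when at least one epitope window overlapping the altered residues has a
   median ensemble IC50 strictly below 500 nM on at least one allele of the
   relevant HLA context; multiple binding registers or peptide lengths per
   variant count once.
2. **TAAs.** Full-length TAA proteins are scanned as 9-mers. A gene
   contributes only when the patient expresses it strictly above the median
   of the nonzero FPKM values in their own tumor (the vaccine is assumed to
   express all TAA genes robustly). Overlapping strong binders sharing ≥ 4
   of 9 residues collapse to a single representative.
3. **Alloantigens.** A germline locus is foreign when ≥ 1 vaccine sample
   genotype contains the alt allele (0/1 or 1/1) and the patient is 0/0.
   Foreign protein-altering variants are counted at the variant level, with
   strong-binder tallies against the patient's alleles (lysate) and the
   vaccine's alleles (cell). These two tallies are asymmetric by definition
   and are deliberately not nested.

### Presentation models

*Lysate-based*: antigens are cross-presented by the patient's own
antigen-presenting cells, so all binding is evaluated against the patient's
HLA class I alleles. *Cell-based*: intact vaccine cells present directly,
so vaccine-cell alleles constrain presentation. For neoantigens the default
cell rule (`both_contexts`) requires a strong binder in both the patient
context and the vaccine context; an alternative rule (`shared_allele`)
requires a strong binder on an allele carried by both. Both rules produce
subsets of the lysate-based set; the subset law is property-tested over
randomized trials. The wording of the two rules differs between the
neoantigen and TAA analyses in the literature this design follows, so both
are implemented and config-switchable rather than silently picking one.

The vaccine-side allele scope is also configurable: `carriers_only`
(default for neoantigens — a cell can only present a mutant peptide it
encodes, so only the haplotypes of the samples actually carrying the
variant count) or `union` (all six-allele sets pooled over the three
samples; used for TAAs and alloantigens, where every vaccine cell carries
the antigen).

## Filtering rules

Somatic variants are retained iff the FILTER column is clean, VAF > 0.05
and depth > 5 — all strict inequalities, read literally from the usual
">5 %, >5 reads" convention, so boundary values fail. VAF defaults to
alt_depth / (ref_depth + alt_depth) from the tumor sample's AD field;
"depth" is taken as the total sample depth (DP), since callers differ on
whether the convention means total or alt-supporting reads. Multi-allelic
records are split per-allele before filtering. Protein-altering means
missense, in-frame indel, or frameshift; stop-gain and stop-loss are
excluded because a pure truncation yields no novel strong-binding sequence
under this framework's epitope construction.

Germline variants use class-specific GATK-style hard filters: a SNP is
removed iff QD < 2.0 ∨ FS > 60.0 ∨ MQ < 40.0 ∨ SOR > 3.0; an indel iff
QD < 2.0 ∨ FS > 200.0 ∨ MQ < 40.0 ∨ SOR > 5.0. Inequalities are strict, so
a SNP at exactly QD = 2.0 survives. A missing metric fails the variant.

## Epitope construction

Missense: single substitution; altered set = {position}. In-frame
insertion: the inserted residues are altered; deletion: the junction
residue is altered (a window must span the novel junction to be
mutation-derived). Frameshift: prefix up to position − 1 plus the annotated
downstream peptide truncated to < 500 novel residues (`frameshift_limit`,
default 500, cap = limit − 1 = 499 aa). Annotated reference residues are
checked against the protein and mismatches are hard errors. Candidate
windows are every k-mer containing ≥ 1 altered position, N-to-C; the
default epitope length set is {9} (8–11 supported) — counting is at the
variant level, so the length set does not change counts, and one length is
the cheapest default preserving those semantics.

### Overlap collapse

Two 9-mers with starts i < j share max(0, 9 − (j − i)) residues; 4 shared
residues (4/9 = 44.4 % > 44 %) triggers a collapse. Collapse is greedy
left-to-right against the last kept window, keeping the N-terminal-most
representative of each run — deterministic, and for a chain constraint of
this form greedy-earliest keeps the maximum possible number of windows.
An all-pairs clique variant was considered and rejected: on chains the
greedy comparison is equivalent and simpler.

## Binding model

The binding interface is a plugin contract: given (peptide, allele) return
IC50 in nM or "not applicable" (e.g. unsupported peptide length). The score
for a peptide:allele pair is the median over applicable algorithms (even
counts average the two middle values); a pair with no applicable algorithm
is skipped. Strong binding is median IC50 < 500 nM, strictly — exactly
500 nM is weak.

Two deterministic predictors ship: a lookup table (exact expectations in
tests and fixtures) and a position-weight model mapping a summed
anchor-residue score s to IC50 = 50000·e^(−s) clamped to [1, 50000] nM,
strictly decreasing in s. The default ensemble is three position-weight
instances sharing one per-allele base table (anchors at positions 2 and 9,
per-residue weights uniform on (0, 3)) plus per-algorithm Gaussian jitter
(σ = 0.35) — real predictors agree broadly and differ in detail, and the
shared base puts roughly 10–15 % of random 9-mer:allele pairs under the
500 nM line, so ensembles, medians, and strong-binder logic are all
exercised non-degenerately. All predictions flow through a
(peptide, allele, algorithm) cache, persistable as TSV; trials over one
cohort then reduce to dictionary lookups after the first evaluation of each
(variant identity, allele) pair, mirroring the variant–HLA pair database a
production run would keep.

## Synthetic cohorts

The generator emulates the structure the analysis consumes, not tumor
biology:

- **HLA**: two i.i.d. draws per locus (A, B, C) from an allele-frequency
  table; homozygosity allowed; inter-locus linkage disequilibrium is not
  modeled (the analysis only consumes final allele sets).
- **Drivers**: each recurrent driver is carried independently with its
  configured prevalence — the BRAF-V600E-at-~50 %-in-melanoma /
  KRAS-G12D/V-in-PAAD pattern that dominates real shared-neoantigen counts.
- **Passengers**: count ~ Poisson(`passenger_rate`), random missense
  positions in random genes; a configurable fraction are frameshifts with
  random downstream tails (15–59 aa), so both epitope classes are exercised
  by configuration rather than surprise.
- **Germline**: biallelic, independent loci; genotypes drawn per
  Hardy–Weinberg from the population allele frequency. Site metrics
  (QD/FS/MQ/SOR) are panel properties with passing defaults; failing values
  can be configured to exercise the hard filter.
- **Expression**: per gene, zero with probability `zero_fraction`,
  otherwise LogNormal(`log_mean`, `log_sd`) — the zero-inflated log-normal
  shape of FPKM tables.

One seeded `numpy` Generator is threaded through all draws in a fixed
order (per patient: HLA → drivers → passengers → germline → expression),
so a (spec, seed) pair serializes byte-identically. Trial iterations use
child streams spawned from the master seed by iteration index, making
results independent of execution order.

What the generator does **not** model: mutational signatures, HLA linkage,
copy number, tumor purity, expression correlation between genes, and
linkage between germline loci. Passing tests therefore demonstrate the
correctness of the accounting machinery and its statistical calibration
under these idealized conditions — not that real cohorts would produce any
particular antigen counts.

## Numerical and reporting choices

- Percentages are rounded half-up to one decimal; whole numbers render
  without the decimal ("6%"). Two printed figures in the source literature
  (14.6 %, 4.6 %) are inconsistent with this rule and are not used as
  checks.
- The expression gate uses the median of the nonzero FPKM multiset for the
  default 50th percentile, strict `>` at the boundary.
- Degenerate inputs: proteins shorter than k yield no windows (logged);
  zero applicable binding algorithms skip the candidate (logged); missing
  VAF/depth or germline metrics fail their variant (logged); a missing
  patient genotype skips the locus (logged).
- Cohort sizes in the test and acceptance runs are chosen for statistical
  resolution, not realism: the parameter-recovery check uses a 3,300-sample
  cohort and 1,000 trials so the closed-form sharing rate p·(1−(1−p)³) is
  resolved within three standard errors, where the error model combines
  empirical between-trial variance (patients within a trial share one
  vaccine draw and are therefore correlated) with a delta-method term for
  the realized cohort prevalence (all trials resample one finite cohort, so
  that deviation does not average out).
- The subset-law suite runs 1,000 randomized trials over a 40-sample
  cohort with all features enabled (drivers, passengers, frameshifts,
  germline panel, TAA gene) and requires zero violations.

## Known limitations

The toy binding ensemble is calibrated for coverage of the decision logic,
not for fidelity to any real predictor; absolute antigen counts from
synthetic cohorts are not comparable to real-cohort counts. Real-predictor
adapters can be registered through the plugin contract, at which point the
surrounding accounting is unchanged. HLA class II presentation, proteasomal
processing/TAP transport, immunogenicity scoring, and percentile-rank
thresholds are out of scope; only IC50 semantics are implemented.
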