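# Methods

## Scope and model

`mkscan` measures selection pressure on protein-coding genes from two
complementary signals and combines them in the McDonald–Kreitman (MK)
framework:

* **Within-species polymorphism.** Population SNPs falling in a gene's CDS
  are classified as synonymous or nonsynonymous against the reference
  codon. Per gene, `Pn` and `Ps` count *distinct segregating sites*, and
  the rates are `dN_SNP = Pn/N` and `dS_SNP = Ps/S`, where `N` and `S` are
  Nei–Gojobori (NG86) nonsynonymous and synonymous site totals.
* **Between-species divergence.** Ortholog pairs are detected by strict
  reciprocal best hit (RBH) on protein similarity tables (admission:
  E-value < 1e-3 and query coverage > 90% in each direction). Coding
  sequences are aligned through their proteins and back-translated; NG86
  pathway-averaged differences give `Dn`, `Ds`, and Jukes–Cantor
  correction turns the proportions into `KA` and `KS`.
* **MK statistics.** Per gene, the neutrality index
  `NI = (Pn/Ps)/(Dn/Ds)` and the direction of selection
  `DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps)`. Departure from neutrality is tested
  with a Pearson chi-squared test (1 df, no continuity correction) on the
  2×2 table, Benjamini–Hochberg adjusted; positively selected genes have
  `NI < 1` (or `DoS > 0`) and `q < 0.05`.
* **Gene-set comparisons.** Per-gene metrics are compared between labeled
  sets (mQTG, mQTG with CNV, non-mQTG with CNV, and a random set of up to
  10,000 genes) with the two-sided Wilcoxon rank-sum test, with box-plot
  summaries (median, 25–75% box, 1–99% whiskers, type-7 quantiles).

## Counting conventions (NG86 core)

These are the conventions of common NG86 implementations, chosen so the
per-codon conservation law stays exactly testable:

* Standard nuclear genetic code; the table is data, not code.
* Single-base changes that create a stop codon count as **nonsynonymous**
  in site counting, so `syn_sites + nonsyn_sites = 3` holds exactly per
  codon (site fractions are exact rationals internally). The alternative
  convention — excluding stop neighbors from the site denominator — is
  noted but not implemented.
* Between two codons, all orderings of the differing positions are
  enumerated and averaged with **uniform weights** (unweighted NG86; no
  transition/transversion weighting). Pathways through a stop codon are
  discarded; if every pathway is inadmissible, all pathways are counted
  with stop-involving steps treated as nonsynonymous so `Nd + Sd` still
  equals the Hamming distance.
* Terminal stop codons are excluded from all site and difference counting;
  internal stops reject the gene with a named error.
* Jukes–Cantor: `d = −(3/4)·ln(1 − 4p/3)`; `p ≥ 3/4` is reported as a
  saturated NA with a reason code, never silently clamped.

The divergence estimator (NG86 + Jukes–Cantor) is deliberately simple and
fully checkable against brute-force enumeration; it sits behind a registry
(`mkscan.inter_divergence.ESTIMATORS`) so a likelihood-based or
Yang–Nielsen-style backend could be added without touching callers. At the
synonymous divergences targeted here (`Ks ≈ 0.1–0.2`) the NG86 and
ML-family estimators agree closely; at much larger divergences NG86 is
known to be biased.

## Statistical validity rules

* `NI` is NA when `Ps = 0` or `Dn = 0`; `Ds = 0` with divergence present
  gives `NI = 0`. `DoS` is NA when either of its defining sums is empty.
  NA genes are never flagged and are excluded (with logged counts) from
  rank-based comparisons; no pseudocount smoothing is applied.
* The chi-squared p is NA when any marginal is zero or any expected cell
  is below 1 — sparse MK tables produce NA rather than unstable p-values.
  A Fisher-exact fallback is available behind `fisher_fallback`.
* Fractional pathway-averaged `Dn`/`Ds` are rounded half-to-even for the
  counts-based test only; `NI` and `DoS` use the exact values.
* Wilcoxon rank-sum: exact enumeration when both sides have n < 20 and the
  pooled data are tie-free, otherwise the tie-corrected normal
  approximation; a comparison of identical pooled constants returns p = 1.
* FDR is Benjamini–Hochberg step-up; NAs pass through untouched.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `evalue_max` | 1e-3 | RBH admission, per direction (strict `<`) |
| `coverage_min` | 0.90 | RBH query-coverage admission (strict `>`) |
| `fdr_alpha` | 0.05 | q-value threshold for positive-selection flags |
| `random_set_size` | 10,000 | size of the random comparison set |
| `estimator` | `ng86_jc` | divergence backend |

Coverage is interpreted as *query* coverage in each direction
independently (the admission thresholds do not specify which side; this is
the package's documented choice). The random set is drawn from the full
analyzed universe including labeled genes; a flag allows their exclusion.
Heterozygous genotype calls count as alt-carrying — the target organisms
are near-homozygous inbred lines and the model is per-accession
presence/absence. When an annotation carries several mRNAs per gene, the
longest total CDS is used (ties broken by transcript id).

## Synthetic data generator

The generator emulates an *Arabidopsis*-like study design end to end — a
reference species with a resequenced accession panel, a diverged sister
species, and labeled gene classes — so the whole pipeline runs and is
validated without any download:

* **Genes.** Random sense-codon CDSs (ATG start, no internal stops,
  terminal stop), 200–400 codons, placed on both strands of a small
  multi-chromosome genome, about half of them split into two exons —
  exercising splicing, strand correction and coordinate arithmetic.
* **Divergence.** Each CDS position receives Poisson(`Ks_target`)
  single-base proposals, applied sequentially; synonymous proposals are
  accepted, nonsynonymous accepted with probability `ω_div(class)`, and
  stop-creating proposals rejected. This calibrates the realized
  synonymous rate per synonymous site to `Ks_target` in expectation.
  Default `Ks_target = 0.15`, within the `Ks ≈ 0.1–0.2` range typical of
  the *A. thaliana* / *A. lyrata* split.
* **Polymorphism.** Segregating synonymous sites per gene are
  Poisson(`θ_syn · S`) and nonsynonymous Poisson(`θ_syn · ω_poly(class) ·
  N′`), where `N′` counts nonsynonymous non-stop changes — the same
  stop-rejection rule as the divergence process, so a fully neutral
  simulation (all ω = 1) is neutral in the MK 2×2 sense and the shared
  stop-exclusion factor cancels from NI and DoS. Default `θ_syn = 0.10`
  gives roughly 20 synonymous segregating sites per gene at these gene
  lengths, the order observed in large *A. thaliana* resequencing panels. Derived-allele carriers are a
  random accession subset (uniform count by default, Beta optional);
  carriers are written homozygous, matching inbred accessions. Default
  panel size: 270 accessions.
* **Labels.** Four gene classes (background, mQTG-only, CNV-only,
  mQTG∩CNV) with default ω elevated in the mQTG∩CNV class
  (ω_div 0.20/0.30/0.30/0.55, ω_poly 0.30/0.40/0.40/0.65), giving the
  expected ordering of the group comparisons. Class fractions
  (0.30/0.05/0.35 labeled) are sized so every compared class holds ≥ 200
  genes at the default 600-gene scale — genome-wide label frequencies
  would leave ~1 gene in the smallest class at desk scale and make rank
  tests meaningless. mQTGs get synthetic metabolite counts
  (1 + Poisson; higher mean for the CNV class).
* **Similarity hits.** True ortholog pairs are emitted as
  BLAST-outfmt6-style rows (bitscore monotone in protein identity, full
  coverage) plus low-scoring paralog-like decoys, so the RBH stage does
  real filtering without an alignment-search dependency.

**What the generator does not model:** linkage and coalescent structure
(sites are independent), transition/transversion bias and codon-usage
bias (mutations are uniform, matching the unweighted estimator),
demography, recombination, gene loss, and CNV as an actual copy-number
process (CNV is a gene label only, mirroring how CNV calls enter the
analysis). Passing calibration tests therefore demonstrates correctness
of the counting and testing machinery under the model's own assumptions,
not robustness of NG86 to real mutational biases.

## Problem sizes used in validation

Neutral calibration aggregates three independent 300-gene simulations
(all ω = 1, 270 accessions); planted-parameter recovery uses one 600-gene
simulation with class ω_div of 0.2/0.5/1.0. These sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances (mean ratios
within ±0.1, mean NI within ±0.15, mean DoS within ±0.05, recovery within
±20% relative). A mild upward Jensen-type bias in mean ratio statistics
(ratios of Poisson counts) is expected and stays within those tolerances
at these gene lengths and rates.

## Known limitations

* NG86 + Jukes–Cantor underestimates divergence under strong
  transition bias or extreme codon usage; the estimator registry is the
  intended extension point.
* Polymorphism classification is per-SNP against the reference codon;
  co-occurring SNPs in one codon are not combined into haplotype codons.
* No derived/ancestral polarization and no low-frequency-polymorphism
  filtering; the MK variants that use them are out of scope.
* BED12 input takes blocks as CDS intervals (no thick-region
  intersection); GFF3 is the primary annotation path.
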