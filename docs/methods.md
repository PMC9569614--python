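# Methods

This note records, in the package's own words, the statistical model behind
each stage, the defaults and their units, and the numerical choices a reader
would otherwise have to reverse-engineer from code.

## 1. Synthetic study generator (`simdata`)

The generator emulates a bi-parental F2 dwarfism study at desk scale. It is
meant to reproduce the *structure* of such a study — segregation, selection of
extremes, pooled sequencing, gene models, expression contrasts — not any
particular organism's genome.

**Genetics.** Two fully inbred parents differ at every marker: the tall line
XYP1 carries allele 0, the dwarf line AYP1 allele 1. F1 gametes are simulated
as a Markov chain along each chromosome: a random starting allele, then a
crossover between adjacent markers with the Haldane probability
r = (1 − e^(−2d))/2 for map distance d (Morgans), independently across
intervals (no interference). An F2 genotype is the sum of two independent
gametes, giving dosages {0, 1, 2} of the dwarf allele.

**Defaults** (all overridable in `SimConfig`): 2 chromosomes × 2 Mb with 2000
markers each; recombination 4 cM/Mb (so a chromosome spans 8 cM — realistic
marker density, deliberately short map); 200 F2 plants; bulks of 30; parent
depth ~Poisson(10), bulk depth ~Poisson(50); sequencing error 0.01 as a
symmetric allele flip; 40 genes per chromosome.

**Phenotype.** height = 100 cm + a·dose + dominance·[dose = 1] + N(0, 10 cm),
with a = −15 cm per dwarf-allele dose by default (the dwarf parent's allele
shortens the plant). At allele frequency ½ the additive variance is a²/2, so
the default QTL explains a²/2 / (a²/2 + σ²) ≈ 53% of the phenotypic variance —
a major-effect locus, as in the emulated design. The F2 height distribution is
approximately normal (a mixture of three normals at ¼:½:¼), which the
phenotype stage verifies by moment criteria.

**Pooled sequencing.** For each bulk, the true dwarf-allele fraction at a
marker is the mean dosage of its members / 2. Read depth is Poisson; the
number of dwarf-allele reads is Binomial(depth, p′) with
p′ = p(1−e) + (1−p)e for error rate e. Parents are emitted as opposite
homozygotes with their own Poisson depths.

**Gene models and expression.** Genes are non-overlapping single-CDS models
(100–299 codons, ATG … stop, frame-complete) placed in evenly spaced slots on
either strand, with the CDS embedded in the simulated chromosome sequence so
extraction round-trips exactly. RNA-seq counts are negative binomial
(var = μ + αμ², α = 0.1) around LogNormal(5, 1) gene means, 3 replicates per
line; genes within 300 kb of the QTL are planted 4-fold *down* in the dwarf
line, and 5% of background genes move 4-fold in random directions to mimic
trans effects. A truth record (QTL position, planted fold changes) accompanies
every study.

**What is not modeled:** mapping/alignment artifacts, indels and multi-allelic
sites, linkage between the expression contrast and the cross (parent lines are
sequenced for RNA, not the bulks), GC or length biases in counts, and
structural variation.

## 2. Phenotype stage

Skewness and kurtosis follow the SPSS/Excel conventions (adjusted
Fisher–Pearson, bias-corrected; kurtosis is excess kurtosis), i.e.
`scipy.stats.skew(..., bias=False)` and `kurtosis(..., fisher=True,
bias=False)`. The normality flag is the common applied-genetics moment rule
|skew| < 1 and |kurtosis| < 1. Bulks are the k lowest and k highest
phenotypes; ties at the boundary break toward the lower individual id, making
selection deterministic.

## 3. SNP-index and marker filters

Markers are retained only where the parents are opposite homozygotes (phased
or unphased notation). The SNP-index of a bulk is the fraction of its reads
carrying the *dwarf-parent* allele — an explicit orientation that is written
into every output header — and Δ = index(high) − index(low). Zero depth gives
a missing index (NaN), never zero.

Study filters, applied per marker: drop if the index is below 0.3 in **both**
pools (uninformative, likely shared hetero/error sites), drop if depth is
below 7 (by default in **either** pool; a config switch `depth_rule="both"`
relaxes this to both pools, since the study phrasing does not pin the pool
scope down), drop if the index is missing in any pool. Boundary values (index
exactly 0.3, depth exactly 7) are retained.

## 4. Windowed Δ profile and permutation thresholds

Windows of 20 kb advance by 2 kb along each chromosome (window starts at
1, 2001, 4001, …, up to the last observed marker). Window statistics are
unweighted means over member markers; windows with fewer than `min_markers`
(default 3) markers are masked (NaN), never zero-filled. Membership is built
once as a sparse windows × markers matrix, so one matrix product evaluates all
windows for all permutation replicates.

The null is generated by **read re-splitting**: at each marker, pool the two
bulks' dwarf/other read counts and redraw the high bulk's dwarf reads from a
hypergeometric distribution conditioned on both depths, 1000 times. This
preserves depths and total allele counts, breaking only the assignment of
reads to bulks. Null windowed deltas are pooled within window *marker-count
classes* (3–5, 6–10, 11–20, > 20 markers) because window precision depends on
marker density, and the 2.5%/97.5% percentiles of each class become its
two-sided 95% thresholds. A window is significant when its observed mean Δ
falls strictly outside. Overlapping or abutting significant windows merge into
candidate regions, clipped to the observed marker extent.

**Calibration and a deliberate limitation.** The re-splitting null models
*read-sampling noise only*. Under that null (both bulks truly at allele
fraction 0.5), the scan is calibrated: ~5% of windows exceed the 95%
thresholds (verified in the acceptance suite against independently simulated
read-noise data). But two finite bulks of 30 plants also carry
*composition drift*: even with zero QTL effect, each bulk's allele frequency
at a locus wanders with SD ≈ √(0.25/60) ≈ 0.065, and the drift is correlated
along whole chromosomes at this map length (8 cM). Windowing averages away
read noise (SE ≈ 0.02 at 20 markers × 50×) but cannot average away drift,
which therefore dominates the windowed Δ genome-wide and pushes many windows
past the read-noise thresholds. This is an inherent property of the
re-splitting scheme used by QTL-seq-style studies, not an implementation
artifact; it is why candidate regions are treated as *preliminary* and refined
by independent evidence (variant effects + expression) rather than taken as
final. Larger bulks shrink drift as 1/√(bulk size).

## 5. Variant-effect classification

Gene models are non-overlapping within a chromosome, so a sorted interval
index resolves each SNV by bisection. Within a CDS, the variant's codon is
re-translated with the standard genetic code (minus-strand alleles are
reverse-complemented; CDS segments are held 5′→3′). Precedence: same amino
acid → synonymous; new stop → stop-gain; lost stop → stop-loss; otherwise
non-synonymous. Positions inside the gene span but outside the CDS are
intronic (the models carry untranslated flanks); everything else is
intergenic. A REF allele disagreeing with the genome raises an error rather
than silently reorienting. The acceptance suite requires 100% agreement with
an oracle that re-translates the *entire* mutant CDS.

## 6. Differential expression

A deliberately minimal negative-binomial pipeline — not a DESeq2 clone:

* **Normalization.** Median-of-ratios size factors over genes with nonzero
  counts in every sample.
* **Dispersion.** One pooled method-of-moments estimate: per gene,
  α_g = (s² − m)/m² from the within-group pooled variance s² and overall mean
  m; α is the mean of α_g across genes, floored at 10⁻⁸. Rationale: at 3-vs-3,
  per-gene variance estimates (4 df) are far too noisy to sit in a Wald
  denominator — plugging them in directly gives ~12% type-I error at nominal
  5%, and heavy-tailed references that fix calibration destroy
  Benjamini–Hochberg power at genome scale. Pooling across genes gives the
  denominator hundreds of effective degrees of freedom, so a standard normal
  reference is honest (measured type-I ≈ 0.05, power > 0.98 on planted 4-fold
  changes). The cost is assuming a roughly common dispersion, which matches
  the generator and is acceptable at this scale.
* **Test.** log2FC = log2((m̄_case + ½)/(m̄_control + ½));
  Var(log NB mean) ≈ (m + αm²)/(n m²) by the delta method; Wald
  z = log2FC / SE against N(0, 1), two-sided.
* **Multiplicity.** Benjamini–Hochberg step-up q-values (own implementation,
  cross-checked against statsmodels), computed over all tested genes.
* **DEG rule.** |log2FC| > 1 and q < 0.05, both strict; direction is relative
  to the tall line XYP1 as control. FPKM = counts·10⁹/(CDS length·library
  size); FPKM > 1 in at least one sample is reported as an `expressed_flag`
  but is *not* a prefilter.
* **Companions.** Upper-tail hypergeometric term enrichment with BH across
  terms; Pearson correlation between samples on log2(normalized count + 1);
  the 2^−ΔΔCt transform for qPCR-style validation.

## 7. Integration and reporting

Genes carrying protein-changing variants (non-synonymous, stop-gain,
stop-loss) inside candidate regions are intersected — by exact gene id — with
the DEG set; an id-format mismatch between the two sources (ids equal only
after case/whitespace normalization) raises instead of silently returning an
empty intersection. Regions whose mutated genes are all non-differential are
dropped; refinement never adds regions. The JSON report carries the phenotype
summary, all/retained regions, candidate genes, Venn counts, DE counts, the
config hash + seed, and — when simulation truth is available — whether the
planted QTL lies inside a retained region.

## 8. Determinism and numerics

All randomness flows from explicit numpy Generators; `simulate_study` spawns
six independent streams from one root `SeedSequence`, so stages are
reproducible independently. Identical seeds give byte-identical outputs (an
acceptance criterion). Sorting uses stable mergesort wherever order feeds
results (BH, bulk ties). External coordinates are 1-based inclusive
(VCF/GFF convention); BED output is 0-based half-open. Heights are re-read
with round-trip float parsing so a simulate-then-reload run reproduces the
in-memory run bit-for-bit. Default problem sizes (2 × 2 Mb, 2000 markers,
desk-scale gene counts) are the package's own choice: large enough for the
window/permutation machinery to behave as at genome scale, small enough that
the full acceptance suite runs in about a minute on one CPU.
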