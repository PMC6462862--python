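# Methods

This note documents the models, decision rules, numerical choices and
limitations behind `tumorhet`, and what the synthetic-data experiments do
and do not establish about real data.

## Study design being modeled

The package targets multi-region tumor WGS: per patient, one germline
control and R ≥ 1 tumor regions (primary tumor and nodal/pleural
metastases), each with an inferred tumor cellularity (purity) and ~150×
mean coverage; per patient, histotype and smoking history in pack-years
(PY, one pack/day for one year). Variants arrive annotated (gene, impact
class, CADD scaled score, caller quality QSS for SNVs / QSI for indels,
population allele frequency, ClinVar status, Pfam-domain flag,
PROVEAN/SIFT/PolyPhen calls); annotation itself is out of scope, as are
read alignment, primary variant calling, purity/ploidy inference and SV
calling.

## Filtration cascades

Three cascades, all thresholds strict inequalities and exposed as keyword
arguments (the printed values are defaults, not constants):

1. **Somatic driver**: gene ∈ driver list, QSS/QSI > 15, population
   AF < 0.01, CADD > 2, impact ∈ {HIGH, MODERATE}.
2. **Somatic LOF + LOH**: all genes queried; same quality/AF/CADD rules;
   impact = HIGH only (loss-of-function candidates are by definition
   high-impact); plus somatic-LOH evidence at the locus.
3. **Germline DNA-repair**: gene ∈ repair list, AF < 0.02; HIGH-impact
   variants pass on these alone; missense (MODERATE) variants additionally
   need ClinVar pathogenic/likely-pathogenic, OR Pfam domain plus ≥ 1
   damaging predictor call, OR ≥ 2 damaging predictor calls.

Missing-data semantics: a missing CADD or population AF *passes* its rule
(the score is applied "if available"; absence of evidence is not grounds
for exclusion), a missing QSS *fails* (no quality evidence at all), and a
missing predictor call counts as not-damaging. One predictor call per
variant is assumed; multi-transcript reconciliation is upstream's job.
Indel quality (QSI) travels in the same field as QSS with the same
threshold.

Mutation burden is variants per callable megabase; a sample is
hypermutated iff burden > 10/Mb (strict).

## Clonal partition and clone trees

Presence of a variant in a region is called from read support: unknown if
depth < 10, present if alt reads ≥ 3 and VAF ≥ 0.05, else absent. The
thresholds are conservative for 150× data and configurable. A variant is
**truncal** when no region shows an absence (unknowns tolerated — they are
missing data, not evidence of absence), **private** when present in exactly
one region, **shared** otherwise; variants present nowhere are dropped and
counted. Rule order matters and is applied truncal → private → shared.

Distinct presence subsets become clone-tree nodes under a perfect-phylogeny
assumption: the trunk carries the all-regions subset (the last common
ancestor); every other subset attaches to its smallest observed strict
superset, defaulting to the trunk. Subsets that overlap an accepted clade
without nesting cannot coexist in a perfect phylogeny; the greedy
resolution keeps the higher-count pattern as a clade (count ties broken by
lexicographic region label) and attaches the conflicting pattern directly
to the trunk, where it no longer serves as a parent. Every region gets a
private leaf, reported with count 0 when unobserved, so branch tallies are
complete. VAF is deliberately *not* used for subclonal deconvolution —
clustering is by presence pattern only; no cancer-cell-fraction modeling or
mutation timing is attempted.

## Mutational signatures

Spectra use the standard 96 channels: pyrimidine-centered substitution
class (C>A, C>G, C>T, T>A, T>C, T>G) × 5' base × 3' base, lexicographic
(A,C,G,T), purine-reference sites reverse-complemented. Indels and
contig-edge positions (no full trinucleotide) are excluded and tallied.

Exposures are fitted by supervised non-negative least squares: minimize
‖m/N − Sᵀe‖₂ over e ≥ 0, where m is the spectrum, N its total and S the
catalog; solved with the Lawson–Hanson active-set algorithm
(`scipy.optimize.nnls`), fractions = e/Σe, exposures rescaled to mutation
counts. Supervised fitting against a fixed catalog was chosen over de novo
NMF because the downstream questions are about *named* processes (tobacco,
APOBEC, 5-mC deamination clock, HR deficiency, Pol η) and supervised fits
are deterministic and directly testable against generating weights. Each
clone-tree branch is fitted on its own SNVs; branches under 50 SNVs are
fitted but flagged low-confidence (multinomial noise at that size makes
fractions unstable); empty branches yield an undefined fit.

The bundled catalog is **synthetic** — six shapes constructed in code
(`make_synthetic_catalog`, serialized as `data/signatures_synthetic.tsv`)
that mimic the qualitative structure of the well-known processes: C>A-only
tobacco-like, CpG-concentrated clock-like, TpC-restricted APOBEC-like, a
broad HR-deficiency-like shape, an A/T-5' T>G Pol-η-like shape, and an
exactly flat background. The matrix is full-rank and the first three are
nearly support-disjoint, which is why recovery tests are tight. Fitted
fractions against this catalog are *not* comparable to COSMIC-based
percentages; for real data, load a real catalog.

Smoking metrics from a fit: tobacco fraction f; smoking variant count
round(f·N); smoking variants per PY = count/PY, undefined for never-smokers
(PY zero or missing) — their signature fractions are still reported.

## Allelic model and LOH

For cellularity p, normal genotype with g ∈ {0,1,2} alt copies, tumor state
(c_alt, c_tot):

    E[VAF] = ((1−p)·g + p·c_alt) / ((1−p)·2 + p·c_tot)

NaN when the denominator vanishes (p = 1, c_tot = 0). At a germline-het
site (g = 1) the retained-diploid expectation is exactly 0.5 for any p,
which is what makes VAF shifts informative about allele loss.

LOH calling scores each het site's tumor (alt, total) counts by binomial
log-likelihood under the retained model versus the best of four loss
states: hemizygous loss of either allele (c_tot = 1) and copy-neutral LOH
in either direction (c_tot = 2). Expected VAFs are nudged by the sequencing
error rate (default 0.001) so boundary states (VAF 0 or 1) remain proper
likelihoods. A site is LOH when the log-likelihood ratio exceeds 3.0 (~e³
odds) and indeterminate below 20× depth; both knobs are configurable and
were chosen for 150× data — at that depth and purity 0.6 the measured
sensitivity is ≈ 0.98–0.99 with specificity ≥ 0.998. Restricting to these
four loss states covers hemizygous and copy-neutral LOH without requiring
allele-specific copy-number inference, which is out of scope; subclonal
LOH and higher-ploidy states will blunt sensitivity.

CNV candidates keep segments with copy number 0 or > 6 and length > 20 kb
(strict). Inter-region heterogeneity rasterizes each profile onto fixed
bins (segment chosen per bin by midpoint coverage, falling back to largest
overlap, then leftmost — which makes the distance invariant to splitting a
segment into equal-CN pieces) and averages |log₂((CN_a+0.5)/(CN_b+0.5))|
over bins covered in both regions; the 0.5 pseudocount keeps homozygous
deletions finite. Bins default to 1 Mb at genome scale; the pipeline uses
5 kb on the 100 kb synthetic reference. The metric is a package choice —
there is no canonical heatmap distance to match.

## Statistics

Welch's t (unequal variances, Welch–Satterthwaite df) and the unpaired
pooled-variance Student t, both two-tailed, are implemented from the
formulas; the p-value uses scipy's t survival function and the
implementation is cross-checked against `scipy.stats.ttest_ind` in the
tests. The association compares patients with ≥ 1 passing germline repair
variant against the rest on smoking fraction and burden (Welch) and
smoking variants per PY (Student; never-smokers excluded there because the
metric is undefined, but included for signature fractions). Fewer than two
patients per group raises an insufficient-data error. No multiple-testing
correction is applied across the three metrics by default (they are
reported as single tests); a Benjamini–Hochberg helper exists.

Measured calibration: empirical type-I error 0.046–0.050 at α = 0.05
(10,000 null simulations, n = 10 + 10), null p-values KS-uniform, and power
1.0 for the simulated effect (tobacco fraction 0.5 vs 0.2, sd 0.1,
n = 10 + 10, 100 replicates).

## Synthetic-data generator

Defaults encode the emulated study conditions: 3 regions/patient, 150×
tumor depth (germline ~35×), cellularity uniform on (0.4, 0.9) — the real
protocol required > 15% cellularity and deep-sequenced those samples —
pack-years uniform on (10, 60), truncal fraction 0.8 (the dominant-trunk
architecture the clone trees exhibit), sequencing/artifact error 0.001 per
base (the upstream pipeline's call error model is not published; this is a
generator choice), and 1000 somatic variants per patient on a 100 kb
reference — a desk-scale problem size whose per-branch SNV counts (~100+)
keep signature fits meaningful. The truncal count is round(truncal_fraction
× n_somatic) (half-up, so the partition is exact and testable); the private
remainder is spread evenly across regions in label order.

Positions are sampled uniformly *without replacement* from interior
positions whose trinucleotide matches the drawn channel (channels drawn
multinomially from catalogᵀ·exposures), so every variant has a full,
consistent context. Read counts: total ~ Poisson(depth), alt ~
Binomial(total, E[VAF] error-adjusted), with absent sites at the error rate
alone. Indels (default 5% of variants) are 1-bp insertions for counting
purposes only. Germline-mutant patients (default probability 0.5) receive
one repair-gene variant constructed to pass the germline cascade (rotating
among the three disjuncts) plus decoys that fail it, and draw their truncal
tobacco fraction from N(0.5, 0.1) versus N(0.2, 0.1) for wild-type — the
gene-by-environment effect downstream stages must recover. Each patient
gets a four-segment CNV layout with one candidate-event slot (CN 0/7/8,
shared or private) and one LOH slot (hemizygous or copy-neutral, shared or
private); a panel of germline-het SNPs feels those LOH states through the
expected-VAF model. Somatic SNV read counts assume diploid-het state
regardless of the CNV layer (the layers are deliberately decoupled).

Everything derives from one seed through `numpy` `SeedSequence` spawning;
identical config + seed reproduces byte-identical output files.

**What passing tests show and what they do not.** The generator draws reads
from exactly the binomial/Poisson model the LOH caller assumes, signatures
from exactly the catalog the fitter uses, and presence patterns with no
contamination, mapping artifacts, subclonal structure within regions, or
purity mis-estimation. Recovery results are therefore consistency checks of
the implementation under its own model — they bound implementation error,
not real-world error. Numbers that depend on the real cohort's controlled-
access sequencing data (per-case burdens, signature percentages, cohort
p-values) are not reproducible here and are not claimed.

## Numerical choices and degenerate inputs

- NNLS is scale-free (spectrum normalized before fitting); empty spectra
  raise an undefined-fit signal rather than returning zeros.
- Half-up rounding (floor(x+0.5)) wherever a count is derived from a
  fraction, avoiding banker's-rounding surprises in partitions.
- Tie-breaks are lexicographic on region labels throughout the tree build,
  making outputs independent of input order; permuting regions relabels
  branches but never changes counts.
- Zero-depth sites report VAF as missing; all-absent variants are dropped
  with a logged count; manifest counts satisfy input = classified + dropped
  at every stage.
- Multi-allelic VCF records are rejected with instruction to pre-split;
  coordinates are 1-based inclusive end to end (CNV tables accept standard
  BED via `--bed0`).

## Known limitations

- No subclonal deconvolution, CCF estimation or mutation timing; the
  perfect-phylogeny conflict rule is greedy, not exact character-compatible.
- The bundled catalog is synthetic; absolute signature fractions are not
  comparable across catalogs.
- LOH calling assumes the provided cellularity is accurate and the site is
  germline-heterozygous; no segment-level aggregation beyond the recovery
  report's majority vote.
- The somatic filters consume annotations as given; no re-scoring, no
  transcript reconciliation, and no manual curation step.
- Indels are placeholders for counting; no indel signatures or realism.
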