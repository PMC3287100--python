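# Methods

`codonuse` quantifies synonymous codon usage bias in sets of protein-coding
sequences and asks how much of that bias is explained by nucleotide
composition (mutation pressure) versus within-family codon preference
(translational selection, e.g. a virus adapting to its host's tRNA pool).
This note records the statistical machinery, the modeling assumptions, the
defaults, and the design choices that were genuinely open.

## Statistics

**Codon counting.** A validated coding sequence is decomposed into in-frame
triplets. Codons containing any symbol outside {A, C, G, T} are flagged
ambiguous and never counted. Stop codons are tallied in the 64-cell count
table (so the table is a faithful record) but every statistic below ignores
them: stops carry no synonymous-usage information. For GenBank input the
default convention concatenates all annotated CDS features of a record,
each read in its own frame. In genomes with overlapping reading frames
(hepadnaviruses are the motivating case) a genomic nucleotide then
contributes once per gene spanning it — the frame-dependent convention
codon statistics require. The alternative (`per-cds`) is exposed for users
who prefer gene-level tables.

**Composition.** Overall percentages (T%, C%, A%, G%) are computed over all
three positions of counted sense codons. The synonymous third-position
pool (T3% … G3%, and GC3) is restricted to the 59 synonymous sense codons —
ATG, TGG and stops are excluded, because their third position is not free
to vary synonymously. GC12 pools positions 1 and 2 of all sense codons.
When a table contains no synonymous sense codon the third-position
quantities are reported missing, not zero.

**RSCU.** For amino acid *i* with *nᵢ* synonymous codons, total count
*Xᵢ* and codon count *xᵢⱼ*,

    RSCU_ij = x_ij · n_i / X_i.

Values are independent of amino-acid composition and sequence length; a
family's values sum to its degeneracy, and 1.0 means equal, random usage.
Families with *Xᵢ* = 0 yield *undefined* entries (NaN), which is distinct
from RSCU 0 (present family, unused codon). Following the conventional
thresholds, RSCU > 1.6 (strict) is called over-represented and RSCU < 0.6
(strict) under-represented; boundary values are "normal".

**ENC (effective number of codons).** Per amino-acid family with *n*
occurrences and within-family frequencies *pⱼ*, the homozygosity

    F = (n · Σ_j p_j² − 1) / (n − 1)

is computed for families with *n* ≥ 2; values F ≤ 0 are discarded as
unusable rather than clamped (they arise at small *n* under near-uniform
usage and would otherwise blow up the reciprocal). Class means F̄ₖ average
F over contributing families of degeneracy k ∈ {2, 3, 4, 6} (9, 1, 5 and 3
families respectively), and

    ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,

capped at 61. The estimator spans 20 (exactly one codon per amino acid) to
61 (all synonymous codons equally used; finite samples overshoot slightly,
hence the cap). Isoleucine is the lone 3-fold family and is often sparse,
so a missing F̄₃ is imputed as (F̄₂ + F̄₄)/2 — standard practice for this
estimator; a missing F̄₂, F̄₄ or F̄₆ cannot be imputed defensibly, so ENC
is then reported missing together with per-class diagnostics.

**Expected-ENC curve.** Under third-position compositional constraint
alone, with s = GC3 as a fraction,

    ENC_exp(s) = 2 + s + 29 / (s² + (1 − s)²).

Strains on or near the curve are compatible with mutation pressure as the
sole force; strains below it show additional bias (selection). The curve
assumes composition symmetric within GC (G ≈ C, A ≈ T at the third
position) — the same symmetry the null generator uses (below).

**PCA.** Each strain is a 59-dimensional RSCU vector (columns in fixed
alphabetical DNA order). The matrix is column-centered and decomposed by
full SVD. Default scaling is `covariance` (no per-column standardization):
RSCU values already share a dimensionless scale, and standardizing inflates
the influence of low-variance codons; `correlation` scaling is available
as a flag and recorded in output metadata. Undefined cells are imputed at
the neutral value 1.0 with a warning — imputing 0 would manufacture strong
apparent bias in families a strain simply never uses. Component signs are
fixed by requiring the largest-magnitude loading of each component to be
positive, making scores reproducible across platforms; interpretations
should rely on configuration (distances, groupings), not raw signs.

**Correlations.** Pearson product-moment correlation with a two-sided p
from the t-distribution on n − 2 degrees of freedom. The suite correlates
each overall base percentage with each synonymous-third-position
percentage (16 pairs), plus GC12–GC3 and, when ENC values are supplied,
ENC–GC3. A Spearman option exists for sensitivity analysis. Zero-variance
inputs yield missing r rather than an error.

**Host comparison.** The bundled `human-Table2` reference is a frozen
published human RSCU column; freezing printed values keeps the comparison
download-free and stable. A codon is *coincident* when virus and host fall
on the same side of the neutral value 1 (ties at exactly 1.0 side with
"preferred or neutral"), otherwise *antagonistic*; this per-codon rule is
deliberately sharper than prose descriptions of "similar patterns", which
tend to be internally inconsistent at the codon level. Codons with virus
RSCU > 1 and host RSCU < 0.6 are listed as highly-used-against-host — the
clearest antagonistic signature. A per-family flag reports whether the
argmax (preferred) codon matches. The bundled pooled viral column from the
same published table is exposed only as a plain vector
(`bundled_virus_rscu`): its printed values do not satisfy the family-sum
identity exactly (typesetting artifacts in the source), so it serves
worked examples, not validation-grade reference duty.

## The synthetic generator

The generator draws an amino-acid sequence i.i.d. from a profile (default:
uniform over the 20 amino acids), then chooses each residue's codon within
its family from the mixture

    (1 − w) · P_mut(codon | family) + w · P_sel(codon | family),

where P_mut is proportional to the product of per-position nucleotide
probabilities and P_sel to the selection model's target RSCU. Amino-acid
composition and synonymous preference are therefore controlled
independently, which is what makes RSCU's invariance properties testable.
Stop codons are never generated internally; one terminal stop drawn from
the mutation model closes each sequence and exercises the reader's
stop-exclusion logic. Output is deterministic given the cohort seed.

The null mutation model used for curve geometry places G = C = s/2 and
A = T = (1 − s)/2 at the third position with uniform positions 1–2 — the
symmetric composition the expected-ENC curve is parameterized by. Cohorts
for curve checks sweep s over [0.2, 0.8] (50 strains, 10,000 codons each):
large enough that estimator bias is small, small enough to run in seconds.
Under this null the mean absolute vertical deviation from the closed-form
curve is below 1 ENC unit; mixing in a concentrated selection model at
w = 0.8 places essentially every strain below the curve.

Parameter recovery is assessed on the pooled count table of a cohort (10
strains × 100,000 codons for the 0.05 max-deviation check). Pooling is the
operative choice: at 100,000 codons a single strain's family totals are
about 5,000, and binomial noise alone then exceeds 0.05 for 6-fold
families, so the pooled table is the unit at which that tolerance is
statistically meaningful.

What the generator does **not** emulate: phylogenetic correlation between
strains (cohort members are independent), overlapping-ORF constraints,
site-wise selection heterogeneity, and dinucleotide/CpG effects. Passing
tests therefore demonstrate correctness of the statistics and the
geometry of the mutation-vs-selection diagnostic under an idealized
cohort, not that real viral data will be this well-behaved.

## Numerical and interface choices

* Percentages are printed at 2 decimals in TSV artifacts; full precision
  is retained in `results.json`.
* ENC is compared against an independent brute-force evaluation of the
  homozygosity formulas to 1e-9 in the test suite; the two
  implementations share only the formula, not code.
* The pipeline computes everything before writing anything, so a failing
  stage (tagged `[stage]` in the error) leaves no partial output.
* The packaged 58-strain manifest reproduces its published source
  verbatim, including one duplicated accession and one truncated
  accession; both are flagged rather than silently corrected.
* Reproducing the published per-strain tables from the original GenBank
  records requires downloading them (out of scope for the tested path)
  and depends on an under-specified whole-coding-sequence convention; the
  default concatenate-all-CDS convention is this package's declared
  choice, and the manifest plus the frozen reference tables make such a
  comparison straightforward for a user with the records on disk.

## Known limitations

* ENC variant choices (rare-family handling, the F ≤ 0 discard, the F̄₃
  imputation) follow one defensible reading of the classical estimator;
  other published implementations differ in the second decimal on short
  sequences.
* The concordance rule is a per-codon surrogate for an inherently fuzzy
  "pattern similarity" notion; the per-family preferred-codon flag is the
  coarser, more robust summary.
* PCA variance fractions on small cohorts (< ~10 strains) are noisy; the
  collinear and group-separation tests use constructed geometry precisely
  because real-data fractions are not sharply reproducible.
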