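# Methods

This note documents the models, conventions and design choices behind
`mirsnp`, in the order the pipeline runs them.

## Seed-match model

A mature miRNA's seed is bases 2–8 from its 5′ end. Because the miRNA
pairs the mRNA antiparallel, a site on the sense-strand 3′-UTR reads, 5′→3′,
as the complements of miRNA positions 8 down to 2, optionally followed by
an A opposite position 1. The scanner anchors on the hexamer core (the
bases opposite positions 2–7), then inspects the one base 5′ of the core
(the m8 match) and the one base 3′ of it (the A1 adenosine) to type the
locus as 8mer, 7mer-m8, 7mer-A1 or 6mer; exactly one site, of the
strongest type, is reported per core locus. Pairing is strict
Watson–Crick: G:U wobbles are mismatches. This binary pairing model — no
thermodynamics, no 3′-supplementary pairing, no context scoring — is
deliberate: the discovery question is whether an allele makes or breaks
canonical pairing, and the downstream effect classification needs exactly
that dichotomy. Evolutionary conservation is never computed; if a
conserved-site database provides a per-position flag track it can be
AND-ed with the scan, and by default "conserved-class" means site type in
{8mer, 7mer-m8, 7mer-A1} (6mers excluded).

Coordinates are 0-based half-open everywhere inside the package; 1-based
conventions appear only when reading VCF and writing BED. Sequences are
held internally in DNA alphabet (U folded to T); miRNAs are presented in
RNA.

### Allele scoring and the shared-core subtlety

`seed_mismatch_count` counts unpaired seed positions for a given allele.
miR-96-5p and miR-182-5p — like any two miRNAs of neighbouring families —
share their first seven bases and differ at position 8, so at one shared
locus only one of them can pair position 8; the other necessarily holds a
7mer-A1-register site whose position 8 is unpaired *by site definition*.
The default count therefore runs over the positions the site type claims
to pair (2–8 for m8-anchored sites, 2–7 for A1/6mer sites), which is what
"fully complementary" means site-by-site. The strict 7-nt window count is
available as `span="m8"`, for which a count of 0 is equivalent to the
site's 7-mer equalling the reverse complement of the seed.

A variant is classified against its ancestral allele (default: the VCF
reference, overridable by a sidecar table, since ancestral and reference
alleles genuinely differ for some variants): site-disrupting when the
ancestral allele pairs perfectly and the derived allele does not,
site-creating in the reverse case, site-preserving when both pair, neutral
when neither does. Only single-nucleotide variants are scored; indels
inside a 6–8-nt site would need re-alignment and are rejected with an
explicit error. Minor-allele frequencies are population inputs and are
never recomputed.

The repaired-miRNA design substitutes the single miRNA base opposite the
SNP with the Watson–Crick complement of the target allele. It refuses
positions outside the seed-opposing span (2–8) and no-op "repairs" toward
an allele the wild type already pairs. The defining identities — zero
mismatches against the target allele, and mismatch counts that swap roles
between the wild-type and repaired miRNA across the two alleles — are
property-tested on planted instances.

## Literature cutoff

The publication-count cutoff is the median count among genes with at
least one publication. Computing the median over the literature-positive
subset (rather than all genes) avoids a zero-dominated cutoff; an
even-cardinality median is the mean of the central pair rounded half up,
because the cutoff is applied as an inclusive integer threshold. Both
choices are package decisions where the procedure's description was
ambiguous.

## Association stage

Expression arrives as normalized RNA-seq-like counts and is
log₂(x+1)-transformed by default before correlation and regression (the
raw scale is heavy-tailed; a flag disables the transform). Correlation is
the product-moment r with a two-sided p from the t transform, pairwise-
complete over missing values, and undefined (an error) for zero-variance
input.

The lymph-node analysis is a nested linear-model F-test with target-gene
expression as the response: reduced model `y ~ T`, full model
`y ~ T + node`, where T is pathologic tumour stage 1–4 and the node term
is either pathologic N stage 0–3 or the H&E-positive node count. Ordinal
stages are coded as integer linear trends — the minimal faithful coding of
an ordinal covariate in an ANOVA. Samples with distant metastasis (M1) or
missing M status are excluded before fitting. A constant node term returns
F = 0, p = 1 rather than an error. Display residuals are the reduced-model
residuals divided by their sample standard deviation (ddof = 1), so the
returned vector has unit sample variance; a perfect fit returns zeros.

### Power

For the two-sided 1-df additive genotype test with per-allele effect β in
phenotype-SD units and effect-allele frequency p (genotype variance
2p(1−p) under Hardy–Weinberg), the noncentrality is
λ = n·β²·2p(1−p)/(1 − β²·2p(1−p)) and power is the upper tail of the
noncentral χ²(1, λ) at the central χ² critical value. β²·2p(1−p) ≥ 1 is
rejected as an invalid standardized effect. The Monte-Carlo cross-check
draws binomial(2, p) genotypes and a phenotype with raw slope
β/√(1 − β²·2p(1−p)) on unit noise — the slope at which the *standardized*
effect equals β — then applies the two-sided slope t-test; both routes
thus share one effect-size definition and agree within Monte-Carlo error
(max gap < 0.01 at 20,000 replicates per cell on the tested grid). At the
reference design n = 460, p = 0.40, β = 0.1, α = 0.05 the closed form
gives 31.9% — an underpowered design, consistent with published power
tools, whose exact effect-size conventions differ enough that only the
qualitative 20–35% band is asserted.

## Synthetic data

The generators are pure functions of (parameters, seed) — byte-identical
on regeneration — and each ships a truth object sufficient to score any
stage exactly.

* **UTRs**: i.i.d. uniform-base sequences (uniform composition makes the
  chance-match expectation analytic: (L−5)·4⁻⁶ core matches per UTR per
  miRNA), lengths uniform on 150–300 nt, laid out with gaps across five
  synthetic chromosomes with random strand. Sites are planted at recorded
  offsets with one guard base each side so they scan as exactly the
  planted type.
* **Variants**: background SNVs at 0.022 per base (≈5,000 over 1,000
  genes) with MAF ~ Uniform(0.01, 0.40) — a common-variant panel whose
  frequencies stay below the planted disruptor's 0.43, making the planted
  SNP the top-frequency candidate by construction, which is the study
  condition the MAF-ranked prioritization presumes. The disruptor is
  planted inside a seed-site core with the reference/ancestral allele
  fully complementary; because miRNAs sharing a hexamer core share the
  site, the truth lists every miRNA whose site covers the SNP.
* **Publication counts**: zero-inflated shifted-geometric counts — zero
  with probability 0.6, otherwise geometric with success probability set
  so the nonzero median is 4 (the realized median equals the target with
  overwhelming probability for gene sets of a few hundred or more).
* **GO annotations**: the query term ("cytoskeleton organization",
  GO:0007010) assigned per gene with probability 0.1, decoy terms
  sprinkled in; forced genes guarantee the planted candidate survives the
  filter.
* **Cohort**: a latent trivariate normal for (target, miR-96, miR-182)
  with correlations (−0.3, −0.2) to the target and +0.5 between the
  co-transcribed miRNAs, mapped to counts as 2^(8+2z)−1 so the log₂(x+1)
  analysis recovers the latent correlations exactly. Pathologic T is
  multinomial (0.25/0.45/0.20/0.10) and independent of expression; N is an
  ordinal discretization (marginals 0.55/0.25/0.13/0.07) of
  0.4·z_T + node_effect·z_target + ε, so node_effect = 0 gives exact
  conditional independence and hence an exact type-I null for the F-test
  — the cost being that "controlling for T" removes no confounding in
  synthetic data. Node counts are Poisson with N-dependent rates
  (0.2/1.5/4/9); M1 prevalence is 2% with 1% missing. The default planted
  node_effect of 0.3 makes the added-term test reject at p ≤ 0.005
  essentially always at n = 1,000.
* **Reporter assay**: normalized ratios with means 1 − repression
  (repression 0.30 and 0.70 for the permissive allele under miR-96 and
  miR-182 respectively; 0 for the disrupted allele, target deletion, and
  control miRNA) and Gaussian replicate noise (SD 0.05), truncated
  positive.

What passing on synthetic data does *not* show: real UTRs are not i.i.d.
uniform (composition bias, repeats), real MAF spectra are not bounded away
from the planted frequency, real cohorts carry confounding between tumour
size and expression, linkage disequilibrium is absent, and the
literature/GO layers are statistical sketches. The synthetic study
validates the machinery and its calibration, not any biological claim.

## Worked-example reference data

The mature miRNA sequences bundled in `refdata` are the canonical miRBase
entries (mouse miR-96 identical to human; mouse miR-182 differing by two
3′-end nucleotides, counted as global-alignment edit distance). The
*PALLD* 3′-UTR fragment is a labelled synthetic reconstruction: flanks and
coordinates are placeholders, while the site core realizes the published
constraints — overlapping miR-96/miR-182 sites, a C/G SNP opposite a seed
G of both miRNAs (position 5), perfect pairing under C, one mismatch under
G. The stronger reporter repression by miR-182 motivated assigning it the
8mer register and miR-96 the overlapping 7mer-A1.

## Numerical and scale choices

Intersection uses an interval tree (the quadratic double loop is kept as
the test oracle). Candidate ordering is descending MAF with (variant id,
miRNA name) lexicographic tie-breaks, so outputs are deterministic; two
runs with the same configuration and seed are byte-identical. Problem
sizes in the test suite and acceptance script (1,000-gene studies,
100–200 cohort replicates, 20,000 Monte-Carlo replicates per power cell)
were chosen to keep full runs in the tens of seconds while leaving
sampling error well inside the asserted tolerances.

## Known limitations

Only canonical seed classes are scanned (no wobble, bulge, or
3′-compensatory sites); indels are out of scope; GO filtering is exact
term match without ontology-graph propagation; the ordinal-linear coding
of staging cannot capture non-monotone stage effects; and the funnel's
absolute counts on real 2013-era databases are not reproducible from this
package — only the funnel's structure and the per-record scoring are.
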