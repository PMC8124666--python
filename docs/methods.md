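# Methods

`clonepair` analyses intra-tumour heterogeneity in a paired-biopsy design:
two spatially separated tumour samples (TU1, TU2) and one matched normal per
patient, sequenced deeply (optionally with unique molecular identifiers).
This note describes the models and procedures implemented, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical choices that matter.

## UMI consensus

Reads sharing an identical UMI and identical leftmost mapping position are
treated as copies of one DNA molecule.  The consensus rule is strict
unanimity: position *i* is called base *b* only if every read in the family
carries *b* at *i*; any disagreement — including a literal `N` in one read,
which cannot certify agreement — masks the position with `N`.  There is no
minimum family size (a singleton passes through unchanged), no UMI
edit-distance clustering, and no base-quality weighting.  A majority-vote
mode exists behind a flag (default off) for comparison only.

Under a per-base substitution error rate *e* (uniform over the three
alternative bases), a family of size *k* is unanimous at a position with
probability `(1-e)^k + 3(e/3)^k`, and a *wrong* unanimous call requires all
*k* reads to err identically — an `(e/3)^k`-order event, which is why the
consensus miscall rate is far below the single-read rate for `k >= 2`.  Both
facts are verified empirically and by enumeration in the tests.

## Variant filters

* **FFPE artifact filter.** Formalin fixation deaminates cytosine, creating
  spurious C>T (reverse strand: G>A) substitutions at low allele fraction.
  A substitution of either type with VAF strictly below 0.10 is removed.
  The inequality is strict (a call at exactly 10% is kept); the default
  threshold 0.10 reflects the 1–10% VAF range in which such artifacts
  concentrate.  Indels are exempt: deamination does not produce them.  The
  filter is strand-agnostic and applied per sample independently — an
  artifact arises in one FFPE block, not both.
* **Copy-number-neutrality filter.** A germline SNP with normal-sample VAF in
  [0.40, 0.60] (inclusive) is heterozygous; if its VAF in the tumour sample
  falls strictly outside those bounds the locus is allelically imbalanced,
  indicating a local copy-number change.  Somatic calls within 4000 bp
  (inclusive; distance `|pos_variant − pos_SNP|`, 1-based coordinates, same
  chromosome) of an imbalanced SNP are removed, leaving the
  copy-number-neutral set required by clone assignment.  The two bounds
  clauses are deliberately complementary (inclusive membership, strict
  exclusion) so they partition VAF space; "within 4000 bp" is read
  inclusively, with both boundary cases pinned by tests and configurable.
* **Impact filter.** HIGH- and MODERATE-impact variants are kept; LOW-impact
  variants are kept except silent ones (synonymous, start-retained,
  stop-retained); MODIFIER-class variants (intronic, UTR, upstream) are
  dropped.  Silent variants still inform clone inference upstream — the
  filter is applied only when building entity–clone matrices for the
  exclusivity test, where only potentially phenotype-changing mutations are
  of interest.

The FFPE and copy-number predicates are independent per-variant tests, so
the two filters commute and are idempotent (property-tested).

## Shared/private classification

Variants are keyed by (chrom, pos, ref, alt); indel normalisation
(left-alignment) is assumed done upstream.  A key present in both tumour
samples' post-filter call sets is *shared*; present in one, *private* to it.
No VAF re-thresholding or read-evidence rescue happens at merge time:
detection thresholds belong to calling and filtering.  Cohort summaries
report per-patient counts, the mean private fraction, the number of patients
with at least one private mutation, per-gene patient frequencies
(patient-level indicator, so several hits of one gene count once), and
convergence events — genes hit by two or more distinct mutations whose
biopsy-presence patterns differ, the paired-biopsy signature of convergent
evolution.

## Clone assignment

A deliberately light-weight stand-in for full phylogenetic latent-feature
inference.  Mutations of a patient live in the 2-D space of per-sample VAFs;
cluster *c* has centre (θ<sub>c1</sub>, θ<sub>c2</sub>) and alt counts are
Binomial(depth<sub>s</sub>, θ<sub>cs</sub>).  EM with k-means++ seeding is
restarted `n_restarts` times per K (default 20, the customary
multiple-restart practice for clone-tree tools); K is selected over a range
(default 1–4) by BIC, `−2 logL + (3K−1) ln n`, ties toward smaller K for
parsimony and determinism.  All randomness flows from one seed via
`SeedSequence(seed, spawn_key=(K, restart))`, so the best-of-*n* restarts is
reproducible and non-decreasing in *n*.

Because input is pre-filtered to copy-number-neutral loci, the cancer cell
fraction of a cluster is CCF = min(1, 2θ) per sample.  Clone fractions are
reported under a linear-chain assumption: clusters sorted by mean CCF
(largest = ancestral), per-sample fractions are the increments of the sorted
CCFs, and the normal-cell row is 1 − CCF<sub>max</sub>.  Negative increments
(pigeonhole violations — the chain assumption contradicted by the data) are
reported on the profile, never silently corrected; topology inference is out
of scope.  Two samples identify clone fractions only for chain topologies;
for branched truths the cumulative CCFs remain the identifiable quantities.

Numerical details: binomial rates are clipped to [1e-6, 1−1e-6]; EM stops at
a log-likelihood gain below 1e-8 or 500 iterations; mutations with zero
depth in both samples are excluded with a warning.

## Clonal exclusivity

Two entities (genes or pathways) are clonally exclusive in a patient when
both clone sets are non-empty and disjoint.  The cohort statistic T counts
exclusive patients among those where both entities are altered
("comparable"); with fewer than `min_patients` (default 2, the smallest
cohort in which recurrence is observable) the pair is untested.  The null
redraws each entity's clone set uniformly at its observed size from the
patient's K clones, giving per-patient exclusivity probability
`C(K−|A|, |B|) / C(K, |B|)` (symmetric; zero when |A|+|B| > K).  T is then
Poisson-binomial; its tail P(T ≥ t<sub>obs</sub>) is computed exactly by
convolution, so p-values are deterministic.  A seeded permutation mode
cross-checks the exact tail.  Benjamini–Hochberg q-values are computed
across the tested family only.  Clones are unordered labels — a mutation
counts in its assigned clone, matching the entity-by-clone matrix
representation; an optional helper propagates alterations to descendant
clones when a tree is available.

This conditional null replaces the likelihood-ratio machinery of dedicated
exclusivity tools that additionally estimate patient-specific background
rates; conditioning on set sizes and clone counts controls the two dominant
confounders (entity mutation burden and clone number) but pools no
information across pairs, so its p-values are generally more conservative.
The bundled two-patient worked example (synthetic stand-in matrices
reconstructed from a published clone-assignment description) illustrates the
consequence: both pathway pairs are exclusive in both patients and rank
first among all pairs, with exact p = (1/3)(2/3) = 2/9 — strong for two
patients under this null, but far from the headline significance a
background-rate-pooling test reports on a 16-patient, 877-pathway cohort.

**Discreteness and study design.**  With few patients the achievable
p-values are coarse.  The calibration study therefore uses 8 patients with
K = 3 and singleton sets, where the 5%-level rejection region is exactly
T = 8 with null mass (2/3)^8 ≈ 0.039 — close enough to the nominal level to
measure calibration meaningfully; most smaller configurations make the test
so conservative that no rejection region below 0.05 exists.  The power study
plants an always-exclusive pair in 4 patients with K = 4 and clone sets of
size two.  Singleton sets would be uninformative here: with |A| = |B| = 1
and K = 4, disjointness is the null-favoured outcome (P = 3/4), so no
evidence can accumulate; with size-two sets each patient contributes
P<sub>excl</sub> = 1/6 and four exclusive patients give p ≈ 7.7×10⁻⁴.

## Over-representation analysis

A gene enters the expressed background if it accumulated at least 10
fragments (inclusive) across the compared tumour and normal samples.  For a
pathway with m background members and overlap k with the n_de DE genes, p is
the exact hypergeometric upper tail P(X ≥ k) on a background of n_bg genes;
BH q-values across tested pathways; pathways without background members are
skipped; DE genes outside the background are dropped with a warning.  DE
calling itself is an input contract — the module consumes gene lists, never
count matrices.  One-sided over-representation and BH were chosen as the
standard pairing; no pathway-hierarchy pruning is performed.

## Synthetic cohorts

The generator emulates the study design the analysis assumes, with full
ground truth:

* **Clone structure.**  K ~ uniform on a small range (default 2–4); the
  clone tree is a uniform random labelled rooted tree (topology enters the
  data only through cumulative clone fractions; a chain option exists for
  identifiability studies).  Each non-root clone is absent from one randomly
  chosen sample with probability 0.5 — exact zeros are what make mutations
  truly private, and the resulting cohort mean private fraction (roughly
  25–50% depending on K) is in the range reported for paired-biopsy kidney
  cancer cohorts.  Per sample, the normal-cell fraction is
  1 − purity·U(0.85, 1), respecting the ≥70%-tumour-content inclusion rule
  (purity default 0.7), and the tumour mass is split over present clones by
  a symmetric Dirichlet (optionally floored).
* **Read counts.**  A mutation assigned to clone c has expected VAF
  0.5·Σ<sub>c′∈subtree(c)</sub> F[c′, s] (diploid, copy-number neutral);
  observed alt counts are Binomial(Poisson(depth), VAF), depth default 500
  in the spirit of deep panel sequencing.  A `noise="none"` mode replaces
  draws with floored expectations (floor, so discretisation never crosses a
  threshold from below) for noise-controlled tests.
* **Artifacts and CNV signal.**  FFPE artifacts are C>T/G>A calls with true
  VAF ~ U(0.01, 0.10), present in one sample only (default 5 per sample).
  CNV regions (default two 20-kb intervals) contain germline SNPs whose
  tumour VAFs are displaced by at least 0.12 from 0.5; SNPs elsewhere draw
  all VAFs inside [0.44, 0.56].  A configurable fraction of somatic
  mutations (default 15%) is placed inside CNV regions to give the
  copy-number filter true positives; all other loci keep a >4-kb buffer from
  CNV regions so the filter's negative side is also testable.
* **Planted exclusivity.**  For each planted pathway pair, member-gene
  mutations are assigned to two disjoint clone sets, and those genes are
  excluded from the random gene pool.
* **Deliberate simplifications.**  True somatic substitutions never use the
  C>T/G>A channel — it is reserved for artifacts so truth labels are
  unambiguous and the no-artifact negative control ("filters remove
  nothing") is exact.  Real data have no such separation, so passing these
  tests shows the filters implement their rules correctly, not that FFPE
  artifacts are perfectly separable in practice.  Likewise there is no
  sequence context, no mapping error, no subclonal copy number beyond the
  imbalanced-SNP signal, and no indel error model.

UMI read families are simulated per locus: molecule sequences of length 30
with the true base at the mapping position, geometric family sizes
(mean 3 — a typical panel-seq figure; the real distribution is a config
knob), independent per-base substitution errors.

## Reproducibility and problem sizes

Per-patient generators are seeded as `SeedSequence([seed, crc32(patient)])`,
so a patient's data are independent of cohort order and size.  The pipeline
fans one global seed out to per-patient clone-fit seeds by stable hashing;
rerunning a fixed configuration is byte-identical (hash-tested).

Validation studies run at: 50 replicates for clone recovery (3 chain clones,
15 mutations/clone, depth 500, 20 restarts — accuracy is Hungarian-matched);
1000 (test) / 3000 (acceptance script) null cohorts for calibration, the
larger figure to stabilise the rate estimate under arbitrary seeds; 200
replicates for power; 300 random instances each for the ORA and
Poisson-binomial enumeration oracles.  These sizes keep the full suite
around half a minute while leaving Monte-Carlo margins of ≥2.5 standard
errors on every asserted band.

## Known limitations

* Clone fractions are only identifiable from two samples under a chain;
  branched topologies are summarised by cumulative CCFs with violations
  flagged, not resolved.
* The exclusivity null conditions on observed set sizes; it does not model
  per-patient background rates of exclusivity, making it conservative
  relative to likelihood-ratio approaches that pool across pairs.
* The VCF layer targets the subset of VCF 4.2 the pipeline emits (AD/DP,
  ANN), not full htslib-grade compliance (no BCF, phasing, or symbolic
  alleles); functional annotation is consumed, never computed.
* Family-size and error models for UMI simulation are idealised
  (independent, uniform substitutions); no paired-end reconciliation or
  quality-aware consensus.
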