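# Methods

This note documents the statistical procedures `sfpage` implements, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
edge cases.

## Catalog and age classes

A catalog is the union of two independently derived candidate gene
lists; each record keeps both source flags so the intersection
("conservative set") is always recoverable. Gene identifiers are
opaque strings matched exactly and case-sensitively — symbol/ID
aliasing is never silently resolved; synonyms must be mapped
explicitly upstream. Age classes are the five phylostratigraphic
strata A–E (oldest to youngest). Genes absent from the age table stay
`unassigned`: silently if they are on the declared exception list
(e.g. pseudogenes, which age-dating frameworks skip), with a warning
otherwise. Unassigned genes are excluded from every age-stratified
statistic.

Cross-validation treats an independent deep-ortholog call (a 1-to-1
ortholog in a lineage that split before the young strata) as evidence
that a gene's class should be old ({A, B, C} by default); a checked
gene assigned to D/E counts as a discrepancy and the report carries
the exact ids. Discrepant genes keep their table ages downstream
(configurable): the validation quantifies reliability, it does not
adjudicate which call is right.

Paralog collapse keeps one representative per group — the member with
the most non-missing annotations, ties broken lexicographically — so
the operation is deterministic and idempotent. When group members
disagree on age the oldest class is kept (a duplicate's parent lineage
is at least as old as any copy), with a warning.

## Composition test

Observed class counts are compared to expectations `E_c = p_c·N` from
genome-wide background proportions with the chi-square goodness-of-fit
statistic (df = k − 1). Per-class post hoc tests use adjusted
standardized residuals `z_c = (O_c − E_c)/√(E_c(1 − p_c))`; the
(1 − p_c) factor accounts for the multinomial constraint so z is
asymptotically standard normal. Two-sided normal p-values are BH
corrected across the k classes of one test — the smallest defensible
multiple-testing family; wider families can be formed by adjusting
externally. No continuity correction is applied (counts here are in
the tens to hundreds). A 2 × k independence variant against raw
background counts is provided for completeness and converges to the
goodness-of-fit form as the background grows; goodness-of-fit is the
default everywhere.

## Tau tissue specificity

`τ = Σᵢ(1 − x̂ᵢ)/(N − 1)` with `x̂ᵢ = xᵢ/maxⱼ xⱼ` over N ≥ 2 tissues.
All-zero genes are undefined (NaN) and excluded from calls. Values are
transformed with log2(x + 1) by default — the standard treatment for
FPKM-scale abundances, preventing one extreme tissue from saturating
the index — with `identity` exposed for raw-scale analysis. Note the
consequence, visible in the test suite: τ is scale-invariant only
under the identity transform, and a 100-fold contrast over a
5-FPKM-everywhere background compresses to τ ≈ 0.71 under the log
transform, below the 0.9 specificity threshold. The threshold
therefore effectively requires a near-silent background on the log
scale, which matches the biology of gland-restricted Sfp genes.
Argmax ties resolve to the first tissue in column order and the tie is
recorded. Sex-shared tissues measured in both sexes are kept as
distinct columns; the target-tissue set (which columns constitute the
male reproductive glands) is an explicit configuration item, defaulting
in the generator to an accessory-gland plus ejaculatory-duct pair.

## Interaction network

Channel confidences are combined after removing the prior π (default
0.041) from each channel: `sᵢ′ = max(0, (sᵢ − π)/(1 − π))`,
`s = 1 − Π(1 − sᵢ′)`, re-adding the prior as `s + π(1 − s)`. A single
channel therefore passes through unchanged, and edges with no channel
above the prior report 0 rather than π. Text mining is excluded by
default; the high-confidence cutoff is a combined score ≥ 0.700. Edge
tables may carry scores as reals in [0, 1] or integers 0–999
(auto-detected per file). Self-loops are dropped with a warning;
duplicate orientations merge keeping the higher score. All Sfp ids
remain as nodes even when isolated so degree-0 genes stay visible.

Subnetworks are connected components of the Sfp-induced subgraph
(paths through non-Sfp proteins do not merge components) with ≥ 4
members, ordered by size with lexicographic tie-break; the largest is
the core. Monte Carlo enrichment draws subnetwork-sized gene sets
without replacement from the universe — by default the union of
subnetwork members, configurable to all Sfps with interaction data —
and uses the pseudo-count estimator p = (r + 1)/(n + 1), which never
returns 0 and is bounded below by 1/(n + 1). Enrichment and depletion
are two one-sided tests, BH-corrected per direction across all
subnetwork × class cells. Each subnetwork draws from a child RNG
stream keyed by its id, so p-values are independent of processing
order and bit-reproducible for a fixed seed. The default resample
count is 100,000.

The reproductive-function association builds the subnetworks ×
{reproductive, non-reproductive} table; its Pearson chi-square p-value
is estimated from 2,000 fixed-margin tables (Patefield sampling via
scipy) with the same empirical estimator, and per-subnetwork post hoc
tests use adjusted residuals of the table under BH. If every gene
carries the same flag the statistic is 0 and p = 1 by convention.

## McDonald–Kreitman rates

Per gene: `ω = (Dn/Ln)/(Ds/Ls)` (per-site by default; raw-count Dn/Ds
is a flag). The corrected nonsynonymous polymorphism count keeps sites
whose derived-allele frequency is strictly above the 5% cutoff — the
boundary frequency is excluded — removing segregating
slightly-deleterious variants that depress α. The SFS is unfolded
(derived-allele counts) by default; a folded mode applies the cutoff
to minor-allele frequency. `α = 1 − (Ds·Pn_corr)/(Dn·Ps)` may be
negative and is reported unclipped with a flag. `ωa = α·ω` and
`ωna = (1 − α)·ω` satisfy ωa + ωna = ω exactly (the implementation
computes ωna as ω − ωa, so the identity holds to the last bit even for
negative α). α is computed per gene, not by asymptotic extrapolation:
the correction modeled here is a single frequency threshold. Only the
nonsynonymous class is thresholded (the synonymous spectrum is not an
input); under a purely neutral 1/i spectrum this makes the corrected α
overshoot upward, while segregating deleterious variation biases the
uncorrected α downward — the calibration tests assert both directions
and that the corrected estimator is closer to truth under a planted
low-frequency deleterious load. Genes with Ds = 0, Ps = 0 or Dn = 0
are flagged unusable with the reason, never silently dropped; a pooled
(summed-count) α over a gene group is provided and is the estimator
used for parameter-recovery checks.

## Shared statistics

Kruskal–Wallis (tie-corrected, chi-square reference with k − 1 df) is
the omnibus for multi-group comparisons; all-identical data returns
statistic 0, p 1. Pairwise post hocs use the Wilcoxon rank-sum test —
exact enumeration for small tie-free samples, tie-corrected normal
approximation without continuity correction otherwise — with BH across
the C(k, 2) pairs. The signed Z and z² are reported alongside U
because two-group rank tests are sometimes printed on a chi-square
scale (z² is asymptotically that statistic). BH adjustment is the
standard step-up procedure (via statsmodels), order-preserving and
capped at 1.

Randomness is governed by one integer seed; every stochastic operation
derives a child generator keyed by (seed, operation, item) with
CRC32-hashed keys, making results independent of execution order and
of Python's per-process hash randomization.

## Synthetic-data generator

The generator emulates the pipeline's external inputs with known
truth; it is validation machinery, not a population-genetic or
transcriptomic simulator.

- **Catalog**: n genes split between two lists with a fixed overlap,
  multinomial age classes (or exact counts), optional unaged
  exceptions, a planted ortholog-validation set with an exact number
  of discrepancies, and a planted "very ancient candidate" set with a
  fixed class-A share.
- **Expression**: planted specific genes at `fg_level` in one peak
  tissue over a `bg_level` background with multiplicative lognormal
  noise (CV 0.2 default). Defaults fg = 500, bg = 0.5: Sfp genes are
  essentially silent outside the male reproductive glands, and the
  near-zero background keeps planted specificity recoverable under the
  log2 transform (see the tau section). Per-gene specificity
  probabilities allow age-dependent expression breadth.
- **Network**: planted-partition blocks on top of a random spanning
  tree (so every block is connected for any p_in > 0), optional
  between-block and Sfp↔non-Sfp edges, sub-threshold components,
  peripheral Sfps interacting only outside the set, weak decoy edges
  and text-mining-only decoys that must be filtered out.
- **MKT counts**: Poisson counts with neutral nonsynonymous rates
  scaled by ω₀, adaptive substitutions added so the expected adaptive
  fraction equals the requested α, a neutral 1/i SFS, and an optional
  deleterious fraction confined below a frequency ceiling. The 1/i
  shape is the standard neutral expectation, not a coalescent
  simulation: the pipeline tests estimator arithmetic and the
  threshold correction, not linkage or demography.

The `paper_like_bundle` preset fixes the marginal structure of the
study system this package models: 357 genes (228 shared, one unaged
pseudogene), class counts (220, 36, 36, 28, 36), a 178-gene validation
set with 5 planted discrepancies, a 98-gene candidate set with 78 in
class A, 31 tissues, interaction blocks (64, 13, 6, 5, 5, 5) plus 17
genes in sub-threshold components and 48 peripheral Sfps (163 with any
interaction data), and two population samples (160 and 154
chromosomes) with age-class-dependent ω₀ and α. The genome-wide
background proportions (0.866, 0.040, 0.034, 0.025, 0.035) are the
generator's own fixture — ancient genes dominate real genomes far more
than they dominate this gene set — so composition statistics computed
against them characterize the method, not any published genome.

What passing tests show — and do not show. Recovery and calibration
results on these inputs validate the estimators and the planted-signal
detection machinery under idealized noise (independent Poisson counts,
lognormal expression noise, Bernoulli edges). They do not certify
behavior under real-data pathologies: correlated tissues, linkage
between sites, mis-specified orthology, or STRING's correlated
evidence channels.

## Numerical choices and limitations

- Empirical p-values are never 0; the smallest attainable value is
  1/(n + 1), so BH-adjusted values inherit that floor.
- Fixed-margin Monte Carlo chi-square p-values are conditionally exact
  and differ from the analytic reference on small tables; they
  converge for large well-conditioned tables.
- Proportion vectors must sum to 1 within 1e−9; expected counts must
  all be positive (sparse classes should be pooled upstream).
- Type-I calibration of the empirical enrichment test is asserted on a
  large universe (1,000 genes, subnetwork 100); on very small
  universes the hypergeometric null is coarsely discrete and the test
  is conservative by construction.
- Problem sizes in the test suite (e.g. 20,000–100,000 resamples,
  200 recovery replicates of 150 genes, 1,000 calibration draws) were
  chosen to keep Monte Carlo error well below the asserted tolerances
  while completing in seconds on one CPU.
- The pipeline does not infer gene ages, query live interaction or
  orthology databases, align sequences, or fit asymptotic-MKT or DFE
  models; those belong upstream of its inputs.
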