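# Methods

## The admixture model

A colony's nuclear genome is modelled as a three-way mixture of the African
(A), Western-European (M) and Eastern-European (C) lineages — the three
lineages relevant in the Americas; the Asian (O) and Arabian/African-Horn (Y)
lineages appear only in the mitochondrial classification, where they have
reference sequences but no nuclear panel counterpart.

At a biallelic ancestry-informative SNP *j* the expected reference-allele
frequency under admixture (A, M, C) is `p_j = A·pA_j + M·pM_j + C·pC_j`.
Pooled sequencing of 20 workers samples n = 40 allele copies, and the
observed copy number `r_j` is treated as Binomial(n, p_j), independent across
loci. The estimate is the simplex point minimizing the summed negative
binomial log-likelihood. Two modelling simplifications are inherited
deliberately and exposed to scrutiny through the simulator:

* **Independence of the 40 pooled alleles.** Workers share a mother and a
  small number of fathers, so pooled counts are really overdispersed relative
  to a binomial. The estimator keeps the binomial form; the simulator's
  `family` mode (explicit queen/drone pedigree) quantifies the consequence —
  point estimates remain unbiased, but their sampling variance exceeds what
  the binomial model implies.
* **Deterministic p given (A, M, C).** The mixture frequency is treated as
  exact, not as a latent per-colony random frequency; the likelihood is the
  product of the per-locus binomial terms at those mixture values.

## Numerical choices

* **Simplex handling.** The estimate is parameterized as softmax over three
  logits with the third pinned to zero, and optimized unconstrained with
  L-BFGS-B. This keeps the problem smooth and constraint-free; the pinned
  logit removes the translation non-identifiability of the softmax.
* **Multi-start.** 8 starts: the three simplex corners, the barycenter, and
  four seeded Gaussian logit draws (sd 2). The likelihood can be multimodal
  on weakly informative panels; on diagnostic panels all starts coincide.
* **Frequency clamping.** Mixture frequencies are clipped to
  `[1e-6, 1 − 1e-6]` before the log terms. Without it, a panel frequency of
  exactly 0 or 1 combined with a disagreeing observed count makes the
  log-likelihood −∞ and the optimizer undefined.
* **Convergence.** Objective tolerance 1e-8, at most 500 iterations per
  start — conventional values; results are insensitive to them on the tested
  problem sizes.
* **Non-identifiability flag.** A fit is flagged when the spread of the
  multi-start optima *and* the spread of the three simplex-corner
  likelihoods are both below 1e-6: on a panel where the lineages are
  indistinguishable every admixture has the same likelihood and the reported
  point is arbitrary.
* **Grid oracle.** An exhaustive evaluation over the lattice
  `{(a, m, 1−a−m): a, m multiples of step}` (default step 0.01, 5151 points)
  with a lexicographic (A, M) tie-break. It exists to verify the optimizer —
  dominance of the smooth fit over the grid optimum is asserted in the test
  battery — and is exposed as `--grid-check` in the CLI.
* **Counts vs frequencies.** The likelihood consumes integer counts. A file
  of observed frequencies is converted once at load time by rounding
  `p̂·n_alleles` half away from zero into `[0, n_alleles]`; the conversion is
  the identity on exact count-derived frequencies. Missing SNPs are dropped
  from a colony's likelihood product, never imputed.

## mtDNA haplotyping

Classification assigns a query COI–COII sequence the lineage of its nearest
reference by unit-cost global-alignment edit distance (substitutions and
indels cost 1), computed with edlib. `N` matches any base at zero cost so
ambiguous base calls cannot create spurious haplotypes or mutational steps.
Ties across lineages yield `unknown` with an ambiguity flag. This
nearest-reference rule is a deterministic, testable proxy for phylogenetic
placement and agrees with it whenever lineages are well separated; no tree
or bootstrap is computed.

Identical normalized sequences (uppercased, gaps stripped) collapse to one
haplotype; ids are assigned by descending carrier count with first-seen
tie-break. The haplotype network retains, among all pairs within `max_steps`
mutational steps (default 10), a minimum-total-distance spanning forest;
non-tree edges whose weight equals the maximum edge weight on the forest path
between their endpoints could replace a retained edge at no cost and are kept
as flagged alternates. The `max_steps` ceiling is a user-set stand-in for a
statistical-parsimony connection limit; the probability-of-parsimony
calculation behind such limits is intentionally out of scope. Haplotype names
are generated ids, not the published haplotype nomenclature, which requires a
curated reference catalogue.

Length variation of the real COI–COII region (P/Q element copy number) is
handled by the unit-cost indel model; users comparing haplotype counts
against catalogues built with other gap conventions should expect
differences.

## Mitochondrial vs nuclear comparison

Within a group (apiary, or region × management) the mitochondrial proportion
of a lineage is the fraction of classified colonies carrying it, with a Wald
interval `p̂ ± 1.96·√(p̂(1−p̂)/n)` at n = colonies with known lineage;
colonies classified `unknown` shrink n rather than entering a denominator.
The nuclear proportion is the unweighted mean of member-colony admixture
fractions, with the same interval at an effective allele count of
`(2 + d)·n_colonies` — each colony contributing the queen's two alleles plus
one allele per drone mate (d = 12 by default, a conservative queen mating
frequency). Applying a binomial-proportion interval to a mean of admixture
fractions is statistically heterodox — the mean is not a binomial count —
but it is the established convention for this comparison and is reproduced
as such; the intervals should be read as approximate. Intervals at p̂ of
exactly 0 or 1 collapse to zero width and carry a degeneracy flag.
Overlapping intervals give the verdict `not_distinguishable`; otherwise the
side with the higher point estimate wins.

## The synthetic-colony generator

The generator emulates the sampling design, with defaults set to the study
conditions the estimators target: L = 94 panel SNPs, 20 pooled workers
(40 allele copies), 12 drone matings, colonies grouped into apiaries across
five named beekeeping regions with a managed:feral ratio of roughly 71:29,
and a default true admixture of (A, M, C) = (0.59, 0.17, 0.24) — an
Africanized population with a Western-European minority, the regime where
three-way estimation is hardest. Maternal lineage is drawn independently of
the nuclear truth (default weights 0.58 / 0.02 / 0.40 over A / M / C,
African maternal lines predominating and M maternal lines rare), so
mito-nuclear discordance scenarios can be composed deliberately.

Panels come in two modes: `diagnostic` (each SNP fixed in one lineage at
frequency 1−ε, ε = 0.01 in the others — ε > 0 keeps every likelihood finite)
and `beta` (iid Beta(0.5, 0.5) frequencies per lineage, a U-shaped
distribution concentrating mass near fixation, emulating panels of varying
informativeness). Observations come in `idealized` mode (pooled counts drawn
exactly from the estimator's binomial model) and `family` mode (explicit
pedigree: per-locus lineage origin for each queen gamete, one whole-genome
lineage per drone, uniform random father per worker — multinomial
patrilines). In family mode the pooled count is by construction the sum of
the workers' alleles, so pooled and mean-individual frequencies agree
exactly; real pooled sequencing adds depth and extraction noise that this
generator does not model. Passing recovery tests on simulated data therefore
demonstrates correctness of the estimators under their stated model, not
robustness to sequencing artefacts, reference panel error, or selection.

mtDNA simulation builds one ancestor per lineage by mutating a random root
at disjoint lineage-private position blocks (pairwise divergence ≥ the
configured minimum, 10 by default), then gives each colony its maternal
ancestor with at most `within_lineage_mutations` (default 2) random
substitutions. The generator enforces
`between_lineage_substitutions > 2 × within_lineage_mutations`, the
separability condition under which nearest-reference classification provably
recovers the simulated lineage. Sequences use {A, C, G, T} only, with no
indels; indel handling in distances is exercised on hand-written fixtures
instead.

All randomness flows from one seeded `numpy` generator per entry point;
identical configurations and seeds reproduce output files byte-for-byte
(run logs deliberately contain no timestamps).

## Problem sizes in the verification battery

The test suite and `scripts/acceptance.py` use 94-SNP panels with 50–200
simulated colonies per scenario, 100 random instances for the
exact-arithmetic likelihood comparison, 500 random triples for the metric
axioms, and ≤ 7-node fixtures for the exhaustive spanning-forest
enumeration — sizes at which the brute-force oracles are exact and the whole
battery runs in well under a minute per scenario on one CPU.

## Known limitations

* Point estimates only: no standard errors or posterior intervals on
  (A, M, C) beyond the non-identifiability flag.
* Three-lineage nuclear model; O/Y nuclear ancestry, if present, is absorbed
  into the nearest of A/M/C.
* Loci are treated as unlinked; linkage between panel SNPs would make the
  likelihood overconfident.
* The Wald intervals and the CI-overlap rule are approximate decision
  devices, not a calibrated test; no multiplicity adjustment is applied.
* Regression of ancestry on latitude/altitude/management is out of scope;
  the summary tables export per-colony covariates so any model can be fitted
  externally.
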