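# Methods

This note documents the statistical models, conventions and default
parameters behind each `ovigene` module, the design choices that were
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Population-genetic summaries (`popgen`)

For a locus with allele frequencies `p_1..p_k` estimated by gene counting
(each diploid animal contributes two genes; heterozygote order is ignored;
missing calls `./.`, blank, `NA` are excluded from N and counted):

* expected homozygosity `Ho = Σ p_i²`,
* gene diversity (expected heterozygosity) `He = 1 − Ho`,
* effective allele number `Ne = 1 / Ho`,
* Botstein's polymorphism information content
  `PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²`, classed low (< 0.25),
  moderate (0.25–0.5) or high (> 0.5).

**`Ho` is the expected, not observed, homozygosity.** Field reports in this
literature tabulate Σp² under the homozygosity heading (it is the
complement of Nei's diversity and the reciprocal of Ne, so the printed
triples are internally consistent), and this package follows that
convention deliberately. The observed homozygote proportion can differ;
at the bundled example locus it is 0.653 versus Σp² = 0.640.

**Class boundaries.** PIC exactly 0.25 or 0.50 is classed moderate. The
conventional description uses strict inequalities, which leaves the
boundary unclassified; boundaries cannot occur for counted data, so the
inclusive choice is purely for totality.

**Hardy–Weinberg test.** Expected counts are `N p_i²` and `2 N p_i p_j`
over all `k(k+1)/2` genotype classes, including classes observed zero
times (a rare-allele homozygote class with expectation N q² belongs in the
statistic). The χ² statistic sums over classes with positive expectation
and is referred to `df = k(k−1)/2` (1 for a biallelic locus, reproducing
the usual 3.841 critical value). Classes expected fewer than 5 times are
flagged with a warning but not pooled: pooling is a modelling choice the
caller should make knowingly, and the flag makes small-expectation
p-values auditable. Monomorphic loci raise an error (the test is
undefined). Reported tables round to 2 decimals; computation is full
precision.

For the 0.97/0.03 locus shipped in the examples the 3-class test gives
χ² ≈ 0.35, p ≈ 0.55 (rare-homozygote class expected 0.33, flagged). A
2-class collapsed variant gives p ≈ 0.94. Published tables in this
literature occasionally print other values for such loci; this package
reports only its own, reproducible statistic.

## Litter-size association (`association`)

The model is `Y_ijn = μ + P_i + G_j + (PG)_ij + e_ijn`, with Y the litter
size of ewe n at parity i (1–3) and genotype j, fitted by least squares.
Because field genotype classes are severely unbalanced (e.g. 256/150/27),
effects are coded sum-to-zero and each term is tested with a **partial
(Type III) F-test**: the term's SS is the increase in residual SS when its
columns are removed from the otherwise complete design. Sequential SS
would make the genotype test depend on term order; with interaction
present on unbalanced data that is not defensible. The implementation is
plain numpy least squares and is verified in the test suite against
statsmodels `anova_lm(typ=3)` to 1e-8 relative.

Degenerate designs: an empty parity×genotype cell drops the interaction
term (warning logged; main effects retained); a saturated design (zero
residual df) and a single genotype class are errors; a zero-variance
response (every litter identical) reports non-computable F statistics with
a flag rather than 0/0.

Two response conventions coexist in this study design: the per-parity
record (used by the model above, which needs the parity factor) and the
per-animal mean (used in summary tables). Both are supported:
`fit_association` models records; `genotype_summary` averages within
animal first and reports per-genotype `n`, mean and the n−1 SD (single
animal ⇒ SD 0.00 with a flag). α defaults to 0.05, configurable.

## Relative expression (`qpcr`)

Livak quantification: technical replicates are averaged within
animal×tissue×gene; `ΔCt = Ct(target) − Ct(reference)` per animal and
tissue; `ΔΔCt = ΔCt − mean ΔCt(calibrator)`; fold change `2^−ΔΔCt`. The
per-tissue fold reported is `2^−mean(ΔΔCt)` so the calibrator is exactly 1;
dispersion is the SD of per-animal fold changes (simple, and it matches
the "mean ± SD" bar-chart convention; transforming the ΔCt SD would be the
alternative). The calibrator defaults to the least-expressed tissue
(largest mean ΔCt), which anchors the panel minimum at 1; pass
`calibrator=` to override.

Differences among tissues: one-way ANOVA on per-animal fold changes
(biological n, default 3 animals). Pairwise comparisons use **protected
Fisher LSD** — pairwise t-tests on the pooled within-group MS, attempted
only when the omnibus F is significant. Protection matters: with 13
tissues there are 78 pairs, and unprotected LSD would splinter the letter
display under the null. Tukey HSD is available by flag. With zero
within-group variance the F statistic is reported as ∞ (p = 0) for unequal
means and 0 (p = 1) otherwise.

**Compact letter display** uses the insert-and-absorb algorithm: start
with one letter column containing all groups; for each significant pair,
split every column containing both (one copy without each member); absorb
columns that are subsets of others. This maintains exactly the defining
relation — two groups share a letter iff their pairwise p ≥ α — which the
suite verifies exhaustively for all patterns on ≤ 4 groups and on sampled
patterns for 5–6.

## Sequence characterization (`seqchar`)

* **ORF**: all three forward frames are scanned for ATG..stop spans; the
  longest wins, ties to the 5′-most start. Input is assumed to be oriented
  cDNA, so reverse-complement scanning is off by default (flag available).
  "No ORF" is an explicit `None` result, not an exception. Peptide length
  is `nt/3 − 1` (terminal stop translated away).
* **Translation**: standard genetic code via Biopython; internal stops and
  non-IUPAC symbols are errors.
* **Molecular weight**: average (not monoisotopic) residue masses plus one
  water, reported in kDa to 2 dp — the convention of cloning reports.
* **Isoelectric point**: Henderson–Hasselbalch net charge over the termini
  and D/E/C/Y/H/K/R side chains, root found by bisection on pH 0–14 to
  |charge| < 1e-4. The pKa table is a fixed module constant (N-term 7.50,
  C-term 3.55, D 4.05, E 4.45, C 9.00, Y 10.00, H 5.98, K 10.00, R 12.00,
  EMBOSS-style); published pKa sets differ by several tenths of a pH unit,
  so the table is pinned rather than configurable-by-accident. The charge
  curve is strictly decreasing with guaranteed sign change, so the root is
  unique.
* **Identity matrix**: pairwise global alignment (match +1, mismatch −1,
  gap −2, linear), identity = matched columns / alignment length.
  Commercial alignment GUIs used in cloning reports do not publish their
  scoring, so percent identities should be read as pattern-level rather
  than bit-exact; 100% self/identical cases are exact by construction.
  Distance is 1 − identity by default; a Poisson correction
  (−ln identity) is available for tree building.
* **Neighbor joining**: Saitou–Nei Q-matrix agglomeration with the
  standard branch-length formulas, ending in the 3-node trifurcation (the
  unrooted tree). Negative branch lengths — possible on non-additive
  input — are clamped to 0 and logged. NJ is exact on additive matrices,
  which the suite exploits: 100 random 4–8-taxon trees are recovered with
  path-length error < 1e-9, and results are cross-checked against
  scikit-bio's independent implementation. Newick output uses full-
  precision floats (`repr`), so write→parse round-trips are exact.

## Synthetic data (`simulate`)

The generators encode the study conditions the analyses assume:

* **Genotypes**: N = 433 animals, biallelic locus, allele frequency
  p = 0.76 (second locus 0.97), genotype probabilities
  `(p² + Fpq, 2pq(1−F), q² + Fpq)`; F = 0 is exact Hardy–Weinberg, F = 1
  eliminates heterozygotes.
* **Litter size**: `1 + Bernoulli(π)` with
  `logit π = logit(π₀) + parity + genotype + interaction`, π₀ = 0.07 by
  default. The 1+Bernoulli form, rather than Poisson, follows from the
  observed scale (group means ≈ 1.07, SD ≈ √(0.07·0.93) ≈ 0.26, and a
  small class at exactly 1.00 ± 0.00): litters are essentially
  singleton-or-twin.
* **Ct tables**: reference gene at a fixed baseline (16 cycles), target at
  `baseline − log2(fold)` (22 cycles at fold 1), biological noise SD 0.2 Ct
  per animal×tissue×gene, technical noise SD 0.05 Ct per well, 3 animals ×
  3 technical replicates across the 13-tissue panel. Default folds span
  1–8 with the reproductive organs, lung and spleen high and *longissimus
  dorsi* lowest — the qualitative pattern this assay family reports. With
  both noise SDs at 0 the analysis inverts the folds exactly, which the
  suite asserts.
* **Sequence families**: random binary tree (branch lengths uniform on
  0.02–0.2, read as per-site substitution probabilities), sequences evolved
  by independent per-site substitution; both the leaves and the generating
  tree are returned, so tree inference can be scored against truth.

What the generators do **not** emulate: genotyping error and missingness
patterns, pedigree/repeated-records covariance (each ewe's three parities
are conditionally independent given the effects), linkage between loci,
amplification-efficiency differences between genes, and realistic
codon-level sequence evolution (no transition/transversion bias, no rate
heterogeneity, no indels — which is why alignment-based identity tests use
small divergences). Passing calibration on synthetic data therefore
demonstrates correctness of the computations under the stated model, not
robustness to those real-data complications.

### Calibration benchmarks

Three simulation studies ship with the package (and are recomputed by
`scripts/acceptance.py`):

* **HWE test size**: 2000 multinomial replicates at N = 433, p = 0.76,
  F = 0; replicates with any expected class < 5 are excluded from the rate
  (the statistic's validity condition, almost never triggered at these
  frequencies). Observed rejection ≈ 0.04–0.05 at α = 0.05.
* **Association size and power**: size under the null at the study's fixed
  class sizes (256/150/27, 2000 replicates); power in a balanced 3×3×20
  recovery design where one genotype's mean litter size is shifted by
  +0.3. The detectable-effect benchmark is defined on the litter-size
  (trait) scale because that is the scale of the linear model being
  assessed; +0.3 lambs corresponds to twin probability 0.07 → 0.37, i.e.
  +2.05 on the generator's log-odds scale. (A +0.3 log-odds effect, by
  contrast, moves the mean by only ≈ 0.03 lambs — a noncentrality below 3
  at this design size, undetectable by any test — so the log-odds reading
  would make the benchmark vacuous.) Observed power ≈ 1.0, with the
  fitted genotype-mean ordering matching the generator in every replicate.
* **End-to-end null**: the default synthetic flock (both loci, F = 0, no
  genotype effects) run through the full pipeline reproduces the expected
  qualitative conclusions — HWE-consistent loci and no litter-size
  association — at the nominal false-positive rate; any single seeded run
  has roughly a 0.95^4 chance of showing all four null results at once.

Problem sizes throughout (2000 null replicates, 200 power replicates, 100
NJ trees, 1000 oracle sequences) were chosen to bound the Monte-Carlo
standard error of each rate well below the tolerance being asserted
(e.g. SE ≈ 0.005 for a 0.05 rate at 2000 replicates, against a ±0.02
band).

## Pipeline (`pipeline`, CLI)

`run_report` validates inputs, runs popgen per locus, joins phenotypes on
`animal_id` and fits the association model, writes one CSV per table and a
run log (package version, seed, row counts, all warnings: low expected
counts, dropped interactions, excluded missing genotypes). Any stage error
aborts with the stage name and offending record. Output tables contain no
timestamps and are byte-identical across reruns; the log line with the
start time is the only non-deterministic output. Config is plain YAML
(`genotypes`, `phenotypes`, `loci: [{name, alleles}]`, `alpha`, `digits`,
`out_dir`, `seed`).

## Known limitations

* HWE testing is asymptotic χ² only; no exact (Monte-Carlo/complete
  enumeration) test is provided, so very rare alleles rely on the flagged
  approximation.
* The association model treats repeated parities as independent records;
  a random-ewe mixed model would be the next step for data with strong
  within-animal correlation.
* No amplification-efficiency correction in the 2^−ΔΔCt pipeline
  (efficiency 100% assumed for both genes).
* Identity percentages depend on the alignment scoring; only the scheme
  above is implemented.
* NJ reports no bootstrap support values.
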