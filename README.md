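# ovigene

Candidate-gene analysis toolkit for sheep reproduction studies.

Low prolificacy is a defining constraint of high-altitude sheep husbandry,
and candidate-gene association studies — genotype a SNP in a few hundred
ewes, summarize the locus, test whether genotype predicts litter size, and
profile the gene's tissue expression — remain a standard design for
screening reproduction genes such as the TGF-β pathway mediators (the SMAD
family). `ovigene` implements that entire computational workflow as a
tested, scriptable package:

* **Population-genetic summaries** (`ovigene.popgen`): genotype and allele
  frequencies, expected homozygosity `Ho = Σp²`, gene diversity
  `He = 1 − Σp²`, effective allele number `Ne = 1/Σp²`, Botstein's
  polymorphism information content
  `PIC = 1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ²` with the conventional
  low / moderate / high classes, and the Hardy–Weinberg χ² goodness-of-fit
  test (`df = k(k−1)/2`).
* **Litter-size association** (`ovigene.association`): the fixed-effects
  linear model `Y_ijn = μ + P_i + G_j + (PG)_ij + e_ijn` with parity and
  genotype as fixed factors, sum-to-zero coding and partial (Type III)
  F-tests — appropriate for the heavily unbalanced genotype classes of a
  field population — plus per-genotype `n, mean ± SD` summaries.
* **Tissue expression** (`ovigene.qpcr`): Livak 2^−ΔΔCt relative
  quantification against a reference gene (technical triplicates averaged,
  ΔΔCt against a calibrator tissue), one-way ANOVA across tissues and a
  compact letter display (protected Fisher LSD or Tukey HSD) so that
  tissues sharing no superscript letter differ at α.
* **cDNA characterization** (`ovigene.seqchar`): longest-ORF detection and
  translation, protein molecular weight and isoelectric point, pairwise
  percent-identity matrices from global alignments, and Saitou–Nei
  neighbor-joining trees with Newick export.
* **Synthetic data** (`ovigene.simulate`): seeded generators for genotypes
  (Hardy–Weinberg with an optional inbreeding-like departure F), litter
  sizes (1 + Bernoulli with logistic parity/genotype effects), Ct panels
  and homolog sequence families evolved along a known tree — so every
  stage can be exercised and calibrated without animal data.
* **Pipeline and CLI** (`ovigene.pipeline`, `ovigene` console script):
  config-driven end-to-end reports with deterministic outputs.

## Worked example

Summarize a locus straight from genotype tallies (433 ewes, a biallelic
SNP with genotype counts AA/AG/GG = 256/150/27):

```python
from ovigene import popgen

gc = popgen.counts_from_mapping("g.51537A>G", {"AA": 256, "AG": 150, "GG": 27})
print(popgen.locus_summary(gc).to_string(index=False))
```

```
     locus genotype  count  genotype_freq allele  allele_freq   Ho   He   Ne  PIC PIC_class  chi2  df  p_HWE
g.51537A>G       AA    256           0.59      A         0.76 0.64 0.36 1.56  0.3  moderate  0.63   1   0.43
g.51537A>G       AG    150           0.35      G         0.24 0.64 0.36 1.56  0.3  moderate  0.63   1   0.43
g.51537A>G       GG     27           0.06                 NaN 0.64 0.36 1.56  0.3  moderate  0.63   1   0.43
```

Reading the row: the A allele is at frequency 0.76, the locus retains
moderate marker informativeness (PIC 0.30, between 0.25 and 0.5), carries
about 1.56 effective alleles, and the genotype counts are compatible with
Hardy–Weinberg proportions (χ² = 0.63 on 1 df, p = 0.43 — well short of
the 3.841 rejection threshold at α = 0.05).

The same thing from the shell, for several loci at once:

```sh
$ ovigene popgen --counts counts.csv --out summary.csv
wrote summary.csv (5 rows, 2 loci)
```

When a genotype class is expected fewer than 5 times (e.g. a missing rare
homozygote at a 0.97/0.03 locus) the HWE test still runs but emits a
warning that the χ² approximation is questionable.

Other subcommands follow the same shape: `ovigene assoc` fits the
litter-size model from phenotype + genotype CSVs, `ovigene qpcr` turns a
Ct table into a fold-change report with significance letters,
`ovigene seqchar` characterizes a FASTA file (ORF table, identity matrix,
optional NJ tree), `ovigene simulate` writes synthetic inputs for any
stage, and `ovigene report --config cfg.yaml` runs the genotype(+phenotype)
pipeline end to end.

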