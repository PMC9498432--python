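# fstscan

Multi-cohort F_st-outlier scans for livestock SNP panels.

`fstscan` is for population geneticists localising genomic regions under
differential selection for a phenotype shared by several breeds — the
motivating case is the grey coat colour found in both indicine (zebu) and
taurine cattle. Given PLINK-format genotypes with breed assignments, it
runs the full workflow of a multi-breed selection-signature study:

* **genotype_io** — PED/MAP and BED/BIM/FAM reading, writing, merging and
  locus QC (`--maf 0.05`, `--geno 0.1` style filtering with exact
  removal accounting);
* **diff_stats** — per-locus Weir–Cockerham theta from allele counts,
  pairwise Reynolds coancestry distances, top-quantile ranking;
* **bayes_outlier** — a Dirichlet-multinomial Bayesian outlier model
  (`logit F_ij = alpha_i·delta_i + beta_j`) fitted by reversible-jump
  MCMC, with posterior inclusion probabilities and q-values;
* **contrasts** — the three contrast designs (every test breed × every
  reference; a pooled meta-population per reference after an MDS cohort
  screen; each test breed vs one same-lineage reference), dual
  significance criteria (q < 0.05 or per-contrast top-1% F_st),
  cross-contrast consensus and ±250 kb gene-window annotation;
* **splits_network** — NeighborNet split networks (circular ordering +
  non-negative least-squares split weights) on Reynolds distances, with a
  neighbor-joining oracle and Nexus output;
* **simulate** — hierarchical Balding–Nichols panels with a deep lineage
  split, small per-breed sample sizes and planted selected loci shared by
  the designated "grey" cohorts, so every stage can be scored against
  known truth.

The core statistic is Weir–Cockerham's variance-component F_st in its
allele-count form, theta = a/(a+b), and the Bayesian model decomposes
locus-by-cohort differentiation on the logit scale into a genome-wide
cohort effect beta_j and a locus-specific selection effect alpha_i whose
inclusion indicator delta_i is sampled by a reversible-jump move; a
locus's q-value is the minimum false-discovery rate at which it would be
declared an outlier. See `docs/methods.md` for the full model statement,
priors, estimator formulas and measured operating characteristics.

## Worked example

Simulate a study-shaped panel (12 breeds: seven grey indicine, one
non-grey indicine, four taurine references; 5,000 SNPs of which 30 carry
a planted sweep shared by all grey breeds), filter it, run the 28
scenario-1 contrasts, and take the cross-contrast consensus:

```bash
fstscan simulate --n-loci 5000 --n-planted 30 --seed 42 --out sim
# wrote 184 samples x 5000 loci to sim/panel.*

fstscan qc --panel sim/panel --out qc
# 5000 loci in, 4489 out (511 failed MAF, 0 failed missingness)

cat > scenario1.yaml <<'YAML'
scenario: 1
test_cohorts: [Bhagnari, Dajal, Guzerat, Hariana, Hissar, Kankrej, Tharparkar]
reference_cohorts: [Angus, Holstein, Charolais, Limousin]
YAML

fstscan contrast --config scenario1.yaml --panel qc/qc_panel --out contrasts
# Bhagnari vs Angus: 45 top-1% loci, 0 q<0.05 loci
# Bhagnari vs Holstein: 45 top-1% loci, 0 q<0.05 loci
# ... (28 contrasts)

fstscan consensus --results contrasts --out consensus.tsv
# 20 consensus loci -> consensus.tsv

fstscan network --panel qc/qc_panel --out net
# 12 cohorts, 4489 loci, 33 splits -> net/network.nex
```

The consensus table lists each retained SNP with the number of test
breeds significant per reference and the supporting contrasts:

```
      snp  chrom       bp  n_refs
snp000166      1 16600001       3
snp000332      2 15900001       4
snp000498      3 15200001       3
snp000529      4  1000001       3
snp000664      4 14500001       4
snp000830      5 13800001       4
```

`n_refs` counts reference breeds for which at least 4 of the 7 grey test
breeds put the SNP in their contrast's top 1%; loci with `n_refs >= 3`
are retained. Of the 20 retained loci here, 14 are planted sweeps —
recovery is deliberately imperfect, because the deep indicine/taurine
background (cross-lineage F_st ≈ 0.19 in the simulation, as in real
panels) pushes lineage-differentiated neutral loci into every contrast's
top 1%; `docs/methods.md` quantifies this. Adding `--engine bayes` scores
contrasts with the MCMC posterior instead of Weir–Cockerham theta and
adds q-values. `fstscan annotate --consensus consensus.tsv --annotation
genes.bed --out annotated.tsv` attaches the genes within ±250 kb of each
retained SNP, and `net/network.nex` opens in any split-network viewer to
check whether breeds group by phenotype on the candidate panel.

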