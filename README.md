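# haplocal

Local haplotype variant calling from paired-end DNA sequencing.

A genetically homogeneous diploid cell population can carry at most two
distinct haplotypes across any short genomic window. When sequenced
fragments that scaffold several proximal SNVs support **more than two**
haplotype sequences with high statistical confidence, the sample must
contain genetically distinct cell subpopulations — somatic mosaicism.
`haplocal` detects such *local haplotype variants* (LHVs) from a
coordinate-sorted BAM and a matching VCF of SNV calls for one sample,
and writes its calls in a vcf-like tab-delimited *haplotype call format*
(hcf) plus an IGV-loadable BED track. It is aimed at anyone analyzing
deep WGS/WES data for mosaicism: cancer genomics, clonal hematopoiesis,
or quality control of supposedly clonal material.

## Model

SNVs within K bp of each other (default K = 500) are chained into
segments of R SNVs. A segment admits L = 2^R candidate haplotypes
h_1, ..., h_L (the product of the two alleles per SNV); presence
indicators λ_j ∈ {0, 1} are the parameters of interest. Each fragment
contributes a call vector s_i over the R SNVs with 'M' for missing
(MCAR), and is modelled as a uniform mixture draw over the present
haplotypes with per-base error e_ir:

    Pr(s_i | λ) = (1/Σλ) Σ_{j: λ_j=1} Π_{r∈A} (1−e_ir) Π_{r∈D} e_ir/3

where A/D are the agreeing/disagreeing observed bases against h_j;
missing bases integrate out to a factor of one. Each λ_j has an
independent Beta-Bernoulli(α, β) prior with marginal presence
probability α/(α+β) (≈ 4.8% at the defaults α = 0.05, β = 1). With
R ≤ 3 the posterior over all 2^L presence configurations is computed
exactly in log space; the marginals ξ_j = Pr(λ_j = 1 | data) follow by
summing the configuration table. Haplotypes are selected by keeping the
largest top-t set whose posterior expected FDR, mean(1 − ξ) over the
set, stays below f0 = 0.01; a segment with ≥ 3 selected haplotypes is
an LHV.

## Worked example

The package ships eight fixture scenarios (fixed read-pattern multisets
over one segment). Scenario 7 is a real-data pattern: two SNVs 97 bp
apart, 42 fragments covering both, 93 covering one.

```sh
haplocal scenarios
```

prints, for scenario 7:

```
--- scenario 7 (R=2, N=135) ---
  haplotype   xi  significant
j
1        GG  1.0         True
2        GC  1.0         True
3        AG  1.0         True
4        AC  0.0        False
selected: GG, GC, AG  [LHV]
```

Three haplotypes (GG, GC, AG) each have posterior presence probability
1.00 — one more than a homogeneous diploid sample can carry, so the
segment is flagged as an LHV. Scenario 2, where every fragment covers
only one SNV, yields ξ ≈ 0.5 for all four candidates and no call: the
data carry no phasing information.

The same analysis from files:

```sh
haplocal simulate --scenario 7 --out-dir demo/
haplocal call --bam demo/fixture.bam --vcf demo/fixture.vcf \
              --out demo/out.hcf --igv-track demo/out.bed
```

The hcf line for the segment reports the positions, alleles, all four
haplotype posteriors, the supporting read-pattern counts (e.g. `MG:43`
— 43 fragments read G at the second SNV only), `N_SIG=3`, and the
filter status. Library users get the same through
`LocalHaplotypeModel(...).fit()`, which returns a results object with
`xi`, `selected_sequences`, `is_lhv` and a `summary()` table.

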