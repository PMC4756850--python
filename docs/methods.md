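# Methods

## Model and assumptions

Segments are maximal runs of SNVs in which consecutive SNVs lie within
K bp (inclusive); chromosome boundaries always break a segment. K should
reflect the sequencing insert length, since a fragment can only scaffold
SNVs its two mates reach; the default is 500 bp, with 50–1000 the
practically useful range for short-read libraries. A segment of R SNVs
defines L = 2^R candidate haplotypes, enumerated with SNV 1 as the most
significant choice bit and ref = 0 < alt = 1, so haplotype 1 is all-ref
and haplotype L all-alt. Exactly two alleles are allowed per SNV; any
other base readout is treated as missing rather than discarding the
fragment, because third alleles at a called SNV are overwhelmingly
sequencing error and the fragment may still be informative elsewhere.

Fragments are modelled as draws from a uniform mixture over the present
haplotypes. Conditional on the emitting haplotype, observed bases are
independent with error e_ir: agree with probability 1 − e_ir, each
specific disagreement e_ir/3. Missing bases are assumed missing
completely at random (they arise from read placement, not from the
underlying sequence), so they contribute a factor of one to the
likelihood — the explicit sum over the four possible hidden bases of
(1 − e) + 3·(e/3) collapses. The presence indicators carry independent
Beta-Bernoulli(α, β) priors; the marginal presence probability is
computed through the Gamma-function form and asserted against its
algebraic simplification α/(α+β) at 1e-12.

The all-absent configuration (Σλ = 0) is given likelihood zero whenever
at least one fragment exists: no haplotype can emit a read, and the
mixture weight 1/Σλ is undefined there. Its prior mass is removed by the
normalization. Any per-read constant in the likelihood cancels in the
configuration posterior; the brute-force oracle (which carries the
explicit missing-base sums) confirms this invariance.

## Inference

With R ≤ 3 (L ≤ 8, at most 256 presence configurations) the posterior
is computed exactly: each configuration's joint log-probability is
evaluated once — per-pattern likelihoods raised to their counts, so cost
scales with distinct patterns, not fragments — and normalized by
log-sum-exp. The marginals ξ_j are sums of the table over the index sets
that fix bit j, reusing every configuration across all 2L marginal sums.
Segments with R > R_max = 3 are reported as not-analyzed rather than
approximated: the 2^(2^R) configuration count makes exact inference at
R = 4 already 65,536 configurations, and the model offers no principled
truncation.

Selection keeps the largest top-t set (ξ sorted decreasing, ties broken
by enumeration index for byte-stable output) whose posterior expected
FDR, the running mean of 1 − ξ, is strictly below f0 (default 0.01).
The empty-prefix ratio is a 0/0; it is treated as 0, which makes the
best single haplotype admissible iff 1 − ξ_(1) < f0 and matches the
optimal posterior-expected-FDR selection rule. A selected set of three
or more haplotypes flags the segment as an LHV.

## Parameters

| parameter | default | meaning |
|---|---|---|
| K | 500 bp | max gap between chained SNVs (inclusive) |
| R_max | 3 | largest segment analyzed exactly |
| α, β | 0.05, 1 | Beta-Bernoulli prior; marginal presence ≈ 4.8% |
| f0 | 0.01 | posterior expected FDR threshold |
| e_ir | 0.001 | per-base error; constant mode |
| MAPQ min | 30 | alignment quality gate |
| baseQ min | 30 | base quality gate (below → missing) |

The constant e = 0.001 is deliberately conservative: it is the largest
error rate compatible with the Q ≥ 30 base gate, so the model never
assumes bases are cleaner than the gate guarantees. The alternative
`phred` mode converts recorded qualities via 10^(−Q/10), clipped to
[1e-6, 1e-3]. Raising e can only blur the likelihood and lose calls;
the tests assert this shrinkage (selection at e = 0.2 is a subset of
selection at e = 0.001 on every fixture scenario).

## Read extraction

Only primary, properly paired, non-duplicate, non-QC-fail alignments
with MAPQ ≥ 30 are used. The two mates of a fragment are merged into one
observation — this is what lets a fragment phase SNVs further apart than
one read length. Mates overlapping the same SNV and disagreeing yield a
missing call (the model has no within-fragment conflict term; a
disagreement is evidence of error); if only one mate is informative its
call stands. Per-SNV strand and distance-to-read-end are recorded in the
same pass so the post-filters need no second traversal.

## Post-processing filters

The filters target alignment/base-calling artifacts that can mimic a
third haplotype, in three stringency levels: I = SNV proximity
(adjacent segment SNVs < 50 bp fail); II adds indel adjacency (SNV
within 10 bp of an indel record in the input VCF) and read-end pileup
(> 90% of covering bases within 5 bp of a read end); III adds strand
bias (two-sided Fisher exact test on the per-SNV allele × strand table,
p < 0.005). All thresholds are configurable; the level composition and
the non-proximity defaults are this package's documented choices.
Filters never delete records or alter posteriors — a failing record
keeps its calls with the failing filter names in its FILTER column.
Degenerate cases (no covering reads; an allele or strand absent) pass
vacuously.

## Synthetic data

Eight fixture scenarios are fixed pattern multisets over one segment,
spanning: clear three-haplotype support at small N, fragments covering
a single SNV each (no phasing information), sparse uniform support that
must stay uncalled, its rescued counterpart with replicated reads, and
two heavily missing real-data count tables. The fixtures need ref/alt
assignments per SNV; the majority/first-listed allele is taken as ref.
The label-equivariance test shows posteriors do not depend on that
choice.

The generator draws each fragment's source haplotype from stated
mixture proportions, marks each SNV missing independently (matching the
model's MCAR assumption — real fragments miss contiguous SNV runs, a
dependence the model ignores by design), and substitutes observed bases
uniformly over the three other bases at the given error rate, coercing
third alleles to missing exactly as extraction does. The alignment
emitter realizes patterns as properly paired reads (MAPQ 60, Q40 at
observed SNVs, Q2 at deliberately-missing ones so the default gate masks
them), which makes extraction reproduce the pattern counts exactly.
Because the generator realizes the model's own assumptions, passing
calibration tests demonstrate correctness of the inference, not
robustness to real-data artifacts (alignment error, correlated
missingness, mapping bias); the post-filters exist for those.

Calibration experiments use three planted haplotypes at 30 noiseless-ish
fragments (e = 0.001) over 200 replicates for recovery, and two planted
haplotypes at 30 fragments with 30% missingness over 500 replicates for
the false-LHV rate — sizes chosen to estimate a ≥ 95% / < 5% rate with
comfortable margin while keeping the default suite fast.

## Numerical choices

All likelihood work is in log space with log-sum-exp normalization;
direct products underflow at thousands of fragments. Posterior ξ values
are clipped to [0, 1] against rounding and serialized to six decimals in
hcf output — stable round trips without false precision. Output is
deterministic: records follow input (chromosome, coordinate) order and
ties in selection break by enumeration index, so identical inputs give
byte-identical files.

## Limitations

No approximate inference for R > 3; no estimation of per-haplotype
cellular fractions; one sample per run (no joint multi-sample model);
no local realignment or base-quality recalibration; indels are used only
as filter anchors, never genotyped. The hcf dialect here is a fully
specified seven-column stand-in for a format whose original column
semantics are not publicly documented.
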