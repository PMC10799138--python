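# Methods

`poolimpute` simulates and evaluates a two-stage strategy for genotyping
large populations of fully homozygous inbred lines (e.g. wheat recombinant
inbred lines from a MAGIC cross) at half the assay cost: samples are
genotyped in overlapping pools on a SNP array, the pool calls are decoded
deterministically into per-sample genotype probabilities, and the
remaining structured missingness is imputed with a Li–Stephens
haplotype-copying HMM against a small founder reference panel.

## Pooling design

Samples are partitioned into blocks of 16, arranged in a 4×4 grid. The 4
row-pools and 4 column-pools of each block (8 assays) replace the 16
individual assays, a 50% reduction; every sample sits in exactly two
pools. Block membership is a seeded uniform permutation chunked into
consecutive blocks, so a run is fully reproducible from its seed.
Populations whose size is not a multiple of 16 are first subsampled
(seeded, uniform) to the largest multiple of 16 — e.g. 504 lines → 496
lines → 31 blocks → 248 pools.

Pool genotyping is modeled as error-free: a pool call is 0 when all four
members are homozygous reference, 2 when all are homozygous alternate,
and 1 when the pooled DNA contains both alleles. An off-by-default noise
hook exists on the outcome array but is excluded from every test and from
the accuracy evaluation.

## Decoding

Because every sample is homozygous (dosage 0 or 2), a block is a 4×4
binary grid and the 8 pool outcomes constrain it exactly. The decoder
runs constraint propagation to a fixpoint:

1. a homogeneous pool (call 0 or 2) pins all four members to that allele;
2. a heterogeneous pool whose members are all resolved but one, with the
   resolved members sharing a single allele, forces the last member to
   the opposite allele;
3. rule 2 repeats until nothing changes.

Resolved samples get the one-hot simplex (1,0,0) or (0,0,1); unresolved
samples get (0.5, 0, 0.5) — the maximum-entropy prior over the two
homozygous states, configurable. Genotypes are therefore either fully
known or fully missing and the heterozygote probability is exactly zero
throughout.

The test suite proves this rule set sound and complete by brute force:
over all 2^16 homozygous block configurations, the decoder resolves a
cell if and only if every configuration consistent with the same pool
outcomes agrees on that cell, and it never contradicts the generating
configuration. Decoding is per-marker (LD-agnostic); the resulting
missingness is strongly structured, concentrating in markers of
intermediate and high minor-allele frequency where most pools are
heterogeneous.

## Genetic map

Marker centimorgan positions come from a 3-column (chrom, pos, cM) map by
linear interpolation in physical position between the flanking anchors
(`numpy.interp`). Markers outside the anchored range are clamped to the
boundary cM, avoiding negative or extrapolated genetic distances.
Distances enter the HMM in Morgans (cM/100), floored at 1e-8 M so the
chain stays irreducible at co-located markers.

## Imputation model

Each study sample is imputed independently (results do not depend on
order or chunking). The hidden state at a marker is an unordered pair of
template haplotypes from the reference panel of k haplotypes (here the 16
homozygous founders, one template each). Over a genetic distance d each
copied haplotype switches template with probability

    r = 1 − exp(−4·Ne·d / k)

and, on a switch, lands uniformly on one of the k templates. Ne defaults
to 16, matching the panel size. Each template allele is read with error
probability λ per marker (default 1e-3), giving the emission
`P(obs | a1, a2) = Σ_g obs_g · P(g | a1, a2)` where `obs` is the decoded
prior simplex: fully decoded markers anchor the copying path, undecided
markers are uninformative between the two homozygous genotypes.

The recursion is the scaled forward–backward algorithm. Internally the
unordered-pair chain is represented on ordered k×k matrices with the
exchangeable initial distribution (uniform over the k(k+1)/2 unordered
pairs); one transition step is two k×k matrix products, and genotype
posteriors are identical to the explicit unordered-pair chain. Per-marker
rescaling makes the pass underflow-free for any realistic marker count.

Genotype posteriors are the state marginals combined with the conditional
of the true genotype given the local observation and the mutation
channel, `P(g | state, obs) ∝ obs_g · P(g | a1, a2)`. This choice matters
for inbred data: since decoded priors carry zero heterozygote mass, the
posterior heterozygote probability is exactly zero at every cell, and a
fully decoded genotype is always reproduced by the best guess. A raw
projection of state mass onto the template-pair dosage is available
(`projection="template"`); it spreads probability onto heterozygous
template pairs near recombination breakpoints, which is undesirable for
fully homozygous populations. A haploid single-copy mode
(`haploid=True`, states = single templates) is provided for explicitly
inbred chromosomes but is not the default.

With λ = 0 and contradictory observations the total likelihood can reach
exactly zero; this raises an error advising λ > 0 rather than returning
NaNs. Ties in the best-guess genotype (p0 == p2 exactly) are written as
`./.` in the VCF GT field while GP keeps the full simplex, and are
counted as discordant in the metrics.

## Synthetic MAGIC generator

The generator produces the structure the method relies on, without any
external download:

- **Founders.** 16 fully homozygous founders; marker cM positions uniform
  on a single chromosome of 150 cM (a realistic scale for a wheat
  chromosome); each marker draws its MAF bin from the profile
  (0.285, 0.343, 0.129, 0.157, 0.086) over bins 0.05–0.10 … 0.40–0.50 and
  a compatible founder minor-allele count (1–8 of 16), so founder MAF is
  never below 1/16. The minor allele is the alternate or the reference
  with equal probability.
- **Lines.** Each of the default 496 lines descends from its own funnel:
  a random permutation of the 16 founders is paired down over 4
  generations of crossing, then selfed for 6 generations. Meioses place
  crossovers as a Poisson process at 1 per Morgan without interference
  (Haldane). Haplotypes are tracked as founder-index mosaics, so the
  emitted mosaic sidecar is exact by construction. Residual heterozygous
  sites after selfing (about (1/2)^6 of initially heterozygous sites) are
  fixed to one allele by a fair coin, mirroring datasets curated to full
  homozygosity.

The study population drifts away from the founder spectrum, so a
0.00–0.05 MAF bin appears in the lines even though founder MAF ≥ 1/16 —
the same drift effect seen in real multi-parent populations.

What the generator does **not** emulate: genotyping error in pools or
individuals, allopolyploid subgenome artifacts, selection during
breeding, multi-funnel pedigree structure shared between lines, and
LD-pruned marker ascertainment. Synthetic lines are *perfect* founder
mosaics with an exactly known genetic map, so absolute imputation
accuracy on synthetic data is higher than on real data; passing tests
demonstrate the qualitative behaviour of the method (which MAF bins decode
poorly, how imputation repairs them, absence of heterozygote calls), not
field-data error rates.

## Evaluation

- **Concordance**: fraction of best-guess genotypes equal to the truth
  over all classes, reported overall and per MAF bin. The overall figure
  is the mean of per-marker concordances (each marker weighted equally);
  pooled-cell averaging is available.
- **Cross-entropy**: −ln p(true genotype) per cell, clipped at
  eps = 1e-12 (so a confidently wrong call costs −ln(1e-12) ≈ 27.6),
  natural log, averaged the same way.
- MAF bins [0, .05, .10, .20, .30, .40, .50], half-open with the last bin
  closed; MAF is computed in the truth study population, not the panel.
- Rolling five-marker windowed scores along ascending MAF and per-0.05-bin
  quantile envelopes (0, 0.01, 0.25, 0.75, 0.99, 1.0) provide plot-ready
  accuracy curves; a column-normalized true-vs-observed AAF joint
  histogram summarizes frequency preservation (decoding alone
  systematically underestimates mid-range alternate-allele frequencies
  because undecodable cells are exactly the alt-carrying ones).

## Numerical and testing choices

- Forward–backward is validated against an independent brute-force path
  enumeration (all ordered template-pair paths, k ≤ 3, M ≤ 4) to 1e-10;
  the decoder against exhaustive enumeration of all 65,536 block
  configurations; both oracles live in the test suite and the acceptance
  script.
- Default problem sizes in tests and the acceptance script are the study
  conditions themselves (16 founders, 496 lines, 1170 markers), which run
  in well under a minute for any single stage; unit tests use 32-line /
  ~120-marker populations.
- VCF output carries GT plus GP as linear probabilities rounded to six
  decimals (undecided → `./.` with informative GP); GL = log10(max(p,
  1e-12)) is optional. Decoded priors contain exact zeros, which GL alone
  could not represent.

## Known limitations

- Error-free pool calls are assumed end to end; the noise hook
  (`pooling.add_pool_noise`) exists for experimentation but no decoding or
  accuracy guarantee holds under noise.
- One chromosome per simulation and per HMM run; multiple chromosomes are
  an outer loop.
- The decoder is specific to the 4×4 row-column design; other pool sizes
  or designs are out of scope.
- The Li–Stephens parameterization (switch rate `1−exp(−4·Ne·d/k)`,
  uniform jump target, per-allele error λ) is one standard choice; other
  imputation engines use different scalings, so numerical agreement with
  them is not expected beyond qualitative behaviour.
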