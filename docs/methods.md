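# Methods

## Genetic model

Four alleles segregate at the target locus of a haplosufficient gene
required for larva-to-adult survival:

| allele | functional | cleavable | meaning |
|--------|-----------|-----------|---------|
| W | yes | yes | wild type |
| T | no  | no  | drive construct (disrupts the gene) |
| R | no  | no  | end-joining product, function lost |
| r | yes | no  | end-joining product, function preserved |

Genotypes are unordered pairs (10 total). An individual is viable iff it
carries at least one functional allele, so T/T, T/R and R/R die between
the juvenile and adult stages. A carrier is any genotype containing T
(dominant fluorescent marker).

Germline homing acts only in W/T individuals — cleavage requires both the
nuclease (T) and a cleavable partner (W). With sex-specific conversion
rate *e*, end-joining fraction *u* and functional-repair probability *p*,
a W/T parent's gametes are

    P(T) = (1+e)/2,  P(W) = (1−e)(1−u)/2,
    P(r) = (1−e)up/2,  P(R) = (1−e)u(1−p)/2.

All other genotypes segregate 1/2 : 1/2. Rates are parameterised from the
measured transmission rate *d* via *e* = 2*d* − 1 (so *d* ≥ 0.5 is
required, and the gamete model returns exactly *d* for P(T)); total
cleavage is *c* = *e* + (1−*e*)*u* and the end-joining share among cleaved
alleles *j* = (1−*e*)*u*/*c*, defined as 0 when *c* = 0 to avoid 0/0.
Defaults: *d_f* = 0.927, *d_m* = 0.913, *u* = 0.266 (measured on pooled
larvae, shared between sexes), *p* = 0. Parental deposition and somatic
cleavage are not modelled; their phenotypic consequences are absorbed by
the fitness costs.

## Population recursion

Two sexes, two life stages, discrete non-overlapping generations, random
mating, frequencies only (no density dependence). One generation:

1. **Gamete pools.** Females contribute frequency × (1 − fecundity cost)
   × gamete distribution; males frequency × gamete distribution (equal
   mating success, no male fecundity component). Pools are renormalised.
2. **Juvenile census.** Zygotes are the outer product of the two pools
   collapsed to unordered genotypes, identically in both sexes (1:1
   primary sex ratio). This census is taken post-hatch — after the
   fecundity cost, before mortality — matching how larvae were scored
   from sampled eggs; reported carrier trajectories use it from
   generation 1 on, while generation 0 reports the released adults.
3. **Adult census.** Juveniles × viability (0 without a functional
   allele) × (1 − somatic cost) for viable carrier heterozygotes,
   sex-specific, renormalised.

Fitness defaults (measured): fecundity cost 0.216 in carrier females
(1 − relative hatching rate); somatic costs 0.378 (M) / 0.462 (F)
(1 − relative eclosion rate). The `high_cost` scenario replaces both
somatic costs with 0.9 (they do not stack on the measured values; the
compounding reading remains expressible through custom schemes) and keeps
the measured fecundity cost. Costs apply to every viable carrier
heterozygote, including T/r. W/R, W/r, r/r and W/W are fully fit. The
Mendelian control (a non-driving null allele in the same gene) uses
*e* = *u* = 0 and no heterozygote costs; recessive lethality still
applies, giving the classical adult decline q′ = q/(1+q).

If the viable weight in either sex falls below 1e-12 the state is flagged
extinct and propagated unchanged instead of dividing by zero; trajectories
truncate at the extinction record.

**Relative reproductive output** is reported per adult census as
(mean fecundity multiplier among females) × (probability that a zygote is
genotypically viable) — the expected viable eggs per female relative to an
all-wild-type population. Somatic survival is excluded; it acts at the
larva-to-adult transition, not on egg viability. The value is 1 for wild
type and falls with both the fecundity cost and the zygotic death load of
the drive.

## Scenarios

* **Release:** 20% W/T, 80% W/W adults in both sexes, default 12
  generations (the published curves do not state their horizon; 12 shows
  the full divergence of the three cost scenarios).
* **Fixation mimic:** founders 100% W/T in both sexes — the regime of
  strongest selection for functional resistance. The canonical setting
  runs without heterozygote costs, isolating the drive's intrinsic
  genetic load: under the measured heterozygote costs the deterministic
  recursion cannot hold the drive at fixation (carriers decline and
  output recovers with no resistance at all), whereas with the intrinsic
  load only, homing keeps carriers near 96% indefinitely, output
  equilibrates near 0.29 when *p* = 0, and any *p* > 0 lets the r allele
  sweep (monotonically, and monotonically in *p*), restoring output
  toward 1 — with *p* = 0.005 the rescue generation (r allele frequency
  crossing 0.5) is 7. Callers may pass any `FitnessScheme`; both regimes
  are exercised in the tests.
* **Resistance sweep:** one release trajectory per *p*, everything else
  fixed; emitted as a tidy (generation, p, carrier_freq) table. Through
  generation 5 the trajectories differ by under 0.02 in carrier
  frequency, so early cage data cannot distinguish *p*.
* **Cost fitting:** grid search minimising the sum of squared differences
  between a modelled and an observed carrier series (generation 0 =
  released adults), replacing both somatic costs with the candidate while
  keeping the base fecundity cost; ties break toward the smaller cost.
  This formalises what was otherwise a visual model-to-data comparison.

## Stochastic cage model

A replicate is a Markov chain conditional on its own realised draws, as a
real cage is: adults of generation t+1 are a multinomial draw (n/2 per
sex, default 400 total) from the deterministic adult distribution given
the realised generation-t adults; the scored juveniles are an independent
multinomial draw (default 450 eggs) from the conditional juvenile
distribution. Marker phenotype equals carrier status (the marker is
dominant and fully penetrant). Means over replicates converge on the
deterministic trajectory as populations grow (error ∝ 1/√n); with 200
replicates at the experimental census sizes the means sit within
Monte-Carlo error of the deterministic path through generation 5.

Progeny screens draw per-female brood sizes from a negative binomial
(default mean 100, shape 5 — a package choice; the source data show
overdispersion but no fitted distribution) and marker counts as
binomial(brood, *d*); the pooled estimate uses a binomial standard error.

## Amplicon classification

* **Reference:** 349 bp with the drive protospacer
  `GAACAACAACAAAAGACTGT` + `AGG` PAM at offset 163. The true genomic
  amplicon sequence is not public; the canonical fixture embeds the real
  protospacer/PAM in seeded synthetic flanks (it is labelled synthetic in
  code). The cut index is the boundary 3 bp 5′ of the PAM
  (protospacer_start + 17; 0-based, half-open throughout).
* **Alignment:** global, affine scoring (match +2, mismatch −1, gap open
  −5 on the first gapped base, extend −1 thereafter), executed by
  Bio.Align.PairwiseAligner with a substitution matrix in which N never
  matches. The aligner's canonical first traceback makes repeated calls
  deterministic. Brute-force enumeration on short instances verifies the
  scores.
* **Quality filter:** keep iff mean Phred (Phred+33) ≥ 30, boundary
  inclusive.
* **Window rule:** a read is modified iff the alignment shows a mismatch
  or deletion at reference positions {cut−1, cut, cut+1}, or an insertion
  anchored exactly at the cut (for the default ±1 window). Reads whose
  aligned span does not cover the window are uninformative and excluded.
  The rule is invariant to padding the reference with extra flank.
* **Frameshift:** net indel (inserted − deleted bases over the read's
  aligned span, end gaps excluded) mod 3 ≠ 0, evaluated only for modified
  reads; substitutions never contribute. The spectrum reports per-allele
  counts/frequencies and two marginals: fraction modified, and fraction
  of modified alleles that are in-frame.

The read simulator draws reads from a configured allele spectrum
(multinomial, or largest-remainder apportionment for exact round trips),
applies uniform per-base substitution errors (≤ 0.1) and constant or
two-level qualities. Error-free round trips through the classifier
reproduce the configured spectrum exactly.

## Numerical conventions and problem sizes

Probabilities are carried at full double precision; printed comparisons
round half away from zero to 3 decimals. Frequency vectors must sum to 1
within 1e-10 (1e-12 for gamete/zygote distributions). Default test and
verification sizes: 200 cage replicates × 5 generations, 1000 progeny
screens, sweeps over 4 *p* values × 12 generations, read sets of
60–10,000; the full suite runs in a few seconds.

## Limitations

Deterministic model: no age structure, spatial structure, mate choice,
density dependence or parental deposition. The stochastic cage model
omits demographic details (egg-number variation between females, sampling
without replacement at small counts). The read simulator's error model is
uniform — no homopolymer or quality-decay structure — so classifier
performance on error-free synthetic data bounds, but does not guarantee,
performance on real amplicon libraries; likewise the synthetic flanks
mean fixture-specific alignments, not the genomic locus. Single-end,
pre-trimmed reads only; no UMI handling or off-target analysis.
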