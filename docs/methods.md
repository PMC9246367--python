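# Methods

## Model

The core model is a symmetric two-population isolation-with-migration (IM)
system at migration–drift equilibrium: two haploid populations of constant
size N, per-lineage gene flow at rate m per generation, and
population-specific substitution rates μ₁, μ₂ under the infinite-site model
(no reverse or repeat mutation, so substitution counts add along branches).
Tracking one lineage from each population backwards in time gives a 6-state
continuous-time Markov chain over the configurations (1|2), (2|1), (12|),
(|12), (0|), (|0) (the bar separates populations; 0 is the coalesced pair).
Its generator A has migration rate m per lineage and coalescence rate 1/N
for a co-located pair; columns sum to zero.

Relative divergence at equilibrium is F_ST = 1/(1+4Nm). Writing
S_{i|j} for the expected pre-coalescence time a lineage sampled in
population j spends in population i, the chain gives S_{1|1} = S_{2|2} =
(1+2Nm)/(2m) and S_{2|1} = S_{1|2} = N, and the observed rate ratio of a
cross-population pair,

    r = (μ₂S_{2|2} + μ₁S_{1|2}) / (μ₁S_{1|1} + μ₂S_{2|1})
      = (1 + r₀ + F_ST(r₀−1)) / (1 + r₀ − F_ST(r₀−1)),   r₀ = μ₂/μ₁.

The identity between the sojourn assembly and the closed form is asserted
numerically to 1e-10 on a parameter grid. Sojourn times are additionally
computed by two independent numeric routes — the transient-block linear
solve ∫₀^∞ e^{Bt}dt = −B⁻¹ and adaptive quadrature of the matrix exponential
with a spectral tail bound — rather than trusting a single discretization;
the routes agree with the closed forms to better than 1e-6 relative error.

Assumptions worth keeping in mind: equilibrium population structure (no
secondary contact), neutrality, infinite sites, and no substructure within
either population. The stepping-stone simulator exists precisely to probe
the last assumption: internal structure inflates F_ST without adding rate
divergence, so (r−1)/(r₀−1) under-runs F_ST there.

## Statistics

**Hudson F_ST** is accumulated per window as a ratio of averages: per-site
numerator (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) and denominator
p₁(1−p₂) + p₂(1−p₁), summed over sites before dividing. This estimator is
robust at small sample sizes and needs at least two called alleles per
population per site. Negative window ratios (sampling noise around zero
divergence) are truncated at 0 so reported values stay in [0, 1]; undefined
windows (monomorphic in both populations) are NA, never silently 0. π and
D_XY are per-site unbiased heterozygosities normalized by window span, or by
accessible bases when a mask is given — invariant sites therefore contribute
zero, which is correct for all-sites VCFs of variant records.

**D₃, D₄ and the rate ratio** are computed from pattern *probabilities*
per site (products of derived-allele frequencies), equivalent to averaging
the classical one-allele-per-taxon sampling and therefore deterministic; a
seeded sampled-allele mode exists for cross-checking. Polarization: D₃
requires its outgroup non-polymorphic, D₄ requires the second outgroup
non-polymorphic, the rate ratio requires every used outgroup fixed for the
same allele; violating sites are excluded, not repaired. The rate ratio is
oriented as r = ⟨n₂⟩/⟨n₁⟩ (numerator = derived alleles exclusive to the
faster-labelled population P₂); `rate_ratio_site_terms(freqs, A, B, ...)`
estimates lineage A's rate relative to B's, so the orientation is always
explicit at the call site.

**Background F_ST** of a SNP covered by several sliding windows is the mean
of the covering windows' F_ST (maximum selectable); partitioning is either
cumulative thresholds {F_ST ≥ t} or ten equal-width bins over the observed
range. Partitions below a configurable site floor are flagged, not
suppressed.

**Block jackknife.** All ratio statistics get delete-one-block standard
errors over 1 Mb blocks (blocks never span chromosomes), using the weighted
formula of Busing, Meijer & van der Leeden (1999) with block site counts as
weights; with equal weights it reduces exactly to the classic delete-one
jackknife. Z = estimate/SE. For the Pearson correlation between segment
statistics the point estimate and SE are reported on the raw ρ scale but the
Z-score is computed on the Fisher (arctanh) scale: the raw-scale jackknife Z
is measurably anti-conservative at the 3σ tail (≈1.0% exceedance under an
independent null at 60 segments, versus ≈0.5% after stabilization), and the
correlation's significance is exactly what the entropy–divergence analysis
consumes.

## Ancestry entropy

Diploid dosages (ELAI-style, in [0, 2]) are halved and snapped to
{0, ½, 1} (ties at 0.25/0.75 round toward ½; snapping tolerance
configurable). Each marker maps to the unit phasor z = e^{iθ} with
θ = arg(p₁ + i·p₂), i.e. the phase of the raw ancestry vector: pure
ancestries sit at 0 and π/2 and the heterozygous state at π/4. This choice
makes the label swap p₁ ↔ p₂ the exact isometry z ↦ i·z̄, so both entropies
are invariant under relabelling the parental populations to machine
precision — a property the analysis should not depend on breaking. The
alternative convention θ = arccos(p₁) (heterozygotes at π/3) is available as
`phase="arccos"` but is not label-symmetric, which is why it is not the
default.

S_w: markers are treated as equally spaced samples of the continuous signal;
the FFT coefficients are normalized to unit total power, folded around zero
frequency (ζ₀ = |Z₀|², ζₙ = |Zₙ|² + |Z₋ₙ|² for n > 0, the Nyquist bin of an
even-length grid being its own mirror), and S_w = −Σζₙ ln ζₙ in nats with
0·ln 0 ≡ 0. A single-marker signal returns S_w = 0 with a warning. The
discrete spectrum converges to the continuous Fourier series as marker
density grows; for the half/half two-step signal the analytic series
(ζ₀ = ½, ζₙ = 4/(πn)² for odd n) is matched to <1% relative error at 4096
markers.

S_b: the cohort matrix C is Hermitian with unit diagonal; eigenvalues within
1e-9 of zero are clipped to zero before the entropy; eigenvalues below
−1e-9 raise. S_b attains 0 for identical cohorts and ln J for cohorts with
zero average cross-correlation. Note that an i.i.d. balanced-dosage cohort
does *not* reach ln J: i.i.d. phasors keep a common nonzero mean, so the
average cross-correlation converges to |E z|² ≈ 0.73 and S_b plateaus well
below the bound; the maximum-entropy endpoint requires genuinely
uncorrelated *signals*, not just i.i.d. markers.

With replicate ancestry estimates (e.g. 50 repeated HMM runs), entropies are
computed per replicate and per segment; the replicate spread provides the
reported standard errors, and S_w is reported per individual plus the cohort
mean. The sex chromosome is excluded from the entropy–divergence correlation
by default (configurable), as its inheritance and effective size differ.

## Recurrent-mutation theory

With true counts n₁, n₂ of sites whose derived allele is exclusive to focal
lineage 1/2 and D̂₃ = (n₁−n₂)/(n₁+n₂), a recurrent mutation in outgroup i
(probability pᵢ per site) converts to the focal derived allele with
probability c (flipping the pattern) and otherwise creates a third allele
(removing the site from biallelic analysis). This gives exactly

    D₃ = D̂₃ (1−(c+1)p₁) / (1+(c−1)p₁)   ≈ (1−2cp₁) D̂₃,

and, to first order in the pᵢ, D₄ = D̂₃(p₂−p₁)/(p₂+p₁). The generator
implements the full per-site process (including double conversions, which
produce patterns counted by neither statistic), so the exact D₄ expectation
is D̂₃(p₂−p₁)/(p₂+p₁−2p₁p₂); the first-order formula is therefore validated
in the small-pᵢ regime it describes (pᵢ ≤ 0.04 in the tests), while the D₃
formula is exact at any p₁.

## Synthetic data

The generators define the conditions under which the pipeline is validated;
all are seeded and bit-reproducible.

- **Pair engine** (`pair_sojourns`): vectorized Gillespie simulation of the
  6-state chain (generalized to any deme graph); exclusive derived-allele
  counts are Poisson with mean Σ_d μ_d × (sojourn in deme d) per lineage.
  Loci are exchangeable draws — no recombination within a pair history.
- **Landscape** (`simulate_im_landscape`): windows in classes with
  class-specific m (or target F_ST), each window containing independent
  non-recombining loci simulated under the full structured coalescent for
  2×4 diploid samples by default, with mutations Poisson per branch at
  deme-specific rates. Outgroups attach above the ingroup root at fixed
  times (4N and 6N generations by default) as homozygous diploids; stem and
  outgroup-branch mutations are included, so polarization-ineligible sites
  occur as in real data. Optional recurrent-mutation injection converts
  outgroup states (probability pᵢ, conversion c) or drops the site as
  multiallelic. Default scale: N = 200, μ₁ = 2.5e-3/generation, 180 windows
  of 50 kb in six F_ST classes (0.1–0.85), 20 loci/window — a deliberately
  scaled-down system (θ = 2Nμ = 1 per locus) that preserves the
  dimensionless quantities the theory depends on (4Nm, r₀, site counts per
  bin) while keeping a full pipeline run under half a minute.
- **Stepping stone**: 1-D chain of demes split into two species with
  adjacent-deme migration (a distinct rate across the species boundary),
  sampled at the chain ends; with two demes it reduces to the pair engine
  (verified on matched moments).
- **Site patterns**: multinomial draws of the recurrent-mutation process
  over jackknife blocks, per the exact process above.
- **Block ancestry**: haploid chromosomes break between adjacent markers
  with a single disassociation probability, blocks draw ancestry i.i.d.
  Bernoulli(q), and haploid pairs sum to diploid dosage — the toy model
  whose entropy response (monotone in disassociation and in contribution
  balance) is reproduced over 1000 replicates of 1000 SNPs.

What the generators do **not** emulate: selection and linked selection,
recombination within loci, non-equilibrium demography (secondary contact,
expansions), sequencing/genotyping error, incomplete lineage sorting with
the outgroups (outgroups always attach above the ingroup root), and
phasing/ancestry-inference error beyond replicate-level noise. Passing tests
therefore demonstrate correctness of the estimators and the internal
consistency of theory and simulation — not robustness to those real-data
complications, of which equilibrium structure is the one the theory itself
flags as critical.

## Numerical choices

- r₀ fitting: weighted least squares on the exact r(F_ST; r₀) curve with
  weights 1/SE² (bins with missing SE get the median weight), solved by
  Brent root-finding on the normal equation within r₀ ∈ [0.1, 10] (the
  model is monotone in r₀), falling back to bounded scalar minimization
  when no interior stationary point exists; SE by bootstrap over bins
  (500 resamples, seeded).
- Eigenvalue clip tolerance 1e-9; folded-spectrum sum asserted to 1 ± 1e-9.
- Windows are left-closed right-open, assigned by start; terminal partial
  windows kept with their site counts. VCF positions converted to 0-based
  half-open at the boundary; BED consumed natively; multiallelic and indel
  records skipped with a logged count.
- Missing genotypes: a site contributes to a population's frequencies when
  the population has ≥1 called allele (≥2 for F_ST's sampling correction
  and π).
- Undefined values are NA and flagged; zero denominators never yield 0.

## Problem sizes in the validation suite

Monte-Carlo checks use 1e5 lineage pairs per parameter point (r and F_ST
within 3 MC-SE of the closed forms over (4Nm, r₀) ∈ {0.25, 1, 4} × {1,
1.837, 3}); end-to-end recovery uses the default landscape at r₀ ∈ {1,
1.837} with a 10% tolerance dominated by F_ST-binning noise; null
calibration uses 100 seeds × 1e5 sites. These sizes were chosen so the full
suite runs in well under a minute per criterion on one CPU while keeping
Monte-Carlo error far below the tested tolerances.

## Known limitations

- The equilibrium assumption is load-bearing: the r–F_ST curve is not
  expected to fit secondary-contact systems quantitatively, though the
  monotone relationship should persist.
- The rate ratio ignores incomplete lineage sorting; shared ancestral
  polymorphism would inflate both numerator and denominator and dilute r
  toward 1.
- Only two parental ancestries are supported by the entropy metrics as
  implemented; the multi-ancestry generalization is not specified here.
- Hudson's F_ST is the only estimator provided (pluggable at the
  `windowed_stats` level); Weir–Cockerham multi-population F_ST is out of
  scope.
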