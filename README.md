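# ratemix

Tools for studying **rate mixing** in hybridizing species: when two sister
lineages accumulate substitutions at different rates (μ₁ ≠ μ₂) while still
exchanging genes, the parts of the genome most open to gene flow evolve at a
blended rate, and the parts locked behind barriers to gene flow keep their
species-specific clocks. `ratemix` implements the statistics and the
coalescent theory needed to detect and quantify this process from
whole-genome data of a few individuals — the typical situation for rare or
hard-to-collect taxa — together with seeded simulators so every stage of the
analysis can be validated without any external data.

The package is aimed at population-genomicists working on hybrid zones and
speciation genomics.

## What it computes

**Divergence scans.** Windowed Hudson F_ST (ratio of averages), D_XY and π
between two focal populations from a VCF, with segment averaging and 1 Mb
block-jackknife machinery (`ratemix.popgen`, `ratemix.jackknife`).

**Ancestry entropy.** Unphased diploid local-ancestry dosage p₁(l) ∈
{0, ½, 1} is mapped to a unit phasor z(l) = e^{iθ(l)}, θ = arg(p₁ + i·p₂).
Two spectral entropies summarize ancestry randomness where tract lengths are
undefined (unphased data, few samples):

- S_w = −Σₙ ζₙ ln ζₙ, the entropy of the folded power spectrum ζₙ of z
  along a chromosome interval (within-individual randomness);
- S_b = −Σⱼ (λⱼ/J) ln(λⱼ/J), the entropy of the eigenvalues of the J×J
  cohort cross-correlation matrix c_{jj'} = ⟨z_j z̄_{j'}⟩ (between-individual
  randomness), with 0 ≤ S_b ≤ ln J.

Low entropy marks ordered ancestry — the signature of linked barrier loci in
a hybrid population (`ratemix.entropy`).

**Site-pattern asymmetry.** With focal taxa P₁, P₂ and outgroups O₁, O₂ and
sites polarized by non-polymorphic outgroups:

- D₃ = (ΣABB − ΣBAB)/(ΣABB + ΣBAB), three-taxon asymmetry;
- D₄ = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA), the ABBA-BABA statistic;
- observed rate ratio r = Σf_{P₂}(1−f_{P₁}) / Σ(1−f_{P₂})f_{P₁} over sites
  where all outgroups are fixed for the same ancestral allele,

each with 1 Mb block-jackknife standard errors, partitioned by background
F_ST thresholds or bins (`ratemix.sitepatterns`). Closed forms for how
recurrent outgroup mutation (probability pᵢ, conversion probability c)
distorts D₃ and makes D₄ spuriously negative are in `ratemix.theory`:
D₃ = D̂₃(1−(c+1)p₁)/(1+(c−1)p₁) and D₄ = D̂₃(p₂−p₁)/(p₂+p₁) — an
ABBA-BABA false positive requiring no gene flow at all.

**Equilibrium theory.** For two haploid populations of size N exchanging
genes at rate m, F_ST = 1/(1+4Nm) at migration–drift equilibrium, and the
observed rate ratio obeys

    r = (1 + r₀ + F_ST(r₀−1)) / (1 + r₀ − F_ST(r₀−1)),   r₀ = μ₂/μ₁,

so (r−1)/(r₀−1) ≈ F_ST when r₀ ≈ 1: the fraction of rate divergence that
survives gene flow equals relative divergence. `ratemix.theory` provides the
6-state pair-coalescent generator, sojourn times by three independent routes
(closed form, linear solve, quadrature), and weighted least-squares fitting
of r₀ from binned (F_ST, r) data.

**Simulators** (`ratemix.simulate`, engines in `ratemix.coalescent`): the
two-deme pair CTMC with population-specific mutation rates, a windowed
multi-sample landscape with heterogeneous gene flow and distant outgroups
(emitted as VCF), 1-D stepping-stone chains, recurrent-mutation site-pattern
draws, and the block-ancestry model behind the entropy metrics. All seeded
and bit-reproducible.

## Worked example

```python
from ratemix.theory import fst_equilibrium, r_from_fst
from ratemix.simulate import simulate_im_pair, pair_rate_ratio

N, m = 100, 0.0025                      # 4Nm = 1
fst = fst_equilibrium(N, m)             # 0.5
print(r_from_fst(fst, r0=2.0))          # 1.4  (theory)

rec = simulate_im_pair(100_000, N, m, mu1=1e-3, mu2=2e-3, seed=1)
r_hat, se = pair_rate_ratio(rec)
print(f"{r_hat:.3f} +/- {se:.3f}")      # 1.403 +/- 0.010  (simulation)
```

At intermediate divergence (F_ST = 0.5) a true two-fold rate difference is
observed as r ≈ 1.4: gene flow has mixed away 60% of the rate divergence
exactly as the equilibrium formula predicts; the Monte-Carlo estimate agrees
within its standard error.

The numbered drivers under `analysis/` run the three full analyses on
synthetic data and write tables under `results/`:

```
python analysis/01_entropy_vs_divergence.py   # entropy vs pi/DXY/FST, jackknife Z
python analysis/02_dstat_scan.py              # D3/D4 vs FST threshold
python analysis/03_rate_fst_fit.py            # r per FST bin, r0 fit
```

The last one prints, for a landscape simulated at r₀ = 1.837:

```
found: fitted r0 = 1.838 (SE 0.030) vs truth 1.837 — 0.0% off
stepping-stone contrast (strong within-species structure): FST = 0.839
but (r-1)/(r0-1) = 0.513 — within-species structure makes the rate
divergence look weaker than FST suggests
```

A `ratemix` command-line interface exposes the same pipeline as subcommands
`stats | entropy | dstats | ratefit | simulate`, each driven by a YAML
config plus `--seed`/`--out` (see `ratemix --help`).

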