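# Methods

`nutmet` analyses balanced multi-environment wheat trials (genotypes ×
site-years × replicates) for mineral nutritional yield and for the
stability and adaptability of that yield. This note records the models,
the numerical choices, and what the synthetic data do and do not emulate.

## Nutritional yield and nutrient density

For mineral *m* with daily recommended intake DRI_m (mg·day⁻¹), a plot
with grain yield *Y* (kg·ha⁻¹ at 13% moisture) and wholemeal
concentration *C* (mg·kg⁻¹) feeds

    NY = Y · C / (DRI_m · 365)        [adults·ha⁻¹·year⁻¹]

adults at 100% of their intake for a year. Defaults are the adult-average
DRIs Fe 12, Zn 8, Cu 0.9, Mg 315 mg·day⁻¹ and a 365-day year. Nutrient
density is reported inversely as grams of wholemeal per day reaching
100% of one DRI, `1000·DRI/C`.

Hulled wheats (spelt, emmer, einkorn — config `hulled_groups`, default
{Spelt, Primitive}) are corrected to a naked-grain basis by multiplying
yield by the dehulling factor 0.75 *before* any nutritional-yield
computation or averaging.

Genotype-level nutritional yield is the arithmetic mean of *per-plot*
values, not the formula applied to mean yield × mean concentration. The
two differ whenever yield and concentration co-vary across plots — and
they do, negatively (the dilution effect) — and only per-plot averaging
is consistent with published genotype summaries of this kind. Rows taken
from the literature carry a single (yield, concentration) pair, so for
those the formula is applied directly.

Reported tables round adults·ha⁻¹·year⁻¹ and grams to the nearest
integer, half away from zero; all internal computation is full
precision.

Trait correlations are computed on genotype × environment cell means
(n = G·E). The observational unit behind published correlation tables of
this kind is usually unstated; cell means are the defensible middle
ground between plot-level (which double-counts replicate noise) and
genotype-level (n too small) and this choice is configurable in the API
by passing a different trait table.

## AMMI

The genotype × environment mean table is decomposed as
Ȳ_ij = μ + g_i + e_j + Σ_k λ_k α_ik γ_jk, with the additive terms from
the two-way ANOVA and the multiplicative terms from the SVD of the
double-centered residual Z. Implementation notes:

* **Scaling.** Scores are stored in symmetric scaling (both sides carry
  √λ), so genotype-score × environment-score products reconstruct the
  interaction directly and the full-rank reconstruction identity holds
  to < 1e-8. Magnitudes under asymmetric scalings differ by √λ factors;
  orderings by |PC1| do not.
* **Sign.** The SVD sign is arbitrary; each component is oriented so the
  environment with the largest |score| is positive.
* **Degenerate input.** Singular values below √(1e-12) × the matrix
  scale are set to exactly zero; a purely additive table therefore
  reports zero scores and 0% variance explained rather than numerical
  noise, and the stability ranking falls back to performance ordering.
* **Variance explained** is λ_k²/Σλ² over the retained k = min(G,E)−1
  components — a share of the *interaction* sum of squares, not of the
  total.
* **Stability ranking** splits genotypes at the grand mean of their
  performance means, lists the above-average class first, and orders
  within class by |PC1| ascending; remaining ties break by performance
  descending, then genotype name. F-tests for G, E and G×E use the
  pooled within-cell error; no multiple-testing adjustment is applied.

## BLUP and harmonic-mean statistics

The per-trait mixed model is y_ijr = μ + E_j + g_i + (ge)_ij + ε_ijr
with environments fixed and genotype and interaction effects random — the
standard single joint model behind HMGV/RPGV/HMRPGV. Per-environment
fits would forfeit the shrinkage sharing that motivates BLUP here.

Variance components: on balanced data the ANOVA closed forms are exact
REML (σ̂²_ε = MS_err, σ̂²_ge = (MS_GE − MS_err)/r,
σ̂²_g = (MS_G − MS_GE)/(r·e)) with negative estimates truncated to zero.
Unbalanced data fall back to EM-REML: deterministic initialisation at
the method-of-moments values, components floored at 1e-12 of the
phenotypic variance, at most 10 000 iterations, and convergence declared
when both the relative log-likelihood change and the largest relative
parameter change drop below 1e-8 (the parameter criterion matters
because EM's log-likelihood flattens before the components settle).

Genotypic values GV_ij = μ̂_j + BLUP(g_i) + BLUP((ge)_ij) solve
Henderson's mixed-model equations at the estimated components. Then

    HMGV_i = e / Σ_j 1/GV_ij,   RPGV_i = (1/e) Σ_j GV_ij/μ̂_j,
    HMRPGV_i = e / Σ_j μ̂_j/GV_ij,

with μ̂_j the observed environment mean of cell means. Ranking is by
HMRPGV descending. The harmonic mean requires GV > 0; a genotype
violating that is reported by name rather than silently dropped. The
AM–HM inequality (HMGV ≤ arithmetic mean GV, HMRPGV ≤ RPGV) is asserted
on every fitted table.

## Selection indexes

**Elston (EMI).** EMI_i = Π_t (x_it − LAL_t) over genotype-mean
nutritional yields, zero (and flagged) when any trait fails its lowest
acceptable limit. Default LALs 28/40/50/25 adults·ha⁻¹·year⁻¹ for
Fe/Zn/Cu/Mg are the trial minima. No recentering is applied: adding a
constant to a trait changes ranks unless the LAL shifts equally, which
is the documented behaviour.

**Desired gains (Pesek–Baker form).** Coefficients solve G·b = d, so the
expected response G·b is proportional to the stated gains d (default
11/4/0/6 toward 50 adults·ha⁻¹·year⁻¹ per mineral). The zero Cu gain is
deliberate — it instructs the index to hold Cu constant and generally
yields a nonzero (here negative) Cu coefficient. G is estimated as the
covariance across genotypes of BLUP genotypic main-effect values, which
is stabler in a 19-genotype trial than raw mean covariances; the solve
is refused when cond(G) > 1e10 unless a ridge term (fraction of the mean
diagonal, default 0) is supplied.

**Combined ranking.** The balanced-genotype ranking is the mean of the
component rank positions — AMMI stability rank and BLUP-HMRPGV rank for
yield and each mineral nutritional yield, plus EMI and BDGI (12
components with the default four-mineral panel) — with lexicographic
tie-breaks. Mean rank is deliberately simple and transparent; it treats
every component equally, which is the point of "balanced".

## Synthetic data

`generate_met` draws yield_ijr = μ + g_i + e_j + Z_ij + ε_ijr with g and
e re-centered to exact zero sum and Z = Σ_k λ_k α_ik γ_jk built from
QR-orthonormalised Gaussian score vectors orthogonal to the constant
vector — so the simulated interaction has exactly the requested rank and
singular values, and AMMI/BLUP estimators can be tested against stored
truth rather than against themselves. Concentrations follow
C = base·(μ/E[yield_ij])^θ·(1+η) with η ~ N(0, cv²), floored at zero:
multiplicative, CV-scaled noise for a positive quantity, with θ > 0
producing the negative yield–concentration (dilution) coupling seen in
real grain.

Defaults mirror the organic-trial design: 19 genotypes × 3 years × 2
replicates, μ = 3959 kg·ha⁻¹, σ_g = 800, σ_env = 400, σ_ε = 300
kg·ha⁻¹, one interaction component λ = 600, Fe/Zn/Cu/Mg bases
43/36/5/1200 mg·kg⁻¹ with θ = 0.5 and 10% CV, and 4/19 hulled
genotypes. The generator does not emulate spatial field trends, weather
covariates, missing plots, or trait-specific error correlations; passing
recovery tests therefore demonstrate estimator correctness under the
stated model, not robustness to those real-data features. Recovery
oracles set `hulled_fraction = 0` so the analysed yield stays on the
generated scale (the dehulling correction would otherwise fold a ×0.75
step into the "truth").

`worked_example_fixture` is not random at all: genotype mean yields are
fixed at the published three-year means, year offsets (+250, −400, +150
kg·ha⁻¹; the middle harvest was the poor one) add environment variation
without disturbing genotype means, concentrations are the published
means for the six study genotypes and are back-solved from published
nutritional yields (C = NY·DRI·365/Y) for the rest, and replicate pairs
sit at yield ×(1±1%) with concentration ×(1∓1%). That last pairing keeps
genotype mean yield and mean concentration exact and mean nutritional
yield exact up to the factor 1−10⁻⁴ (well inside integer rounding); its
side effect — plot nutritional yield has no within-cell variance — is
harmless to every statistic computed here. The plot-level spread of the
original trial is unpublished, so the ±1% is a free, documented choice.
Yield in this fixture is additive (degenerate AMMI, exercising the
fallback ranking) while each nutritional yield carries a genuine rank-1
interaction c_i·δ_j, exercising the SVD path.

## Problem sizes and determinism

Every analysis in this repository runs on the 19 × 3 × 2 worked example
or on simulated trials up to 200 genotypes; Monte-Carlo calibration of
the variance-component estimator uses 200 replicates of a 30 × 5 × 2
design, which completes in seconds. All simulation is seeded through
`numpy.random.default_rng`; identical seeds reproduce datasets
bit-for-bit, and the QR sign convention is fixed explicitly so scores do
not depend on the underlying LAPACK build.

## Known limitations

* Published rankings derived from the unpublished plot-level data (exact
  correlation coefficients, PC1 percentages, HMGV magnitudes, the
  desired-gains ranking) cannot be recomputed exactly; the worked
  example reproduces orderings and every quantity derivable from
  published genotype-level numbers.
* Incomplete genotype × environment cells are a hard error for AMMI and
  BLUP — no imputation. The design this package targets is balanced.
* One interaction-variance component is shared across all environments
  (no heterogeneous G×E variances), and no pedigree/kinship information
  enters the genotype effects.
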