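# Methods

## Scope and assumptions

`transferforce` models a one-sex (female), age-classified population in
1-year classes 0..ω with a closed life table (q_ω = 1). The population is a
"focal sharing group": all food produced is pooled and redistributed by
caloric need, so every member experiences the same food ratio. The model is
deterministic and density-independent; there is no individual heterogeneity,
no sex-specific production, and no age-targeted sharing rule. Transfers act
on fitness only through nutrition: more food raises fertility and lowers
mortality for everyone at once.

Projection uses a birth-pulse, pre-breeding Leslie matrix with fertility
m_x directly in the first row (F_x = m_x) and survival p_x on the
subdiagonal. This keeps "sensitivity to fertility at age x" and
"sensitivity to survival from x to x+1" each attached to a single matrix
entry, which is what the serial production sensitivity needs. Under this
convention the Euler–Lotka identity is Σ_x λ^−(x+1) l_x m_x = 1, which the
tests verify to 1e−8 at the computed λ. A post-breeding alternative
(F_x = p_x m_{x+1}) was considered and not adopted; switching would change
third-decimal details of the sensitivities but none of the qualitative
results, and the pre-breeding form keeps the bookkeeping minimal.

## Nutrition

The food ratio is E = P_T / D_T with P_T = Σ P_x l_x and D_T = Σ D_x l_x.
Vital rates respond through Z(E, γ) = E(γ+1)/(E+γ): m_x(E) = Z m_x⁽⁰⁾ and
q_x(E) = q_x⁽⁰⁾ / Z, clipped at q = 1 (clips are logged at debug level; the
calibrated operating range never triggers them). The input rates are
interpreted as the replete rates — the best the population can do when
demand is fully met. γ has no units; small values give a concave response
(mild deprivation nearly free, starvation catastrophic), large values
approach the linear response Z = E. Analyses here default to γ = 0.3, a
moderately concave response, and every claim made by the test suite is also
exercised at other γ (0.1–1.0 in specific tests). Food ratios above 1 are
capped: surplus beyond replete demand confers no benefit (no
"hypernutrition" penalty either).

The derivatives used by the sensitivity chain are the exact algebraic
forms, each verified against central finite differences in the tests:

- dZ/dE = γ(γ+1)/(E+γ)²
- dm_x/dE = m_x⁽⁰⁾ γ(γ+1)/(E+γ)²
- dp_x/dE = q_x⁽⁰⁾ γ / (E²(γ+1))
- dE/dP_x = l_x / D_T (pooled, need-based sharing)

### Self-consistency and the collapsed branch

When survivorship is allowed to respond to E, the food ratio is a fixed
point of E = P_T(l(E)) / D_T(l(E)). This equation is bistable for
realistically shaped profiles: besides the nourished solution there is a
collapsed one in which starvation shortens lives, removing productive
adults and depressing E further. The solver therefore scans downward from
E = 1 and refines the *largest* fixed point in (0, 1] by bracketed root
finding (brentq, xtol 1e−10) — the branch a population actually sits on
when production is reduced gradually from replete. If no fixed point exists
the population cannot persist at that production level and an error is
raised.

## Calibration

1. **Replete scale.** Production is multiplied by the constant that makes
   P_T = D_T under replete survivorship, so E = 1 and growth equals its
   replete maximum r_max (≈3 %/yr for both synthetic regimes).
2. **Baseline reduction.** A single factor ρ ∈ (0, 1] then reduces
   production at every age until the self-consistent intrinsic growth rate
   equals the target r = 1 %/yr (the long-run average for subsistence
   populations); ρ is found by brentq on the monotone map ρ → r.
3. **E_min.** The food ratio at stationarity (λ = 1) is solved on the same
   nutrition pathway; below it the population declines toward collapse.

The contracts r(E₀) = r_target and λ(E_min) = 1 hold to 1e−8 and are
asserted in the acceptance tests. An optional switch rescales baseline
fertility by a constant so that r(E = 1) matches a prescribed maximum
exactly; it is off by default — input rates are trusted as the replete
rates.

## Selection on production transfers

All derivatives are evaluated at the calibrated baseline (E₀, baseline
survivorship, baseline D_T) with no re-equilibration inside the derivative:
the metrics are a first-order expansion around the operating point. The
sensitivity of λ to per-capita production at age x is

s_Px = r̃_x · k · S · l_x / D_T,
S = Σ_y s_{y+1,y} dp_y/dE + Σ_y s_{1y} dm_y/dE,

where s_{ij} = v_i w_j / ⟨v, w⟩ are the eigenvalue sensitivities of the
baseline matrix. The recipient sum S runs over all ages including the
donor's own (self-provisioning is not excluded) and is donor-independent;
the donor's age enters only through survivorship l_x and the social
discounts. Relatedness is scaled against the direct-offspring benchmark,
r̃_x = r_x / 0.5, uniformly across all transfer metrics, so r_x = 0.5 with
k = 1 reproduces the undiscounted pipeline. Consequences asserted in tests:
every transfer metric is exactly linear in k and in r̃_x, and under flat
social profiles Δλ_Px / (P_x l_x) is constant across ages to 1e−12 — so
flat changes in kinship or cooperation rescale the metrics without moving
their age profile.

Production elasticities e_Px = s_Px P_x / λ do not obey the unit-sum
constraint of vital-rate elasticities, so for cross-population comparison
of age profiles they are rescaled to sum to the total fertility elasticity.
Fertility equivalents solve s_mx m_x* = s_Px P_x; where the fertility
sensitivity is zero m_x* is reported as missing. TFR₅₀ doubles the sum of
m_x* over ages 50–80 inclusive (both sexes from a one-sex female model),
unconditioned on survival to those ages.

### Weighting conventions

"Production remaining after age a" weights the schedule by baseline
survivorship, share(a) = Σ_{x>a} P_x l_x / Σ_x P_x l_x, consistent with the
pooled total P_T = Σ P_x l_x; fertility-contribution shares use
Δλ_mx = m_x s_mx. Mean ages of reproduction, production and demand are
likewise reported with survivorship weighting. The unweighted textbook
formula (Σ x m_x / Σ m_x, with P or D substituted) and stable-structure
weighting are both available for sensitivity analysis; the survivorship
default was chosen because it is the only convention under which the net
flow of food runs from older producers to younger consumers (x_P > x_D) in
long-lived forager-like profiles — the unweighted formula drags the mean
demand age toward the (rarely reached) oldest classes and reverses the
sign.

## Productive value

ΔR_Py is the drop in net reproductive rate when age-y production is removed
from the pooled budget: E is recomputed one-shot at baseline survivorship
(a local perturbation; a full re-equilibration variant is available behind
a flag), nutrition is re-applied, and R0 recomputed. Then

PV_x = r̃_x k (λ^{x−1} / l_x) Σ_{y≥x} λ^{−y} ΔR_Py.

Substituting l_y m_y for ΔR_Py recovers the classic discrete
reproductive-value profile exactly (asserted in tests), which is the sense
in which PV is the transfer analogue of Fisher's RV. PV is reported raw and
normalized to its own maximum; curves should be compared as shapes. The
normalized shape is invariant to γ to first order: with the growth target
shared across γ the discount rate cancels, leaving only a weak survivorship
dependence, so rank correlations across γ come out ≈1 (0.9999+) with
adjacent near-ties on the plateau occasionally swapping rank. The tests
assert rank correlation 1.0 within 1e−3 together with a sup-norm bound of
0.01 on the normalized curves.

## Pedagogy

The skill-production model is a transparent parametric stand-in (the
underlying skill-acquisition theory is developed elsewhere):
P_x = amp · M_x · S_x^w, with M_x a biomechanical capacity curve (logistic
rise, logistic senescent fall) and S_x a saturating skill stock,
S_{x+1} = S_x + ρ_s (1 − S_x). The niche presets live in
`pedagogy_presets.yaml`, not in code: *high_skill* (w = 0.9, slow
saturation ρ_s = 0.035) and *low_skill* (w = 0.3, fast saturation
ρ_s = 0.30), with amplitudes giving adult production in the plausible
2 000–4 000 kcal/day range against a forager demand schedule.

A regime (φ, θ, a, b, t) taxes teacher production by φ on ages [b, b+t) and
multiplies pupils' skill-accumulation rate by (1+θ) on ages [a, a+t). The
boost in instruction year j is additionally scaled by the fraction
l_{b+j}/l_b of the teacher cohort still alive — pupils cannot learn from
dead teachers. This coupling is what creates the interior cost/benefit
tradeoff: old teachers are cheap (little production left to tax) but die
mid-instruction; prime-age teachers deliver the full boost but forfeit peak
production. At a regime steady state every cohort passes through both
roles, so the cross-sectional production schedule carries both effects and
survivorship weighting happens in P_T. The fitness gain is the change in
self-consistent intrinsic growth from swapping in the modified schedule at
the calibrated scale, discounted by the teacher's r̃_b and k. Because the
skill model is a stand-in, only qualitative orderings are meaningful (and
tested): the null regime is an exact fixed point; gains increase in θ and
decrease in φ; the optimal teacher age is older when teaching is costlier;
and the high-skill niche profits more from pedagogy than the low-skill
niche.

## Synthetic profiles

The generator emulates two stylized regimes, with Siler mortality, a
Gaussian fertility curve (truncated at cessation for the human-like
regime), logistic-rise × logistic-fall production, and a logistic demand
ramp:

- **chimp-like** (ω = 60): production meets demand by ~age 5 and peaks
  before 20 with near-zero surplus after 40; adult mortality high (Siler
  baseline hazard 0.020/yr, Gompertz doubling ~6 y); fertility from age 12
  with no cessation.
- **human-like** (ω = 90): production crosses demand near age 20, peaks in
  the mid-30s, and stays above demand past age 60; adult mortality low
  (baseline hazard 0.008/yr); fertility from 17, ceasing at 50.

Fertility levels were set so that replete growth is ≈3 %/yr in both regimes
— the replete-maximum operating assumption — which for the chimp-like
regime implies survival like the best-observed wild populations. Caloric
scales (demand ~1 750 kcal/day for the chimp-like adult, ~2 500 for the
human-like) are round figures in the observed range; production amplitudes
only matter up to the calibration rescaling. Optional lognormal noise
applies to production only and is deterministic given the seed.

These schedules are smooth idealizations: they carry no year-to-year
variance, no sex differences, no cohort effects, and their exact share
values (e.g. 59 % of human-like production remaining after age 30) are
properties of the chosen curves, not estimates for any real population.
Passing tests on them demonstrates the correctness and internal consistency
of the machinery and the robustness of the qualitative contrasts
(early-peaking vs late-sustained production), not empirical agreement with
any particular society; empirical per-age tables in the same CSV format can
be analyzed unchanged.

## Numerical choices

- Dense eigendecomposition throughout (matrices ≤ 131×131). Among
  eigenvalues tied in modulus (periodic life cycles generate
  complex/negative partners of the Perron root) the one with the largest
  real part is selected; eigenvectors are sign-normalized, clipped at zero
  against roundoff, and scaled (w sums to 1, v₀ = 1).
- Reproductive value is set exactly to zero at ages with no remaining
  reproduction rather than leaving eigen-solver noise.
- All root finds use brentq: xtol 1e−10 for food ratios, 1e−12 for ρ and
  E_min; the self-consistent solver brackets on a 512-point downward scan.
- Degenerate inputs: a matrix with no reproduction is nilpotent (λ = 0) and
  has no sensitivities; zero total production makes scaled elasticities
  undefined (reported as zeros with a warning); m_x* is missing where
  s_mx = 0; PV is missing at unreachable ages (l_x = 0).
- Life expectancy uses the plain discrete sum e₀ = Σ l_x (no half-interval
  correction); it is reporting-only and feeds no metric.

## Known limitations

One-sex model with female schedules only (a conservative choice where male
late-life production is large); equal-proportion need-based sharing with no
preferential allocation to children, which would raise the benefits of
transfers; cooperation k is a flat compliance probability with no internal
group dynamics; the pedagogy skill model is a parametric stand-in, so its
outputs are orderings, not magnitudes; and the counterfactual permutation
reconciles differing ω by truncation to the shared age range, re-closing
the life table at the new ω.
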