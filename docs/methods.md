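# Methods

## Model chain

`mbrplan` treats each bone lesion as a uniformly irradiated, uniformly
seeded target. The chain from absorbed dose to planning output is:

1. **LQ survival with dose protraction.** The surviving fraction after a
   completed radiopharmaceutical delivery is
   `SF(D) = exp(-(α D + β G D²))` with `β = α/(α/β)`. Because dose rates
   in molecular radiotherapy are low and decay over days, much of the
   sub-lethal (single-strand) damage is repaired during irradiation; the
   Lea–Catcheside factor `G ∈ (0, 1]` scales the quadratic term down
   accordingly. For a mono-exponential dose rate allowed to decay to
   completion, `G = λ/(λ+μ)` with `λ = ln2/T½,eff` and repair rate `μ`.
   With the defaults (62 h half-life, μ = 0.46 h⁻¹), `G ≈ 0.0237`: the
   quadratic term is almost, but not entirely, suppressed.
2. **Biological effective dose.** `BED = -ln(SF)/α = D(1 + G·D/(α/β))`.
   The analytic inverse — the positive root of `aD² + D − BED = 0`,
   `a = G/(α/β)` — is evaluated in the cancellation-free form
   `2·BED/(1+√(1+4a·BED))` and round-trips with the forward map to
   ~1e-15 relative.
3. **Tumour control probability.** `TCP = exp(-ρc·V·SF)`, the Poisson
   probability that no clonogen survives, with `N₀ = ρc·V` kept as a
   continuous mean (volumes are macroscopic; ml ≡ cm³). The threshold
   dose at a cutoff `c` follows in closed form from
   `BED* = ln(ρc·V/(−ln c))/α`; lesions small enough that
   `ρc·V ≤ −ln c` are controlled at zero dose.
4. **Patient-level models.** MCP is the product of lesion TCPs. MBR is
   the volume fraction of lesions whose TCP reaches the eradication
   cutoff (a lesion exactly at the cutoff counts as eradicated). Both are
   driven by a single scale factor applied to the patient's relative
   lesion-dose distribution; the patient mean absorbed dose (PMAD) is the
   arithmetic mean of lesion doses, so planned doses are reported as
   `scale × PMAD_delivered`.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| α | 0.15 | Gy⁻¹ | linear radiosensitivity (prostate-cancer estimate); 0.25 models less radio-resistant disease |
| α/β | 3.1 | Gy | fractionation sensitivity; low for prostate cancer |
| μ | 0.46 | h⁻¹ | sub-lethal damage repair rate (repair half-times of ~16 min–3 h are plausible; only the default is exposed) |
| T½,eff | 62 | h | effective (physical + biological) half-life of the radiopharmaceutical |
| ρc | 3·10⁶ | cm⁻³ | clonogenic cell density, uniform across lesions and patients |
| TCP cutoff | 0.95 | — | per-lesion eradication threshold in the MBR k-rule |
| MCP target | 0.95 | — | whole-patient control target for the inverse solver |

All are overridable via a flat `key=value` config file. Repopulation,
RBE weighting, microscale dose heterogeneity and normal-tissue toxicity
are out of scope; lesion volumes are baseline volumes throughout (no
shrinkage dynamics).

## Numerical choices

- **G(T) oracle.** The general double-integral definition of the
  protraction factor is evaluated by adaptive quadrature
  (`scipy.integrate.quad`, abs. tol. 1e-8), with the inner integral in
  closed form for mono-exponential and constant profiles (the stable form
  `(e^{-λt} − e^{-μt})/(μ−λ)` avoids overflow at large t, with the
  `μ → λ` limit special-cased). This quadrature exists purely as the
  independent check of the `λ/(λ+μ)` closed form used everywhere else.
- **MCP inversion.** Bisection on the scale factor (bracket grown
  geometrically, relative tolerance 1e-9). Bisection rather than Newton
  because MCP is near-flat then steep in the scale; bisection is
  unconditionally convergent on a monotone function. The *upper* bracket
  endpoint is returned, so the reported scale provably achieves
  MCP ≥ target — this makes the ordering PMAD(MBR=1) ≤ PMAD(MCP=target)
  exact rather than tolerance-dependent, since at any scale with
  MCP ≥ 0.95 every individual TCP is ≥ 0.95.
- **MBR inversion.** MBR is a step function with one jump per lesion at
  scale `sᵢ* = threshold(vᵢ)/Dᵢ`, so the curve is built analytically:
  sort the `sᵢ*`, accumulate volume fractions, merge ties into a single
  breakpoint (determinism), and pin the final value to exactly 1 when all
  lesions are accounted for (guards against float-summation drift).
  `PMAD_MBR=f` is the infimum breakpoint with MBR ≥ f under the
  right-continuous convention — the only scale-free, tie-stable reading
  of a step curve; the exported curves are exact steps with an optional
  densified grid for plotting.
- **Degenerate inputs.** Zero-dose ("cold") lesions never reach
  threshold: curves are capped below 1 and solvers return flagged
  non-finite doses instead of raising, so cohort runs complete. Doses
  are guarded at 10⁴ Gy (a solver result pushing any lesion beyond that
  is flagged); survival fractions underflow cleanly to 0.
- **Statistics.** Pearson r with the exact two-sided t-transform p-value
  (scipy), OLS fits with 95% mean-response confidence bands
  (statsmodels; on the log-log scale for the power form), quantiles by
  linear interpolation between order statistics (numpy default), sample
  (n−1) variance with the n = 1 variance defined as 0.

## Synthetic cohorts

No lesion-level dosimetry for this setting is publicly deposited, so the
generator emulates the published *summary* structure of a 22-patient
¹⁸⁶Re-HEDP cohort: median 11 lesions per patient (IQR 3–25), median
burden 227 ml (IQR 81–300 ml), median delivered PMAD 19 Gy
(IQR 14–23 Gy). Distribution families are not published; lognormals are
used (positive support, right skew consistent with the asymmetric IQRs),
with (μ, σ) solved from the median and symmetrised log-IQR. Per patient:
lesion count = rounded lognormal clamped to ≥ 1; burden drawn lognormal
and split across lesions by normalised lognormal shares (log-sd 1.0,
giving order-of-magnitude volume spread); doses = lognormal multipliers
(log-sd = `dose_dispersion`) renormalised to the drawn patient mean. The
default dispersion 0.5 yields max/min lesion-dose ratios spanning ~1–10
across a cohort, matching the range reported clinically; 0 gives
perfectly uniform doses. An optional log-scale volume–dose correlation
knob exists (default 0) because uptake-driven correlation is plausible
but unquantified. Patients are sub-seeded from (master seed, patient
index), so cohorts are reproducible and extensible without rewriting
earlier patients.

What the generator does **not** emulate: anatomical lesion placement,
dosimetric uncertainty, intra-lesion dose heterogeneity, inter-patient
radiosensitivity variation, or any volume–dose ratio joint structure
beyond the optional correlation knob. Tests passing on these cohorts
therefore validate the *model chain and solvers*, not the clinical
accuracy of predictions for any real patient.

## Verification strategy and problem sizes

Every closed form is checked against an independent route: the
protraction factor against quadrature of its defining double integral;
the single-lesion MCP solve against the analytic TCP inverse (volumes
0.1–1000 ml); the analytic step curve against a 10⁴-point brute-force
scan of the MBR definition on 100 random patients; BED/inverse as a
round-trip property. Cohort-level invariants (cutoff monotonicity, the
MBR ≤ MCP dose ordering) run on a 1000-patient seeded cohort; the
α-sensitivity direction (mean planned-dose reduction of ~31% for
α = 0.25 Gy⁻¹, checked against a 20–40% band) on 300 patients; and the
dose-variability correlations on a dispersion sweep of 6 levels
(0–0.5) × 200 patients, the range that reproduces max/min dose ratios of
~1–10. These sizes keep the full suite under half a minute while leaving
Monte-Carlo margins far from the asserted bounds.

## Known limitations

- Radiobiological parameters are external-beam prostate-cancer
  estimates; absolute planned doses shift with them, though relative
  patient orderings are stable.
- The Poisson TCP with uniform ρc ignores hypoxia, clonogen
  heterogeneity and repopulation; planned doses are best read
  comparatively, not as prescriptions.
- The MBR k-rule is binary at the TCP cutoff, so partial (sub-threshold)
  volume response is invisible to the model.
- PMAD averages over all lesions, including any with zero dose; such
  patients carry unreachable-target flags rather than adjusted means.
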