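# Methods

## Scope and data model

The package operates on tabular soil surveys: one row per sample with a site
group (`community`, `burning`, `dismantling`, `background`), optional local
coordinates in meters, and per-element concentrations in mg/kg that may be
left-censored ("<LOD"). Units are fixed by convention — mg/kg for soil,
µg/L for extraction fluids, kg/day for soil ingestion — and never inferred;
silent unit conversion is the dominant error mode in this kind of pipeline,
so none is attempted.

The packaged element registry carries the twelve toxicologically significant
metals retained for analysis (Ag, As, Au, Cd, Cr, Cu, Mo, Ni, Pb, Sb, Sn,
Zn) with their XRF detection limits, oral tolerable daily intakes (TDI), the
arsenic oral cancer slope factor (1.8 (mg·kg⁻¹·d⁻¹)⁻¹), CCME residential
and Dutch intervention screening values, and the per-element RBA resolution
rule. Fe is carried as a thirteenth entry solely because the enrichment
factor normalizes to it. Background means M_b are site-specific properties
of a control area, so they are supplied through the run config rather than
packaged; no default background values are invented.

## Censored statistics

Nondetects are handled with the standard flipping construction for
left-censored environmental data: all values and bounds are reflected about
a constant M chosen as max(data) + 1 (any valid M gives the same estimates,
which a property test asserts; the constant is overridable). A "<L" result
becomes a right-censored survival time M − L, the Kaplan–Meier product-limit
curve is fitted (via lifelines), and means and quantiles are mapped back.
Conventions:

- The mean is the restricted mean over the observed range. Survival mass that
  never reaches an event — which happens exactly when the smallest
  observation is censored — is carried to the smallest observed bound and the
  summary is flagged `censored_min`. The KM mean therefore always lies inside
  the substitution bracket [mean with censored→0, mean with censored→LOD].
- At a tie between an observed value and a censoring bound the observed value
  is taken to occur first on the flipped scale (the standard right-censoring
  tie rule).
- SD uses the product-limit probability masses with an n/(n−1) small-sample
  factor; quantiles are inverted-CDF quantiles of the discrete KM
  distribution. With zero censoring all summaries reduce exactly to the
  arithmetic mean, sample SD and empirical quantiles.
- A group that is entirely censored admits no distribution estimate: the
  mean/median are reported as upper bounds at the smallest detection limit
  with flags `all_censored, upper_bound`.

Group comparisons use the Peto–Peto generalized Wilcoxon test on the flipped
data, weighting the log-rank increments by the Peto–Peto modified survival
estimate S̃(tᵢ) = Π_{j≤i} (1 − dⱼ/(nⱼ+1)). The score and its hypergeometric
variance are accumulated directly (the implementation is verified against
lifelines' weighted log-rank to machine precision), which makes a
permutation option cheap: the permutation p-value of |U| is computed
exhaustively when the number of group assignments is small and by Monte
Carlo otherwise. The default p-value refers U²/V to χ²(1), two-sided. The
"95% confidence limit" convention is interpreted as α = 0.05 throughout; no
KM confidence bands are computed because nothing downstream consumes them.

The pairwise screen tests every site-group pair for every element and
adjusts the whole family with Benjamini–Hochberg (the screening decision
uses adjusted p-values; raw p-values are reported alongside). An element
whose every adjusted pairwise p ≥ α is flagged as showing no group
difference. Degenerate groups (all values censored at one bound) skip the
test with an explicit flag rather than fabricating a p-value.

QA helpers: ordinary least squares of confirmatory ICP-MS on field XRF
concentrations (slope, intercept, R², slope p-value) and percent recovery
against certified reference-material values.

## Pollution indices

EF = (Mₛ × Fe_b)/(M_b × Feₛ) with Fe as the fixed normalizer; Igeo =
log₂(Mₛ/(1.5·M_b)). Both are invariant to global unit rescaling. Descriptive
classes follow the usual bins (EF: <2, 2–5, 5–20, 20–40, >40; Igeo: ≤0
through 5–6), intervals closed on the right so a boundary value takes the
lower class; an Igeo above 6 keeps the top label and is flagged
out-of-scale. Indices are computed per sample by default (censored cells via
the LOD convention, flagged); group-level indices can be formed from KM
means. Guideline screening compares KM mean concentrations against every
available guideline with strict inequality — a mean exactly at the guideline
does not "exceed".

## Bioaccessibility and RBA

IVBA% = 100 × (extract µg/L × fluid L / soil g) / total mg/kg; with the
default 1 g / 100 mL vessel this is 10 × extract/total. Records whose
extract concentration is below the extract detection limit get no IVBA and
are flagged; their RBA falls back per the element rule. RBA resolution:

- As: RBA% = 0.79·IVBA% + 3; Pb: RBA% = 0.878·IVBA% − 2.8. Outputs are
  clamped to [0, 100] before use as a fraction — the Pb regression goes
  negative below IVBA ≈ 3.2% and measured IVBA can exceed 100% (silver
  maxima well above 100% occur in practice), and a bioavailability fraction
  outside [0, 1] is physically meaningless. Raw values remain recoverable
  from the recorded IVBA; clamping is flagged.
- Ag, Cr, Cu, Ni, Zn: IVBA used directly (capped at 100%).
- Cd, Mo, Sb, Sn: RBA = 1 (extracts below detection; maximally protective).

Per-sample RBA values take precedence; per-element arithmetic mean IVBA is
the fallback for samples without their own extraction, and a direct-IVBA
element with no IVBA anywhere defaults to RBA = 1 with flag `rba_defaulted`.

## Exposure and risk

CDI = Msoil × IngR × ET / BW. The exposure term ET is implemented as the
dimensionless fraction (days/week ÷ 7) × (weeks/year ÷ 52) — the literal
days × weeks product would carry units of days/year and could not yield a
dimensionless HQ — and defaults to 1 (continuous residential exposure).
Life expectancy (64 y) enters only for carcinogens, as the factor
exposure_duration/LE with default duration = LE. Default receptors: child
0.0004 kg/day, 30 kg; adult 0.0001 kg/day, 70 kg. With receptor-independent
ET and RBA, the child/adult HI ratio is exactly (0.0004/30)/(0.0001/70) =
28/3.

HQ = CDI × RBA / TDI; HI sums HQs over the eleven HI elements (Au has no
oral TDI and is excluded; an element with a missing TDI is skipped with a
flag, never silently zeroed). CR = CDI × CSF × RBA for arsenic only — the
slope factor is treated as (mg·kg⁻¹·d⁻¹)⁻¹ so CR is a dimensionless
lifetime excess probability. Cancer risk is assessed for the adult receptor
by default; a child carcinogen assessment must be requested explicitly on
the receptor profile. Censored concentrations enter risk arithmetic at
LOD/2 by default, with `lod` and `zero` available to bracket the answer; the
convention used is recorded in the output flags. Thresholds default to
HI > 1 and CR > 1 × 10⁻⁵.

## Synthetic surveys

The generator emulates the structure of an e-waste-site survey, not any
measured dataset. Log-concentration of element e in sample i is

    log C = log GM_e + Σ_s log(loading_{s,e}) · exp(−d(i, s)/λ) + ε,

with ε ~ N(0, log GSD_e): lognormal background (heavy right skew, analytic
means available as ground truth), multiplicative source factors for burning
and dismantling with exponential decay (λ = 150 m) away from fixed hotspots,
and a uniform natural-enrichment factor (Cr/Ni/Zn ×1.5) with no hotspot.
Burning and dismantling members sit exactly at their hotspot (full loading),
community samples on a 300 m grid around the sites, background controls far
outside the decay range. Group sizes default to the emulated survey design
(burning 14, dismantling 11, community 64, background 12 = 101 samples);
detection limits default to the XRF LODs in the registry, and any latent
value below its LOD is emitted censored, with the latent truth recorded.
Background geometric means and GSDs (≈2.2; Fe 1.6) and hotspot loadings were
chosen once as realistic for tropical urban topsoil and heavily contaminated
recycling areas, such that hotspot levels land at the observed order of
magnitude (e.g. Pb GM 30 × 220 = 6 600 mg/kg at the burning site) and
low-level elements (Ag, As, Cd, Ni) are substantially censored in the
community, mirroring real surveys.

Bioaccessibility inputs are drawn per sample × element from normals
truncated at zero with the observed per-element (mean, SD) of gastric IVBA;
extract concentrations are back-computed for the vessel so the IVBA
calculation recovers the drawn value exactly, and the drawn value is kept in
a ground-truth column.

What the generator does **not** emulate: spatial autocorrelation beyond the
deterministic hotspot decay (no variogram structure), inter-element
correlation beyond shared source factors, measurement error distinct from
population variability, and any attempt to reproduce actual site numbers.
Passing recovery/power tests therefore demonstrate correctness of the
estimators under a plausible data-generating process, not performance
guarantees on any particular field dataset.

## Numerical and design choices

- Flip constant M = max(data) + 1, overridable; results are M-invariant.
- BH adjustment treats all element × pair tests as one family; the screen
  uses adjusted p-values (3 pairs × 12 elements inflates family-wise error).
- Exceedance, HI and CR comparisons are strict (>), so ties at a limit do
  not flag.
- Exhaustive permutation is used whenever C(n, n_a) does not exceed the
  requested draw count; otherwise Monte Carlo with the given seed, counting
  the observed assignment (p = (b+1)/(B+1)).
- Published mean-concentration tables occasionally disagree between sources
  within a report (e.g. abstract-level rounded means vs. summary-table
  means); packaged example inputs follow the summary tables and the
  discrepancy is noted rather than resolved.
- Calibration/recovery test sizes (2 000 null replicates at n = 20+20;
  n = 2 000 recovery; 200 power replicates at n = 14 vs 64) were chosen to
  make Monte-Carlo error small relative to the tolerances while keeping the
  suite fast.

## Known limitations

- Oral ingestion only; inhalation and dermal pathways are out of scope, as
  is probabilistic (Monte-Carlo) exposure assessment.
- KM-only nondetect handling; no regression-on-order-statistics or MLE
  estimators.
- The per-sample exceedance counts of an original field survey cannot be
  reproduced without the unpublished per-sample data; the generator's
  source-structure property (within-pathway correlations exceed
  between-pathway ones) is the qualitative stand-in.
- Bioaccessibility is a fixed arithmetic contract on extraction
  measurements; no gastric chemistry, and no intestinal-phase IVBA.
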