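# Methods

## Scope and model

`acidflux` implements the quantitative analysis layer of a five-arm cell
culture experiment on primary human aortic smooth muscle cells
(HAoSMCs): control (pH 7.4), hydrochloric acidosis (HCl, pH 6.8), lactic
acidosis (LA, pH 6.8 + 24 mmol/l lactate), a mannitol osmolarity control
and sodium lactate (both pH 7.4, 24 mmol/l), treated for 48 h.  The
package does not model cell biology; it models the *measurements*:
linear plate-assay calibration, extracellular-flux (OCR) parameter
extraction, a stoichiometric ATP budget, DEG-set post-processing, and
the accompanying nonparametric statistics.  Everything upstream of these
readouts (sequencing, read counting, differential-expression model
fits, image segmentation) is out of scope; the package consumes their
tabular outputs.

## Plate-assay quantification

Every colorimetric/luminescent assay is modeled as a linear instrument:
`signal = gain * amount + offset`.  Quantification fits an ordinary
least-squares line through the standards (six points including the
blank), inverts sample signals through it, and references amounts
against the fresh medium (consumption = medium − sample; production =
sample − medium).  Choices:

* **OLS with intercept, r² warning at 0.98.**  The blank is the fitted
  signal at amount 0.  A poor fit is flagged, never silently rejected.
* **Negative post-blank amounts retained and flagged** (`below_blank`),
  not clamped, so replicate means stay unbiased.
* **Units**: concentrations mmol/l, time minutes, amounts pmol
  downstream.  Flux normalization is
  `flux = Δc · V · 10⁹ / t / (cells/1000)` in pmol·min⁻¹·(1000 cells)⁻¹.
  The well volume `V` is a required argument with no default: it is an
  experimental fact, not a package constant.
* **Δlactate/Δglucose** of 2 marks purely glycolytic glucose disposal
  (`pure_glycolysis` flag).  Lactate under LA is *always* marked
  `reliable = False`: the produced increment (&lt;0.1 mmol/l at the
  default truth) is unmeasurable against the 24 mmol/l background, and
  the synthetic instrument reproduces exactly this failure mode.
* **Intracellular pH** is linear in the BCECF emission ratio between the
  two nigericin calibration points — two points admit nothing richer.
  Extrapolation outside the calibrated ratio range is flagged, not
  blocked.

## OCR parameter extraction

Traces must visit the four phases in order (baseline → oligomycin →
FCCP → rotenone/antimycin A) with ≥1 cycle each.  Default phase
summaries follow the standard Mito-Stress convention — *last* baseline
cycle, *min* after oligomycin, *max* after FCCP, *min* after
rotenone/antimycin A — and are configurable per phase (`mean`
available).  The derived parameters satisfy
`basal = atp_linked + proton_leak` and `spare = maximal − basal` exactly
by construction.  Negative baseline-corrected rates are flagged
(`negative_rate`), not clamped; a non-positive basal rate leaves the
coupling efficiency NaN (`undefined_coupling`).

## ATP budget

Fixed molar yields: 2 ATP per glucose through glycolysis, 30 ATP per
glucose fully oxidized, 10 ATP per glutamine at a cost of 2 O₂.  The
ATP:O₂ conversion used for ATP-linked respiration is therefore 5 —
consistent between both substrates (30 ATP / 6 O₂ = 10 ATP / 2 O₂) —
and is exposed through `StoichiometryConstants` rather than hard-coded,
since instrument vendors use slightly different P/O conventions.  The
budget assumes measured lactate derives from glucose; glutamine-derived
lactate is not bookkept.  The measured cellular ATP *content* (panel 8)
is an independent assay input and is never derived from the budget: the
comparison of production capacity against content is the point of the
reconciliation.  The glutamine "red line" is the glutamine flux needed
to fuel OCR-derived mitochondrial ATP production
(`mito_atp / 10`); a condition is "sufficient" when measured glutamine
consumption meets it.

## DEG post-processing

* **Filter**: |log2FC| ≥ 0.59 (inclusive), FDR ≤ 0.05 (inclusive), mean
  FPM strictly &gt; 5 in at least one group.  The strict abundance bound
  follows the filtering convention stated with the DEG counts; all three
  thresholds are configurable.
* **Concordance**: over genes present in both tables and in the union
  (default) or intersection of the two DEG sets; a log2FC of exactly 0
  is discordant with any nonzero partner (conservative).  The slope is
  OLS of B on A with intercept (matching the "regression line" reading);
  a total-least-squares option is provided because OLS slopes are not
  reciprocal under A↔B exchange.
* **Enrichment**: hypergeometric upper tail (observed intersection or
  larger), Benjamini–Hochberg adjustment across the tested terms, term
  size window 5–3000, gates adjusted-p ≤ 0.001 and fold enrichment
  E = (intersection/query)/(term/domain) ≥ 2.5.  BH is a deliberate,
  documented deviation from web-service multiple-testing schemes
  (g:SCS-style corrections are not reproducible from their description);
  with BH the reported adjusted p-values are conventional FDRs.

## Statistics

Two groups: Wilcoxon/Mann–Whitney rank-sum, exact when sample sizes
permit and no ties are present, otherwise the tie-corrected normal
approximation (no continuity correction, so identical samples give
p = 1).  More groups: Kruskal–Wallis ("ANOVA on ranks") followed by
pairwise rank-sum tests with BH adjustment.  Outlier screening uses the
chi-squared criterion on the observation farthest from the mean with
sample variance (n−1), one screen per call, removal at p &lt; 0.05,
distance ties broken deterministically toward the larger |x| then the
larger x.  Note the statistic is bounded by (n−1)²/n, so n ≤ 4 can never
reject at 0.05 (minimum attainable p ≈ 0.13 at n = 4) — small-sample
screens are honest no-ops, which the tests assert explicitly.  In the
pipeline the screen is applied per (condition, assay) cell; this locality
is configurable in principle because the alternative (global screening)
is equally defensible.

## Synthetic-data generator

The generator emulates the measurement process, not the biology: true
per-condition quantities (`GroundTruth`) are pushed through the same
linear instrument model the analysis inverts, with multiplicative
Gaussian noise (`signal·(1+cv·z)`, truncated at zero) because
plate-reader error scales with signal.  One master seed feeds an
independent substream per artifact, so outputs are bit-identical for
identical (design, truth, seed) and adding wells to one assay never
perturbs another.

Default study conditions: 6 replicate wells/condition, 48 h (2880 min),
100 000 cells/well, 1 ml supernatant, DMEM with 5.5 mmol/l glucose and
2 mmol/l glutamine, 24 mmol/l lactate background under LA and
Na-lactate, plate-reader CV 2 %, OCR CV 3 % with 3 cycles/phase.  The
default truth encodes the qualitative effect ordering LA > HCl ≫
lactate ≈ 0 in fluxes and DEG counts; control glucose disposal is fully
glycolytic (lactate = 2 × glucose); OCR plateaus are scaled so that
glycolysis and OXPHOS sit near parity under control, glutamine covers the
OCR-derived ATP demand under control and HCl but not LA, and ATP content
drops under LA only.  DEG tables are parameterized by Venn-region counts
(defaults 59 / 1212 / 15 specific, 433 shared between the acidoses),
an effect scale (HCl = 0.7 × LA for shared genes) and a 5 % sign-flip
probability; member magnitudes are drawn ≥ the fold-change gate so the
designed counts survive filtering exactly.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: count-level sequencing noise and
dispersion (log2FC/FDR are drawn directly, not fitted), plate position
or batch effects, drift within OCR phases or injection transients,
saturating standard curves, pipetting error correlated across wells,
and any biological coupling between readouts beyond the encoded
ordering.  One realistic failure mode *is* reproduced: a single
calibration shared across wells makes small concentration differences on
large backgrounds noisy, which is visible as run-to-run spread in the
Δlactate/Δglucose ratio (unbiased, SD ≈ 0.17 at default noise) and as
the unreliability of Δlactate under LA.

## Numerical choices and degenerate inputs

Calibration rejects identical amounts and zero slopes; quantification of
a signal equal to the blank returns exactly 0.  Kruskal–Wallis on fully
tied data returns H = 0, p = 1 (the library form is 0/0).  The
concordance slope is NaN when the predictor contrast has zero log2FC
variance.  Hypergeometric p-values use the survival function at k−1;
the enrichment E statistic is computed before any gating so `return_all`
exposes the full tested list.  Monte-Carlo recovery tests average across
independently calibrated plates so that calibration error — which is
shared within a plate and does not shrink with well count — is captured
in the standard error.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: plates of
6–20 wells (one Monte-Carlo test uses 50 plates × 20 wells), 500
single-cycle OCR traces for parameter recovery, 10 000–12 000 genes for
DEG/concordance/enrichment work, exhaustive oracles at n ≤ 10 (rank
permutations), ≤ 20 elements (Venn enumeration) and a domain of 50
(hypergeometric enumeration).

## Known limitations

* The ATP:O₂ = 5 conversion is a stoichiometric convention, not a
  measured P/O ratio; budgets scale linearly in it.
* The pipeline's per-condition fluxes average wells before computing the
  delta; well-level flux distributions are available from the quantified
  tables but are not propagated into the budget.
* The enrichment module assumes the query and all terms are drawn from a
  single effective domain given by its size only; gene-identifier
  mismatches are the caller's responsibility.
* Venn-region counts of the default DEG truth give a LA total of 1645;
  region counts are the generator's primitives and margins follow from
  them.
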