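# Methods

## Quantification model

The tracer model is irreversible trapping of ¹⁸F-FDG. With a decay-corrected
blood input function `C_b(t)` and a tissue curve `C_t(t)`, the fractional
glucose extraction is estimated as a fractional uptake rate (FUR):

    GE = mean over steady-phase frames of C_t  /  ∫₀^T C_b dτ

- **Steady phase**: frames whose midpoints fall in the 40–60 min window of a
  60-min scan. **Integration endpoint** `T`: the window midpoint (50 min).
  Neither is uniquely fixed by FUR practice; the window-midpoint endpoint is
  the natural compromise between normalizing to the start and to the end of
  the averaging window, and both are configurable (`SteadyPhaseRule`).
- **Quadrature**: TAC samples are taken at frame midpoints; the blood
  integral is a composite trapezoid over those samples after prepending a
  `(t=0, 0)` origin — activity is zero at the moment of an intraperitoneal
  injection. The value at `T` is linearly interpolated.
- **Units**: GE in min⁻¹ (mL of plasma cleared per minute per mL of tissue);
  tissue density is taken as 1 g/mL, so per-100-mL and per-100-g uptake
  coincide. GU = GE × scan glycemia × 100 (mmol/L ≡ µmol/mL); scan glycemia
  rather than fasting glycemia multiplies GE, since it is the glucose pool
  actually competing with the tracer during the scan. Whole-depot SAT mass
  is 1.5 % (young) / 2.0 % (adult) of body weight; whole-SAT GU = GU × mass
  / 100. Group BAT/SAT ratios are means of per-animal ratios (not ratios of
  group means); animals with non-positive SAT GU are flagged and excluded.

## Synthetic cohort generator

The generator emulates the statistical structure of a two-age cross-
sectional maternal-programming study. It is first-class, tested code: every
downstream stage runs end-to-end on its output.

**Animals.** Eight (age × diet × sex) cells. Phenotype variables are
normal per cell; published group means arrive with standard errors, so
generating SDs are SEM·√5 (≈ the study's per-cell size of 38 animals / 8
cells). Adult HFD offspring first draw a latent obesity class — Bernoulli
per animal with sex-specific probability, default 2/3 for males and 0 for
females, reflecting that maternally induced obesity occurred in males — and
the class then overrides body weight (MIO 42.8 ± 0.7 g; MIOR at the
sex-specific normal range), leptin, resistin and food intake. This mixture
reproduces both the reported male adult HFD cell mean (≈ 38 g) and the
MIO/MIOR weight separation. Leptin, resistin and food-intake distributions
are invented (directions, not values, were reported): MIO ≈ 4× ND adipokine
levels, food intake MIO > MIOR > ND.

**True kinetics.** Per-cell true GE medians are back-calculated from
reported GU and scan glycemia (GE = GU / (glycemia × 100)); per-animal GE is
log-normal with log-SD matched to the reported GU coefficient of variation.
CT radiodensities are normal per cell, clipped to the representable CT
range.

**Input function and TACs.** The blood curve is a peak-normalized
two-exponential, amplitude · (e^(−c·t) − e^(−a·t)) — the simplest shape with
an intraperitoneal rise-then-clearance — with defaults a = 0.3 min⁻¹,
c = 0.05 min⁻¹ (peak ≈ 7 min), amplitude 150 kBq/mL with 10 % animal-level
variability (amplitude cancels out of FUR). All activities are generated
decay-corrected. Frame values are exact analytic frame averages of the
model curves; multiplicative Gaussian noise (default relative SD 5 %) is
applied per frame. The default schedule is 4×1 + 2×3 + 10×5 min (16 frames,
0–60 min): denser early sampling is standard for dynamic acquisitions, and
with a 5-min first frame the trapezoid integral would clip the absorption
peak enough to push noise-free FUR recovery past 1 %. With these defaults,
noise-free recovery error is ≈ 0.4 % (quadrature only) across
GE ∈ [0.001, 0.02] min⁻¹, and the tissue blood-volume fraction defaults to
0 (vascular spillover is supported but not emulated, since FUR does not
correct for it).

**Microbiota and pathway tables.** Features are log-normal (default log-SD
0.6, "Other" remainder tighter), then total-sum-scaled per sample, giving
overdispersed compositions. Two planted structures:

- *Rank correlations* (taxon × imaging parameter within one age group) via
  a Gaussian copula: the parameter's pooled within-age ranks are
  Gaussianized and mixed into the taxon's latent normal with correlation
  r = 2·sin(π·ρ/6).
- *Class effects* as relative (post-TSS) fold changes — default 10× caecum
  Unclassified.Rikenellaceae in MIO and 0.25× Unclassified.Clostridiales in
  MIOR, both versus adult ND.

Closure is the complication: dividing by the sample total attenuates a
planted correlation and bends a raw-scale fold away from its relative-scale
target. Both are therefore calibrated on a deterministic pilot population
(the cohort's latent parameters tiled to ≥ 3000 rows, fixed pilot RNG,
two fixed-point passes) so the post-TSS Spearman ρ and relative folds land
on target; the class multipliers start from the analytic closure correction
e = f(S−p)/(S−f·p). The headline fold-change taxa deliberately carry *no*
copula entry: their association with BAT/SAT metabolism emerges from the
class structure itself, and stacking both would compound the two effects.

**What the generator does not emulate** (hence what passing tests do not
show about real data): PET reconstruction and partial-volume effects,
attenuation/scatter, CT artifacts, registration error between PET and CT,
any real 16S count process (no sequencing depth, zero inflation or
compositional count noise beyond log-normal + TSS), litter/dam random
effects, and the reported adipokine–radiodensity correlations. Voxel
phantoms are box ROIs with i.i.d. Gaussian voxel noise, built to exercise
the extraction path, not to mimic scanner data.

## Statistics

- **Summaries**: mean ± SEM per cell; Welch t for two groups (small unequal
  cells), one-way ANOVA for more, Wilcoxon rank-sum / Kruskal–Wallis for
  variables flagged non-normal. No multiplicity correction across phenotype
  variables (raw p, as in compact cohort tables); noted in output.
- **MIO/MIOR stratification**: MIO iff weight > ND mean + z·SD(ND), default
  z = 2 — this reproduces the published split (42.8 g obese vs 29.6 g
  resistant against ND 27.8 ± 1.5) without a hard-coded cutoff; a fixed
  cutoff is available, and is required when the ND reference has zero
  spread. The 2-SD rule gives each ND-like animal ≥ 95 % specificity.
- **Associations**: average-rank Spearman; p exact by full permutation
  enumeration for n ≤ 9, t-approximation otherwise; BH-FDR within each
  (site × level × imaging parameter) family — per-level correction is what
  a published table implies when the same raw p receives different adjusted
  values at family vs genus level. Features named `Unclassified.X` are
  ordinary features. An optional prevalence/abundance filter
  (default: detected in ≥ 20 % of samples, mean ≥ 10⁻⁴) drops rare
  features without renormalizing the remainder, so reported mean abundances
  stay on the original composition scale.

## Numerical and interface choices

- Masks are voxel-aligned (array indexing); ROI statistic is the unweighted
  voxel mean. No registration, DICOM or partial-volume handling.
- TSVs are written with fixed decimal formats so write → read → write is
  byte-identical; the pipeline is file-in/file-out per stage with a JSON
  manifest (config SHA-256, seed, row counts). Default global seed
  20220828.
- A published figure legend gives the extraction constant in "mL/min";
  consistency of GU = GE × glycemia × 100 with the tabulated uptake values
  fixes the interpretation as mL·min⁻¹ per mL of tissue (min⁻¹), which is
  what the package uses.
- Degenerate inputs fail loudly: empty ROIs, non-positive blood integrals,
  all-zero abundance rows, overlapping phantom boxes, glycemia ≤ 0.

## Problem sizes

Association recovery is validated at 500 animals per cell (age-group
n = 2000, weight classes ≥ 300 per group); parameter recovery on a GE grid
with 100 noisy replicates per point; FDR behaviour on six null cohorts of
8 per cell and on 1000 random p-vectors against a brute-force step-up
oracle; end-to-end determinism at 4 per cell.

## Known limitations

FUR is a late-window approximation — no Patlak fit, compartment model or
lumped-constant correction, so absolute GU inherits the approximations of
the steady-phase convention. The SEM→SD reconstruction assumes equal cell
sizes. The copula calibration targets the *population* Spearman ρ; at small
n the realized coefficient varies with sampling error as it should. Group
sizes per cell in the source study were not published per sex; the
generator exposes `n_per_cell` as free configuration.
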