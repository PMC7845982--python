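# tpnmrds

Mark–recapture distance sampling (MRDS) with a **two-piece normal detection
function**: stratified abundance and harvest-rate estimation for
dual-observer aerial line-transect surveys.

## Who this is for

Wildlife biometricians analysing aerial strip surveys flown with a pilot
and a backseat observer — the design used for brown bear surveys in
southwest Alaska — where two standard assumptions of conventional distance
sampling fail:

- detection does **not** peak on the transect line: a blind spot under the
  aircraft (width *w_b*) pushes the detection apex off the line, producing
  a skewed, unimodal detection shape;
- detection at the apex is **not** perfect, so it must be estimated from
  the dual-observer capture histories (pilot-only / backseat-only / both).

## The model

**Distance stage (MCDS).** Perpendicular distances *x* on the truncated
strip [*w_b*, *w*] follow a two-piece (split) normal detection shape

```
g(x | z) = exp( -(x - μ)² / 2σ(x,z)² ),          g(μ) = 1,
ln σ(x,z) = β₀ + β_A·1[x > μ] + Σ_c β_c z_c (+ interactions with 1[x > μ])
```

with covariates *z* (search-distance bin, transect type, …) acting
log-linearly on the scale, and the indicator `1[x > μ]` giving different
scales left and right of the apex μ. Parameters (ln μ, β) are estimated by
maximising the conditional likelihood Π g(xᵢ|zᵢ)/∫g(u|zᵢ)du, with the
normalising integral in closed form via the Gaussian CDF.

**Mark-resight stage (MR).** Conditional on detection, the capture history
is multinomial with cells p₁(1−p₂)/p•, (1−p₁)p₂/p•, p₁p₂/p•, where
`logit p_j = γ·z_j` and p• = p₁+p₂−p₁p₂. Under **point independence** the
observers are treated as independent only at the apex; p̂•(μ̂, z) rescales
the distance model into an absolute detection probability

```
p̂(z) = p̂•(μ̂, z) · ∫ g(u|z) du / (w − w_b).
```

**Abundance.** Horvitz–Thompson per stratum *s*:
N̂_s = (A_s / a_s) Σᵢ sizeᵢ / p̂(zᵢ), with a_s = 2(w−w_b)L_s the covered
strip. Variance combines the among-transect (length-weighted R2)
encounter-rate component with a delta-method model component on the CV
scale; intervals are log-normal. Harvest rate is H/(H+N̂) with the interval
inherited monotonically from the abundance interval.

Model selection is forward AIC (add while ΔAIC < −2) gated by χ²/KS
goodness of fit and a low-detection-probability screen; pooled-versus-
stratified models are compared by adding the stratum AICs.

## Worked example

Simulate a survey at the study's scale (two strata with the published
areas and efforts, true parameters at the published combined-model
coefficients), then run the whole analysis from CSVs through the CLI:

```python
from tpnmrds import simulate_survey, study_scenario, write_detections
scn = study_scenario()
det, tr, truth = simulate_survey(scn, seed=7)      # truth.total_n ≈ 838 bears
write_detections(det, "detections.csv")
tr[["stratum", "transect_id", "length"]].to_csv("transects.csv", index=False)
```

```sh
tpnmrds estimate --config config.yaml --out run
```

prints (stderr carries the fit log):

```
truncation at [22.0, 1000.0] m removed 0 of 348 detections (0.0%)
MCDS model ['bin2sd1000', 'tranflat']: AIC = 4533.14, apex = 107.0 m
MR model ['bed', 'observer', 'pilot_group', 'distance', 'pcvr5', 'observer_group']: AIC = 682.00
apex detection p(mu) = 0.880 (SE 0.027); screening: True

stratum      N-hat        SE       CV    lower95    upper95  dens/1000km2
10            151.3     19.31  12.76%      117.9      194.1        52.74
9D            692.7     63.02   9.10%      579.8      827.6        80.10
total         844.0     71.20   8.44%      715.6      995.5        73.28

stratum    harvest/yr   rate      SE    lower95  upper95
10              10.0   6.20%   0.79%    4.90%    7.82%
9D              76.5   9.95%   0.90%    8.46%   11.66%
```

Reading the output: the fitted apex sits at 107 m (truth 110.5 m), the
estimated probability that at least one observer sees a group at the apex
is 0.880, and the stratified Horvitz–Thompson total of 844 bears brackets
the generating truth of 838 inside its log-normal interval. The harvest
rows divide each stratum's effective annual harvest (the biennial 153/0
pair averages to 76.5) by harvest + abundance.

The config file maps CSV columns, sets truncation (w = 1000 m,
w_b = 22 m), stratum habitat areas, crew groupings, model formulas (or
candidate lists for forward selection), and harvest counts; see the
docstring in `tpnmrds/cli.py` for the full schema. `tpnmrds fit` writes
the fitted-model JSON only; `tpnmrds simulate` runs
simulate → fit → estimate replicates and reports bias and interval
coverage.

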