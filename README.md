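# btsel

Behavioural-type selection analysis for GPS-tracked game birds.

Hunting removes animals non-randomly: individuals whose consistent
behaviour ("behavioural type") makes them easier to find — birds that
live near forest–open edges, near roads and hunter access points, or
that move a lot — may be harvested or predated at different rates than
shyer conspecifics. `btsel` implements, as a tested and reusable
pipeline, the full analysis used to quantify this in male wild turkeys
(*Meleagris gallopavo*) from two hunted populations (Georgia and South
Carolina), together with a synthetic-data generator with known ground
truth so every stage can be validated end to end.

The pipeline has four stages:

1. **Trait derivation** (`btsel.landscape`, `btsel.traits`).  From GPS
   fixes and 30 m landcover/road rasters, four daily movement traits are
   computed per bird: mean distance to open landcover, to edge landcover
   (forest adjacent to open or road cells) and to hunter access points
   (metres), and average hourly speed (total diurnal path length divided
   by the 15-hour sampling window).  Fixes with dilution of precision
   (DOP) > 7 are discarded and tracks are truncated at mortality.

2. **Variance partitioning** (`btsel.hmodel`).  Each standardized trait
   y is fitted with a Bayesian Gaussian mixed model

       y_ij = x_ij' β + u_i + e_ij,   u_i ~ N(0, V_ind),  e_ij ~ N(0, V_e)

   with fixed effects of hunting stage (pre-hunt / hunt / post-hunt),
   population, and their interaction, and a random intercept u_i per
   bird.  Repeatability — the share of phenotypic variance attributable
   to among-individual differences — is

       r = V_ind / (V_ind + V_e)

   computed per posterior draw.  Sampling is by a conjugate Gibbs sampler
   (collapsed β update; half-Student-t(3, 2.5) priors on both SDs via
   inverse-gamma parameter expansion), run as 2 chains × 15 300
   iterations with burn-in 300 and thinning 15 by default, retaining
   exactly 2000 draws.  Summaries report posterior medians, equal-tailed
   95% credible intervals, probability of direction (PD) and ROPE
   percentages; convergence is checked with split R-hat (< 1.1).

3. **Selection analysis** (`btsel.selection`).  For each trait and fate
   contrast (survived vs harvested; survived vs predated) one logistic
   regression `survival ~ BLUP` is fitted **per retained posterior
   draw**, using that draw's random-intercept values — 2000 GLMs per
   trait — and the per-draw slopes are summarised by median, 95% CrI and
   PD.  Risk (distance) traits are multiplied by −1 first so a positive
   log-odds ratio always reads "riskier birds survive more".

4. **Synthetic cohorts** (`btsel.simulate`).  A generator draws
   landscapes, behavioural types, daily trait values, GPS tracks and
   competing-risk fates (harvest hazard restricted to the hunting
   season) whose defaults reproduce the study structure: 59 + 50 males,
   ~88 daily records each (range 7–153) over 1 March–31 July, fate
   splits of 36/13/10 and 29/14/7, and the fitted variance components
   and stage × population effects of the real populations.

## Worked example

```python
import numpy as np
from btsel import simulate, traits, hmodel, selection

params = simulate.SimulationParams(seed=42)
profiles, records = simulate.simulate_cohort(params)
print(f"cohort: {len(profiles)} males, {len(records)} bird-days")

std, scaling = traits.standardize(records)
spec = hmodel.ModelSpec(response="speed_m_per_h", iterations=2100,
                        burnin=300, thin=9, chains=2, seed=42)
draws = hmodel.fit_lmm(std, spec)
r = hmodel.repeatability(draws)
print(f"speed repeatability r = {r.median:.2f} "
      f"(95% CrI {r.ci_low:.2f}-{r.ci_high:.2f})")

contrast = selection.FateContrast("hunter", "Georgia")
table = selection.subset_by_fate(profiles, contrast)
blups = selection.blup_matrix(draws, table["individual_id"].tolist())
result = selection.iterate_glms(blups, table["outcome"].to_numpy(),
                                flip=False, trait="speed", contrast=contrast)
s = result.summary
print(f"hunter selection on speed (Georgia): log-odds = {s.median:.2f} "
      f"(95% CrI {s.ci_low:.2f}, {s.ci_high:.2f}; PD {s.pd:.1f}%)")
```

Output:

```
cohort: 109 males, 9467 bird-days
speed repeatability r = 0.40 (95% CrI 0.34-0.48)
hunter selection on speed (Georgia): log-odds = 0.26 (95% CrI 0.01, 0.52; PD 97.8%)
```

The cohort here uses a shortened MCMC schedule (2 × 200 retained draws)
for speed.  The repeatability recovers the generator's speed-trait truth
(0.44/(0.44+0.58) ≈ 0.43) within posterior uncertainty.  The positive
selection log-odds says faster explorers survived hunters *more* often
in this synthetic Georgia cohort — consistent with the generator's
default harvest gradient on speed (+0.16 on the death-hazard scale,
attenuated and sign-flipped through the survival parameterisation).

The same pipeline is scriptable from the shell:

```sh
btsel simulate --config config.yaml --seed 3 --out out/sim
btsel derive   --fixes out/sim/fixes.csv --profiles out/sim/profiles.csv \
               --landscape-dir out/sim --config config.yaml --seed 3 --out out/derived
btsel fit      --traits out/derived/trait_table.csv --config config.yaml --seed 3 --out out/fit
btsel select   --draws-dir out/fit --profiles out/sim/profiles.csv \
               --config config.yaml --seed 3 --out out/sel
```

Every command writes a manifest (file hashes, seed, config hash) and the
whole chain is byte-reproducible from one master seed.

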