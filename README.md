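# thialloc

Optimal allocation of thiamine (vitamin B1) between muscles and gonads in a
female salmonid, and the tissue-correlation signal that betrays thiamine
limitation.

Episodic thiamine deficiency kills salmonid yolk-sac fry en masse (the
early-mortality / M74 syndrome) in systems such as the Baltic Sea, yet the
deficiency is hard to detect before a spawning season fails. `thialloc`
implements a state-dependent life-history model for researchers in
ecophysiology and conservation: a female fish allocates her daily blood
free-thiamine pool between locomotor tissue (muscle TDP, which buys adult
survival) and gonads (free thiamine, which buys offspring recruitment),
while renal excretion removes thiamine at a concentration-dependent rate.
The model's practical output is an early-warning indicator: the
cross-sectional correlation between gonadal and muscle thiamine across
females, whose sign and persistence diagnose whether a population is
thiamine-limited.

## Model

State: gonadal free-thiamine concentration `c_g` and muscle TDP
concentration `c_m` (nmol/g wet weight, both capped at `c_x` = 30 nmol/g).
Each day a fraction `alpha` of the blood pool `c_b * w_b` goes to muscles
(converted to TDP with efficiency `q_m` = 0.9), the rest to gonads; daily
amount balances are

    d(c_g w_g) = (1 - alpha) c_b w_b - k_g(c_g) w_g
    d(c_m w_m) = q_m alpha c_b w_b - k_m(c_m) w_m

with tissue masses `w_g, w_m, w_b` following a deterministic salmon-like
growth trajectory (gonads ramp up before each spawning and leave with the
eggs).  Fitness components:

* recruitment probability `r = (c_g / c_x)^v` at spawning,
* daily adult survival `p = p0 + (px - p0)(c_m / c_x)^u`, anchored so a
  female at `c_m = 0` survives a year with probability 0.001 and one at the
  ceiling with probability 0.25,
* post-spawning migration survival `p_f = (c_m / c_x)^l`, `l` = 0.2.

The loss rate `k(c)` encodes renal physiology: a sigmoid (reabsorption at
low concentration switching to active secretion at high concentration), a
reabsorption power law joined continuously to linear passive transport at
a threshold `c_t`, or a plain linear law.  Maximal rates are 0.5 (gonads)
and 0.35 (muscles) nmol/g/day.

Lifetime fitness `V = R_1 + sum_{i>=2} (chained p_f) R_i`, with
`R_i = r(c_g) w_g(d_s, i) * prod p`, is maximized by backward induction
over a discretized `(day, year, c_g, c_m)` grid, giving the optimal policy
`alpha(d, i, c_g, c_m)`.  Populations of N = 1000 females following that
policy under stochastic daily input (beta-distributed, +/- 2 nmol/g around
the scenario mean) are then simulated forward, and each day's
cross-sectional OLS regression of `c_m` on `c_g` is fitted with the
inclusion filters (females with `c_g` > 0; more than 2/3 of the population
included; spread above 0.5 nmol/g in both tissues) and reported when
R² > 0.2.

## Worked example

```bash
python examples/03_slope_diagnostics.py
```

```
limited (c_b = 2 nmol/g): signal = positive
  102 reported days (102 positive, 0 negative)
  first reported day 246: slope +0.061 (R^2 0.53)
  last  reported day 353: slope +0.203 (R^2 0.25)
replete (c_b = 6 nmol/g): signal = negative
  87 reported days (0 positive, 87 negative)
  first reported day 260: slope -0.098 (R^2 0.31)
  last  reported day 361: slope -0.113 (R^2 0.21)
```

Under a limited input (blood level 2 nmol/g) the daily gonad-to-muscle
regression slope is positive for a sustained stretch of the pre-spawning
season and rises toward spawning: females with more muscle TDP can afford
to shift allocation to their gonads earlier.  Under a replete input
(6 nmol/g) the slope is negative — at near-ceiling muscle levels, extra
muscle allocation barely increases losses, so the best-provisioned females
keep allocating to muscle.  A sustained positive correlation across
sampled females is therefore a field-measurable sign of thiamine
limitation before any fry die.

Other example scripts: `01_response_curves.py` (the physiological response
functions), `02_optimize_and_simulate.py` (policy structure and the
allocation switch), `04_synthetic_tissue_table.py` (empirical-style
two-system tissue tables and their Spearman analysis),
`05_scenario_sweep.py` (input sweep under linear excretion, which yields no
correlation signal).

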