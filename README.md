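# palaeocr

Capture-recapture estimation of fossil biodiversity dynamics on
stratigraphic time bins: per-bin genus richness, origination and
extinction rates per Myr, and per-bin cohort survivorship/longevity
metrics, together with a birth–death–sampling simulator that makes every
stage verifiable against known truth.

## The problem

Fossil occurrence data (e.g. Paleobiology Database downloads: one row per
genus per collection, with an age range in Ma) undersample the living
biota of every time interval: a genus extant in a bin is only *sometimes*
sampled there. Treating each time bin as a sampling occasion and each
genus as an individual turns the fossil record into a classic
open-population capture-recapture problem, so detection can be modelled
instead of ignored.

`palaeocr` implements the two standard open-population models on
genus × bin incidence matrices:

* **Jolly–Seber in the POPAN formulation** — a superpopulation of `N`
  genera enters the study window through a per-bin entry distribution
  `β` (simplex), persists through transition *i* with survival `φᵢ`, and
  is detected in bin *i* with probability `pᵢ`. The extant-richness
  series follows `N₁ = Nβ₁`, `Nᵢ₊₁ = Nᵢφᵢ + Nβᵢ₊₁`.
* **Pradel survival/seniority** — survival `φᵢ` forward in time and
  seniority `γᵢ₊₁` backward in time (the probability that a genus extant
  in bin *i+1* was already extant in bin *i*). Survival and seniority
  convert to per-Myr rates on uneven bins via `rate = −ln(prob)/Δt`:
  extinction from `φ`, origination from `γ`.

On top of the fitted Pradel chains sit the cohort survivorship metrics:
for each focal bin *tᵢ* the modelled cohort richness is 100% at *tᵢ*,
shrinks backward through products of `γ` and forward through products of
`φ`, and reading the antecedent/posterior bins still holding 50/70/90% of
the focal richness gives the backward survivorship `l_bw` (cohort genus
age), the forward survivorship `l_fw` (life expectancy), and the overall
longevity `l_o = l_bw + l_fw`, all in Myr.

Supporting steps: relative diversification
`(n_gen(t) − n_gen(t−1))/n_gen(t)`; Alroy's second-for-third turnover
rates as a sampling-robust comparison baseline; and at-most-one-
changepoint detection (Gaussian mean-shift cost, SIC penalty) for regime
shifts in rate series.

## Worked example

```python
import palaeocr as pc
from palaeocr.cr import FitOptions

cfg = pc.scenario("stable", seed=1)          # low steady turnover, K=10 bins
table, truth = pc.simulate_occurrences(cfg)  # 9031 occurrence rows
mat = pc.bin_occurrences(table, cfg.scheme)  # 1922 genera x 10 bins

popan = pc.fit_popan(mat, FitOptions(n_restarts=2, seed=0))
print(popan.richness.round(1)[:3])           # [1308.1 1335.6 1302.8]
print(truth.expected_richness.round(1)[:3])  # [1298.7 1298.7 1298.7]

pradel = pc.fit_pradel(mat, FitOptions(n_restarts=2, seed=0))
rates = pc.evolutionary_rates(pradel, cfg.scheme)
print(rates.series("extinction_rate").round(3))
# [0.033 0.025 0.031 0.024 0.035 0.028 0.023 0.031 0.041   nan]

surv = pc.longevity_series(pradel, cfg.scheme)
print(surv.series("l_fw", 0.9))
# [3.45 3.45 3.45 3.45 3.45 3.45 3.45 3.45 3.45 1.15]
```

The richness estimates sit within ~1–3% of the generator's expectation
(observed richness is only ~910 per bin — the model corrects for the 30%
of extant genera the sampling misses). The fitted extinction rates
scatter around the true 0.027/Myr, and the 90% life expectancy reads
3.45 Myr at every interior bin: half the 2.3-Myr focal bin plus one full
bin, because one transition at `φ = 0.94` retains ≥ 90% of a cohort but
two (0.88) do not. The last value is censored at the window edge (the
series carries censoring flags).

The same pipeline runs from the shell (`palaeocr simulate`, `palaeocr
bin`, `palaeocr fit-popan`, `palaeocr rates`, `palaeocr survivorship`,
`palaeocr changepoint`, or `palaeocr run-all`), and the numbered scripts
under `analysis/` walk the full study: simulate the three regimes
(stable, volatile, extinction pulse), bin, fit, derive rates and the
regime-shift changepoint, and read the survivorship contrast.

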