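# Methods

## Data model

The unit of observation is a fossil occurrence: a genus name, a
collection identifier, and an age range in Ma (ages decrease toward the
present; durations are in Myr). Occurrences are assigned to an ordered,
non-overlapping scheme of stratigraphic time bins. The default **strict
containment** policy assigns an occurrence to a bin only when its whole
age range lies inside the bin, and drops (but counts) range-spanning
occurrences; a **majority-overlap** policy (assign when > 50% of the age
range falls in one bin) is available for coarsely dated material. Genus
names are normalized deterministically — subgenus parentheses stripped,
whitespace collapsed, case-sensitive matching thereafter — because
occurrence databases are messy and a documented rule beats silent
divergence; no synonymization is attempted. Duplicate genus/bin
assignments collapse to a single incidence: the capture-recapture models
use presence, not abundance.

The resulting genus × bin 0/1 matrix is the set of capture histories.
Bins with zero observed genera are retained as occasions (their detection
estimate lands on a boundary with a warning) so the time axis is never
silently compressed.

## Capture-recapture models

**POPAN (Jolly–Seber).** Parameters: superpopulation size `N ≥ D` (D =
observed genera), entry simplex `β` over bins, survival `φᵢ ∈ (0,1)` per
transition, detection `pᵢ ∈ (0,1)` per bin. The likelihood is the full
superpopulation form: each observed history contributes a sum over latent
entry/exit bins (computed by forward/backward recursions), and the
`N − D` never-detected genera contribute a binomial term with the
never-detected probability. `N` is treated as continuous (gamma-function
binomial coefficient). Derived richness: `N₁ = Nβ₁`,
`Nᵢ₊₁ = Nᵢφᵢ + Nβᵢ₊₁`.

**Pradel (survival/seniority).** Parameters: `φᵢ`, seniority `γᵢ₊₁`
(probability a genus extant in bin i+1 was already extant in bin i), and
`pᵢ`. Seniority pins the relative cohort sizes,
`Nᵢ₊₁/Nᵢ = φᵢ/γᵢ₊₁`, hence the relative in-flows
`Bᵢ = Nᵢ(1 − γᵢ)`; normalizing the in-flows yields the entry
distribution of the equivalent superpopulation model, and each history's
probability is conditioned on the genus being detected at least once.
This detection-conditional form is algebraically the same model as the
usual backward-ξ/forward-χ recursion presentation, makes every capture
history a proper probability (the likelihood is informative about γ), and
is exactly time-symmetric: reversing the bin order swaps φ̂ and γ̂.

Both likelihoods are verified against a brute-force latent-interval
enumeration (`palaeocr.enumeration`) to 1e-10 in the test suite; the
enumeration shares no code with the production recursions.

### Fitting and uncertainty

Probabilities are fitted on logit links, the entry simplex through a
softmax with the first logit pinned, and the superpopulation through
`log(N − D)`. Optimization is L-BFGS-B from a data-driven start (range-
through counts give crude `φ`, `γ`, `p`, and first-detection frequencies
give `β`) plus jittered restarts (default 5; the bundled studies use 2
because the data-driven start is reliable at their sizes). Link
parameters are bounded at ±15; estimates near the bound raise a boundary
warning (e.g. saturated matrices drive `p̂ → 1`).

First- and last-occasion detection is not separately identifiable in open
models (confounded with entry in the first bin, with survival out of the
last). By default the fitter ties `p` in the edge bins to their interior
neighbours (`tie_edge_detection=True`); leaving the edges free pushes
them to a boundary and biases the edge richness by tens of percent.
Fully time-varying parameters are the default, matching per-bin
estimation; a constant-parameter variant (`time_varying=False`) is
available as regularization for sparse matrices.

Standard errors come from the inverse (pseudo-inverse, to tolerate the
structurally singular directions of fully time-varying fits) of a
central-difference Hessian on the link scale; 95% CIs are link-scale Wald
intervals back-transformed, and richness CIs use the delta method on
log-richness so intervals stay positive. Profile-likelihood and bootstrap
intervals are out of scope.

## Rates on uneven bins

`rate = −ln(prob)/Δt` converts per-transition probabilities to per-Myr
rates: extinction from `φᵢ`, origination from `γᵢ₊₁`. `Δt` defaults to
the **midpoint-to-midpoint** distance of the two bins — bins are extended
sampling occasions, not instants — with the full older-bin duration as an
alternative convention. Assignment: the extinction rate of transition
i → i+1 is reported at bin i, origination at bin i+1; the convention is
written into the output metadata. Rate CIs transform the probability CI
endpoints through the monotone map.

Relative diversification is `(n_t − n_{t−1})/n_t`, undefined at the first
bin and wherever `n_t = 0`.

**Second-for-third comparison rates** follow Alroy's (2015) substitution
algorithm: per focal bin, counts of two-timers, three-timers,
part-timers, and the three "sampled in exactly one of the next three
windows" patterns; the middle of the three substitution counts replaces
the third-interval count, giving an extinction proportion
`E = (s1d − mid(s1d, s2d, s3d))/(t2d + part)` and rate `ln(1/(1−E))`
(origination mirrored). Rates are undefined where the four-bin window is
incomplete. Because the raw form is per-interval and ignores bin length,
both raw and duration-normalized (per-Myr, divided by the focal bin
length) variants are emitted; noisy bins can yield negative values, which
are reported as computed — this module is a comparison baseline, not the
estimator of record.

**Changepoint.** At-most-one-changepoint on a rate series: Gaussian
mean-shift cost with the common variance profiled out, minimum segment
length 2, accepted iff `n·ln(RSS₀/n) − n·ln(RSS₁/n) > 2·ln n` (SIC
penalty for the extra mean and the break location). NaN entries (edge
bins) are dropped; reported indices refer to the original series.

## Cohort survivorship and longevity

For focal bin tᵢ the modelled cohort fraction is 1 at tᵢ, the product of
the fitted `φ` chain forward, and of the fitted `γ` chain backward
(deterministic chain products of the global fit; a per-cohort refit mode
exists for sensitivity analysis). For each level q ∈ {0.5, 0.7, 0.9} the
threshold bin is the most distal bin on each side with fraction ≥ q (ties
inclusive), and the reading is the time from the **midpoint of tᵢ to the
distal boundary of the threshold bin** — the maximum elapsed time
consistent with bin-level resolution, and an anchor that keeps
`l_o = l_bw + l_fw` free of double counting. If even the adjacent bin is
below q the threshold bin is tᵢ itself (reading: half the focal bin's
duration). Levels still met at the window edge are flagged censored and
never silently truncated; censoring propagates to `l_o`. By construction
`l(0.9) ≤ l(0.7) ≤ l(0.5)` on each side, and time-reversing the matrix
swaps the `l_bw` and `l_fw` series.

## Synthetic data

The generator draws exactly the process the models assume: entry bin from
`β`, persistence through `φ`, detection through `p`; detected genus-bin
pairs become occurrence rows with age ranges strictly inside the bin so
strict-containment binning round-trips them. The truth object records
entry/exit bins, realized and expected richness
(`Nᵢ₊₁ = Nᵢφᵢ + n·βᵢ₊₁`), the implied seniority
`γᵢ₊₁ = Nᵢφᵢ/Nᵢ₊₁`, and the per-Myr true rates on the same
midpoint-duration scale the estimates use.

Scenario presets (uniform 2.3-Myr bins, the average bin length of the
early-Palaeozoic scheme the analysis emulates; `n_super = 2000`,
`p = 0.7`):

* **stable** (Ordovician–Silurian analogue): `φ = 0.94` per transition
  with a steady-state entry schedule, i.e. matched origination and
  extinction rates of ≈ 0.027/Myr. The value was chosen to sit at the
  stated low-turnover regime (≈ 0.03/Myr) while staying clear of the 0.9
  survivorship read-off level: a survival probability exactly at a level
  makes `l_fw(0.9)` a knife-edge tie that flips on estimation noise,
  which would make the regime contrast a coin toss rather than a property
  of the system.
* **volatile** (Cambrian analogue): extinction rates alternating
  0.08–0.25/Myr (mean ≈ 0.16) and a spiky entry schedule putting
  origination in the same band; true longevities are short.
* **extinction_pulse** (Late Ordovician mass-extinction analogue): stable
  background, one transition crashed to `φ = 0.35` (K = 12, pulse at
  transition 7), entries nearly shut off in the bin after the pulse
  (survivors dominate, so cohort age jumps) and recovering afterwards.

What the generator does **not** emulate: phylogenetic structure,
geographic ranges, abundance, age-model error beyond bin membership,
lithology/facies sampling biases, or correlated detection across bins.
Passing recovery tests therefore shows the estimators are correct for the
assumed observation process, not that real occurrence data satisfy it.

## Problem sizes and numerical choices

The bundled studies use K = 10–20 bins and superpopulations of 800–4000
genera — large enough that per-bin parameters are well identified, small
enough that the whole suite runs in well under a minute per study.
Optimizer function tolerance is 1e-11 (relative), Hessian steps 1e-4,
richness-gradient steps 1e-5; probabilities inside likelihoods are
floored at 1e-300 before logs so exact-zero parameters yield −inf-like
values without NaNs. Monte-Carlo acceptance checks use 20 replicates for
recovery (coverage tolerance band [0.88, 0.99]) and 100 seeded series for
changepoint localization.

## Known limitations

* Delta-method intervals can be optimistic near boundaries (e.g. `γ̂`
  near 1 in low-origination worlds); the structurally unidentified
  directions of fully time-varying fits are handled by pseudo-inversion,
  which inflates those SEs rather than failing.
* The second-for-third implementation targets the documented algorithm,
  not bit-level parity with any particular release of other software.
* Survivorship readings are bin-resolution quantities; they change with
  the anchor convention (midpoint vs boundary), which is therefore
  recorded in the output metadata.
* The binning default (strict containment) discards coarsely dated
  occurrences; on real data the choice between strict and majority
  binning materially changes observed richness and should be reported.
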