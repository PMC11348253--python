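# gmpda

Detection of one or more periodicities in **binary event time series** —
series that record only *when* events happen (leg movements during sleep,
heartbeats, log-ons), not how strongly. Given the sorted event timestamps
`S = {s_i}` of a series of length `N_T`, the package infers the set of
*prime* periods `μ*` (the smallest periods explaining the inter-event
intervals — not their integer multiples, which also fit), the jitter `σ*` of
each period, and a goodness-of-fit loss that can be calibrated against
non-periodic noise.

## Method

The detector fits a Gaussian mixture to the histogram `D(μ)` of *all*
forward pairwise inter-event intervals. Under a generative model, `D` is
expected to peak at every multiple `m·μ` of a true period:

    G(μ) = Σ_p Σ_m c_m · N(μ; m·μ_p, v_m),    c_m = N_T/μ_p − (m − 1)

with component variance `v_m = σ_p²` under the **clock model** (a pacemaker
places event *i* at `α + i·μ + ε`; jitter does not accumulate) or
`v_m = m·σ_p²` under the **random-walk model** (each event is offset from
the previous by `μ + ε`; variance grows linearly with interval order).
Intervals involving uniform false positives or crossing different
periodicities follow a linearly decaying curve `ẑ·(1 − μ/N_T)` whose
amplitude is estimated from sub-periodic lags and subtracted. Candidate
periods come from comb-folding the cleaned histogram (a lag `q` scores the
mean histogram mass over its multiples, so a prime period beats its
harmonics); widths are refined by bounded least squares; and the subset of
candidates minimizing the normalized L1 loss between histogram and mixture
is selected, an extra period being kept only when it improves the loss by
more than a tolerance. Full details are in `docs/methods.md`.

Four classical baselines (periodogram of the binary series, of its
autocorrelation, of the interval histogram, and modulus folding) and a
benchmark harness with the ±0.5σ accuracy criterion are included.

## Worked example

Simulate a noisy random-walk series (true period 23, jitter σ=2, one noise
event per periodic event) and detect:

```sh
$ gmpda simulate --model rw --mu 23 --sigma 2 --beta 1 --n 120 --seed 7 --out events.csv
wrote 234 events (N_T=2725) to events.csv

$ gmpda detect --input events.csv --model rw --lmin 10 --max-periods 3 \
      --loss-tol-change 0.1 --json result.json
periods=[23] sigmas=[1.77] loss=0.5387 model=random_walk
```

The detector recovers the prime period 23 (not 46 or 69, which also explain
many intervals) and estimates the jitter at 1.77 against a true σ of 2. The
loss 0.54 is the L1 distance between the noise-subtracted interval histogram
and the fitted mixture, both normalized to unit mass — 0 is a perfect shape
match, 2 is disjoint support. Whether 0.54 is *significant* is answered by
the reference loss, the 0.01 quantile of the same loss on purely uniform
event series:

```sh
$ gmpda refloss --reps 3 --q 0.01 --seed 1
reference loss (0.01 quantile, 3 reps/cell): 0.83556
```

0.54 < 0.84, so the detected periodicity is significant at that reference.

The same functionality is available as a library:

```python
from gmpda import GenerativeSpec, GmpdaConfig, simulate, gmpda_detect

spec = GenerativeSpec("random_walk", periods=(23,), sigmas=(2,), beta=1,
                      events_per_period=120, seed=7)
est = gmpda_detect(simulate(spec), GmpdaConfig(model="random_walk", l_min=10,
                                               loss_tol_change=0.1))
print(est.periods, est.loss)   # (23,) 0.538...
```

`gmpda benchmark` sweeps simulation grids over jitter rules, noise rates and
event counts for all detectors and writes a tidy CSV of per-cell accuracies.

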