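# transjs

Jolly–Seber (POPAN) mark–recapture models for **translocated
populations** — for conservation practitioners and quantitative
ecologists monitoring reintroductions with capture–recapture surveys.

When a population is founded by releasing a known number of animals, the
release is effectively a survey at which every individual is detected.
The standard, unconstrained POPAN Jolly–Seber model ignores this: it
estimates entry and detection at the release occasion like any other,
and under low capture probability this systematically **overestimates
abundance during the establishment phase** — exactly when managers must
decide whether to reinforce.  `transjs` implements a joint likelihood
with a separate component for the released cohort:

    L(N, φ, p, β) ∝ N!/(N−D_w)! · Π_{i≤n0} Pr(h*_i) · Π_{i>n0} Pr(h_i) · Pr(h0)^{N−D_w}

where `n0` released animals have known entry and certain detection at
the release (`p_1 = 1`), wild-born recruits enter from occasion `τ`
onwards with proportions `β` of a wild superpopulation `N`, `φ` is
apparent survival, `p` capture probability, `D_w` the number of observed
wild animals and `Pr(h0)` the probability of never being detected.
Abundance follows by recursion: `N_1 = n0`,
`N_{t+1} = N_t·φ̂_t + N̂·β̂_{t+1}`.

The package provides both model families (translocation and standard
POPAN), maximum-likelihood fitting with multi-start quasi-Newton
optimization on link scales (log `N`, logit `φ`/`p`, multinomial-logit
`β`), uneven survey intervals via monthly survival, occasion covariates
and sex/group effects, nonparametric bootstrap confidence intervals, AIC
model selection, a scenario simulator, and the simulation study that
quantifies the bias of the unconstrained model.  See
[`docs/methods.md`](docs/methods.md) for the full model description.

## Worked example

Simulate one replicate of a release of 30 animals into a superpopulation
of 500 with mid-range detection (scenario 5 of the built-in grid), then
fit both families:

```python
from transjs import (TranslocationJollySeber, StandardJollySeber,
                     scenario, simulate_dataset)

data, truth = simulate_dataset(scenario(5), seed_or_rng=12345)
print(data.n_observed, data.n_translocated)   # 397 26

tjs = TranslocationJollySeber(n_starts=2).fit(data)
sjs = StandardJollySeber(n_starts=2).fit(data)
print(round(tjs.loglik_, 1), tjs.n_params_)   # 359.2 9
print([round(n) for n in tjs.abundance_])
# [26, 22, 19, 133, 164, 197, 209, 262, 282, 328]
print([round(n) for n in sjs.abundance_])
# [32, 28, 24, 130, 161, 193, 205, 256, 274, 318]
print([int(n) for n in truth.true_n])
# [26, 25, 19, 110, 161, 187, 203, 246, 284, 283]
```

The translocation fit starts exactly at the released count (26) and
tracks the true trajectory; the standard fit inflates the pre-recruitment
occasions (32 vs 26 at release) — mildly here, and drastically when
capture probability is low.  `tjs.bootstrap(B=999)` adds percentile
confidence intervals for every parameter and each `N_t`.

The same operations are available from the shell:

```sh
transjs simulate --scenario 5 --reps 1 --seed 7 --out data/
transjs fit --model translocation --data data/s05_r000.csv \
            --design data/s05_r000.design.yaml
transjs study --reps 250 --seed 1 --out study_out/   # full bias study
```

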