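# stoptf — Bayesian trigger-failure race model for stop-signal data

Response inhibition is commonly studied with the stop-signal paradigm: a
choice reaction-time task occasionally interrupted by a stop signal that
instructs the participant to withhold the response.  The classic independent
race model describes each stop trial as a race between a *go* process
(latency: the go RT) and a *stop* process launched at the stop-signal delay
(SSD); the stop-process latency (SSRT) is unobservable and must be inferred.
A response escapes whenever go RT < SSD + SSRT — **or** whenever the stop
process is simply never launched, a *trigger failure*.  Undetected trigger
failures masquerade as slow stopping and can severely bias SSRT estimates
and group comparisons.

`stoptf` estimates the full SSRT distribution *jointly* with the
trigger-failure probability P(TF).  Go RTs and SSRTs are ex-Gaussian:
μ and σ describe the leading edge of each distribution, τ its exponential
tail (mean μ + τ).  The likelihood of a signal-respond RT *t* at a given SSD
is the two-path mixture

```
L_SR(t) = P(TF) · f_go(t)  +  [1 − P(TF)] · [1 − F_stop(t − SSD)] · f_go(t)
```

and the likelihood of a successful inhibition is

```
L_I = [1 − P(TF)] · ∫ [1 − F_go(t)] · f_stop(t − SSD) dt ,
```

the probability that a launched stop process beats the go process, evaluated
by numerical quadrature.  The integral is also the normalising constant of
the censored signal-respond density, so the two pieces form a proper
probability measure at every SSD.  Posteriors are sampled by
Metropolis-within-Gibbs (scalar random-walk blocks plus an adaptive joint
proposal), with weakly informative uniform priors, for three model variants:

* `individual` — one participant, seven free parameters;
* `standard` — the same race model with P(TF) ≡ 0 (the classic censored
  formulation; an exact nested restriction);
* `hierarchical` — subject-level parameters drawn from truncated-normal
  group distributions, with P(TF) modelled on the probit scale.

The package also provides a race-model simulator (fixed-SSD,
staircase-tracking, and relative-SSD schedules), the traditional
integration-method and mean-method SSRT point estimators, and model
criticism via DIC and posterior-predictive checks of inhibition functions
with per-SSD p values.

## Worked example

```python
from stoptf import (ExGaussParams, SSDSchedule, SubjectParams,
                    SamplerSettings, classic_from_table, fit,
                    simulate_dataset, summarize_posterior)

sp = SubjectParams(go=ExGaussParams(440, 80, 60),       # mean go RT 500 ms
                   stop=ExGaussParams(190, 40, 50),     # mean SSRT 240 ms
                   ptf=0.1)                             # 10% trigger failures
data = simulate_dataset(sp, n_go=750, n_stop=250, sched=SSDSchedule(), seed=12)
print("signal-respond rate:",
      round(data.loc[data["is_stop"], "responded"].mean(), 3))
print("classic mean-method SSRT:",
      round(classic_from_table(data, "mean").ssrt, 1))

chains = fit(data, model="individual",
             settings=SamplerSettings(seed=3, n_burnin=1000, n_retained=1000))
print(summarize_posterior(chains).round(3).to_string(index=False))
print("max R-hat:", round(chains.rhat_table()["rhat"].max(), 3))
```

prints

```
signal-respond rate: 0.496
classic mean-method SSRT: 257.1
 parameter  median   ci_lo   ci_hi
     mu_go 441.677 426.932 456.503
  sigma_go  80.046  71.675  88.683
    tau_go  58.785  44.030  74.706
   mu_stop 174.734 118.217 238.114
sigma_stop  51.144   4.166 112.190
  tau_stop  65.490   4.856 134.521
       ptf   0.034   0.001   0.146
max R-hat: 1.008
```

The staircase drove the signal-respond rate to ≈ 0.50.  The mean method,
which cannot separate trigger failures from slow stopping, returns 257 ms
for a true mean SSRT of 240 ms, while the race-model posterior puts the mean
SSRT (μ_stop + τ_stop) near its generating value and brackets every
generating parameter — at 250 stop trials the stop-parameter posteriors are
wide, and they tighten as trials accumulate.  All chains converged
(R-hat < 1.1).

## Command line

```bash
stoptf simulate --config sim.yaml --seed 7 --out data.csv
stoptf fit --data data.csv --model individual --seed 7 --out fit/
stoptf classic --data data.csv --method mean
stoptf dic --fit fit_tf/ --fit fit_standard/ --data data.csv
stoptf ppc --fit fit/ --data data.csv --reps 1000 --seed 7 --out ppc.json
stoptf config --show-defaults
```

Trial tables are CSVs with columns `subj_idx, ss_presented, inhibited, ssd,
rt` and `-999` for structurally missing entries.  Every run writes a
`manifest.json` (config, seed, versions) for exact reproduction.

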