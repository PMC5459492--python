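# cprsim

A simulator for **continuous-time common-pool-resource (CPR) experiments**:
the computational core of an experiment platform in which a group of users
harvests from a shared, dynamically renewing resource by adjusting a
personal effort slider in real time. The package is aimed at experimental
economists and ecologists who want to design, dry-run and analyse such
sessions entirely offline — synthetic agents stand in for the human
participants, so every part of the pipeline (resource dynamics, event
handling, payoffs, logging, analysis) is testable and exactly reproducible
from a seed.

## The model

The resource stock *R* follows the Gordon–Schaefer bioeconomic model:
logistic renewal minus harvest that is bilinear in stock and total effort,

    dR/dt = μ_R R (1 − R/K) − q R Σᵢ Eᵢ

with carrying capacity *K*, maximum growth rate *μ_R*, and catchability
*q*. Each user *i* harvests at rate *Hᵢ = q R Eᵢ* and earns the return rate
*Bᵢ = p Hᵢ − c Eᵢ* given a price *p* per resource unit and a cost *c* per
unit effort. At constant total effort *F* the stock settles at
*K(1 − qF/μ_R)* (zero once *qF ≥ μ_R*, the collapse regime); the maximum
sustainable yield *μ_R K/4* is reached at total effort *E_MSY = μ_R/(2q)*;
logistic productivity peaks at *K/2*.

Users change their efforts at arbitrary moments. Between changes total
effort is constant, so the dynamics are integrated **exactly** with the
closed-form logistic solution, a new integration starting at each effort
event with the stock carried over continuously. Cumulative harvests and
returns use the exact segment antiderivative of *R(t)*, making the
accounting independent of the output sampling grid.

On top of the model sit:

* **event engine** — piecewise-constant effort schedules, per-agent
  submission lockout, sampled trajectories (`cprsim.events`);
* **agents** — constant / myopic bang-bang / sustainable MSY-split /
  threshold / noisy / scripted policies and seeded whole-experiment runs
  (`cprsim.agents`);
* **session** — ordered stages (information, questionnaire, incentivised
  allocation task, model, waiting) and the standard payoff scheme:
  harvesting earnings + 2 € questionnaire fee + one randomly selected
  allocation decision per random pair (`cprsim.session`);
* **io** — strict JSON configs, CSV event/trajectory logs in round-trip
  float precision, bit-stable replay, and the client/server message-schema
  contract (`cprsim.io`);
* **analysis** — run summaries, recovery-episode detection, treatment
  contrasts with optional permutation p-values, trajectory figures
  (`cprsim.analysis`), plus a thin `cprsim` command-line tool
  (`run`, `replay`, `analyze`, `plot`, `validate`).

## Worked example

```python
from cprsim import (SchaeferParams, MyopicPolicy, SustainablePolicy,
                    run_experiment, treatment_pair, summarize, compare_treatments)

params = SchaeferParams()   # mu_R=0.1/s, K=100, q=0.01, p=1, c=0.1, E_max=10

myopic = run_experiment(
    params, {f"a{i}": MyopicPolicy(params) for i in range(5)}, 600.0, seed=0
).trajectory
print(myopic.R.min(), myopic.R[-1])         # 0.19 7.17

pair = treatment_pair(params, n_runs=10, seed=0, t_end=300.0)
contrast = compare_treatments(
    [summarize(r.trajectory) for r in pair.communication],
    [summarize(r.trajectory) for r in pair.no_communication],
)
print(contrast.arm_a["mean_resource"], contrast.arm_b["mean_resource"])
# 52.30 4.47
print(contrast.arm_a["effort_sd"], contrast.arm_b["effort_sd"])
# 0.24 18.31
```

Five myopic agents at full effort put the group deep into the collapse
regime (q·N·E_max = 0.5 ≫ μ_R): the stock crashes from the carrying
capacity 100 to a minimum of 0.19 and then oscillates around the bang-bang
switch point c/(pq) = 10. Coordinated groups that split the MSY effort
("communication" arm) hold the stock near 52 with almost constant group
effort, while myopic groups ("no communication") sit near 4.5 with group
effort swinging between 0 and 50 — the classic qualitative ordering:
communication yields higher resource levels and less volatile effort.

The `examples/` directory contains one short script per capability
(analytics, event simulation, agents and treatments, sessions and payoffs,
logging and replay); each prints the numbers it computes with a line on
what they mean.

## Command line

```bash
cprsim validate --config config.json
cprsim run --config config.json --seed 1 --out logs/run1
cprsim replay --log logs/run1 --config config.json   # "trajectories identical"
cprsim analyze --logs A=logs/run1 --logs B=logs/run2 --out report.json
cprsim plot --log logs/run1 --out run1.png
```

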