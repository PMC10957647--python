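# hazdiff

Tools for quantifying when the hazard difference estimated from a
randomized trial stops being the causal effect, under Aalen's additive
hazards model with unobserved effect heterogeneity.

## The problem

For a binary exposure `a ∈ {0, 1}` and potential event times `T^a`, suppose
each individual's hazard is additive in an unobserved frailty `U0` and an
unobserved effect modifier `U1`:

    λ_i^a(t) = f0(t, U0i) + U1i · g(t) · a,

with `g ≡ 1` by default (a *time-invariant* individual causal effect). The
population causal hazard difference (CHD) is

    CHD(t) = E[λ^1(t)] − E[λ^0(t)] = E[U1] · g(t).

What an additive-hazards regression on trial data estimates, however, is the
hazard difference among *survivors*, the survivor-marginalized CHD (SMCHD):

    SMCHD(t) = E[U1 g(t) | T^1 ≥ t] + E[f0(t,U0) | T^1 ≥ t] − E[f0(t,U0) | T^0 ≥ t].

Individuals with harmful `U1` die earlier in the exposed universe, so the
surviving exposed are selected toward favourable modifiers: the SMCHD drifts
away from the CHD even though every individual effect is constant in time.
The integrated curve `B(t) = ∫₀ᵗ SMCHD(s) ds` — exactly what an Aalen fit
plots — then bends, and a time-invariant heterogeneous effect is
observationally indistinguishable from a homogeneous time-varying one.

When `U0 ⟂ U1` the frailty terms cancel and the SMCHD is the exponentially
tilted (Laplace-transform) survivor mean

    SMCHD(t) = −L′(G(t)) / L(G(t)) · g(t),   L(c) = E[e^{−c U1}],  G(t) = ∫₀ᵗ g,

with elementary closed forms for the three-point Benefit/Harm/Neutral law
`BHN(p1, μ1, p2, μ2)` (`U1 = μ1 ≤ 0` w.p. `p1`, `μ2 ≥ 0` w.p. `p2`, else 0).
For dependent `(U0, U1)` — coupled by a Gaussian copula with Kendall's τ —
the three survivor terms are estimated by Monte Carlo from simulated
potential outcomes.

The package provides:

- **`hazdiff.distributions`** — modifier/frailty laws (BHN, shifted gamma,
  degenerate), Laplace transforms, Gaussian-copula joint sampling.
- **`hazdiff.scm`** — the structural model: closed-form cumulative hazards,
  potential-outcome event times by cumulative-hazard inversion with shared
  structural noise, randomized-trial data generation, survival curves.
- **`hazdiff.estimands`** — CHD, analytic SMCHD, bias, integrated curves.
- **`hazdiff.montecarlo`** — survivor-expectation decomposition, SMCHD
  curves with Riemann integration (step 0.1, n = 10,000 by default).
- **`hazdiff.aalen`** — a from-scratch Aalen additive-hazards least-squares
  estimator (`AalenAdditive`, scikit-learn style) with martingale variances
  and pointwise confidence bands.
- **`hazdiff.cli` / `hazdiff.config`** — `hazdiff curves|simulate|fit|reproduce`
  over YAML configs.

## Worked example

A synthetic trial (n = 10,000, constant baseline `f0 = 0.2 + U0`,
`U0 ~ Gamma(1,1)`) whose modifier is `BHN(0.5, −0.1, 0.5, 0.4)`: half the
population benefits (−0.1), half is harmed (+0.4), so the CHD is 0.15 at
every time point.

```sh
hazdiff reproduce casestudy --n 10000 --seed 1 --out-dir cs
```

Reading `cs/casestudy_overlay.csv` at a few landmark times:

```
t=0.500  fitted=0.0663  integrated_smchd=0.0672  naive=0.0750
t=1.001  fitted=0.1127  integrated_smchd=0.1191  naive=0.1501
t=2.000  fitted=0.1506  integrated_smchd=0.1799  naive=0.3000
t=3.995  fitted=0.2040  integrated_smchd=0.1664  naive=0.5992
```

The fitted cumulative treatment curve (`fitted`) tracks the analytic
integrated SMCHD, not the straight line `0.15·t` (`naive`) that the constant
causal effect would suggest: by `t = 4` the naive line predicts 0.60 while
the observable curve has flattened and begun to decrease, its slope heading
toward −0.1 — the harmed half of the population has been selected out of
the exposed survivors. In Python:

```python
from hazdiff import BHNModifier, bhn_survivor_mean, bhn_integrated_curve
bhn = BHNModifier(p1=0.5, mu1=-0.1, p2=0.5, mu2=0.4)
bhn.mean()                      # 0.15   — CHD, constant in t
bhn_survivor_mean(bhn, 100.0)   # -0.100 — SMCHD limit: only beneficiaries survive
bhn_integrated_curve(bhn, 2.0)  # 0.180  — B(2), already below 0.15*2 = 0.30
```

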