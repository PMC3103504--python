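# granulosim

A dynamical model of granulomatous Th1 inflammation, built for in-silico
experiments on sarcoidosis-like disease: when does a single antigen
exposure resolve, when does it lock into a self-sustaining granulomatous
state, and which cytokine-targeted therapies can unlock it again?

The package is aimed at systems-immunology modellers and at anyone who
wants a small, fully reproducible testbed for bistable immune switches,
square-pulse perturbation protocols and dose-titration of inhibitors.

## The model

**Minimal switch.** Th1 activity $T$ follows

$$\frac{dT}{dt} = \beta_T - \varepsilon_T T + f_T\,\frac{T^2}{\theta_T^2 + T^2},
\qquad f_T = \eta_1 A + \eta_2 c ,$$

a basal influx/clearance balance plus an autocatalytic, sigmoidal
activation term driven by antigen $A$ and a lumped cytokine level $c$.
The steady states solve a cubic, so there is a range of drives $f_T$ with
two stable branches (low/healthy and high/inflamed) separated by an
unstable middle branch — a bistable switch with hysteresis.  Raising the
activation threshold $\theta_T$ (a proxy for regulatory-T-cell activity)
shifts the switch-on drive upward.

**Detailed network.** Six variables: effector T cells $T$, regulatory T
cells $R$, macrophages $M$, and the cytokines IL-2 ($\delta$), IFN-γ
($\gamma$) and TNF-α ($\alpha$):

$$\frac{dT}{dt}=\beta_T-\varepsilon_T T-k_{1e}\alpha T+
 \frac{k_{1a}AM+k_{1b}\delta+k_{1c}\gamma}{1+k_{1d}R}\cdot\frac{T^2}{\theta_T^2+T^2}$$

$$\frac{dR}{dt}=\beta_R-\varepsilon_R R+
 \frac{k_{2a}\delta}{1+k_{2b}\alpha}\cdot\frac{R^2}{\theta_R^2+R^2},\qquad
\frac{dM}{dt}=\beta_M-\varepsilon_M M+
 \frac{k_{6}\gamma+k_{6b}\alpha}{1+k_{6c}R}\cdot\frac{M^2}{\theta_M^2+M^2}$$

$$\dot\delta=\beta_\delta+k_3T-(\varepsilon_\delta+I_\delta)\delta,\quad
\dot\gamma=\beta_\gamma+k_{4a}T+k_{4b}M-(\varepsilon_\gamma+I_\gamma)\gamma,\quad
\dot\alpha=\beta_\alpha+k_{5a}T+k_{5b}M-(\varepsilon_\alpha+I_\alpha)\alpha$$

Macrophages present antigen to Teffs (the $AM$ product), Tregs divide the
Teff proliferative drive, TNF-α kills Teffs and antagonizes Tregs, IFN-γ
and TNF-α activate macrophages, and Tregs suppress macrophages.  Therapy
pulses $I_\delta, I_\gamma, I_\alpha$ (anti-IL-2, anti-IFN-γ, anti-TNF-α)
neutralize their target cytokine by first-order mass action during a time
window.  All densities are dimensionless; the shipped defaults are the
published base parameter table.  See `docs/methods.md` for how the
equation algebra was fixed and what was calibrated.

Long-term outcomes are summarized on a coarse low/high grid per cell
population: state 1 ($000$, healthy), state 7 ($+0+$, sarcoid), states 6
and 8 ($++0$, $+++$: sarcoid with Treg expansion, the lymphopenia/anergy
paradox), with the remaining four combinations structurally unlikely.

## Worked example

Induce the disease state with the canonical protocol (settle to the
healthy state, antigen pulse of amplitude 100 from t=20 to 70, Treg IL-2
sensitivity raised to $k_{2a}=2.1$), then classify the outcome:

```
$ granulosim classify --fixture fig3_CD
state 8 (+++: sarcoid, lymphopenia)  T=12.48 R=1.799 M=2.03
```

Teffs settle ~250-fold above their healthy level (0.05): a single
transient exposure has produced permanent granulomatous inflammation with
expanded Tregs — the anergy paradox.  End the same pulse one time unit
earlier and the response is self-limited:

```
$ granulosim classify --fixture fig3_AB
state 1 (000: healthy)  T=0.05051 R=0.05003 M=0.05005
```

The antigen-duration threshold separating the two lies exactly between
those pulses:

```
$ granulosim threshold --fixture fig3_CD --knob t_off --lo 60 --hi 80 --step 1
threshold t_off = 70 (largest failing value 69)
```

The same machinery scans amplitudes — for the minimal model's antigen
threshold (pulse t=5..10 from initial $T=0.34$):

```
$ granulosim threshold --fixture fig1 --lo 1 --hi 6 --step 0.5
threshold amplitude = 3.5 (largest failing value 3)
```

i.e. a 3.0 pulse decays back while 3.5 tips the system over the unstable
middle branch to the high-activity steady state ($T_2 \approx 2.64$).
In the library API, the minimal model's bistable drive range is

```python
>>> from granulosim import MinimalParams, bistable_range
>>> bistable_range(MinimalParams(beta_T=0.05, eps_T=1.0, theta_T=1.0))
(1.8972, 5.0505)          # f_lo, f_hi
>>> bistable_range(MinimalParams(beta_T=0.05, eps_T=1.0, theta_T=0.5))
(0.8936, 1.3022)          # weaker Treg proxy: switch-on comes earlier
```

Therapy experiments work the same way: `granulosim titrate` maps
anti-IL-2 x anti-IFN-γ dose planes (at $k_{2a}=2.0$ the pair
$I_\delta=I_\gamma=20$ over t=100..120 produces full remission where
either drug alone fails), and `granulosim reproduce-paper` re-runs all 18
shipped figure-panel fixtures against their expected outcomes.

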