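# bloomdyn

Coastal monitoring programmes measure chlorophyll-a, nutrients and
physical drivers roughly once a month, on different days each year, with
frequent gaps. `bloomdyn` turns such scattered records into an
*interpretable dynamical model* of the annual phytoplankton bloom cycle:
it trains an ensemble of neural ODEs against the pooled day-of-year
observations and then distils the learned vector field into sparse
polynomial governing equations whose terms can be read as growth and
loss processes.

The package is aimed at aquatic ecologists and modellers who have
station-level monitoring data (Chl-a, DIN, DIP, totN, totP plus
temperature, salinity and Secchi/Kd) and want a data-driven differential
equation per blooming pattern rather than a purely descriptive smoother.

## Model

State x = (Chl-a, DIN, DIP, totN, totP), all log-transformed and
z-scored; external drivers Temp(t), Sal(t), Kd(t) are fitted polynomial
annual climatologies (order 5/4/4 in t/366). The dynamics are learned in
two steps:

1. **Neural ODE.** dx/dt = ANN(x, Temp(t), Sal(t), Kd(t)), an
   8-16x4-5 GELU network trained for 500 iterations by simulating the
   ODE across the year and comparing the trajectory with every
   observation at its day of year under the trajectory loss
   0.2 * (length difference)^2 + 0.8 * (1 - cosine similarity).
   Twenty networks are trained from different seeds; their pointwise
   mean trajectory is the headline fit.

2. **Sparse identification (SInDy).** The member closest to the ensemble
   mean serves as a derivative oracle. Its vector field, sampled along
   (and slightly around) its trajectory, is regressed onto a 45-function
   second-order polynomial library with an L1 penalty followed by a
   least-squares refit, giving equations of the form

       dChl-a/dt = c1 + c2*Chl-a + c3*Chl-a^2 + c4*DIN + ... + c45*Kd^2

   with most coefficients exactly zero.

Each surviving term's contribution (coefficient x basis value) is traced
through the year, classified as growth or loss by the product-sign rule,
and ranked by its integrated share during bloom growth phases (periods
with Chl-a above average and increasing). A penalised cyclic cubic
spline per variable provides the descriptive baseline, and both model
kinds are compared with data via mean squared errors.

A fully synthetic ground-truth system (the `two_bloom` preset: a
spring-and-summer double bloom driven by a Chl-a/DIN consumer-resource
oscillator under seasonal temperature and light-attenuation gating) makes
every stage testable against known equations without any data download.

## Worked example

Run the whole pipeline on synthetic monitoring data at a reduced profile
(2 hidden layers, 300 iterations, 5 members; a few minutes on one CPU):

```
bloomdyn run-all --config examples/quick.yaml --seed 1
```

with `examples/quick.yaml`:

```yaml
synthetic_preset: two_bloom
outdir: bloomdyn_out
network: {hidden_layers: 2, hidden_width: 16}
training: {iterations: 300, members: 5}
sindy: {kappa: 0.015}
```

This prints per-stage progress and ends with

```
wrote 17 artifacts to bloomdyn_out (config 7e17fc3492c5d804, seed 1)
```

`bloomdyn_out/equations.txt` then holds the compact fitted equations
(output of this exact run):

```
dChl-a/dt = -0.00373324*Chl-a + 0.0165025*DIP + 0.00293771*DIN^2 - 0.00489806*Chl-a*Kd + 0.00655673*DIP*totN - 0.00468787*DIP*totP
dDIN/dt = -0.00666015*Chl-a - 0.0127938*totN - 0.0133774*Temp - 0.00373531*Chl-a^2 - 0.00317662*Chl-a*totN
dDIP/dt = -0.0106107*Chl-a - 0.0121285*totN + 0.0066263*Kd - 0.00062145*totN^2 - 0.00246348*Chl-a*DIN + 0.00240417*Chl-a*Temp + 0.00980101*Temp*Kd
dtotN/dt = -0.0188495*Chl-a + 0.00768495*DIP - 0.00907923*Chl-a^2 - 0.00233614*Chl-a*Kd + 0.00315185*DIP*Kd
dtotP/dt = -0.0115899*Chl-a - 0.0051427*Temp - 0.00121491*totN^2 - 0.00405237*Chl-a*Kd
```

Read against the generating system, the robust structure comes through:
nutrient growth terms and a light-attenuation (Kd) loss in the Chl-a
equation, and Chl-a-proportional consumption with negative sign in every
nutrient equation. Other generating terms are blurred into correlated
surrogates (DIP standing in for DIN, for example) — the expected
behaviour at this reduced training budget, where the network's vector
field is only loosely pinned down; the full profile (4x16 network, 500
iterations, 20 members) sharpens the attribution.

`bloomdyn_out/term_rankings.csv` ranks the terms inside each bloom growth
window (Chl-a above average and rising). In this run the spring window
spans days 50-97 and the dissolved-phosphorus term carries the largest
positive share of dChl-a/dt:

```
pattern,window,window_start,window_end,sign_group,term,proportion,top
two_bloom,1,50,97,positive,DIP,0.4798699923,True
two_bloom,1,50,97,negative,DIP*totP,0.4558249876,True
```

`metrics.csv` reports the mean squared errors (z-score units): here the
Chl-a data-vs-baseline MSE is 0.115 (train) / 0.121 (validation), the
data-vs-neural-ODE-mean MSE 0.180 / 0.214, and the baseline-vs-mean
curve difference 0.119 — the descriptive spline tracks the pooled data
slightly more closely, while the dynamical model provides the
closed-form equations above.

The same stages are available individually (`bloomdyn simulate`,
`preprocess`, `fit-drivers`, `fit-baseline`, `train-ude`,
`extract-sindy`, `interpret`, `evaluate`), all reading and writing the
configured output directory, and as library functions
(`bloomdyn.train_ensemble`, `bloomdyn.fit_sparse`, ...).

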