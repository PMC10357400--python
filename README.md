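# scorrflow

Transit-time-aware single-particle colocalization for multicolor
single-vesicle flow cytometry, with the classical cross-correlation
baseline, a Monte Carlo simulator of particles in Poiseuille flow, and
the metrics needed to benchmark one against the other.

## The problem

Immunophenotyping extracellular vesicles (EVs, ~30–300 nm) in a flow
analyzer means deciding which fluorescence bursts recorded in different
color channels — each excited by a spatially offset laser — came from
the *same* vesicle. Small vesicles cannot be flow-focused, so in a
micrometer-scale channel they sample the laminar (Poiseuille) velocity
profile v(r) = v_max·(1 − (r/R)²): every particle has its own speed,
and two particles can swap their order of appearance between lasers.

The classical remedy, **Xcorr**, maximizes the discrete
cross-correlation R_xy(k) = Σ_t x(t)·y(t+k) of the two channel traces
to get one average lag k and accepts peak pairs within a window W of
the shifted times. One lag cannot serve a distribution of speeds: slow
particles fall outside W, fast ones collide, order swaps mismatch, and
the intensity-weighted sum lets bright contaminants drag k.

**Scorr** instead shifts each peak by its own predicted travel time.
A particle crossing the upstream (red) beam of width ΔX2 in transit
time PT2 moves at v2 = ΔX2/PT2, so it should reappear in the
downstream (blue) channel after PT3 = ΔX3/v2 (the *coarse shift*,
constant-speed assumption). Blue peaks within W1 of that prediction are
candidates; for each, the estimate is refined with the average of the
speeds measured at both beams, v_avg = (v1 + v2)/2 with v1 = ΔX1/PT1
(the *fine shift*), and pairs with ΔT = |t_blue − t′_blue| ≤ W2 are
accepted. Contested peaks go to the pairing with minimum ΔT (ties: the
least relative transit-time change |PT1 − PT2|/PT2); losers rematch
their next-best surviving candidate until the matching is one-to-one.

## Worked example

Simulate a 60 s acquisition at 35 particles/s (1:1 dim:bright mixture,
intensity ratio 3, 10% transit-time error, v_max = 3 μm/ms, 1 μm beams
15 μm apart), then colocalize with both methods and score against the
ground truth:

```bash
cat > demo.yaml <<EOF
arrival_rate: 35
duration: 60
bright_fraction: 0.5
seed: 42
EOF
scorrflow all --config demo.yaml --out-dir demo_out --w1 5 --w2 4
```

prints

```
scorr: true 97.76% loss 2.24%
xcorr: true 66.62% loss 33.38%
```

and `demo_out/report.json` holds the full metrics: of 2139 simulated
particles the transit-time method correctly pairs 97.8% (83.2% of its
matches land within ΔT ≤ 0.5 ms, and only 0.7% of particles are dim
peaks mis-paired with bright ones), while the global-lag baseline —
which estimated k = 5.3 ms, the travel time of the *fastest* particles —
loses 33.4% of particles and mis-pairs 4.3%. The same comparison is
available from Python:

```python
import scorrflow as sf

config = sf.SimulationConfig(arrival_rate=35, duration=60, seed=42)
gt = sf.simulate_particles(config)
red, blue = sf.peak_tables(gt)
geom = sf.LaserGeometry(dx1=1.0, dx2=1.0, dx3=15.0)
ms = sf.scorr_colocalize(red, blue, geom, sf.ScorrParams(w1=5, w2=4))
print(sf.score_matches(ms, gt).true_colocalized_pct)
```

For real acquisitions, start from raw traces instead:
`scorrflow detect` fits a single Gaussian to each above-threshold event
(the fitted FWHM is the transit time; non-Gaussian events such as
coelutions are rejected by an R² gate), and `scorrflow colocalize`
consumes the resulting peak tables. Three-channel data is handled
pairwise via `scorrflow.cli.run_pipeline` with an instrument
configuration describing the laser positions.

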