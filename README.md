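# ppmir — mutual information rate between point processes

`ppmir` estimates, in continuous time, the rate of information exchanged
between two point processes — processes fully described by their event
times, such as heartbeat (R-peak) times and the arrival times of the blood
pressure wave at the periphery. It is aimed at cardiovascular-variability
and Network Physiology analyses, where records are short (a few hundred
events) and strongly autocorrelated, and at anyone needing a non-parametric,
binning-free coupling measure for event data (spike trains, event logs).

## The measure

For stationary point processes `X = {x_i}` and `Y = {y_j}` with no
simultaneous events, the mutual information rate (MIR) decomposes exactly
into the two directed transfer entropy rates (TER):

    I(X;Y) = T(X→Y) + T(Y→X)        [nats/s]

Each TER is estimated from *history embeddings*: the past of each process,
seen either from a target event `x_i` or from a random time point `u`, is
approximated by the time elapsed since the most recent event followed by
`l−1` preceding inter-event intervals. With `λ̄_X = N_X/T` the target event
rate, the TER is a combination of four entropy terms,

    T̂(Y→X) = λ̄_X [ Ĥ_pu(X^l,Y^l) − Ĥ_px(X^l,Y^l) + Ĥ_px(X^l) − Ĥ_pu(X^l) ],

where `Ĥ_px` terms are nearest-neighbor (Kozachenko–Leonenko, maximum norm)
estimates over embeddings sampled at target events and `Ĥ_pu` terms score
the same points against embeddings sampled at `N_U = N_X` random times. The
default estimator evaluates the two log-density ratios with shared per-point
radii so that volume and digamma constants cancel exactly (see
`docs/methods.md`); `k = 30` neighbors throughout.

On short records the MIR estimate has a strong negative bias. The corrected
measure

    cMIR = MIR − median(MIR over M surrogate pairs)

subtracts the median MIR over surrogates consistent with the uncoupled null
hypothesis, and the surrogate distribution's 95th percentile provides a
significance test. Four surrogate engines are available: local permutation
of history embeddings (conditional-independence null, the default), random
shuffling of inter-event intervals, IAAFT (distribution + spectrum
preserving), and an autocorrelation-preserving interval permutation.

Built-in simulators generate the test systems: uncoupled renewal processes
(exponential / Gaussian / inverse-Gaussian intervals), a history-dependent
inverse-Gaussian (HDIG) heartbeat model with VLF/LF/HF spectral structure
coupled to AR(2) pulse-arrival delays (delay SD `σ_PAT` tunes the coupling
down), and a common-LF-driver variant (`σ_PAT` tunes the coupling up).

## Worked example

Simulate a coupled heartbeat / pulse-arrival pair (300 events,
`σ_PAT = 85 ms`) and estimate its coupling:

```bash
ppmir simulate --scenario sim2 --sigma-pat 0.085 --n-events 300 --seed 7 \
      --out x.txt --out y.txt
ppmir estimate --x x.txt --y y.txt --l 1 --k 30 \
      --surrogates local_permutation --n-surrogates 100 --seed 9 --json est.json
```

prints

```
MIR  = +0.2798 nats/s
cMIR = +0.5741 nats/s (surrogate median -0.2942)
significant at 95th surrogate percentile: yes
```

The raw MIR (+0.28 nats/s) is biased downward at N = 300; the surrogate
median (−0.29 nats/s) measures that bias under the uncoupled null, and the
corrected cMIR (+0.57 nats/s) is the bias-compensated information rate. The
pair is detected as significantly coupled.

The same pair through the per-subject workflow (descriptive statistics plus
cMIR across embedding lengths, as used on R-time / systolic-time records):

```python
import ppmir
report = ppmir.analyze_pair("x.txt", "y.txt",
    ppmir.ExperimentConfig(scenario="real_pair", l_grid=(1, 2), seed=3))
```

```
RR  mean 1.003 s, SD 0.111 s
PAT mean 0.291 s, SD 0.075 s
l=1: cMIR 0.495 nats/s, significant True
l=2: cMIR 0.549 nats/s, significant True
```

The recovered RR mean (≈1 s), PAT mean (≈0.3 s) and PAT SD (≈0.085 s) match
the generative parameters. Larger experiments (bias assessment over
distribution grids, coupling curves over the `σ_PAT` grid, sample-size
sweeps) run through `ppmir experiment --config cfg.yaml --out dir/` with a
YAML config; tables are written as CSV and are a pure function of the master
seed.

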