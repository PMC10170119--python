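# chaosmorph

Simulation toolkit for robust pattern generation by complex dynamics:

- **`rd_core`** — finite-difference integration of gradient-forced
  reaction–diffusion systems on a periodic strip (second-order central
  differences, RK4, additive Euler–Maruyama noise), plus a dispersion-relation
  oracle (Turing instability) and a sparse screened-Poisson solver.
- **`segment_dynamics`** — localized segment bases (periodized Gaussians),
  Galerkin projection of fields onto segment amplitudes, a constructive
  embedding of prescribed amplitude vector fields (e.g. the Rössler system)
  into a two-component RD realization with a measured projection defect,
  Benettin Lyapunov estimators (variational and two-orbit), and enumeration of
  coexisting local attractors of weakly coupled group systems (2^M
  attractors for M weakly coupled bistable groups).
- **`stochastic_tm`** — absorbing Markov chains as stochastic Turing machines:
  Monte-Carlo absorption, exact fundamental-matrix moments, hitting-time
  dispersion statistics, random-chain ensembles, staged Boolean-hypercube
  target search, and the linear fit of mean absorption time against state
  count.
- **`cdp`** — cellular developmental programs: binary cell-type encoding,
  morphogen-space partitions, the morphogenetic operator mapping concentration
  histories to positions × times symbol matrices, the u → w morphogen field,
  and emission of prescribed strings from ergodic dynamics (exact-bitstream
  tent map, thresholded Rössler coordinate) with a stop signal.
- **`cli_io`** — JSON configs with full-violation reporting, deterministic
  seed splitting, regenerable synthetic fixtures, and lossless readers/writers
  (float64 field dumps with JSON sidecars, CSV series, CDP matrices).

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the headline end-to-end checks (hitting-time
dispersion ≈ 1, cv ∝ 1/√k staging, Eτ ∝ n, staged hypercube acceleration,
2^M attractor multiplicity, positive Lyapunov exponent of the embedded
Rössler RD system, oracle equivalences, worked encoding, tent-map string
emission).

## CLI

```sh
chaosmorph simulate-rd --config cfg.json --out out/
chaosmorph embed --target rossler --seed 1
chaosmorph lyapunov --system rossler --horizon 300
chaosmorph attractors --inits corners
chaosmorph stm --n 64 --replicates 2000 --seed 7
chaosmorph hypercube --m 12 --stages 4 --replicates 2000
chaosmorph cdp emit --map tent --target rbrbbr --seed 3
chaosmorph cdp extract --trajectory out/ --operator op.json
chaosmorph fixtures --kind random-chain --param n=16 --seed 1
```

Every command derives sub-seeds deterministically from `--seed` and writes a
manifest sufficient to reproduce the run.

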