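# nanorheo

Nanorheology of living cells from AFM force–distance curves.

`nanorheo` simulates force–distance curves (FDCs) on soft, finite-thickness
samples under **power-law rheology** (PLR) and inverts measured curves into
the two PLR parameters — the scaling modulus `E0` and the fluidity exponent
`gamma` — using a supervised machine-learning regressor trained entirely on
synthetic data, with a classical least-squares fit as an exact but slower
baseline. A force-volume pipeline turns grids of curves into nanomechanical
maps and compositional (height + stiffness) images.

## The science in one paragraph

Living cells are not springs: their mechanical response follows a power law
in time, `psi(t) = E0/Gamma(1-gamma) * (t/t0)^(-gamma)`, where `gamma = 0`
is an elastic solid and `gamma -> 1` a Newtonian fluid. When an AFM tip
indents and retracts, the force is a weakly singular hereditary integral
over the indentation history (Ting's model), truncated during retraction at
a contact time `t1(t)` that must itself be solved for — and on thin samples
the substrate stiffens the response (bottom-effect correction). Fitting this
model per curve is accurate but slow. The inversion is therefore learned: a
**nested functional-basis regressor** — an outer network predicting `gamma`
from the normalized force shape plus functional (B-spline) expansions of the
indentation history, and an inner network predicting the mean dimensionless
force `f_bar`, from which `E0` follows in closed form — is trained on tens
of thousands of simulated curves and then evaluates thousands of pixels per
second. See `docs/methods.md` for the full model and numerics.

## Worked example

Simulate one curve on a 7 µm-thick sample, fit it classically, and check
the round trip:

```python
import math
import nanorheo as nr

geom = nr.ProbeCellGeometry(theta=math.radians(25.0), h=7e-6)
profile = nr.make_triangular(1e-6, 10e-6, 10e-6)   # 1 um at 10 um/s
material = nr.PLRMaterial(E0=5000.0, gamma=0.30)    # 5 kPa, gamma 0.3
curve = nr.simulate_force_curve(profile, material, geom)
print(f"peak force {curve.F.max()*1e9:.2f} nN at t = {curve.t_max*1e3:.0f} ms")

res = nr.fit_curve(curve, profile, geom)
print(f"fit: E0 = {res.E0_hat:.1f} Pa, gamma = {res.gamma_hat:.4f}")
```

```
peak force 3.95 nN at t = 100 ms
fit: E0 = 5000.0 Pa, gamma = 0.3000
```

Train a small regressor (a few thousand curves — accurate training uses
40,000, see below) and predict:

```python
ds = nr.build_dataset(4000, seed=7)
model = nr.train(ds, nr.TrainConfig(seed=0))
tr, val = ds.split_indices()
metrics = nr.evaluate(model, ds, val)
print(f"MAPE(E0) = {metrics['MAPE_E0']:.2f} %, "
      f"NRMSE(gamma) = {metrics['NRMSE_gamma']:.2f} %")
```

```
MAPE(E0) = 2.43 %, NRMSE(gamma) = 2.52 %
```

The same pipeline is scriptable from the command line:

```
nanorheo simulate --e0 5000 --gamma 0.3 --out curve.txt
nanorheo fit --curve curve.txt
nanorheo make-dataset --n 42000 --seed 1 --out ds.h5
nanorheo train --dataset ds.h5 --seed 1 --out model.h5
nanorheo evaluate --dataset ds.h5 --model model.h5
nanorheo make-phantom --kind two-region --seed 1 --out cell.h5
nanorheo map --volume cell.h5 --engine sml --model model.h5 --out cellmap
nanorheo render --map cellmap --out cell.png
```

Every subcommand takes `--config file.ini` (one section per subcommand,
flags override) and writes a `*.manifest.json` with the resolved settings
hash, library versions and per-stage timings.

## Accuracy

Trained on 40,000 synthetic curves (`gamma ~ U(0, 0.99)`, `r_max/h ~
U(0.001, 1)`, `E0` log-uniform 0.1–100 kPa, mixed triangular / sinusoidal /
random-spline indentation profiles) and evaluated on 2,000 held-out curves,
single CPU:

| metric | value | target |
| --- | --- | --- |
| MAPE(E0) | 0.47 % | ≤ 2 % |
| NRMSE(gamma) | 0.40 % | ≤ 0.5 % |

Generation takes about 8 min and training + evaluation about 8.5
min on one CPU.

## Layout

- `src/nanorheo/contact.py` — PLR material, bottom-effect geometry, fast
  Ting-model solver, dimensionless reduction, closed-form modulus recovery
- `src/nanorheo/profiles.py`, `basis.py` — indentation histories on a
  clamped cubic B-spline basis; admissibility validation; Gram matrices
- `src/nanorheo/dataset.py` — synthetic corpus generation and features
- `src/nanorheo/fbnn.py` — nested functional-basis regressor (training,
  pure-NumPy inference, HDF5 model files)
- `src/nanorheo/fit.py` — classical profile-likelihood least squares
- `src/nanorheo/fvmap.py` — phantoms, force-volume processing,
  nanomechanical and compositional maps
- `src/nanorheo/io.py`, `cli.py` — curve/volume/map file formats and the
  `nanorheo` command
- `docs/methods.md` — model, assumptions, numerical choices, limitations
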