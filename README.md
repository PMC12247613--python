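# nexikit

Neurite EXchange Imaging (NEXI) for gray-matter diffusion MRI: forward
models, simulation study, voxelwise fitting, and model comparison.

## The problem

Diffusion MRI models of cortical gray matter must account for water
exchange across the (mostly unmyelinated) neurite membrane. NEXI describes
the tissue as two exchanging pools in the barrier-limited Kärger regime:
intra-neurite water in randomly oriented sticks with parallel diffusivity
*D*<sub>i</sub>, and isotropic extra-neurite water with diffusivity
*D*<sub>e</sub>, occupying signal fractions *f* and 1 − *f* and exchanging
with characteristic time *t*<sub>ex</sub>. The directional signal is the
solution of the 2×2 linear system **S**′ = −**M S** with

```
M = [ q²·D_i·(g·n)² + k_ie      −k_ei          ]      k_ie = (1−f)/t_ex
    [ −k_ie                     q²·D_e + k_ei  ]      k_ei = f/t_ex
```

under the narrow-pulse convention q² = b/t<sub>d</sub>; the measured
powder-average (spherical-mean) signal is S̄(b, t<sub>d</sub>) =
∫₀¹ 𝒦(u) du over the cosine u = g·n. Two extensions matter in practice:

* **dot compartment** — a stationary water fraction *f*<sub>dot</sub> whose
  signal does not decay: S̄<sub>dot</sub> = (1 − f_dot)·S̄ + f_dot;
* **Rician-mean (RM) correction** — at high b and moderate SNR the
  magnitude signal is dominated by the Rician noise floor; the expected
  magnitude is √(π/2)·σ·L<sub>1/2</sub>(−S̄²/(2σ²)), which this package
  evaluates in a numerically stable Bessel form and uses as the forward
  model when σ is known.

The package implements the four resulting model variants (NEXI, NEXI_dot,
NEXI_RM, NEXI_dot_RM), the synthetic study that quantifies their estimation
errors on a Connectom-style protocol (b = 1–7.5 ms/µm² at Δ = 20–49 ms),
grid-search-initialized bounded least-squares fitting, the Kärger
time-dependent-kurtosis route to *t*<sub>ex</sub>
(K<sub>KM</sub>(t) = 2(t_ex/t)[1 − (t_ex/t)(1 − e^{−t/t_ex})]), and the
comparison statistics (median absolute error, AICc, Bland–Altman,
dot-fraction-vs-noise-floor diagnostics). It is aimed at microstructure
researchers running simulation studies or fitting powder-averaged
multi-shell multi-diffusion-time data (NIfTI + FSL-style sidecars).

## Worked example

```python
import numpy as np
from nexikit import (NoiseModel, TissueParameters, connectom_protocol,
                     generate_dataset, fit_many, model_predict)
from nexikit.evaluation import median_absolute_error

protocol = connectom_protocol()
print(protocol.n_volumes)                 # 700

p = TissueParameters(t_ex=40, D_i=3.0, D_e=1.0, f=0.4)
s = model_predict("nexi_rm", p, protocol, NoiseModel(0.03))
print(np.round(s[:5], 4))                 # Δ = 20 ms shells, b = 1..7.5
# [0.4187 0.1709 0.1049 0.0777 0.0691]

ds = generate_dataset(1, 200, seed=1)     # sigma = 0.03, 20-realization avg
fits = fit_many(ds, "nexi_rm")
print({k: round(v, 3) for k, v in
       median_absolute_error(fits, ds.truths).items()})
# {'t_ex': 20.33, 'D_i': 0.439, 'D_e': 0.058, 'f': 0.056, 'f_dot': 0.0}
```

The last line is the median absolute error of each recovered parameter over
200 random ground truths at SNR ≈ 34 — e.g. exchange-time estimates are
typically within ~20 ms of truth over the broad [1, 150] ms prior, and the
neurite fraction within ~0.06.

A command-line surface wraps the same pipeline:

```bash
nexikit simulate --dataset 2 --n 100 --seed 1 --out ds/
nexikit fit --input ds/ --variant nexi_rm --out fits.csv
nexikit evaluate --fits fits.csv --truths ds/truths.csv --out report.json
nexikit kurtosis --input ds/ --out kurt.csv
nexikit fixtures --out fx/ --seed 1        # small synthetic NIfTI dataset
```

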