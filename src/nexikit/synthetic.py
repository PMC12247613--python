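"""Synthetic powder-averaged signal generation for the simulation study.

Three dataset families are provided, differing in their ground-truth
sampling ranges:

* **Dataset 1** — broad uniform priors: t_ex ∈ [1, 150] ms, both
  diffusivities ∈ [0.1, 3.5] µm²/ms with the constraint D_i > D_e
  (enforced by rejection), f ∈ [0.1, 0.9].
* **Dataset 2** — in-vivo-like cortical ranges: t_ex ∈ [1, 110] ms,
  D_i ∈ [2.5, 3.5], D_e ∈ [0.5, 1.5], f ∈ [0.3, 0.5].
* **Dataset 3** — Dataset-2 ranges plus a stationary dot fraction
  f_dot ∈ [0, 0.1]; signals are generated with the dot forward model.

The noise model mimics powder averaging of magnitude images: for each
shell, ``n_noise_avg`` independent Rician realizations
√((S̄+n₁)² + n₂²), n₁,n₂ ~ N(0, σ²) are drawn and averaged.  Averaging
raises the SNR but does not remove the Rician floor — the expectation
stays at the Rician mean of S̄ regardless of ``n_noise_avg``, which is the
premise of the RM-corrected model variants.

Default noise level is σ = 0.03 (SNR ≈ 34 at b = 0).  Reproducibility is
per-truth: a master seed spawns one independent stream per ground truth,
so truth *i* is identical no matter how many truths are generated.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import NoiseModel, TissueParameters, predict_batch
from .protocol import AcquisitionProtocol, connectom_protocol

__all__ = [
    "DATASET_BOUNDS",
    "DEFAULT_SIGMA",
    "DEFAULT_N_NOISE_AVG",
    "SimulatedDataset",
    "sample_ground_truths",
    "simulate_measurement",
    "generate_dataset",
]

DEFAULT_SIGMA = 0.03
DEFAULT_N_NOISE_AVG = 20

#: Uniform sampling bounds per dataset; Dataset 1 additionally enforces
#: D_i > D_e by rejection.
DATASET_BOUNDS = {
    1: {"t_ex": (1.0, 150.0), "D_i": (0.1, 3.5), "D_e": (0.1, 3.5),
        "f": (0.1, 0.9)},
    2: {"t_ex": (1.0, 110.0), "D_i": (2.5, 3.5), "D_e": (0.5, 1.5),
        "f": (0.3, 0.5)},
    3: {"t_ex": (1.0, 110.0), "D_i": (2.5, 3.5), "D_e": (0.5, 1.5),
        "f": (0.3, 0.5), "f_dot": (0.0, 0.1)},
}


def _uniform(rng, lo, hi):
    return lo + (hi - lo) * rng.random()


def _draw_one(rng, bounds, reject_di_le_de):
    t_ex = _uniform(rng, *bounds["t_ex"])
    while True:
        D_i = _uniform(rng, *bounds["D_i"])
        D_e = _uniform(rng, *bounds["D_e"])
        if not reject_di_le_de or D_i > D_e:
            break
    f = _uniform(rng, *bounds["f"])
    f_dot = _uniform(rng, *bounds["f_dot"]) if "f_dot" in bounds else 0.0
    return TissueParameters(t_ex, D_i, D_e, f, f_dot)


def sample_ground_truths(dataset_id: int, n: int, seed: int):
    """Draw ``n`` ground-truth parameter sets for the given dataset.

    Each truth has its own spawned random stream, so the first ``m`` truths
    are identical for any ``n >= m`` under the same seed.
    """
    if dataset_id not in DATASET_BOUNDS:
        raise ValueError(f"unknown dataset_id {dataset_id!r}; expected 1, 2 or 3")
    if n < 0:
        raise ValueError("n must be >= 0")
    bounds = DATASET_BOUNDS[dataset_id]
    reject = dataset_id == 1
    children = np.random.SeedSequence(seed).spawn(n)
    return [_draw_one(np.random.default_rng(c), bounds, reject)
            for c in children]


def _rician_average(clean, sigma, n_noise_avg, rng):
    """Average of ``n_noise_avg`` Rician magnitude realizations of the
    noise-free vector ``clean``."""
    shape = (n_noise_avg,) + clean.shape
    n1 = rng.normal(0.0, sigma, size=shape)
    n2 = rng.normal(0.0, sigma, size=shape)
    return np.sqrt((clean + n1) ** 2 + n2 ** 2).mean(axis=0)


def simulate_measurement(p: TissueParameters, protocol: AcquisitionProtocol,
                         noise, n_noise_avg: int = DEFAULT_N_NOISE_AVG,
                         seed=None, rng=None):
    """Noisy powder-averaged signal vector for one ground truth.

    Rician magnitude noise at normalized level σ is applied to the
    noise-free spherical-mean signal of every nonzero shell (canonical
    Δ-ascending, b-ascending order) and averaged over ``n_noise_avg``
    realizations.
    """
    sigma = noise.sigma if isinstance(noise, NoiseModel) else float(noise)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if n_noise_avg < 1:
        raise ValueError("n_noise_avg must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    b, t_d = protocol.shell_table()
    clean = predict_batch(p.to_array()[None, :], b, t_d)[0]
    return _rician_average(clean, sigma, n_noise_avg, rng)


@dataclass
class SimulatedDataset:
    """Ground truths, noisy signals, and everything needed to re-fit them."""

    dataset_id: int
    truths: list
    signals: np.ndarray          # (n, n_shells) noisy powder averages
    sigmas: np.ndarray           # (n,) per-truth normalized noise level
    protocol: AcquisitionProtocol
    seed: int
    n_noise_avg: int

    def __len__(self):
        return len(self.truths)

    def truths_frame(self) -> pd.DataFrame:
        rows = [t.to_array() for t in self.truths]
        df = pd.DataFrame(rows, columns=["t_ex", "D_i", "D_e", "f", "f_dot"])
        df["sigma"] = self.sigmas
        return df

    def save(self, outdir: str):
        """Write truths + σ (CSV), signals (CSV), protocol and metadata
        (JSON) as plain text."""
        os.makedirs(outdir, exist_ok=True)
        self.truths_frame().to_csv(os.path.join(outdir, "truths.csv"),
                                   index=False)
        b, t_d = self.protocol.shell_table()
        cols = [f"b{bb:g}_d{dd:g}" for bb, dd in zip(b, t_d)]
        pd.DataFrame(self.signals, columns=cols).to_csv(
            os.path.join(outdir, "signals.csv"), index=False)
        self.protocol.to_json(os.path.join(outdir, "protocol.json"))
        meta = {"dataset_id": self.dataset_id, "seed": self.seed,
                "n_noise_avg": self.n_noise_avg}
        with open(os.path.join(outdir, "meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, outdir: str) -> "SimulatedDataset":
        truths_df = pd.read_csv(os.path.join(outdir, "truths.csv"))
        signals = pd.read_csv(os.path.join(outdir, "signals.csv")).to_numpy()
        protocol = AcquisitionProtocol.from_json(
            os.path.join(outdir, "protocol.json"))
        with open(os.path.join(outdir, "meta.json")) as fh:
            meta = json.load(fh)
        truths = [TissueParameters(r.t_ex, r.D_i, r.D_e, r.f, r.f_dot)
                  for r in truths_df.itertuples()]
        return cls(meta["dataset_id"], truths, signals,
                   truths_df["sigma"].to_numpy(), protocol,
                   meta["seed"], meta["n_noise_avg"])


def generate_dataset(dataset_id: int, n: int, seed: int,
                     sigma: float = DEFAULT_SIGMA,
                     n_noise_avg: int = DEFAULT_N_NOISE_AVG,
                     snr_sampler=None,
                     protocol: AcquisitionProtocol | None = None
                     ) -> SimulatedDataset:
    """Generate a complete simulated dataset on the Connectom protocol.

    Parameters
    ----------
    sigma : float
        Fixed normalized noise level (default 0.03, i.e. SNR ≈ 34).
    snr_sampler : callable(rng) -> float, optional
        If given, a per-truth SNR is drawn from it (σ = 1/SNR), emulating
        an experimental SNR distribution; the default keeps σ fixed.
    """
    if protocol is None:
        protocol = connectom_protocol()
    truths = sample_ground_truths(dataset_id, n, seed)
    b, t_d = protocol.shell_table()
    m = b.size
    signals = np.empty((n, m))
    sigmas = np.empty(n)
    noise_children = np.random.SeedSequence((seed, 1)).spawn(n)
    if n:
        params = np.stack([t.to_array() for t in truths])
        clean = predict_batch(params, b, t_d)
    for i, child in enumerate(noise_children):
        rng = np.random.default_rng(child)
        sigmas[i] = 1.0 / snr_sampler(rng) if snr_sampler else sigma
        signals[i] = _rician_average(clean[i], sigmas[i], n_noise_avg, rng)
    return SimulatedDataset(dataset_id, truths, signals, sigmas, protocol,
                            seed, n_noise_avg)
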