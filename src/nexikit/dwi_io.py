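"""NIfTI-based I/O: loading multi-diffusion-time DWI series, powder
averaging with b0 normalization, and a synthetic in-vivo fixture writer.

Conventions: FSL-style whitespace-delimited bval/bvec files; b-values are
auto-detected as s/mm² (converted by 1/1000) or ms/µm²; the per-volume
diffusion-time table is a plain-text file with one Δ (ms) per volume.
Powder averaging is the arithmetic mean over directions within each
(b, Δ) shell, normalized by the mean b = 0 signal of the *same* Δ.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .models import NoiseModel, predict_batch
from .protocol import AcquisitionProtocol

__all__ = ["DwiSeries", "PowderSignalMap", "load_dwi_series",
           "powder_average", "fixture_generator"]

_B_UNIT_THRESHOLD = 100.0  # any b above this is taken to be in s/mm²
_SHELL_DECIMALS = 6


@dataclass
class DwiSeries:
    """A loaded 4D diffusion series with per-volume metadata."""

    data: np.ndarray          # (x, y, z, n_volumes)
    bvals: np.ndarray         # (n,) ms/µm²
    bvecs: np.ndarray         # (n, 3) unit vectors (zero rows for b = 0)
    deltas: np.ndarray        # (n,) diffusion time per volume (ms)
    mask: np.ndarray          # (x, y, z) bool
    sigma: object = None      # scalar or (x, y, z) normalized σ map
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


def _read_table(path, name):
    try:
        arr = np.loadtxt(path, ndmin=2)
    except OSError as exc:
        raise ValueError(f"cannot read {name} file {path!r}: {exc}") from exc
    return arr


def load_dwi_series(image_path, bval_path, bvec_path, delta_path,
                    mask_path=None, sigma=None) -> DwiSeries:
    """Load and validate a 4D DWI series with FSL-style sidecars.

    ``sigma`` may be a scalar, an array, or a path to a NIfTI σ map
    (already normalized to the b = 0 signal).
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{image_path!r} is not a 4D image")
    n = data.shape[-1]

    bvals = _read_table(bval_path, "bval").ravel()
    if bvals.size != n:
        raise ValueError(f"bval file {bval_path!r} has {bvals.size} entries, "
                         f"image has {n} volumes")
    if bvals.max() > _B_UNIT_THRESHOLD:  # s/mm² → ms/µm²
        bvals = bvals / 1000.0

    bvecs = _read_table(bvec_path, "bvec")
    if bvecs.shape == (3, n):
        bvecs = bvecs.T
    if bvecs.shape != (n, 3):
        raise ValueError(f"bvec file {bvec_path!r} has shape {bvecs.shape}, "
                         f"expected 3x{n} or {n}x3")
    norms = np.linalg.norm(bvecs, axis=1)
    bad = (bvals > 0) & (np.abs(norms - 1.0) > 1e-3)
    if np.any(bad):
        raise ValueError(f"bvec file {bvec_path!r}: non-unit vectors for "
                         f"{int(bad.sum())} diffusion-weighted volumes")

    deltas = _read_table(delta_path, "diffusion-time").ravel()
    if deltas.size != n:
        raise ValueError(f"diffusion-time table {delta_path!r} has "
                         f"{deltas.size} entries, image has {n} volumes")

    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape does not match image")
    else:
        mask = np.ones(data.shape[:3], dtype=bool)

    if isinstance(sigma, (str, os.PathLike)):
        sigma = np.asarray(nib.load(str(sigma)).get_fdata(), dtype=float)
    return DwiSeries(data, bvals, bvecs, deltas, mask, sigma,
                     np.asarray(img.affine))


@dataclass
class PowderSignalMap:
    """Per-voxel normalized spherical-mean signals over nonzero shells."""

    signals: np.ndarray        # (n_voxels, n_shells)
    shells: list               # [(b, delta)] canonical (Δ asc, b asc) order
    b0_reference: np.ndarray   # (n_voxels, n_deltas) mean b0 per Δ
    voxel_index: np.ndarray    # (n_voxels, 3) coordinates inside the mask
    shape: tuple               # spatial shape of the source image
    n_clipped: int = 0         # negative voxel values clipped to zero

    def to_volume(self, values) -> np.ndarray:
        """Scatter per-voxel values back into a (masked) 3D/4D volume."""
        values = np.asarray(values)
        out = np.full(self.shape + values.shape[1:], np.nan)
        out[tuple(self.voxel_index.T)] = values
        return out


def powder_average(series: DwiSeries) -> PowderSignalMap:
    """Arithmetic-mean powder average per (b, Δ) shell, normalized by the
    mean b = 0 signal of the same Δ, for every voxel in the mask."""
    data = series.data[series.mask]        # (n_voxels, n_volumes)
    n_clipped = int(np.count_nonzero(data < 0))
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} negative voxel values to 0")
        data = np.clip(data, 0.0, None)

    b = np.round(series.bvals, _SHELL_DECIMALS)
    d = np.round(series.deltas, _SHELL_DECIMALS)
    deltas = np.unique(d)
    b0_ref = np.empty((data.shape[0], deltas.size))
    for i, dd in enumerate(deltas):
        sel = (d == dd) & (b == 0)
        if not np.any(sel):
            raise ValueError(f"no b = 0 volumes for diffusion time {dd} ms")
        b0_ref[:, i] = data[:, sel].mean(axis=1)

    shells = sorted({(bb, dd) for bb, dd in zip(b, d) if bb > 0})
    shells = sorted(shells, key=lambda s: (s[1], s[0]))
    signals = np.empty((data.shape[0], len(shells)))
    for j, (bb, dd) in enumerate(shells):
        sel = (b == bb) & (d == dd)
        if not np.any(sel):
            raise ValueError(f"empty shell (b={bb}, delta={dd})")
        ref = b0_ref[:, np.searchsorted(deltas, dd)]
        with np.errstate(divide="ignore", invalid="ignore"):
            signals[:, j] = data[:, sel].mean(axis=1) / ref
    vox = np.argwhere(series.mask)
    return PowderSignalMap(signals, [(float(bb), float(dd))
                                     for bb, dd in shells],
                           b0_ref, vox, series.mask.shape, n_clipped)


def _fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on the sphere."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1.0 + 5.0 ** 0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def fixture_generator(params_map: dict, protocol: AcquisitionProtocol,
                      noise, seed: int, outdir: str,
                      quad_order: int = 64) -> dict:
    """Write a small synthetic on-disk DWI dataset with known ground truth.

    ``params_map`` maps parameter names (t_ex, D_i, D_e, f, optionally
    f_dot) to 3D arrays; voxels where any parameter is NaN fall outside the
    mask.  Every direction of a shell carries the voxel's spherical-mean
    value (orientation dispersion is fully averaged), plus per-volume
    Rician noise at level σ when σ > 0.  Volumes are ordered by Δ, with the
    b = 0 references first within each Δ block.

    Returns a dict of written file paths (image, bval, bvec, delta, mask,
    sigma, truth).
    """
    os.makedirs(outdir, exist_ok=True)
    sigma = noise.sigma if isinstance(noise, NoiseModel) else float(noise or 0)
    names = ["t_ex", "D_i", "D_e", "f"]
    shape = np.asarray(params_map["t_ex"]).shape
    maps = [np.asarray(params_map[n], dtype=float) for n in names]
    fdot = np.asarray(params_map.get("f_dot", np.zeros(shape)), dtype=float)
    maps.append(fdot)
    stack = np.stack([m.ravel() for m in maps], axis=1)   # (n_vox, 5)
    mask = np.all(np.isfinite(stack), axis=1)
    params = np.where(mask[:, None], stack, 1.0)

    b, t_d = protocol.shell_table()
    sbar = predict_batch(params, b, t_d, quad_order=quad_order)

    vols, bvals, bvecs, deltas = [], [], [], []
    shell_lookup = {(bb, dd): j for j, (bb, dd) in enumerate(zip(b, t_d))}
    for dd in protocol.deltas:
        for _ in range(protocol.b0_per_delta):
            vols.append(np.ones(params.shape[0]))
            bvals.append(0.0)
            bvecs.append(np.zeros(3))
            deltas.append(dd)
        for sh in protocol.nonzero_shells():
            if sh.delta != dd:
                continue
            dirs = _fibonacci_directions(sh.n_directions)
            col = sbar[:, shell_lookup[(sh.b, sh.delta)]]
            for v in dirs:
                vols.append(col.copy())
                bvals.append(sh.b)
                bvecs.append(v)
                deltas.append(sh.delta)
    image = np.stack(vols, axis=1)                         # (n_vox, n_volumes)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, sigma, image.shape)
        n2 = rng.normal(0.0, sigma, image.shape)
        image = np.sqrt((image + n1) ** 2 + n2 ** 2)
    image[~mask] = 0.0
    image4d = image.reshape(shape + (image.shape[1],))

    paths = {k: os.path.join(outdir, v) for k, v in {
        "image": "dwi.nii", "bval": "dwi.bval", "bvec": "dwi.bvec",
        "delta": "dwi.delta", "mask": "mask.nii", "sigma": "sigma.nii",
        "truth": "truth.json"}.items()}
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(image4d.astype(np.float32), affine),
             paths["image"])
    np.savetxt(paths["bval"], np.asarray(bvals)[None, :], fmt="%.6g")
    np.savetxt(paths["bvec"], np.stack(bvecs, axis=1), fmt="%.8f")
    np.savetxt(paths["delta"], np.asarray(deltas), fmt="%.6g")
    nib.save(nib.Nifti1Image(mask.reshape(shape).astype(np.uint8), affine),
             paths["mask"])
    nib.save(nib.Nifti1Image(np.full(shape, sigma, dtype=np.float32),
                             affine), paths["sigma"])
    truth = {n: np.where(mask.reshape(shape), m, np.nan).tolist()
             for n, m in zip(names + ["f_dot"], maps)}
    truth["seed"] = seed
    truth["sigma"] = sigma
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh)
    return paths
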