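"""Multi-shell, multi-diffusion-time acquisition protocols.

A protocol is a set of (b, Δ) shells with direction counts plus b = 0
reference volumes per diffusion time.  The narrow-pulse convention is used
throughout: the diffusion time t_d is identified with the gradient
separation Δ and q² = b / Δ; the gradient duration δ is carried as
metadata only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Shell", "AcquisitionProtocol", "connectom_protocol"]


@dataclass(frozen=True)
class Shell:
    """One diffusion-weighting shell: b-value (ms/µm²), diffusion time Δ (ms),
    number of gradient directions."""

    b: float
    delta: float
    n_directions: int

    def __post_init__(self):
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")

    @property
    def q2(self) -> float:
        """Squared wave vector q² = b/Δ (1/ms · 1/µm²)."""
        return self.b / self.delta


@dataclass(frozen=True)
class AcquisitionProtocol:
    shells: tuple
    b0_per_delta: int = 0
    delta_small: float | None = None  # gradient duration δ (ms), metadata

    def __post_init__(self):
        object.__setattr__(self, "shells", tuple(self.shells))
        if self.b0_per_delta < 0:
            raise ValueError("b0_per_delta must be >= 0")

    # -- shell bookkeeping ---------------------------------------------------

    @property
    def deltas(self) -> np.ndarray:
        """Distinct diffusion times, ascending."""
        return np.unique([s.delta for s in self.shells])

    def nonzero_shells(self):
        """Nonzero-b shells ordered by (Δ ascending, b ascending) — the
        canonical ordering of every signal vector in this package."""
        return sorted((s for s in self.shells if s.b > 0),
                      key=lambda s: (s.delta, s.b))

    def shell_table(self):
        """(b, t_d) arrays over nonzero shells in canonical order."""
        sh = self.nonzero_shells()
        return (np.array([s.b for s in sh], dtype=float),
                np.array([s.delta for s in sh], dtype=float))

    @property
    def n_measurements(self) -> int:
        """Number of nonzero powder-averaged data points."""
        return sum(1 for s in self.shells if s.b > 0)

    @property
    def n_volumes(self) -> int:
        """Total acquired volumes, including b = 0 references."""
        return (sum(s.n_directions for s in self.shells)
                + self.b0_per_delta * len(self.deltas))

    def n_volumes_at_or_below(self, b_max: float) -> int:
        """Volume count with b ≤ b_max, including b = 0 references."""
        n = sum(s.n_directions for s in self.shells if s.b <= b_max)
        return n + self.b0_per_delta * len(self.deltas)

    # -- serialization --------------------------------------------------------

    def to_json(self, path=None) -> str:
        obj = {
            "shells": [[s.b, s.delta, s.n_directions] for s in self.shells],
            "b0_per_delta": self.b0_per_delta,
            "delta_small": self.delta_small,
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "AcquisitionProtocol":
        if hasattr(source, "read"):
            obj = json.load(source)
        else:
            try:
                obj = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    obj = json.load(fh)
        shells = tuple(Shell(b, d, int(n)) for b, d, n in obj["shells"])
        return cls(shells, int(obj.get("b0_per_delta", 0)),
                   obj.get("delta_small"))


_CONNECTOM_B = (1.0, 2.5, 4.0, 6.0, 7.5)
_CONNECTOM_NDIR = (13, 25, 25, 32, 65)
_CONNECTOM_DELTAS = (20.0, 29.0, 39.0, 49.0)


def connectom_protocol() -> AcquisitionProtocol:
    """The 300 mT/m Connectom gray-matter protocol used throughout:

    b = 1, 2.5, 4, 6, 7.5 ms/µm² with 13/25/25/32/65 directions, at each of
    Δ = 20, 29, 39, 49 ms, plus 15 b = 0 volumes per Δ (700 volumes total);
    δ = 9 ms is retained as metadata only.
    """
    shells = tuple(
        Shell(b, delta, n)
        for delta in _CONNECTOM_DELTAS
        for b, n in zip(_CONNECTOM_B, _CONNECTOM_NDIR)
    )
    return AcquisitionProtocol(shells, b0_per_delta=15, delta_small=9.0)
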