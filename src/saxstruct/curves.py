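"""One-dimensional scattering data containers.

:class:`ScatteringCurve` is the pipeline's universal currency: a momentum
transfer grid ``q`` (A^-1, strictly increasing) with intensities ``I`` and
optional 1-sigma uncertainties. :class:`FrameSeries` holds an ordered stack
of curves from one SEC-SAXS injection that share a single q grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class ScatteringCurve:
    """A 1-D scattering profile I(q) with optional uncertainties.

    Parameters
    ----------
    q : array
        Momentum transfer in A^-1; must be positive and strictly increasing.
    I : array
        Intensity, arbitrary units.
    sigma : array, optional
        1-sigma uncertainty of I, same units; positive where present.
    label : str
        Free-text identifier carried through I/O.
    q_max_usable : float, optional
        Analysis cutoff in A^-1 (e.g. from a signal-to-noise criterion).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    q_max_usable: float | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("q must be a non-empty 1-D array")
        if self.I.shape != self.q.shape:
            raise ValueError("q and I must have the same length")
        if self.sigma is not None and self.sigma.shape != self.q.shape:
            raise ValueError("sigma must have the same length as q")
        if np.any(self.q <= 0):
            raise ValueError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.I)):
            raise ValueError("q and I must be finite")
        if self.sigma is not None and (
            np.any(~np.isfinite(self.sigma)) or np.any(self.sigma <= 0)
        ):
            raise ValueError("sigma must be finite and > 0 where present")

    def __len__(self) -> int:
        return int(self.q.size)

    @property
    def has_sigma(self) -> bool:
        return self.sigma is not None

    def truncate(self, q_min: float = 0.0, q_max: float = np.inf) -> "ScatteringCurve":
        """Return the sub-curve with q_min <= q <= q_max."""
        mask = (self.q >= q_min) & (self.q <= q_max)
        if not np.any(mask):
            raise ValueError("truncation leaves no points")
        return replace(
            self,
            q=self.q[mask],
            I=self.I[mask],
            sigma=None if self.sigma is None else self.sigma[mask],
        )

    def interpolate_to(self, q_new: np.ndarray) -> "ScatteringCurve":
        """Linear interpolation of I (and sigma) onto a new q grid.

        The new grid must lie inside the current q range.
        """
        q_new = np.asarray(q_new, dtype=float)
        if q_new.min() < self.q[0] - 1e-12 or q_new.max() > self.q[-1] + 1e-12:
            raise ValueError("interpolation grid extends outside the data range")
        I_new = np.interp(q_new, self.q, self.I)
        s_new = None if self.sigma is None else np.interp(q_new, self.q, self.sigma)
        return replace(self, q=q_new, I=I_new, sigma=s_new)

    def copy(self) -> "ScatteringCurve":
        return replace(
            self,
            q=self.q.copy(),
            I=self.I.copy(),
            sigma=None if self.sigma is None else self.sigma.copy(),
        )


@dataclass
class FrameSeries:
    """Ordered SEC-SAXS frames sharing one q grid.

    ``frames`` are individual exposures in elution order; ``frame_index``
    is strictly increasing; ``exposure`` is seconds per frame.
    """

    frames: list[ScatteringCurve]
    frame_index: np.ndarray | None = None
    exposure: float = 3.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("FrameSeries requires at least one frame")
        q0 = self.frames[0].q
        for fr in self.frames[1:]:
            if fr.q.shape != q0.shape or not np.allclose(fr.q, q0):
                raise ValueError("all frames must share an identical q grid")
        if self.frame_index is None:
            self.frame_index = np.arange(len(self.frames))
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.frame_index.size != len(self.frames):
            raise ValueError("frame_index length mismatch")
        if np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def q(self) -> np.ndarray:
        return self.frames[0].q

    def intensity_matrix(self) -> np.ndarray:
        """(n_frames, n_q) intensity stack."""
        return np.stack([fr.I for fr in self.frames])

    def sigma_matrix(self) -> np.ndarray | None:
        if any(fr.sigma is None for fr in self.frames):
            return None
        return np.stack([fr.sigma for fr in self.frames])
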