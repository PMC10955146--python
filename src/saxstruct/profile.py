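"""Theoretical scattering from structural models and profile fitting.

The orientationally averaged intensity of a rigid particle with point
scatterers f_i at positions x_i is the Debye sum

    I(q) = sum_ij f_i f_j sin(q d_ij) / (q d_ij),   sin(0)/0 := 1.

Exact evaluation is O(n^2) per q value; here pair distances are binned
(0.1 A default) so the sum over pairs collapses to a sum over distance
bins, trading <0.5% error for O(n_bins x n_q) evaluation. Solvent
excluded-volume and hydration-shell contrast are deliberately not
modelled: profiles are used for relative model ranking and for
self-consistent synthetic data, not for absolute-scale comparison with
wet experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import ScatteringCurve
from .structures import AtomicModel, BeadModel

ELEMENT_ELECTRONS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16,
    "FE": 26, "ZN": 30, "SE": 34,
}

_DISTANCE_BIN = 0.1  # A


@dataclass
class FitReport:
    """Outcome of fitting a calculated profile to an experimental curve."""

    chi2: float                 # reduced chi-square
    scale: float                # fitted multiplicative constant
    offset: float | None = None  # fitted additive constant, if requested
    nsd: float | None = None    # normalized spatial discrepancy vs envelope
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be non-negative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def summary(self) -> str:
        lines = [f"profile fit over {self.n_points} points",
                 f"  reduced chi^2 = {self.chi2:.4g}",
                 f"  scale         = {self.scale:.4g}"]
        if self.offset is not None:
            lines.append(f"  offset        = {self.offset:.4g}")
        if self.nsd is not None:
            lines.append(f"  NSD vs envelope = {self.nsd:.3f}")
        return "\n".join(lines)


def _scatterers(model: AtomicModel | BeadModel, level: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(model, BeadModel):
        return model.centers, model.occupancy.astype(float)
    if level == "residue":
        return model.ca_coords(), model.residue_electrons()
    if level == "atom":
        f = np.array([
            ELEMENT_ELECTRONS.get(str(e).strip().upper(), 6.0)
            for e in model.element
        ], dtype=float)
        return model.coords, f
    raise ValueError(f"unknown level {level!r}")


def pair_distance_histogram(
    coords: np.ndarray, weights: np.ndarray, bin_width: float = _DISTANCE_BIN
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted histogram of the i<j pair distances.

    Returns (bin centers, summed f_i*f_j weights). Chunked so memory stays
    O(chunk x n) for large models.
    """
    n = coords.shape[0]
    counts: np.ndarray | None = None
    # row-wise accumulation keeps memory at O(n) while staying vectorized
    for ii in range(n - 1):
        d_row = np.linalg.norm(coords[ii + 1:] - coords[ii], axis=1)
        idx = np.rint(d_row / bin_width).astype(np.int64)
        w = weights[ii] * weights[ii + 1:]
        binc = np.bincount(idx, weights=w)
        if counts is None or counts.size < binc.size:
            new = np.zeros(binc.size)
            if counts is not None:
                new[: counts.size] = counts
            counts = new
        counts[: binc.size] += binc
    if counts is None:
        counts = np.zeros(1)
    centers = np.arange(counts.size) * bin_width
    return centers, counts


def debye_profile(
    model: AtomicModel | BeadModel,
    q_grid: np.ndarray,
    level: str = "residue",
    binned: bool = True,
) -> ScatteringCurve:
    """Debye-sum scattering profile of a model on ``q_grid``.

    ``level='residue'`` uses one scatterer per residue at the C-alpha with
    the residue electron count as form factor; ``level='atom'`` uses all
    atoms with elemental electron counts. Bead models use occupancies as
    weights. ``binned=False`` forces the exact O(n^2) pair sum (testing).
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    coords, f = _scatterers(model, level)
    if coords.shape[0] == 0:
        raise ValueError("model has no scatterers")
    self_term = float(np.sum(f**2))
    if coords.shape[0] == 1:
        return ScatteringCurve(q=np.maximum(q, np.finfo(float).tiny),
                               I=np.full(q.size, self_term))
    if binned:
        centers, wsum = pair_distance_histogram(coords, f)
        nz = wsum > 0
        centers, wsum = centers[nz], wsum[nz]
        # sinc(x) in numpy is sin(pi x)/(pi x)
        cross = 2.0 * np.sum(
            wsum[None, :] * np.sinc(q[:, None] * centers[None, :] / np.pi), axis=1
        )
    else:
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.linalg.norm(diff, axis=2)
        iu = np.triu_indices(coords.shape[0], k=1)
        dv = d[iu]
        wv = (f[:, None] * f[None, :])[iu]
        cross = 2.0 * np.sum(wv[None, :] * np.sinc(q[:, None] * dv[None, :] / np.pi), axis=1)
    I = self_term + cross
    q_out = q.copy()
    if q_out[0] == 0:
        q_out[0] = np.finfo(float).tiny  # container requires q > 0
    return ScatteringCurve(q=q_out, I=I, label=getattr(model, "label", ""))


def fit_profile(
    calc: ScatteringCurve,
    exp: ScatteringCurve,
    fit_offset: bool = False,
) -> FitReport:
    """Least-squares scale (and optional offset) of ``calc`` onto ``exp``.

    The experimental curve must carry uncertainties. The reduced
    chi-square uses N-1 degrees of freedom (N-2 with offset).
    """
    if exp.sigma is None:
        raise ValueError("experimental curve must have sigma for chi^2 fitting")
    qlo = max(calc.q[0], exp.q[0])
    qhi = min(calc.q[-1], exp.q[-1])
    mask = (exp.q >= qlo) & (exp.q <= qhi)
    if int(mask.sum()) < 10:
        raise ValueError("fewer than 10 shared q points")
    qe = exp.q[mask]
    Ie = exp.I[mask]
    se = exp.sigma[mask]
    Ic = np.interp(qe, calc.q, calc.I)
    w = 1.0 / se**2
    n = qe.size
    if fit_offset:
        # weighted linear model Ie ~ c*Ic + b
        A = np.column_stack([Ic, np.ones(n)])
        Aw = A * w[:, None]
        beta = np.linalg.solve(A.T @ Aw, Aw.T @ Ie)
        c, b = float(beta[0]), float(beta[1])
        resid = (Ie - c * Ic - b) / se
        dof = n - 2
        offset = b
    else:
        c = float(np.sum(w * Ie * Ic) / np.sum(w * Ic**2))
        resid = (Ie - c * Ic) / se
        dof = n - 1
        offset = None
    chi2 = float(np.sum(resid**2) / dof)
    return FitReport(chi2=chi2, scale=max(c, np.finfo(float).tiny),
                     offset=offset, n_points=n)


def model_rg(model: AtomicModel | BeadModel, weights: str = "electrons") -> float:
    """Weighted radius of gyration, sqrt(sum w |x - xbar|^2 / sum w), in A."""
    if isinstance(model, BeadModel):
        coords, w = model.centers, model.occupancy.astype(float)
    elif weights == "electrons":
        coords, w = model.ca_coords(), model.residue_electrons()
    elif weights == "uniform":
        coords, w = model.ca_coords(), np.ones(model.ca_coords().shape[0])
    else:
        raise ValueError(f"unknown weights {weights!r}")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("non-positive total weight")
    center = (coords * w[:, None]).sum(axis=0) / wsum
    return float(np.sqrt(np.sum(w * np.sum((coords - center) ** 2, axis=1)) / wsum))
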