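"""SEC-SAXS frame-series processing.

Turns a series of per-frame scattering curves from one size-exclusion
chromatography injection into a single validated, averaged,
background-subtracted curve: chromatogram integration, per-frame Guinier
Rg, homogeneous-window selection (minimum Rg scatter at maximum frame
count), averaging with error propagation, reduced-chi-square dataset
comparison, and linear/log re-binning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .curves import FrameSeries, ScatteringCurve

logger = logging.getLogger("saxstruct")


@dataclass
class SelectionWindow:
    """A contiguous frame window judged homogeneous in Rg."""

    first_frame: int
    last_frame: int
    mean_rg: float
    sigma_rg: float      # std. dev. of per-frame Rg over the window
    fallback: bool = False  # True when no window met the homogeneity bound

    def __post_init__(self) -> None:
        if self.first_frame > self.last_frame:
            raise ValueError("first_frame must be <= last_frame")
        if self.sigma_rg < 0:
            raise ValueError("sigma_rg must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.last_frame - self.first_frame + 1

    def frames(self) -> np.ndarray:
        return np.arange(self.first_frame, self.last_frame + 1)


def chromatogram(series: FrameSeries) -> np.ndarray:
    """Total scattered intensity per frame (trapezoidal integral over q)."""
    I = series.intensity_matrix()
    return np.trapezoid(I, series.q, axis=1)


def frame_rg(
    series: FrameSeries,
    buffer_curve: ScatteringCurve | None = None,
    qrg_limit: float = 1.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Guinier Rg (and its uncertainty) for every buffer-subtracted frame.

    The Guinier q window is selected automatically on the strongest frame
    and then held fixed for the whole series, so per-frame Rg values are
    directly comparable (range re-selection would add frame-to-frame
    variance that the formal uncertainties do not describe). Frames whose
    fit fails (no decay, too few usable points, or negative intensities
    everywhere) get NaN, not an exception. Raises only if every frame
    fails.
    """
    from .guinier_pr import guinier_fit

    if buffer_curve is not None and (
        buffer_curve.q.shape != series.q.shape
        or not np.allclose(buffer_curve.q, series.q)
    ):
        raise ValueError("buffer curve must share the series q grid")
    n = len(series)
    rg = np.full(n, np.nan)
    rg_err = np.full(n, np.nan)
    I_all = series.intensity_matrix()
    buf = buffer_curve.I if buffer_curve is not None else 0.0
    strongest = int(np.argmax(np.trapezoid(I_all - buf, series.q, axis=1)))
    shared_range = None
    try:
        ref = ScatteringCurve(q=series.q, I=I_all[strongest] - buf,
                              sigma=series.frames[strongest].sigma)
        shared_range = guinier_fit(ref, qrg_limit=qrg_limit).q_range_used
    except (ValueError, FloatingPointError):
        pass  # fall back to per-frame automatic ranges
    for i, fr in enumerate(series.frames):
        I = fr.I - buf
        sigma = fr.sigma
        try:
            sub = ScatteringCurve(q=fr.q, I=I, sigma=sigma)
            res = guinier_fit(sub, qrg_limit=qrg_limit, q_range=shared_range)
            rg[i] = res.rg
            rg_err[i] = res.rg_err
        except (ValueError, FloatingPointError):
            continue
    if np.all(np.isnan(rg)):
        raise ValueError("Guinier fit failed for every frame")
    return rg, rg_err


def select_window(
    series: FrameSeries,
    rg_values: np.ndarray,
    peak_region: tuple[int, int],
    rg_errors: np.ndarray | None = None,
    kappa: float = 1.0,
) -> SelectionWindow:
    """Longest contiguous frame window with Rg scatter within measurement error.

    Among all contiguous windows of valid-Rg frames inside ``peak_region``,
    returns the longest whose sigma<Rg> is at most ``kappa`` times the
    median per-frame Rg uncertainty; ties are broken by smaller sigma<Rg>,
    then by earlier start. If no window of length >= 3 satisfies the bound,
    the global sigma<Rg>-minimizing window of length 3 is returned with
    ``fallback=True``.
    """
    rg_values = np.asarray(rg_values, dtype=float)
    lo, hi = int(peak_region[0]), int(peak_region[1])
    if lo > hi:
        raise ValueError("peak_region must be (first, last) with first <= last")
    lo = max(lo, 0)
    hi = min(hi, len(series) - 1)
    idx = np.arange(lo, hi + 1)
    valid = idx[np.isfinite(rg_values[idx])]
    if valid.size < 3:
        raise ValueError("need >= 3 frames with valid Rg inside peak_region")
    if rg_errors is None:
        tol = np.inf
    else:
        errs = np.asarray(rg_errors, dtype=float)[valid]
        tol = kappa * float(np.nanmedian(errs))

    def window_stats(a: int, b: int) -> tuple[float, float] | None:
        w = np.arange(a, b + 1)
        if not np.all(np.isfinite(rg_values[w])):
            return None  # windows must be contiguous in valid frames
        vals = rg_values[w]
        return float(vals.mean()), float(vals.std(ddof=0))

    best: tuple[int, float, int, int, float] | None = None  # (-len, sigma, a, b, mean)
    fallback_best: tuple[float, int, int, float] | None = None
    for a in range(lo, hi - 1):
        for b in range(a + 2, hi + 1):
            st = window_stats(a, b)
            if st is None:
                continue
            mean, sd = st
            length = b - a + 1
            if length == 3:
                key3 = (sd, a)
                if fallback_best is None or key3 < (fallback_best[0], fallback_best[1]):
                    fallback_best = (sd, a, b, mean)
            if sd <= tol:
                key = (-length, sd, a)
                if best is None or key < (best[0], best[1], best[2]):
                    best = (-length, sd, a, b, mean)
    if best is not None:
        return SelectionWindow(first_frame=best[2], last_frame=best[3],
                               mean_rg=best[4], sigma_rg=best[1])
    if fallback_best is None:
        raise ValueError("no contiguous window of 3 valid frames in peak_region")
    logger.warning("select_window: no window met the homogeneity bound; "
                   "falling back to the minimum-sigma length-3 window")
    return SelectionWindow(first_frame=fallback_best[1], last_frame=fallback_best[2],
                           mean_rg=fallback_best[3], sigma_rg=fallback_best[0],
                           fallback=True)


def average_and_subtract(
    series: FrameSeries,
    window: SelectionWindow | tuple[int, int],
    buffer_frames: np.ndarray | list[int] | None,
) -> ScatteringCurve:
    """Mean sample curve over the window minus the mean buffer curve.

    Uncertainty propagates as sqrt(var_s/n_s^2-summed + var_b/n_b^2-summed)
    per point, i.e. the standard error of each mean added in quadrature.
    An empty buffer set averages without subtraction (logged).
    """
    if isinstance(window, SelectionWindow):
        sample_idx = window.frames()
    else:
        sample_idx = np.arange(int(window[0]), int(window[1]) + 1)
    buffer_idx = np.asarray(buffer_frames if buffer_frames is not None else [], dtype=int)
    if np.intersect1d(sample_idx, buffer_idx).size:
        raise ValueError("sample window and buffer frames must be disjoint")
    I = series.intensity_matrix()
    S = series.sigma_matrix()
    n_s = sample_idx.size
    if n_s == 0:
        raise ValueError("empty sample window")
    mean_s = I[sample_idx].mean(axis=0)
    var = None
    if S is not None:
        var = np.sum(S[sample_idx] ** 2, axis=0) / n_s**2
    label = "averaged"
    if buffer_idx.size:
        mean_b = I[buffer_idx].mean(axis=0)
        out_I = mean_s - mean_b
        if S is not None:
            var = var + np.sum(S[buffer_idx] ** 2, axis=0) / buffer_idx.size**2
        label = "averaged, buffer-subtracted"
    else:
        logger.warning("average_and_subtract: empty buffer set; no subtraction applied")
        out_I = mean_s
        label = "averaged (unsubtracted)"
    sigma = np.sqrt(var) if var is not None else None
    if sigma is not None and np.any(sigma <= 0):
        sigma = np.maximum(sigma, np.finfo(float).tiny)
    return ScatteringCurve(q=series.q.copy(), I=out_I, sigma=sigma, label=label)


def default_buffer_frames(
    series: FrameSeries, n_buffer: int = 20, before_frame: int | None = None
) -> np.ndarray:
    """Lowest-chromatogram frames, restricted to before the first peak.

    ``before_frame`` defaults to the global chromatogram maximum.
    """
    chrom = chromatogram(series)
    if before_frame is None:
        before_frame = int(np.argmax(chrom))
    candidates = np.arange(0, max(before_frame, 1))
    order = candidates[np.argsort(chrom[candidates], kind="stable")]
    return np.sort(order[:n_buffer])


def compare_datasets(
    curve_a: ScatteringCurve, curve_b: ScatteringCurve
) -> tuple[float, float]:
    """Reduced chi-square similarity test between two curves.

    B is interpolated onto A's grid over the shared q range; A is scaled to
    B by analytic least squares; the statistic uses combined variances and
    N-1 degrees of freedom (one fitted scale). Returns (reduced chi^2,
    p-value from the chi^2 survival function).
    """
    if curve_a.sigma is None or curve_b.sigma is None:
        raise ValueError("both curves need sigma for the chi^2 test")
    qlo = max(curve_a.q[0], curve_b.q[0])
    qhi = min(curve_a.q[-1], curve_b.q[-1])
    mask = (curve_a.q >= qlo) & (curve_a.q <= qhi)
    if int(mask.sum()) < 10:
        raise ValueError("fewer than 10 shared q points")
    qa = curve_a.q[mask]
    Ia, sa = curve_a.I[mask], curve_a.sigma[mask]
    Ib = np.interp(qa, curve_b.q, curve_b.I)
    sb = np.interp(qa, curve_b.q, curve_b.sigma)
    # scale A onto B; variance of (c*Ia - Ib) is c^2 sa^2 + sb^2, so iterate
    # the analytic scale once with provisional weights
    c = float(np.sum(Ia * Ib / (sa**2 + sb**2)) / np.sum(Ia**2 / (sa**2 + sb**2)))
    for _ in range(3):
        var = c**2 * sa**2 + sb**2
        c = float(np.sum(Ia * Ib / var) / np.sum(Ia**2 / var))
    var = c**2 * sa**2 + sb**2
    n = qa.size
    chi2 = float(np.sum((c * Ia - Ib) ** 2 / var) / (n - 1))
    p = float(stats.chi2.sf(chi2 * (n - 1), df=n - 1))
    return chi2, p


def rebin(
    curve: ScatteringCurve,
    mode: str = "log",
    n_points: int | None = None,
    merge_every: int | None = None,
) -> ScatteringCurve:
    """Re-bin a curve to improve signal-to-noise.

    ``mode`` 'linear' or 'log' with ``n_points`` bins over the q range, or
    ``merge_every`` to join every m-th point. Within each bin, I is the
    sigma^-2-weighted mean, sigma_bin = (sum sigma^-2)^-1/2, and q_bin the
    weighted mean q; empty bins are dropped. ``merge_every=1`` is identity.
    """
    if (n_points is None) == (merge_every is None):
        raise ValueError("specify exactly one of n_points or merge_every")
    q, I = curve.q, curve.I
    s = curve.sigma
    if merge_every is not None:
        if merge_every < 1:
            raise ValueError("merge_every must be >= 1")
        if merge_every == 1:
            return curve.copy()
        edges_idx = np.arange(0, q.size + merge_every, merge_every)
        groups = [np.arange(a, min(b, q.size)) for a, b in zip(edges_idx[:-1], edges_idx[1:])]
        groups = [g for g in groups if g.size]
    else:
        if n_points < 5:
            raise ValueError("n_points must be >= 5")
        if n_points >= q.size:
            return curve.copy()
        if mode == "linear":
            edges = np.linspace(q[0], q[-1], n_points + 1)
        elif mode == "log":
            edges = np.geomspace(q[0], q[-1], n_points + 1)
        else:
            raise ValueError(f"unknown rebin mode {mode!r}")
        which = np.clip(np.searchsorted(edges, q, side="right") - 1, 0, n_points - 1)
        groups = [np.nonzero(which == b)[0] for b in range(n_points)]
        groups = [g for g in groups if g.size]
    w = 1.0 / s**2 if s is not None else np.ones_like(q)
    q_out, I_out, s_out = [], [], []
    for g in groups:
        wg = w[g]
        wsum = wg.sum()
        q_out.append(float(np.sum(wg * q[g]) / wsum))
        I_out.append(float(np.sum(wg * I[g]) / wsum))
        if s is not None:
            s_out.append(float(1.0 / np.sqrt(wsum)))
    return ScatteringCurve(
        q=np.array(q_out), I=np.array(I_out),
        sigma=np.array(s_out) if s is not None else None,
        label=curve.label, q_max_usable=curve.q_max_usable,
    )
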