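"""Dual-space validation and envelope-restrained flexible fitting.

An atomic model is validated in reciprocal space by the reduced chi^2 of
its Debye profile against the experimental curve, and in direct space by
the normalized spatial discrepancy (NSD) of its C-alpha set against the ab
initio envelope (NSD < 3 is the customary bound for a full-atom model vs
a dummy-atom envelope; < 1 among envelope reconstructions themselves).

Flexible fitting is a deliberately simple C-alpha-level energy
minimization, not thermostatted molecular dynamics: a density-map
attraction term (trilinear interpolation, analytic gradient), virtual
C-alpha bonds at 3.8 A, per-domain rigidity restraints toward reference
coordinates (a targeted-MD surrogate), and optional harmonic metal-site
restraints (default k = 50 energy units/A^2 toward 2.5 A, mirroring
Zn-coordination springs). Steps use gradient descent with backtracking, so
the energy is non-increasing along the accepted trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .curves import ScatteringCurve
from .envelope import align_nsd, bead_density
from .profile import FitReport, debye_profile, fit_profile
from .structures import AtomicModel, BeadModel, DensityGrid

logger = logging.getLogger("saxstruct")


# ---------------------------------------------------------------------------
# superposition


def kabsch(mobile: np.ndarray, fixed: np.ndarray, allow_reflection: bool = False):
    """Least-squares superposition of ``mobile`` onto ``fixed``.

    Returns (R, t, rmsd) with the transform acting as x -> x @ R.T + t.
    By default R is a proper rotation (determinant +1).
    """
    P = np.asarray(mobile, dtype=float).reshape(-1, 3)
    Q = np.asarray(fixed, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("superposition needs matching sets of >= 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if not allow_reflection else 1.0])
    R = Vt.T @ D @ U.T
    t = cq - cp @ R.T
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# dual-space validation


def validate_dual(
    model: AtomicModel,
    curve: ScatteringCurve,
    envelope: BeadModel,
    level: str = "residue",
) -> FitReport:
    """Reciprocal-space chi^2 plus direct-space NSD for one atomic model."""
    calc = debye_profile(model, curve.q, level=level)
    report = fit_profile(calc, curve)
    _, nsd = align_nsd(envelope, model.ca_coords())
    report.nsd = nsd
    return report


# ---------------------------------------------------------------------------
# model splicing


@dataclass
class SpliceReport:
    """Junction sanity data for a spliced model."""

    overlap_rmsd: float                 # Kabsch RMSD over the overlap CA set
    junction_distances: list[float]     # consecutive-CA distances at take-range joins
    junctions_ok: bool                  # all within the 2.9-4.1 A CA-CA window


def splice_models(
    model_a: AtomicModel,
    model_b: AtomicModel,
    overlap_range: tuple[int, int],
    take_from_a: tuple[int, int],
    take_from_b: tuple[int, int],
) -> tuple[AtomicModel, SpliceReport]:
    """Combine two overlapping construct models into one mixed model.

    B is superposed onto A by Kabsch over the common-region C-alphas (the
    lever arm), then the output takes A's atoms on ``take_from_a`` and the
    transformed B's atoms on ``take_from_b``. The take ranges must not
    claim the same residue twice; consecutive-CA distances at the joins
    are checked against the 2.9-4.1 A plausibility window.
    """
    lo, hi = overlap_range
    ca_a_idx = model_a.ca_residue_index()
    ca_b_idx = model_b.ca_residue_index()
    common = np.intersect1d(ca_a_idx, ca_b_idx)
    common = common[(common >= lo) & (common <= hi)]
    if common.size < 10:
        raise ValueError("overlap of fewer than 10 residues")
    if max(take_from_a[0], take_from_b[0]) <= min(take_from_a[1], take_from_b[1]):
        raise ValueError("take ranges overlap: residue-numbering conflict")
    pa = _ca_subset(model_a, common)
    pb = _ca_subset(model_b, common)
    R, t, rmsd = kabsch(pb, pa)
    b_moved = model_b.transformed(R, t)
    part_a = model_a.select_residues(*take_from_a)
    part_b = b_moved.select_residues(*take_from_b)
    merged = _concat_models(part_a, part_b, label="spliced model")
    # junction check: CA-CA distance across each take-range boundary
    ca = merged.ca_coords()
    idx = merged.ca_residue_index()
    order = np.argsort(idx)
    ca, idx = ca[order], idx[order]
    junctions = []
    boundaries = {take_from_a[0] - 1, take_from_a[1], take_from_b[0] - 1, take_from_b[1]}
    for i in range(len(idx) - 1):
        if idx[i + 1] == idx[i] + 1 and idx[i] in boundaries:
            junctions.append(float(np.linalg.norm(ca[i + 1] - ca[i])))
    ok = all(2.9 <= d <= 4.1 for d in junctions)
    if not ok:
        logger.warning("splice_models: junction CA-CA distances %s outside 2.9-4.1 A",
                       [f"{d:.2f}" for d in junctions])
    return merged, SpliceReport(overlap_rmsd=rmsd, junction_distances=junctions,
                                junctions_ok=ok)


def _ca_subset(model: AtomicModel, residues: np.ndarray) -> np.ndarray:
    ca = model.ca_coords()
    idx = model.ca_residue_index()
    sel = np.isin(idx, residues)
    order = np.argsort(idx[sel])
    return ca[sel][order]


def _concat_models(a: AtomicModel, b: AtomicModel, label: str = "") -> AtomicModel:
    merged = AtomicModel(
        coords=np.vstack([a.coords, b.coords]),
        residue_index=np.concatenate([a.residue_index, b.residue_index]),
        residue_name=np.concatenate([a.residue_name, b.residue_name]),
        atom_name=np.concatenate([a.atom_name, b.atom_name]),
        chain=np.concatenate([a.chain, b.chain]),
        element=np.concatenate([a.element, b.element]),
        hetero=np.concatenate([a.hetero, b.hetero]),
        label=label,
    )
    order = np.argsort(merged.residue_index, kind="stable")
    return merged._subset(order)


# ---------------------------------------------------------------------------
# combined envelope restraint


def combine_envelopes(
    env_a: BeadModel,
    env_b: BeadModel,
    model: AtomicModel,
    range_a: tuple[int, int],
    range_b: tuple[int, int],
    voxel: float = 3.0,
) -> DensityGrid:
    """Merge two construct envelopes into one density restraint.

    Each envelope is NSD-aligned to the C-alpha set of its corresponding
    residue range of ``model``, converted to a Gaussian density on one
    common grid, and combined by voxelwise maximum (so each lobe retains
    its own envelope's support).
    """
    placed = []
    for env, rng in ((env_a, range_a), (env_b, range_b)):
        target = model.select_residues(*rng).ca_coords()
        (R, t), nsd = align_nsd(target, env)
        placed.append(env.transformed(R, t))
        logger.info("combine_envelopes: envelope aligned with NSD %.3f", nsd)
    sigma = max(p.bead_radius for p in placed)
    pad = 3.0 * sigma
    all_pts = np.vstack([p.centers for p in placed])
    lo = all_pts.min(axis=0) - pad
    hi = all_pts.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 2)
    combined = np.zeros(shape)
    for p in placed:
        g = _density_on_grid(p, lo, voxel, shape, sigma)
        combined = np.maximum(combined, g)
    return DensityGrid(origin=lo, voxel=voxel, values=combined)


def _density_on_grid(model: BeadModel, origin, voxel, shape, sigma) -> np.ndarray:
    axes = [origin[d] + voxel * np.arange(shape[d]) for d in range(3)]
    values = np.zeros(shape)
    norm = (2.0 * np.pi * sigma**2) ** -1.5
    reach = 4.0 * sigma
    for c, w in zip(model.centers, model.occupancy):
        sl, loc = [], []
        for d in range(3):
            a = int(np.searchsorted(axes[d], c[d] - reach))
            b = int(np.searchsorted(axes[d], c[d] + reach))
            sl.append(slice(a, b))
            loc.append(axes[d][a:b])
        dx2 = [(ax - c[d]) ** 2 for d, ax in enumerate(loc)]
        g = np.exp(-(dx2[0][:, None, None] + dx2[1][None, :, None]
                     + dx2[2][None, None, :]) / (2.0 * sigma**2))
        values[sl[0], sl[1], sl[2]] += w * norm * g
    return values


# ---------------------------------------------------------------------------
# density correlation


def corr(grid: DensityGrid, model: AtomicModel | BeadModel,
         threshold_frac: float = 0.01) -> float:
    """Cross-correlation between a target map and a model's simulated density.

    The model density is computed on the target's own grid geometry; the
    Pearson correlation runs over voxels where either map exceeds
    ``threshold_frac`` of its maximum.
    """
    if isinstance(model, AtomicModel):
        beads = BeadModel(centers=model.ca_coords(), bead_radius=grid.voxel)
    else:
        beads = model
    sim = _density_on_grid(beads, grid.origin, grid.voxel, grid.values.shape,
                           sigma=beads.bead_radius)
    a = grid.values.ravel()
    b = sim.ravel()
    mask = (a > threshold_frac * a.max()) | (b > threshold_frac * max(b.max(), 1e-300))
    if int(mask.sum()) < 8:
        raise ValueError("no overlapping support between map and model density")
    av, bv = a[mask], b[mask]
    if av.std() == 0:
        raise ValueError("zero variance in the thresholded density region")
    if bv.std() == 0:
        return 0.0  # model entirely outside the map support
    return float(np.corrcoef(av, bv)[0, 1])


# ---------------------------------------------------------------------------
# flexible fitting


@dataclass
class FlexFitResult:
    """Refined model plus per-step trajectory metrics."""

    model: AtomicModel
    corr_series: np.ndarray        # map cross-correlation per step
    rmsd_series: np.ndarray        # CA RMSD to the start model per step
    energy_series: np.ndarray
    converged: bool = True


def flexfit(
    model: AtomicModel,
    grid: DensityGrid,
    rigid_domains: list[tuple[int, int]] | None = None,
    zn_restraints: list[tuple[int, int]] | None = None,
    steps: int = 150,
    step_size: float = 0.5,
    k_bond: float = 10.0,
    k_domain: float = 20.0,
    k_zn: float = 50.0,
    zn_r0: float = 2.5,
    map_weight: float | None = None,
    corr_every: int = 1,
    rigid_polish: bool = True,
) -> FlexFitResult:
    """Fit a C-alpha model into a density map by restrained minimization.

    U = -w sum_i rho(x_i) + k_bond sum (|x_{i+1}-x_i| - 3.8)^2
        + k_domain sum_domains sum_i |x_i - y_i|^2 + Zn harmonic terms,

    where y_i are the domain's reference coordinates after optimal
    superposition onto the current conformation (recomputed each step) and
    rho is the trilinearly interpolated map. ``map_weight=None`` auto-scales
    w so map and bond force magnitudes match at step 0. Gradient descent
    with backtracking keeps the energy non-increasing.
    """
    ca_mask = model.ca_mask()
    x = model.coords[ca_mask].copy()
    resid = model.residue_index[ca_mask]
    order = np.argsort(resid, kind="stable")
    x = x[order]
    resid = resid[order]
    n = x.shape[0]
    # bond i..i+1 where residues are contiguous AND the start geometry is
    # chain-like; larger initial separations are treated as chain breaks
    start_sep = np.linalg.norm(np.diff(x, axis=0), axis=1)
    bonds = np.flatnonzero((np.diff(resid) == 1) & (start_sep <= 4.5))
    d0 = 3.8
    x_start = x.copy()
    domains = []
    for lo, hi in rigid_domains or []:
        sel = np.flatnonzero((resid >= lo) & (resid <= hi))
        if sel.size >= 3:
            domains.append((sel, x_start[sel].copy()))
    zn_pairs = zn_restraints or []

    def map_terms(pos):
        rho, g = grid.interpolate_with_gradient(pos)
        return rho, g

    def bonded_energy_grad(pos):
        e = 0.0
        grad = np.zeros_like(pos)
        if bonds.size:
            dvec = pos[bonds + 1] - pos[bonds]
            dist = np.linalg.norm(dvec, axis=1)
            dist = np.maximum(dist, 1e-9)
            dev = dist - d0
            e += k_bond * float(np.sum(dev**2))
            f = (2.0 * k_bond * dev / dist)[:, None] * dvec
            np.add.at(grad, bonds, -f)
            np.add.at(grad, bonds + 1, f)
        for sel, ref in domains:
            R, t, _ = kabsch(ref, pos[sel])
            target = ref @ R.T + t
            diff = pos[sel] - target
            e += k_domain * float(np.sum(diff**2))
            grad[sel] += 2.0 * k_domain * diff
        for i, j in zn_pairs:
            dvec = pos[j] - pos[i]
            dist = max(float(np.linalg.norm(dvec)), 1e-9)
            dev = dist - zn_r0
            e += k_zn * dev**2
            f = 2.0 * k_zn * dev / dist * dvec
            grad[i] -= f
            grad[j] += f
        return e, grad

    rho0, gmap0 = map_terms(x)
    if map_weight is None:
        # scale so the typical map force matches the restoring force of a
        # bond stretched by 0.5 A (2 * k_bond * 0.5); the start bond force
        # itself can be zero for an ideal-geometry start
        gmag = np.linalg.norm(gmap0, axis=1)
        gm = float(gmag[gmag > 0].mean()) if np.any(gmag > 0) else 0.0
        map_weight = k_bond / gm if gm > 0 else 1.0

    def total_energy_grad(pos):
        rho, gmap = map_terms(pos)
        e_b, g_b = bonded_energy_grad(pos)
        e = -map_weight * float(rho.sum()) + e_b
        g = -map_weight * gmap + g_b
        return e, g

    def model_with(pos):
        out = model._subset(np.ones(len(model), dtype=bool))
        ca_idx = np.flatnonzero(ca_mask)[order]
        out.coords = model.coords.copy()
        out.coords[ca_idx] = pos
        return out

    corr_series, rmsd_series, energy_series = [], [], []
    e, g = total_energy_grad(x)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient at step 0")
    s = step_size
    converged = True
    for step in range(steps):
        if step % corr_every == 0:
            try:
                c = corr(grid, model_with(x))
            except ValueError:
                c = 0.0
            corr_series.append(c)
            rmsd_series.append(float(np.sqrt(np.mean(np.sum((x - x_start) ** 2, axis=1)))))
            energy_series.append(e)
        accepted = False
        s_try = s
        for _ in range(25):
            x_new = x - s_try * g
            e_new, g_new = total_energy_grad(x_new)
            if not np.all(np.isfinite(g_new)):
                raise FloatingPointError(f"non-finite gradient at step {step}")
            if e_new <= e:
                accepted = True
                break
            s_try *= 0.5
        if not accepted:
            converged = True  # at a (local) stationary point
            break
        x, e, g = x_new, e_new, g_new
        s = min(s_try * 1.5, step_size * 4)
    if rigid_polish and domains:
        x = _polish_rigid_domains(x, domains, grid, map_weight, bonds, d0, k_bond)
        e, g = total_energy_grad(x)
    try:
        c = corr(grid, model_with(x))
    except ValueError:
        c = 0.0
    corr_series.append(c)
    rmsd_series.append(float(np.sqrt(np.mean(np.sum((x - x_start) ** 2, axis=1)))))
    energy_series.append(e)
    return FlexFitResult(
        model=model_with(x),
        corr_series=np.array(corr_series),
        rmsd_series=np.array(rmsd_series),
        energy_series=np.array(energy_series),
        converged=converged,
    )


def _polish_rigid_domains(x, domains, grid, map_weight, bonds, d0, k_bond):
    """Rigid-body (6-dof) refinement of each restrained domain in the map.

    Per-atom gradients vanish in the flat interior of a smooth map, which
    stalls descent before a domain is optimally posed; a direct rigid
    search over rotation and translation resolves this. Bond terms keep
    the chain anchored during the search.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation as _Rot

    x = x.copy()

    def score(trial):
        beads = BeadModel(centers=trial, bead_radius=grid.voxel)
        try:
            c = corr(grid, beads)
        except ValueError:
            return np.inf
        pen = 0.0
        if bonds.size:
            dvec = trial[bonds + 1] - trial[bonds]
            dist = np.linalg.norm(dvec, axis=1)
            pen = 0.02 * float(np.sum((dist - d0) ** 2))
        return -c + pen

    for sel, _ref in domains:
        dom = x[sel].copy()
        center = dom.mean(axis=0)

        def objective(p, dom=dom, center=center, sel=sel):
            R = _Rot.from_rotvec(p[:3]).as_matrix()
            trial = x.copy()
            trial[sel] = (dom - center) @ R.T + center + p[3:]
            return score(trial)

        base = objective(np.zeros(6))
        res = minimize(objective, np.zeros(6), method="Powell",
                       options={"maxiter": 200, "xtol": 1e-3, "ftol": 1e-5})
        if res.fun < base:
            R = _Rot.from_rotvec(res.x[:3]).as_matrix()
            x[sel] = (dom - center) @ R.T + center + res.x[3:]
    return x


# ---------------------------------------------------------------------------
# simple table statistics


def concentration_qmax_correlation(table) -> float:
    """Pearson correlation between loaded concentration and usable q_max.

    ``table`` is a pandas DataFrame with columns 'concentration' and
    'q_max', or any sequence of (concentration, q_max) pairs.
    """
    try:
        conc = np.asarray(table["concentration"], dtype=float)
        qmax = np.asarray(table["q_max"], dtype=float)
    except (TypeError, IndexError, KeyError):
        arr = np.asarray(table, dtype=float).reshape(-1, 2)
        conc, qmax = arr[:, 0], arr[:, 1]
    if conc.size < 3:
        raise ValueError("need at least 3 (concentration, q_max) pairs")
    if np.std(conc) == 0 or np.std(qmax) == 0:
        raise ValueError("zero variance in correlation input")
    r, _ = stats.pearsonr(conc, qmax)
    return float(r)
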