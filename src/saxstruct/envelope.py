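"""Ab initio dummy-atom shape reconstruction and envelope handling.

A bead model is a binary occupancy state over a hexagonally close-packed
lattice filling a sphere of diameter Dmax. Simulated annealing minimizes

    E = chi^2(Debye profile of occupied beads, data)
        + lambda * (looseness + disconnectivity)

where looseness is the mean fraction of empty neighbor sites over occupied
beads (favoring compact shapes) and disconnectivity counts occupied beads
outside the largest connected component. Moves are single-bead flips over
the occupied set and its empty boundary; cooling is geometric per plateau.
Multiple seeded runs are aligned by normalized spatial discrepancy (NSD),
occupancy-averaged on a common lattice, volume-corrected, and optionally
refined by a cold restart with the high-occupancy core frozen.

Chirality note: a scattering curve cannot distinguish enantiomers, so NSD
alignment scores both hands and keeps the better one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .curves import ScatteringCurve
from .secsaxs import rebin
from .structures import AtomicModel, BeadModel, DensityGrid

logger = logging.getLogger("saxstruct")

__all__ = [
    "AnnealParams", "anneal_beads", "align_nsd", "compute_nsd",
    "average_models", "AverageResult", "refine_beads", "bead_density",
    "hcp_lattice", "DensityGrid",
]


# ---------------------------------------------------------------------------
# lattice


def hcp_lattice(diameter: float, bead_radius: float) -> np.ndarray:
    """Hexagonally close-packed sites filling a sphere of the given diameter."""
    a = 2.0 * bead_radius
    basis = np.array([
        [a, 0.0, 0.0],
        [a / 2.0, a * np.sqrt(3.0) / 2.0, 0.0],
        [a / 2.0, a / (2.0 * np.sqrt(3.0)), a * np.sqrt(2.0 / 3.0)],
    ])
    R = diameter / 2.0
    n = int(np.ceil(R / (a * np.sqrt(2.0 / 3.0)))) + 2
    rng = np.arange(-2 * n, 2 * n + 1)
    I, J, K = np.meshgrid(rng, rng, rng, indexing="ij")
    ijk = np.column_stack([I.ravel(), J.ravel(), K.ravel()])
    pts = ijk @ basis
    keep = np.einsum("ij,ij->i", pts, pts) <= R * R
    return pts[keep]


@dataclass
class AnnealParams:
    """Tunables of the bead-model annealing schedule."""

    bead_radius: float | None = None   # default Dmax/20
    n_q_fit: int = 50                  # curve is re-binned to this many points
    init_fill: float | None = None     # None: from the Porod-volume bead count
    q_fit_max: float | None = None     # None: 8/Rg (shape-information band)
    lambda_scale: float = 0.1          # penalty weight relative to start balance
    cooling: float = 0.9               # geometric temperature factor
    moves_per_level: int | None = None  # default 3 x n_sites
    stop_acceptance: float = 0.01
    max_moves: int = 60_000
    start_temperature: float | None = None  # default: ~50% uphill acceptance


class _BeadState:
    """Incremental Debye/penalty bookkeeping over a fixed site lattice."""

    def __init__(self, sites: np.ndarray, curve: ScatteringCurve,
                 bead_radius: float, n_q: int, q_fit_max: float | None = None):
        self.sites = sites
        n = sites.shape[0]
        if q_fit_max is not None and curve.q[0] < q_fit_max:
            curve = curve.truncate(q_max=q_fit_max)
        fit_curve = rebin(curve, mode="log", n_points=n_q) if len(curve) > n_q else curve
        self.q = fit_curve.q
        self.Ie = fit_curve.I
        sigma = fit_curve.sigma if fit_curve.sigma is not None else np.full_like(self.Ie, 1.0)
        self.w = 1.0 / sigma**2
        # solid-sphere bead form factor (Guinier-level approximation);
        # without it the flat point-scatterer self-term biases the search
        self.ff2 = np.exp(-(self.q**2) * bead_radius**2 / 5.0)
        self.sww = float(np.sum(self.w * self.Ie**2))
        # pair distances quantized to 0.1 A -> shared sinc lookup table
        diff = sites[:, None, :] - sites[None, :, :]
        d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        self.bin_width = 0.1
        self.bins = np.rint(d / self.bin_width).astype(np.int32)
        n_bins = int(self.bins.max()) + 1
        d_table = np.arange(n_bins) * self.bin_width
        self.sinc = np.sinc(np.outer(d_table, self.q) / np.pi)  # (n_bins, n_q)
        # neighbor bookkeeping (up to 12 HCP contacts)
        tree = cKDTree(sites)
        pairs = tree.query_pairs(2.0 * bead_radius * 1.05, output_type="ndarray")
        nb_lists: list[list[int]] = [[] for _ in range(n)]
        for i, j in pairs:
            nb_lists[i].append(j)
            nb_lists[j].append(i)
        self.max_nb = max((len(x) for x in nb_lists), default=1)
        self.nb = np.full((n, self.max_nb), -1, dtype=np.int32)
        for i, lst in enumerate(nb_lists):
            self.nb[i, : len(lst)] = lst
        self.n_nb = np.array([len(x) for x in nb_lists], dtype=np.int32)
        self.occ = np.zeros(n, dtype=bool)
        self.occ_nb = np.zeros(n, dtype=np.int32)  # occupied neighbors per site
        self.S = np.zeros_like(self.q)             # sum over occupied pairs of sinc
        self.n_occ = 0
        self.disc = 0

    # -- state manipulation -------------------------------------------------

    def set_occupancy(self, occ: np.ndarray) -> None:
        self.occ = occ.astype(bool).copy()
        self.n_occ = int(self.occ.sum())
        idx = np.flatnonzero(self.occ)
        self.S[:] = 0.0
        for k in idx:
            others = idx[idx > k]
            if others.size:
                self.S += self.sinc[self.bins[k, others]].sum(axis=0)
        self.occ_nb[:] = 0
        for k in idx:
            nbk = self.nb[k, : self.n_nb[k]]
            self.occ_nb[nbk] += 1
        self.disc = self._disconnect(self.occ)

    def delta_S(self, k: int) -> np.ndarray:
        idx = np.flatnonzero(self.occ)
        idx = idx[idx != k]
        if idx.size == 0:
            return np.zeros_like(self.q)
        return self.sinc[self.bins[k, idx]].sum(axis=0)

    def chi2_of(self, n_occ: int, S: np.ndarray) -> float:
        if n_occ == 0:
            return np.inf
        Im = (n_occ + 2.0 * S) * self.ff2
        swc = float(np.sum(self.w * self.Ie * Im))
        scc = float(np.sum(self.w * Im * Im))
        if scc <= 0:
            return np.inf
        c = swc / scc
        chi2 = (self.sww - c * swc) / max(self.q.size - 1, 1)
        return max(chi2, 0.0)

    def looseness_of(self, occ: np.ndarray, occ_nb: np.ndarray) -> float:
        idx = np.flatnonzero(occ)
        if idx.size == 0:
            return 1.0
        frac_empty = 1.0 - occ_nb[idx] / np.maximum(self.n_nb[idx], 1)
        return float(frac_empty.mean())

    def _disconnect(self, occ: np.ndarray) -> int:
        """Occupied beads outside the largest connected component."""
        n_occ = int(occ.sum())
        if n_occ == 0:
            return 0
        visited = np.zeros_like(occ)
        best = 0
        remaining = n_occ
        for start in np.flatnonzero(occ):
            if visited[start]:
                continue
            size = self._bfs(occ, visited, int(start))
            best = max(best, size)
            remaining -= size
            if remaining <= best:
                break
        # finish marking for correctness of later starts is unnecessary:
        # best can no longer be beaten once remaining <= best
        return n_occ - best

    def _bfs(self, occ: np.ndarray, visited: np.ndarray, start: int) -> int:
        frontier = np.array([start], dtype=np.int64)
        visited[start] = True
        size = 1
        scratch = np.zeros(occ.size, dtype=bool)
        while frontier.size:
            cand = self.nb[frontier].ravel()
            cand = cand[cand >= 0]
            # boolean scatter deduplicates without sorting
            scratch[cand] = True
            scratch &= occ & ~visited
            cand = np.flatnonzero(scratch)
            scratch[cand] = False
            visited[cand] = True
            size += cand.size
            frontier = cand
        return size

    def disconnect_after_flip(self, k: int) -> int:
        """Disconnectivity of the state with site k flipped (shortcuts where
        the answer is implied; BFS otherwise)."""
        occ_k_nbrs = int(self.occ_nb[k])
        if not self.occ[k]:
            # addition
            if self.disc == 0:
                return 0 if (occ_k_nbrs > 0 or self.n_occ == 0) else 1
            occ2 = self.occ.copy()
            occ2[k] = True
            return self._disconnect(occ2)
        # removal
        if occ_k_nbrs <= 1:
            # leaf or isolated bead cannot split the remainder
            was_isolated = occ_k_nbrs == 0
            if self.n_occ == 1:
                return 0
            if was_isolated:
                return max(self.disc - 1, 0)
            return self.disc
        if self.disc == 0 and self._neighbors_connected_without(k):
            return 0  # interior bead of a single connected component
        occ2 = self.occ.copy()
        occ2[k] = False
        return self._disconnect(occ2)

    def _neighbors_connected_without(self, k: int) -> bool:
        """True if k's occupied neighbors stay mutually connected when k is
        removed (early-exit BFS; usually resolves within a couple of hops)."""
        nbk = self.nb[k, : self.n_nb[k]]
        targets = nbk[self.occ[nbk]]
        if targets.size <= 1:
            return True
        occ = self.occ
        visited = np.zeros(occ.size, dtype=bool)
        visited[k] = True  # excluded from paths
        frontier = targets[:1].astype(np.int64)
        visited[frontier] = True
        found = 1
        target_mask = np.zeros(occ.size, dtype=bool)
        target_mask[targets] = True
        scratch = np.zeros(occ.size, dtype=bool)
        while frontier.size:
            cand = self.nb[frontier].ravel()
            cand = cand[cand >= 0]
            scratch[cand] = True
            scratch &= occ & ~visited
            cand = np.flatnonzero(scratch)
            scratch[cand] = False
            visited[cand] = True
            found += int(np.count_nonzero(target_mask[cand]))
            if found == targets.size:
                return True
            frontier = cand
        return False

    def apply_flip(self, k: int, dS: np.ndarray, disc_new: int) -> None:
        if self.occ[k]:
            self.S -= dS
            self.occ[k] = False
            self.n_occ -= 1
            nbk = self.nb[k, : self.n_nb[k]]
            self.occ_nb[nbk] -= 1
        else:
            self.S += dS
            self.occ[k] = True
            self.n_occ += 1
            nbk = self.nb[k, : self.n_nb[k]]
            self.occ_nb[nbk] += 1
        self.disc = disc_new

    def candidate_sites(self) -> np.ndarray:
        """Occupied sites plus empty sites touching an occupied one."""
        boundary = (~self.occ) & (self.occ_nb > 0)
        return np.flatnonzero(self.occ | boundary)

    def energy_terms(self) -> tuple[float, float, int]:
        chi2 = self.chi2_of(self.n_occ, self.S)
        loose = self.looseness_of(self.occ, self.occ_nb)
        return chi2, loose, self.disc


def _anneal_one(
    state: _BeadState,
    rng: np.random.Generator,
    params: AnnealParams,
    lam: float,
    t0: float,
    frozen: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Run one annealing schedule; returns (best occupancy, best energy)."""

    def energy(chi2: float, loose: float, disc: int) -> float:
        return chi2 + lam * (loose + disc)

    chi2, loose, disc = state.energy_terms()
    e_cur = energy(chi2, loose, disc)
    best_occ = state.occ.copy()
    e_best = e_cur
    T = t0
    moves_per_level = params.moves_per_level or 3 * state.sites.shape[0]
    total = 0
    while total < params.max_moves:
        accepted = 0
        attempted = 0
        for _ in range(moves_per_level):
            total += 1
            attempted += 1
            cands = state.candidate_sites()
            if frozen is not None:
                cands = cands[~frozen[cands]]
            if cands.size == 0:
                break
            k = int(cands[rng.integers(cands.size)])
            dS = state.delta_S(k)
            if state.occ[k]:
                n_new, S_new = state.n_occ - 1, state.S - dS
                d_nb = -1
            else:
                n_new, S_new = state.n_occ + 1, state.S + dS
                d_nb = +1
            if n_new == 0:
                continue
            disc_new = state.disconnect_after_flip(k)
            chi2_new = state.chi2_of(n_new, S_new)
            # looseness after flip via neighbor counters
            occ_nb = state.occ_nb
            nbk = state.nb[k, : state.n_nb[k]]
            occ_nb[nbk] += d_nb
            occ2 = state.occ
            occ2[k] = not occ2[k]
            loose_new = state.looseness_of(occ2, occ_nb)
            occ2[k] = not occ2[k]
            occ_nb[nbk] -= d_nb
            e_new = energy(chi2_new, loose_new, disc_new)
            dE = e_new - e_cur
            if dE <= 0 or rng.random() < np.exp(-dE / max(T, 1e-12)):
                state.apply_flip(k, dS, disc_new)
                e_cur = e_new
                accepted += 1
                if e_cur < e_best:
                    e_best = e_cur
                    best_occ = state.occ.copy()
            if total >= params.max_moves:
                break
        if attempted == 0 or accepted / max(attempted, 1) < params.stop_acceptance:
            break
        T *= params.cooling
    return best_occ, e_best


def _initial_temperature(state: _BeadState, rng: np.random.Generator,
                         lam: float, n_probe: int = 60) -> float:
    """Temperature at which ~50% of uphill moves would be accepted."""
    chi2, loose, disc = state.energy_terms()
    e0 = chi2 + lam * (loose + disc)
    ups = []
    for _ in range(n_probe):
        cands = state.candidate_sites()
        k = int(cands[rng.integers(cands.size)])
        dS = state.delta_S(k)
        if state.occ[k]:
            n_new, S_new = state.n_occ - 1, state.S - dS
        else:
            n_new, S_new = state.n_occ + 1, state.S + dS
        if n_new == 0:
            continue
        disc_new = state.disconnect_after_flip(k)
        chi2_new = state.chi2_of(n_new, S_new)
        e_new = chi2_new + lam * (state.looseness_of(state.occ, state.occ_nb) + disc_new)
        if e_new > e0:
            ups.append(e_new - e0)
    if not ups:
        return 1.0
    return float(np.median(ups) / np.log(2.0))


def anneal_beads(
    curve: ScatteringCurve,
    dd,
    n_runs: int = 20,
    params: AnnealParams | None = None,
    seed: int = 0,
) -> list[BeadModel]:
    """Generate ``n_runs`` independent bead-model reconstructions.

    ``dd`` supplies Dmax (a DistanceDistribution or a plain float). Each
    run anneals a fresh random occupancy with its own sub-seed; a fixed
    ``seed`` reproduces the whole ensemble bit for bit.
    """
    params = params or AnnealParams()
    dmax = float(getattr(dd, "dmax", dd))
    bead_radius = params.bead_radius or dmax / 20.0
    if dmax < 8.0 * bead_radius:
        raise ValueError("Dmax smaller than 4 bead diameters")
    sites = hcp_lattice(dmax, bead_radius)
    q_fit_max = params.q_fit_max
    if q_fit_max is None:
        rg_est = getattr(dd, "rg_real", None)
        q_fit_max = 8.0 / rg_est if rg_est else None
    fill = params.init_fill
    if fill is None:
        # start near the expected particle volume (Porod estimate) so the
        # anneal optimizes shape, not gross size
        try:
            from .guinier_pr import estimate_mw

            v_est = estimate_mw(curve, dd) * 1000.0 * 1.6
            n_init = v_est / ((4.0 / 3.0) * np.pi * bead_radius**3)
            fill = float(np.clip(n_init / sites.shape[0], 0.02, 0.6))
        except (ValueError, AttributeError, TypeError):
            fill = 0.25
    models = []
    for run in range(n_runs):
        rng = np.random.default_rng((seed + run) % (2**31))
        state = _BeadState(sites, curve, bead_radius, params.n_q_fit,
                           q_fit_max=q_fit_max)
        occ0 = rng.random(sites.shape[0]) < fill
        if not occ0.any():
            occ0[rng.integers(sites.shape[0])] = True
        state.set_occupancy(occ0)
        chi2_0, loose_0, disc_0 = state.energy_terms()
        lam = params.lambda_scale * chi2_0 / max(loose_0 + disc_0, 1e-6)
        t0 = params.start_temperature or _initial_temperature(state, rng, lam)
        best_occ, e_best = _anneal_one(state, rng, params, lam, t0)
        centers = sites[best_occ]
        models.append(BeadModel(centers=centers, bead_radius=bead_radius,
                                label=f"anneal run {run}"))
        logger.info("anneal run %d: %d beads, E = %.3f", run, centers.shape[0], e_best)
    return models


# ---------------------------------------------------------------------------
# NSD alignment


def _points_of(model) -> np.ndarray:
    if isinstance(model, BeadModel):
        return model.centers
    if isinstance(model, AtomicModel):
        return model.ca_coords()
    return np.asarray(model, dtype=float).reshape(-1, 3)


def compute_nsd(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Normalized spatial discrepancy between two point sets (no alignment).

    NSD^2 = 1/2 [ (1/(N1 d2^2)) sum_i min_j |a_i - b_j|^2
                + (1/(N2 d1^2)) sum_j min_i |b_j - a_i|^2 ],
    with d_k the mean nearest-neighbor distance within set k.
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 3)
    b = np.asarray(points_b, dtype=float).reshape(-1, 3)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("NSD needs at least 2 points per set")
    d_a = float(cKDTree(a).query(a, k=2)[0][:, 1].mean())
    d_b = float(cKDTree(b).query(b, k=2)[0][:, 1].mean())
    ab = cKDTree(b).query(a)[0]
    ba = cKDTree(a).query(b)[0]
    nsd2 = 0.5 * (np.mean(ab**2) / d_b**2 + np.mean(ba**2) / d_a**2)
    return float(np.sqrt(nsd2))


def _pca_axes(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt.T  # columns = principal axes


def align_nsd(reference, mobile, refine: bool = True):
    """Optimal NSD superposition of ``mobile`` onto ``reference``.

    The search covers centroid superposition, principal-axis alignment
    over all 8 axis-sign combinations (including improper ones — the
    enantiomer is indistinguishable by SAXS), and an optional local
    rotation/translation refinement. Returns ``((R, t), nsd)`` with the
    transform acting as ``x -> x @ R.T + t``.
    """
    ref = _points_of(reference)
    mob = _points_of(mobile)
    if ref.shape[0] < 2 or mob.shape[0] < 2:
        raise ValueError("alignment needs at least 2 points per model")
    c_ref = ref.mean(axis=0)
    c_mob = mob.mean(axis=0)
    V_ref = _pca_axes(ref)
    V_mob = _pca_axes(mob)
    mob0 = mob - c_mob
    best = None
    for signs in np.array(np.meshgrid([1, -1], [1, -1], [1, -1])).T.reshape(-1, 3):
        R = V_ref @ np.diag(signs) @ V_mob.T
        moved = mob0 @ R.T + c_ref
        val = compute_nsd(ref, moved)
        if best is None or val < best[0]:
            best = (val, R)
    val, R0 = best
    if refine:
        from scipy.optimize import minimize

        def objective(x):
            R = Rotation.from_rotvec(x[:3]).as_matrix() @ R0
            moved = mob0 @ R.T + c_ref + x[3:]
            return compute_nsd(ref, moved)

        res = minimize(objective, np.zeros(6), method="Powell",
                       options={"maxiter": 300, "xtol": 1e-3, "ftol": 1e-4})
        if res.fun < val:
            val = float(res.fun)
            R0 = Rotation.from_rotvec(res.x[:3]).as_matrix() @ R0
            t_extra = res.x[3:]
        else:
            t_extra = np.zeros(3)
    else:
        t_extra = np.zeros(3)
    t = c_ref + t_extra - c_mob @ R0.T
    return (R0, t), val


# ---------------------------------------------------------------------------
# averaging and refinement


@dataclass
class AverageResult:
    """Outcome of multi-reconstruction averaging."""

    averaged: BeadModel            # volume-corrected consensus model
    occupancy_map: BeadModel       # all lattice sites with occupancy in [0,1]
    mean_pairwise_nsd: float
    excluded: list[int] = field(default_factory=list)
    pairwise_nsd: np.ndarray | None = None
    reference_index: int = 0


def average_models(models: list[BeadModel], refine_alignment: bool = True) -> AverageResult:
    """Align, occupancy-average, and volume-correct an ensemble of bead models.

    All models are aligned to the one with the lowest mean NSD to the
    others; models whose NSD to the reference exceeds the leave-one-out
    mean + 2 SD of the remaining models are excluded as outliers. Beads are snapped to a common lattice; occupancy is the
    fraction of models populating a site. The volume-corrected model keeps
    the top-occupancy sites down to the median single-model bead count.
    """
    n = len(models)
    if n < 2:
        raise ValueError("averaging needs at least 2 models")
    nsd_mat = np.zeros((n, n))
    transforms: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            (R, t), val = align_nsd(models[i], models[j], refine=refine_alignment)
            nsd_mat[i, j] = nsd_mat[j, i] = val
            transforms[(i, j)] = (R, t)
    mean_to_others = nsd_mat.sum(axis=1) / (n - 1)
    ref_idx = int(np.argmin(mean_to_others))
    # leave-one-out mean + 2 SD: a single outlier must not inflate the
    # statistics that are supposed to catch it
    others = np.array([i for i in range(n) if i != ref_idx])
    vals = nsd_mat[ref_idx, others]
    excluded = []
    for pos, i in enumerate(others):
        rest = np.delete(vals, pos)
        if rest.size == 0:
            continue  # two models: no peers to judge an outlier against
        cut = rest.mean() + 2.0 * rest.std(ddof=0) + 0.05
        if vals[pos] > cut:
            excluded.append(int(i))
    keep = [i for i in range(n) if i not in excluded]
    if excluded:
        logger.info("average_models: excluded outliers %s", excluded)
    aligned = []
    for i in keep:
        if i == ref_idx:
            aligned.append(models[i].centers)
        else:
            key = (min(ref_idx, i), max(ref_idx, i))
            R, t = transforms[key]
            if key[1] == i:
                aligned.append(models[i].centers @ R.T + t)
            else:
                # stored transform maps i's partner onto i; invert it
                aligned.append((models[i].centers - t) @ R)
    radius = models[ref_idx].bead_radius
    all_pts = np.vstack(aligned)
    center = all_pts.mean(axis=0)
    span = float(np.linalg.norm(all_pts - center, axis=1).max()) + 2 * radius
    lattice = hcp_lattice(2 * span, radius) + center
    tree = cKDTree(lattice)
    counts = np.zeros(lattice.shape[0])
    for pts in aligned:
        idx = np.unique(tree.query(pts)[1])
        counts[idx] += 1.0
    occ_frac = counts / len(keep)
    used = occ_frac > 0
    occupancy_map = BeadModel(centers=lattice[used], bead_radius=radius,
                              occupancy=occ_frac[used], label="occupancy map")
    n_target = int(np.median([len(m) for m in (models[i] for i in keep)]))
    order = np.lexsort((
        np.linalg.norm(lattice[used] - center, axis=1),
        -occ_frac[used],
    ))
    chosen = order[:n_target]
    averaged = BeadModel(centers=lattice[used][chosen], bead_radius=radius,
                         label="averaged model")
    iu = np.triu_indices(n, k=1)
    return AverageResult(
        averaged=averaged,
        occupancy_map=occupancy_map,
        mean_pairwise_nsd=float(nsd_mat[iu].mean()),
        excluded=excluded,
        pairwise_nsd=nsd_mat,
        reference_index=ref_idx,
    )


def refine_beads(
    start: BeadModel,
    curve: ScatteringCurve,
    seed: int = 0,
    params: AnnealParams | None = None,
    core_occupancy: float = 0.7,
    start_occupancy: float = 0.5,
    temperature_factor: float = 0.01,
) -> BeadModel:
    """Cold-restart refinement of an averaged model against the data.

    The search space is the start model's own lattice (for an occupancy
    map, the union support of all reconstructions). Sites with occupancy
    >= ``core_occupancy`` are frozen in; annealing runs at a low
    temperature so the move sequence is mostly downhill. The returned
    model's profile chi^2 never exceeds the start configuration's.
    """
    params = params or AnnealParams()
    rng = np.random.default_rng(seed % (2**31))
    sites = start.centers
    q_fit_max = params.q_fit_max
    if q_fit_max is None:
        from .profile import model_rg

        core = BeadModel(centers=start.centers[start.occupancy >= start_occupancy]
                         if np.any(start.occupancy >= start_occupancy)
                         else start.centers,
                         bead_radius=start.bead_radius)
        q_fit_max = 8.0 / model_rg(core)
    state = _BeadState(sites, curve, start.bead_radius, params.n_q_fit,
                       q_fit_max=q_fit_max)
    occ0 = start.occupancy >= start_occupancy
    if not occ0.any():
        occ0 = start.occupancy >= float(np.median(start.occupancy))
    frozen = start.occupancy >= core_occupancy
    state.set_occupancy(occ0)
    chi2_start = state.chi2_of(state.n_occ, state.S)
    chi2_0, loose_0, disc_0 = state.energy_terms()
    lam = params.lambda_scale * chi2_0 / max(loose_0 + disc_0, 1e-6)
    t0 = temperature_factor * _initial_temperature(state, rng, lam)
    best_occ, _ = _anneal_one(state, rng, params, lam, t0, frozen=frozen)
    # guarantee: never worse in chi^2 than the start configuration
    state.set_occupancy(best_occ)
    if state.chi2_of(state.n_occ, state.S) > chi2_start:
        best_occ = occ0
    best_occ = best_occ | frozen
    return BeadModel(centers=sites[best_occ], bead_radius=start.bead_radius,
                     label="refined model")


# ---------------------------------------------------------------------------
# density maps


def bead_density(
    model: BeadModel,
    voxel: float = 3.0,
    kernel_sigma: float | None = None,
) -> DensityGrid:
    """Occupancy-weighted Gaussian-kernel density of a bead model.

    Each bead contributes a normalized 3-D Gaussian (sigma defaults to the
    bead radius) so the grid integral equals the total occupancy; the grid
    is padded by 3 sigma on all sides.
    """
    sigma = kernel_sigma if kernel_sigma is not None else model.bead_radius
    pad = 3.0 * sigma
    lo = model.centers.min(axis=0) - pad
    hi = model.centers.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 2)
    values = np.zeros(shape)
    axes = [lo[d] + voxel * np.arange(shape[d]) for d in range(3)]
    norm = (2.0 * np.pi * sigma**2) ** -1.5
    reach = 4.0 * sigma
    for c, w in zip(model.centers, model.occupancy):
        sl = []
        local_axes = []
        for d in range(3):
            a = int(np.searchsorted(axes[d], c[d] - reach))
            b = int(np.searchsorted(axes[d], c[d] + reach))
            sl.append(slice(a, b))
            local_axes.append(axes[d][a:b])
        dx2 = [(ax - c[d]) ** 2 for d, ax in enumerate(local_axes)]
        g = np.exp(-(dx2[0][:, None, None] + dx2[1][None, :, None]
                     + dx2[2][None, None, :]) / (2.0 * sigma**2))
        values[sl[0], sl[1], sl[2]] += w * norm * g
    return DensityGrid(origin=lo, voxel=voxel, values=values)
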