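"""Protein angular value (PAV) profiles and ensemble comparison.

PAV folds the two backbone dihedrals of a residue into a single bounded
descriptor:

    PAV_i = (180/pi) * arccos(cos(psi_i + phi_i)),

so it depends only on the sum phi+psi and lives in [0, 180] degrees
regardless of how the circular angles wrap. Profiles from an ensemble of
models are stacked into a models x residues matrix (restricted to shared
residue indices) and compared by PCA and average-linkage hierarchical
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .structures import AtomicModel

CHAIN_BREAK_CA = 4.5  # A; larger CA-CA gaps break phi/psi continuity


@dataclass
class PAVProfile:
    """Per-residue PAV values of one model."""

    residue_index: np.ndarray
    pav: np.ndarray           # degrees in [0, 180]
    model_label: str = ""

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.pav = np.asarray(self.pav, dtype=float)
        if self.residue_index.shape != self.pav.shape:
            raise ValueError("residue_index and pav must match")
        finite = np.isfinite(self.pav)
        if np.any((self.pav[finite] < 0) | (self.pav[finite] > 180)):
            raise ValueError("PAV values must lie in [0, 180] degrees")


def pav_from_angles(phi_deg: np.ndarray, psi_deg: np.ndarray) -> np.ndarray:
    """PAV = (180/pi) arccos(cos(psi + phi)), angles in degrees."""
    total = np.deg2rad(np.asarray(phi_deg, dtype=float)
                       + np.asarray(psi_deg, dtype=float))
    return np.rad2deg(np.arccos(np.clip(np.cos(total), -1.0, 1.0)))


def _dihedral(p0, p1, p2, p3) -> float:
    """IUPAC torsion angle in degrees for four points."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(model: AtomicModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(residue_index, phi, psi) in degrees for residues with full backbone.

    phi_i needs C(i-1), N(i), CA(i), C(i); psi_i needs N(i), CA(i), C(i),
    N(i+1). Chain breaks (consecutive CA farther than 4.5 A) interrupt
    continuity, yielding NaN dihedrals at the flanking residues.
    """
    atoms: dict[tuple[int, str], np.ndarray] = {}
    for i in range(len(model)):
        if model.hetero[i]:
            continue
        name = str(model.atom_name[i]).strip()
        if name in ("N", "CA", "C"):
            atoms[(int(model.residue_index[i]), name)] = model.coords[i]
    residues = sorted({k[0] for k in atoms if all(
        (k[0], nm) in atoms for nm in ("N", "CA", "C"))})
    if len(residues) < 3:
        raise ValueError("need at least 3 residues with N, CA, C atoms")

    def contiguous(r1: int, r2: int) -> bool:
        if r2 != r1 + 1:
            return False
        ca1, ca2 = atoms.get((r1, "CA")), atoms.get((r2, "CA"))
        if ca1 is None or ca2 is None:
            return False
        return bool(np.linalg.norm(ca2 - ca1) <= CHAIN_BREAK_CA)

    idx, phis, psis = [], [], []
    rset = set(residues)
    for r in residues:
        phi = np.nan
        psi = np.nan
        if (r - 1) in rset and contiguous(r - 1, r):
            phi = _dihedral(atoms[(r - 1, "C")], atoms[(r, "N")],
                            atoms[(r, "CA")], atoms[(r, "C")])
        if (r + 1) in rset and contiguous(r, r + 1):
            psi = _dihedral(atoms[(r, "N")], atoms[(r, "CA")],
                            atoms[(r, "C")], atoms[(r + 1, "N")])
        idx.append(r)
        phis.append(phi)
        psis.append(psi)
    return np.array(idx), np.array(phis), np.array(psis)


def pav_profile(model: AtomicModel) -> PAVProfile:
    """PAV profile of a model with full N/CA/C backbone.

    Residues missing either dihedral (chain termini, chain breaks) are
    omitted.
    """
    idx, phi, psi = backbone_dihedrals(model)
    good = np.isfinite(phi) & np.isfinite(psi)
    if not np.any(good):
        raise ValueError("no residue has both phi and psi defined")
    return PAVProfile(residue_index=idx[good],
                      pav=pav_from_angles(phi[good], psi[good]),
                      model_label=model.label)


def pav_matrix(profiles: list[PAVProfile | AtomicModel]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack PAV profiles into a (models x shared residues) matrix.

    Residues absent from any model are excluded column-wise. Returns
    (matrix, shared residue indices, model labels).
    """
    profs = [p if isinstance(p, PAVProfile) else pav_profile(p) for p in profiles]
    if len(profs) < 2:
        raise ValueError("need at least 2 models")
    shared = profs[0].residue_index
    for p in profs[1:]:
        shared = np.intersect1d(shared, p.residue_index)
    if shared.size == 0:
        raise ValueError("models share no residues")
    if shared.size < 10:
        raise ValueError("models share fewer than 10 residues")
    rows = []
    for p in profs:
        pos = {int(r): v for r, v in zip(p.residue_index, p.pav)}
        rows.append([pos[int(r)] for r in shared])
    return np.array(rows), shared, [p.model_label for p in profs]


def pca(matrix: np.ndarray, n_components: int = 2):
    """Column-mean-centered PCA of a models x residues matrix.

    Returns (scores, loadings, explained variance fractions); with zero
    total variance (identical rows) all fractions are zero.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    n_components = min(n_components, X.shape[0], X.shape[1])
    Xc = X - X.mean(axis=0, keepdims=True)
    total_var = float(np.sum(Xc**2))
    if total_var == 0.0:
        return (np.zeros((X.shape[0], n_components)),
                np.zeros((n_components, X.shape[1])),
                np.zeros(n_components))
    from sklearn.decomposition import PCA as _PCA

    p = _PCA(n_components=n_components, svd_solver="full")
    scores = p.fit_transform(X)
    return scores, p.components_, p.explained_variance_ratio_


def hcluster(
    matrix: np.ndarray,
    k: int | None = None,
    linkage: str = "average",
    metric: str = "euclidean",
):
    """Agglomerative clustering of PAV profiles.

    Returns (scipy linkage matrix, labels at ``k`` clusters or None).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    labels = None
    if k is not None:
        if k > X.shape[0]:
            raise ValueError("cannot request more clusters than rows")
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Z, labels
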