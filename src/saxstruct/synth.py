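"""Synthetic ground-truth generators for the whole pipeline.

Everything the analysis stages consume can be produced here with known
truth: multi-domain C-alpha toy structures (domains as lattice-filled
spheres/ellipsoids joined by extended linkers), simulated scattering
curves with q-dependent noise, closed-form sphere oracles, and SEC-SAXS
frame series emulating a two-peak elution with an optional leading
shoulder. Outputs carry a JSON-serializable manifest of their ground
truth and every stochastic step is seed-reproducible.

Defaults mirror a synchrotron SEC-SAXS setup: q on [0.0026, 0.340] A^-1,
relative noise a = 0.01 growing toward high q (b = 4), 3 s frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .constants import CA_CA_DISTANCE
from .curves import FrameSeries, ScatteringCurve
from .profile import debye_profile
from .structures import AtomicModel

DEFAULT_Q_GRID = np.linspace(0.0026, 0.340, 512)
DEFAULT_NOISE = (0.01, 4.0)  # (a, b): sigma(q) = a*I(q)*(1 + b*q/q_max)


@dataclass
class DomainSpec:
    """One globular domain of a toy structure."""

    shape: str = "sphere"          # 'sphere' or 'ellipsoid'
    radius: float | tuple[float, float, float] = 15.0  # A; 3 semi-axes if ellipsoid
    name: str = "domain"

    def semiaxes(self) -> np.ndarray:
        if self.shape == "sphere":
            return np.full(3, float(self.radius))
        if self.shape == "ellipsoid":
            ax = np.asarray(self.radius, dtype=float).reshape(3)
            return ax
        raise ValueError(f"unknown domain shape {self.shape!r}")


@dataclass
class ToyStructure:
    """A generated model together with its ground truth."""

    model: AtomicModel
    rg: float                      # uniform-weight C-alpha Rg, A
    dmax: float                    # maximum intra-particle distance, A
    domain_ranges: list[tuple[int, int]]
    manifest: dict = field(default_factory=dict)


def _fill_ellipsoid(semiaxes: np.ndarray, spacing: float) -> np.ndarray:
    """C-alpha sites on a cubic lattice inside an ellipsoid."""
    ax = np.asarray(semiaxes, dtype=float)
    n = np.ceil(ax / spacing).astype(int)
    grids = [np.arange(-k, k + 1) * spacing for k in n]
    X, Y, Z = np.meshgrid(*grids, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = np.sum((pts / ax) ** 2, axis=1) <= 1.0
    return _serpentine_order(pts[inside], spacing)


def _serpentine_order(pts: np.ndarray, spacing: float) -> np.ndarray:
    """Boustrophedon ordering so consecutive points are (near-)bonded.

    Emulates a chain threading the domain: z runs alternate direction per
    (x, y) column, y columns alternate per x slab, so consecutive C-alpha
    distances are one lattice step except for short hops at column ends.
    """
    key = np.rint(pts / spacing).astype(int)
    order = []
    xs = np.unique(key[:, 0])
    for si, xv in enumerate(xs):
        slab = np.flatnonzero(key[:, 0] == xv)
        ys = np.unique(key[slab, 1])
        if si % 2:
            ys = ys[::-1]
        for ci, yv in enumerate(ys):
            col = slab[key[slab, 1] == yv]
            col = col[np.argsort(key[col, 2])]
            if (si + ci) % 2:
                col = col[::-1]
            order.extend(col.tolist())
    return pts[np.array(order)]


def make_toy_structure(
    domains: list[DomainSpec | dict],
    linker_residues: list[int] | None = None,
    seed: int = 0,
    spacing: float = CA_CA_DISTANCE,
    max_attempts: int = 100,
) -> ToyStructure:
    """Build a C-alpha-level multi-domain model with known Rg and Dmax.

    Each domain is a sphere/ellipsoid filled on a ``spacing`` lattice;
    consecutive domains are joined by extended linkers of the requested
    residue counts. Domain centers are placed sequentially in seeded
    random directions; placements that overlap a previous domain are
    retried (up to ``max_attempts``).
    """
    if not domains:
        raise ValueError("need at least one domain")
    specs = [d if isinstance(d, DomainSpec) else DomainSpec(**d) for d in domains]
    if linker_residues is None:
        linker_residues = [10] * (len(specs) - 1)
    if len(linker_residues) != len(specs) - 1:
        raise ValueError("need one linker length per adjacent domain pair")
    rng = np.random.default_rng(seed)

    centers = [np.zeros(3)]
    radii = [float(np.max(specs[0].semiaxes()))]
    for i in range(1, len(specs)):
        r_new = float(np.max(specs[i].semiaxes()))
        gap = (linker_residues[i - 1] + 1) * spacing
        dist = radii[-1] + gap + r_new
        placed = False
        for _ in range(max_attempts):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = centers[-1] + u * dist
            ok = all(
                np.linalg.norm(cand - c) >= (r_new + rr) * 0.999
                for c, rr in zip(centers, radii)
            )
            if ok:
                centers.append(cand)
                radii.append(r_new)
                placed = True
                break
        if not placed:
            raise ValueError("could not place domains without overlap")

    coords_parts: list[np.ndarray] = []
    domain_ranges: list[tuple[int, int]] = []
    next_res = 1
    for i, (spec, c) in enumerate(zip(specs, centers)):
        pts = _fill_ellipsoid(spec.semiaxes(), spacing) + c
        domain_ranges.append((next_res, next_res + len(pts) - 1))
        next_res += len(pts)
        coords_parts.append(pts)
        if i < len(specs) - 1:
            n_link = linker_residues[i]
            if n_link > 0:
                # straight linker between domain surfaces
                direction = centers[i + 1] - c
                direction = direction / np.linalg.norm(direction)
                start = c + direction * float(np.max(spec.semiaxes()))
                t = np.arange(1, n_link + 1) * spacing
                coords_parts.append(start + t[:, None] * direction)
                next_res += n_link
    coords = np.vstack(coords_parts)
    model = AtomicModel.from_ca(coords, label="toy structure")
    rg = float(np.sqrt(np.mean(np.sum((coords - coords.mean(axis=0)) ** 2, axis=1))))
    dmax = float(pdist(coords).max())
    manifest = {
        "seed": int(seed),
        "n_residues": int(coords.shape[0]),
        "rg": rg,
        "dmax": dmax,
        "domain_ranges": [list(dr) for dr in domain_ranges],
        "domains": [
            {"shape": s.shape, "semiaxes": s.semiaxes().tolist(), "name": s.name}
            for s in specs
        ],
        "linker_residues": list(linker_residues),
    }
    return ToyStructure(model=model, rg=rg, dmax=dmax,
                        domain_ranges=domain_ranges, manifest=manifest)


def nsd3_like_toy(seed: int = 0) -> ToyStructure:
    """Three-domain stand-in mirroring a PWWP2 / AWS-SET-postSET / PHD4
    topology (84, 249, and 105 residues) joined by short linkers.

    Sphere radii follow from the residue counts at ~134 A^3 per residue.
    """
    def radius(n_res: int) -> float:
        return float((3.0 * n_res * 134.0 / (4.0 * np.pi)) ** (1.0 / 3.0))

    domains = [
        DomainSpec(shape="sphere", radius=radius(84), name="PWWP2"),
        DomainSpec(shape="sphere", radius=radius(249), name="AWS-SET-postSET"),
        DomainSpec(shape="sphere", radius=radius(105), name="PHD4"),
    ]
    return make_toy_structure(domains, linker_residues=[8, 6], seed=seed)


_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7}


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF internal-to-Cartesian placement of the next atom."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_helix_model(
    n_res: int = 40,
    phi: float = -57.0,
    psi: float = -47.0,
    dihedral_noise: float = 0.0,
    seed: int = 0,
    label: str = "helix",
) -> AtomicModel:
    """Full-backbone (N, CA, C) model with prescribed phi/psi dihedrals.

    Ideal alpha-helical angles by default; ``dihedral_noise`` (degrees,
    1 sigma) perturbs every phi and psi independently. Useful wherever a
    real backbone is required (dihedral descriptors) but a real structure
    is not.
    """
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    phis = phi + rng.normal(0.0, dihedral_noise, n_res)
    psis = psi + rng.normal(0.0, dihedral_noise, n_res)
    coords = [np.array([0.0, 0.0, 0.0]),                 # N1
              np.array([_BOND["N-CA"], 0.0, 0.0])]      # CA1
    # C1 via the N-CA-C angle in the xy plane
    ang = np.deg2rad(_ANGLE["N-CA-C"])
    coords.append(coords[1] + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0]))
    names = ["N", "CA", "C"]
    for i in range(1, n_res):
        N = _place_atom(coords[-3], coords[-2], coords[-1],
                        _BOND["C-N"], _ANGLE["CA-C-N"], psis[i - 1])
        CA = _place_atom(coords[-2], coords[-1], N,
                         _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)  # omega trans
        C = _place_atom(coords[-1], N, CA,
                        _BOND["CA-C"], _ANGLE["N-CA-C"], phis[i])
        coords.extend([N, CA, C])
        names.extend(["N", "CA", "C"])
    coords = np.asarray(coords)
    n_atoms = coords.shape[0]
    residx = np.repeat(np.arange(1, n_res + 1), 3)
    elements = np.array([nm[0] for nm in names], dtype=object)
    return AtomicModel(
        coords=coords,
        residue_index=residx,
        residue_name=np.full(n_atoms, "ALA", dtype=object),
        atom_name=np.array(names, dtype=object),
        chain=np.full(n_atoms, "A", dtype=object),
        element=elements,
        hetero=np.zeros(n_atoms, dtype=bool),
        label=label,
    )


@dataclass
class SphereOracle:
    """Closed-form scattering of a uniform sphere of radius R.

    I(q) = [3 (sin(qR) - qR cos(qR)) / (qR)^3]^2 (normalized to I(0)=1),
    p(r) = r^2 (1 - 1.5 x + 0.5 x^3) with x = r/D, D = 2R,
    Rg = sqrt(3/5) R, Dmax = 2R.
    """

    radius: float

    @property
    def rg(self) -> float:
        return float(np.sqrt(3.0 / 5.0) * self.radius)

    @property
    def dmax(self) -> float:
        return 2.0 * self.radius

    def intensity(self, q: np.ndarray) -> np.ndarray:
        x = np.asarray(q, dtype=float) * self.radius
        out = np.ones_like(x)
        nz = x != 0
        out[nz] = (3.0 * (np.sin(x[nz]) - x[nz] * np.cos(x[nz])) / x[nz] ** 3) ** 2
        return out

    def pr(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        x = r / self.dmax
        p = r**2 * (1.0 - 1.5 * x + 0.5 * x**3)
        return np.where((r >= 0) & (r <= self.dmax), p, 0.0)

    def curve(
        self,
        q_grid: np.ndarray = DEFAULT_Q_GRID,
        noise: tuple[float, float] = (0.0, 0.0),
        i0_scale: float = 1.0,
        seed: int = 0,
    ) -> ScatteringCurve:
        """Sphere curve with the standard noise model applied."""
        I = i0_scale * self.intensity(q_grid)
        return _apply_noise(np.asarray(q_grid, dtype=float), I, noise, seed,
                            label=f"sphere R={self.radius:g}")


def sphere_oracles(radius: float) -> SphereOracle:
    """Analytic (I(q), P(r), Rg, Dmax) bundle for a uniform sphere."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return SphereOracle(radius=radius)


def _apply_noise(q, I_true, noise, seed, label=""):
    a, b = noise
    if a == 0.0:
        # exact curve; carry a tiny positive sigma so downstream fits work
        sigma = np.maximum(1e-6 * np.abs(I_true), 1e-12)
        return ScatteringCurve(q=q, I=I_true.copy(), sigma=sigma, label=label)
    rng = np.random.default_rng(seed)
    sigma = a * np.abs(I_true) * (1.0 + b * q / q[-1])
    sigma = np.maximum(sigma, 1e-12)
    I = I_true + rng.normal(0.0, sigma)
    return ScatteringCurve(q=q, I=I, sigma=sigma, label=label)


def simulate_curve(
    model: AtomicModel,
    q_grid: np.ndarray = DEFAULT_Q_GRID,
    i0_scale: float = 1.0,
    noise: tuple[float, float] = DEFAULT_NOISE,
    seed: int = 0,
    level: str = "residue",
) -> ScatteringCurve:
    """Debye profile of a model plus Gaussian noise with
    sigma(q) = a * I(q) * (1 + b q/q_max); the sigma column carries the
    true noise level."""
    q = np.asarray(q_grid, dtype=float)
    calc = debye_profile(model, q, level=level)
    I_true = i0_scale * calc.I / calc.I[0] if i0_scale != 1.0 else calc.I
    curve = _apply_noise(q, np.asarray(I_true), noise, seed,
                         label=f"simulated from {model.label or 'model'}")
    return curve


def simulate_secsaxs(
    species: list[tuple[AtomicModel, float, float, float]],
    n_frames: int = 200,
    buffer_level: float = 5.0,
    q_grid: np.ndarray = DEFAULT_Q_GRID,
    noise: tuple[float, float] = DEFAULT_NOISE,
    seed: int = 0,
    exposure: float = 3.0,
) -> tuple[FrameSeries, dict]:
    """Simulate a SEC-SAXS run: frames = buffer + Gaussian elution peaks.

    ``species`` entries are (model, peak_center_frame, peak_width_frames,
    amplitude). Overlapping species emulate a peak shoulder. Returns the
    frame series and a ground-truth manifest (per-frame composition,
    species Rg values, seeds).
    """
    if not species:
        raise ValueError("need at least one species")
    q = np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(seed)
    profiles = []
    truths = []
    for model, center, width, amp in species:
        calc = debye_profile(model, q, level="residue")
        profiles.append(calc.I / calc.I[0])  # normalized; amplitude scales it
        coords = model.ca_coords()
        rg = float(np.sqrt(np.mean(np.sum((coords - coords.mean(0)) ** 2, axis=1))))
        truths.append({
            "label": model.label, "center": float(center),
            "width": float(width), "amplitude": float(amp), "rg": rg,
        })
    frames = []
    a, b = noise
    weights = np.zeros((n_frames, len(species)))
    buffer_I = buffer_level * np.ones_like(q)
    for f in range(n_frames):
        I_true = buffer_I.copy()
        for s, (model, center, width, amp) in enumerate(species):
            w = amp * np.exp(-0.5 * ((f - center) / width) ** 2)
            weights[f, s] = w
            I_true = I_true + w * profiles[s]
        sigma = np.maximum(a * np.abs(I_true) * (1.0 + b * q / q[-1]), 1e-12)
        if a == 0.0:
            sigma = np.maximum(1e-6 * np.abs(I_true), 1e-12)
            I = I_true
        else:
            I = I_true + rng.normal(0.0, sigma)
        frames.append(ScatteringCurve(q=q, I=I, sigma=sigma, label=f"frame {f}"))
    series = FrameSeries(frames=frames, exposure=exposure,
                         meta={"seed": int(seed)})
    manifest = {
        "seed": int(seed),
        "n_frames": int(n_frames),
        "buffer_level": float(buffer_level),
        "noise": {"a": float(a), "b": float(b)},
        "species": truths,
        "weights": weights.tolist(),
    }
    return series, manifest
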