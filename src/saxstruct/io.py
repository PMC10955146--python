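"""Readers and writers for the pipeline's on-disk formats.

Scattering curves use the 3-column ``q I sigma`` text convention of
SASBDB/ATSAS (``#``-prefixed comments). Atomic and dummy-atom models use
PDB format, parsed and written through gemmi; bead models follow the
envelope-program convention of one ``CA`` atom per bead in residue ``DUM``,
with the occupancy column carrying the bead weight.
"""

from __future__ import annotations

import logging
import os
import re

import gemmi
import numpy as np

from .curves import ScatteringCurve
from .structures import AtomicModel, BeadModel

logger = logging.getLogger("saxstruct")

_BEAD_RESNAME = "DUM"
_BEAD_RADIUS_REMARK = re.compile(r"REMARK\s+265\s+BEAD RADIUS:\s*([0-9.eE+-]+)")

# q_max above this is assumed to be nm^-1 data (silent unit mix-ups are a
# classic SAXS error source; we reject rather than auto-convert)
_QMAX_ANGSTROM_LIMIT = 3.0


class ParseError(ValueError):
    """Raised when a file cannot be interpreted in the expected format."""


def read_dat(path: str | os.PathLike) -> ScatteringCurve:
    """Read a 3-column (q, I[, sigma]) text scattering curve.

    Comment lines (``#``) and non-numeric header/footer lines are skipped.
    Rows with non-positive q or non-finite values are dropped (count
    logged); rows are sorted by q and exact-duplicate q values collapsed.
    """
    rows: list[tuple[float, ...]] = []
    n_cols = None
    n_dropped = 0
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            try:
                vals = tuple(float(p) for p in parts[:3])
            except ValueError:
                continue
            if len(vals) < 2:
                continue
            if not all(np.isfinite(v) for v in vals) or vals[0] <= 0:
                n_dropped += 1
                continue
            if len(vals) >= 3 and vals[2] <= 0:
                vals = vals[:2]
            rows.append(vals)
            n_cols = len(vals) if n_cols is None else min(n_cols, len(vals))
    if n_dropped:
        logger.info("read_dat(%s): dropped %d unusable rows", path, n_dropped)
    if len(rows) < 5:
        raise ParseError(f"{path}: fewer than 5 usable data rows")
    arr = np.array([r[:n_cols] for r in rows], dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    keep = np.concatenate([[True], np.diff(arr[:, 0]) > 0])
    arr = arr[keep]
    if arr[-1, 0] > _QMAX_ANGSTROM_LIMIT:
        raise ParseError(
            f"{path}: q_max = {arr[-1, 0]:.3g} looks like nm^-1 data; "
            "convert to A^-1 before loading (no silent unit conversion)"
        )
    sigma = arr[:, 2] if n_cols >= 3 else None
    label = os.path.splitext(os.path.basename(str(path)))[0]
    return ScatteringCurve(q=arr[:, 0], I=arr[:, 1], sigma=sigma, label=label)


def write_dat(curve: ScatteringCurve, path: str | os.PathLike) -> None:
    """Write a curve as 2/3-column text with a ``#`` header."""
    with open(path, "w") as fh:
        fh.write(f"# {curve.label or 'scattering curve'}\n")
        fh.write("# q(A^-1)  I(a.u.)" + ("  sigma\n" if curve.has_sigma else "\n"))
        for i in range(len(curve)):
            if curve.sigma is not None:
                fh.write(f"{curve.q[i]:.6e} {curve.I[i]:.6e} {curve.sigma[i]:.6e}\n")
            else:
                fh.write(f"{curve.q[i]:.6e} {curve.I[i]:.6e}\n")


def read_model(path: str | os.PathLike) -> AtomicModel | BeadModel:
    """Read a PDB file as an AtomicModel, or a BeadModel if it uses the
    dummy-atom dialect (all residues named ``DUM``)."""
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    coords, resi, resn, atname, chain, element, hetero, occ = ([] for _ in range(8))
    for model in st:
        for ch in model:
            for res in ch:
                is_het = res.het_flag == "H"
                for atom in res:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    resi.append(res.seqid.num)
                    resn.append(res.name.strip())
                    atname.append(atom.name.strip())
                    chain.append(ch.name)
                    element.append(atom.element.name.upper())
                    hetero.append(is_het)
                    occ.append(atom.occ)
        break  # first MODEL only
    if not coords:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    # the dummy-atom dialect is recognized by residue name alone: PDB
    # parsers commonly flag the non-standard DUM residues as HETATM
    if set(resn) == {_BEAD_RESNAME}:
        centers = np.array(coords)
        occupancy = np.clip(occ, 0.0, 1.0)
        radius = _read_bead_radius(path)
        if radius is None:
            radius = _infer_bead_radius(centers)
        return BeadModel(centers=centers, bead_radius=radius,
                         occupancy=np.asarray(occupancy),
                         label=os.path.basename(str(path)))
    return AtomicModel(
        coords=np.array(coords),
        residue_index=np.array(resi),
        residue_name=np.array(resn, dtype=object),
        atom_name=np.array(atname, dtype=object),
        chain=np.array(chain, dtype=object),
        element=np.array(element, dtype=object),
        hetero=np.array(hetero, dtype=bool),
        label=os.path.basename(str(path)),
    )


def _read_bead_radius(path: str | os.PathLike) -> float | None:
    with open(path) as fh:
        for line in fh:
            m = _BEAD_RADIUS_REMARK.search(line)
            if m:
                return float(m.group(1))
            if line.startswith(("ATOM", "HETATM")):
                break
    return None


def _infer_bead_radius(centers: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    if centers.shape[0] < 2:
        return 1.0
    d, _ = cKDTree(centers).query(centers, k=2)
    return float(np.median(d[:, 1]) / 2.0)


def write_model(model: AtomicModel | BeadModel, path: str | os.PathLike) -> None:
    """Write a model as PDB; bead models use the ``DUM``/``CA`` dialect with
    occupancy = bead weight and a REMARK carrying the bead radius."""
    st = gemmi.Structure()
    st.name = getattr(model, "label", "") or "saxstruct model"
    gm = gemmi.Model("1")
    if isinstance(model, BeadModel):
        ch = gemmi.Chain("A")
        for i, (c, w) in enumerate(zip(model.centers, model.occupancy), start=1):
            res = gemmi.Residue()
            res.name = _BEAD_RESNAME
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.pos = gemmi.Position(*c)
            atom.occ = float(w)
            atom.element = gemmi.Element("C")
            res.add_atom(atom)
            ch.add_residue(res)
        gm.add_chain(ch)
    else:
        chains: dict[str, gemmi.Chain] = {}
        for i in range(len(model)):
            cname = str(model.chain[i])
            if cname not in chains:
                chains[cname] = gemmi.Chain(cname)
            ch = chains[cname]
            resnum = int(model.residue_index[i])
            if len(ch) == 0 or ch[-1].seqid.num != resnum or ch[-1].name != str(model.residue_name[i]):
                res = gemmi.Residue()
                res.name = str(model.residue_name[i])
                res.seqid = gemmi.SeqId(resnum, " ")
                res.het_flag = "H" if model.hetero[i] else "A"
                ch.add_residue(res)
            atom = gemmi.Atom()
            atom.name = str(model.atom_name[i])
            atom.pos = gemmi.Position(*model.coords[i])
            atom.occ = 1.0
            atom.element = gemmi.Element(str(model.element[i]).capitalize())
            ch[-1].add_atom(atom)
        for ch in chains.values():
            gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    pdb_text = st.make_pdb_string()
    with open(path, "w") as fh:
        if isinstance(model, BeadModel):
            fh.write(f"REMARK 265 BEAD RADIUS: {model.bead_radius:.4f}\n")
        fh.write(pdb_text)
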