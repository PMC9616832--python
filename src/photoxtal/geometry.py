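"""Conformer and environment analysis on atomic models.

Torsion angles follow the IUPAC sign convention (right-hand rule about the
2→3 bond, range (−180°, 180°]); distances can search P1 periodic images;
superposition uses the Kabsch algorithm with optional outlier-rejection
cycles; the hydrogen-bond census works from heavy-atom geometry (no
hydrogens required) with configurable distance/angle criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .structio import Atom, AtomicModel

__all__ = [
    "TorsionSpec",
    "HBond",
    "torsion",
    "dihedral_from_points",
    "distance",
    "nearest_atom",
    "kabsch_rmsd",
    "hbond_census",
    "hbond_diff",
    "bfactor_stats",
]


@dataclass(frozen=True)
class TorsionSpec:
    """Four atom selectors, each a (chain, residue_number, atom_id) triple."""

    atoms: tuple

    def __post_init__(self):
        if len(self.atoms) != 4 or len(set(self.atoms)) != 4:
            raise ValueError("a torsion needs four distinct atom selectors")


@dataclass(frozen=True)
class HBond:
    donor: tuple  # (chain, residue_number, atom_id)
    acceptor: tuple
    distance: float
    angle: float | None  # N-H...O at the placed amide H; None when unplaceable


# --------------------------------------------------------------------------
# Torsions


def dihedral_from_points(p1, p2, p3, p4) -> float:
    """Signed dihedral (deg) of four points, IUPAC convention, (−180, 180].

    Positive sign means the far bond is rotated clockwise from the near bond
    when viewed along the 2→3 axis (right-hand rule).
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise ValueError("torsion undefined: coincident central atoms")
    b1 = b1 / nb1
    v = b0 - (b0 @ b1) * b1  # components perpendicular to the central bond
    w = b2 - (b2 @ b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise ValueError("torsion undefined: three consecutive atoms collinear")
    ang = np.degrees(np.arctan2(np.cross(b1, v) @ w, v @ w))
    return float(180.0 if np.isclose(ang, -180.0) else ang)


def torsion(model: AtomicModel, spec: TorsionSpec) -> float:
    """Dihedral angle of the four selected atoms in the model (degrees)."""
    pts = []
    for sel in spec.atoms:
        try:
            atom = model.atom(*sel)
        except KeyError as exc:
            raise KeyError(f"torsion selector {sel} matches no atom") from exc
        pts.append(model.cell.orthogonalize(atom.frac))
    return dihedral_from_points(*pts)


# --------------------------------------------------------------------------
# Distances


def _atom_cart(model: AtomicModel, atom: Atom | tuple) -> tuple[Atom, np.ndarray]:
    if isinstance(atom, tuple):
        atom = model.atom(*atom)
    return atom, model.cell.orthogonalize(atom.frac)


def distance(model: AtomicModel, atom_a, atom_b, use_symmetry: bool = False) -> float:
    """Euclidean distance (Å); with ``use_symmetry`` the minimum over P1
    periodic images within ±1 cell."""
    a, pa = _atom_cart(model, atom_a)
    b, pb = _atom_cart(model, atom_b)
    if not use_symmetry:
        return float(np.linalg.norm(pa - pb))
    dfrac = a.frac - b.frac
    shifts = np.array(list(product((-1, 0, 1), repeat=3)))
    cands = model.cell.orthogonalize(dfrac + shifts)
    return float(np.linalg.norm(cands, axis=1).min())


def nearest_atom(model: AtomicModel, reference_atom, candidates: list,
                 use_symmetry: bool = False) -> tuple[Atom, float]:
    """Closest candidate atom to the reference (the reference itself is
    excluded); ties broken deterministically by atom key order."""
    ref, _ = _atom_cart(model, reference_atom)
    pool = [c if isinstance(c, Atom) else model.atom(*c) for c in candidates]
    pool = [c for c in pool if c.key != ref.key]
    if not pool:
        raise ValueError("empty candidate selection")
    scored = sorted(((distance(model, ref, c, use_symmetry), c.key, c) for c in pool),
                    key=lambda t: (t[0], t[1]))
    d, _, atom = scored[0]
    return atom, d


# --------------------------------------------------------------------------
# Superposition


def _kabsch(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Residual distances after optimal superposition of p onto q."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return np.linalg.norm((rot @ pc.T).T - qc, axis=1)


def kabsch_rmsd(model_a: AtomicModel, model_b: AtomicModel,
                selection: list | None = None,
                outlier_cycles: int = 0) -> tuple[float, int]:
    """Least-squares superposition RMSD over paired atoms.

    ``selection`` lists (chain, residue_number, atom_id) keys present in both
    models; by default all atoms are paired in order.  Each outlier cycle
    drops pairs whose residual exceeds twice the current RMSD, then refits.
    Returns (rmsd, n_pairs_used).
    """
    if selection is None:
        if len(model_a) != len(model_b):
            raise ValueError("models differ in length; provide a selection")
        pa = model_a.cart
        pb = model_b.cart
    else:
        pa = np.array([model_a.cell.orthogonalize(model_a.atom(*k).frac)
                       for k in selection])
        pb = np.array([model_b.cell.orthogonalize(model_b.atom(*k).frac)
                       for k in selection])
    if len(pa) < 3:
        raise ValueError("need at least 3 atom pairs for superposition")
    keep = np.ones(len(pa), bool)
    for _ in range(outlier_cycles):
        resid = _kabsch(pa[keep], pb[keep])
        rmsd = float(np.sqrt(np.mean(resid**2)))
        new_keep = keep.copy()
        new_keep[np.where(keep)[0][resid > 2.0 * max(rmsd, 1e-12)]] = False
        if new_keep.sum() < 3 or new_keep.sum() == keep.sum():
            break
        keep = new_keep
    resid = _kabsch(pa[keep], pb[keep])
    return float(np.sqrt(np.mean(resid**2))), int(keep.sum())


# --------------------------------------------------------------------------
# Hydrogen bonds


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbond_census(model: AtomicModel, d_max: float = 3.5,
                 angle_min: float = 120.0, scope: str = "backbone") -> list[HBond]:
    """Donor–acceptor census from heavy-atom geometry.

    Backbone scope pairs amide N donors with carbonyl O acceptors of
    residues at least two apart in sequence.  The amide hydrogen is placed
    geometrically (anti to the bisector of the C′–N and CA–N bonds, in the
    peptide plane) and the reported angle is the N–H···O angle at that
    hydrogen, which must reach ``angle_min``; donors lacking the antecedent
    C′ or CA fall back to the distance criterion alone.  ``scope="all"``
    additionally treats every N/O as both donor and acceptor candidate on
    the distance criterion alone.
    """
    cell = model.cell
    if scope == "backbone":
        donors = [a for a in model.atoms if a.id == "N"]
        acceptors = [a for a in model.atoms if a.id == "O"]
    elif scope == "all":
        donors = [a for a in model.atoms if a.element in ("N", "O")]
        acceptors = [a for a in model.atoms if a.element in ("N", "O")]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out = []
    for don in donors:
        pd_ = cell.orthogonalize(don.frac)
        h_pos = None
        if scope == "backbone":
            prev = model.select(chain=don.chain, residue_number=don.residue_number - 1,
                                atom_id="C")
            ca = model.select(chain=don.chain, residue_number=don.residue_number,
                              atom_id="CA")
            if prev and ca:
                pc = cell.orthogonalize(prev[0].frac)
                pca = cell.orthogonalize(ca[0].frac)
                u = ((pd_ - pc) / np.linalg.norm(pd_ - pc)
                     + (pd_ - pca) / np.linalg.norm(pd_ - pca))
                h_pos = pd_ + u / np.linalg.norm(u) * 1.0  # N-H 1.0 Å
        for acc in acceptors:
            if acc.key == don.key:
                continue
            if (scope == "backbone"
                    and don.chain == acc.chain
                    and abs(don.residue_number - acc.residue_number) < 2):
                continue
            pa = cell.orthogonalize(acc.frac)
            d = float(np.linalg.norm(pd_ - pa))
            if d > d_max:
                continue
            ang = None
            if h_pos is not None:
                ang = _angle(pd_, h_pos, pa)  # N-H...O angle at the hydrogen
                if ang < angle_min:
                    continue
            out.append(HBond(donor=don.key, acceptor=acc.key, distance=d, angle=ang))
    return sorted(out, key=lambda h: (h.donor, h.acceptor))


def hbond_diff(census_a: list[HBond], census_b: list[HBond]) -> dict:
    """Created/lost H-bond sets going from state a to state b, keyed by
    (donor, acceptor)."""
    ka = {(h.donor, h.acceptor) for h in census_a}
    kb = {(h.donor, h.acceptor) for h in census_b}
    return {"created": sorted(kb - ka), "lost": sorted(ka - kb)}


# --------------------------------------------------------------------------
# B factors


def bfactor_stats(model: AtomicModel, group_by: str = "residue") -> pd.DataFrame:
    """Descriptive B-factor statistics grouped by atom, residue or chain."""
    rows = [{"chain": a.chain, "residue_number": a.residue_number,
             "residue_name": a.residue_name, "atom_id": a.id, "b": a.b_iso}
            for a in model.atoms]
    df = pd.DataFrame(rows)
    keys = {"atom": ["chain", "residue_number", "atom_id"],
            "residue": ["chain", "residue_number", "residue_name"],
            "chain": ["chain"]}
    if group_by not in keys:
        raise ValueError(f"unknown grouping {group_by!r}")
    g = (df.groupby(keys[group_by], sort=True)["b"]
           .agg(["mean", "min", "max", "count"]).reset_index())
    return g
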