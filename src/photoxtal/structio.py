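"""Core domain types and file IO for structures, reflections, maps and spectra.

Everything downstream (difference maps, extrapolation, geometry, kinetics)
consumes only the containers defined here.  Coordinates are stored as
fractional coordinates of the unit cell; Cartesian positions are a derived
view.  All Fourier computation elsewhere in the package operates in P1 —
models may carry any space-group label, but symmetry expansion, when needed,
is explicit.

File formats are delegated to gemmi (PDB/mmCIF models, MTZ reflections,
CCP4/MRC maps); CSV reflection and spectra tables go through pandas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "UnitCell",
    "Atom",
    "AtomicModel",
    "ReflectionSet",
    "DensityMap",
    "SpectroDataset",
    "read_model",
    "write_model",
    "read_reflections",
    "write_reflections",
    "read_map",
    "write_map",
    "read_spectra",
    "write_spectra",
]


class StructIOError(ValueError):
    """Raised when an input file violates its format's structural contract."""


# --------------------------------------------------------------------------
# Unit cell


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: edge lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if np.linalg.det(self.orthogonalization_matrix) <= 0:
            raise ValueError("cell metric is not positive definite")

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix M with x_cart = M @ x_frac (PDB convention)."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cos_al, cos_be, cos_ga = np.cos([al, be, ga])
        sin_ga = np.sin(ga)
        v = math.sqrt(
            1 - cos_al**2 - cos_be**2 - cos_ga**2 + 2 * cos_al * cos_be * cos_ga
        )
        return np.array(
            [
                [self.a, self.b * cos_ga, self.c * cos_be],
                [0.0, self.b * sin_ga, self.c * (cos_al - cos_be * cos_ga) / sin_ga],
                [0.0, 0.0, self.c * v / sin_ga],
            ]
        )

    @property
    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.orthogonalization_matrix))

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, float) @ self.orthogonalization_matrix.T

    def fractionalize(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, float) @ self.fractionalization_matrix.T

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) of reflections, rows of integer (h,k,l)."""
        hkl = np.atleast_2d(np.asarray(hkl, float))
        # reciprocal metric: G* = (M^-1) (M^-1)^T
        g_star = self.fractionalization_matrix @ self.fractionalization_matrix.T
        inv_d2 = np.einsum("ij,jk,ik->i", hkl, g_star, hkl)
        with np.errstate(divide="ignore"):
            d = 1.0 / np.sqrt(inv_d2)
        return d

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @classmethod
    def from_gemmi(cls, cell: gemmi.UnitCell) -> "UnitCell":
        return cls(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)


# --------------------------------------------------------------------------
# Atoms and models

_PERIODIC = {gemmi.Element(z).name.upper() for z in range(1, 104)}


@dataclass
class Atom:
    """A single atom site; ``frac`` is the fractional coordinate triple."""

    id: str  # atom name, e.g. "CA", "C12", "CL"
    element: str
    chain: str
    residue_name: str
    residue_number: int
    frac: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self):
        self.frac = np.asarray(self.frac, float)
        el = self.element.capitalize()
        if el.upper() not in _PERIODIC:
            raise ValueError(f"unrecognized element symbol: {self.element!r}")
        self.element = el
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_iso < 0:
            raise ValueError(f"negative B factor {self.b_iso}")

    @property
    def key(self) -> tuple:
        return (self.chain, self.residue_number, self.id)


@dataclass
class AtomicModel:
    """Unit cell plus an ordered list of atom sites (P1 working frame)."""

    cell: UnitCell
    atoms: list[Atom] = field(default_factory=list)
    spacegroup: str = "P 1"
    provenance: str = ""

    def __post_init__(self):
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom id within residue: {dup}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def frac(self) -> np.ndarray:
        return np.array([a.frac for a in self.atoms]).reshape(-1, 3)

    @property
    def cart(self) -> np.ndarray:
        return self.cell.orthogonalize(self.frac)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            cell=self.cell,
            atoms=[replace(a, frac=a.frac.copy()) for a in self.atoms],
            spacegroup=self.spacegroup,
            provenance=self.provenance,
        )

    def select(self, chain=None, residue_name=None, residue_number=None, atom_id=None,
               element=None) -> list[Atom]:
        """Filter atoms by any combination of labels (None matches all)."""
        out = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if residue_number is not None and a.residue_number != residue_number:
                continue
            if atom_id is not None and a.id != atom_id:
                continue
            if element is not None and a.element != element.capitalize():
                continue
            out.append(a)
        return out

    def atom(self, chain: str, residue_number: int, atom_id: str) -> Atom:
        hits = self.select(chain=chain, residue_number=residue_number, atom_id=atom_id)
        if not hits:
            raise KeyError(f"no atom {chain}:{residue_number}:{atom_id}")
        return hits[0]

    def water_count(self) -> int:
        return sum(1 for a in self.atoms
                   if a.residue_name in ("HOH", "WAT") and a.element == "O")


# --------------------------------------------------------------------------
# Reflections


@dataclass
class ReflectionSet:
    """Indexed structure-factor amplitudes with optional phases.

    Columns are parallel numpy arrays; ``phase`` is in degrees and may be
    None for experimental amplitude-only data.
    """

    cell: UnitCell
    hkl: np.ndarray  # (n, 3) int
    f: np.ndarray  # amplitudes, e-
    sigf: np.ndarray | None = None
    phase: np.ndarray | None = None  # degrees
    label: str = ""
    free_flag: np.ndarray | None = None

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, int).reshape(-1, 3)
        self.f = np.asarray(self.f, float)
        if self.sigf is not None:
            self.sigf = np.asarray(self.sigf, float)
        if self.phase is not None:
            self.phase = np.asarray(self.phase, float)
        n = len(self.hkl)
        if len(self.f) != n:
            raise ValueError("hkl / F length mismatch")
        if np.any(self.f < 0):
            bad = self.hkl[np.argmax(self.f < 0)]
            raise StructIOError(f"negative amplitude at reflection {tuple(bad)}")
        uniq = np.unique(self.hkl, axis=0)
        if len(uniq) != n:
            idx, counts = np.unique(self.hkl, axis=0, return_counts=True)
            dup = tuple(int(x) for x in idx[counts > 1][0])
            raise StructIOError(f"duplicate reflection index {dup}")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    @property
    def d_min(self) -> float | None:
        return float(self.d.min()) if len(self) else None

    @property
    def d_max(self) -> float | None:
        return float(self.d.max()) if len(self) else None

    @property
    def complex_f(self) -> np.ndarray:
        if self.phase is None:
            raise ValueError(f"reflection set {self.label!r} carries no phases")
        return self.f * np.exp(1j * np.radians(self.phase))

    def index_map(self) -> dict[tuple, int]:
        return {tuple(h): i for i, h in enumerate(self.hkl)}

    def common_with(self, other: "ReflectionSet") -> tuple[np.ndarray, np.ndarray]:
        """Positional indices (into self, into other) of shared hkl, sorted."""
        m = other.index_map()
        pairs = [(i, m[tuple(h)]) for i, h in enumerate(self.hkl) if tuple(h) in m]
        if not pairs:
            return np.empty(0, int), np.empty(0, int)
        ia, ib = map(np.array, zip(*pairs))
        return ia, ib


# --------------------------------------------------------------------------
# Density maps


@dataclass
class DensityMap:
    """Real-space scalar field on a regular grid over the unit cell.

    ``values[i, j, k]`` sits at fractional coordinate (i/na, j/nb, k/nc).
    """

    cell: UnitCell
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3-axis array")

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sigma(self) -> float:
        return float(self.values.std())

    def spacing(self) -> np.ndarray:
        """Approximate grid spacing (Å) along each cell axis."""
        na, nb, nc = self.grid
        return np.array([self.cell.a / na, self.cell.b / nb, self.cell.c / nc])

    def value_at_frac(self, frac: np.ndarray) -> np.ndarray:
        """Nearest-voxel lookup with periodic wrapping."""
        frac = np.atleast_2d(np.asarray(frac, float))
        dims = np.array(self.grid)
        idx = np.rint(frac * dims).astype(int) % dims
        return self.values[idx[:, 0], idx[:, 1], idx[:, 2]]


# --------------------------------------------------------------------------
# Spectra


@dataclass
class SpectroDataset:
    """Time-resolved spectra: time x channel matrix of absorbance (or ΔOD).

    ``kind`` distinguishes UV/Vis (channels in nm) from FTIR (channels in
    cm⁻¹).  ``integration_window`` is the acquisition time per stored
    spectrum; rows then represent time averages over [t, t + window].
    """

    times: np.ndarray
    channels: np.ndarray
    values: np.ndarray
    kind: str = "uvvis"
    integration_window: float = 0.0
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.channels = np.asarray(self.channels, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.channels) <= 0):
            raise ValueError("channels must be strictly increasing")
        if self.values.shape != (len(self.times), len(self.channels)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match axes "
                f"({len(self.times)}, {len(self.channels)})"
            )
        if self.kind not in ("uvvis", "ftir"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")


# --------------------------------------------------------------------------
# Model IO (gemmi)


def _model_from_structure(st: gemmi.Structure, path: str) -> AtomicModel:
    cell = st.cell
    if cell.a <= 1.0 and cell.b <= 1.0 and cell.c <= 1.0:
        raise StructIOError(f"{path}: no unit cell present; refusing to default")
    atoms = []
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                frac = cell.fractionalize(at.pos)
                atoms.append(
                    Atom(
                        id=at.name,
                        element=at.element.name,
                        chain=chain.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        frac=np.array([frac.x, frac.y, frac.z]),
                        occupancy=at.occ,
                        b_iso=at.b_iso,
                    )
                )
    return AtomicModel(
        cell=UnitCell.from_gemmi(cell),
        atoms=atoms,
        spacegroup=st.spacegroup_hm or "P 1",
        provenance=str(path),
    )


def read_model(path, format: str | None = None) -> AtomicModel:
    """Read an atomic model from PDB or mmCIF.

    All ATOM and HETATM records are retained with occupancy and B factor;
    the format is inferred from the extension when not given.
    """
    path = str(path)
    fmt = format or ("mmcif" if path.endswith((".cif", ".mmcif")) else "pdb")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt == "mmcif":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown model format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructIOError(f"{path}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise StructIOError(f"{path}: no atoms parsed")
    return _model_from_structure(st, path)


def _structure_from_model(model: AtomicModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.cell = model.cell.to_gemmi()
    st.spacegroup_hm = model.spacegroup
    gm = gemmi.Model("1")
    # gemmi add_* copy their argument, so residues/chains are built fully
    # before being attached
    by_chain: dict[str, dict[tuple, gemmi.Residue]] = {}
    for a in model.atoms:
        rkey = (a.residue_number, a.residue_name)
        res = by_chain.setdefault(a.chain, {}).get(rkey)
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "H" if a.residue_name in ("HOH", "LIG", "CAN") else "A"
            by_chain[a.chain][rkey] = res
        ga = gemmi.Atom()
        ga.name = a.id
        ga.element = gemmi.Element(a.element)
        cart = model.cell.orthogonalize(a.frac)
        ga.pos = gemmi.Position(*cart)
        ga.occ = a.occupancy
        ga.b_iso = a.b_iso
        res.add_atom(ga)
    for chain_name, residues in by_chain.items():
        ch = gemmi.Chain(chain_name)
        for res in residues.values():
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_model(model: AtomicModel, path) -> None:
    """Write a model to PDB or mmCIF (by extension; default PDB)."""
    path = str(path)
    st = _structure_from_model(model)
    if path.endswith((".cif", ".mmcif")):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)


# --------------------------------------------------------------------------
# Reflection IO

_DEFAULT_COLUMNS = {"h": "h", "k": "k", "l": "l", "F": "F", "sigF": "sigF",
                    "phase": "phase", "free": "free"}


def read_reflections(path, format: str | None = None,
                     columns: dict | None = None,
                     cell: UnitCell | None = None,
                     label: str = "") -> ReflectionSet:
    """Read reflections from MTZ or CSV into a :class:`ReflectionSet`.

    CSV files need a header row; ``columns`` maps the logical names
    (h, k, l, F, sigF, phase, free) onto the file's column names.  For CSV a
    ``cell`` must be supplied since the file carries none.
    """
    path = str(path)
    fmt = format or ("mtz" if path.endswith(".mtz") else "csv")
    if fmt == "mtz":
        cols = {"h": "H", "k": "K", "l": "L", "F": "F", "sigF": "SIGF",
                "phase": "PHI", "free": "FreeR_flag"}
    else:
        cols = dict(_DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)

    if fmt == "mtz":
        mtz = gemmi.read_mtz_file(path)
        df = pd.DataFrame(np.array(mtz, copy=False), columns=mtz.column_labels())
        use_cell = UnitCell.from_gemmi(mtz.cell)
    elif fmt == "csv":
        if cell is None:
            raise StructIOError(f"{path}: CSV reflections need an explicit unit cell")
        df = pd.read_csv(path)
        use_cell = cell
    else:
        raise ValueError(f"unknown reflection format {fmt!r}")

    if df.empty:
        return ReflectionSet(cell=use_cell, hkl=np.empty((0, 3), int),
                             f=np.empty(0), label=label or path)

    for logical in ("h", "k", "l", "F"):
        if cols[logical] not in df.columns:
            raise StructIOError(
                f"{path}: required column {cols[logical]!r} ({logical}) missing"
            )
    hkl = df[[cols["h"], cols["k"], cols["l"]]].to_numpy()
    if not np.allclose(hkl, np.rint(hkl)):
        raise StructIOError(f"{path}: non-integer Miller indices")
    kwargs = {}
    if cols["sigF"] in df.columns:
        kwargs["sigf"] = df[cols["sigF"]].to_numpy(float)
    if cols["phase"] in df.columns:
        kwargs["phase"] = df[cols["phase"]].to_numpy(float)
    if cols["free"] in df.columns:
        kwargs["free_flag"] = df[cols["free"]].to_numpy()
    return ReflectionSet(cell=use_cell, hkl=np.rint(hkl).astype(int),
                         f=df[cols["F"]].to_numpy(float),
                         label=label or path, **kwargs)


def write_reflections(rset: ReflectionSet, path, format: str | None = None) -> None:
    """Write reflections to MTZ or CSV (columns h,k,l,F[,sigF][,phase])."""
    path = str(path)
    fmt = format or ("mtz" if path.endswith(".mtz") else "csv")
    if fmt == "csv":
        data = {"h": rset.hkl[:, 0], "k": rset.hkl[:, 1], "l": rset.hkl[:, 2],
                "F": rset.f}
        if rset.sigf is not None:
            data["sigF"] = rset.sigf
        if rset.phase is not None:
            data["phase"] = rset.phase
        pd.DataFrame(data).to_csv(path, index=False)
        return
    mtz = gemmi.Mtz(with_base=True)
    mtz.cell = rset.cell.to_gemmi()
    mtz.spacegroup = gemmi.SpaceGroup("P 1")
    mtz.add_dataset("photoxtal")
    mtz.add_column("F", "F")
    ncol = 4
    if rset.sigf is not None:
        mtz.add_column("SIGF", "Q")
        ncol += 1
    if rset.phase is not None:
        mtz.add_column("PHI", "P")
        ncol += 1
    n = len(rset)
    arr = np.zeros((n, ncol), np.float32)
    arr[:, 0:3] = rset.hkl
    arr[:, 3] = rset.f
    col = 4
    if rset.sigf is not None:
        arr[:, col] = rset.sigf
        col += 1
    if rset.phase is not None:
        arr[:, col] = rset.phase
    mtz.set_data(arr)
    mtz.write_to_file(path)


# --------------------------------------------------------------------------
# Map IO


def write_map(dmap: DensityMap, path) -> None:
    """Write a density map in CCP4/MRC format (float32, full cell)."""
    grid = gemmi.FloatGrid(*dmap.grid)
    grid.set_unit_cell(dmap.cell.to_gemmi())
    grid.spacegroup = gemmi.SpaceGroup("P 1")
    arr = np.array(grid, copy=False)
    arr[...] = dmap.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header(2, True)
    m.write_ccp4_map(str(path))


def read_map(path, label: str = "") -> DensityMap:
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))
    values = np.array(m.grid, copy=True).astype(float)
    return DensityMap(cell=UnitCell.from_gemmi(m.grid.unit_cell), values=values,
                      label=label or str(path))


# --------------------------------------------------------------------------
# Spectra IO


def write_spectra(ds: SpectroDataset, path) -> None:
    """CSV matrix: first column ``time``, remaining headers are channels."""
    df = pd.DataFrame(ds.values, columns=[f"{c:g}" for c in ds.channels])
    df.insert(0, "time", ds.times)
    df.to_csv(path, index=False)


def read_spectra(path, kind: str = "uvvis", integration_window: float = 0.0,
                 label: str = "") -> SpectroDataset:
    df = pd.read_csv(path)
    if df.columns[0] != "time":
        raise StructIOError(f"{path}: first column must be 'time'")
    channels = np.array([float(c) for c in df.columns[1:]])
    return SpectroDataset(times=df["time"].to_numpy(float), channels=channels,
                          values=df.iloc[:, 1:].to_numpy(float), kind=kind,
                          integration_window=integration_window,
                          label=label or str(path))
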