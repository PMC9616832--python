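"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Three generators emulate the experiments the pipeline analyses:

* a two-state toy crystal — a P1 cell holding a polyene-like carbon chain
  whose light conformer differs from the dark one only by rotation about a
  designated torsion, mixed with known occupancy α into observed amplitudes
  with Gaussian noise;
* continuous-illumination photo-kinetics — a sequential compartment scheme
  with stated lifetimes and per-species band spectra, optionally
  time-averaged over an FTIR-style acquisition window;
* a single-wavelength saturating double-exponential trace.

Every dataset carries exactly one :class:`SyntheticTruth` so recovery tests
can compare fitted quantities against the generating parameters.  The same
seed always regenerates bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import diffmap
from .spectrokinetics import KineticScheme, windowed_concentrations
from .structio import Atom, AtomicModel, ReflectionSet, SpectroDataset, UnitCell

__all__ = [
    "SyntheticTruth",
    "make_two_state_crystal",
    "make_photo_timeseries",
    "make_linked_photo_pair",
    "make_saturating_trace",
    "default_species_spectra",
    "build_helix_backbone",
]

DEFAULT_CELL = UnitCell(20.0, 22.0, 24.0, 90.0, 90.0, 90.0)


@dataclass
class SyntheticTruth:
    """Generating parameters attached to a synthetic dataset."""

    seed: int
    description: str
    alpha_true: float | None = None
    lifetimes_true: tuple | None = None
    species_spectra_true: np.ndarray | None = None
    noise_sigma: float | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = asdict(self)
        if d["species_spectra_true"] is not None:
            d["species_spectra_true"] = np.asarray(d["species_spectra_true"]).tolist()
        if d["lifetimes_true"] is not None:
            d["lifetimes_true"] = [None if math.isinf(t) else t
                                   for t in d["lifetimes_true"]]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=str)


# --------------------------------------------------------------------------
# Two-state crystal


def _rodrigues(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
               angle_deg: float) -> np.ndarray:
    u = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    p = points - origin
    rot = (p * math.cos(th)
           + np.cross(u, p) * math.sin(th)
           + np.outer(p @ u, u) * (1.0 - math.cos(th)))
    return rot + origin


def _build_chain_cart(n: int = 10, bond: float = 1.4, angle: float = 120.0) -> np.ndarray:
    """Planar zig-zag carbon chain (polyene-like) in Cartesian Å."""
    half = math.radians(angle / 2.0)
    dx = bond * math.sin(half)
    dy = bond * math.cos(half)
    pts = np.array([[i * dx, (i % 2) * dy, 0.0] for i in range(n)])
    return pts - pts.mean(axis=0)


def make_two_state_crystal(seed: int, cell: UnitCell = DEFAULT_CELL,
                           n_atoms: int = 90, torsion_change: float = 80.0,
                           alpha: float = 0.25, noise_frac: float = 0.03,
                           d_min: float = 1.3, chain_len: int = 10,
                           torsion_atoms: tuple = (3, 4, 5, 6)):
    """Dark/light conformer pair plus mixed-occupancy reflection data.

    The light model differs from the dark only by a rotation of
    ``torsion_change`` degrees about the bond between torsion atoms 2 and 3
    (all bond lengths and angles preserved).  Observed light amplitudes are
    the coherent mixture |α·F_light + (1−α)·F_dark| with independent Gaussian
    noise of sd = noise_frac·|F| on both sets; σF records the applied sd.

    Returns (dark_model, light_model, f_dark_obs, f_light_obs, truth).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha {alpha} outside [0, 1]")
    if n_atoms < chain_len:
        raise ValueError(f"n_atoms must be at least the chain length {chain_len}")
    if d_min < 0.8:
        raise ValueError("d_min below 0.8 Å is outside the toy regime")
    rng = np.random.default_rng(seed)

    chain = _build_chain_cart(chain_len)
    center = cell.orthogonalize(np.array([0.5, 0.5, 0.5]))
    chain = chain + center
    i1, i2, i3, i4 = torsion_atoms
    v1 = chain[i2] - chain[i1]
    v2 = chain[i3] - chain[i2]
    if np.linalg.norm(np.cross(v1, v2)) < 1e-6:
        raise ValueError("designated torsion atoms are collinear")

    atoms = []
    for i, p in enumerate(chain):
        atoms.append(Atom(id=f"C{i + 1}", element="C", chain="A",
                          residue_name="LIG", residue_number=1,
                          frac=cell.fractionalize(p),
                          occupancy=1.0, b_iso=10.0 + 2.0 * rng.random()))
    # decoy atoms: protein-like scatterers at >= 2 A separation
    decoys_cart = []
    elements = ["C", "N", "O"]
    guard = 0
    while len(decoys_cart) < n_atoms - chain_len:
        guard += 1
        if guard > 10000:
            raise RuntimeError("could not place decoy atoms")
        p = cell.orthogonalize(rng.random(3))
        all_pts = np.vstack([chain] + decoys_cart) if decoys_cart else chain
        dfrac = cell.fractionalize(p - all_pts)
        dfrac -= np.rint(dfrac)
        if np.min(np.linalg.norm(cell.orthogonalize(dfrac), axis=1)) < 2.0:
            continue
        decoys_cart.append(p[None, :])
        j = len(decoys_cart)
        atoms.append(Atom(id=f"X{j}", element=elements[j % 3], chain="B",
                          residue_name="DEC", residue_number=j,
                          frac=cell.fractionalize(p),
                          occupancy=1.0, b_iso=12.0 + 4.0 * rng.random()))
    dark = AtomicModel(cell=cell, atoms=atoms, spacegroup="P 1",
                       provenance=f"synthetic dark seed={seed}")

    light = dark.copy()
    light.provenance = f"synthetic light seed={seed}"
    branch = list(range(i3 + 1, chain_len))  # atoms beyond the rotation bond
    axis = chain[i3] - chain[i2]
    for bi in branch:
        newp = _rodrigues(chain[bi][None, :], chain[i2], axis, torsion_change)[0]
        light.atoms[bi].frac = cell.fractionalize(newp)

    f_dark_c = diffmap.calc_structure_factors(dark, d_min)
    f_light_c = diffmap.calc_structure_factors(light, d_min)
    mix = np.abs(alpha * f_light_c.complex_f + (1.0 - alpha) * f_dark_c.complex_f)

    sig_dark = noise_frac * f_dark_c.f
    sig_light = noise_frac * mix
    f_dark_obs = ReflectionSet(
        cell=cell, hkl=f_dark_c.hkl.copy(),
        f=np.maximum(f_dark_c.f + rng.normal(0.0, 1.0, len(f_dark_c)) * sig_dark, 0.0),
        sigf=sig_dark, label="F_dark_obs")
    f_light_obs = ReflectionSet(
        cell=cell, hkl=f_light_c.hkl.copy(),
        f=np.maximum(mix + rng.normal(0.0, 1.0, len(f_light_c)) * sig_light, 0.0),
        sigf=sig_light, label="F_light_obs")

    disp = {da.id: float(np.linalg.norm(cell.orthogonalize(da.frac - la.frac)))
            for da, la in zip(dark.atoms, light.atoms)}
    truth = SyntheticTruth(
        seed=seed, alpha_true=alpha, noise_sigma=noise_frac,
        description="two-state toy crystal",
        extra={"torsion_change": torsion_change, "torsion_atoms": list(torsion_atoms),
               "moved_atoms": [f"C{b + 1}" for b in branch],
               # atoms displaced far enough that their dark-position density
               # fully vacates: the natural mask for the N_EXT scan
               "mask_atoms": [aid for aid, d in disp.items() if d >= 2.0],
               "displacements": disp, "d_min": d_min},
    )
    return dark, light, f_dark_obs, f_light_obs, truth


# --------------------------------------------------------------------------
# Photo-kinetic time series


def _gaussian_bands(channels: np.ndarray, bands: list) -> np.ndarray:
    out = np.zeros(len(channels))
    for center, width, amp in bands:
        out += amp * np.exp(-0.5 * ((channels - center) / width) ** 2)
    return out


def default_species_spectra(channels: np.ndarray, kind: str = "uvvis") -> np.ndarray:
    """Distinct per-compartment band spectra for a 4-species scheme.

    UV/Vis species are positive Gaussian absorption bands shifting to the
    red as the photoproduct evolves; FTIR species are signed difference-like
    band patterns (induced positive, bleached negative).
    """
    if kind == "uvvis":
        bands = [
            [(480.0, 30.0, 0.2), (350.0, 25.0, 0.05)],
            [(510.0, 35.0, 0.5), (350.0, 25.0, 0.15)],
            [(530.0, 40.0, 0.8), (360.0, 28.0, 0.25)],
            [(550.0, 45.0, 1.0), (365.0, 30.0, 0.3)],
        ]
    else:
        bands = [
            [(1650.0, 8.0, 0.3), (1542.0, 6.0, -0.2)],
            [(1640.0, 9.0, 0.6), (1542.0, 6.0, -0.5), (1620.0, 7.0, 0.2)],
            [(1655.0, 10.0, 0.8), (1542.0, 6.0, -0.8), (1600.0, 9.0, 0.3)],
            [(1660.0, 11.0, 1.0), (1542.0, 6.0, -1.0), (1580.0, 10.0, 0.4)],
        ]
    return np.array([_gaussian_bands(channels, b) for b in bands])


def make_photo_timeseries(seed: int, scheme: KineticScheme,
                          species_spectra: np.ndarray, channels: np.ndarray,
                          t_max: float, dt: float,
                          integration_window: float = 0.0,
                          noise_sigma: float = 0.0,
                          kind: str = "uvvis", label: str = ""):
    """D(t, λ) = Σ_i c_i(t)·S_i(λ) + N(0, noise_sigma²).

    When ``integration_window`` exceeds the sampling step, each stored row is
    the analytic time average of the concentrations over [t, t + window]
    (FTIR emulation).  Returns (dataset, truth).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    species_spectra = np.atleast_2d(np.asarray(species_spectra, float))
    channels = np.asarray(channels, float)
    if species_spectra.shape != (scheme.n_comp, len(channels)):
        raise ValueError(
            f"species_spectra shape {species_spectra.shape} does not match "
            f"({scheme.n_comp}, {len(channels)})")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + 0.5 * dt, dt)
    c = windowed_concentrations(scheme, times, integration_window)
    values = c @ species_spectra + rng.normal(0.0, noise_sigma, (len(times), len(channels)))
    ds = SpectroDataset(times=times, channels=channels, values=values, kind=kind,
                        integration_window=integration_window,
                        label=label or f"synthetic-{kind}")
    truth = SyntheticTruth(seed=seed, lifetimes_true=scheme.lifetimes,
                           species_spectra_true=species_spectra,
                           noise_sigma=noise_sigma,
                           description=f"sequential-scheme {kind} time series")
    return ds, truth


def make_linked_photo_pair(seed: int,
                           scheme: KineticScheme = KineticScheme((13.0, 38.0, 162.0, math.inf)),
                           t_max: float = 600.0, dt_uvvis: float = 1.0,
                           ftir_window: float = 35.0,
                           noise_frac: float = 0.01):
    """Linked UV/Vis + FTIR pair sharing one concentration history.

    Emulates the study conditions: 10 min of continuous illumination, 1 s
    UV/Vis sampling, FTIR spectra acquired over 35 s windows; noise sd is
    ``noise_frac`` of each dataset's maximum signal.  Returns
    (uvvis_dataset, ftir_dataset, truth).
    """
    ch_uv = np.arange(320.0, 651.0, 5.0)
    ch_ir = np.arange(1500.0, 1701.0, 2.0)
    s_uv = default_species_spectra(ch_uv, "uvvis")
    s_ir = default_species_spectra(ch_ir, "ftir")
    noise_uv = noise_frac * np.abs(windowed_concentrations(scheme,
                                   np.arange(0.0, t_max, dt_uvvis), 0.0) @ s_uv).max()
    noise_ir = noise_frac * np.abs(s_ir).max()
    uv, truth = make_photo_timeseries(seed, scheme, s_uv, ch_uv, t_max, dt_uvvis,
                                      0.0, noise_uv, "uvvis", "uvvis-synthetic")
    ir, _ = make_photo_timeseries(seed + 1, scheme, s_ir, ch_ir,
                                  t_max - ftir_window, ftir_window,
                                  ftir_window, noise_ir, "ftir", "ftir-synthetic")
    truth.description = "linked uvvis+ftir sequential-scheme pair"
    truth.extra = {"noise_uvvis": noise_uv, "noise_ftir": noise_ir,
                   "ftir_window": ftir_window}
    return uv, ir, truth


# --------------------------------------------------------------------------
# Saturating trace


def make_saturating_trace(seed: int, a1: float = 0.02, t1: float = 38.0,
                          a2: float = 0.44, t2: float = 291.0,
                          t_max: float = 600.0, dt: float = 0.5,
                          noise_sigma: float = 0.005, channel: float = 550.0):
    """Y(t) = A1·(1 − e^{−t/t1}) + A2·(1 − e^{−t/t2}) + N(0, noise_sigma²).

    Defaults are the photoconversion trace parameters at 550 nm.  Returns
    (single-channel dataset, truth).
    """
    if t1 <= 0 or t2 <= 0:
        raise ValueError("lifetimes must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + 0.5 * dt, dt)
    y = a1 * -np.expm1(-times / t1) + a2 * -np.expm1(-times / t2)
    y = y + rng.normal(0.0, noise_sigma, len(times))
    ds = SpectroDataset(times=times, channels=np.array([channel]),
                        values=y[:, None], kind="uvvis", label="trace-synthetic")
    truth = SyntheticTruth(seed=seed, noise_sigma=noise_sigma,
                           description="saturating double-exponential trace",
                           extra={"A1": a1, "t1": t1, "A2": a2, "t2": t2})
    return ds, truth


# --------------------------------------------------------------------------
# Ideal helix backbone (geometry test fixture generator)

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: new atom at given internal coordinates from a-b-c."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  bond * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_helix_backbone(n_res: int = 10, phi: float = -57.0, psi: float = -47.0,
                         cell: UnitCell | None = None) -> AtomicModel:
    """Ideal polyalanine-like backbone (N, CA, C, O) at given (φ, ψ).

    The α-helical default places O_i···N_{i+4} at hydrogen-bonding distance;
    intended as a reproducible fixture for H-bond and torsion analysis.
    """
    n_i = np.array([0.0, 0.0, 0.0])
    ca_i = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = math.radians(_ANGLE["N-CA-C"])
    c_i = ca_i + _BOND["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords: list[tuple[str, int, np.ndarray]] = [
        ("N", 1, n_i), ("CA", 1, ca_i), ("C", 1, c_i)]
    for i in range(2, n_res + 1):
        # psi: N-CA-C-N(+1); omega (180): CA-C-N(+1)-CA(+1); phi: C-N(+1)-CA(+1)-C(+1)
        n_next = _place_atom(n_i, ca_i, c_i, _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        ca_next = _place_atom(ca_i, c_i, n_next,
                              _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
        c_next = _place_atom(c_i, n_next, ca_next,
                             _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        n_i, ca_i, c_i = n_next, ca_next, c_next
        coords += [("N", i, n_i), ("CA", i, ca_i), ("C", i, c_i)]

    # carbonyl O anti to the following N: torsion N-CA-C-O = psi + 180
    by_key = {(name, num): xyz for name, num, xyz in coords}
    full: list[tuple[str, int, np.ndarray]] = []
    for name, num, xyz in coords:
        full.append((name, num, xyz))
        if name == "C":
            o = _place_atom(by_key[("N", num)], by_key[("CA", num)], xyz,
                            _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0)
            full.append(("O", num, o))

    pts = np.array([xyz for _, _, xyz in full])
    if cell is None:
        span = pts.max(axis=0) - pts.min(axis=0) + 20.0
        cell = UnitCell(float(span[0]), float(span[1]), float(span[2]))
    shift = -pts.min(axis=0) + 10.0
    atoms = [Atom(id=name, element=name[0], chain="A", residue_name="ALA",
                  residue_number=num, frac=cell.fractionalize(xyz + shift),
                  occupancy=1.0, b_iso=15.0)
             for name, num, xyz in full]
    return AtomicModel(cell=cell, atoms=atoms, spacegroup="P 1",
                       provenance=f"ideal helix phi={phi} psi={psi}")
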