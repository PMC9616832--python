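"""Sequential-compartment kinetics and global analysis of transient spectra.

The kinetic model is the unbranched, unidirectional chain
EAS1 → EAS2 → … → EASn with first-order rates k_i = 1/τ_i; the terminal
compartment may be a steady-state sink (infinite lifetime).  Concentration
profiles follow the Bateman closed form; global fitting uses variable
projection — spectra are eliminated by linear least squares at each step of
a nonlinear search over the shared lifetimes — so several datasets (UV/Vis
and FTIR, H₂O and D₂O buffers) can be linked on one lifetime set while each
keeps its own evolution-associated spectra (EAS).

Continuous-illumination data on the seconds scale need no instrument
response function; time zero is the illumination onset.  FTIR acquisition
windows (tens of seconds per spectrum) are handled by analytic time
averaging of the concentration profiles over each window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .structio import SpectroDataset

logger = logging.getLogger(__name__)

__all__ = [
    "KineticScheme",
    "EASResult",
    "DoubleExpFit",
    "StickSpectrum",
    "concentrations",
    "windowed_concentrations",
    "global_fit",
    "fit_double_exponential",
    "composition_at",
    "broaden_sticks",
    "stick_difference",
]


# --------------------------------------------------------------------------
# Scheme and Bateman solution


@dataclass(frozen=True)
class KineticScheme:
    """Sequential compartments with lifetimes in seconds.

    The last lifetime may be ``inf`` — an absorbing steady-state compartment.
    """

    lifetimes: tuple

    def __post_init__(self):
        lts = tuple(float(t) for t in self.lifetimes)
        object.__setattr__(self, "lifetimes", lts)
        if not lts:
            raise ValueError("scheme needs at least one compartment")
        for i, t in enumerate(lts):
            if t <= 0:
                raise ValueError(f"non-positive lifetime {t}")
            if math.isinf(t) and i != len(lts) - 1:
                raise ValueError("only the last compartment may be steady-state")

    @property
    def n_comp(self) -> int:
        return len(self.lifetimes)

    @property
    def rates(self) -> np.ndarray:
        return np.array([0.0 if math.isinf(t) else 1.0 / t for t in self.lifetimes])


def _bateman_coeffs(rates: np.ndarray) -> np.ndarray:
    """Coefficients a[i, j] with c_i(t) = Σ_j a[i, j]·exp(−k_j t).

    Valid for pairwise-distinct rates; c(0) = (1, 0, …, 0).
    """
    n = len(rates)
    a = np.zeros((n, n))
    for i in range(n):
        prod_k = np.prod(rates[:i]) if i > 0 else 1.0
        for j in range(i + 1):
            denom = 1.0
            for m in range(i + 1):
                if m != j:
                    denom *= rates[m] - rates[j]
            a[i, j] = prod_k / denom
    return a


def _rates_distinct(rates: np.ndarray, rtol: float = 1e-6) -> bool:
    scale = max(rates.max(), 1e-300)
    for i in range(len(rates)):
        for j in range(i + 1, len(rates)):
            if abs(rates[i] - rates[j]) < rtol * scale:
                return False
    return True


def _rate_matrix(rates: np.ndarray) -> np.ndarray:
    n = len(rates)
    a = np.diag(-rates)
    for i in range(1, n):
        a[i, i - 1] = rates[i - 1]
    return a


def concentrations(scheme: KineticScheme, times: np.ndarray) -> np.ndarray:
    """Time × compartment concentration matrix, c(0) = (1, 0, …, 0).

    Uses the Bateman closed form; near-degenerate rates fall back to the
    matrix exponential evaluated per time point (the continuous limit).
    """
    times = np.atleast_1d(np.asarray(times, float))
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    k = scheme.rates
    if _rates_distinct(k):
        a = _bateman_coeffs(k)
        basis = np.exp(-np.outer(times, k))  # (nt, n)
        return basis @ a.T
    amat = _rate_matrix(k)
    c0 = np.zeros(scheme.n_comp)
    c0[0] = 1.0
    return np.array([scipy.linalg.expm(amat * t) @ c0 for t in times])


def windowed_concentrations(scheme: KineticScheme, times: np.ndarray,
                            window: float) -> np.ndarray:
    """Concentrations averaged over [t, t + window] per stored time point.

    The average of each exponential basis term is analytic:
    (1/w)∫ e^{−k(t+u)} du = e^{−kt}·(1 − e^{−kw})/(kw).  With ``window`` ≤ 0
    this reduces to :func:`concentrations`.
    """
    if window <= 0:
        return concentrations(scheme, times)
    times = np.atleast_1d(np.asarray(times, float))
    k = scheme.rates
    if _rates_distinct(k):
        a = _bateman_coeffs(k)
        damp = np.where(k > 0, -np.expm1(-k * window) / np.where(k > 0, k * window, 1.0), 1.0)
        basis = np.exp(-np.outer(times, k)) * damp
        return basis @ a.T
    # degenerate rates: Gauss-Legendre quadrature over each window
    nodes, weights = np.polynomial.legendre.leggauss(12)
    u = 0.5 * window * (nodes + 1.0)
    w = 0.5 * weights  # weights for the mean over the window
    stacked = np.concatenate([times + ui for ui in u])
    c = concentrations(scheme, stacked).reshape(len(u), len(times), scheme.n_comp)
    return np.einsum("q,qtc->tc", w, c)


# --------------------------------------------------------------------------
# Global fitting (variable projection)


@dataclass
class EASResult:
    """Linked sequential-model global fit: lifetimes shared, EAS per dataset."""

    lifetimes: np.ndarray  # fitted τ_i (s); terminal may be inf
    lifetime_stderr: np.ndarray  # stderr of finite lifetimes (nan for inf)
    eas: list  # per-dataset (n_comp, n_channels) spectra
    concentrations: list  # per-dataset (n_times, n_comp), window-averaged
    residual_rms: list  # per dataset
    labels: list

    @property
    def rates(self) -> np.ndarray:
        return np.array([0.0 if math.isinf(t) else 1.0 / t for t in self.lifetimes])


def _design_matrices(datasets, lifetimes) -> list:
    scheme = KineticScheme(tuple(lifetimes))
    return [windowed_concentrations(scheme, ds.times, ds.integration_window)
            for ds in datasets]


def _project(datasets, lifetimes):
    """For fixed lifetimes solve the linear spectra; return residuals + EAS."""
    cs = _design_matrices(datasets, lifetimes)
    residuals, eas = [], []
    for ds, c in zip(datasets, cs):
        s, *_ = np.linalg.lstsq(c, ds.values, rcond=None)
        eas.append(s)
        residuals.append((ds.values - c @ s).ravel())
    return np.concatenate(residuals), eas, cs


def global_fit(datasets, n_comp: int, tau_init, link: bool = True,
               n_starts: int = 3, seed: int = 7,
               max_nfev: int = 400) -> EASResult:
    """Fit shared lifetimes of a sequential scheme across linked datasets.

    ``tau_init`` gives starting lifetimes; a trailing ``inf`` declares a
    steady-state terminal compartment whose rate is fixed at zero.  The
    search runs over log-lifetimes (bounded positive by construction) with
    ``n_starts`` seeded multistarts to escape local minima; spectra are never
    explicit parameters (variable projection).

    With ``link=False`` each dataset is fitted separately and the per-dataset
    results are merged (lifetimes averaged), mainly as a diagnostic.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets")
    tau_init = [float(t) for t in tau_init]
    if len(tau_init) != n_comp:
        raise ValueError("tau_init length must equal n_comp")
    has_terminal = math.isinf(tau_init[-1])
    finite_init = np.array(tau_init[:-1] if has_terminal else tau_init)
    if np.any(finite_init <= 0):
        raise ValueError("initial lifetimes must be positive")

    if not link and len(datasets) > 1:
        parts = [global_fit([ds], n_comp, tau_init, link=True, n_starts=n_starts,
                            seed=seed, max_nfev=max_nfev) for ds in datasets]
        lifetimes = np.mean([p.lifetimes for p in parts], axis=0)
        return EASResult(
            lifetimes=lifetimes,
            lifetime_stderr=np.mean([p.lifetime_stderr for p in parts], axis=0),
            eas=[p.eas[0] for p in parts],
            concentrations=[p.concentrations[0] for p in parts],
            residual_rms=[p.residual_rms[0] for p in parts],
            labels=[ds.label for ds in datasets],
        )

    # rank diagnostic: more compartments than the data can support
    for ds in datasets:
        rank = np.linalg.matrix_rank(ds.values, tol=None)
        if rank < n_comp:
            logger.warning(
                "global_fit: dataset %r has numerical rank %d < n_comp %d; "
                "fit may be degenerate", ds.label, rank, n_comp,
            )

    def full_tau(log_tau):
        tau = list(np.exp(log_tau))
        if has_terminal:
            tau.append(math.inf)
        return tau

    def resid(log_tau):
        r, _, _ = _project(datasets, full_tau(log_tau))
        return r

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        x0 = np.log(finite_init)
        if start > 0:
            x0 = x0 + rng.normal(0.0, 0.3, size=x0.shape)
        sol = scipy.optimize.least_squares(resid, x0, method="lm", max_nfev=max_nfev)
        if best is None or sol.cost < best.cost:
            best = sol
    if not best.success and best.cost > 1e-6:
        logger.warning("global_fit: optimizer flag %s (%s)", best.status, best.message)

    tau_hat = np.exp(best.x)
    # stderr via Gauss-Newton covariance in log space, mapped back
    m, p = len(best.fun), len(best.x)
    stderr = np.full(len(tau_hat), np.nan)
    if m > p:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * 2.0 * best.cost / (m - p)
            stderr = np.sqrt(np.diag(cov)) * tau_hat  # delta method from log
        except np.linalg.LinAlgError:
            pass

    _, eas, cs = _project(datasets, full_tau(best.x))
    lifetimes = np.concatenate([tau_hat, [math.inf]]) if has_terminal else tau_hat
    stderr_full = np.concatenate([stderr, [np.nan]]) if has_terminal else stderr
    rms = [float(np.sqrt(np.mean((ds.values - c @ s) ** 2)))
           for ds, c, s in zip(datasets, cs, eas)]
    return EASResult(lifetimes=lifetimes, lifetime_stderr=stderr_full, eas=eas,
                     concentrations=cs, residual_rms=rms,
                     labels=[ds.label for ds in datasets])


# --------------------------------------------------------------------------
# Double-exponential trace fit


@dataclass
class DoubleExpFit:
    """Y(t) = A1·(1 − e^{−t/t1}) + A2·(1 − e^{−t/t2}), t1 ≤ t2."""

    a1: float
    t1: float
    a2: float
    t2: float
    residual_rms: float


def _double_exp(t, a1, t1, a2, t2):
    return a1 * -np.expm1(-t / t1) + a2 * -np.expm1(-t / t2)


def fit_double_exponential(trace: SpectroDataset,
                           init: tuple = (0.1, 30.0, 0.4, 300.0)) -> DoubleExpFit:
    """Least-squares fit of a saturating double exponential to one channel.

    The rising saturating form (negative exponents) is used; lifetimes are
    reported ordered t1 ≤ t2.
    """
    if trace.values.shape[1] != 1:
        raise ValueError("trace must have exactly one channel")
    t = trace.times
    y = trace.values[:, 0]
    if len(t) < 8:
        raise ValueError("need at least 8 points for a double-exponential fit")
    a1, t1, a2, t2 = init
    if t1 <= 0 or t2 <= 0:
        raise ValueError("initial lifetimes must be positive")

    def resid(p):
        return _double_exp(t, p[0], np.exp(p[1]), p[2], np.exp(p[3])) - y

    sol = scipy.optimize.least_squares(
        resid, [a1, np.log(t1), a2, np.log(t2)], method="lm", max_nfev=2000)
    if not sol.success and np.sqrt(np.mean(sol.fun**2)) > 10 * np.std(y):
        raise RuntimeError(f"double-exponential fit did not converge: {sol.message}; "
                           f"best iterate {sol.x}")
    pa1, pt1, pa2, pt2 = sol.x[0], np.exp(sol.x[1]), sol.x[2], np.exp(sol.x[3])
    if pt1 > pt2:
        pa1, pt1, pa2, pt2 = pa2, pt2, pa1, pt1
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return DoubleExpFit(a1=float(pa1), t1=float(pt1), a2=float(pa2),
                        t2=float(pt2), residual_rms=rms)


# --------------------------------------------------------------------------
# Composition


def composition_at(scheme: KineticScheme, t: float,
                   exclude_terminal: bool = True) -> np.ndarray:
    """Percentage composition of the compartments at time t.

    With ``exclude_terminal`` the steady-state sink (infinite lifetime) is
    dropped before renormalizing to 100% — the population estimate among the
    still-evolving species.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    c = concentrations(scheme, np.array([t]))[0]
    if exclude_terminal and math.isinf(scheme.lifetimes[-1]):
        c = c[:-1]
    total = c.sum()
    if total <= 0:
        raise ValueError("all included concentrations are zero")
    return 100.0 * c / total


# --------------------------------------------------------------------------
# Stick-spectrum broadening


@dataclass
class StickSpectrum:
    """Computed vibrational lines: positions (cm⁻¹) and intensities (km/mol).

    ``scale`` is the harmonic-frequency scaling factor applied before
    broadening; ``fwhm`` the Lorentzian full width at half maximum.
    """

    frequencies: np.ndarray
    intensities: np.ndarray
    scale: float = 0.97
    fwhm: float = 4.0

    def __post_init__(self):
        self.frequencies = np.atleast_1d(np.asarray(self.frequencies, float))
        self.intensities = np.atleast_1d(np.asarray(self.intensities, float))
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if len(self.frequencies) != len(self.intensities):
            raise ValueError("frequency/intensity length mismatch")


def broaden_sticks(sticks: StickSpectrum, grid: np.ndarray) -> np.ndarray:
    """Lorentzian-broadened spectrum on ``grid`` (cm⁻¹).

    Each line becomes a Lorentzian centred at scale × frequency with the
    stick's FWHM and area proportional to its intensity:
    L(x) = I · (Γ/2π) / ((x − x0)² + (Γ/2)²).
    """
    grid = np.asarray(grid, float)
    gamma = sticks.fwhm
    centers = sticks.scale * sticks.frequencies
    x = grid[:, None] - centers[None, :]
    lor = (gamma / (2.0 * np.pi)) / (x**2 + (gamma / 2.0) ** 2)
    return lor @ sticks.intensities


def stick_difference(a: StickSpectrum, b: StickSpectrum,
                     grid: np.ndarray) -> np.ndarray:
    """broaden(a) − broaden(b): induced-minus-bleached difference spectrum."""
    return broaden_sticks(a, grid) - broaden_sticks(b, grid)
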