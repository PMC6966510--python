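"""MSD analysis: per-trajectory mean-squared displacement, confined-
diffusion model fitting (D, L), and group summaries.

The measured time-averaged MSD of a receptor confined by the cortical
meshwork is modelled as

    rho(dt) = (L**2 / 3) * (1 - exp(-dt / tau)) + 4 * D_M * dt + c

i.e. a confined plateau ``L**2 / 3`` (square corral, two axes) reached
with relaxation time ``tau``, a long-time linear term from inter-
compartment hopping with macroscopic diffusivity ``D_M``, and a static
offset ``c = 4 * sigma_loc**2`` from localization noise.

The headline short-time diffusivity ``D`` is estimated separately as the
slope / 4 of an offset-corrected weighted linear fit to lags 2-5; lag 1
is excluded to limit the leverage of the noise offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .membrane_sim import Trajectory2D

__all__ = [
    "MSDCurve",
    "ConfinedFit",
    "GroupSummary",
    "TooShortTrajectoryError",
    "compute_msd",
    "fit_confined",
    "estimate_short_time_D",
    "summarize_group",
    "percent_increase",
]

MIN_LEN_DEFAULT = 50  # QC: frames below which a track is rejected


class TooShortTrajectoryError(ValueError):
    """Raised when a trajectory fails the minimum-length QC filter."""


@dataclass
class MSDCurve:
    """Time-averaged MSD versus lag with displacement-pair counts."""

    lags: np.ndarray  # s, strictly increasing, starting at dt
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray  # pairs per lag, decreasing

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be >= 0")
        if np.any(np.diff(self.n_pairs) > 0):
            raise ValueError("n_pairs must be non-increasing in lag")


@dataclass
class ConfinedFit:
    """Per-trajectory estimates from the confined-diffusion MSD model.

    ``D`` is the short-time (lags 2-5) estimate in µm²/s; ``L`` the
    confinement size in nm from the plateau term; ``D_M`` the long-time
    hop diffusivity; ``c`` the static noise offset.  ``confined`` is
    False when the plateau is not resolved within the fitted lag window
    (tau comparable to the window), in which case ``L`` is unreliable.
    """

    D: float  # µm²/s, short-time slope estimate
    L: float  # nm
    tau: float  # s
    c: float  # µm²
    D_M: float  # µm²/s
    rss: float
    converged: bool
    confined: bool = True


@dataclass
class GroupSummary:
    """Mean ± SEM of D and L over the converged fits of one group."""

    label: str
    mean_D: float
    sem_D: float
    mean_L: float
    sem_L: float
    n: int


def compute_msd(traj: Trajectory2D, max_lag_frac: float = 0.25,
                min_len: int = MIN_LEN_DEFAULT) -> MSDCurve:
    """Time-averaged MSD with overlapping pairs.

    rho(k*dt) = mean over i of |r(i+k) - r(i)|**2, for lags
    k = 1 .. floor(max_lag_frac * len(traj)).
    """
    if not (0.0 < max_lag_frac <= 0.5):
        raise ValueError("max_lag_frac must be in (0, 0.5]")
    n = len(traj)
    if n < min_len:
        raise TooShortTrajectoryError(
            f"trajectory of {n} frames is below the QC minimum of {min_len}"
        )
    max_lag = max(1, int(max_lag_frac * n))
    dt = traj.dt
    r = np.column_stack([traj.x, traj.y])
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=int)
    for k in range(1, max_lag + 1):
        d = r[k:] - r[:-k]
        msd[k - 1] = np.mean(np.sum(d * d, axis=1))
        n_pairs[k - 1] = n - k
    return MSDCurve(lags=np.arange(1, max_lag + 1) * dt, msd=msd, n_pairs=n_pairs)


def _confined_model(t: np.ndarray, plateau: float, tau: float,
                    D_M: float, c: float) -> np.ndarray:
    return plateau * (1.0 - np.exp(-t / tau)) + 4.0 * D_M * t + c


def estimate_short_time_D(msd: MSDCurve, lag_lo: int = 2, lag_hi: int = 5) -> float:
    """Offset-corrected short-time diffusivity: slope / 4 of a weighted
    (by n_pairs) linear fit with intercept to lags ``lag_lo``-``lag_hi``,
    clipped below at 0."""
    if len(msd.lags) < lag_hi:
        raise ValueError(f"need at least {lag_hi} lag points")
    sl = slice(lag_lo - 1, lag_hi)
    t, y, w = msd.lags[sl], msd.msd[sl], msd.n_pairs[sl].astype(float)
    slope, _ = np.polyfit(t, y, 1, w=np.sqrt(w))
    return max(0.0, slope / 4.0)


def fit_confined(msd: MSDCurve, sigma_loc_guess: float = 20.0,
                 max_nfev: int = 500) -> ConfinedFit:
    """Fit the confined + hop + static-noise MSD model.

    Weighted least squares (weights = n_pairs) with non-negative bounds
    on all parameters.  Initialization: plateau from the tail of the
    curve minus the extrapolated offset, tau from the lag at half
    plateau, D_M from the tail slope, c from the lag-0 extrapolation.
    Non-convergence is flagged, not raised.
    """
    if len(msd.lags) < 8:
        raise ValueError("need >= 8 lag points for the confined fit")
    t, y = msd.lags, msd.msd
    sigma = 1.0 / np.sqrt(msd.n_pairs.astype(float))

    c0 = max(1e-12, min(2.0 * y[0] - y[1], np.min(y)))
    tail = y[-max(3, len(y) // 10):]
    plateau0 = max(np.mean(tail) - c0, 0.5 * y[0], 1e-9)
    above = np.flatnonzero(y - c0 >= 0.5 * plateau0)
    tau0 = t[above[0]] if above.size else t[len(t) // 4]
    k_tail = max(3, len(y) // 5)
    slope_tail = np.polyfit(t[-k_tail:], y[-k_tail:], 1)[0]
    DM0 = max(slope_tail / 4.0, 0.0)

    D_short = estimate_short_time_D(msd)
    try:
        popt, _ = curve_fit(
            _confined_model, t, y,
            p0=[plateau0, tau0, DM0, c0],
            sigma=sigma, absolute_sigma=False,
            bounds=([0.0, 1e-8, 0.0, 0.0], [np.inf] * 4),
            max_nfev=max_nfev,
        )
        plateau, tau, D_M, c = popt
        rss = float(np.sum(msd.n_pairs * (y - _confined_model(t, *popt)) ** 2))
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, ValueError):
        return ConfinedFit(D=D_short, L=np.nan, tau=np.nan, c=np.nan,
                           D_M=np.nan, rss=np.nan, converged=False,
                           confined=False)
    # plateau unresolved when relaxation is not much shorter than the window
    confined = bool(tau < 0.5 * t[-1])
    L_nm = float(np.sqrt(3.0 * plateau) * 1000.0)
    return ConfinedFit(D=D_short, L=L_nm, tau=float(tau), c=float(c),
                       D_M=float(D_M), rss=rss, converged=converged,
                       confined=confined)


def summarize_group(fits: list[ConfinedFit], label: str) -> GroupSummary:
    """Arithmetic mean and SEM (SD/sqrt(n), ddof=1) of D and L over the
    converged fits; a single fit yields SEM = 0 by convention."""
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError(f"group {label!r} has no converged fits")
    D = np.array([f.D for f in ok])
    L = np.array([f.L for f in ok])
    n = len(ok)
    sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0  # noqa: E731
    return GroupSummary(label=label, mean_D=float(D.mean()), sem_D=sem(D),
                        mean_L=float(L.mean()), sem_L=sem(L), n=n)


def percent_increase(a: float, b: float) -> float:
    """Percent by which ``a`` exceeds ``b``: 100 * (a - b) / b.

    Display convention rounds to the nearest integer percent.
    """
    if b <= 0:
        raise ValueError("reference value must be > 0")
    return 100.0 * (a - b) / b
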