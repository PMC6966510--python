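"""Receptor internalization metrics from 3D trajectories.

Internalization of a membrane receptor appears in a 3D track as a
membrane-resident phase (z fluctuating about the membrane plane) followed
by directed inward transport.  Two summary metrics are computed from the
inward-displacement series d(t) = z(t) - z_mem:

* time-weighted inward movement (twi, µm): the dwell-time-weighted mean
  of d(t), i.e. the time integral of d divided by the track duration;
* internalization velocity (v_in, µm/s): the drift of the transport
  phase of a two-phase (flat membrane phase, linear transport phase)
  model of d(t).

The phase boundary (onset of directed transport) is located by a profile
likelihood that models membrane-phase positions as white noise about a
plateau and transport-phase displacement increments as white noise about
a constant drift.  Working in increments for the transport phase is the
generalized-least-squares treatment of Brownian path fluctuations;
fitting the transport phase by ordinary least squares on positions would
let the accumulated (correlated) Brownian deviations drag the breakpoint
and bias the velocity upward.  Given the onset, the drift estimate is
the mean post-onset increment per frame interval, i.e. the endpoint
displacement over the transport-phase duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .membrane_sim import Trajectory3D

__all__ = ["InwardResult", "inward_series", "analyze_inward"]


@dataclass
class InwardResult:
    twi: float  # µm, time-weighted inward movement
    v_in: float  # µm/s, internalization velocity (>= 0)
    t_onset: float  # s, onset of the directed phase (NaN if none detected)
    rss: float  # residual sum of squares of the accepted model
    directed: bool  # True if a two-phase model beat a single line


def inward_series(traj: Trajectory3D) -> tuple[np.ndarray, np.ndarray]:
    """Inward displacement d(t) = z(t) - z_mem at the trajectory sampling.

    If ``z_mem`` is unset (NaN), it defaults to the median z over the
    first second of the track (robust to initial localization noise).
    """
    if traj.z.size == 0:
        raise ValueError("trajectory has no z coordinate")
    z_mem = traj.z_mem
    if not np.isfinite(z_mem):
        first = traj.t <= traj.t[0] + 1.0
        z_mem = float(np.median(traj.z[first]))
    return traj.t.copy(), traj.z - z_mem


def _hinge_rss_scan(t: np.ndarray, d: np.ndarray,
                    margin: int) -> tuple[float, int]:
    """Min RSS of d ~ b0 + b2 * max(t - t_j, 0) over breakpoints j.

    Closed-form normal equations via suffix cumulative sums; O(n).
    """
    n = len(t)
    j = np.arange(margin, n - margin)
    rt = np.cumsum(t[::-1])[::-1]
    rtt = np.cumsum((t * t)[::-1])[::-1]
    rd = np.cumsum(d[::-1])[::-1]
    rtd = np.cumsum((t * d)[::-1])[::-1]

    def suffix(arr, k):  # sum over i > k
        return np.where(k + 1 < n, np.append(arr, 0.0)[k + 1], 0.0)

    nc = n - 1 - j
    sh = suffix(rt, j) - nc * t[j]
    shh = suffix(rtt, j) - 2 * t[j] * suffix(rt, j) + nc * t[j] ** 2
    shd = suffix(rtd, j) - t[j] * suffix(rd, j)
    sd = np.sum(d)
    sdd = np.sum(d * d)
    det = n * shh - sh ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        b2 = (n * shd - sh * sd) / det
        b0 = (sd - b2 * sh) / n
        rss = sdd - b0 * sd - b2 * shd
    rss = np.where(det > 1e-300, rss, np.inf)
    i = int(np.argmin(rss))
    return float(rss[i]), int(j[i])


def _onset_likelihood_scan(d: np.ndarray, margin: int) -> int | None:
    """Two-phase changepoint: plateau positions before j, drift
    increments after j; returns argmax of the profile log-likelihood."""
    n = len(d)
    u = np.diff(d)
    m = len(u)
    j = np.arange(margin, min(n - margin, m - 2))
    if j.size == 0:
        return None
    c1 = np.cumsum(d)
    c2 = np.cumsum(d * d)
    s1 = c2[j - 1] / j - (c1[j - 1] / j) ** 2
    su1 = np.cumsum(u)
    su2 = np.cumsum(u * u)
    cnt = m - j
    mean2 = (su1[-1] - su1[j - 1]) / cnt
    s2 = (su2[-1] - su2[j - 1]) / cnt - mean2 ** 2
    valid = (s1 > 0) & (s2 > 0)
    if not valid.any():
        return None
    ll = np.where(valid,
                  -0.5 * j * np.log(np.where(valid, s1, 1.0))
                  - 0.5 * cnt * np.log(np.where(valid, s2, 1.0)),
                  -np.inf)
    return int(j[int(np.argmax(ll))])


def analyze_inward(traj: Trajectory3D, min_duration: float = 10.0,
                   rss_ratio_threshold: float = 0.8,
                   margin: int = 5) -> InwardResult:
    """Compute time-weighted inward movement and internalization velocity.

    twi is the trapezoidal time integral of d(t) over the track divided
    by its duration (exact for piecewise-linear d).  A directed phase is
    accepted when the best plateau-plus-line model improves on a single
    line by an RSS ratio below ``rss_ratio_threshold``; its velocity is
    the mean post-onset displacement increment per frame (clipped at 0),
    with the onset from the profile-likelihood changepoint.  Without a
    directed phase, v_in is a robust (Theil-Sen) overall slope clipped
    at 0 and t_onset is NaN.
    """
    t, d = inward_series(traj)
    T = t[-1] - t[0]
    if T < min_duration:
        raise ValueError(
            f"track duration {T:.1f} s below the {min_duration:.0f} s QC minimum"
        )
    twi = float(np.trapezoid(d, t) / T)
    dt = float(np.median(np.diff(t)))

    # single-line reference fit
    A = np.column_stack([np.ones_like(t), t])
    beta1, res1, *_ = np.linalg.lstsq(A, d, rcond=None)
    rss1 = float(res1[0]) if res1.size else float(np.sum((d - A @ beta1) ** 2))

    if rss1 == 0.0:
        # exactly linear d(t): slope unambiguous, onset at track start
        v = float(beta1[1])
        return InwardResult(twi=twi, v_in=max(0.0, v), t_onset=t[0],
                            rss=0.0, directed=v > 0)

    rss2, _ = _hinge_rss_scan(t, d, margin)
    if rss2 / rss1 < rss_ratio_threshold:
        j = _onset_likelihood_scan(d, margin)
        if j is not None:
            u = np.diff(d)
            v = float(np.mean(u[j:]) / dt)
            return InwardResult(twi=twi, v_in=max(0.0, v), t_onset=float(t[j]),
                                rss=rss2, directed=True)
    robust = stats.theilslopes(d, t).slope
    return InwardResult(twi=twi, v_in=max(0.0, float(robust)), t_onset=np.nan,
                        rss=rss1, directed=False)
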