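"""Spot detection and trajectory linking for SPT movies.

Detection: local maxima above a robust background threshold
(median + threshold_sigmas * 1.4826 * MAD), refined to subpixel
coordinates by least-squares 2D Gaussian fitting in a local window.

Linking: greedy mutual-nearest-neighbour frame-to-frame assignment
within a maximum displacement, with gap closing over short detection
drop-outs; short tracks are discarded by a minimum-length filter.
Movies in this assay are sparse (a few particles per field), so global
assignment buys little over the greedy scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from .membrane_sim import ImageStack, Trajectory2D

__all__ = ["Localization", "LinkParams", "detect_spots", "link_spots",
           "track_movie"]


@dataclass
class Localization:
    frame: int
    x_px: float
    y_px: float
    intensity: float  # fitted integrated intensity, a.u.
    fit_sigma: float  # px
    success: bool


@dataclass(frozen=True)
class LinkParams:
    max_disp: float = 4.0  # px per frame
    max_gap: int = 2  # frames a particle may vanish
    min_len: int = 50  # minimum trajectory length, frames

    def __post_init__(self) -> None:
        if self.max_disp <= 0:
            raise ValueError("max_disp must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")


def _gaussian_fit(window: np.ndarray, sigma0: float) -> tuple[float, float, float, float, bool]:
    """LS fit of A*exp(-((x-x0)^2+(y-y0)^2)/(2 s^2)) + b to a window.

    Returns (x0, y0, amplitude, sigma, success) in window coordinates.
    """
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w]
    b0 = float(np.median(window))
    a0 = float(window.max() - b0)
    cy, cx = np.unravel_index(np.argmax(window), window.shape)

    def resid(p):
        x0, y0, a, s, b = p
        model = a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s ** 2)) + b
        return (model - window).ravel()

    try:
        res = least_squares(
            resid, [cx, cy, max(a0, 1e-6), sigma0, b0],
            bounds=([-1, -1, 0, 0.3, -np.inf], [w, h, np.inf, max(w, h), np.inf]),
            max_nfev=200,
        )
        x0, y0, a, s, _ = res.x
        return float(x0), float(y0), float(a * 2 * np.pi * s ** 2), float(s), bool(res.success)
    except Exception:
        return float(cx), float(cy), float(a0), sigma0, False


def detect_spots(frame: np.ndarray, threshold_sigmas: float = 5.0,
                 psf_sigma_px: float = 1.2,
                 frame_index: int = 0) -> list[Localization]:
    """Detect and localize diffraction-limited spots in one frame.

    Candidates are local maxima of the matched-filtered (PSF-width
    Gaussian-smoothed) image above a robust threshold
    (median + threshold_sigmas * 1.4826 * MAD of the smoothed image);
    matched filtering suppresses single-pixel shot noise.  Each
    candidate is refined on the raw image by a least-squares 2D
    Gaussian fit for subpixel coordinates.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("detect_spots expects a single 2D frame")
    smooth = gaussian_filter(frame, psf_sigma_px)
    bg = float(np.median(smooth))
    mad = float(np.median(np.abs(smooth - bg)))
    noise = 1.4826 * mad
    thresh = bg + threshold_sigmas * noise + 1e-9
    min_dist = max(2, int(round(2 * psf_sigma_px)))
    peaks = peak_local_max(smooth, min_distance=min_dist, threshold_abs=thresh,
                           exclude_border=False)

    half = max(3, int(round(3 * psf_sigma_px)))
    out: list[Localization] = []
    for py, px in peaks:
        y0, y1 = max(0, py - half), min(frame.shape[0], py + half + 1)
        x0, x1 = max(0, px - half), min(frame.shape[1], px + half + 1)
        win = frame[y0:y1, x0:x1]
        fx, fy, inten, s, ok = _gaussian_fit(win, psf_sigma_px)
        out.append(Localization(frame=frame_index, x_px=x0 + fx, y_px=y0 + fy,
                                intensity=inten, fit_sigma=s, success=ok))
    return out


def link_spots(locs: list[list[Localization]], params: LinkParams,
               pixel_nm: float = 107.0, fps: float = 20.0) -> list[Trajectory2D]:
    """Link per-frame localizations into trajectories.

    ``locs[f]`` holds the localizations of frame f.  Assignment is
    greedy by globally smallest distance among mutually admissible
    track-head/detection pairs; a track stays open for ``max_gap``
    missed frames, with the admissible distance scaled by the number of
    frames bridged.  Each localization joins at most one track; tracks
    shorter than ``min_len`` detections are discarded.
    """
    for f, fl in enumerate(locs):
        if any(loc.frame != f for loc in fl):
            raise ValueError("locs must be grouped per frame, in frame order")

    open_tracks: list[dict] = []  # each: {'pts': [Localization], 'last': frame}
    done: list[list[Localization]] = []
    for f, frame_locs in enumerate(locs):
        # retire tracks that exceeded the gap allowance
        still_open = []
        for tr in open_tracks:
            if f - tr["last"] > params.max_gap + 1:
                done.append(tr["pts"])
            else:
                still_open.append(tr)
        open_tracks = still_open

        unassigned = list(range(len(frame_locs)))
        if open_tracks and unassigned:
            pairs = []
            for ti, tr in enumerate(open_tracks):
                head = tr["pts"][-1]
                span = f - tr["last"]
                allowed = params.max_disp * span
                for li in unassigned:
                    loc = frame_locs[li]
                    d = np.hypot(loc.x_px - head.x_px, loc.y_px - head.y_px)
                    if d <= allowed:
                        pairs.append((d, ti, li))
            pairs.sort()  # ties: smaller distance, then lower track index
            used_t: set[int] = set()
            used_l: set[int] = set()
            for d, ti, li in pairs:
                if ti in used_t or li in used_l:
                    continue
                open_tracks[ti]["pts"].append(frame_locs[li])
                open_tracks[ti]["last"] = f
                used_t.add(ti)
                used_l.add(li)
            unassigned = [li for li in unassigned if li not in used_l]
        for li in unassigned:
            open_tracks.append({"pts": [frame_locs[li]], "last": f})
    done.extend(tr["pts"] for tr in open_tracks)

    px_um = pixel_nm / 1000.0
    trajs: list[Trajectory2D] = []
    tid = 0
    for pts in done:
        if len(pts) < params.min_len:
            continue
        frames = np.array([p.frame for p in pts])
        trajs.append(Trajectory2D(
            track_id=tid,
            frames=frames,
            t=frames / fps,
            x=np.array([p.x_px for p in pts]) * px_um,
            y=np.array([p.y_px for p in pts]) * px_um,
        ))
        tid += 1
    return trajs


def track_movie(stack: ImageStack, params: LinkParams | None = None,
                threshold_sigmas: float = 5.0, psf_sigma_px: float | None = None,
                fps: float | None = None) -> tuple[list[Trajectory2D], dict]:
    """Detect and link over a whole movie; returns trajectories and a QC
    dict with per-frame detection counts."""
    params = params or LinkParams()
    if psf_sigma_px is None:
        psf_sigma_px = 1.2
    if fps is None:
        fps = 1.0 / stack.dt if np.isfinite(stack.dt) else 20.0
    locs = [detect_spots(fr, threshold_sigmas, psf_sigma_px, frame_index=i)
            for i, fr in enumerate(stack.data)]
    trajs = link_spots(locs, params, pixel_nm=stack.pixel_size, fps=fps)
    n_det = int(sum(len(fl) for fl in locs))
    n_linked = int(sum(len(tr) for tr in trajs))
    if n_linked > n_det:  # pragma: no cover - defensive
        warnings.warn("linked more localizations than detected")
    qc = {"detections_per_frame": [len(fl) for fl in locs],
          "n_detections": n_det, "n_tracks": len(trajs),
          "n_linked_localizations": n_linked}
    return trajs, qc
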