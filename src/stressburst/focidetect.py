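"""Image operations for mismatch-focus detection.

Band-pass filtering (difference of Gaussians), intensity-threshold spot
detection with phasor subpixel localization, a simple Otsu threshold
segmentation for synthetic trench images, and cross-frame deduplication of
persistent foci (an event is counted only at its first frame).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = ["gaussian_bandpass", "phasor_localize", "detect_foci",
           "segment_trench_cells", "deduplicate_events", "robust_threshold",
           "PhasorUndefinedError"]


class PhasorUndefinedError(ValueError):
    """First Fourier harmonic vanishes; no phase to localize from."""


def gaussian_bandpass(image: np.ndarray, sigma_small: float = 1.0,
                      sigma_large: float = 3.0, clip: bool = True) -> np.ndarray:
    """Difference-of-Gaussians band-pass filter, negative response clipped to 0.

    The small sigma matches the spot scale (PSF ≈ 1 px), the large sigma
    removes slowly varying cytoplasmic background. ``clip=False`` keeps the
    signed response, which :func:`robust_threshold` needs for an unbiased
    background-noise estimate.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("gaussian_bandpass expects a 2-D image")
    if not sigma_small < sigma_large:
        raise ValueError("sigma_small must be < sigma_large")
    out = ndimage.gaussian_filter(image, sigma_small) - ndimage.gaussian_filter(
        image, sigma_large
    )
    return np.clip(out, 0.0, None) if clip else out


def phasor_localize(window: np.ndarray) -> tuple[float, float]:
    """Subpixel position of a spot inside a window from the first Fourier phase.

    Returns (x, y) in window coordinates (x along columns, y along rows);
    pixel centers are at integer coordinates. Raises
    :class:`PhasorUndefinedError` for windows with no first harmonic
    (e.g. uniform intensity).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or min(window.shape) < 3:
        raise ValueError("phasor window must be 2-D and at least 3x3")
    f = np.fft.fft2(window)
    gx = f[0, 1]  # first harmonic along columns (x)
    gy = f[1, 0]  # first harmonic along rows (y)
    if abs(gx) < 1e-12 * window.size or abs(gy) < 1e-12 * window.size:
        raise PhasorUndefinedError("zero first harmonic; position undefined")
    ny, nx = window.shape
    x = (np.arctan2(-gx.imag, gx.real) * nx / (2.0 * np.pi)) % nx
    y = (np.arctan2(-gy.imag, gy.real) * ny / (2.0 * np.pi)) % ny
    return float(x), float(y)


def robust_threshold(filtered: np.ndarray, n_sigma: float = 5.0,
                     mask: np.ndarray | None = None) -> float:
    """Detection threshold as a multiple of the robust background SD.

    The background SD of the band-passed image is estimated from the median
    absolute deviation (x1.4826), which is insensitive to the few bright
    spot pixels. Pass the *unclipped* band-pass response
    (``gaussian_bandpass(..., clip=False)``); on the clipped response the
    MAD degenerates because half the noise sits exactly at zero.
    """
    vals = filtered[mask] if mask is not None else filtered.ravel()
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    return float(med + n_sigma * 1.4826 * mad)


def detect_foci(filtered: np.ndarray, mask: np.ndarray, threshold: float,
                frame: int = 0, window: int = 7) -> pd.DataFrame:
    """Detect foci as thresholded local maxima with phasor subpixel positions.

    Parameters
    ----------
    filtered
        Band-passed image (see :func:`gaussian_bandpass`).
    mask
        Integer label image; 0 = outside cells, values = cell_id + 1.
    threshold
        Absolute intensity threshold in the filtered image (> 0).

    Returns a DataFrame with columns cell_id, frame, x_px, y_px, intensity.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    filtered = np.asarray(filtered, dtype=float)
    mask = np.asarray(mask)
    # the 1-px image border is excluded: boundary-reflected filtering
    # inflates the noise variance there and real foci never sit on it
    peaks = peak_local_max(filtered, min_distance=2, threshold_abs=threshold,
                           exclude_border=1)
    half = window // 2
    rows = []
    for r, c in peaks:
        if mask[r, c] == 0:
            continue
        r0, r1 = max(r - half, 0), min(r + half + 1, filtered.shape[0])
        c0, c1 = max(c - half, 0), min(c + half + 1, filtered.shape[1])
        patch = filtered[r0:r1, c0:c1]
        try:
            x_w, y_w = phasor_localize(patch)
            x, y = c0 + x_w, r0 + y_w
        except PhasorUndefinedError:
            x, y = float(c), float(r)
        rows.append((int(mask[r, c]) - 1, frame, x, y, float(filtered[r, c])))
    return pd.DataFrame(rows, columns=["cell_id", "frame", "x_px", "y_px",
                                       "intensity"])


def segment_trench_cells(image: np.ndarray, trench_rois) -> list[dict]:
    """Threshold segmentation of the cytoplasmic channel, one trench at a time.

    ``trench_rois`` is a sequence of (col_start, col_stop) pairs. The closed
    end of every trench is row 0; the mother cell is the connected component
    nearest the closed end. Returns one record per trench with keys
    ``mask`` (bool, trench-shaped), ``area`` (px²), ``length_px`` (extent
    along the trench axis) and ``empty``.
    """
    image = np.asarray(image, dtype=float)
    out = []
    for c0, c1 in trench_rois:
        sub = image[:, c0:c1]
        rec = {"mask": np.zeros_like(sub, dtype=bool), "area": 0,
               "length_px": 0.0, "empty": True, "col_start": int(c0)}
        if sub.max() > sub.min():
            thr = threshold_otsu(sub)
            fg = sub > thr
            if fg.any():
                lbl = label(fg)
                props = regionprops(lbl)
                # mother = component whose top edge is nearest the closed end
                props.sort(key=lambda p: p.bbox[0])
                mother = props[0]
                rec["mask"] = lbl == mother.label
                rec["area"] = int(mother.area)
                rec["length_px"] = float(mother.bbox[2] - mother.bbox[0])
                rec["empty"] = False
        out.append(rec)
    return out


def deduplicate_events(detections: pd.DataFrame, link_radius: float = 3.0,
                       max_gap: int = 0) -> pd.DataFrame:
    """Merge persistent focus detections into events counted at the first frame.

    Detections of the same cell within ``link_radius`` pixels in consecutive
    frames (allowing up to ``max_gap`` missed frames) belong to one event.
    Greedy closest-pair matching per frame; ties broken by input order.

    Returns a DataFrame with columns cell_id, first_frame, frames_spanned,
    x_px, y_px. Idempotent: re-running on the events (one detection at each
    first frame) reproduces them.
    """
    cols = ["cell_id", "first_frame", "frames_spanned", "x_px", "y_px"]
    if len(detections) == 0:
        return pd.DataFrame(columns=cols)
    events = []
    for cell_id, grp in detections.groupby("cell_id", sort=True):
        open_chains: list[dict] = []
        for frame, fgrp in grp.sort_values("frame").groupby("frame", sort=True):
            frame = int(frame)
            # retire chains too old to extend
            still_open = []
            for ch in open_chains:
                if frame - ch["last_frame"] > max_gap + 1:
                    events.append(ch)
                else:
                    still_open.append(ch)
            open_chains = still_open

            xs = fgrp["x_px"].to_numpy(float)
            ys = fgrp["y_px"].to_numpy(float)
            pairs = []
            for ci, ch in enumerate(open_chains):
                if frame == ch["last_frame"]:
                    continue  # one detection per chain per frame
                d = np.hypot(xs - ch["x"], ys - ch["y"])
                for di in range(len(xs)):
                    if d[di] <= link_radius:
                        pairs.append((d[di], ci, di))
            pairs.sort(key=lambda p: (p[0], p[2], p[1]))
            used_c, used_d = set(), set()
            for _, ci, di in pairs:
                if ci in used_c or di in used_d:
                    continue
                used_c.add(ci)
                used_d.add(di)
                ch = open_chains[ci]
                ch["last_frame"] = frame
                ch["x"], ch["y"] = xs[di], ys[di]
            for di in range(len(xs)):
                if di not in used_d:
                    open_chains.append(
                        {"cell_id": int(cell_id), "first_frame": frame,
                         "last_frame": frame, "x": xs[di], "y": ys[di],
                         "x0": xs[di], "y0": ys[di]}
                    )
        events.extend(open_chains)

    rows = [
        (
            ev["cell_id"],
            ev["first_frame"],
            ev["last_frame"] - ev["first_frame"] + 1,
            ev.get("x0", ev["x"]),
            ev.get("y0", ev["y"]),
        )
        for ev in events
    ]
    return (
        pd.DataFrame(rows, columns=cols)
        .sort_values(["first_frame", "cell_id"], kind="stable")
        .reset_index(drop=True)
    )
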