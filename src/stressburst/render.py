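"""Rendering of synthetic trench image stacks.

Each mother cell occupies one dead-end trench (closed end at row 0). The
cell footprint is a uniform cytoplasmic rectangle; foci are 2-D Gaussians
at their ground-truth positions; noise is Poisson shot noise plus Gaussian
read noise. Ground-truth label masks are emitted alongside the images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from stressburst.config import ScenarioConfig
from stressburst.containers import CellTrace

__all__ = ["RenderError", "RenderResult", "render_frames"]

#: rendered cell width in pixels
CELL_WIDTH_PX = 6
#: gap between adjacent trenches, pixels
TRENCH_GAP_PX = 2


class RenderError(ValueError):
    pass


@dataclass
class RenderResult:
    stack: np.ndarray        # foci channel, (n_frames, H, W) uint16
    seg_stack: np.ndarray    # cytoplasmic segmentation channel, same shape
    masks: np.ndarray        # (n_frames, H, W) int32, 0 = background, cell_id + 1
    trench_rois: list[tuple[int, int]]  # (col_start, col_stop) per cell
    cell_ids: list[int]


def _gaussian_spot(shape: tuple[int, int], x: float, y: float, amp: float,
                   sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2))


def render_frames(traces: list[CellTrace], detections: pd.DataFrame,
                  cfg: ScenarioConfig, seed: int = 0,
                  noise: bool = True) -> RenderResult:
    """Render trench movies for a set of traces and their focus detections.

    ``detections`` uses trench-local coordinates (x across the trench,
    y from the closed end), as produced by
    :func:`stressburst.simkit.simulate_lineage`; rendered coordinates are
    offset by each trench's column origin.

    Two channels are rendered, as in a two-colour experiment: a bright
    constitutive cytoplasmic channel (``seg_stack``) used for
    segmentation, and the foci channel (``stack``) in which the diffuse
    reporter signal inside cells is faint relative to a focus. Cell bodies
    are blurred by the PSF; foci are PSF-sized Gaussians.
    """
    opt = cfg.optics
    if cfg.division_length_um / cfg.pixel_size > opt.trench_length_px:
        raise RenderError(
            "trench is smaller than the cell footprint at division "
            f"({cfg.division_length_um / cfg.pixel_size:.1f} px needed, "
            f"{opt.trench_length_px} px available)"
        )
    rng = np.random.default_rng(seed)
    n_frames = traces[0].n_frames
    H = opt.trench_length_px
    w = opt.trench_width_px
    W = len(traces) * (w + TRENCH_GAP_PX) - TRENCH_GAP_PX
    x_margin = (w - CELL_WIDTH_PX) // 2

    stack = np.zeros((n_frames, H, W), dtype=float)
    seg = np.zeros((n_frames, H, W), dtype=float)
    masks = np.zeros((n_frames, H, W), dtype=np.int32)
    rois = []
    for j, trace in enumerate(traces):
        c0 = j * (w + TRENCH_GAP_PX)
        rois.append((c0, c0 + w))

    det_by_frame = {int(f): g for f, g in detections.groupby("frame")} if len(
        detections
    ) else {}
    col_of_cell = {t.cell_id: rois[j][0] for j, t in enumerate(traces)}

    from scipy import ndimage

    for k in range(n_frames):
        body = np.zeros((H, W))
        for j, trace in enumerate(traces):
            L = trace.lengths[k]
            if np.isnan(L):
                continue  # lysed: mask vanished
            n_rows = min(int(np.round(L / cfg.pixel_size)), H)
            c0, _ = rois[j]
            sl = np.s_[0:n_rows, c0 + x_margin:c0 + x_margin + CELL_WIDTH_PX]
            body[sl] = 1.0
            masks[k][sl] = trace.cell_id + 1
        body = ndimage.gaussian_filter(body, opt.psf_sigma_px)
        seg[k] = opt.background_offset + opt.cell_signal * body
        stack[k] = opt.background_offset + opt.foci_cell_signal * body
        if k in det_by_frame:
            for _, d in det_by_frame[k].iterrows():
                cid = int(d["cell_id"])
                if cid not in col_of_cell:
                    continue
                stack[k] += _gaussian_spot(
                    (H, W), col_of_cell[cid] + d["x_px"], d["y_px"],
                    d["intensity"], opt.psf_sigma_px,
                )
    if noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
        stack += rng.normal(0.0, opt.read_noise_sd, size=stack.shape)
        seg = rng.poisson(np.clip(seg, 0, None)).astype(float)
        seg += rng.normal(0.0, opt.read_noise_sd, size=seg.shape)
    stack = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    seg = np.clip(np.round(seg), 0, 65535).astype(np.uint16)
    return RenderResult(stack=stack, seg_stack=seg, masks=masks,
                        trench_rois=rois, cell_ids=[t.cell_id for t in traces])
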