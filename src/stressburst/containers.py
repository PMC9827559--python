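"""Core in-memory containers shared across the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: fate labels a mother-cell trace can carry
FATES = ("alive", "arrest", "lysis", "filamentation")


@dataclass
class CellTrace:
    """One mother cell's time-stamped observables.

    Times are minutes on the experiment clock (not treatment-relative).
    ``lengths`` may contain NaN after lysis (mask vanished). ``truncation_time``
    marks the detected death time; observations after it are not trusted.
    """

    cell_id: int
    times: np.ndarray            # minutes, strictly increasing
    lengths: np.ndarray          # μm
    reporter_intensity: np.ndarray | None = None  # mean au inside mask, bg-subtracted
    total_intensity: np.ndarray | None = None     # au
    area: np.ndarray | None = None                # px²
    fate: str = "alive"
    truncation_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.lengths.shape:
            raise ValueError("times and lengths must be matching 1-D arrays")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")

    @property
    def n_frames(self) -> int:
        return self.times.size

    def observed_mask(self) -> np.ndarray:
        """Frames at which the cell is observed (pre-truncation, non-NaN length)."""
        ok = ~np.isnan(self.lengths)
        if self.truncation_time is not None:
            ok &= self.times <= self.truncation_time
        return ok


@dataclass
class RateSeries:
    """A per-frame population summary: value, SEM and cells contributing.

    ``times`` are minutes relative to treatment onset. Missing values are
    NaN, never zero-filled.
    """

    times: np.ndarray
    values: np.ndarray
    n_cells_per_frame: np.ndarray
    sem: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_cells_per_frame = np.asarray(self.n_cells_per_frame)
        self.sem = np.asarray(self.sem, dtype=float)
        n = self.times.size
        for name in ("values", "n_cells_per_frame", "sem"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length must match times")
        if np.any(self.n_cells_per_frame < 0):
            raise ValueError("n_cells_per_frame must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "value": self.values,
                "n_cells": self.n_cells_per_frame,
                "sem": self.sem,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RateSeries":
        return cls(
            df["time_min"].to_numpy(float),
            df["value"].to_numpy(float),
            df["n_cells"].to_numpy(),
            df["sem"].to_numpy(float),
        )


@dataclass(frozen=True)
class FocusDetection:
    """A single-frame focus detection at subpixel position (x, y)."""

    frame: int
    x: float
    y: float
    peak_intensity: float
    cell_id: int


@dataclass(frozen=True)
class FocusEvent:
    """A deduplicated focus event, counted at its first frame only."""

    first_frame: int
    frames_spanned: int
    x: float
    y: float
    cell_id: int

    def __post_init__(self) -> None:
        if self.frames_spanned < 1:
            raise ValueError("frames_spanned must be >= 1")


@dataclass
class Track:
    """An ordered sequence of localizations for one molecule.

    Positions are in μm; frames are consecutive up to one-frame gaps.
    ``d_est`` is filled by :func:`stressburst.diffusionfit.track_diffusion_coefficient`.
    """

    track_id: int
    frames: np.ndarray
    positions: np.ndarray  # (n, 2) μm
    d_est: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape != (self.frames.size, 2):
            raise ValueError("positions must be (n_frames, 2)")
        if self.frames.size < 2:
            raise ValueError("a track needs >= 2 localizations")
        gaps = np.diff(self.frames)
        if np.any(gaps < 1) or np.any(gaps > 2):
            raise ValueError("frames must increase with gaps of at most one frame")


@dataclass
class DiffusionFitResult:
    """Result of the two-species diffusion-coefficient mixture fit."""

    d1: float                 # μm²/s, immobile species
    d2: float                 # μm²/s, mobile species
    a1: float                 # bound fraction
    n_tracks: int
    d1_fixed: bool
    log_likelihood: float
    se_d1: float = np.nan
    se_d2: float = np.nan
    se_a1: float = np.nan
    unidentifiable: bool = False

    @property
    def a2(self) -> float:
        return 1.0 - self.a1

    def to_dict(self) -> dict:
        return {
            "D1": self.d1,
            "D2": self.d2,
            "A1": self.a1,
            "A2": self.a2,
            "n_tracks": self.n_tracks,
            "D1_fixed": self.d1_fixed,
            "log_likelihood": self.log_likelihood,
            "se_D1": self.se_d1,
            "se_D2": self.se_d2,
            "se_A1": self.se_a1,
            "unidentifiable": self.unidentifiable,
        }


@dataclass
class BurstMetrics:
    """Summary of a transient burst in a rate time course."""

    baseline: float
    peak_value: float
    peak_time: float          # minutes post-treatment
    duration_fwhm: float      # minutes
    fold_change: float
    no_burst: bool = False

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "peak_value": self.peak_value,
            "peak_time": self.peak_time,
            "duration_fwhm": self.duration_fwhm,
            "fold_change": self.fold_change,
            "no_burst": self.no_burst,
        }


@dataclass
class GroundTruth:
    """Registry of everything the generator actually did, for recovery tests."""

    division_times: dict[int, np.ndarray] = field(default_factory=dict)
    foci_events: pd.DataFrame | None = None   # cell_id, time_min, first_frame, x_px, y_px
    fates: pd.DataFrame | None = None         # cell_id, fate, death_time_min
    states: pd.DataFrame | None = None        # track_id, bound (per molecule)
    true_positions: dict[int, np.ndarray] = field(default_factory=dict)  # μm, noise-free
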