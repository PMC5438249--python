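"""Shared data containers for the imaging/analysis pipeline.

The pipeline moves through three in-memory representations:

``Movie``
    a raw (or registered) fluorescence stack, frames x rows x cols;
``TrialTensor``
    per-cell traces cut into stimulus trials, (cell, stimulus, trial, frame);
``ResponseTable``
    per-cell scalar responses, one number per (cell, odorant, dilution,
    trial) — the substrate of every population statistic.

All containers are plain dataclasses around numpy arrays / pandas frames and
round-trip through standard text or TIFF formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile


@dataclass(frozen=True)
class TrialLayout:
    """Timing of a single odor trial, in seconds.

    Default is an 8 s pre-stimulus baseline, 2 s of odor, and 20 s of
    post-stimulus acquisition (30 s total).
    """

    pre_s: float = 8.0
    odor_s: float = 2.0
    post_s: float = 20.0

    def __post_init__(self) -> None:
        if min(self.pre_s, self.odor_s, self.post_s) <= 0:
            raise ValueError("all trial-layout durations must be positive")

    @property
    def total_s(self) -> float:
        return self.pre_s + self.odor_s + self.post_s

    def n_frames(self, frame_rate: float) -> int:
        return int(round(self.total_s * frame_rate))

    def onset_frame(self, frame_rate: float) -> int:
        return int(round(self.pre_s * frame_rate))


@dataclass
class Movie:
    """A fluorescence stack with acquisition metadata.

    data : float array, shape (n_frames, n_rows, n_cols)
    frame_rate : Hz
    pixel_size : micrometres per pixel
    """

    data: np.ndarray
    frame_rate: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("movie data must be 3-D (frames, rows, cols)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def to_tiff(self, path: str | Path) -> None:
        """Write as a multi-page 16-bit TIFF (linearly rescaled to uint16)."""
        lo = float(self.data.min())
        hi = float(self.data.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        raw = np.round((self.data - lo) * scale).astype(np.uint16)
        tifffile.imwrite(path, raw, metadata={
            "frame_rate": self.frame_rate, "pixel_size": self.pixel_size,
        })

    @classmethod
    def from_tiff(cls, path: str | Path, frame_rate: float,
                  pixel_size: float = 1.0) -> "Movie":
        data = tifffile.imread(path).astype(np.float64)
        return cls(data=data, frame_rate=frame_rate, pixel_size=pixel_size)


@dataclass
class TrialTensor:
    """Per-cell traces organized by trial.

    data : array (n_cells, n_stimuli, n_trials, n_frames)
    stimuli : list of (odorant, dilution) pairs, one per stimulus axis entry
    """

    data: np.ndarray
    stimuli: list[tuple[str, float]]
    frame_rate: float
    layout: TrialLayout = field(default_factory=TrialLayout)
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("trial tensor must be 4-D")
        if self.data.shape[1] != len(self.stimuli):
            raise ValueError("stimulus axis does not match stimulus list")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.data.shape[0])

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def onset_frame(self) -> int:
        return self.layout.onset_frame(self.frame_rate)


class ResponseTable:
    """Long-format table of per-trial scalar responses.

    Columns: cell_id, odorant, dilution, trial, response.  Every cell must
    cover the identical stimulus/trial grid (checked lazily by ``matrix``).
    """

    COLUMNS = ["cell_id", "odorant", "dilution", "trial", "response"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"response table missing columns: {missing}")
        self.df = df[self.COLUMNS].copy()

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_array(cls, responses: np.ndarray,
                   stimuli: Sequence[tuple[str, float]],
                   cell_ids: Sequence | None = None) -> "ResponseTable":
        """Build from an array (n_cells, n_stimuli, n_trials)."""
        responses = np.asarray(responses, dtype=float)
        n_cells, n_stim, n_trials = responses.shape
        if n_stim != len(stimuli):
            raise ValueError("stimulus axis does not match stimulus list")
        if cell_ids is None:
            cell_ids = np.arange(n_cells)
        odors = np.array([s[0] for s in stimuli])
        dils = np.array([s[1] for s in stimuli])
        idx = pd.MultiIndex.from_product(
            [cell_ids, range(n_stim), range(n_trials)],
            names=["cell_id", "stim", "trial"]).to_frame(index=False)
        df = pd.DataFrame({
            "cell_id": idx["cell_id"],
            "odorant": odors[idx["stim"]],
            "dilution": dils[idx["stim"]],
            "trial": idx["trial"],
            "response": responses.ravel(),
        })
        return cls(df)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResponseTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    # -- views -------------------------------------------------------------
    @property
    def cell_ids(self) -> np.ndarray:
        return self.df["cell_id"].unique()

    @property
    def stimuli(self) -> list[tuple[str, float]]:
        """Stimuli sorted by (odorant, dilution) — the ``array`` axis order."""
        pairs = self.df[["odorant", "dilution"]].drop_duplicates()
        return sorted(pairs.itertuples(index=False, name=None))

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_trials(self) -> int:
        return int(self.df["trial"].nunique())

    def matrix(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Pivot to (n_cells, n_trial_vectors) plus per-column metadata.

        Columns are ordered by (odorant, dilution, trial); raises if the
        stimulus coverage differs across cells.
        """
        pivot = self.df.pivot_table(
            index="cell_id", columns=["odorant", "dilution", "trial"],
            values="response")
        if pivot.isna().any().any():
            raise ValueError("uneven stimulus coverage across cells")
        meta = pivot.columns.to_frame(index=False)
        return pivot.to_numpy(), meta

    def array(self) -> np.ndarray:
        """Responses as (n_cells, n_stimuli, n_trials), stimuli sorted."""
        mat, meta = self.matrix()
        n_stim = len(meta[["odorant", "dilution"]].drop_duplicates())
        n_trials = mat.shape[1] // n_stim
        return mat.reshape(mat.shape[0], n_stim, n_trials)

    def subset_cells(self, cell_ids: Sequence) -> "ResponseTable":
        mask = self.df["cell_id"].isin(np.asarray(cell_ids))
        return ResponseTable(self.df[mask].reset_index(drop=True))
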