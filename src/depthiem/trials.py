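"""Trial-by-voxel response container shared by the encoding and decoding stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TrialMatrix"]


@dataclass
class TrialMatrix:
    """Per-trial voxel responses with run and stimulus-position labels.

    ``responses`` is (n_trials, n_voxels). ``row``/``col`` index the grid
    cell of each trial (-1 on null trials, where ``x``/``z`` are NaN).
    ``run`` is the 1-based run number; ``mirrored`` flags trials from runs
    whose grid was horizontally flipped.
    """

    responses: np.ndarray
    run: np.ndarray
    row: np.ndarray
    col: np.ndarray
    x: np.ndarray
    z: np.ndarray
    is_null: np.ndarray
    mirrored: np.ndarray
    subject: str = "s00"

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        n = self.responses.shape[0]
        self.run = np.asarray(self.run, dtype=int)
        self.row = np.asarray(self.row, dtype=int)
        self.col = np.asarray(self.col, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.is_null = np.asarray(self.is_null, dtype=bool)
        self.mirrored = np.asarray(self.mirrored, dtype=bool)
        for name in ("run", "row", "col", "x", "z", "is_null", "mirrored"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"label '{name}' does not match {n} trials")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[1]

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run)

    def select(self, mask: np.ndarray) -> "TrialMatrix":
        mask = np.asarray(mask)
        return TrialMatrix(
            responses=self.responses[mask],
            run=self.run[mask],
            row=self.row[mask],
            col=self.col[mask],
            x=self.x[mask],
            z=self.z[mask],
            is_null=self.is_null[mask],
            mirrored=self.mirrored[mask],
            subject=self.subject,
        )

    def stimulus_trials(self) -> "TrialMatrix":
        """Drop null trials (pure-noise events with no stimulus)."""
        return self.select(~self.is_null)

    def coordinate(self, axis: str) -> np.ndarray:
        if axis == "x":
            return self.x
        if axis == "z":
            return self.z
        raise ValueError(f"axis must be 'x' or 'z', got {axis!r}")

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "subject": self.subject,
                "run": self.run,
                "trial": np.arange(self.n_trials),
                "position_row": self.row,
                "position_col": self.col,
                "x_scene": self.x,
                "z_scene": self.z,
                "is_null": self.is_null.astype(int),
                "mirrored": self.mirrored.astype(int),
            }
        )
        vox = pd.DataFrame(
            self.responses, columns=[f"v{i:04d}" for i in range(self.n_voxels)]
        )
        return pd.concat([meta, vox], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "TrialMatrix":
        vox_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
        subjects = df["subject"].unique()
        if len(subjects) != 1:
            raise ValueError("frame holds multiple subjects; split it first")
        return TrialMatrix(
            responses=df[vox_cols].to_numpy(dtype=float),
            run=df["run"].to_numpy(),
            row=df["position_row"].to_numpy(),
            col=df["position_col"].to_numpy(),
            x=df["x_scene"].to_numpy(dtype=float),
            z=df["z_scene"].to_numpy(dtype=float),
            is_null=df["is_null"].to_numpy(dtype=bool),
            mirrored=df["mirrored"].to_numpy(dtype=bool),
            subject=str(subjects[0]),
        )

    @staticmethod
    def from_csv(path) -> "TrialMatrix":
        return TrialMatrix.from_frame(pd.read_csv(path))

    @staticmethod
    def concat(parts: list["TrialMatrix"]) -> "TrialMatrix":
        """Stack run-level matrices of one subject into a session matrix."""
        if not parts:
            raise ValueError("nothing to concatenate")
        return TrialMatrix(
            responses=np.concatenate([p.responses for p in parts]),
            run=np.concatenate([p.run for p in parts]),
            row=np.concatenate([p.row for p in parts]),
            col=np.concatenate([p.col for p in parts]),
            x=np.concatenate([p.x for p in parts]),
            z=np.concatenate([p.z for p in parts]),
            is_null=np.concatenate([p.is_null for p in parts]),
            mirrored=np.concatenate([p.mirrored for p in parts]),
            subject=parts[0].subject,
        )
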