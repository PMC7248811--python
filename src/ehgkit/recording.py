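"""Container for a single electrohysterogram (EHG) recording.

An EHG recording is a uniformly sampled voltage trace (microvolts) from
abdominal-surface electrodes, either one of the two monopolar channels
(M1/M2) or the bipolar difference channel on which all analysis runs.
A boolean artifact mask marks samples that experts (or the synthetic
generator) flagged as motion/respiration artifact; masked samples are
excluded from analysis by whole-window rejection, never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

CHANNEL_ROLES = ("monopolar_M1", "monopolar_M2", "bipolar")


@dataclass
class EHGRecording:
    """One EHG channel: samples in microvolts at a fixed sampling rate.

    Parameters
    ----------
    samples : ndarray
        Signal in microvolts.
    fs : float
        Sampling rate in Hz (> 0).
    channel_role : str
        One of ``monopolar_M1``, ``monopolar_M2``, ``bipolar``.
    artifact_mask : ndarray of bool, optional
        True marks samples excluded from analysis. Defaults to all-False.
    recording_id : str
    metadata : dict
    """

    samples: np.ndarray
    fs: float
    channel_role: str = "bipolar"
    artifact_mask: np.ndarray | None = None
    recording_id: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(f"channel_role must be one of {CHANNEL_ROLES}")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.samples.size, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != self.samples.shape:
            raise ValueError("artifact_mask must have the same length as samples")
        clean = self.samples[~self.artifact_mask]
        if clean.size and not np.all(np.isfinite(clean)):
            raise ValueError("non-finite samples outside masked regions")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with columns time_s, ehg_uv, artifact_flag."""
        return pd.DataFrame(
            {
                "time_s": np.arange(self.samples.size) / self.fs,
                "ehg_uv": self.samples,
                "artifact_flag": self.artifact_mask.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        fs: float | None = None,
        channel_role: str = "bipolar",
        recording_id: str | None = None,
    ) -> "EHGRecording":
        """Read a recording from CSV (time_s, ehg_uv[, artifact_flag]).

        The sampling rate is inferred from the time column unless given.
        """
        df = pd.read_csv(path)
        if "ehg_uv" not in df.columns:
            raise ValueError(f"{path}: missing required column 'ehg_uv'")
        if fs is None:
            if "time_s" not in df.columns or len(df) < 2:
                raise ValueError(f"{path}: cannot infer fs without a time_s column")
            dt = np.median(np.diff(df["time_s"].to_numpy()))
            fs = 1.0 / dt
        mask = None
        if "artifact_flag" in df.columns:
            mask = df["artifact_flag"].to_numpy().astype(bool)
        rid = recording_id if recording_id is not None else Path(path).stem
        return cls(
            samples=df["ehg_uv"].to_numpy(dtype=float),
            fs=float(fs),
            channel_role=channel_role,
            artifact_mask=mask,
            recording_id=rid,
        )


def read_mask_intervals(path: str | Path, fs: float, n_samples: int) -> np.ndarray:
    """Read an artifact mask from an interval file (start_s, end_s per line).

    Lines may be comma- or whitespace-separated; intervals are half-open in
    seconds and clipped to the recording extent.
    """
    mask = np.zeros(n_samples, dtype=bool)
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed interval line {line!r}")
        start_s, end_s = float(parts[0]), float(parts[1])
        i0 = max(0, int(np.floor(start_s * fs)))
        i1 = min(n_samples, int(np.ceil(end_s * fs)))
        if i1 > i0:
            mask[i0:i1] = True
    return mask
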