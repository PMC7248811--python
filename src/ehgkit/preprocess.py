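"""EHG signal conditioning: bipolar derivation, band-limiting, decimation
and mask-aware segmentation into fixed-length analysis windows.

The processing order matters at the target rate of 20 Hz: the raw 500 Hz
monopolar channels are anti-alias filtered and decimated first, and the
0.1-4 Hz analysis band is applied afterwards (4 Hz sits below the 10 Hz
Nyquist limit of the decimated signal). All filters are zero-phase
(forward-backward Butterworth), so features sensitive to waveform
asymmetry (time reversibility) are not distorted by filter phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .recording import EHGRecording

#: analysis band of the bipolar EHG signal, Hz
DEFAULT_BAND = (0.1, 4.0)
#: analysis window length / overlap used for whole-window characterization
DEFAULT_WINDOW_S = 120.0
DEFAULT_OVERLAP = 0.5


@dataclass
class WindowSet:
    """Equal-length analysis windows cut from one recording.

    ``windows[i]`` starts at sample ``start_indices[i]`` of the source
    signal. Windows that would intersect any masked sample are dropped at
    construction, so every emitted window is artifact-free.
    """

    windows: list[np.ndarray]
    window_s: float
    overlap: float
    start_indices: np.ndarray
    fs: float

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.fs))


def derive_bipolar(m1: EHGRecording, m2: EHGRecording) -> EHGRecording:
    """Bipolar channel = M1 - M2; rejects common-mode interference.

    The artifact mask of the result is the union of the input masks.
    """
    if m1.channel_role != "monopolar_M1" or m2.channel_role != "monopolar_M2":
        raise ValueError("derive_bipolar expects channel roles monopolar_M1 and monopolar_M2")
    if m1.fs != m2.fs:
        raise ValueError(f"sampling rates differ: {m1.fs} vs {m2.fs}")
    if m1.n_samples != m2.n_samples:
        raise ValueError(f"lengths differ: {m1.n_samples} vs {m2.n_samples}")
    return EHGRecording(
        samples=m1.samples - m2.samples,
        fs=m1.fs,
        channel_role="bipolar",
        artifact_mask=m1.artifact_mask | m2.artifact_mask,
        recording_id=m1.recording_id or m2.recording_id,
        metadata={**m2.metadata, **m1.metadata},
    )


def bandpass(
    rec: EHGRecording,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    order: int = 4,
) -> EHGRecording:
    """Zero-phase Butterworth band-pass; removes DC, preserves length."""
    nyq = rec.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return EHGRecording(
        samples=filtered,
        fs=rec.fs,
        channel_role=rec.channel_role,
        artifact_mask=rec.artifact_mask.copy(),
        recording_id=rec.recording_id,
        metadata=dict(rec.metadata),
    )


def downsample(rec: EHGRecording, fs_out: float) -> EHGRecording:
    """Anti-alias filter and resample to ``fs_out``.

    Rational-ratio polyphase resampling (FIR anti-alias filter built in).
    The artifact mask is decimated conservatively: an output sample is
    masked if *any* source sample in its decimation span was masked, so
    artifacts can only grow, never silently shrink, under resampling.
    """
    if fs_out >= rec.fs:
        raise ValueError(f"fs_out ({fs_out}) must be below the source rate ({rec.fs})")
    ratio = Fraction(fs_out / rec.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    out = signal.resample_poly(rec.samples, up, down)
    n_out = out.size
    # conservative mask: span of input samples feeding output sample j
    mask_out = np.zeros(n_out, dtype=bool)
    if rec.artifact_mask.any():
        step = down / up
        for j in np.arange(n_out):
            i0 = int(np.floor(j * step))
            i1 = min(rec.n_samples, int(np.ceil((j + 1) * step)))
            if rec.artifact_mask[i0:i1].any():
                mask_out[j] = True
    return EHGRecording(
        samples=out,
        fs=float(fs_out),
        channel_role=rec.channel_role,
        artifact_mask=mask_out,
        recording_id=rec.recording_id,
        metadata=dict(rec.metadata),
    )


def segment_windows(
    rec: EHGRecording,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
) -> WindowSet:
    """Cut the recording into fixed windows, dropping artifacted ones.

    Windows are anchored at sample 0 with step ``window_s * fs * (1 -
    overlap)``; a trailing partial window is discarded. Any window that
    intersects a masked sample is dropped — this implements whole-window
    exclusion of expert-flagged artifact segments. A recording shorter
    than one window, or fully artifacted, yields an empty set (flagged
    unusable upstream).
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    L = int(round(window_s * rec.fs))
    if L < 2:
        raise ValueError("window too short for the sampling rate")
    step = int(round(L * (1 - overlap)))
    if step < 1:
        raise ValueError("overlap too close to 1 for this window length")
    n = rec.n_samples
    windows: list[np.ndarray] = []
    starts: list[int] = []
    for s0 in range(0, n - L + 1, step):
        if rec.artifact_mask[s0 : s0 + L].any():
            continue
        windows.append(rec.samples[s0 : s0 + L].copy())
        starts.append(s0)
    return WindowSet(
        windows=windows,
        window_s=window_s,
        overlap=overlap,
        start_indices=np.asarray(starts, dtype=int),
        fs=rec.fs,
    )


def preprocess_recording(
    rec: EHGRecording,
    fs_out: float = 20.0,
    band: tuple[float, float] = DEFAULT_BAND,
) -> EHGRecording:
    """Standard conditioning chain: decimate (if needed) then band-pass."""
    out = rec
    if out.fs > fs_out:
        out = downsample(out, fs_out)
    return bandpass(out, band[0], band[1])
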