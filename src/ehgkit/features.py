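"""The 23 temporal, spectral and non-linear EHG characteristics.

Whole-window characterization: every feature is computed on each 120 s
analysis window and summarized per recording by the median over windows,
which damps the redundancy introduced by the 50% overlap and is robust
to the occasional odd window.

Feature groups
--------------
temporal   peak-to-peak amplitude (app), Teager energy
spectral   dominant frequencies DF1 (0.2-1 Hz) and DF2 (0.34-1 Hz),
           high/low energy ratio (0.34-1 over 0.2-0.34 Hz), spectral
           deciles D1-D9 on 0.2-1 Hz
nonlinear  binary and 6-state Lempel-Ziv, sample entropy, spectral
           entropy (0.34-4 Hz), fuzzy entropy, time reversibility,
           Poincare SD1/SD2 and their ratio

Non-spectral features are computed on the window after restriction to
the 0.34-4 Hz fast-wave-high band; spectral features come from a Welch
PSD of the full-band (0.1-4 Hz) window, each on its own sub-band. The
two EHG fast-wave components motivate the band split: fast wave low
(0.2-0.34 Hz) reflects propagation, fast wave high (> 0.34 Hz) cell
excitability, which rises as labor approaches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._fast import fuzzen_phis, lz76_complexity, sampen_counts
from .preprocess import segment_windows
from .recording import EHGRecording

logger = logging.getLogger(__name__)

#: canonical feature order; defines the FeatureVector layout
FEATURE_NAMES: tuple[str, ...] = (
    "app",
    "df1",
    "df2",
    "hl_ratio",
    "d1",
    "d2",
    "d3",
    "d4",
    "d5",
    "d6",
    "d7",
    "d8",
    "d9",
    "teager",
    "lz_bin",
    "lz_multi",
    "sampen",
    "specen",
    "fuzzen",
    "tr",
    "sd1",
    "sd2",
    "sd_ratio",
)

OBSTETRIC_NAMES: tuple[str, ...] = (
    "cervical_length",
    "gestational_age",
    "maternal_age",
    "gestations",
    "parity",
    "abortions",
)


class UndefinedFeature(ValueError):
    """A feature is not defined for this window (e.g. zero in-band energy)."""


@dataclass
class SpectralConfig:
    """Frequency bands (Hz) for the spectral EHG parameters."""

    fwh_band: tuple[float, float] = (0.34, 4.0)
    df1_band: tuple[float, float] = (0.2, 1.0)
    df2_band: tuple[float, float] = (0.34, 1.0)
    hl_high: tuple[float, float] = (0.34, 1.0)
    hl_low: tuple[float, float] = (0.2, 0.34)
    decile_band: tuple[float, float] = (0.2, 1.0)

    def __post_init__(self) -> None:
        for name in ("fwh_band", "df1_band", "df2_band", "hl_high", "hl_low", "decile_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: requires low < high, got ({lo}, {hi})")


@dataclass
class FeatureConfig:
    """All tunables of the feature stage.

    Entropy settings follow the methodological literature (none are fixed
    by convention alone): template length m = 2, tolerance r = 0.15 of
    the window SD, fuzzy membership gradient 2. Time reversibility uses
    lag tau = 1 sample. The Welch PSD uses 512-sample Hann segments with
    50% overlap inside each 120 s window.
    """

    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    window_s: float = 120.0
    overlap: float = 0.5
    entropy_m: int = 2
    entropy_r_frac: float = 0.15
    fuzzy_gradient: float = 2.0
    tr_tau: int = 1
    welch_nperseg: int = 512
    lz_multi_levels: int = 6


# ---------------------------------------------------------------------------
# temporal


def peak_to_peak(window: np.ndarray) -> float:
    """max - min of the window (microvolts)."""
    w = np.asarray(window, dtype=float)
    if w.size == 0 or np.all(np.isnan(w)):
        raise UndefinedFeature("empty or all-NaN window")
    return float(np.nanmax(w) - np.nanmin(w))


def teager_energy(window: np.ndarray) -> float:
    """Mean Teager-Kaiser operator psi[n] = x[n]^2 - x[n-1]*x[n+1].

    Tracks instantaneous amplitude *and* frequency: a tone A*sin(w n)
    gives A^2 sin^2(w).
    """
    w = np.asarray(window, dtype=float)
    if w.size < 3:
        raise UndefinedFeature("window too short for Teager energy")
    psi = w[1:-1] ** 2 - w[:-2] * w[2:]
    return float(psi.mean())


# ---------------------------------------------------------------------------
# spectral


def power_spectrum(
    window: np.ndarray, fs: float, nperseg: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD (Hann, 50% overlap), rescaled to satisfy Parseval exactly.

    Returns (freqs, psd) with the trapezoid integral of the PSD equal to
    the variance of the window. The rescaling leaves every ratio-based
    spectral feature untouched and pins the absolute scale to the signal
    energy.
    """
    w = np.asarray(window, dtype=float)
    if w.size < 2:
        raise UndefinedFeature("window too short for a spectrum")
    nper = min(nperseg, w.size)
    freqs, psd = sps.welch(w, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2)
    var = float(np.var(w))
    total = float(np.trapezoid(psd, freqs))
    if total > 0 and var > 0:
        psd = psd * (var / total)
    return freqs, psd


def band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0]) & (freqs <= band[1])


def dominant_frequency(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]
) -> float:
    """Frequency of the PSD maximum within ``band``; ties go low."""
    sel = band_mask(freqs, band)
    if not sel.any():
        raise UndefinedFeature(f"PSD grid does not cover band {band}")
    p = psd[sel]
    f = freqs[sel]
    if not (p > 0).any():
        raise UndefinedFeature(f"no energy in band {band}")
    return float(f[np.argmax(p)])  # argmax returns the first (lowest-f) maximum


def hl_energy_ratio(
    freqs: np.ndarray,
    psd: np.ndarray,
    high: tuple[float, float] = (0.34, 1.0),
    low: tuple[float, float] = (0.2, 0.34),
) -> float:
    """Energy(0.34-1 Hz) / energy(0.2-0.34 Hz): labor-proximity marker."""
    e_high = float(np.trapezoid(psd[band_mask(freqs, high)], freqs[band_mask(freqs, high)]))
    e_low = float(np.trapezoid(psd[band_mask(freqs, low)], freqs[band_mask(freqs, low)]))
    if e_low <= 0:
        raise UndefinedFeature("zero energy in the low band")
    return e_high / e_low


def spectral_deciles(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float] = (0.2, 1.0)
) -> np.ndarray:
    """d1..d9: smallest grid frequency reaching k/10 of in-band energy.

    d5 is the in-band median frequency. Monotone non-decreasing by
    construction.
    """
    sel = band_mask(freqs, band)
    p = psd[sel]
    f = freqs[sel]
    total = p.sum()
    if total <= 0:
        raise UndefinedFeature(f"no energy in band {band}")
    cum = np.cumsum(p) / total
    deciles = np.empty(9)
    for k in range(1, 10):
        idx = int(np.searchsorted(cum, k / 10.0 - 1e-12))
        deciles[k - 1] = f[min(idx, f.size - 1)]
    return deciles


def spectral_entropy(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float] = (0.34, 4.0)
) -> float:
    """Normalized Shannon entropy of the in-band PSD, in [0, 1].

    1 for a flat spectrum (white, maximally complex), 0 for a single
    spectral line (perfectly regular oscillation).
    """
    p = psd[band_mask(freqs, band)]
    total = p.sum()
    if total <= 0:
        raise UndefinedFeature(f"no energy in band {band}")
    prob = p / total
    nz = prob[prob > 0]
    if nz.size <= 1:
        return 0.0
    h = -float(np.sum(nz * np.log(nz)))
    return h / math.log(prob.size)


# ---------------------------------------------------------------------------
# non-linear


def sample_entropy(window: np.ndarray, m: int = 2, r_frac: float = 0.15) -> float:
    """SampEn(m, r): -ln(A/B) over Chebyshev template matches.

    r is ``r_frac`` times the window SD; self-matches excluded. Raises
    :class:`UndefinedFeature` when no template pair matches (A or B = 0),
    in which case the window is dropped from the recording median.
    """
    w = np.asarray(window, dtype=float)
    if w.size < m + 2:
        raise UndefinedFeature("window too short for sample entropy")
    sd = float(w.std())
    if sd == 0:
        return 0.0  # constant signal: all templates match at any r > 0
    a, b = sampen_counts(w, m, r_frac * sd)
    if a == 0 or b == 0:
        raise UndefinedFeature("no matching templates at this tolerance")
    return float(-math.log(a / b))


def fuzzy_entropy(
    window: np.ndarray, m: int = 2, r_frac: float = 0.15, gradient: float = 2.0
) -> float:
    """FuzzyEn(m, r, n): like SampEn but with graded template similarity.

    Templates are baseline-removed and matched through the membership
    function exp(-(d/r)^n); always finite, which makes it better behaved
    than SampEn on short or very regular windows.
    """
    w = np.asarray(window, dtype=float)
    if w.size < m + 2:
        raise UndefinedFeature("window too short for fuzzy entropy")
    sd = float(w.std())
    if sd == 0:
        return 0.0
    phi_m1, phi_m = fuzzen_phis(w, m, r_frac * sd, gradient)
    return float(-math.log(phi_m1 / phi_m))


def _quantize(window: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-probability quantization: median split (binary) / quantile bins."""
    w = np.asarray(window, dtype=float)
    if n_levels == 2:
        return (w > np.median(w)).astype(np.int64)
    edges = np.quantile(w, np.arange(1, n_levels) / n_levels)
    return np.searchsorted(edges, w, side="left").astype(np.int64)


def lempel_ziv(window: np.ndarray, n_levels: int = 2) -> float:
    """Normalized LZ76 complexity of the quantized window.

    The signal is quantized into ``n_levels`` equal-probability symbols
    (binary: median split), parsed with the exhaustive-history rule into
    c phrases, and normalized as c * log_k(N) / N, which tends to 1 for
    i.i.d. symbol streams. A zero-variance window has minimal
    complexity by convention (single phrase, c = 1).
    """
    w = np.asarray(window, dtype=float)
    if w.size < 2:
        raise UndefinedFeature("window too short for Lempel-Ziv")
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    if float(w.std()) == 0.0:
        c = 1
    else:
        c = int(lz76_complexity(_quantize(w, n_levels)))
    n = w.size
    return c * (math.log(n) / math.log(n_levels)) / n


def time_reversibility(window: np.ndarray, tau: int = 1) -> float:
    """Third moment of lagged differences: mean (x[n] - x[n-tau])^3.

    Zero in expectation for any linear Gaussian process (those are
    statistically time-reversible); deviations flag non-linear,
    time-asymmetric dynamics such as fast-rise/slow-decay bursts.
    """
    w = np.asarray(window, dtype=float)
    if w.size <= tau:
        raise UndefinedFeature("window shorter than the reversibility lag")
    diff = w[tau:] - w[:-tau]
    return float(np.mean(diff**3))


def poincare_descriptors(window: np.ndarray) -> tuple[float, float, float]:
    """(SD1, SD2, SD1/SD2) of the lag-1 return map x[n+1] vs x[n].

    SD1 (minor axis) captures sample-to-sample variation, SD2 (major
    axis) the longer-term spread; their ratio indexes signal randomness
    (1 for white noise, small for smooth oscillations).
    """
    w = np.asarray(window, dtype=float)
    if w.size < 3:
        raise UndefinedFeature("window too short for Poincare descriptors")
    diff = np.diff(w)
    sd1_sq = float(np.var(diff)) / 2.0
    sd2_sq = 2.0 * float(np.var(w)) - sd1_sq
    if sd2_sq <= 0:
        raise UndefinedFeature("degenerate Poincare ellipse (constant window)")
    sd1 = math.sqrt(sd1_sq)
    sd2 = math.sqrt(sd2_sq)
    return sd1, sd2, sd1 / sd2


# ---------------------------------------------------------------------------
# per-window / per-recording drivers


def _fwh_filter(window: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    hi = min(band[1], 0.999 * fs / 2)
    sos = sps.butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, window)


def window_features(window: np.ndarray, fs: float, cfg: FeatureConfig) -> dict[str, float]:
    """All 23 features for one window; undefined entries come back NaN."""
    out: dict[str, float] = {}
    spec = cfg.spectral
    fwh = _fwh_filter(window, fs, spec.fwh_band)
    freqs, psd = power_spectrum(window, fs, cfg.welch_nperseg)

    def grab(name: str, fn, *args, **kwargs) -> None:
        try:
            out[name] = fn(*args, **kwargs)
        except UndefinedFeature as exc:
            logger.debug("feature %s undefined: %s", name, exc)
            out[name] = np.nan

    grab("app", peak_to_peak, fwh)
    grab("df1", dominant_frequency, freqs, psd, spec.df1_band)
    grab("df2", dominant_frequency, freqs, psd, spec.df2_band)
    grab("hl_ratio", hl_energy_ratio, freqs, psd, spec.hl_high, spec.hl_low)
    try:
        dec = spectral_deciles(freqs, psd, spec.decile_band)
        for k in range(9):
            out[f"d{k + 1}"] = float(dec[k])
    except UndefinedFeature:
        for k in range(9):
            out[f"d{k + 1}"] = np.nan
    grab("teager", teager_energy, fwh)
    grab("lz_bin", lempel_ziv, fwh, 2)
    grab("lz_multi", lempel_ziv, fwh, cfg.lz_multi_levels)
    grab("sampen", sample_entropy, fwh, cfg.entropy_m, cfg.entropy_r_frac)
    grab("specen", spectral_entropy, freqs, psd, spec.fwh_band)
    grab("fuzzen", fuzzy_entropy, fwh, cfg.entropy_m, cfg.entropy_r_frac, cfg.fuzzy_gradient)
    grab("tr", time_reversibility, fwh, cfg.tr_tau)
    try:
        sd1, sd2, ratio = poincare_descriptors(fwh)
        out["sd1"], out["sd2"], out["sd_ratio"] = sd1, sd2, ratio
    except UndefinedFeature:
        out["sd1"] = out["sd2"] = out["sd_ratio"] = np.nan
    return out


def extract_features(rec: EHGRecording, cfg: FeatureConfig | None = None) -> pd.Series:
    """Per-recording feature vector: median over artifact-free windows.

    Windows where a feature is undefined are dropped from that feature's
    median (never zero-filled). Raises ValueError when segmentation
    yields no usable window, so callers can exclude the recording with a
    logged reason.
    """
    cfg = cfg or FeatureConfig()
    ws = segment_windows(rec, cfg.window_s, cfg.overlap)
    if len(ws) == 0:
        raise ValueError(
            f"recording {rec.recording_id!r}: no artifact-free window of "
            f"{cfg.window_s} s available"
        )
    rows = [window_features(w, rec.fs, cfg) for w in ws.windows]
    frame = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    medians = frame.median(axis=0, skipna=True)
    medians.name = rec.recording_id
    return medians


def extract_cohort_features(
    recordings: list[EHGRecording], cfg: FeatureConfig | None = None
) -> pd.DataFrame:
    """Feature matrix for a cohort, one row per usable recording."""
    cfg = cfg or FeatureConfig()
    rows = []
    for rec in recordings:
        try:
            rows.append(extract_features(rec, cfg))
        except ValueError as exc:
            logger.warning("excluding recording: %s", exc)
    return pd.DataFrame(rows)
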