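"""Time- and frequency-domain feature bank.

Each kinematic channel contributes 17 time-domain and 4 frequency-domain
statistics, so a 22-channel trial maps to a 462-dimension vector laid
out channel-major (all 21 features of channel 1, then channel 2, ...).

The time-domain set follows standard vibration-analysis conventions:

==================  ==========================================
maximum             max(x)
minimum             min(x)
peak                max |x|
peak_to_peak        max(x) - min(x)
mean                (1/T) sum x
average_amplitude   (1/T) sum |x|
root_amplitude      ((1/T) sum sqrt|x|)^2
variance            population variance (divisor T)
std                 sqrt(variance)
rms                 sqrt((1/T) sum x^2)
kurtosis            m4 / sigma^4  (NOT excess: no -3)
skewness            m3 / sigma^3
shape_factor        rms / average_amplitude
peak_factor         peak / rms
pulse_factor        peak / average_amplitude
margin_factor       peak / root_amplitude
clearance_factor    peak / average_amplitude^2
==================  ==========================================

Margin and clearance factors are often used interchangeably in the
literature; here they are deliberately distinct (margin normalizes by
the root amplitude, clearance by the squared mean absolute value) so
the bank holds 17 genuinely different statistics.

Frequency-domain features use the one-sided DFT amplitude spectrum
``s_k = |X_k|`` at frequencies ``f_k``, DC bin excluded, no windowing:

========================  ====================================
mean_frequency            (1/K) sum s_k
gravity_frequency         sum f_k s_k / sum s_k        (FC)
rms_frequency             sqrt(sum f_k^2 s_k / sum s_k) (RMSF)
root_variance_frequency   sqrt(sum (f_k-FC)^2 s_k / sum s_k)
========================  ====================================

These satisfy RVF^2 + FC^2 = RMSF^2 identically.

Degenerate signals (all-zero for the normalized factors, zero variance
for kurtosis/skewness, empty spectrum for the spectral centroids) raise
:class:`~gaitfuse.errors.DegenerateSignalError` by default; pass
``on_degenerate="nan"`` to substitute NaN and keep batch extraction
alive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError
from .registry import CHANNEL_ABBRS, N_CHANNELS

TIME_FEATURE_LABELS: tuple[str, ...] = (
    "maximum",
    "minimum",
    "peak",
    "peak_to_peak",
    "mean",
    "average_amplitude",
    "root_amplitude",
    "variance",
    "std",
    "rms",
    "kurtosis",
    "skewness",
    "shape_factor",
    "peak_factor",
    "pulse_factor",
    "margin_factor",
    "clearance_factor",
)

FREQ_FEATURE_LABELS: tuple[str, ...] = (
    "mean_frequency",
    "gravity_frequency",
    "rms_frequency",
    "root_variance_frequency",
)

FEATURE_LABELS: tuple[str, ...] = TIME_FEATURE_LABELS + FREQ_FEATURE_LABELS

N_TIME = len(TIME_FEATURE_LABELS)
N_FREQ = len(FREQ_FEATURE_LABELS)
N_PER_CHANNEL = N_TIME + N_FREQ
N_FEATURES = N_CHANNELS * N_PER_CHANNEL  # 462

_NAME_SEP = "."


def feature_names() -> tuple[str, ...]:
    """All 462 feature names, channel-major, as ``"<channel>.<label>"``."""
    return tuple(
        f"{abbr}{_NAME_SEP}{label}"
        for abbr in CHANNEL_ABBRS
        for label in FEATURE_LABELS
    )


FEATURE_NAMES: tuple[str, ...] = feature_names()
_NAME_TO_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}


def parse_feature_name(name: str) -> tuple[str, str]:
    """Split a feature name into (channel_abbr, feature_label)."""
    channel, sep, label = name.rpartition(_NAME_SEP)
    if not sep or channel not in CHANNEL_ABBRS or label not in FEATURE_LABELS:
        raise ValueError(f"not a valid feature name: {name!r}")
    return channel, label


def feature_index(channel_abbr: str, feature_label: str) -> int:
    """Column index of one (channel, label) pair in the 462-vector."""
    return _NAME_TO_INDEX[f"{channel_abbr}{_NAME_SEP}{feature_label}"]


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got shape {v.shape}")
        object.__setattr__(self, "values", v)


def _degenerate(msg: str, on_degenerate: str) -> float:
    if on_degenerate == "nan":
        return float("nan")
    raise DegenerateSignalError(msg)


def compute_time_features(x, on_degenerate: str = "raise") -> np.ndarray:
    """17 time-domain statistics of one signal, in documented order."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be 1-D with at least 2 samples")
    ax = np.abs(x)
    maximum = float(x.max())
    minimum = float(x.min())
    peak = float(ax.max())
    mean = float(x.mean())
    avg_amp = float(ax.mean())
    root_amp = float(np.sqrt(ax).mean()) ** 2
    var = float(np.mean((x - mean) ** 2))
    std = float(np.sqrt(var))
    rms = float(np.sqrt(np.mean(x**2)))

    if std > 0:
        z = (x - mean) / std
        kurtosis = float(np.mean(z**4))
        skewness = float(np.mean(z**3))
    else:
        kurtosis = _degenerate("zero-variance signal: kurtosis undefined", on_degenerate)
        skewness = _degenerate("zero-variance signal: skewness undefined", on_degenerate)

    if avg_amp > 0:
        shape = rms / avg_amp
        pulse = peak / avg_amp
        clearance = peak / avg_amp**2
        peak_f = peak / rms
        margin = peak / root_amp
    else:
        shape = _degenerate("all-zero signal: shape factor undefined", on_degenerate)
        pulse = peak_f = margin = clearance = shape  # all NaN together in "nan" mode

    return np.array(
        [
            maximum,
            minimum,
            peak,
            maximum - minimum,
            mean,
            avg_amp,
            root_amp,
            var,
            std,
            rms,
            kurtosis,
            skewness,
            shape,
            peak_f,
            pulse,
            margin,
            clearance,
        ]
    )


def amplitude_spectrum(x, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided DFT amplitude spectrum with the DC bin excluded.

    Returns ``(f, s)``: bin frequencies in Hz and spectrum magnitudes.
    Isolated here so a power-spectrum convention could be swapped in
    without touching the feature formulas.
    """
    x = np.asarray(x, dtype=float)
    s = np.abs(np.fft.rfft(x))[1:]
    f = np.fft.rfftfreq(x.size, d=1.0 / fs)[1:]
    return f, s


def compute_freq_features(x, fs: float, on_degenerate: str = "raise") -> np.ndarray:
    """4 spectral statistics of one signal, in documented order."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("signal must be 1-D with at least 8 samples")
    if fs <= 0:
        raise ValueError("sample rate must be positive")
    f, s = amplitude_spectrum(x, fs)
    mf = float(s.mean())
    total = float(s.sum())
    if total > 0:
        fc = float((f * s).sum() / total)
        rmsf = float(np.sqrt((f**2 * s).sum() / total))
        rvf = float(np.sqrt(((f - fc) ** 2 * s).sum() / total))
    else:
        fc = _degenerate("all-zero spectrum: gravity frequency undefined", on_degenerate)
        rmsf = rvf = fc
    return np.array([mf, fc, rmsf, rvf])


def compute_channel_features(x, fs: float, on_degenerate: str = "raise") -> np.ndarray:
    """All 21 features of one channel: 17 time-domain then 4 frequency-domain."""
    return np.concatenate(
        [
            compute_time_features(x, on_degenerate),
            compute_freq_features(x, fs, on_degenerate),
        ]
    )


def extract_features(trial, on_degenerate: str = "raise") -> FeatureVector:
    """462-dimension channel-major feature vector of one trial."""
    ch = np.asarray(trial.channels, dtype=float)
    if ch.ndim != 2 or ch.shape[0] != N_CHANNELS:
        raise ValueError(
            f"expected a ({N_CHANNELS}, T) channel matrix, got shape {ch.shape}"
        )
    blocks = []
    for i, abbr in enumerate(CHANNEL_ABBRS):
        try:
            blocks.append(
                compute_channel_features(ch[i], trial.sample_rate, on_degenerate)
            )
        except DegenerateSignalError as err:
            raise DegenerateSignalError(f"channel {abbr!r}: {err}") from err
    return FeatureVector(values=np.concatenate(blocks), names=FEATURE_NAMES)


def extract_matrix(trials, on_degenerate: str = "raise") -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (n_trials x 462) and aligned label vector."""
    X = np.vstack([extract_features(t, on_degenerate).values for t in trials])
    y = np.array([t.label for t in trials], dtype=int)
    return X, y
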