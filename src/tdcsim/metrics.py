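"""Spectral and functional-connectivity outcome measures.

Six quantities summarize each simulated epoch, mirroring the markers used
for quantitative EEG/MEG in Alzheimer's disease: relative power in the
lower (8-10 Hz) and upper (10-13 Hz) alpha bands, total spectral power,
posterior peak frequency, and two complementary functional-connectivity
measures computed in the lower alpha band - the phase lag index (PLI,
asymmetry of the instantaneous phase-difference distribution, insensitive
to zero-lag coupling) and the amplitude envelope correlation (AEC,
Pearson correlation of analytic-signal envelopes, no leakage correction).
Theta (4-8 Hz) and beta (13-30 Hz) relative power are computed alongside
to expose shifts out of the alpha range, but are not scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "BANDS",
    "REFERENCE_BAND",
    "CONNECTIVITY_BAND",
    "MEASURES",
    "SpectralSummary",
    "ConnectivitySummary",
    "PeakFrequency",
    "psd",
    "relative_band_power",
    "peak_frequency",
    "bandpass_analytic",
    "pli",
    "aec",
    "pli_matrix",
    "aec_matrix",
    "global_fc",
    "epoch_measures",
    "posterior_region_indices",
]

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "lower_alpha": (8.0, 10.0),
    "upper_alpha": (10.0, 13.0),
    "beta": (13.0, 30.0),
}
#: Reference range for relative power: union of the four analyzed bands.
REFERENCE_BAND = (4.0, 30.0)
#: Band for both functional-connectivity measures.
CONNECTIVITY_BAND = (8.0, 10.0)
PEAK_SEARCH_BAND = (4.0, 13.0)

#: The six scored measures, in canonical order.
MEASURES = ("lower_alpha", "upper_alpha", "total_power", "peak_frequency", "pli", "aec")

#: AAL label fragments defining the posterior set used for peak frequency.
_POSTERIOR_FRAGMENTS = (
    "Occipital", "Cuneus", "Precuneus", "Calcarine",
    "Parietal_Sup", "Parietal_Inf",
)


@dataclass(frozen=True)
class SpectralSummary:
    relative_power: dict[str, float]
    total_power: float
    peak_frequency: float


@dataclass(frozen=True)
class ConnectivitySummary:
    pli: float
    aec: float


@dataclass(frozen=True)
class PeakFrequency:
    hz: float
    flat: bool = False


def psd(x: np.ndarray, fs: float, nperseg: int | None = None):
    """Welch periodogram with frequency resolution <= 0.5 Hz.

    ``x`` may be (n_samples,) or (n_signals, n_samples).  Requires at
    least two seconds of signal so the resolution bound is attainable.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2 * fs:
        raise ValueError(f"signal too short for spectral estimation: {n} samples at {fs} Hz")
    if nperseg is None:
        nperseg = min(n, int(2 ** np.ceil(np.log2(2 * fs))))
    return sps.welch(x, fs=fs, nperseg=nperseg, detrend="constant")


def _band_power(f: np.ndarray, p: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        raise ValueError(f"no spectral bins inside band {band}")
    return np.trapezoid(p[..., mask], f[mask], axis=-1)


def relative_band_power(
    f: np.ndarray,
    p: np.ndarray,
    band: tuple[float, float],
    reference: tuple[float, float] = REFERENCE_BAND,
) -> float | np.ndarray:
    """Band-integrated power divided by reference-band power, in [0, 1]."""
    if band[0] >= band[1]:
        raise ValueError("empty frequency band")
    if band[0] < reference[0] or band[1] > reference[1]:
        raise ValueError("band must lie within the reference range")
    out = _band_power(f, p, band) / _band_power(f, p, reference)
    return float(out) if np.ndim(out) == 0 else out


def peak_frequency(
    f: np.ndarray,
    psds: np.ndarray,
    search: tuple[float, float] = PEAK_SEARCH_BAND,
) -> PeakFrequency:
    """Frequency of the maximum of the (region-averaged) PSD.

    ``psds`` is one spectrum or a stack of posterior-region spectra that
    are averaged before the search.  Ties break toward the lower
    frequency (argmax convention); a flat spectrum returns the interval
    midpoint with the ``flat`` flag set and a warning.
    """
    psds = np.atleast_2d(np.asarray(psds, dtype=float))
    mean = psds.mean(axis=0)
    mask = (f >= search[0]) & (f <= search[1])
    if not mask.any():
        raise ValueError(f"no spectral bins inside search interval {search}")
    seg = mean[mask]
    if np.allclose(seg, seg[0]):
        warnings.warn("flat spectrum in peak search interval; returning midpoint")
        return PeakFrequency(hz=0.5 * (search[0] + search[1]), flat=True)
    return PeakFrequency(hz=float(f[mask][np.argmax(seg)]), flat=False)


def bandpass_analytic(
    x: np.ndarray, fs: float, band: tuple[float, float] = CONNECTIVITY_BAND
) -> np.ndarray:
    """Zero-phase FIR band-pass followed by the analytic signal.

    A Hamming-window FIR (order ~ 3.3 cycles of the low band edge,
    transition band about 2 Hz at the default setting) is applied
    forward-backward, then the Hilbert transform yields the complex
    analytic signal.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    numtaps = int(2 * (fs // 4) + 1)
    if numtaps >= n // 2:
        numtaps = max(n // 2 - 1, 3) | 1
    if numtaps < 31:
        raise ValueError("signal too short for band-pass filtering")
    taps = sps.firwin(numtaps, band, fs=fs, pass_zero=False)
    filtered = sps.filtfilt(taps, 1.0, x, axis=-1, padlen=min(3 * numtaps, n - 2))
    return sps.hilbert(filtered, axis=-1)


def _phases(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    return np.angle(x) if np.iscomplexobj(x) else np.angle(sps.hilbert(x, axis=-1))


def _envelope(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    return np.abs(x) if np.iscomplexobj(x) else np.abs(sps.hilbert(x, axis=-1))


def pli(x: np.ndarray, y: np.ndarray) -> float:
    """Phase lag index of two band-limited (or analytic) signals.

    ``| mean_t sign(delta_phi(t)) |`` with the instantaneous phase
    difference wrapped to (-pi, pi].  1 for a consistent nonzero lag,
    0 for zero-lag (or inconsistent) phase relations.
    """
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape or x.shape[-1] == 0:
        raise ValueError("signals must be equal-length and non-empty")
    dphi = _phases(x) - _phases(y)
    return float(np.abs(np.mean(np.sign(np.sin(dphi)))))


def aec(x: np.ndarray, y: np.ndarray) -> float:
    """Amplitude envelope correlation (Pearson, no leakage correction)."""
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape or x.shape[-1] == 0:
        raise ValueError("signals must be equal-length and non-empty")
    ex, ey = _envelope(x), _envelope(y)
    if np.std(ex) == 0 or np.std(ey) == 0:
        warnings.warn("constant amplitude envelope; AEC undefined")
        return float("nan")
    return float(np.corrcoef(ex, ey)[0, 1])


def _pair_matrix(values: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros((n, n))
    m[np.triu_indices(n, 1)] = values
    return m + m.T


def pli_matrix(analytic: np.ndarray) -> np.ndarray:
    """Pairwise PLI over rows of an analytic-signal array (n, t)."""
    ph = np.angle(analytic)
    n = ph.shape[0]
    iu = np.triu_indices(n, 1)
    dphi = ph[iu[0]] - ph[iu[1]]
    return _pair_matrix(np.abs(np.mean(np.sign(np.sin(dphi)), axis=-1)), n)


def aec_matrix(analytic: np.ndarray) -> np.ndarray:
    """Pairwise envelope correlation over rows of an analytic array."""
    env = np.abs(analytic)
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(env)
    np.fill_diagonal(c, 0.0)
    return c


def global_fc(matrix: np.ndarray) -> float:
    """Mean of the strictly-upper-triangle entries of a symmetric matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("pairwise matrix must be square")
    n = m.shape[0]
    if n < 2:
        raise ValueError("global connectivity needs at least two regions")
    if not np.allclose(m, m.T, equal_nan=True):
        raise ValueError("pairwise matrix must be symmetric")
    return float(m[np.triu_indices(n, 1)].mean())


def posterior_region_indices(labels: Sequence[str]) -> list[int]:
    """Indices of posterior regions (occipital, cuneus/precuneus,
    calcarine, superior/inferior parietal) by AAL label fragment; all
    regions if no label matches (e.g. synthetic region names)."""
    idx = [
        i
        for i, lab in enumerate(labels)
        if any(fragment in lab for fragment in _POSTERIOR_FRAGMENTS)
    ]
    return idx if idx else list(range(len(labels)))


def epoch_measures(
    signals: np.ndarray,
    fs: float,
    posterior: Sequence[int] | None = None,
) -> dict[str, float]:
    """All outcome measures for one epoch of network output.

    ``signals`` is (n_samples, n_regions) of excitatory membrane
    potentials.  Regional quantities are averaged over regions (or region
    pairs); total power is the mean per-region signal variance.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected (n_samples, n_regions) signals")
    x = x - x.mean(axis=0)
    n_regions = x.shape[1]
    f, p = psd(x.T, fs)
    out: dict[str, float] = {}
    for name, band in BANDS.items():
        out[name] = float(np.mean(relative_band_power(f, p, band)))
    out["total_power"] = float(x.var(axis=0).mean())
    post = list(posterior) if posterior is not None else list(range(n_regions))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["peak_frequency"] = peak_frequency(f, p[post]).hz
    if n_regions >= 2:
        analytic = bandpass_analytic(x.T, fs, CONNECTIVITY_BAND)
        out["pli"] = global_fc(pli_matrix(analytic))
        out["aec"] = global_fc(aec_matrix(analytic))
    else:
        out["pli"] = float("nan")
        out["aec"] = float("nan")
    return out
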