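"""Event-related potential extraction and quantification.

Target-locked epochs are common-average referenced, zero-phase low-pass
filtered, and linearly detrended; trials are averaged, the parieto-occipital
region of interest is averaged, and the waveform is baseline-corrected on
the pre-target interval. Components are quantified by the mean voltage and
the fractional-area latency (FAL) within a priori windows: N1 (negative,
90-200 ms) and P3 (positive, 250-400 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as spsig
from scipy import stats as sps
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigurationError, DataError, DomainError, InferenceError
from .stats import adjust_pvalues
from .taskgen import EEGEpochs

#: Parieto-occipital electrodes used for ERP quantification.
ROI_PARIETO_OCCIPITAL = ("Pz", "P5", "P6", "P7", "P8", "PO3", "PO4",
                         "O1", "O2")


@dataclass(frozen=True)
class ComponentWindow:
    name: str
    t_lo_ms: float
    t_hi_ms: float
    polarity: str  # labeling only; area is computed on the rectified signal

    def __post_init__(self):
        if self.t_lo_ms >= self.t_hi_ms:
            raise ConfigurationError("component window must have t_lo < t_hi")


N1_WINDOW = ComponentWindow("N1", 90.0, 200.0, "negative")
P3_WINDOW = ComponentWindow("P3", 250.0, 400.0, "positive")


@dataclass
class ERPWaveform:
    """ROI-averaged, baseline-corrected ERP (uV over seconds)."""

    values: np.ndarray
    times: np.ndarray
    n_trials: int
    meta: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

def design_lowpass(sampling_rate: float, cutoff: float = 30.0,
                   transition: float = 7.5) -> np.ndarray:
    """Windowed-sinc (Hamming) low-pass FIR kernel.

    Transition band ``cutoff`` -> ``cutoff + transition`` Hz, stopband
    attenuation >= 53 dB single-pass (about double after forward-backward
    application).
    """
    nyq = sampling_rate / 2.0
    if cutoff + transition >= nyq:
        raise ConfigurationError(
            f"cutoff {cutoff} + transition {transition} Hz reaches Nyquist "
            f"({nyq} Hz)")
    numtaps = int(np.ceil(3.3 * sampling_rate / transition))
    numtaps += 1 - numtaps % 2  # zero-phase filtering needs an odd kernel
    return spsig.firwin(numtaps, cutoff + transition / 2.0, fs=sampling_rate,
                        window="hamming")


def preprocess_epochs(epochs: EEGEpochs, lp_cutoff: float = 30.0
                      ) -> EEGEpochs:
    """Common-average reference, zero-phase low-pass, per-channel detrend.

    The order (reference -> filter -> detrend) is fixed so outputs are
    bit-stable; all three steps are linear.
    """
    if lp_cutoff >= epochs.sampling_rate / 2.0:
        raise ConfigurationError("low-pass cutoff must be below Nyquist")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    kernel = design_lowpass(epochs.sampling_rate, lp_cutoff)
    padlen = min(3 * len(kernel), data.shape[-1] - 1)
    data = spsig.filtfilt(kernel, [1.0], data, axis=-1, padlen=padlen)
    data = spsig.detrend(data, axis=-1, type="linear")
    out = EEGEpochs(data=data, times=epochs.times.copy(),
                    sampling_rate=epochs.sampling_rate,
                    alignment=epochs.alignment,
                    channel_names=epochs.channel_names,
                    trials=epochs.trials.copy(),
                    provenance=dict(epochs.provenance))
    out.provenance["preprocessed"] = {"lp_cutoff_hz": lp_cutoff,
                                      "reference": "common_average"}
    return out


# --------------------------------------------------------------------------
# Extraction and measures
# --------------------------------------------------------------------------

def extract_erp(epochs: EEGEpochs,
                roi: tuple[str, ...] = ROI_PARIETO_OCCIPITAL,
                baseline: tuple[float, float] = (-0.1, 0.0)) -> ERPWaveform:
    """Trial-average, ROI-average, then baseline-subtract."""
    missing = [ch for ch in roi if ch not in epochs.channel_names]
    if missing:
        raise DataError(f"ROI channels missing from epochs: {missing}")
    if epochs.n_trials == 0:
        raise DataError("cannot extract an ERP from zero trials")
    idx = [epochs.channel_names.index(ch) for ch in roi]
    wave = epochs.data[:, idx, :].mean(axis=(0, 1))
    bmask = (epochs.times >= baseline[0]) & (epochs.times <= baseline[1])
    if not bmask.any():
        raise DomainError(f"baseline {baseline} outside epoch span")
    wave = wave - wave[bmask].mean()
    return ERPWaveform(values=wave, times=epochs.times.copy(),
                       n_trials=epochs.n_trials,
                       meta={"roi": tuple(roi), "baseline": baseline})


def _window_mask(times_s: np.ndarray, window: ComponentWindow) -> np.ndarray:
    # closed interval with half-sample slack against grid misalignment
    dt_ms = np.median(np.diff(times_s)) * 1000.0
    t_ms = times_s * 1000.0
    mask = (t_ms >= window.t_lo_ms - dt_ms / 2.0) & \
           (t_ms <= window.t_hi_ms + dt_ms / 2.0)
    if not mask.any() or t_ms[0] > window.t_lo_ms or t_ms[-1] < window.t_hi_ms:
        raise DomainError(f"window {window.name} [{window.t_lo_ms}, "
                          f"{window.t_hi_ms}] ms outside epoch span")
    return mask


def mean_amplitude(erp: ERPWaveform, window: ComponentWindow) -> float:
    """Mean voltage (uV) over the component window."""
    return float(erp.values[_window_mask(erp.times, window)].mean())


def fractional_area_latency(erp: ERPWaveform, window: ComponentWindow,
                            fraction: float = 0.5) -> float:
    """Fractional-area latency (ms) within the component window.

    The baseline-corrected waveform is rectified (absolute value), its
    cumulative trapezoidal area computed, and the latency is the linearly
    interpolated time at which the cumulative area reaches ``fraction`` of
    the total. Fractions 0.25 and 0.75 are supported for sensitivity checks.
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("fraction must lie in (0, 1)")
    mask = _window_mask(erp.times, window)
    t_ms = erp.times[mask] * 1000.0
    rect = np.abs(erp.values[mask])
    cum = np.concatenate([[0.0], cumulative_trapezoid(rect, t_ms)])
    total = cum[-1]
    if total <= 0.0:
        raise InferenceError(f"zero rectified area in {window.name} window; "
                             "latency undefined")
    target = fraction * total
    k = int(np.searchsorted(cum, target))
    k = min(max(k, 1), len(cum) - 1)
    c0, c1 = cum[k - 1], cum[k]
    if c1 == c0:
        return float(t_ms[k])
    return float(t_ms[k - 1] + (t_ms[k] - t_ms[k - 1])
                 * (target - c0) / (c1 - c0))


def component_measures(erp: ERPWaveform, windows=(N1_WINDOW, P3_WINDOW),
                       fraction: float = 0.5) -> dict[str, dict[str, float]]:
    """Mean amplitude and FAL for each component window."""
    return {w.name: {"mean_amp_uv": mean_amplitude(erp, w),
                     "fal_ms": fractional_area_latency(erp, w, fraction),
                     "fraction": fraction}
            for w in windows}


# --------------------------------------------------------------------------
# Time-resolved pre/post contrast
# --------------------------------------------------------------------------

@dataclass
class TimewiseResult:
    times: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray  # BH-adjusted p < alpha


def timewise_tests(waveforms_pre: np.ndarray, waveforms_post: np.ndarray,
                   times: np.ndarray, alpha: float = 0.05) -> TimewiseResult:
    """Per-timepoint paired t-tests with Benjamini-Hochberg control.

    ``waveforms_pre``/``waveforms_post`` are subjects x timepoints arrays on
    a common grid with subjects matched across rows.
    """
    pre = np.asarray(waveforms_pre, dtype=float)
    post = np.asarray(waveforms_post, dtype=float)
    if pre.shape != post.shape:
        raise DataError("pre and post waveform arrays must share a shape")
    if pre.shape[0] < 2:
        raise InferenceError("paired t-tests need at least 2 subjects")
    diff = post - pre
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), n - 1)
    p = np.where(sd > 0, p, 1.0)
    p_adj = adjust_pvalues(p, method="bh_fdr")
    return TimewiseResult(times=np.asarray(times), t=t, p=p, p_adj=p_adj,
                          significant=p_adj < alpha)
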