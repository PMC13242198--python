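"""Synthetic data generation for a pre/post-stimulation Posner cueing experiment.

This module fabricates everything the downstream analyses consume:

* stratified task schedules (cue type x cue-target interval x validity),
* per-trial reaction-time tables with group x session x trial-type effects,
* multichannel EEG epochs containing a scale-free background with a target
  DFA exponent, band-limited alpha/gamma oscillations of controllable power,
  and target-locked N1/P3 deflections,
* a 2x2 blinding contingency table,
* a 32-channel 10-20 montage with a distance-based adjacency graph.

All randomness is drawn from an explicit integer seed per operation; there is
no global random state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import h5py
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError

# --------------------------------------------------------------------------
# Task structure constants
# --------------------------------------------------------------------------

CUE_TYPES = ("endogenous", "exogenous")
SIDES = ("left", "right")
CTIS = (0.5, 1.0)

#: Total trial duration (s) per (cue_type, cti) class; cue/fixation timing
#: differs between endogenous and exogenous cues, hence the class-specific
#: totals. A default 120-trial session sums to 523.92 s.
TRIAL_DURATIONS: Mapping[tuple[str, float], float] = {
    ("endogenous", 0.5): 4.55,
    ("endogenous", 1.0): 5.05,
    ("exogenous", 0.5): 3.682,
    ("exogenous", 1.0): 4.182,
}

TRIAL_TYPES = ("Endo-Valid", "Endo-Invalid", "Exo-Valid", "Exo-Invalid")


def trial_type_label(cue_type: str, validity: str) -> str:
    """Map (cue_type, validity) onto the four canonical trial-type labels."""
    prefix = {"endogenous": "Endo", "exogenous": "Exo"}[cue_type]
    suffix = {"valid": "Valid", "invalid": "Invalid"}[validity]
    return f"{prefix}-{suffix}"


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the cueing task.

    ``validity == "valid"`` iff the target appears on the cued side;
    ``trial_duration`` is fixed by the (cue_type, cti) class.
    """

    index: int
    cue_type: str
    cue_side: str
    validity: str
    target_side: str
    cti: float
    trial_duration: float


@dataclass(frozen=True)
class TaskSchedule:
    trials: tuple[TrialSpec, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([dataclasses.asdict(t) for t in self.trials])
        if df.empty:
            df = pd.DataFrame(
                columns=["index", "cue_type", "cue_side", "validity",
                         "target_side", "cti", "trial_duration"])
        return df


@dataclass(frozen=True)
class ScheduleConfig:
    """Stratified cell counts of one session.

    Counts are exact, not Bernoulli: each (cue_type x cti) cell holds
    ``n_per_cell`` trials of which ``n_valid_per_cell`` are valid. Defaults
    give 120 trials, 30 per cell, 24 valid / 6 invalid within each cell.
    """

    n_per_cell: int = 30
    n_valid_per_cell: int = 24
    cue_types: tuple[str, ...] = CUE_TYPES
    ctis: tuple[float, ...] = CTIS
    durations: Mapping[tuple[str, float], float] = field(
        default_factory=lambda: dict(TRIAL_DURATIONS))

    def validate(self) -> None:
        if self.n_per_cell < 0 or self.n_valid_per_cell < 0:
            raise ConfigurationError("cell counts must be non-negative")
        if self.n_valid_per_cell > self.n_per_cell:
            raise ConfigurationError(
                f"n_valid_per_cell ({self.n_valid_per_cell}) exceeds "
                f"n_per_cell ({self.n_per_cell})")
        for cue in self.cue_types:
            for cti in self.ctis:
                if (cue, cti) not in self.durations:
                    raise ConfigurationError(
                        f"no trial duration configured for ({cue}, {cti})")


def generate_schedule(config: ScheduleConfig | None = None,
                      seed: int = 0) -> TaskSchedule:
    """Generate one session's trial schedule.

    Cell counts and the valid/invalid split within each cell are exact;
    cue sides are drawn 50/50 and the final trial order is a uniform
    shuffle. Deterministic given (config, seed).
    """
    config = config or ScheduleConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    protos: list[tuple[str, float, str]] = []
    for cue in config.cue_types:
        for cti in config.ctis:
            protos.extend((cue, cti, "valid")
                          for _ in range(config.n_valid_per_cell))
            protos.extend((cue, cti, "invalid")
                          for _ in range(config.n_per_cell
                                         - config.n_valid_per_cell))
    order = rng.permutation(len(protos))
    trials = []
    for i, j in enumerate(order):
        cue, cti, validity = protos[j]
        cue_side = SIDES[rng.integers(2)]
        target_side = cue_side if validity == "valid" else \
            SIDES[1 - SIDES.index(cue_side)]
        trials.append(TrialSpec(
            index=i, cue_type=cue, cue_side=cue_side, validity=validity,
            target_side=target_side, cti=float(cti),
            trial_duration=config.durations[(cue, cti)]))
    return TaskSchedule(trials=tuple(trials), seed=seed)


def schedule_duration(schedule: TaskSchedule) -> float:
    """Exact sum of per-trial durations in seconds (0 for an empty schedule)."""
    return float(sum(t.trial_duration for t in schedule.trials))


# --------------------------------------------------------------------------
# Reaction-time model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RTModelSpec:
    """Truncated-normal reaction-time model, parameterized per trial type.

    ``mean_ms``/``sd_ms`` describe the pre-session distribution per trial
    type. ``practice_shift_ms`` is added to the mean in every post session
    (both groups: familiarization), and ``group_time_effect_ms`` is the
    additional post-session shift for the active group (the planted
    stimulation after-effect). Lapses produce missing responses; fast
    guesses are anticipatory presses uniform on [0, 100) ms.
    """

    mean_ms: Mapping[str, float] = field(default_factory=lambda: {
        "Endo-Valid": 334.4, "Endo-Invalid": 425.4,
        "Exo-Valid": 355.5, "Exo-Invalid": 373.0})
    sd_ms: Mapping[str, float] = field(default_factory=lambda: {
        "Endo-Valid": 65.9, "Endo-Invalid": 110.0,
        "Exo-Valid": 88.2, "Exo-Invalid": 79.7})
    practice_shift_ms: Mapping[str, float] = field(default_factory=lambda: {
        "Endo-Valid": -5.2, "Endo-Invalid": -9.7,
        "Exo-Valid": -9.4, "Exo-Invalid": -12.2})
    group_time_effect_ms: Mapping[str, float] = field(default_factory=lambda: {
        "Endo-Valid": -17.7, "Endo-Invalid": -23.9,
        "Exo-Valid": -35.9, "Exo-Invalid": 6.0})
    lapse_rate: float = 0.01
    fast_guess_rate: float = 0.02

    def validate(self, trial_types: Sequence[str] = TRIAL_TYPES) -> None:
        for tt in trial_types:
            if tt not in self.mean_ms or tt not in self.sd_ms:
                raise ConfigurationError(f"no RT parameters for {tt!r}")
            if self.sd_ms[tt] < 0:
                raise ConfigurationError(f"sd must be >= 0 for {tt!r}")
        for r in (self.lapse_rate, self.fast_guess_rate):
            if not 0.0 <= r <= 1.0 or self.lapse_rate + self.fast_guess_rate > 1:
                raise ConfigurationError("lapse/fast-guess rates must lie in "
                                         "[0,1] and sum to at most 1")

    def cell_mean_ms(self, trial_type: str, group: str, session: str) -> float:
        mu = self.mean_ms[trial_type]
        if session == "post":
            mu += self.practice_shift_ms.get(trial_type, 0.0)
            if group == "active":
                mu += self.group_time_effect_ms.get(trial_type, 0.0)
        return mu


def simulate_rts(schedule: TaskSchedule, model: RTModelSpec | None = None,
                 subject: str = "S01", group: str = "sham",
                 session: str = "pre", seed: int = 0) -> pd.DataFrame:
    """Draw one subject-session behavioral table for a schedule.

    Returns a frame with columns (subject, group, session, trial_index,
    cue_type, cue_side, validity, cti_s, rt_s); ``rt_s`` is NaN for lapses
    (no response). RTs are truncated-at-zero normal per cell.
    """
    model = model or RTModelSpec()
    trial_types = sorted({trial_type_label(t.cue_type, t.validity)
                          for t in schedule.trials})
    model.validate(trial_types)
    rng = np.random.default_rng(seed)
    n = len(schedule.trials)
    tts = np.array([trial_type_label(t.cue_type, t.validity)
                    for t in schedule.trials])
    mu = np.array([model.cell_mean_ms(tt, group, session) / 1000.0
                   for tt in tts])
    sd = np.array([model.sd_ms[tt] / 1000.0 for tt in tts])
    u = rng.random(n)
    u_guess = rng.random(n)
    u_rt = rng.random(n)
    rt = mu.copy()
    pos = sd > 0
    if pos.any():
        rt[pos] = sps.truncnorm.ppf(u_rt[pos], -mu[pos] / sd[pos], np.inf,
                                    loc=mu[pos], scale=sd[pos])
    rt = np.where(u < model.lapse_rate, np.nan, rt)
    guess = (u >= model.lapse_rate) & \
        (u < model.lapse_rate + model.fast_guess_rate)
    rt = np.where(guess, u_guess * 0.1, rt)
    return pd.DataFrame({
        "subject": subject, "group": group, "session": session,
        "trial_index": [t.index for t in schedule.trials],
        "cue_type": [t.cue_type for t in schedule.trials],
        "cue_side": [t.cue_side for t in schedule.trials],
        "validity": [t.validity for t in schedule.trials],
        "cti_s": [t.cti for t in schedule.trials],
        "rt_s": rt})


# --------------------------------------------------------------------------
# Scale-free series and EEG epochs
# --------------------------------------------------------------------------

def synthesize_scalefree_series(n_samples: int, target_alpha: float,
                                variance: float = 1.0,
                                seed: int | np.random.Generator = 0
                                ) -> np.ndarray:
    """Spectral-synthesis surrogate with a target DFA scaling exponent.

    Power spectral density follows f**-(2*alpha - 1) with Gaussian random
    Fourier coefficients and random phases, so the expected DFA exponent over
    the fit range equals ``target_alpha`` (alpha = 0.5 is white noise,
    alpha = 1.5 the cumulative sum of white noise). The realized sample
    variance is rescaled exactly to ``variance``.
    """
    if not 0.0 < target_alpha < 2.0:
        raise ConfigurationError("target_alpha must lie in (0, 2)")
    if n_samples < 8:
        raise ConfigurationError("n_samples too small for spectral synthesis")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    beta = 2.0 * target_alpha - 1.0
    n_freq = n_samples // 2 + 1
    f = np.arange(n_freq, dtype=float)
    amp = np.zeros(n_freq)
    amp[1:] = f[1:] ** (-beta / 2.0)
    coeff = amp * (rng.standard_normal(n_freq)
                   + 1j * rng.standard_normal(n_freq))
    coeff[0] = 0.0
    x = np.fft.irfft(coeff, n_samples)
    v = x.var()
    if v > 0 and variance > 0:
        x *= np.sqrt(variance / v)
    elif variance == 0:
        x = np.zeros(n_samples)
    return x


def _bandlimited_noise(n: int, fs: float, band: tuple[float, float],
                       variance: float, rng: np.random.Generator
                       ) -> np.ndarray:
    """White noise spectrally masked to ``band``, rescaled to exact variance."""
    if variance <= 0:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    v = x.var()
    if v == 0:
        raise ConfigurationError(
            f"band {band} resolves no frequency bin at n={n}, fs={fs}")
    return x * np.sqrt(variance / v)


@dataclass(frozen=True)
class ErpTemplate:
    """Gaussian-windowed component template: amp * exp(-(t-lat)^2 / 2w^2)."""

    amplitude_uv: float
    latency_ms: float
    width_ms: float

    def waveform(self, times_s: np.ndarray) -> np.ndarray:
        t_ms = times_s * 1000.0
        return self.amplitude_uv * np.exp(
            -0.5 * ((t_ms - self.latency_ms) / self.width_ms) ** 2)


@dataclass(frozen=True)
class EffectSpec:
    """Post-session changes applied to active-group epochs.

    Multiplicative power scalings, an additive shift of the background
    scaling exponent, amplitude scalings of the component templates, and
    additive latency shifts (ms).
    """

    alpha_power_scale: float = 0.7
    gamma_power_scale: float = 1.4
    exponent_shift: float = -0.1
    n1_amp_scale: float = 1.3
    p3_amp_scale: float = 1.25
    n1_latency_shift_ms: float = 0.0
    p3_latency_shift_ms: float = -15.0


#: 32-channel 10-20 layout containing every electrode the analyses name.
CHANNELS_32 = (
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P5", "P3", "Pz", "P4", "P6", "P8",
    "PO3", "PO4", "O1", "O2",
)

ALPHA_BAND = (8.0, 12.0)
GAMMA_BAND = (30.0, 45.0)


@dataclass(frozen=True)
class EEGSpec:
    """Parameters of the synthetic EEG epochs (units: uV, uV**2, Hz, ms)."""

    channel_names: tuple[str, ...] = CHANNELS_32
    sampling_rate: float = 256.0
    background_variance: float = 10.0
    background_alpha_exponent: float = 0.8
    alpha_power: float = 5.0
    gamma_power: float = 1.0
    n1: ErpTemplate = ErpTemplate(-3.0, 140.0, 25.0)
    p3: ErpTemplate = ErpTemplate(4.0, 320.0, 50.0)
    effect_spec: EffectSpec = EffectSpec()
    target_window: tuple[float, float] = (-0.1, 0.5)

    def validate(self) -> None:
        if self.sampling_rate < 2 * GAMMA_BAND[1]:
            raise ConfigurationError(
                f"sampling_rate {self.sampling_rate} Hz cannot represent the "
                f"gamma band (need >= {2 * GAMMA_BAND[1]} Hz)")
        if not 0.0 < self.background_alpha_exponent < 2.0:
            raise ConfigurationError(
                "background_alpha_exponent must lie in (0, 2)")


@dataclass
class EEGEpochs:
    """Trials x channels x samples array plus metadata.

    ``times`` is in seconds relative to the alignment event
    (``cue_onset`` for CTI epochs, ``target_onset`` for target epochs);
    ``trials`` carries one metadata row per epoch.
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    alignment: str
    channel_names: tuple[str, ...]
    trials: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class SessionEpochs:
    """Epochs of one subject-session: target-locked plus per-CTI-length."""

    target: EEGEpochs
    cti: dict[float, EEGEpochs]


def _session_effects(spec: EEGSpec, group: str, session: str):
    """Resolve (alpha_power, gamma_power, exponent, n1, p3) for one session."""
    if group == "active" and session == "post":
        e = spec.effect_spec
        n1 = ErpTemplate(spec.n1.amplitude_uv * e.n1_amp_scale,
                         spec.n1.latency_ms + e.n1_latency_shift_ms,
                         spec.n1.width_ms)
        p3 = ErpTemplate(spec.p3.amplitude_uv * e.p3_amp_scale,
                         spec.p3.latency_ms + e.p3_latency_shift_ms,
                         spec.p3.width_ms)
        return (spec.alpha_power * e.alpha_power_scale,
                spec.gamma_power * e.gamma_power_scale,
                np.clip(spec.background_alpha_exponent + e.exponent_shift,
                        0.05, 1.95),
                n1, p3)
    return (spec.alpha_power, spec.gamma_power,
            spec.background_alpha_exponent, spec.n1, spec.p3)


def simulate_epochs(schedule: TaskSchedule, spec: EEGSpec | None = None,
                    subject: str = "S01", group: str = "sham",
                    session: str = "pre", seed: int = 0) -> SessionEpochs:
    """Simulate one subject-session of epoched EEG.

    Every trial yields a cue-aligned CTI segment (length = the trial's CTI)
    and a target-locked segment spanning the configured window, each built as
    scale-free background + band-limited alpha and gamma processes at the
    specified band variances; target segments additionally carry the N1
    (negative) and P3 (positive) Gaussian templates. Active-group
    post-session epochs apply ``spec.effect_spec``.
    """
    spec = spec or EEGSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    fs = spec.sampling_rate
    a_pow, g_pow, exponent, n1, p3 = _session_effects(spec, group, session)

    t0, t1 = spec.target_window
    n_target = int(round((t1 - t0) * fs))
    times_target = t0 + np.arange(n_target) / fs
    erp = n1.waveform(times_target) + p3.waveform(times_target)

    n_ch = len(spec.channel_names)
    meta_cols = ["subject", "group", "session", "trial_index", "cue_type",
                 "validity", "cti_s", "trial_type"]

    def _segment(n: int) -> np.ndarray:
        x = synthesize_scalefree_series(n, exponent,
                                        spec.background_variance, rng)
        x = x + _bandlimited_noise(n, fs, ALPHA_BAND, a_pow, rng)
        x = x + _bandlimited_noise(n, fs, GAMMA_BAND, g_pow, rng)
        return x

    target_data = np.empty((len(schedule.trials), n_ch, n_target))
    meta_rows = []
    cti_store: dict[float, tuple[list[np.ndarray], list[tuple]]] = {
        cti: ([], []) for cti in sorted({t.cti for t in schedule.trials})}
    for i, t in enumerate(schedule.trials):
        tt = trial_type_label(t.cue_type, t.validity)
        row = (subject, group, session, t.index, t.cue_type, t.validity,
               t.cti, tt)
        meta_rows.append(row)
        n_cti = int(round(t.cti * fs))
        cti_trial = np.empty((n_ch, n_cti))
        for c in range(n_ch):
            target_data[i, c] = _segment(n_target) + erp
            cti_trial[c] = _segment(n_cti)
        cti_store[t.cti][0].append(cti_trial)
        cti_store[t.cti][1].append(row)

    prov = {"subject": subject, "group": group, "session": session,
            "seed": int(seed), "spec": _spec_provenance(spec)}
    target = EEGEpochs(
        data=target_data, times=times_target, sampling_rate=fs,
        alignment="target_onset", channel_names=tuple(spec.channel_names),
        trials=pd.DataFrame(meta_rows, columns=meta_cols), provenance=prov)
    cti_epochs = {}
    for cti, (arrays, rows) in cti_store.items():
        n_cti = int(round(cti * fs))
        cti_epochs[cti] = EEGEpochs(
            data=np.stack(arrays), times=np.arange(n_cti) / fs,
            sampling_rate=fs, alignment="cue_onset",
            channel_names=tuple(spec.channel_names),
            trials=pd.DataFrame(rows, columns=meta_cols), provenance=prov)
    return SessionEpochs(target=target, cti=cti_epochs)


def _spec_provenance(spec: EEGSpec) -> dict:
    d = dataclasses.asdict(spec)
    return json.loads(json.dumps(d, default=str))


# --------------------------------------------------------------------------
# HDF5 persistence
# --------------------------------------------------------------------------

def save_epochs(epochs: EEGEpochs, path) -> None:
    """Write epochs to HDF5 (datasets /epochs, /times; string metadata under
    /trials) plus a JSON provenance sidecar at ``path + '.json'``."""
    path = str(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("epochs", data=epochs.data)
        h5.create_dataset("times", data=epochs.times)
        h5.attrs["sampling_rate_hz"] = epochs.sampling_rate
        h5.attrs["alignment"] = epochs.alignment
        h5.attrs["channel_names"] = [str(c) for c in epochs.channel_names]
        grp = h5.create_group("trials")
        for col in epochs.trials.columns:
            vals = epochs.trials[col].to_numpy()
            if vals.dtype == object or str(vals.dtype).startswith("str"):
                vals = np.array([str(v) for v in vals], dtype="S32")
            grp.create_dataset(col, data=vals)
        grp.attrs["columns"] = list(epochs.trials.columns)
    with open(path + ".json", "w") as fh:
        json.dump(epochs.provenance, fh, indent=2, sort_keys=True)


def load_epochs(path) -> EEGEpochs:
    path = str(path)
    with h5py.File(path, "r") as h5:
        data = h5["epochs"][()]
        times = h5["times"][()]
        fs = float(h5.attrs["sampling_rate_hz"])
        alignment = str(h5.attrs["alignment"])
        channels = tuple(str(c) for c in h5.attrs["channel_names"])
        cols = list(h5["trials"].attrs["columns"])
        trials = {}
        for col in cols:
            vals = h5["trials"][col][()]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() for v in vals])
            trials[col] = vals
    prov = {}
    try:
        with open(path + ".json") as fh:
            prov = json.load(fh)
    except FileNotFoundError:
        pass
    return EEGEpochs(data=data, times=times, sampling_rate=fs,
                     alignment=alignment, channel_names=channels,
                     trials=pd.DataFrame(trials)[cols], provenance=prov)


# --------------------------------------------------------------------------
# Blinding contingency table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = conditioned group (active, sham); columns = reported group.

    ``a``: conditioned active / reported active, ``b``: conditioned active /
    reported sham, ``c``: conditioned sham / reported active, ``d``:
    conditioned sham / reported sham.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConfigurationError("contingency counts must be >= 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def usable_for_inference(self) -> bool:
        return self.total > 0 and (self.b + self.c) > 0


def generate_blinding_table(n_per_group: int = 9,
                            report_probabilities: tuple[float, float]
                            = (7 / 9, 6 / 9),
                            seed: int = 0,
                            counts: tuple[int, int, int, int] | None = None
                            ) -> ContingencyTable2x2:
    """Simulate the end-of-session blinding survey.

    ``report_probabilities`` are the per-row probabilities of reporting
    "active" for the conditioned-active and conditioned-sham rows; draws are
    binomial per row. Passing ``counts`` bypasses sampling and returns a
    fixed table (e.g. (7, 2, 6, 3))."""
    if counts is not None:
        return ContingencyTable2x2(*counts)
    p_active, p_sham = report_probabilities
    for p in (p_active, p_sham):
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError("report probabilities must lie in [0,1]")
    if n_per_group < 0:
        raise ConfigurationError("n_per_group must be >= 0")
    rng = np.random.default_rng(seed)
    a = int(rng.binomial(n_per_group, p_active))
    c = int(rng.binomial(n_per_group, p_sham))
    return ContingencyTable2x2(a=a, b=n_per_group - a, c=c,
                               d=n_per_group - c)


# --------------------------------------------------------------------------
# Montage and adjacency
# --------------------------------------------------------------------------

#: 2-D head projection (unit-circle azimuthal layout, nose at +y).
MONTAGE_POSITIONS: Mapping[str, tuple[float, float]] = {
    "Fp1": (-0.26, 0.75), "Fpz": (0.0, 0.82), "Fp2": (0.26, 0.75),
    "F7": (-0.65, 0.47), "F3": (-0.34, 0.50), "Fz": (0.0, 0.52),
    "F4": (0.34, 0.50), "F8": (0.65, 0.47),
    "FC5": (-0.55, 0.22), "FC1": (-0.18, 0.27), "FC2": (0.18, 0.27),
    "FC6": (0.55, 0.22),
    "T7": (-0.80, 0.0), "C3": (-0.40, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.40, 0.0), "T8": (0.80, 0.0),
    "CP5": (-0.55, -0.22), "CP1": (-0.18, -0.27), "CP2": (0.18, -0.27),
    "CP6": (0.55, -0.22),
    "P7": (-0.65, -0.47), "P5": (-0.49, -0.50), "P3": (-0.33, -0.52),
    "Pz": (0.0, -0.54), "P4": (0.33, -0.52), "P6": (0.49, -0.50),
    "P8": (0.65, -0.47),
    "PO3": (-0.24, -0.66), "PO4": (0.24, -0.66),
    "O1": (-0.25, -0.76), "O2": (0.25, -0.76),
}


def build_adjacency(positions: Mapping[str, tuple[float, float]] | None = None,
                    scale: float = 1.3) -> nx.Graph:
    """Distance-thresholded electrode adjacency graph.

    Electrodes are neighbors when their 2-D distance is below ``scale``
    times the median nearest-neighbor distance of the layout.
    """
    positions = dict(positions or MONTAGE_POSITIONS)
    labels = list(positions)
    xy = np.array([positions[l] for l in labels])
    dist = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    threshold = scale * np.median(dist.min(axis=1))
    graph = nx.Graph()
    graph.add_nodes_from(labels)
    nx.set_node_attributes(graph, positions, "pos")
    for i, li in enumerate(labels):
        for j in range(i + 1, len(labels)):
            if dist[i, j] < threshold:
                graph.add_edge(li, labels[j])
    return graph


def write_montage_tsv(path, positions=None) -> None:
    positions = positions or MONTAGE_POSITIONS
    with open(path, "w") as fh:
        fh.write("label\tx\ty\n")
        for label, (x, y) in positions.items():
            fh.write(f"{label}\t{x}\t{y}\n")


def write_adjacency_tsv(path, graph: nx.Graph) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{v}\n")


def read_adjacency_tsv(path) -> nx.Graph:
    graph = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        assert header.strip().split("\t") == ["source", "target"]
        for line in fh:
            u, v = line.strip().split("\t")
            graph.add_edge(u, v)
    return graph
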