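"""End-to-end orchestration: simulate -> behavior -> erp -> power -> dfa -> stats.

A run is driven by a single JSON-serializable :class:`RunConfig`; one
top-level seed fans out to every stochastic stage through named
sub-streams, so re-running an identical config reproduces byte-identical
CSV/JSON outputs. Each stage persists its results under the output
directory and later stages consume only those persisted artifacts, making
runs re-entrant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import erp as erpmod
from . import lrtc, spectral, taskgen
from . import stats as st
from .errors import ConfigurationError, TacsAttnError

logger = logging.getLogger("tacsattn")

__version__ = "0.1.0"

STAGES = ("simulate", "behavior", "erp", "power", "dfa", "stats")


class PipelineStageError(TacsAttnError):
    """A stage failed; upstream outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects_per_group: int = 9
    out_dir: str = "tacsattn_out"
    schedule: taskgen.ScheduleConfig = field(
        default_factory=taskgen.ScheduleConfig)
    rt_model: taskgen.RTModelSpec = field(
        default_factory=taskgen.RTModelSpec)
    eeg: taskgen.EEGSpec = field(default_factory=taskgen.EEGSpec)
    run_eeg: bool = True
    run_erp: bool = True
    run_power: bool = True
    run_dfa: bool = True
    run_stats: bool = True
    cluster_n_perm: int = 2000

    def validate(self) -> "RunConfig":
        if self.n_subjects_per_group < 1:
            raise ConfigurationError("n_subjects_per_group must be >= 1")
        if self.cluster_n_perm < 1:
            raise ConfigurationError("cluster_n_perm must be >= 1")
        self.schedule.validate()
        self.rt_model.validate()
        if self.eeg.sampling_rate <= 0:
            raise ConfigurationError("eeg.sampling_rate must be positive")
        if self.run_eeg:
            self.eeg.validate()
        return self

    def to_document(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["schedule"]["durations"] = {
            f"{cue}|{cti}": v
            for (cue, cti), v in self.schedule.durations.items()}
        return json.loads(json.dumps(doc))

    def stage_seed(self, *names) -> int:
        """Deterministic sub-stream seed derived from the top-level seed."""
        tag = zlib.crc32("/".join(str(n) for n in names).encode())
        ss = np.random.SeedSequence([self.seed, tag])
        return int(ss.generate_state(1)[0] % (2 ** 31))


_NESTED_BUILDERS = {
    "schedule": taskgen.ScheduleConfig,
    "rt_model": taskgen.RTModelSpec,
    "eeg": taskgen.EEGSpec,
}


def _build_dataclass(cls, doc: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in doc.items():
        if key not in fields:
            raise ConfigurationError(f"unknown config key {path}{key!r}")
        ftype = fields[key].type
        if key in ("n1", "p3") and isinstance(value, dict):
            value = _build_dataclass(taskgen.ErpTemplate, value,
                                     f"{path}{key}.")
        elif key == "effect_spec" and isinstance(value, dict):
            value = _build_dataclass(taskgen.EffectSpec, value,
                                     f"{path}{key}.")
        elif key == "durations" and isinstance(value, dict):
            value = {(k.split("|")[0], float(k.split("|")[1])): float(v)
                     for k, v in value.items()}
        elif key in ("channel_names", "cue_types", "ctis") and \
                isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def validate_config(document: dict | None = None) -> RunConfig:
    """Build a typed, range-checked RunConfig from a JSON document.

    An empty/missing document yields the full-default configuration;
    unknown keys and out-of-range values raise a ``ConfigurationError``
    naming the offending field.
    """
    document = dict(document or {})
    kwargs = {}
    for key, value in document.items():
        if key in _NESTED_BUILDERS and isinstance(value, dict):
            kwargs[key] = _build_dataclass(_NESTED_BUILDERS[key], value,
                                           f"{key}.")
        elif key in {f.name for f in dataclasses.fields(RunConfig)}:
            kwargs[key] = value
        else:
            raise ConfigurationError(f"unknown config key {key!r}")
    return RunConfig(**kwargs).validate()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(json.load(fh))


@dataclass
class RunReport:
    stage_outputs: dict
    summary: dict
    version: str
    config: dict
    checksums: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _subjects(config: RunConfig):
    n = config.n_subjects_per_group
    for gi, group in enumerate(("sham", "active")):
        for k in range(n):
            yield f"S{gi * n + k + 1:02d}", group


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    outputs = []
    frames = []
    epochs_dir = out / "epochs"
    if config.run_eeg:
        epochs_dir.mkdir(exist_ok=True)
    for subject, group in _subjects(config):
        for session in ("pre", "post"):
            sched = taskgen.generate_schedule(
                config.schedule, config.stage_seed("schedule", subject,
                                                   session))
            frames.append(taskgen.simulate_rts(
                sched, config.rt_model, subject=subject, group=group,
                session=session,
                seed=config.stage_seed("rt", subject, session)))
            if config.run_eeg:
                ses = taskgen.simulate_epochs(
                    sched, config.eeg, subject=subject, group=group,
                    session=session,
                    seed=config.stage_seed("eeg", subject, session))
                for tag, ep in [("target", ses.target)] + \
                        [(f"cti{cti}", e) for cti, e in sorted(ses.cti.items())]:
                    ep.data = ep.data.astype(np.float32)
                    p = epochs_dir / f"{subject}_{session}_{tag}.h5"
                    taskgen.save_epochs(ep, p)
                    outputs.append(p)
    behavioral = pd.concat(frames, ignore_index=True)
    p = out / "behavioral.csv"
    behavioral.to_csv(p, index=False)
    outputs.insert(0, p)
    taskgen.write_montage_tsv(out / "montage.tsv")
    graph = taskgen.build_adjacency()
    taskgen.write_adjacency_tsv(out / "adjacency.tsv", graph)
    table = taskgen.generate_blinding_table(
        n_per_group=config.n_subjects_per_group,
        seed=config.stage_seed("blinding"))
    (out / "blinding.json").write_text(json.dumps(
        {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        sort_keys=True))
    outputs += [out / "montage.tsv", out / "adjacency.tsv",
                out / "blinding.json"]
    return outputs


def _stage_behavior(config: RunConfig, out: Path) -> list[Path]:
    table = pd.read_csv(out / "behavioral.csv")
    kept, rejected = beh.filter_rts(table)
    kept, _counts = beh.categorize_trials(kept)
    means = beh.subject_condition_means(kept)
    summary = beh.summarize_rt(kept)
    outputs = []
    for name, df in [("behavior_filtered.csv", kept),
                     ("behavior_rejection.csv", rejected.reset_index()),
                     ("behavior_subject_means.csv", means),
                     ("behavior_summary.csv", summary)]:
        p = out / name
        df.to_csv(p, index=False)
        outputs.append(p)
    return outputs


def _erp_condition_sets(epochs):
    for tt in taskgen.TRIAL_TYPES:
        mask = (epochs.trials["trial_type"] == tt).to_numpy()
        if mask.any():
            yield tt, mask


def _stage_erp(config: RunConfig, out: Path) -> list[Path]:
    rows = []
    wave_rows = []
    for subject, group in _subjects(config):
        for session in ("pre", "post"):
            path = out / "epochs" / f"{subject}_{session}_target.h5"
            ep = taskgen.load_epochs(path)
            ep = erpmod.preprocess_epochs(ep)
            for tt, mask in _erp_condition_sets(ep):
                sub = taskgen.EEGEpochs(
                    data=ep.data[mask], times=ep.times,
                    sampling_rate=ep.sampling_rate, alignment=ep.alignment,
                    channel_names=ep.channel_names,
                    trials=ep.trials.loc[mask].reset_index(drop=True))
                wave = erpmod.extract_erp(sub)
                for comp, meas in erpmod.component_measures(wave).items():
                    rows.append((subject, group, session, tt, comp,
                                 meas["mean_amp_uv"], meas["fal_ms"],
                                 meas["fraction"]))
                for t, v in zip(wave.times, wave.values):
                    wave_rows.append((subject, group, session, tt,
                                      float(t), float(v)))
    measures = pd.DataFrame(rows, columns=[
        "subject", "group", "session", "trial_type", "component",
        "mean_amp_uv", "fal_ms", "fraction"])
    waves = (pd.DataFrame(wave_rows, columns=[
        "subject", "group", "session", "trial_type", "time_s",
        "amplitude_uv"])
        .groupby(["group", "session", "trial_type", "time_s"],
                 observed=True)["amplitude_uv"].mean().reset_index())
    p1, p2 = out / "erp_measures.csv", out / "erp_waveforms.csv"
    measures.to_csv(p1, index=False)
    waves.to_csv(p2, index=False)
    return [p1, p2]


def _load_cti_epochs(config: RunConfig, out: Path, subject: str,
                     session: str) -> dict:
    store = {}
    for cti in config.schedule.ctis:
        path = out / "epochs" / f"{subject}_{session}_cti{cti}.h5"
        if path.exists():
            store[cti] = taskgen.load_epochs(path)
    return store


def _stage_power(config: RunConfig, out: Path) -> list[Path]:
    frames = []
    for subject, _group in _subjects(config):
        for session in ("pre", "post"):
            cti = _load_cti_epochs(config, out, subject, session)
            frames.append(spectral.band_powers_by_condition(cti))
    df = pd.concat(frames, ignore_index=True)
    p = out / "band_power.csv"
    df.to_csv(p, index=False)
    return [p]


def _stage_dfa(config: RunConfig, out: Path) -> list[Path]:
    frames = []
    for subject, _group in _subjects(config):
        for session in ("pre", "post"):
            cti = _load_cti_epochs(config, out, subject, session)
            frames.append(lrtc.dfa_epochs(cti))
    df = pd.concat(frames, ignore_index=True)
    p = out / "dfa.csv"
    df.to_csv(p, index=False)
    return [p]


def _paired_matrices(df: pd.DataFrame, value: str, channels: list[str]):
    """subjects x channels matrices for pre and post of the active group."""
    sub = df[df["group"] == "active"]
    pre = sub[sub["session"] == "pre"].pivot(index="subject",
                                             columns="channel", values=value)
    post = sub[sub["session"] == "post"].pivot(index="subject",
                                               columns="channel",
                                               values=value)
    pre, post = pre[channels], post.loc[pre.index, channels]
    return post.to_numpy(), pre.to_numpy()


def _stage_stats(config: RunConfig, out: Path) -> list[Path]:
    outputs = []
    summary: dict = {}
    means = pd.read_csv(out / "behavior_subject_means.csv")
    anova = st.mixed_anova(means, dv="mean_rt_ms", subject="subject",
                           between="group", within=["session", "trial_type"])
    p = out / "anova_rt.csv"
    anova.to_csv(p, index=False)
    outputs.append(p)
    inter = anova.set_index("effect")
    summary["rt_group_by_time"] = {
        "F": float(inter.loc["group:session", "F"]),
        "p": float(inter.loc["group:session", "p"])}

    # planned contrasts: between-group comparison of post-pre change scores
    contrast_rows = []
    for tt in taskgen.TRIAL_TYPES:
        sub = means[means["trial_type"] == tt].pivot_table(
            index=["subject", "group"], columns="session",
            values="mean_rt_ms").reset_index()
        if not {"pre", "post"} <= set(sub.columns):
            continue
        sub["delta"] = sub["post"] - sub["pre"]
        res = st.ttest(sub.loc[sub["group"] == "active", "delta"].to_numpy(),
                       sub.loc[sub["group"] == "sham", "delta"].to_numpy(),
                       mode="independent")
        contrast_rows.append((tt, res.t, res.df, res.p, res.cohen_d))
    contrasts = pd.DataFrame(contrast_rows, columns=[
        "trial_type", "t", "df", "p", "cohen_d"])
    if len(contrasts):
        contrasts["p_holm"] = st.adjust_pvalues(contrasts["p"].to_numpy(),
                                                method="holm")
    p = out / "rt_contrasts.csv"
    contrasts.to_csv(p, index=False)
    outputs.append(p)

    if (out / "erp_measures.csv").exists():
        measures = pd.read_csv(out / "erp_measures.csv")
        erp_rows = []
        for comp in sorted(measures["component"].unique()):
            for value in ("mean_amp_uv", "fal_ms"):
                sub = measures[measures["component"] == comp]
                tab = st.mixed_anova(sub, dv=value, subject="subject",
                                     between="group",
                                     within=["session", "trial_type"])
                tab.insert(0, "measure", value)
                tab.insert(0, "component", comp)
                erp_rows.append(tab)
        p = out / "anova_erp.csv"
        pd.concat(erp_rows, ignore_index=True).to_csv(p, index=False)
        outputs.append(p)

    adjacency = taskgen.read_adjacency_tsv(out / "adjacency.tsv")
    cluster_report = {}
    if (out / "band_power.csv").exists():
        power = pd.read_csv(out / "band_power.csv")
        channels = sorted(power["channel"].unique())
        for band in sorted(power["band"].unique()):
            for cue in sorted(power["cue_type"].unique()):
                sub = power[(power["band"] == band)
                            & (power["cue_type"] == cue)]
                post, pre = _paired_matrices(sub, "power_uv2", channels)
                if post.shape[0] < 2:
                    continue
                res = st.cluster_permutation(
                    post, pre, adjacency, channels, design="paired",
                    n_perm=config.cluster_n_perm,
                    seed=config.stage_seed("cluster", band, cue))
                cluster_report[f"power_{band}_{cue}"] = [
                    {"electrodes": list(c.electrodes), "sign": c.sign,
                     "mass": c.mass, "p_perm": c.p_perm}
                    for c in res.clusters]
    if (out / "dfa.csv").exists():
        dfa_df = pd.read_csv(out / "dfa.csv")
        channels = sorted(dfa_df["channel"].unique())
        for cue in sorted(dfa_df["cue_type"].unique()):
            sub = dfa_df[dfa_df["cue_type"] == cue]
            post, pre = _paired_matrices(sub, "alpha", channels)
            if post.shape[0] >= 2:
                res = st.cluster_permutation(
                    post, pre, adjacency, channels, design="paired",
                    n_perm=config.cluster_n_perm,
                    seed=config.stage_seed("cluster", "dfa", cue))
                cluster_report[f"dfa_{cue}"] = [
                    {"electrodes": list(c.electrodes), "sign": c.sign,
                     "mass": c.mass, "p_perm": c.p_perm}
                    for c in res.clusters]
    p = out / "clusters.json"
    p.write_text(json.dumps(cluster_report, indent=2, sort_keys=True))
    outputs.append(p)

    blinding = json.loads((out / "blinding.json").read_text())
    table = taskgen.ContingencyTable2x2(**blinding)
    if table.usable_for_inference:
        chi_sq, p_mc = st.mcnemar_cc(table)
        summary["blinding"] = {"chi_sq": chi_sq, "p": p_mc}
    else:
        summary["blinding"] = {"chi_sq": None, "p": None,
                               "note": "no discordant pairs"}

    sens = {}
    for alpha in (0.05, 0.0125):
        sol = st.min_detectable_d(config.n_subjects_per_group, alpha=alpha)
        sens[f"alpha_{alpha}"] = {"d_min": sol.d_min, "power": sol.power}
    summary["sensitivity"] = sens
    p = out / "stats_summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs.append(p)
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "behavior": _stage_behavior,
    "erp": _stage_erp,
    "power": _stage_power,
    "dfa": _stage_dfa,
    "stats": _stage_stats,
}


def _enabled_stages(config: RunConfig) -> list[str]:
    stages = ["simulate", "behavior"]
    if config.run_eeg and config.run_erp:
        stages.append("erp")
    if config.run_eeg and config.run_power:
        stages.append("power")
    if config.run_eeg and config.run_dfa:
        stages.append("dfa")
    if config.run_stats:
        stages.append("stats")
    return stages


def run_pipeline(config: RunConfig, stages=None) -> RunReport:
    """Execute the enabled stages in order and persist all artifacts.

    Raises :class:`PipelineStageError` naming the failing stage; artifacts
    of earlier stages remain on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(config.to_document(), indent=2, sort_keys=True))
    stage_outputs = {}
    checksums = {}
    for stage in stages or _enabled_stages(config):
        if stage not in _STAGE_FUNCS:
            raise ConfigurationError(f"unknown stage {stage!r}")
        logger.info("running stage %s", stage)
        try:
            paths = _STAGE_FUNCS[stage](config, out)
        except TacsAttnError:
            raise
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            raise PipelineStageError(stage, exc) from exc
        stage_outputs[stage] = [str(p) for p in paths]
        for pth in paths:
            checksums[str(pth)] = _sha256(Path(pth))
        logger.info("stage %s wrote %d artifacts", stage, len(paths))
    summary = {}
    summary_path = out / "stats_summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
    report = RunReport(stage_outputs=stage_outputs, summary=summary,
                       version=__version__, config=config.to_document(),
                       checksums=checksums)
    (out / "report.json").write_text(report.to_json())
    return report
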