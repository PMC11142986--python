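"""End-to-end orchestration: simulate -> sync -> events -> clean -> power -> stats.

The entry point :func:`run` produces, per subject, tidy ERD/ERS% tables,
gaze metrics and pupil summaries, then a statistics layer across subjects
(repeated-measures ANOVA at the channels of interest, Holm post hocs,
pairwise sign-flip permutation tests over channels with BH correction, and
repeated-measures correlations between the physiological measures).  All
randomness flows from the seeds in the config, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clean, gaze, spectral, stats, sync_io, synth
from .types import EventTable

__all__ = ["RunConfig", "PipelineError", "run", "process_subject", "load_config"]

BANDS = {"theta": (4.0, 6.0), "alpha": (8.0, 13.0)}
CHANNELS_OF_INTEREST = {"theta": "Fz", "alpha": "Pz"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and subject."""


@dataclass
class RunConfig:
    """Run-level configuration; module parameters carry the method defaults
    (2 s epochs, ±100 µV, 500 ms / 0.125 Hz spectra, theta 4-6 / alpha 8-13,
    lambda = 6, alpha level 0.05)."""

    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    analysis: str = "both"  # stimulus | fixation | both
    bands: dict = field(default_factory=lambda: dict(BANDS))
    channels_of_interest: dict = field(
        default_factory=lambda: dict(CHANNELS_OF_INTEREST)
    )
    alpha_level: float = 0.05
    length_s: float = 2.0
    reject_uv: float = 100.0
    apply_filter: bool = True
    apply_ica: bool = True
    ica_corr_threshold: float = 0.7
    lambda_thresh: float = 6.0
    min_saccade_ms: float = 12.0
    smooth_window: int = 5
    min_fix_ms: float = 50.0
    blink_pad_ms: float = 50.0
    min_anchor_gap_s: float | None = None
    n_perm: int = 2000
    stats_seed: int = 7

    def __post_init__(self) -> None:
        if self.analysis not in ("stimulus", "fixation", "both"):
            raise ValueError(f"unknown analysis {self.analysis!r}")
        for band, ch in self.channels_of_interest.items():
            if ch not in self.sim.channels:
                raise ValueError(f"channel of interest {ch!r} not in montage")
        if self.analysis in ("fixation", "both") and self.sim.task != "reading":
            raise ValueError("fixation-related analysis requires the reading task")


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file of overrides."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_kwargs = raw.pop("sim", {})
    for key in ("conditions",):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    cfg = RunConfig(sim=synth.SimConfig(**sim_kwargs), **raw)
    return cfg


def _condition_intervals_from_events(
    events: EventTable, n_samples: int
) -> list[tuple[int, int, str]]:
    """Reconstruct blocked condition intervals from trigger attributes."""
    seen: list[tuple[int, str]] = []
    for s, _lab, at in events:
        cond = at.get("condition")
        if cond is None:
            continue
        if not seen or seen[-1][1] != cond:
            seen.append((s, cond))
    intervals = []
    for i, (start, cond) in enumerate(seen):
        end = seen[i + 1][0] if i + 1 < len(seen) else n_samples
        intervals.append((start, end, cond))
    return intervals


def process_subject(config: RunConfig, subject_seed: int, subject_id: str) -> dict:
    """Simulate and analyze one subject; returns tidy per-subject results."""
    sim_cfg = dataclasses.replace(config.sim, seed=subject_seed)
    stage = "simulate"
    try:
        eeg, et, eeg_ev, et_ev, truth = synth.simulate_session(sim_cfg)

        stage = "sync"
        # trigger jitter plus up to half an ET sample of rounding error
        jitter_allow = (
            sim_cfg.trigger_jitter_max + sim_cfg.eeg_rate / sim_cfg.et_rate / 2 + 1.0
        )
        mapping = sync_io.estimate_offset(eeg_ev, et_ev, max_jitter=jitter_allow)
        session = sync_io.merge(eeg, et, mapping, eeg_events=eeg_ev, et_events=et_ev)
        cond_intervals = _condition_intervals_from_events(eeg_ev, eeg.n_samples)
        conditions = sim_cfg.conditions

        stage = "events"
        pupil_clean_et, blinks = gaze.interpolate_blinks(
            et.channel("pupil"), et.rate, config.blink_pad_ms
        )
        saccades = gaze.detect_saccades(
            et.channel("gaze_x"),
            et.channel("gaze_y"),
            et.rate,
            config.lambda_thresh,
            config.min_saccade_ms,
            config.smooth_window,
        )
        fixations = gaze.derive_fixations(
            saccades,
            blinks,
            et.rate,
            (0, et.n_samples),
            config.min_fix_ms,
            gaze_x=et.channel("gaze_x"),
            gaze_y=et.channel("gaze_y"),
        )
        aois = [
            gaze.AOI("text", sim_cfg.aoi_text),
            gaze.AOI("picture", sim_cfg.aoi_picture),
        ]
        fixations = gaze.assign_aoi(fixations, aois)
        metrics = gaze.gaze_metrics(fixations)

        stage = "clean"
        rec = clean.fir_filter(eeg) if config.apply_filter else eeg
        ica_removed = None
        if config.apply_ica and "EOG" in rec.channel_labels:
            rec, eog_report = clean.remove_eog(
                rec, ["EOG"], config.ica_corr_threshold, seed=subject_seed
            )
            ica_removed = eog_report.removed if eog_report.converged else []
        rec = clean.rereference_average(rec, exclude_labels=["EOG"])

        # condition of each fixation (EEG timeline), for fixation-locked work
        fix_eeg = []
        for f in fixations:
            on = int(mapping.apply(f.onset))
            off = int(mapping.apply(f.offset))
            cond = next(
                (c for s, e, c in cond_intervals if s <= on < e), None
            )
            fix_eeg.append((on, off, cond, f.aoi))

        # blink-interpolated pupil on the EEG timeline
        pupil_eeg = session.eeg.channel("pupil")
        pupil_eeg_clean, _ = gaze.interpolate_blinks(
            pupil_eeg, session.eeg.rate, config.blink_pad_ms
        )

        analyses = (
            ["stimulus", "fixation"] if config.analysis == "both" else [config.analysis]
        )
        erd_rows = []
        pupil_rows = []
        provenance = {
            "subject": subject_id,
            "seed": subject_seed,
            "n_saccades": len(saccades),
            "n_fixations": len(fixations),
            "n_blinks": len(blinks),
            "ica_removed": ica_removed,
            "epochs": {},
        }
        excluded = []
        for analysis in analyses:
            stage = f"epoch/{analysis}"
            if analysis == "stimulus":
                anchors = eeg_ev
                if sim_cfg.task == "nback":
                    keep_rows = [
                        i
                        for i, at in enumerate(anchors.attributes)
                        if at.get("correct", True)
                    ]
                    anchors = EventTable(
                        anchors.sample[keep_rows],
                        [anchors.label[i] for i in keep_rows],
                        [anchors.attributes[i] for i in keep_rows],
                    )
                epochs = clean.extract_epochs(
                    rec,
                    anchors,
                    "stimulus",
                    cond_intervals,
                    config.length_s,
                    tile=sim_cfg.task == "reading",
                )
            else:
                pic_onsets = [
                    on for on, _off, cond, aoi in fix_eeg
                    if aoi == "picture" and cond is not None
                ]
                anchors = EventTable(
                    np.asarray(sorted(pic_onsets), dtype=np.int64),
                    ["fix"] * len(pic_onsets),
                )
                epochs = clean.extract_epochs(
                    rec,
                    anchors,
                    "fixation",
                    cond_intervals,
                    config.length_s,
                    min_anchor_gap_s=config.min_anchor_gap_s,
                )
            epochs = clean.reject_artifacts(epochs, config.reject_uv)
            kept = epochs.kept()
            provenance["epochs"][analysis] = {
                "total": int(epochs.n_epochs),
                "kept": int(kept.n_epochs),
                "per_condition": {
                    c: int(sum(1 for x in kept.condition if x == c))
                    for c in conditions
                },
            }

            stage = f"power/{analysis}"
            for band_name, band in config.bands.items():
                bp, labels = spectral.epoch_band_power(epochs, band)
                try:
                    values, baseline, _ = spectral.erd_ers(bp, labels, conditions)
                except spectral.ConditionEmptyError:
                    excluded.append((analysis, band_name))
                    continue
                for ci, cond in enumerate(conditions):
                    for chi, ch in enumerate(rec.channel_labels):
                        erd_rows.append(
                            {
                                "subject": subject_id,
                                "task": sim_cfg.task,
                                "analysis": analysis,
                                "band": band_name,
                                "condition": cond,
                                "channel": ch,
                                "value_percent": values[ci, chi],
                                "baseline_power": baseline[chi],
                                "n_epochs": provenance["epochs"][analysis][
                                    "per_condition"
                                ][cond],
                            }
                        )

            stage = f"pupil/{analysis}"
            try:
                if analysis == "stimulus":
                    summary = spectral.pupil_summary_stimulus(
                        pupil_eeg_clean, epochs, conditions
                    )
                else:
                    intervals = [
                        (on, off, cond)
                        for on, off, cond, aoi in fix_eeg
                        if aoi == "picture" and cond is not None
                    ]
                    summary = spectral.pupil_summary_fixation(
                        pupil_eeg_clean, intervals, conditions
                    )
            except ValueError:
                summary = None
            if summary is not None:
                for cond, val in summary.items():
                    pupil_rows.append(
                        {
                            "subject": subject_id,
                            "task": sim_cfg.task,
                            "analysis": analysis,
                            "condition": cond,
                            "pupil_mean": val,
                        }
                    )

        gaze_rows = [
            {
                "subject": subject_id,
                "n_fixations_text": metrics.n_fixations_per_aoi.get("text", 0),
                "n_fixations_picture": metrics.n_fixations_per_aoi.get("picture", 0),
                "mean_fixation_duration_ms": metrics.mean_fixation_duration_ms,
                "n_transitions": metrics.n_transitions,
            }
        ]
        return {
            "erd": erd_rows,
            "pupil": pupil_rows,
            "gaze": gaze_rows,
            "provenance": provenance,
            "excluded": excluded,
            "truth": truth,
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - abort with stage + subject
        raise PipelineError(
            f"stage {stage!r} failed for subject {subject_id}: {exc}"
        ) from exc


def _run_stats(config: RunConfig, erd: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA at the channels of interest; pairwise topo tests over channels."""
    anova_rows = []
    topo_rows = []
    conditions = list(config.sim.conditions)
    scalp = [ch for ch in config.sim.channels if ch != "EOG"]
    for (analysis, band), grp in erd.groupby(["analysis", "band"], sort=True):
        ch_int = config.channels_of_interest.get(band)
        if ch_int is None:
            continue
        sub = grp[grp.channel == ch_int]
        # only subjects with all conditions (exclusion rule)
        pivot = sub.pivot_table(
            index="subject", columns="condition", values="value_percent"
        ).dropna()
        if len(pivot) >= 3 and len(pivot.columns) >= 2:
            table = pivot.reset_index().melt(
                id_vars="subject", var_name="condition", value_name="value"
            )
            for res in stats.rm_anova(table, within=["condition"]):
                anova_rows.append(
                    {
                        "analysis": analysis,
                        "band": band,
                        "channel": ch_int,
                        "effect": res.effect,
                        "F": res.F,
                        "df1": res.df[0],
                        "df2": res.df[1],
                        "p": res.p,
                        "gg_epsilon": res.gg_epsilon,
                        "p_gg": res.p_gg,
                        "eta_p2": res.eta_p2,
                        "n_subjects": len(pivot),
                    }
                )
        # pairwise channel-wise permutation tests
        wide = grp.pivot_table(
            index="subject", columns=["condition", "channel"], values="value_percent"
        ).dropna()
        for i in range(len(conditions)):
            for j in range(i + 1, len(conditions)):
                ca, cb = conditions[i], conditions[j]
                try:
                    A = wide[ca][scalp].to_numpy()
                    B = wide[cb][scalp].to_numpy()
                except KeyError:
                    continue
                if A.shape[0] < 3:
                    continue
                res = stats.permutation_topo_test(
                    A, B, config.n_perm, config.stats_seed, config.alpha_level
                )
                for chi, ch in enumerate(scalp):
                    topo_rows.append(
                        {
                            "analysis": analysis,
                            "band": band,
                            "pair": f"{ca}-{cb}",
                            "channel": ch,
                            "t": res.t[chi],
                            "p": res.p[chi],
                            "q": res.q[chi],
                            "sig": bool(res.significant[chi]),
                        }
                    )
    return pd.DataFrame(anova_rows), pd.DataFrame(topo_rows)


def _rmcorr_table(config: RunConfig, erd: pd.DataFrame, pupil: pd.DataFrame) -> pd.DataFrame:
    """rmcorr between pupil, theta and alpha ERD (stimulus-locked)."""
    measures = {}
    stim = erd[erd.analysis == "stimulus"]
    for band, ch in config.channels_of_interest.items():
        sub = stim[(stim.band == band) & (stim.channel == ch)]
        measures[band] = sub.set_index(["subject", "condition"])["value_percent"]
    if len(pupil):
        pstim = pupil[pupil.analysis == "stimulus"]
        measures["pupil"] = pstim.set_index(["subject", "condition"])["pupil_mean"]
    rows = []
    names = sorted(measures)
    raw_ps = []
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            joined = pd.concat(
                [measures[a].rename("x"), measures[b].rename("y")], axis=1
            ).dropna()
            if joined.empty:
                continue
            subj = joined.index.get_level_values(0).to_numpy()
            try:
                res = stats.rmcorr(subj, joined.x.to_numpy(), joined.y.to_numpy())
            except ValueError:
                continue
            pairs.append((a, b, res))
            raw_ps.append(res.p)
    m = len(raw_ps)
    for (a, b, res), p in zip(pairs, raw_ps):
        rows.append(
            {
                "measure_a": a,
                "measure_b": b,
                "r": res.r,
                "df": res.df,
                "p": p,
                "p_bonferroni": min(p * m, 1.0),
                "ci_lo": res.ci95[0],
                "ci_hi": res.ci95[1],
            }
        )
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run(config: RunConfig, out_dir) -> dict:
    """Run the full study pipeline and write result TSVs plus provenance.

    Returns the in-memory results bundle (DataFrames keyed ``erd``,
    ``gaze``, ``pupil``, ``anova``, ``topo``, ``rmcorr``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    erd_rows, gaze_rows, pupil_rows, provenance = [], [], [], []
    for s in range(config.sim.n_subjects):
        subject_id = f"S{s + 1:02d}"
        result = process_subject(config, config.sim.seed + s, subject_id)
        erd_rows.extend(result["erd"])
        gaze_rows.extend(result["gaze"])
        pupil_rows.extend(result["pupil"])
        provenance.append(result["provenance"])

    erd = pd.DataFrame(erd_rows)
    gaze_df = pd.DataFrame(gaze_rows)
    pupil = pd.DataFrame(pupil_rows)
    anova, topo = _run_stats(config, erd) if len(erd) else (pd.DataFrame(), pd.DataFrame())
    rmc = _rmcorr_table(config, erd, pupil) if len(erd) else pd.DataFrame()

    _write_tsv(erd, out_dir / "erd.tsv")
    _write_tsv(gaze_df, out_dir / "gaze_metrics.tsv")
    _write_tsv(pupil, out_dir / "pupil.tsv")
    _write_tsv(anova, out_dir / "anova.tsv")
    _write_tsv(topo, out_dir / "topo.tsv")
    _write_tsv(rmc, out_dir / "rmcorr.tsv")
    log = {
        "seed": config.sim.seed,
        "n_subjects": config.sim.n_subjects,
        "task": config.sim.task,
        "analysis": config.analysis,
        "bands": {k: list(v) for k, v in config.bands.items()},
        "alpha_level": config.alpha_level,
        "reject_uv": config.reject_uv,
        "n_perm": config.n_perm,
        "stats_seed": config.stats_seed,
        "subjects": provenance,
    }
    (out_dir / "provenance.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return {
        "erd": erd,
        "gaze": gaze_df,
        "pupil": pupil,
        "anova": anova,
        "topo": topo,
        "rmcorr": rmc,
    }
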