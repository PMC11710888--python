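"""End-to-end orchestration: simulate -> QC -> preprocess -> epoch -> stats.

The subject-level chain is: CV-based channel QC on raw intensities,
conversion to optical density against the recording-mean reference,
zero-phase band-pass (0.01-0.2 Hz), modified Beer-Lambert inversion, CBSI,
block segmentation with 10-s pre-onset baseline, and early/late phase
means.  Group level: channel-wise one-sided activation tests with BH-FDR
per (condition, phase), repeated-measures condition comparisons with
Bonferroni-corrected pairs, and a channel x condition summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .epochs import EpochConfig, PHASES, phase_summary, segment_blocks
from .montage import Montage, Schedule, TASK_CONDITIONS, default_montage, read_events, write_events, write_montage
from .preprocess import bandpass_od, cbsi, default_mbll_params, intensity_to_od, mbll
from .qc import QCConfig, QCReport, run_qc
from .recording import RawRecording
from .simulate import NoiseModel, SimTruth, simulate_cohort
from .stats import StatsConfig, activation_test, condition_comparison, group_summary

logger = logging.getLogger("nirsblock")

__all__ = [
    "PipelineConfig",
    "process_recording",
    "analyze_cohort",
    "run_simulate",
    "run_analyze",
    "run_recover",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the analysis chain, serializable to YAML."""

    sampling_rate_hz: float = 10.0
    filter_band_hz: tuple[float, float] = (0.01, 0.2)
    filter_order: int = 4
    dpf: tuple[float, float] = (6.0, 6.0)
    apply_cbsi: bool = True
    cbsi_zero_variance: str = "error"
    qc: QCConfig = field(default_factory=QCConfig)
    epoch: EpochConfig = field(default_factory=EpochConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    n_subjects: int = 12
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter_band_hz"] = list(self.filter_band_hz)
        d["dpf"] = list(self.dpf)
        d["epoch"]["early_window_s"] = list(self.epoch.early_window_s)
        d["epoch"]["late_window_s"] = list(self.epoch.late_window_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "qc" in d:
            d["qc"] = QCConfig(**d["qc"])
        if "epoch" in d:
            e = dict(d["epoch"])
            for k in ("early_window_s", "late_window_s"):
                if k in e:
                    e[k] = tuple(e[k])
            d["epoch"] = EpochConfig(**e)
        if "stats" in d:
            d["stats"] = StatsConfig(**d["stats"])
        for k in ("filter_band_hz", "dpf"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def process_recording(
    raw: RawRecording,
    subject: str,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, QCReport]:
    """Run the full subject-level chain; returns (phase table, QC report)."""
    qc = run_qc(raw, config.qc)
    od = intensity_to_od(raw)
    od = bandpass_od(od, *config.filter_band_hz, order=config.filter_order)
    hb = mbll(od, default_mbll_params(raw.montage, dpf=config.dpf))
    if config.apply_cbsi:
        hb = cbsi(hb, zero_variance=config.cbsi_zero_variance)
    epochs = segment_blocks(hb, raw.schedule, config.epoch, qc=qc)
    return phase_summary(epochs, subject, config.epoch), qc


def _qc_table(qc_by_subject: dict[str, QCReport]) -> pd.DataFrame:
    rows = []
    for subject, qc in qc_by_subject.items():
        for c, cid in enumerate(qc.channel_ids):
            for w, wl in enumerate(qc.wavelengths_nm):
                rows.append(
                    {
                        "subject": subject,
                        "channel_id": cid,
                        "wavelength_nm": wl,
                        "cv_chan_pct": float(qc.cv_chan[c, w]),
                        "cv_trial_max_pct": float(qc.cv_trial[c, :, w].max()),
                        "rejected": cid in qc.rejected,
                    }
                )
    return pd.DataFrame(rows)


def analyze_cohort(
    recordings: list[tuple[str, RawRecording]],
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Subject pipelines plus group inference for a cohort.

    Returns a dict with the pooled phase table, per-subject QC, the
    activation tables for every (condition, phase), the omnibus and
    pairwise condition comparisons per phase, and the group summary table.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    summaries, qc_by_subject = [], {}
    for subject, raw in recordings:
        try:
            summary, qc = process_recording(raw, subject, config)
        except ValueError as exc:
            raise ValueError(f"subject {subject}: {exc}") from exc
        logger.info("subject %s: %d channels rejected", subject, len(qc.rejected))
        summaries.append(summary)
        qc_by_subject[subject] = qc
    summary = pd.concat(summaries, ignore_index=True)

    conditions = sorted(summary["condition"].unique())
    activation = pd.concat(
        [
            activation_test(summary, cond, phase, config.stats)
            for cond in conditions
            for phase in PHASES
        ],
        ignore_index=True,
    )
    omnibus, pairwise = [], []
    if len(conditions) > 1:
        for phase in PHASES:
            omni, pw = condition_comparison(summary, phase, config.stats)
            omnibus.append(omni)
            pairwise.append(pw)
        omnibus = pd.concat(omnibus, ignore_index=True)
        pairwise = pd.concat(pairwise, ignore_index=True)
    else:
        omnibus = pd.DataFrame()
        pairwise = pd.DataFrame()

    early_act = activation[activation["phase"] == "early"]
    group = group_summary(summary, early_act, phase="early")
    return {
        "summary": summary,
        "qc": qc_by_subject,
        "qc_table": _qc_table(qc_by_subject),
        "activation": activation,
        "omnibus": omnibus,
        "pairwise": pairwise,
        "group": group,
    }


# ---------------------------------------------------------------------------
# file-level entry points (the CLI is a thin wrapper over these)
# ---------------------------------------------------------------------------

def run_simulate(
    out_dir,
    config: PipelineConfig = PipelineConfig(),
    truth: SimTruth | None = None,
    noise: NoiseModel | None = None,
) -> dict[str, list[Path]]:
    """Simulate a cohort and write raw/events/truth/montage files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    montage = default_montage(config.sampling_rate_hz)
    truth = truth if truth is not None else SimTruth(seed=config.seed)
    noise = noise if noise is not None else NoiseModel()
    cohort = simulate_cohort(config.n_subjects, truth, noise, montage, seed=config.seed)

    paths: dict[str, list[Path]] = {"raw": [], "events": []}
    for i, (raw, _) in enumerate(cohort, start=1):
        raw_path = out_dir / f"sub-{i:02d}_raw.tsv"
        ev_path = out_dir / f"sub-{i:02d}_events.tsv"
        nio.write_raw(raw, raw_path)
        write_events(raw.schedule, ev_path)
        paths["raw"].append(raw_path)
        paths["events"].append(ev_path)
    truth_path = out_dir / "truth.json"
    nio.write_truth(truth, truth_path)
    montage_path = out_dir / "montage.yaml"
    write_montage(montage, montage_path)
    config.save(out_dir / "config.yaml")
    paths["truth"] = [truth_path]
    paths["montage"] = [montage_path]
    return paths


def run_analyze(
    raw_paths,
    events_paths,
    montage: Montage,
    out_dir,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Analyze a cohort of raw/events file pairs and write result tables."""
    raw_paths = sorted(Path(p) for p in raw_paths)
    events_paths = sorted(Path(p) for p in events_paths)
    if len(raw_paths) != len(events_paths) or not raw_paths:
        raise ValueError("need matching, nonempty raw and events file lists")
    recordings = []
    for rp, ep in zip(raw_paths, events_paths):
        schedule = read_events(ep)
        raw = nio.read_raw(rp, montage, schedule)
        recordings.append((rp.stem.replace("_raw", ""), raw))
    results = analyze_cohort(recordings, config)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nio.write_results(
        out_dir,
        montage,
        results["group"],
        results["activation"],
        pd.concat([results["omnibus"], results["pairwise"]], ignore_index=True)
        if len(results["pairwise"])
        else None,
        results["qc_table"],
    )
    config.save(out_dir / "config.yaml")
    results["summary"].to_csv(out_dir / "phase_summary.tsv", sep="\t", index=False)
    return results


def run_recover(truth: SimTruth, activation: pd.DataFrame, phase: str = "early") -> dict:
    """Confusion of significant vs truly-active channels per condition.

    Returns per-condition sensitivity and false-discovery proportion plus
    pooled counts across conditions.
    """
    report: dict = {"phase": phase, "conditions": {}}
    tp = fp = fn = tn = 0
    for cond in TASK_CONDITIONS:
        act = activation[(activation["condition"] == cond) & (activation["phase"] == phase)]
        if act.empty:
            continue
        truly = truth.active_map.get(cond, frozenset())
        sig = set(act.loc[act["significant"], "channel_id"].astype(int))
        all_ch = set(act["channel_id"].astype(int))
        ctp = len(sig & truly)
        cfp = len(sig - truly)
        cfn = len((truly & all_ch) - sig)
        ctn = len(all_ch - truly - sig)
        tp, fp, fn, tn = tp + ctp, fp + cfp, fn + cfn, tn + ctn
        report["conditions"][cond] = {
            "true_positives": ctp,
            "false_positives": cfp,
            "false_negatives": cfn,
            "true_negatives": ctn,
            "sensitivity": ctp / (ctp + cfn) if (ctp + cfn) else None,
            "fdp": cfp / (ctp + cfp) if (ctp + cfp) else 0.0,
        }
    report["pooled"] = {
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": fn,
        "true_negatives": tn,
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "fdp": fp / (tp + fp) if (tp + fp) else 0.0,
    }
    return report
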