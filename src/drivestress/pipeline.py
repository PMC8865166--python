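"""Pipeline orchestration: simulate -> preprocess -> epoch -> analyze -> report.

Each stage reads and writes plain tab-delimited tables under the output
directory, so any stage can be rerun in isolation on saved intermediates and
produce the identical result. A run is fully determined by (config, seed).

Output layout::

    out/
      sessions/            per-participant raw bundles + cohort_manifest.tsv
      derived/             beat trains per trip, inclusion verdicts
      tables/              epochs, AUC, ANOVA, contrasts, post hocs, paired AUC
      figures/             mean-change curves with SE bands (optional)
      run_report.json      counts, exclusions, config echo
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .epochs import (
    EpochMatrix,
    ParticipantSeries,
    build_epoch_matrices,
    matrix_aucs,
    median_split,
)
from .preprocess import BeatSeries, EcgRecord, instantaneous_hr, process_ecg
from .simulate import (
    CONDITIONS,
    POSTWINDOW_END,
    SessionConfig,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .stats import bonferroni_posthoc, paired_auc_test, polynomial_contrast, rm_anova_2x_k

logger = logging.getLogger(__name__)

#: cue-bearing analysis cells whose postcue HR pattern is trend-tested
CONTRAST_CELLS = (("P", "experimental"), ("PF", "experimental"), ("PF", "control"))


@dataclass
class PipelineConfig:
    out_dir: str = "runs/run0"
    seed: int = 0
    n_participants: int = 34
    exclusions: dict[str, int] = field(
        default_factory=lambda: {"motion_sickness": 5, "bad_ecg": 2}
    )
    stress_split: dict[str, int] | None = None
    filter_low: float = 2.0
    filter_high: float = 40.0
    grid_step: float = 0.5
    window_ends: dict[str, float] = field(default_factory=lambda: dict(POSTWINDOW_END))
    median_split_threshold: float = 2.5
    alpha: float = 0.05
    channels: tuple[str, ...] = ("hr", "speed")
    plots: bool = True
    simulator: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        bad = set(self.channels) - {"hr", "speed"}
        if bad:
            raise ValueError(f"unknown channels: {sorted(bad)}")
        missing = set(CONDITIONS) - set(self.window_ends)
        if missing:
            raise ValueError(f"window_ends missing conditions: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "channels" in raw:
            raw["channels"] = tuple(raw["channels"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        return d

    def session_config(self) -> SessionConfig:
        return SessionConfig(**self.simulator)

    @property
    def out(self) -> Path:
        return Path(self.out_dir)


@dataclass
class RunReport:
    seed: int
    version: str
    enrolled: int
    excluded: dict[str, int]
    included: int
    stage_counts: dict[str, int]
    tables: list[str]
    config: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> Path:
    cohort = generate_cohort(
        config.n_participants,
        base_config=config.session_config(),
        exclusion_spec=config.exclusions,
        stress_split=config.stress_split,
        seed=config.seed,
    )
    path = write_cohort(config.out / "sessions", cohort)
    logger.info("simulate: wrote %d sessions to %s", config.n_participants, path)
    return path


def stage_preprocess(config: PipelineConfig) -> pd.DataFrame:
    """Detect and correct beats per trip; decide inclusion per participant.

    Participants flagged motion_sickness in the cohort manifest (did not
    complete the protocol) are excluded up front; bad-ECG exclusions are
    decided by the artifact-correction verdict, not the manifest.
    """
    sessions_dir = config.out / "sessions"
    derived = config.out / "derived"
    derived.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(sessions_dir / "cohort_manifest.tsv", sep="\t")

    rows = []
    cohort = read_cohort(sessions_dir)
    for session, truth in zip(cohort.sessions, cohort.manifests):
        pid = session.participant_id
        flag = manifest.loc[manifest["pid"] == pid, "exclusion_flag"].iloc[0]
        if flag == "motion_sickness":
            rows.append({"pid": pid, "included": False, "reason": "motion_sickness"})
            continue
        has_ecg = any(d.ecg is not None for d in session.trips.values())
        if flag == "bad_ecg" and not has_ecg:
            # beat-level sessions carry no ECG for the corrector to judge;
            # defer to the manifest's quality verdict
            rows.append({"pid": pid, "included": False, "reason": "bad_ecg"})
            continue
        verdicts = []
        for trip, data in session.trips.items():
            if data.ecg is not None:
                fs = 1.0 / float(np.median(np.diff(data.ecg_time)))
                beats = process_ecg(
                    EcgRecord(data.ecg, fs, t0=float(data.ecg_time[0])),
                    config.filter_low,
                    config.filter_high,
                )
            elif truth is not None:
                beats = BeatSeries(truth.true_beats[trip])
            else:
                raise FileNotFoundError(f"{pid}: no ECG and no ground-truth beats")
            verdicts.append(beats.quality)
            t_hr, hr = instantaneous_hr(beats)
            pd.DataFrame(
                {
                    "r_time_s": beats.r_times,
                    "rri_s": np.concatenate([[np.nan], beats.rri]),
                    "hr_bpm": np.concatenate([[np.nan], hr]),
                    "flag": beats.flags,
                }
            ).to_csv(derived / f"{pid}_trip{trip}_beats.tsv", sep="\t", index=False)
        if "bad_ecg" in verdicts:
            rows.append({"pid": pid, "included": False, "reason": "bad_ecg"})
        else:
            rows.append({"pid": pid, "included": True, "reason": ""})
    frame = pd.DataFrame(rows)
    frame.to_csv(derived / "included.tsv", sep="\t", index=False)
    logger.info(
        "preprocess: %d/%d participants included", int(frame["included"].sum()), len(frame)
    )
    return frame


def stage_epoch(config: PipelineConfig) -> dict[tuple, EpochMatrix]:
    """Build epoch matrices for included participants; write epochs/auc/ratings."""
    sessions_dir = config.out / "sessions"
    derived = config.out / "derived"
    tables = config.out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    included = pd.read_csv(derived / "included.tsv", sep="\t")
    pids = included.loc[included["included"] == True, "pid"].tolist()  # noqa: E712

    participants = []
    ratings_rows = []
    cohort = read_cohort(sessions_dir)
    by_pid = {s.participant_id: s for s in cohort.sessions}
    for pid in pids:
        session = by_pid[pid]
        hr_knots = {}
        for trip in (1, 2):
            beats = pd.read_csv(derived / f"{pid}_trip{trip}_beats.tsv", sep="\t")
            t = beats["r_time_s"].to_numpy()
            hr = beats["hr_bpm"].to_numpy()
            hr_knots[trip] = (t[1:], hr[1:])
        speed = {
            trip: (data.speed_time, data.speed) for trip, data in session.trips.items()
        }
        participants.append(
            ParticipantSeries(pid, hr_knots, speed, session.markers, session.ratings)
        )
        for cond, rating in session.ratings.items():
            ratings_rows.append({"pid": pid, "condition": cond, "rating": rating})

    matrices = build_epoch_matrices(
        participants, channels=config.channels,
        window_ends=config.window_ends, step=config.grid_step,
    )

    epoch_rows = []
    auc_frames = []
    for (cond, ctype, window, channel), m in matrices.items():
        for i, pid in enumerate(m.participant_ids):
            for rel, val in zip(m.rel_times, m.data[i]):
                epoch_rows.append(
                    {
                        "pid": pid, "condition": cond, "type": ctype,
                        "window": window, "channel": channel,
                        "rel_time_s": rel, "change": val,
                    }
                )
        auc_frames.append(matrix_aucs(m))
    pd.DataFrame(epoch_rows).to_csv(tables / "epochs.tsv", sep="\t", index=False)
    pd.concat(auc_frames, ignore_index=True).to_csv(
        tables / "auc.tsv", sep="\t", index=False
    )
    pd.DataFrame(ratings_rows).to_csv(tables / "ratings.tsv", sep="\t", index=False)
    logger.info("epoch: %d matrices over %d participants", len(matrices), len(pids))
    return matrices


def load_epoch_matrices(config: PipelineConfig) -> dict[tuple, EpochMatrix]:
    """Rebuild EpochMatrix objects from the saved epochs.tsv."""
    frame = pd.read_csv(config.out / "tables" / "epochs.tsv", sep="\t")
    out: dict[tuple, EpochMatrix] = {}
    for key, g in frame.groupby(["condition", "type", "window", "channel"], sort=False):
        cond, ctype, window, channel = key
        pids = list(dict.fromkeys(g["pid"]))
        rel = np.sort(g["rel_time_s"].unique())
        pivot = g.pivot_table(index="pid", columns="rel_time_s", values="change", sort=False)
        pivot = pivot.loc[pids, rel]
        out[(cond, ctype, window, channel)] = EpochMatrix(
            cond, ctype, window, channel, pids, rel, pivot.to_numpy()
        )
    return out


def stage_analyze(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the inferential battery on the saved epoch and AUC tables."""
    tables = config.out / "tables"
    matrices = load_epoch_matrices(config)
    aucs = pd.read_csv(tables / "auc.tsv", sep="\t")
    ratings = pd.read_csv(tables / "ratings.tsv", sep="\t")
    groups = median_split(ratings, config.median_split_threshold)

    anova_rows, posthoc_rows, contrast_rows, paired_rows = [], [], [], []
    for cond in CONDITIONS:
        for window in ("postcue", "postevent"):
            for channel in config.channels:
                key_exp = (cond, "experimental", window, channel)
                key_ctrl = (cond, "control", window, channel)
                if key_exp not in matrices or key_ctrl not in matrices:
                    continue
                exp, ctrl = matrices[key_exp], matrices[key_ctrl]
                res = rm_anova_2x_k(exp.post_data, ctrl.post_data)
                for eff in res.effects.values():
                    anova_rows.append(
                        {
                            "condition": cond, "window": window, "channel": channel,
                            "effect": eff.name, "F": eff.F,
                            "df1": eff.df, "df2": eff.df_error,
                            "p_uncorrected": eff.p_uncorrected,
                            "mauchly_W": eff.mauchly_W, "mauchly_p": eff.mauchly_p,
                            "gg_epsilon": eff.gg_epsilon,
                            "df1_gg": None if eff.df_gg is None else eff.df_gg[0],
                            "df2_gg": None if eff.df_gg is None else eff.df_gg[1],
                            "p_gg": eff.p_gg, "p_report": eff.p_report,
                            "partial_eta_sq": eff.partial_eta_sq,
                            "n": res.n_subjects,
                        }
                    )
                rel_post = exp.rel_times[exp.rel_times >= 0.0]
                for row in bonferroni_posthoc(exp.post_data, ctrl.post_data, config.alpha):
                    posthoc_rows.append(
                        {
                            "condition": cond, "window": window, "channel": channel,
                            "rel_time_s": rel_post[row["time_index"]],
                            "t": row["t"], "p": row["p"], "p_adj": row["p_adj"],
                            "significant": row["significant"],
                        }
                    )

    # trend contrasts: cue-bearing cells, postcue window, cardiac channel only
    if "hr" in config.channels:
        for cond, ctype in CONTRAST_CELLS:
            key = (cond, ctype, "postcue", "hr")
            if key not in matrices:
                continue
            for name, c in polynomial_contrast(matrices[key].post_data).items():
                contrast_rows.append(
                    {
                        "condition": cond, "type": ctype, "trend": name,
                        "t": c.t, "df": c.df, "p": c.p,
                    }
                )

    # AUC comparisons within perceived-stress groups (U and P carry ratings)
    for cond in ("U", "P"):
        cond_groups = groups[groups["condition"] == cond]
        for channel in config.channels:
            for window in ("postcue", "postevent"):
                sub = aucs[
                    (aucs["condition"] == cond)
                    & (aucs["channel"] == channel)
                    & (aucs["window"] == window)
                ]
                if sub.empty:
                    continue
                wide = sub.pivot_table(index="pid", columns="type", values="auc")
                for gname in ("high", "low"):
                    gpids = cond_groups.loc[cond_groups["group"] == gname, "pid"]
                    gw = wide.loc[wide.index.intersection(gpids)]
                    if len(gw) < 2:
                        logger.warning(
                            "stress group %s too small (n=%d) for %s/%s/%s",
                            gname, len(gw), cond, window, channel,
                        )
                        continue
                    r = paired_auc_test(
                        gw["experimental"].to_numpy(), gw["control"].to_numpy()
                    )
                    paired_rows.append(
                        {
                            "condition": cond, "channel": channel, "window": window,
                            "group": gname, "n": r.n,
                            "auc_exp_mean": gw["experimental"].mean(),
                            "auc_exp_sd": gw["experimental"].std(ddof=1),
                            "auc_ctrl_mean": gw["control"].mean(),
                            "auc_ctrl_sd": gw["control"].std(ddof=1),
                            "t": r.t, "p": r.p, "d": r.cohens_d,
                        }
                    )

    frames = {
        "anova_results": pd.DataFrame(anova_rows),
        "posthoc": pd.DataFrame(posthoc_rows),
        "contrasts": pd.DataFrame(contrast_rows),
        "paired_auc": pd.DataFrame(paired_rows),
    }
    for name, frame in frames.items():
        frame.to_csv(tables / f"{name}.tsv", sep="\t", index=False)
    logger.info(
        "analyze: %d ANOVA effects, %d contrasts, %d paired AUC tests",
        len(anova_rows), len(contrast_rows), len(paired_rows),
    )
    return frames


def stage_report(config: PipelineConfig) -> Path:
    """Render human-readable summary tables and (optionally) figures."""
    tables = config.out / "tables"
    required = ["anova_results.tsv", "contrasts.tsv", "paired_auc.tsv"]
    for name in required:
        if not (tables / name).exists():
            raise FileNotFoundError(f"missing upstream table {tables / name}")
    anova = pd.read_csv(tables / "anova_results.tsv", sep="\t")
    contrasts = pd.read_csv(tables / "contrasts.tsv", sep="\t")
    paired = pd.read_csv(tables / "paired_auc.tsv", sep="\t")

    lines = ["# Analysis summary", ""]
    lines.append("## Repeated-measures ANOVAs (condition-type x time)")
    for _, r in anova.iterrows():
        star = "*" if r["p_report"] < config.alpha else ""
        lines.append(
            f"{r['condition']:>3} {r['window']:<9} {r['channel']:<5} "
            f"{r['effect']:<14} F({r['df1_gg'] if pd.notna(r['df1_gg']) else r['df1']:.2f}, "
            f"{r['df2_gg'] if pd.notna(r['df2_gg']) else r['df2']:.2f}) = {r['F']:.3f}, "
            f"p = {r['p_report']:.4f}{star}, eta2p = {r['partial_eta_sq']:.3f}"
        )
    lines.append("")
    lines.append("## Cardiac pattern trends (postcue window)")
    for _, r in contrasts.iterrows():
        star = "*" if r["p"] < config.alpha else ""
        lines.append(
            f"{r['condition']:>3} {r['type']:<13} {r['trend']:<10} "
            f"t({r['df']}) = {r['t']:.2f}, p = {r['p']:.4f}{star}"
        )
    lines.append("")
    lines.append("## AUC by perceived-stress group (experimental vs control)")
    if paired.empty:
        lines.append("(no stress groups large enough to compare)")
    for _, r in paired.iterrows():
        star = "*" if r["p"] < config.alpha else ""
        lines.append(
            f"{r['condition']:>3} {r['channel']:<5} {r['window']:<9} {r['group']:<4} "
            f"n={r['n']:>2}  exp {r['auc_exp_mean']:8.2f} ({r['auc_exp_sd']:.2f})  "
            f"ctrl {r['auc_ctrl_mean']:8.2f} ({r['auc_ctrl_sd']:.2f})  "
            f"p = {r['p']:.4f}{star} (d = {r['d']:.2f})"
        )
    out_path = tables / "summary.txt"
    out_path.write_text("\n".join(lines) + "\n")

    if config.plots:
        _plot_mean_curves(config)
    return out_path


def _plot_mean_curves(config: PipelineConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figures = config.out / "figures"
    figures.mkdir(parents=True, exist_ok=True)
    matrices = load_epoch_matrices(config)
    cells = sorted({(k[0], k[2], k[3]) for k in matrices})
    for cond, window, channel in cells:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for ctype, color in (("experimental", "tab:blue"), ("control", "0.5")):
            m = matrices.get((cond, ctype, window, channel))
            if m is None:
                continue
            mean = m.data.mean(axis=0)
            se = m.data.std(axis=0, ddof=1) / np.sqrt(m.data.shape[0])
            ax.plot(m.rel_times, mean, color=color, label=ctype)
            ax.fill_between(m.rel_times, mean - se, mean + se, color=color, alpha=0.25)
        ax.axhline(0.0, lw=0.5, color="k")
        ax.set_xlabel("time from onset (s)")
        ax.set_ylabel("HR change (bpm)" if channel == "hr" else "speed change (km/h)")
        ax.set_title(f"{cond} {window}")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(figures / f"{cond}_{window}_{channel}.png", dpi=110)
        plt.close(fig)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run all stages in order and write run_report.json."""
    config.out.mkdir(parents=True, exist_ok=True)
    (config.out / "config_echo.yaml").write_text(yaml.safe_dump(config.to_dict()))

    stage_simulate(config)
    included = stage_preprocess(config)
    matrices = stage_epoch(config)
    frames = stage_analyze(config)
    stage_report(config)

    excluded = (
        included.loc[~included["included"], "reason"].value_counts().to_dict()
    )
    n_included = int(included["included"].sum())
    report = RunReport(
        seed=config.seed,
        version=__version__,
        enrolled=config.n_participants,
        excluded={k: int(v) for k, v in excluded.items()},
        included=n_included,
        stage_counts={
            "sessions": config.n_participants,
            "epoch_matrices": len(matrices),
            **{f"{k}_rows": len(v) for k, v in frames.items()},
        },
        tables=sorted(str(p) for p in (config.out / "tables").glob("*.tsv")),
        config=config.to_dict(),
    )
    (config.out / "run_report.json").write_text(report.to_json())
    assert report.included == report.enrolled - sum(report.excluded.values())
    return report
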