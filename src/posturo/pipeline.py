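"""End-to-end orchestration: simulate -> sway -> LyE -> respiration -> stats.

A run takes one JSON configuration and an output directory and produces:

* ``trials/`` (optional) — COP trial CSVs, one per design cell repetition;
* ``resp/`` (optional) — respiration CSVs, one per (subject, type, time);
* ``sway_metrics.tsv`` — per-trial sway path lengths;
* ``lye_metrics.tsv`` — per-trial embedding delay, dimension and LyE;
* ``breathing_rate.tsv`` — per-cell breathing-rate estimates;
* ``cohort_table.tsv`` — aggregated cell means feeding the statistics;
* ``results.tsv`` — ANOVA effects, pairwise comparisons and correlations;
* ``descriptives.tsv`` — cell means and SDs per outcome;
* ``manifest.json`` — config echo, seed, version and output digests;
* ``run.log`` — plain-text log of every stage decision.

All stages after generation are deterministic, so a rerun with the same
configuration and seed reproduces the result files byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import DURING_TIMEPOINTS, RunConfig, load_config
from .core import AP, ML, CopTrial, DataError, DesignError
from .io import (
    read_cop_trial,
    read_resp_signal,
    write_cohort_table,
    write_cop_trial,
    write_resp_signal,
    write_results_table,
)
from .nonlinear import trial_lye
from .respiration import (
    RateDetectorSettings,
    UndefinedRateError,
    estimate_breathing_rate,
    resample_signal,
)
from .simulate import simulate_cohort, simulate_resp_signal, subject_id
from .stats import aggregate_trials, change_correlation, rm_anova_2way, screen_outliers
from .sway import compute_sway_paths

SIMULATE = "SIMULATE"
FROM_FILES = "FROM_FILES"

#: Outcomes analysed with the full 2 x (timepoints) design.
SWAY_OUTCOMES = ("total_path", "ml_path", "ap_path", "lye_ml", "lye_ap")
RESP_TRACE_SECONDS = 40.0
RESP_WINDOW = (5.0, 35.0)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def trial_filename(trial: CopTrial) -> str:
    return (
        f"cop_{trial.subject}_{trial.inhalation_type}_"
        f"{trial.timepoint}_r{trial.rep}.csv"
    )


class Pipeline:
    """Stateful runner; each ``stage_*`` method reads/writes declared files."""

    def __init__(self, config: RunConfig, out_dir: str | Path, seed: int | None = None):
        self.config = config
        if seed is not None:
            self.config.simulation.seed = int(seed)
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._log_lines: list[str] = []
        self.log(f"posturo {__version__} on {platform.python_version()}")
        self.log(f"seed: {self.config.simulation.seed}")

    def log(self, message: str) -> None:
        self._log_lines.append(message)

    # -- stage: simulate ---------------------------------------------------

    def stage_simulate(self, write_files: bool = False) -> tuple[list[CopTrial], pd.DataFrame]:
        sim = self.config.simulation
        trials, truth = simulate_cohort(sim)
        self.log(f"simulated {len(trials)} COP trials "
                 f"({sim.n_subjects} subjects x {len(sim.inhalation_types)} types "
                 f"x {len(sim.timepoints)} timepoints x {sim.reps_per_timepoint} reps)")
        truth.to_csv(self.out / "ground_truth.tsv", sep="\t", index=False,
                     float_format="%.12g")
        if write_files:
            trial_dir = self.out / "trials"
            trial_dir.mkdir(exist_ok=True)
            for trial in trials:
                write_cop_trial(trial, trial_dir / trial_filename(trial))
            self.log(f"wrote {len(trials)} trial files to {trial_dir}")
        return trials, truth

    def _resp_seed(self, s_idx: int, t_idx: int, tp_idx: int) -> int:
        return (self.config.simulation.seed + 7919 * s_idx + 104729 * t_idx
                + 1299709 * tp_idx) & 0x7FFFFFFF

    def stage_simulate_resp(self, write_files: bool = False) -> dict[tuple[str, str, str], "object"]:
        """One respiration trace per (subject, type, timepoint) cell."""
        sim = self.config.simulation
        rng = np.random.default_rng(
            np.random.SeedSequence([sim.seed & 0x7FFFFFFF, 11])
        )
        subject_offset = rng.normal(0.0, 1.0, sim.n_subjects)  # breaths/min
        signals = {}
        for s in range(sim.n_subjects):
            for ti, itype in enumerate(sim.inhalation_types):
                for pi, tp in enumerate(sim.timepoints):
                    phase = "POST" if tp == "POST" else "DURING"
                    rate = sim.resp_rate_mean[itype][phase] + subject_offset[s]
                    rate = float(np.clip(rate, 7.0, 19.0))
                    sig = simulate_resp_signal(
                        rate_bpm=rate,
                        duration=RESP_TRACE_SECONDS,
                        sampling_rate=sim.resp_sampling_rate,
                        noise=sim.resp_noise,
                        seed=self._resp_seed(s, ti, pi),
                    )
                    signals[(subject_id(s), itype, tp)] = sig
        self.log(f"simulated {len(signals)} respiration traces")
        if write_files:
            resp_dir = self.out / "resp"
            resp_dir.mkdir(exist_ok=True)
            for (subj, itype, tp), sig in signals.items():
                write_resp_signal(sig, resp_dir / f"resp_{subj}_{itype}_{tp}.csv")
            self.log(f"wrote {len(signals)} respiration files to {resp_dir}")
        return signals

    # -- stage: load from files -------------------------------------------

    def stage_load_trials(self, in_dir: str | Path) -> list[CopTrial]:
        trial_dir = Path(in_dir)
        paths = sorted(trial_dir.glob("cop_*.csv"))
        if not paths:
            raise PipelineError("load", f"no COP trial files in {trial_dir}")
        trials = [read_cop_trial(p) for p in paths]
        self._check_balanced(trials)
        self.log(f"loaded {len(trials)} trials from {trial_dir}")
        return trials

    def _check_balanced(self, trials: list[CopTrial]) -> None:
        sim = self.config.simulation
        seen = {(t.subject, t.inhalation_type, t.timepoint, t.rep) for t in trials}
        for s in range(sim.n_subjects):
            for itype in sim.inhalation_types:
                for tp in sim.timepoints:
                    for rep in range(sim.reps_per_timepoint):
                        cell = (subject_id(s), itype, tp, rep)
                        if cell not in seen:
                            raise PipelineError(
                                "load", f"missing design cell {cell}"
                            )

    def stage_load_resp(self, in_dir: str | Path) -> dict:
        resp_dir = Path(in_dir)
        signals = {}
        for path in sorted(resp_dir.glob("resp_*.csv")):
            subj, itype, tp = path.stem.split("_")[1:4]
            signals[(subj, itype, tp)] = read_resp_signal(path)
        if not signals:
            raise PipelineError("load", f"no respiration files in {resp_dir}")
        return signals

    # -- stage: sway -------------------------------------------------------

    def stage_sway(self, trials: list[CopTrial]) -> pd.DataFrame:
        rows = []
        for trial in trials:
            m = compute_sway_paths(trial)
            for outcome, value in (
                ("total_path", m.total_path),
                ("ml_path", m.ml_path),
                ("ap_path", m.ap_path),
            ):
                rows.append(
                    {"subject": trial.subject, "inhalation_type": trial.inhalation_type,
                     "inhalation_time": trial.timepoint, "rep": trial.rep,
                     "outcome": outcome, "value": value}
                )
        frame = pd.DataFrame(rows)
        frame.to_csv(self.out / "sway_metrics.tsv", sep="\t", index=False,
                     float_format="%.12g")
        self.log(f"sway metrics for {len(trials)} trials")
        return frame

    # -- stage: local dynamic stability -----------------------------------

    def stage_lye(self, trials: list[CopTrial], jobs: int = 1) -> pd.DataFrame:
        ana = self.config.analysis

        def one(trial: CopTrial) -> list[dict]:
            out = []
            for direction, outcome in ((ML, "lye_ml"), (AP, "lye_ap")):
                spec, curve = trial_lye(
                    trial,
                    direction=direction,
                    dimension=ana.embedding_dimension,
                    ami_max_lag=ana.ami_max_lag,
                    ami_n_bins=ana.ami_n_bins,
                    track_time=ana.track_time,
                    fit_window=ana.fit_window,
                )
                out.append(
                    {"subject": trial.subject, "inhalation_type": trial.inhalation_type,
                     "inhalation_time": trial.timepoint, "rep": trial.rep,
                     "outcome": outcome, "value": curve.slope,
                     "delay": spec.delay, "dimension": spec.dimension,
                     "n_pairs": int(curve.n_pairs[0])}
                )
            return out

        if jobs > 1:
            from joblib import Parallel, delayed

            chunks = Parallel(n_jobs=jobs)(delayed(one)(t) for t in trials)
        else:
            chunks = [one(t) for t in trials]
        frame = pd.DataFrame([row for chunk in chunks for row in chunk])
        frame.to_csv(self.out / "lye_metrics.tsv", sep="\t", index=False,
                     float_format="%.12g")
        mean_delays = frame.groupby("outcome")["delay"].agg(["mean", "std"])
        for outcome, row in mean_delays.iterrows():
            self.log(f"{outcome}: mean embedding delay "
                     f"{row['mean']:.1f} +/- {row['std']:.1f} samples")
        return frame

    # -- stage: respiration ------------------------------------------------

    def stage_resp(self, signals: dict) -> pd.DataFrame:
        """Breathing rate per design cell, on the resampled trace.

        The trace is anti-alias resampled to the analysis rate; rate
        detection runs on the respiration-band signal directly because the
        fundamental of quiet breathing (0.1-0.33 Hz) lies below the
        documented 0.5-1 Hz FIR passband (see the methods note).
        """
        ana = self.config.analysis
        detector = RateDetectorSettings(
            baseline_window_ms=ana.br_baseline_window_ms,
            noise_rejection=ana.br_noise_rejection,
            min_rate=ana.br_min_rate,
            max_rate=ana.br_max_rate,
        )
        rows = []
        for (subj, itype, tp), sig in sorted(signals.items()):
            resampled = resample_signal(sig, ana.resp_target_rate)
            try:
                rate = estimate_breathing_rate(resampled, detector, RESP_WINDOW)
            except UndefinedRateError as exc:
                raise PipelineError(
                    "resp", f"undefined rate for cell ({subj}, {itype}, {tp}): {exc}"
                ) from exc
            rows.append({"subject": subj, "inhalation_type": itype,
                         "inhalation_time": tp, "rep": 0,
                         "outcome": "breathing_rate", "value": rate})
        frame = pd.DataFrame(rows)
        frame.to_csv(self.out / "breathing_rate.tsv", sep="\t", index=False,
                     float_format="%.12g")
        self.log(f"breathing rate estimated for {len(rows)} cells")
        return frame

    # -- stage: statistics -------------------------------------------------

    def stage_stats(self, per_trial: pd.DataFrame) -> tuple[list, list[dict], pd.DataFrame]:
        ana = self.config.analysis
        cohort = aggregate_trials(per_trial)
        # outlier screening per outcome on per-subject grand means
        for outcome, sub in cohort.groupby("outcome"):
            subject_means = sub.groupby("subject")["value"].mean()
            retained, removed = screen_outliers(subject_means, ana.outlier_z_cut)
            if removed:
                self.log(f"{outcome}: removed subjects {removed} "
                         f"(> {ana.outlier_z_cut} SD from mean)")
                cohort = cohort[
                    ~((cohort["outcome"] == outcome)
                      & (cohort["subject"].isin(removed)))
                ]
            else:
                self.log(f"{outcome}: no outlier subjects removed")
        write_cohort_table(cohort, self.out / "cohort_table.tsv")

        anovas = []
        rows: list[dict] = []
        for outcome in sorted(cohort["outcome"].unique()):
            table = cohort
            if outcome == "breathing_rate":
                # BR design is during- vs post-inhalation: the during level
                # is the mean of the three balance windows (T5, T10, T15)
                table = cohort[cohort["outcome"] == outcome].copy()
                table["inhalation_time"] = np.where(
                    table["inhalation_time"].isin(DURING_TIMEPOINTS),
                    "DURING", "POST",
                )
                table = (table.groupby(
                    ["subject", "inhalation_type", "inhalation_time", "outcome"],
                    sort=False)["value"].mean().reset_index())
            result = rm_anova_2way(table, outcome, alpha=ana.alpha)
            anovas.append(result)
            for name, eff in result.effects.items():
                rows.append({"outcome": outcome, "effect": name,
                             "df1": eff.df1, "df2": eff.df2,
                             "F_or_r": eff.F, "p": eff.p,
                             "eta_p2_or_band": eff.eta_p2,
                             "epsilon_GG": eff.epsilon_gg})
            for name, comps in result.pairwise.items():
                for c in comps:
                    rows.append({"outcome": outcome,
                                 "effect": f"{name} pairwise {c.level_a} vs {c.level_b}",
                                 "df1": c.n - 1, "df2": None,
                                 "F_or_r": c.mean_difference,
                                 "p": c.p_bonferroni,
                                 "eta_p2_or_band": None, "epsilon_GG": None})
        rows.extend(self._correlation_rows(cohort))
        write_results_table(rows, self.out / "results.tsv")

        desc = (cohort.groupby(["outcome", "inhalation_type", "inhalation_time"])
                ["value"].agg(["mean", "std", "count"]).reset_index())
        desc.to_csv(self.out / "descriptives.tsv", sep="\t", index=False,
                    float_format="%.12g")
        self.log(f"statistics: {len(anovas)} ANOVA tables, "
                 f"{sum(1 for r in rows if 'corr' in r['effect'])} correlations")
        return anovas, rows, cohort

    def _correlation_rows(self, cohort: pd.DataFrame) -> list[dict]:
        """BR-change vs total-path-change correlations per condition."""
        sim = self.config.simulation
        rows: list[dict] = []
        have = set(cohort["outcome"].unique())
        if not {"breathing_rate", "total_path"} <= have:
            return rows
        tps = list(sim.timepoints)
        intervals = list(zip(tps[:-1], tps[1:]))
        for itype in sim.inhalation_types:
            for t0, t1 in intervals:
                deltas = {}
                for outcome in ("breathing_rate", "total_path"):
                    sub = cohort[(cohort["outcome"] == outcome)
                                 & (cohort["inhalation_type"] == itype)]
                    wide = sub.pivot(index="subject", columns="inhalation_time",
                                     values="value")
                    deltas[outcome] = (wide[t1] - wide[t0]).dropna()
                joined = pd.concat(
                    [deltas["breathing_rate"], deltas["total_path"]], axis=1,
                    join="inner", keys=["br", "path"],
                ).dropna()
                corr = change_correlation(joined["br"].to_numpy(),
                                          joined["path"].to_numpy())
                rows.append({"outcome": "br_vs_total_path",
                             "effect": f"corr {itype} {t0}->{t1}",
                             "df1": corr.n - 2, "df2": None,
                             "F_or_r": corr.r, "p": corr.p,
                             "eta_p2_or_band": corr.band, "epsilon_GG": None})
        return rows

    # -- manifest ----------------------------------------------------------

    def write_manifest(self) -> Path:
        files = {
            p.name: _sha256(p)
            for p in sorted(self.out.glob("*.tsv"))
        }
        manifest = {
            "package_version": __version__,
            "root_seed": self.config.simulation.seed,
            "config": self.config.model_dump(mode="json"),
            "output_digests": files,
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        }
        path = self.out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        (self.out / "run.log").write_text("\n".join(self._log_lines) + "\n")
        return path


def run_pipeline(
    config: RunConfig | str | Path | None,
    out_dir: str | Path,
    mode: str = SIMULATE,
    seed: int | None = None,
    in_dir: str | Path | None = None,
    jobs: int = 1,
    write_files: bool = False,
) -> Path:
    """Execute all stages; returns the manifest path.

    ``SIMULATE`` generates the cohort from the configuration;
    ``FROM_FILES`` loads COP/respiration files from ``in_dir`` (layout as
    written by ``write_files=True``).  Any stage failure raises
    :class:`PipelineError` naming the stage and the offending input.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config)
    pipe = Pipeline(config, out_dir, seed=seed)
    try:
        if mode == SIMULATE:
            trials, _ = pipe.stage_simulate(write_files=write_files)
            signals = pipe.stage_simulate_resp(write_files=write_files)
        elif mode == FROM_FILES:
            if in_dir is None:
                raise PipelineError("load", "FROM_FILES mode requires in_dir")
            trials = pipe.stage_load_trials(Path(in_dir) / "trials")
            signals = pipe.stage_load_resp(Path(in_dir) / "resp")
        else:
            raise DesignError(f"unknown mode {mode!r}")
        sway = pipe.stage_sway(trials)
        lye = pipe.stage_lye(trials, jobs=jobs)
        resp = pipe.stage_resp(signals)
        per_trial = pd.concat(
            [sway, lye[sway.columns.intersection(lye.columns)], resp],
            ignore_index=True,
        )
        pipe.stage_stats(per_trial)
    except (DataError, DesignError) as exc:
        pipe.log(f"ABORT: {exc}")
        pipe.write_manifest()
        raise PipelineError("pipeline", str(exc)) from exc
    return pipe.write_manifest()
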