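"""End-to-end orchestration: simulate → extract → estimate → test.

`run_pipeline` drives a full synthetic study: cohort generation, the
electrical stimulation session (skin-conductance traces, currents and
ratings), sensation/pain threshold probes, two-point discrimination and
touch detection staircases at three body sites, the constant-stimuli
touch comparison task, and the complete statistical battery (mixed
ANOVAs with partial η², pooled t-tests with Cohen's d, Mann-Whitney
follow-ups, Bonferroni post-hocs, and questionnaire correlations with
Benjamini-Hochberg control).  Every stage is reproducible from
(config, seed); all outputs are plain CSV/JSON.
"""

from __future__ import annotations

import contextlib
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import psychometric, scr_events, staircase, stats, synthetic_data
from .psychometric import ConstantStimuliDesign
from .scr_events import STRONG, WEAK, StimulusEvent
from .staircase import TOUCH_DETECTION_LADDER, TWO_POINT_LADDER
from .synthetic_data import (AASP_SUBSCALES, BODY_SITES, INTENSITIES,
                             RATING_CATEGORIES, SRS2_SUBSCALES, Cohort,
                             CohortSpec, generate_cohort, substream)

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

TASK_EST = "est"
TASK_THRESHOLDS = "thresholds"
TASK_TWO_POINT = "two_point"
TASK_TOUCH_DETECTION = "touch_detection"
TASK_TOUCH_COMPARISON = "touch_comparison"
ALL_TASKS = (TASK_EST, TASK_THRESHOLDS, TASK_TWO_POINT,
             TASK_TOUCH_DETECTION, TASK_TOUCH_COMPARISON)

REASON_SCHEDULING = "scheduling"
REASON_REFUSAL = "refusal"
REASON_EXPERIMENTAL_ERROR = "experimental_error"
REASON_NO_SCR_PEAK = "no_scr_peak"


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@contextlib.contextmanager
def _stage(name: str):
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage={name}: {exc}") from exc


def default_exclusion_annotations() -> dict:
    """Cohort facts supplied as annotations, not computed rules: the
    scheduling / refusal / experimental-error drop-outs of the emulated
    study (2 + 1 ASD missing the electrical tasks, one TD recording error,
    and one ASD recording error in each staircase task)."""
    return {
        TASK_EST: {"ASD01": REASON_SCHEDULING, "ASD02": REASON_SCHEDULING,
                   "ASD03": REASON_REFUSAL, "TD01": REASON_EXPERIMENTAL_ERROR},
        TASK_THRESHOLDS: {"ASD01": REASON_SCHEDULING, "ASD02": REASON_SCHEDULING,
                          "ASD03": REASON_REFUSAL},
        TASK_TWO_POINT: {"ASD04": REASON_EXPERIMENTAL_ERROR},
        TASK_TOUCH_DETECTION: {"ASD05": REASON_EXPERIMENTAL_ERROR},
        TASK_TOUCH_COMPARISON: {},
    }


@dataclass(frozen=True)
class RunConfig:
    """Everything `run_pipeline` needs, reproducible from one seed."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    tasks: tuple = ALL_TASKS
    amplitude_criterion_uS: float = scr_events.DEFAULT_AMPLITUDE_CRITERION_US
    window_s: float = scr_events.DEFAULT_WINDOW_S
    staircase_start_level: float | None = None  # None = ladder maximum
    reset_on_change: bool = True
    lapse_rate: float = 0.0
    tie_correction: bool = True
    continuity: bool = False
    fdr_q: float = 0.05
    design: ConstantStimuliDesign = field(default_factory=ConstantStimuliDesign)
    exclusion_annotations: Mapping[str, Mapping[str, str]] = field(
        default_factory=default_exclusion_annotations)

    def __post_init__(self) -> None:
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        # keep one seed: the cohort inherits the run seed
        object.__setattr__(self, "cohort",
                           dataclasses.replace(self.cohort, seed=int(self.seed)))

    def annotated(self, task: str) -> Mapping[str, str]:
        return dict(self.exclusion_annotations.get(task, {}))


def config_from_dict(raw: Mapping) -> RunConfig:
    """Build a RunConfig from a plain mapping (YAML-friendly subset).

    Recognized keys: any scalar RunConfig field, plus ``n_asd``/``n_td``
    and any scalar CohortSpec field under ``cohort``.
    """
    raw = dict(raw)
    cohort_kwargs = dict(raw.pop("cohort", {}))
    for key in ("n_asd", "n_td"):
        if key in raw:
            cohort_kwargs[key] = raw.pop(key)
    cohort = dataclasses.replace(CohortSpec(), **cohort_kwargs)
    if "tasks" in raw:
        raw["tasks"] = tuple(raw["tasks"])
    return RunConfig(cohort=cohort, **raw)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


# --------------------------------------------------------------------------
# simulation stage

def simulate_frames(config: RunConfig) -> dict:
    """Generate every raw data table the analysis stage consumes.

    Returns a dict with participants, traits, est_events, traces (mapping
    participant id → SkinConductanceTrace), thresholds, staircase trials
    and results, and touch-comparison trials.  Participants annotated as
    dropped for a task simply have no rows for it.
    """
    cohort = generate_cohort(config.cohort)
    ids = list(cohort.participants["participant_id"])
    frames: dict = {"participants": cohort.participants, "traits": cohort.traits}

    if TASK_EST in config.tasks:
        dropped = set(config.annotated(TASK_EST))
        events_frames, traces = [], {}
        for pid in ids:
            if pid in dropped:
                continue
            session = synthetic_data.simulate_est_session(cohort, pid)
            events_frames.append(session.trials)
            traces[pid] = session.trace
        frames["est_events"] = (pd.concat(events_frames, ignore_index=True)
                                if events_frames else pd.DataFrame())
        frames["traces"] = traces
        log.info("stage=est participants_in=%d simulated=%d dropped=%d",
                 len(ids), len(traces), len(dropped))

    if TASK_THRESHOLDS in config.tasks:
        dropped = set(config.annotated(TASK_THRESHOLDS))
        keep = [pid for pid in ids if pid not in dropped]
        tr = cohort.traits.set_index("participant_id")
        frames["thresholds"] = pd.DataFrame({
            "participant_id": keep,
            "group": [tr.loc[p, "group"] for p in keep],
            "sensation_threshold_uA": [tr.loc[p, "sensation_threshold"] for p in keep],
            "pain_threshold_uA": [tr.loc[p, "pain_threshold"] for p in keep],
        })
        log.info("stage=thresholds participants_in=%d measured=%d", len(ids), len(keep))

    staircase_tasks = [(TASK_TWO_POINT, TWO_POINT_LADDER, "2pdt",
                        cohort.two_point_observer),
                       (TASK_TOUCH_DETECTION, TOUCH_DETECTION_LADDER, "tdt",
                        cohort.detection_observer)]
    trial_rows, result_rows = [], []
    for task, ladder, tag, observer_of in staircase_tasks:
        if task not in config.tasks:
            continue
        dropped = set(config.annotated(task))
        n_run = 0
        for pid in ids:
            if pid in dropped:
                continue
            for site in BODY_SITES:
                rng = substream(config.seed, tag, pid, site)
                deco = substream(config.seed, tag + "-deco", pid, site)
                result = staircase.run_staircase(
                    observer_of(pid, site), ladder,
                    config.staircase_start_level, rng,
                    reset_on_change=config.reset_on_change)
                for i, (level, correct) in enumerate(result.history):
                    order = "AB" if deco.random() < 0.5 else "BA"
                    target = order[0]
                    response = target if correct else order[1]
                    trial_rows.append({
                        "participant_id": pid, "task": task, "body_site": site,
                        "trial_index": i, "level": level,
                        "interval_order": order, "response": response,
                        "correct": correct})
                result_rows.append({
                    "participant_id": pid, "task": task, "body_site": site,
                    "threshold": result.threshold if result.threshold is not None
                    else np.nan,
                    "termination_reason": result.termination_reason,
                    "n_trials": result.n_trials})
                n_run += 1
        log.info("stage=%s staircases_run=%d dropped=%d", task, n_run, len(dropped))
    if trial_rows:
        frames["staircase_trials"] = pd.DataFrame(trial_rows)
        frames["staircase_results"] = pd.DataFrame(result_rows)

    if TASK_TOUCH_COMPARISON in config.tasks:
        dropped = set(config.annotated(TASK_TOUCH_COMPARISON))
        tct = []
        for pid in ids:
            if pid in dropped:
                continue
            row = cohort.trait_row(pid)
            rng = substream(config.seed, "tct", pid)
            trials = psychometric.simulate_comparison_trials(
                lambda f: synthetic_data.comparison_p_stronger(row, f),
                config.design, rng)
            trials.insert(0, "participant_id", pid)
            tct.append(trials)
        frames["tct_trials"] = pd.concat(tct, ignore_index=True)
        log.info("stage=touch_comparison participants=%d trials=%d",
                 len(tct), len(frames["tct_trials"]))
    return frames


# --------------------------------------------------------------------------
# analysis stage

def _effect_dict(e: stats.EffectResult) -> dict:
    return {"statistic": e.F, "df": [e.df_num, e.df_den], "p": e.p,
            "effect_size": e.partial_eta_sq, "effect_size_type": "partial_eta_sq"}


def _anova_dict(res: stats.MixedAnovaResult) -> dict:
    return {"between": _effect_dict(res.between),
            "within": _effect_dict(res.within),
            "interaction": _effect_dict(res.interaction),
            "sphericity_corrected": res.sphericity_corrected}


def _ttest_dict(res: stats.TTestResult) -> dict:
    return {"statistic": res.t, "df": res.df, "p": res.p,
            "effect_size": res.cohens_d, "effect_size_type": "cohens_d",
            "mean1": res.mean1, "mean2": res.mean2, "n1": res.n1, "n2": res.n2}


def extract_scr_trials(config: RunConfig, est_events: pd.DataFrame,
                       traces: Mapping[str, scr_events.SkinConductanceTrace]
                       ) -> pd.DataFrame:
    """Run event-related SCR extraction for every simulated stimulation."""
    rows = []
    for pid, events in est_events.groupby("participant_id", sort=False):
        trace = traces[pid]
        events = events.sort_values("trial_index")
        onsets = list(events["onset_s"])
        for i, (_, ev) in enumerate(events.iterrows()):
            event = StimulusEvent(onset=float(ev["onset_s"]), offset=float(ev["offset_s"]),
                                  intensity_label=str(ev["intensity"]),
                                  current=float(ev["current_uA"]))
            nxt = onsets[i + 1] if i + 1 < len(onsets) else None
            res = scr_events.extract_event_scr(
                trace, event, window_s=config.window_s,
                amplitude_criterion_uS=config.amplitude_criterion_uS,
                next_event_onset=nxt)
            rows.append({"participant_id": pid, "trial_index": int(ev["trial_index"]),
                         "intensity": event.intensity_label,
                         "pre_stimulus_uS": res.pre_stimulus_value,
                         "peak_uS": res.peak_value,
                         "peak_latency_s": res.peak_latency,
                         "delta_uS": res.delta, "responded": res.responded})
    return pd.DataFrame(rows)


def summarize_scr_trials(scr_trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for pid, df in scr_trials.groupby("participant_id", sort=False):
        by_int = {
            intensity: [scr_events.EventRelatedSCR(
                pre_stimulus_value=r.pre_stimulus_uS, peak_value=r.peak_uS,
                peak_latency=r.peak_latency_s, delta=r.delta_uS,
                responded=bool(r.responded))
                for r in df[df["intensity"] == intensity].itertuples()]
            for intensity in INTENSITIES}
        s = scr_events.summarize_scr(pid, by_int)
        rows.append(dataclasses.asdict(s))
    return pd.DataFrame(rows)


def apply_exclusions(config: RunConfig, participants: pd.DataFrame,
                     scr_summary: pd.DataFrame | None,
                     staircase_results: pd.DataFrame | None) -> pd.DataFrame:
    """Build the exclusion ledger: one row per participant per task.

    Annotated drop-outs (scheduling / refusal / experimental error) take
    precedence; participants whose recordings lack a response peak at one
    of the intensities are excluded with reason ``no_scr_peak``.
    Staircase runs that passed the ladder minimum stay included — the
    threshold is recorded at the minimum level — with an explanatory note.
    """
    rows = []
    included_scr = (set(scr_summary[scr_summary["included"]]["participant_id"])
                    if scr_summary is not None else set())
    measured_scr = (set(scr_summary["participant_id"])
                    if scr_summary is not None else set())
    passed = {}
    if staircase_results is not None:
        pm = staircase_results[
            staircase_results["termination_reason"] == staircase.TEN_CORRECT_AT_MINIMUM]
        for r in pm.itertuples():
            passed.setdefault((r.task, r.participant_id), []).append(r.body_site)
    for pid in participants["participant_id"]:
        for task in config.tasks:
            annotated = config.annotated(task)
            status, reason, note = "included", "", ""
            if pid in annotated:
                status, reason = "excluded", annotated[pid]
            elif task == TASK_EST and pid in measured_scr and pid not in included_scr:
                status, reason = "excluded", REASON_NO_SCR_PEAK
            if (task, pid) in passed:
                sites = ",".join(passed[(task, pid)])
                note = f"passed ladder minimum ({sites}); threshold recorded at minimum"
            rows.append({"participant_id": pid, "task": task,
                         "status": status, "reason": reason, "note": note})
    ledger = pd.DataFrame(rows)
    n_excluded = int((ledger["status"] == "excluded").sum())
    log.info("stage=exclusions rows=%d excluded=%d", len(ledger), n_excluded)
    return ledger


def _correlation_block(participants: pd.DataFrame, scr_summary: pd.DataFrame,
                       subscales, prefix: str, Q: float) -> dict:
    merged = scr_summary.merge(participants, on="participant_id")
    tests, ps, labels = [], [], []
    for sub in subscales:
        for intensity in INTENSITIES:
            res = stats.pearson_test(merged[f"{prefix}_{sub}"],
                                     merged[f"mean_delta_{intensity}"])
            tests.append({"subscale": sub, "intensity": intensity,
                          "r": res.r, "p": res.p, "n": res.n})
            ps.append(res.p)
            labels.append(f"{sub}:{intensity}")
    fdr = stats.bh_fdr(ps, Q=Q, labels=labels)
    for test, (_, row) in zip(tests, fdr.iterrows()):
        test.update({"rank": int(row["rank"]), "q": float(row["q"]),
                     "significant": bool(row["significant"])})
    return {"m": len(tests), "Q": Q, "tests": tests}


def analyze_frames(config: RunConfig, frames: Mapping) -> dict:
    """Run every analysis stage on raw frames; returns derived frames and
    the nested statistics summary."""
    participants = frames["participants"]
    group_of = participants.set_index("participant_id")["group"]
    summary: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed,
                     "amplitude_criterion_uS": config.amplitude_criterion_uS}
    derived: dict = {}
    scr_summary = None

    if TASK_EST in config.tasks and len(frames.get("est_events", ())):
        est_events = frames["est_events"]
        scr_trials = extract_scr_trials(config, est_events, frames["traces"])
        scr_summary = summarize_scr_trials(scr_trials)
        derived["scr_trials"] = scr_trials
        derived["scr_summary"] = scr_summary
        included = scr_summary[scr_summary["included"]]["participant_id"]
        inc = scr_summary[scr_summary["included"]].copy()
        inc["group"] = inc["participant_id"].map(group_of)

        long_rows = []
        per_part = scr_trials[scr_trials["participant_id"].isin(included)]
        means = per_part.groupby(["participant_id", "intensity"]).agg(
            delta=("delta_uS", "mean"), baseline=("pre_stimulus_uS", "mean")
        ).reset_index()
        currents = est_events[est_events["participant_id"].isin(included)].groupby(
            ["participant_id", "intensity"])["current_uA"].mean().reset_index()
        means = means.merge(currents, on=["participant_id", "intensity"])
        means["group"] = means["participant_id"].map(group_of)
        del long_rows

        est_block = {}
        for name, dv in (("current", "current_uA"), ("baseline", "baseline"),
                         ("event_scr", "delta")):
            res = stats.mixed_anova(means, dv=dv, within="intensity",
                                    subject="participant_id", between="group")
            est_block[name] = _anova_dict(res)
        trials_inc = scr_trials[scr_trials["participant_id"].isin(included)]
        per_participant_lat = trials_inc.groupby("participant_id")["peak_latency_s"].mean()
        est_block["peak_latency"] = {
            "per_trial_mean_s": float(trials_inc["peak_latency_s"].mean()),
            "per_trial_sd_s": float(trials_inc["peak_latency_s"].std(ddof=1)),
            "per_participant_mean_s": float(per_participant_lat.mean()),
            "per_participant_sd_s": float(per_participant_lat.std(ddof=1))}
        est_block["cell_means_uS"] = {
            f"{g}_{i}": float(means[(means["group"] == g)
                                    & (means["intensity"] == i)]["delta"].mean())
            for g in sorted(means["group"].unique()) for i in INTENSITIES}
        est_block["n_included"] = {
            g: int((inc["group"] == g).sum()) for g in sorted(inc["group"].unique())}
        summary["est"] = est_block

        # subjective ratings, same included participants
        ratings_block = {}
        ev_inc = est_events[est_events["participant_id"].isin(included)]
        for category in RATING_CATEGORIES:
            col = {"intensity": "rating_intensity", "painful": "rating_pain",
                   "unpleasant": "rating_unpleasant"}[category]
            rmeans = ev_inc.groupby(["participant_id", "intensity"])[col].mean().reset_index()
            rmeans["group"] = rmeans["participant_id"].map(group_of)
            res = stats.mixed_anova(rmeans, dv=col, within="intensity",
                                    subject="participant_id", between="group")
            block = _anova_dict(res)
            if category == "painful":
                block["mann_whitney"] = {}
                for intensity in INTENSITIES:
                    sub = rmeans[rmeans["intensity"] == intensity]
                    mwu = stats.mann_whitney(
                        sub[sub["group"] == "ASD"][col], sub[sub["group"] == "TD"][col],
                        tie_correction=config.tie_correction,
                        continuity=config.continuity)
                    block["mann_whitney"][intensity] = {
                        "U": mwu.U, "z": mwu.z, "p": mwu.p}
            ratings_block[category] = block
        summary["ratings"] = ratings_block

        summary["correlations"] = {
            "srs2": _correlation_block(participants, inc, SRS2_SUBSCALES,
                                       "srs2", config.fdr_q),
            "aasp": _correlation_block(participants, inc, AASP_SUBSCALES,
                                       "aasp", config.fdr_q)}

    if TASK_THRESHOLDS in config.tasks and "thresholds" in frames:
        th = frames["thresholds"]
        block = {}
        for name, col in (("sensation", "sensation_threshold_uA"),
                          ("pain", "pain_threshold_uA")):
            res = stats.t_test(th[th["group"] == "ASD"][col],
                               th[th["group"] == "TD"][col])
            block[name] = _ttest_dict(res)
        summary["thresholds"] = block

    if "staircase_results" in frames:
        sres = frames["staircase_results"]
        for task, ladder, key in ((TASK_TWO_POINT, TWO_POINT_LADDER, "two_point"),
                                  (TASK_TOUCH_DETECTION, TOUCH_DETECTION_LADDER,
                                   "touch_detection")):
            if task not in config.tasks:
                continue
            sub = sres[sres["task"] == task].copy()
            if not len(sub):
                continue
            # passed-minimum runs enter the ANOVA at the smallest level
            nsub = int(sub["threshold"].isna().sum())
            if nsub:
                log.info("stage=%s passed_minimum_substituted=%d level=%s",
                         task, nsub, ladder.levels[0])
            sub["threshold"] = sub["threshold"].fillna(ladder.levels[0])
            sub["group"] = sub["participant_id"].map(group_of)
            res = stats.mixed_anova(sub, dv="threshold", within="body_site",
                                    subject="participant_id", between="group")
            posthoc = stats.bonferroni_pairwise(sub, dv="threshold",
                                                within="body_site",
                                                subject="participant_id")
            summary[key] = {
                "anova": _anova_dict(res),
                "posthoc": posthoc.to_dict(orient="records"),
                "n_passed_minimum_runs": nsub,
                "n_participants": int(sub["participant_id"].nunique())}

    if TASK_TOUCH_COMPARISON in config.tasks and "tct_trials" in frames:
        tct = frames["tct_trials"]
        fit_rows = []
        for pid, trials in tct.groupby("participant_id", sort=False):
            table = psychometric.tabulate(trials, config.design)
            fit = psychometric.fit_logistic(table, lapse_rate=config.lapse_rate)
            fit_rows.append({
                "participant_id": pid, "a": fit.a, "b": fit.b, "pse_g": fit.pse,
                "slope": psychometric.slope_at_pse(fit) if fit.converged else np.nan,
                "converged": fit.converged, "loglik": fit.log_likelihood})
        fits = pd.DataFrame(fit_rows)
        fits["group"] = fits["participant_id"].map(group_of)
        derived["tct_fits"] = fits
        conv = fits[fits["converged"]]
        slope_t = stats.t_test(conv[conv["group"] == "ASD"]["slope"],
                               conv[conv["group"] == "TD"]["slope"])
        pct = tct.copy()
        pct["group"] = pct["participant_id"].map(group_of)
        pct_long = pct.groupby(["participant_id", "group", "comparison_g"])[
            "response_stronger"].mean().reset_index()
        pct_long["pct_stronger"] = 100.0 * pct_long["response_stronger"]
        res = stats.mixed_anova(pct_long, dv="pct_stronger", within="comparison_g",
                                subject="participant_id", between="group")
        posthoc = stats.bonferroni_pairwise(pct_long, dv="pct_stronger",
                                            within="comparison_g",
                                            subject="participant_id")
        summary["touch_comparison"] = {
            "slope_t": _ttest_dict(slope_t),
            "anova": _anova_dict(res),
            "posthoc": posthoc.to_dict(orient="records"),
            "n_fitted": int(len(fits)), "n_converged": int(len(conv)),
            "trials_per_participant": int(
                tct.groupby("participant_id").size().iloc[0])}

    ledger = apply_exclusions(config, participants, scr_summary,
                              frames.get("staircase_results"))
    derived["exclusions"] = ledger
    summary["exclusions"] = {
        "n_excluded": int((ledger["status"] == "excluded").sum()),
        "by_reason": ledger[ledger["status"] == "excluded"]["reason"]
        .value_counts().to_dict()}
    return {"summary": summary, "derived": derived}


# --------------------------------------------------------------------------
# reporting and I/O

def render_report(summary: Mapping) -> str:
    """Human-readable digest of the statistics summary."""
    lines = [f"psytact report (seed={summary.get('seed')})", "=" * 40]

    def anova_lines(title: str, block: Mapping) -> None:
        lines.append(title)
        for name in ("between", "within", "interaction"):
            e = block[name]
            lines.append(
                f"  {name:<12} F({e['df'][0]}, {e['df'][1]}) = {e['statistic']:.3f}, "
                f"p = {e['p']:.3g}, partial eta^2 = {e['effect_size']:.3f}")

    if "est" in summary:
        est = summary["est"]
        lines.append(f"Electrical stimulation task (n included: {est['n_included']})")
        lat = est["peak_latency"]
        lines.append(f"  peak latency: per-trial mean {lat['per_trial_mean_s']:.3f} s "
                     f"(SD {lat['per_trial_sd_s']:.3f}); per-participant mean "
                     f"{lat['per_participant_mean_s']:.3f} s")
        for name in ("current", "baseline", "event_scr"):
            anova_lines(f"  ANOVA on {name}:", est[name])
    if "ratings" in summary:
        for category, block in summary["ratings"].items():
            anova_lines(f"Subjective {category} ratings:", block)
            for intensity, m in block.get("mann_whitney", {}).items():
                lines.append(f"    Mann-Whitney {intensity}: U = {m['U']:.1f}, "
                             f"z = {m['z']:.3f}, p = {m['p']:.3f}")
    if "thresholds" in summary:
        for name, t in summary["thresholds"].items():
            lines.append(f"{name.capitalize()} threshold: t({t['df']}) = "
                         f"{abs(t['statistic']):.3f}, p = {t['p']:.3f}, "
                         f"d = {t['effect_size']:.2f}")
    for key, title in (("two_point", "Two-point discrimination"),
                       ("touch_detection", "Touch detection")):
        if key in summary:
            anova_lines(f"{title} (site x group):", summary[key]["anova"])
    if "touch_comparison" in summary:
        tc = summary["touch_comparison"]
        t = tc["slope_t"]
        lines.append(f"Touch comparison slope: t({t['df']}) = "
                     f"{abs(t['statistic']):.3f}, p = {t['p']:.3f}, "
                     f"d = {t['effect_size']:.2f}")
        anova_lines("  ANOVA on % stronger:", tc["anova"])
    if "correlations" in summary:
        for inst, block in summary["correlations"].items():
            lines.append(f"{inst.upper()} correlations with event-related SCR "
                         f"(m = {block['m']}, Q = {block['Q']}):")
            for test in block["tests"]:
                flag = "*" if test["significant"] else " "
                lines.append(
                    f"  {flag} {test['subscale']:<34} {test['intensity']:<6} "
                    f"r = {test['r']:+.3f}, p = {test['p']:.3f}, q = {test['q']:.3f}")
    if "exclusions" in summary:
        lines.append(f"Exclusions: {summary['exclusions']['n_excluded']} "
                     f"({summary['exclusions']['by_reason']})")
    return "\n".join(lines) + "\n"


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_outputs(out_dir, frames: Mapping, result: Mapping, config: RunConfig) -> dict:
    """Write all raw and derived tables plus the statistics JSON/report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = str(path)

    for name in ("participants", "traits", "est_events", "thresholds",
                 "staircase_trials", "staircase_results", "tct_trials"):
        if name in frames:
            _write(name, frames[name])
    for pid, trace in frames.get("traces", {}).items():
        path = out / f"trace_{pid}.csv"
        scr_events.write_trace_csv(trace, path)
        written[f"trace_{pid}"] = str(path)
    for name, df in result["derived"].items():
        _write("scr_trials" if name == "scr_trials" else name, df)

    stats_path = out / "stats_summary.json"
    with open(stats_path, "w") as fh:
        json.dump(result["summary"], fh, indent=2, sort_keys=True,
                  default=_json_default)
        fh.write("\n")
    written["stats_summary"] = str(stats_path)
    report_path = out / "report.txt"
    report_path.write_text(render_report(result["summary"]))
    written["report"] = str(report_path)
    manifest = {"schema_version": SCHEMA_VERSION, "seed": config.seed,
                "files": sorted(written)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return written


def load_frames(out_dir) -> dict:
    """Re-load the raw frames written by the simulate stage."""
    out = Path(out_dir)
    frames: dict = {}
    for name in ("participants", "traits", "est_events", "thresholds",
                 "staircase_trials", "staircase_results", "tct_trials"):
        path = out / f"{name}.csv"
        if path.exists():
            frames[name] = pd.read_csv(path)
    if "est_events" in frames:
        frames["traces"] = {
            pid: scr_events.read_trace_csv(out / f"trace_{pid}.csv")
            for pid in frames["est_events"]["participant_id"].unique()}
    return frames


@dataclass(frozen=True)
class PipelineResult:
    config: RunConfig
    frames: Mapping
    summary: Mapping
    derived: Mapping
    written: Mapping


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """simulate → extract → estimate → test; optionally write everything.

    Fully reproducible: the same (config, seed) yields byte-identical
    statistics JSON.
    """
    with _stage("simulate"):
        frames = simulate_frames(config)
    with _stage("analyze"):
        result = analyze_frames(config, frames)
    written = {}
    if out_dir is not None:
        with _stage("write"):
            written = write_outputs(out_dir, frames, result, config)
    return PipelineResult(config=config, frames=frames, summary=result["summary"],
                          derived=result["derived"], written=written)
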