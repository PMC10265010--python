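"""End-to-end orchestration: simulate -> QC -> kinematics -> energetics ->
advantages -> logistic fits -> verdicts.

All stages are importable functions over in-memory objects; the CLI is a
thin shell.  Every output row is traceable to a trial id, QC discards are
logged with reasons, and identical configs and seeds give identical outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decision, energetics, kinematics, synthetic
from .anthro import AnthropometricTable, default_table
from .types import MarkerTrajectorySet, Participant, TrialSpec, standard_grid

logger = logging.getLogger("gapcross")

__all__ = ["PipelineConfig", "run_pipeline", "qc_trials", "process_trial", "analyse_trials"]

#: The four candidate control targets of the main comparison; the CoM-cost
#: candidates are reported separately.
MAIN_CANDIDATES = ("task_cot_tot", "step_cot_tot", "speed_max", "speed_conservation")
COM_CANDIDATES = ("task_cot_com", "step_cot_com")


@dataclass
class PipelineConfig:
    n_participants: int = 13
    mass_mean: float = 72.3
    mass_sd: float = 15.5
    leg_mean: float = 0.88
    leg_sd: float = 0.04
    seed: int = 0
    n_dropout: int = 6
    jitter_sigma: float = 0.002
    filter_corner_hz: float = 6.0
    stance_threshold_frac: float = 0.20
    stance_refine_frac: float = 0.05
    stance_min_duration: float = 0.10
    alpha: float = 0.05
    include_rotational: bool = False
    out_dir: str = "results"
    generator: synthetic.GeneratorParams | None = None
    anthropometry: AnthropometricTable | None = None

    def make_participants(self) -> list[Participant]:
        rng = np.random.default_rng(self.seed + 1)
        parts = []
        for i in range(self.n_participants):
            mass = float(np.clip(rng.normal(self.mass_mean, self.mass_sd), 45, 120))
            leg = float(np.clip(rng.normal(self.leg_mean, self.leg_sd), 0.6, 1.2))
            parts.append(Participant(f"P{i:02d}", mass, leg))
        return parts


def qc_trials(
    trials: list[tuple[TrialSpec, MarkerTrajectorySet]],
) -> tuple[list[tuple[TrialSpec, MarkerTrajectorySet]], pd.DataFrame]:
    """Discard trials with marker gaps anywhere in the analysed window.

    Returns retained trials and a per-trial QC report (trial id, retained,
    reason).
    """
    kept = []
    rows = []
    for spec, mset in trials:
        gap_labels = [lb for lb in mset.labels if mset.missing(lb).any()]
        if gap_labels:
            rows.append((spec.trial_id, False, f"marker gaps: {','.join(gap_labels)}"))
        else:
            kept.append((spec, mset))
            rows.append((spec.trial_id, True, ""))
    report = pd.DataFrame(rows, columns=["trial_id", "retained", "reason"])
    return kept, report


def process_trial(
    spec: TrialSpec, mset: MarkerTrajectorySet, config: PipelineConfig | None = None
) -> dict:
    """Kinematics and energetics for one QC-passed trial.

    Returns the per-trial outcome record: task and worst-step costs of
    transport (total and CoM), traversal and approach Froude numbers, and
    their absolute difference.
    """
    cfg = config or PipelineConfig()
    filtered = kinematics.lowpass_filter(mset, cfg.filter_corner_hz)
    ev_l = kinematics.detect_stance_phases(
        filtered,
        "left",
        cfg.stance_threshold_frac,
        cfg.stance_refine_frac,
        cfg.stance_min_duration,
    )
    ev_r = kinematics.detect_stance_phases(
        filtered,
        "right",
        cfg.stance_threshold_frac,
        cfg.stance_refine_frac,
        cfg.stance_min_duration,
    )
    if not ev_l or not ev_r:
        raise ValueError(f"trial {spec.trial_id}: no stance phases detected")
    steps = kinematics.segment_steps(ev_l, ev_r, filtered)
    x0 = float(mset.meta["obstacle_x0"])
    traversal = kinematics.identify_traversal(
        steps, spec.obstacle, (x0, x0 + spec.obstacle.length_abs), spec.strategy
    )
    table = cfg.anthropometry or default_table(cfg.include_rotational)
    cost = energetics.traversal_energetics(filtered, traversal, table)

    leg = spec.participant.leg_length
    traversal_fr = kinematics.froude(traversal.speed, leg)
    if traversal.approach_step is not None:
        approach_fr = kinematics.froude(traversal.approach_step.speed, leg)
        speed_dev = abs(approach_fr - traversal_fr)
    else:
        approach_fr = np.nan
        speed_dev = np.nan
    return {
        "trial_id": spec.trial_id,
        "participant": spec.participant.id,
        "depth_rel": spec.obstacle.depth_rel,
        "length_rel": spec.obstacle.length_rel,
        "strategy": spec.strategy,
        "condition": spec.condition,
        "n_traversal_steps": len(traversal.steps),
        "task_cot_tot": cost.cot_tot,
        "task_cot_com": cost.cot_com,
        "step_cot_tot": max(s.cot_tot for s in cost.steps),
        "step_cot_com": max(s.cot_com for s in cost.steps),
        "speed_max": traversal_fr,
        "approach_froude": approach_fr,
        "speed_conservation": speed_dev,
        "task_distance": cost.work.distance,
        "w_com": cost.work.w_com,
        "w_int": cost.work.w_int,
        "w_tot": cost.work.w_tot,
        "flags": ";".join(traversal.flags),
    }


def compute_advantages(trials_df: pd.DataFrame, candidate: str) -> list[decision.AdvantageRecord]:
    """Per-geometry advantage records for one candidate control target.

    Candidate means pool preferred and enforced trials; choice counts come
    from preferred (free choice) trials only.  Geometries observed under
    only one strategy are flagged and excluded from fitting.
    """
    records = []
    for (d, ln), grp in trials_df.groupby(["depth_rel", "length_rel"]):
        over = grp.loc[grp.strategy == "OVER", candidate].dropna()
        in_ = grp.loc[grp.strategy == "IN", candidate].dropna()
        pref = grp[grp.condition == "preferred"]
        n_trials = len(pref)
        n_over = int((pref.strategy == "OVER").sum())
        if len(over) == 0 or len(in_) == 0:
            rec = decision.AdvantageRecord(candidate, 0.0, (d, ln), n_trials, n_over, flagged=True)
        else:
            rec = decision.compute_advantage(
                candidate, float(over.mean()), float(in_.mean()), (d, ln), n_trials, n_over
            )
        records.append(rec)
    return records


def analyse_trials(trials_df: pd.DataFrame, alpha: float = 0.05):
    """Advantages, logistic fits and verdicts for all candidate targets.

    Returns (advantages_df, coefficients_df, verdicts_df); the coefficient
    table mirrors the usual reporting (b0, t, p, b1, t, p plus CIs) with one
    row per candidate.
    """
    adv_rows, coef_rows, verdict_rows = [], [], []
    for cand in MAIN_CANDIDATES + COM_CANDIDATES:
        records = compute_advantages(trials_df, cand)
        for r in records:
            adv_rows.append(
                {
                    "candidate": cand,
                    "depth_rel": r.obstacle[0],
                    "length_rel": r.obstacle[1],
                    "x": r.x,
                    "n_trials": r.n_trials,
                    "n_over": r.n_over,
                    "flagged": r.flagged,
                }
            )
        fit = decision.fit_logistic([r for r in records if not r.flagged])
        coef_rows.append(
            {
                "candidate": cand,
                "main": cand in MAIN_CANDIDATES,
                "b0": fit.b0,
                "b0_t": fit.t_b0,
                "b0_p": fit.p_b0,
                "b0_ci_lo": fit.ci95_b0[0],
                "b0_ci_hi": fit.ci95_b0[1],
                "b1": fit.b1,
                "b1_t": fit.t_b1,
                "b1_p": fit.p_b1,
                "b1_ci_lo": fit.ci95_b1[0],
                "b1_ci_hi": fit.ci95_b1[1],
                "log_likelihood": fit.log_likelihood,
                "converged": fit.converged,
                "pse": decision.point_of_subjective_equality(fit) if fit.b1 != 0 else np.nan,
            }
        )
        if fit.converged:
            verdict = decision.evaluate_control_target(fit, cand, alpha)
            verdict_rows.append(
                {
                    "candidate": cand,
                    "feature_b1": verdict.feature_b1,
                    "feature_b0": verdict.feature_b0,
                    "consistent": verdict.consistent,
                }
            )
        else:
            verdict_rows.append(
                {"candidate": cand, "feature_b1": None, "feature_b0": None, "consistent": None}
            )
    return pd.DataFrame(adv_rows), pd.DataFrame(coef_rows), pd.DataFrame(verdict_rows)


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run the full synthetic-session analysis and write all result tables.

    Writes trials.csv, qc.csv, advantages.csv, coefficients.csv (the four
    main candidates), coefficients_com.csv, verdicts.csv and run_log.txt to
    ``config.out_dir``; returns the tables in a dict.
    """
    cfg = config or PipelineConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("pipeline running or aborted\n")
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        gen = cfg.generator or synthetic.GeneratorParams(jitter_sigma=cfg.jitter_sigma)
        participants = cfg.make_participants()
        log(f"seed={cfg.seed} participants={len(participants)}")
        session = synthetic.generate_session(
            participants,
            standard_grid(),
            seed=cfg.seed,
            n_dropout=cfg.n_dropout,
            params=gen,
        )
        log(f"simulate: {len(session)} trials generated")

        kept, qc_report = qc_trials(session)
        n_discarded = int((~qc_report.retained).sum())
        log(f"qc: retained {len(kept)} of {len(session)} trials ({n_discarded} discarded)")

        records = []
        for spec, mset in kept:
            try:
                records.append(process_trial(spec, mset, cfg))
            except (ValueError, kinematics.MissingMarkerError) as exc:
                raise RuntimeError(f"kinematics/energetics stage failed: {exc}") from exc
        trials_df = pd.DataFrame(records)
        log(f"kinematics+energetics: {len(trials_df)} trials processed")

        advantages, coefficients, verdicts = analyse_trials(trials_df, cfg.alpha)
        log(f"decision: {coefficients.shape[0]} candidate fits")

        trials_df.to_csv(out / "trials.csv", index=False)
        qc_report.to_csv(out / "qc.csv", index=False)
        advantages.to_csv(out / "advantages.csv", index=False)
        coefficients[coefficients.main].drop(columns="main").to_csv(
            out / "coefficients.csv", index=False
        )
        coefficients[~coefficients.main].drop(columns="main").to_csv(
            out / "coefficients_com.csv", index=False
        )
        verdicts.to_csv(out / "verdicts.csv", index=False)
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    except Exception:
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\nABORTED\n")
        raise
    marker.unlink()
    return {
        "trials": trials_df,
        "qc": qc_report,
        "advantages": advantages,
        "coefficients": coefficients,
        "verdicts": verdicts,
        "log": log_lines,
    }
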