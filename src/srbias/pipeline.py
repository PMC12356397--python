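"""End-to-end simulation and analysis of the noisy-letter experiment.

``run_simulate`` pushes a cohort of synthetic observers through the full
block structure — practice, QUEST titration, the undisclosed-base-rate
block, the bias flip, and the two noise-ladder blocks — and returns the
canonical trial log.  ``run_analyze`` folds a trial log into per-participant
SDT summaries and runs the group inference stack.

All randomness descends from the single root seed through named
per-participant substreams, so enlarging the cohort never reshuffles the
trials of earlier participants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import inference, paradigm, sdt
from .config import RunConfig
from .io import frame_to_records, records_to_frame
from .observer import ObserverParams, TemplateBank, simulate_participant, simulate_trial
from .quest import (QuestParams, quest_estimate, quest_init,
                    quest_next_intensity, quest_update)
from .stimuli import make_noise_ladder

__all__ = ["ParticipantMeta", "run_participant", "run_simulate",
           "run_analyze", "AnalysisOutput"]


@dataclass(frozen=True)
class ParticipantMeta:
    participant_id: str
    increment: float
    quest_runs: int
    block2_letter_accuracy: float
    frequent_category: str
    block3_criterion: float
    status: str                      # include | exclude


def _sample_observer(cfg: RunConfig, rng: np.random.Generator) -> ObserverParams:
    obs = cfg.observer
    theta = max(0.0, rng.normal(obs.theta_mean, obs.theta_sd))
    w = max(obs.w_min, rng.normal(obs.w_mean, obs.w_sd))
    preferred = ("consonant" if rng.random() < obs.p_prefer_consonant
                 else "vowel")
    return ObserverParams(theta=theta, w=w, lapse=obs.lapse,
                          n_frames_integrated=obs.n_frames_integrated,
                          category_prior=obs.category_prior,
                          internal_noise_sd=obs.internal_noise_sd,
                          decision_noise_sd=obs.decision_noise_sd,
                          preferred_category=preferred)


def _quest_params(cfg: RunConfig) -> QuestParams:
    q = cfg.quest
    grid = np.linspace(q.prior_mean - q.grid_span, q.prior_mean + q.grid_span,
                       q.grid_points)
    return QuestParams(beta=q.beta, delta=q.delta, gamma=q.gamma,
                       target_p=q.target_p, prior_mean=q.prior_mean,
                       prior_sd=q.prior_sd, grid=grid)


def _titrate(design, params: ObserverParams, cfg: RunConfig,
             bank: TemplateBank, rng: np.random.Generator,
             participant_id: str) -> tuple[float, list]:
    """Run the staircase block; returns (increment, trial records)."""
    q = cfg.quest
    state = quest_init(_quest_params(cfg))
    records = []
    for i, (letter, sigma) in enumerate(design.letter_sequence["quest"], 1):
        x = quest_next_intensity(state)
        inc = float(np.clip(10.0 ** x, q.min_increment, q.max_increment))
        resp = simulate_trial(letter, sigma, inc, params, bank, rng)
        state = quest_update(state, np.log10(inc), resp == letter)
        records.append(sdt.TrialRecord(
            participant_id=participant_id, block="quest", trial_index=i,
            sigma=sigma, letter_shown=letter, response_letter=resp,
            increment=inc))
    _, inc = quest_estimate(state)
    return float(np.clip(inc, q.min_increment, q.max_increment)), records


def _simulate_blocks(design, labels, params, increment, bank, rng, pid):
    sub = dataclasses.replace(design,
                              blocks=tuple(b for b in design.blocks
                                           if b.label in labels))
    return simulate_participant(sub, params, increment, bank=bank, rng=rng,
                                participant_id=pid)


def run_participant(index: int, cfg: RunConfig,
                    bank: TemplateBank | None = None
                    ) -> tuple[list, ParticipantMeta]:
    """Simulate one participant through blocks 0-5.

    The QUEST block is re-run (followed by a fresh block 2) when the
    letter-exact block-2 accuracy strays outside 70 +/- 10%, up to
    ``blocks.max_quest_reruns`` extra attempts; the last attempt's records
    enter the log either way, mirroring a session that proceeds after
    repeated titration.
    """
    pid = f"p{index:02d}"
    if bank is None:
        bank = TemplateBank(cfg.field_geometry.glyph_height,
                            (cfg.field_geometry.rows, cfg.field_geometry.cols))
    ladder = make_noise_ladder(cfg.ladder.sigma_min, cfg.ladder.sigma_max,
                               cfg.ladder.n_nonzero)
    root = np.random.SeedSequence(cfg.seed)
    param_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=root.entropy, spawn_key=(index, 0)))
    design_seed = np.random.SeedSequence(entropy=root.entropy,
                                         spawn_key=(index, 1))
    trial_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=root.entropy, spawn_key=(index, 2)))

    params = _sample_observer(cfg, param_rng)
    design = paradigm.build_design(
        design_seed, frequent_category="consonant", ladder=ladder,
        n_per_level=cfg.blocks.n_per_level,
        quest_trials=cfg.blocks.quest_trials,
        bias_block_trials=cfg.blocks.bias_block_trials)

    practice = _simulate_blocks(design, {"practice"}, params, 1.0, bank,
                                trial_rng, pid)

    quest_runs = 0
    while True:
        quest_runs += 1
        increment, quest_records = _titrate(design, params, cfg, bank,
                                            trial_rng, pid)
        block2 = _simulate_blocks(design, {"block2"}, params, increment,
                                  bank, trial_rng, pid)
        acc6 = float(np.mean([r.correct_letter for r in block2]))
        if not paradigm.quest_rerun_rule(acc6):
            break
        if quest_runs > cfg.blocks.max_quest_reruns:
            break

    frequent = paradigm.assign_frequent_category(block2)
    if frequent != design.frequent_category:
        design = paradigm.build_design(
            design_seed, frequent_category=frequent, ladder=ladder,
            n_per_level=cfg.blocks.n_per_level,
            quest_trials=cfg.blocks.quest_trials,
            bias_block_trials=cfg.blocks.bias_block_trials)

    rare = "vowel" if frequent == "consonant" else "consonant"
    block3 = _simulate_blocks(design, {"block3"}, params, increment, bank,
                              trial_rng, pid)
    counts3 = sdt.classify_responses(block3, rare)
    hr3, far3, _ = sdt.rates(counts3)
    crit3 = sdt.criterion(hr3, far3)

    noise = _simulate_blocks(design, {"block4", "block5"}, params, increment,
                             bank, trial_rng, pid)
    records = practice + quest_records + block2 + block3 + noise
    meta = ParticipantMeta(pid, increment, quest_runs, acc6, frequent,
                           crit3, paradigm.exclusion_rule(crit3))
    return records, meta


def run_simulate(cfg: RunConfig) -> tuple[pd.DataFrame, list[ParticipantMeta]]:
    """Simulate the full cohort; returns (trial log frame, metadata)."""
    bank = TemplateBank(cfg.field_geometry.glyph_height,
                        (cfg.field_geometry.rows, cfg.field_geometry.cols))
    frames, metas = [], []
    for i in range(cfg.cohort_size):
        records, meta = run_participant(i, cfg, bank)
        frames.append(records_to_frame(records))
        metas.append(meta)
    return pd.concat(frames, ignore_index=True), metas


@dataclass
class AnalysisOutput:
    summary: pd.DataFrame            # per participant x sigma SDT summary
    results: pd.DataFrame            # group statistics, tidy
    excluded: list[str]              # participant ids failing the bias rule
    report: str


def _frequent_category_of(pdf: pd.DataFrame) -> str:
    """Infer a participant's frequent category from the noise-block base rates."""
    noise = pdf[pdf["block"].isin(("block4", "block5"))]
    share = (noise["category_shown"] == "consonant").mean()
    return "consonant" if share >= 0.5 else "vowel"


def run_analyze(trial_log: pd.DataFrame, cfg: RunConfig) -> AnalysisOutput:
    """SDT summaries plus the group inference stack on a trial log."""
    summaries, excluded, kept = [], [], []
    for pid, pdf in trial_log.groupby("participant_id", sort=True):
        frequent = _frequent_category_of(pdf)
        rare = "vowel" if frequent == "consonant" else "consonant"
        records = frame_to_records(pdf)
        block3 = [r for r in records if r.block == "block3"]
        if block3:
            c3 = sdt.classify_responses(block3, rare)
            hr3, far3, _ = sdt.rates(c3)
            if paradigm.exclusion_rule(sdt.criterion(hr3, far3)) == "exclude":
                excluded.append(pid)
                continue
        kept.append(pid)
        summaries.append(sdt.summarize(records, rare))
    if not summaries:
        raise ValueError("no participants left after exclusion")
    summary = pd.concat(summaries, ignore_index=True)

    sigmas = sorted(summary["sigma"].unique())
    mats = {m: summary.pivot(index="participant_id", columns="sigma",
                             values=m).loc[kept, sigmas].to_numpy()
            for m in ("accuracy", "dprime", "criterion")}
    labels = [f"{round(s, 2):g}" for s in sigmas]

    rows = []
    for measure, direction in (("accuracy", "greater"), ("dprime", "greater"),
                               ("criterion", "less")):
        mat = mats[measure]
        if measure != "criterion":
            a = inference.rm_anova_oneway(mat)
            rows.append({"measure": measure, "level": "omnibus",
                         "statistic": "F", "value": a.value,
                         "df1": a.df[0], "df2": a.df[1], "p_raw": a.p_raw,
                         "p_corr": None, "cohens_d": None, "ln_bf10": None})
        for r in inference.posthoc_vs_baseline(mat, baseline_level=0,
                                               direction=direction,
                                               labels=labels):
            rows.append({"measure": measure, "level": r.label,
                         "statistic": "t", "value": r.value, "df1": r.df,
                         "df2": None, "p_raw": r.p_raw, "p_corr": r.p_corr,
                         "cohens_d": r.cohens_d, "ln_bf10": None})

    baseline_c = mats["criterion"][:, 0]
    t_base = inference.one_sample_t(baseline_c, 0.0, tails=2)
    bf_base = inference.jzs_bf_one_sample(t_base.value, baseline_c.size,
                                          cfg.analysis.bf_prior_scale)
    rows.append({"measure": "criterion", "level": "baseline-vs-0",
                 "statistic": "t", "value": t_base.value, "df1": t_base.df,
                 "df2": None, "p_raw": t_base.p_raw, "p_corr": None,
                 "cohens_d": t_base.cohens_d, "ln_bf10": bf_base.ln_bf10})

    # independence of the accuracy and criterion shifts at the lowest
    # nonzero noise level (both measured as change from baseline)
    d_acc = mats["accuracy"][:, 1] - mats["accuracy"][:, 0]
    d_crit = mats["criterion"][:, 1] - mats["criterion"][:, 0]
    try:
        bf_corr = inference.jzs_bf_correlation(
            d_acc, d_crit, cfg.analysis.correlation_prior_width)
        rows.append({"measure": "acc-crit-shift", "level": labels[1],
                     "statistic": "r", "value": float(np.corrcoef(d_acc, d_crit)[0, 1]),
                     "df1": d_acc.size - 2, "df2": None, "p_raw": None,
                     "p_corr": None, "cohens_d": None,
                     "ln_bf10": bf_corr.ln_bf10})
    except (ValueError, ArithmeticError):
        pass

    results = pd.DataFrame(rows)
    report = _format_report(summary, results, excluded, kept, sigmas)
    return AnalysisOutput(summary=summary, results=results,
                          excluded=excluded, report=report)


def _format_report(summary, results, excluded, kept, sigmas) -> str:
    lines = ["Stochastic-resonance letter task: group analysis",
             "=" * 49, "",
             f"participants analysed: {len(kept)}"]
    if excluded:
        lines.append("excluded (no bias toward the frequent category in "
                     f"block 3): {', '.join(excluded)}")
    lines.append("")
    lines.append("mean per noise level (sigma: accuracy, d', criterion):")
    g = summary.groupby("sigma")[["accuracy", "dprime", "criterion"]].mean()
    for s in sigmas:
        lines.append(f"  sigma {s:6.2f}: acc {g.loc[s, 'accuracy']:.3f}  "
                     f"d' {g.loc[s, 'dprime']:.3f}  "
                     f"c {g.loc[s, 'criterion']:+.3f}")
    lines.append("")
    for _, r in results.iterrows():
        if r["statistic"] == "F":
            lines.append(f"{r['measure']:>9} omnibus: F({r['df1']:.0f},"
                         f"{r['df2']:.0f}) = {r['value']:.2f}, "
                         f"p = {r['p_raw']:.3g}")
        elif r["level"] == "baseline-vs-0":
            lines.append(f"criterion baseline vs 0: t({r['df1']:.0f}) = "
                         f"{r['value']:.2f}, p = {r['p_raw']:.3g}, "
                         f"d = {r['cohens_d']:.2f}, "
                         f"lnBF10 = {r['ln_bf10']:.2f}")
        elif r["statistic"] == "t":
            lines.append(f"{r['measure']:>9} sigma {r['level']:>6}: "
                         f"t({r['df1']:.0f}) = {r['value']:+.2f}, "
                         f"p_corr = {r['p_corr']:.3g}, "
                         f"d = {r['cohens_d']:+.2f}")
        else:
            lines.append(f"accuracy/criterion shift correlation at sigma "
                         f"{r['level']}: r = {r['value']:+.2f}, "
                         f"lnBF10 = {r['ln_bf10']:.2f}")
    return "\n".join(lines) + "\n"
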