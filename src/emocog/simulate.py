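"""Synthetic cohort generator for the emotional-cognitive battery.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any recorded child data:

* ages drawn from a truncated normal (mean 7.2, SD 1.4, range 4-10 years);
* self-reported depression (CES-DC) and anxiety (STAI-CH) scores sharing a
  latent factor calibrated so their observed Pearson correlation is ~0.493,
  with the parent-reported ADHD scale (K-ARS) independent of both;
* trial-level reaction times that are log-normal, speed up with age, and are
  slowed on emotional stimuli by an additive (ms-scale) interference term
  proportional to a subject's emotional sensitivity, which loads on the
  shared depression/anxiety factor;
* a general-slowness component loading on the depression score specifically;
* accuracy from logistic models with age gains, an ADHD-linked (impulsivity)
  deficit on emotional and incongruent stimuli, and extra commission errors
  on positive no-go stimuli;
* attention lapses, response deadlines (2000 ms on go trials), and an
  engagement-dropout process that produces runs of consecutive misses.

Latent traits (processing speed, emotional sensitivity, impulsivity) are the
generative stand-ins for the constructs the three composite E-scores are
meant to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats as sps

from .design import (
    COLORS,
    NEGATIVE,
    NEUTRAL,
    POSITIVE,
    TASK_DESIGNS,
    TASKS,
    TaskDesign,
    base_conditions,
)
from .schemas import TRIAL_COLUMNS, write_participants, write_trials

__all__ = [
    "AgeModel",
    "ScaleModel",
    "RTModel",
    "AccuracyModel",
    "SimConfig",
    "TrialSchedule",
    "CohortData",
    "make_schedule",
    "sample_participants",
    "simulate_session",
    "simulate_cohort",
]


class AgeModel(BaseModel):
    mean: float = 7.2
    sd: float = Field(1.4, gt=0)
    min: float = 4.0
    max: float = 10.0

    @model_validator(mode="after")
    def _ordered(self):
        if not self.min < self.max:
            raise ValueError("age bounds must satisfy min < max")
        return self


class ScaleModel(BaseModel):
    """Survey-scale generator: discretized latent Gaussians.

    CES-DC and STAI-CH share a latent factor g with loading sqrt(latent_corr)
    each, so their latent correlation equals ``latent_corr``; rounding and
    clipping to the instruments' ranges attenuate the observed correlation
    only marginally (< 0.01 at these means/SDs).  K-ARS is independent.
    """

    latent_corr: float = Field(0.493, ge=0, lt=1)
    cesdc_mean: float = 14.0
    cesdc_sd: float = Field(8.0, gt=0)
    cesdc_range: tuple[int, int] = (0, 60)
    staich_mean: float = 33.0
    staich_sd: float = Field(7.0, gt=0)
    staich_range: tuple[int, int] = (20, 60)
    kars_mean: float = 10.0
    kars_sd: float = Field(8.0, gt=0)
    kars_range: tuple[int, int] = (0, 54)


class RTModel(BaseModel):
    """Log-normal reaction-time model (all effects additive on log ms)."""

    #: baseline log RT on neutral/non-emotional go trials, per task
    base_log_rt: dict[str, float] = {
        "eflanker": 7.03,
        "egonogo": 7.10,
        "estroop": 6.68,
    }
    #: change in log RT per year of age (negative = speeding)
    age_slope: float = -0.12
    #: SD of the subject random intercept (log ms)
    subject_sd: float = Field(0.15, gt=0)
    #: loading of the subject intercept on the depression-specific latent
    #: (general slowness in children with more depressive symptoms, over and
    #: above the shared internalizing factor)
    dep_loading: float = 0.10
    #: trial-level residual SD (log ms)
    resid_sd: float = Field(0.35, gt=0)
    #: mean slowing on emotional (vs neutral) eFlanker targets, ms.
    #: Emotional interference is additive in milliseconds (not on the log
    #: scale): the study's emotional RT differences are age-invariant, which
    #: a multiplicative effect (scaling with overall slowness) would violate.
    emo_shift_ms: float = 170.0
    #: additional slowing per SD of emotional sensitivity, ms (eFlanker)
    emo_sens_slope_ms: float = 130.0
    #: slowing per SD of emotional sensitivity, ms, negative eStroop trials
    estroop_neg_sens_slope_ms: float = 60.0
    #: slowing on incongruent eFlanker trials per SD of emotional
    #: sensitivity, ms (individual congruency effects track emotional
    #: sensitivity; the group-mean congruency effect stays ~0)
    incong_sens_slope_ms: float = 40.0
    #: probability of an attention lapse (no touch) on a required trial
    lapse_prob: float = Field(0.01, ge=0, le=1)
    #: probability that a would-be-late go response is rushed in just under
    #: the deadline instead of timing out (children race the visible clock)
    rush_prob: float = Field(0.8, ge=0, le=1)


class AccuracyModel(BaseModel):
    """Logistic accuracy model (all effects on the logit scale)."""

    #: eFlanker baseline logit of a correct face choice (neutral target)
    eflanker_base: float = 4.1
    #: logit gain per year of age (all tasks)
    age_slope: float = 0.25
    #: SD of the subject accuracy intercept, shared across tasks
    subject_sd: float = Field(0.4, gt=0)
    #: mean deficit on emotional eFlanker targets
    emo_shift: float = 0.35
    #: emotional deficit per SD of emotional sensitivity (eFlanker)
    emo_sens_slope: float = 0.30
    #: emotional deficit per SD of impulsivity (eFlanker)
    emo_adhd_slope: float = 0.2
    #: mean incongruency deficit (eFlanker; ~0, no group-level congruency effect)
    incong_shift: float = 0.0
    #: incongruency deficit per SD of impulsivity (eFlanker)
    incong_adhd_slope: float = 0.1
    #: baseline logit of a correct withhold, negative no-go (eGoNoGo)
    egonogo_nogo_base: float = 3.2
    #: extra commission tendency on positive no-go stimuli (eGoNoGo)
    egonogo_pos_shift: float = 0.8
    #: commission tendency per SD of impulsivity (eGoNoGo no-go)
    nogo_adhd_slope: float = 0.18
    #: additional impulsivity effect on positive no-go stimuli
    nogo_adhd_pos_slope: float = 0.08
    #: commission tendency on positive no-go stimuli per SD of emotional
    #: sensitivity (attentional bias toward rewarding stimuli)
    nogo_sens_pos_slope: float = 0.15
    #: baseline logit of a correct withhold, neutral no-go (eStroop)
    estroop_nogo_base: float = 3.7
    #: commission shifts on positive / negative eStroop no-go stimuli
    estroop_pos_shift: float = 0.45
    estroop_neg_shift: float = 0.15
    #: commission tendency per SD of impulsivity (eStroop no-go)
    estroop_nogo_adhd_slope: float = 0.12
    #: commission tendency per SD of emotional sensitivity on emotional
    #: eStroop no-go stimuli
    estroop_nogo_sens_slope: float = 0.10


class SimConfig(BaseModel):
    """Full generator configuration; the seed fixes the entire dataset."""

    n_participants: int = Field(78, ge=2)
    seed: int = 0
    female_prob: float = Field(0.5, ge=0, le=1)
    self_report_prob: float = Field(0.5, ge=0, le=1)
    age: AgeModel = AgeModel()
    scales: ScaleModel = ScaleModel()
    rt: RTModel = RTModel()
    accuracy: AccuracyModel = AccuracyModel()
    #: per-task probability that a participant disengages mid-session
    dropout_prob: dict[str, float] = {
        "eflanker": 2 / 78,
        "egonogo": 4 / 78,
        "estroop": 10 / 78,
    }
    dropout_threshold: int = Field(4, ge=1)

    @model_validator(mode="after")
    def _probabilities(self):
        for task, p in self.dropout_prob.items():
            if task not in TASKS:
                raise ValueError(f"unknown task in dropout_prob: {task!r}")
            if not 0 <= p <= 1:
                raise ValueError("dropout probabilities must lie in [0, 1]")
        return self

    @classmethod
    def null(cls, n_participants: int = 64, seed: int = 0, **overrides) -> "SimConfig":
        """Configuration with every trait-to-behavior slope set to zero.

        Scales keep their joint distribution but carry no information about
        behavior, so all downstream associations are null.  The dropout
        process is disabled so the analysed cohort size is exactly
        ``n_participants``.
        """
        cfg = cls(n_participants=n_participants, seed=seed, **overrides)
        cfg.rt.dep_loading = 0.0
        cfg.rt.emo_sens_slope_ms = 0.0
        cfg.rt.estroop_neg_sens_slope_ms = 0.0
        cfg.rt.incong_sens_slope_ms = 0.0
        cfg.accuracy.emo_sens_slope = 0.0
        cfg.accuracy.emo_adhd_slope = 0.0
        cfg.accuracy.incong_adhd_slope = 0.0
        cfg.accuracy.nogo_adhd_slope = 0.0
        cfg.accuracy.nogo_adhd_pos_slope = 0.0
        cfg.accuracy.nogo_sens_pos_slope = 0.0
        cfg.accuracy.estroop_nogo_adhd_slope = 0.0
        cfg.accuracy.estroop_nogo_sens_slope = 0.0
        cfg.dropout_prob = {task: 0.0 for task in TASKS}
        return cfg

    @classmethod
    def recovery(cls, n_participants: int = 200, seed: int = 0, **overrides) -> "SimConfig":
        """Default planted effects with the dropout process disabled, so the
        analysed cohort size is exactly ``n_participants``."""
        cfg = cls(n_participants=n_participants, seed=seed, **overrides)
        cfg.dropout_prob = {task: 0.0 for task in TASKS}
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.model_dump(), indent=2))
        return path


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered condition list (practice block 0 + main blocks) for one task."""

    task: str
    trials: pd.DataFrame  # block, trial_index, target_emotion, distractor_emotion, color, is_target
    design: TaskDesign

    @property
    def main(self) -> pd.DataFrame:
        return self.trials[self.trials["block"] > 0]


_BASE_CACHE: dict[str, dict[str, np.ndarray]] = {}


def _base_arrays(task: str) -> dict[str, np.ndarray]:
    if task not in _BASE_CACHE:
        base = base_conditions(task)
        _BASE_CACHE[task] = {
            "target_emotion": base["target_emotion"].to_numpy(object),
            "distractor_emotion": base["distractor_emotion"].to_numpy(object),
            "color": base["color"].to_numpy(object),
            "is_target": base["is_target"].to_numpy(bool),
        }
    return _BASE_CACHE[task]


def make_schedule(task: str, seed: int | np.random.Generator = 0) -> TrialSchedule:
    """Randomly ordered trial schedule with exact main-phase condition counts.

    The eGoNoGo color-emotion target pairing and the eStroop target color are
    drawn from the rng (counterbalanced across participants in the study).
    """
    if task not in TASK_DESIGNS:
        raise ValueError(f"unknown task {task!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = TASK_DESIGNS[task]
    base = _base_arrays(task)
    n_main = design.main_trials

    emo = base["target_emotion"]
    dist = base["distractor_emotion"]
    color = base["color"]
    is_target = base["is_target"]
    if task == "egonogo":
        perm = rng.permutation(COLORS)
        remap = dict(zip(COLORS, perm))
        color = np.array([remap[c] for c in color], object)
    elif task == "estroop":
        target_color = str(rng.choice(COLORS))
        is_target = color == target_color

    order = rng.permutation(n_main)
    practice_rows = rng.choice(n_main, size=design.practice_trials, replace=False)
    rows = np.concatenate([practice_rows, order])

    blocks = np.concatenate([
        np.zeros(design.practice_trials, int),
        np.repeat(np.arange(1, design.main_blocks + 1), design.trials_per_block),
    ])
    trial_index = np.concatenate([
        np.arange(1, design.practice_trials + 1),
        np.tile(np.arange(1, design.trials_per_block + 1), design.main_blocks),
    ])
    trials = pd.DataFrame(
        {
            "block": blocks,
            "trial_index": trial_index,
            "target_emotion": emo[rows],
            "distractor_emotion": dist[rows],
            "color": color[rows],
            "is_target": is_target[rows],
        }
    )
    return TrialSchedule(task=task, trials=trials, design=design)


# ---------------------------------------------------------------------------
# participants and latent traits

TRAIT_COLUMNS = [
    "participant_id", "shared_internalizing", "dep_latent", "anx_latent",
    "adhd_latent", "dep_specific", "speed_resid", "acc_resid",
    "emo_sensitivity", "impulsivity",
]


def _discretize(latent: np.ndarray, mean: float, sd: float, lo: int, hi: int) -> np.ndarray:
    return np.clip(np.rint(mean + sd * latent), lo, hi).astype(int)


def sample_participants(
    config: SimConfig, seed: int | np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the participant table and the latent traits that drive behavior.

    Returns ``(participants, traits)``; rows align on participant_id.
    """
    n = config.n_participants
    if n < 2:
        raise ValueError("need at least 2 participants")
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    age_cfg = config.age
    a = (age_cfg.min - age_cfg.mean) / age_cfg.sd
    b = (age_cfg.max - age_cfg.mean) / age_cfg.sd
    ages = sps.truncnorm.rvs(a, b, loc=age_cfg.mean, scale=age_cfg.sd,
                             size=n, random_state=rng)

    sc = config.scales
    g = rng.standard_normal(n)
    load = np.sqrt(sc.latent_corr)
    resid = np.sqrt(1.0 - sc.latent_corr)
    dep_latent = load * g + resid * rng.standard_normal(n)
    anx_latent = load * g + resid * rng.standard_normal(n)
    adhd_latent = rng.standard_normal(n)

    pids = [f"P{i + 1:04d}" for i in range(n)]
    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "age_years": np.round(ages, 2),
            "gender": np.where(rng.random(n) < config.female_prob, "female", "male"),
            "cesdc": _discretize(dep_latent, sc.cesdc_mean, sc.cesdc_sd, *sc.cesdc_range),
            "staich": _discretize(anx_latent, sc.staich_mean, sc.staich_sd, *sc.staich_range),
            "kars": _discretize(adhd_latent, sc.kars_mean, sc.kars_sd, *sc.kars_range),
            "admin_mode": np.where(rng.random(n) < config.self_report_prob,
                                   "self", "experimenter"),
        }
    )
    traits = pd.DataFrame(
        {
            "participant_id": pids,
            "shared_internalizing": g,
            "dep_latent": dep_latent,
            "anx_latent": anx_latent,
            "adhd_latent": adhd_latent,
            "speed_resid": rng.standard_normal(n),
            "acc_resid": rng.standard_normal(n),
        }
    )
    traits["dep_specific"] = (traits["dep_latent"] - load * traits["shared_internalizing"]) / resid
    traits["emo_sensitivity"] = traits["shared_internalizing"]
    traits["impulsivity"] = traits["adhd_latent"]
    return participants, traits[TRAIT_COLUMNS]


# ---------------------------------------------------------------------------
# sessions


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_session(
    participant: pd.Series,
    traits: pd.Series,
    schedule: TrialSchedule,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one participant's full session (practice + main) on one task."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    task = schedule.task
    design = schedule.design
    cond = schedule.trials
    n = len(cond)

    age_c = float(participant["age_years"]) - config.age.mean
    e_sens = float(traits["emo_sensitivity"])
    impul = float(traits["impulsivity"])

    rt_cfg = config.rt
    acc_cfg = config.accuracy

    mix = rt_cfg.dep_loading * float(traits["dep_specific"]) + np.sqrt(
        max(0.0, 1.0 - rt_cfg.dep_loading**2)) * float(traits["speed_resid"])
    subj_u = rt_cfg.subject_sd * mix
    subj_v = acc_cfg.subject_sd * float(traits["acc_resid"])

    emo = cond["target_emotion"].to_numpy(object)
    is_target = cond["is_target"].to_numpy(bool)
    emotional = emo != NEUTRAL

    # latent touch latency on every trial (used only where a touch occurs)
    mu = rt_cfg.base_log_rt[task] + rt_cfg.age_slope * age_c + subj_u
    shift_ms = np.zeros(n)
    if task == "eflanker":
        shift_ms[emotional] += rt_cfg.emo_shift_ms + rt_cfg.emo_sens_slope_ms * e_sens
        dist_pre = cond["distractor_emotion"].to_numpy(object)
        shift_ms[emo != dist_pre] += rt_cfg.incong_sens_slope_ms * e_sens
    elif task == "estroop":
        shift_ms[emo == NEGATIVE] += rt_cfg.estroop_neg_sens_slope_ms * e_sens
    log_rt = mu + rt_cfg.resid_sd * rng.standard_normal(n)
    rt = np.maximum(np.exp(log_rt) + shift_ms, 1.0)

    lapse = rng.random(n) < rt_cfg.lapse_prob

    responded = np.zeros(n, bool)
    correct = np.zeros(n, bool)
    timeout = np.zeros(n, bool)
    rt_out = np.full(n, np.nan)

    if task == "eflanker":
        dist = cond["distractor_emotion"].to_numpy(object)
        incong = emo != dist
        logit = (acc_cfg.eflanker_base + acc_cfg.age_slope * age_c + subj_v
                 - emotional * (acc_cfg.emo_shift
                                + acc_cfg.emo_sens_slope * e_sens
                                + acc_cfg.emo_adhd_slope * impul)
                 - incong * (acc_cfg.incong_shift + acc_cfg.incong_adhd_slope * impul))
        choice_ok = rng.random(n) < _sigmoid(logit)
        responded = ~lapse
        timeout = lapse
        correct = responded & choice_ok
        rt_out[responded] = rt[responded]
    else:
        deadline = design.response_deadline_ms
        # go trials: a touch happens unless the child lapses or is too slow;
        # most would-be-late responses are rushed in just under the deadline
        go = is_target
        too_slow = rt > deadline
        rushed = too_slow & (rng.random(n) < rt_cfg.rush_prob)
        rt = np.where(rushed, deadline - rng.uniform(0.0, 300.0, n), rt)
        too_slow &= ~rushed
        responded[go] = (~lapse & ~too_slow)[go]
        timeout[go] = (lapse | too_slow)[go]
        correct[go] = responded[go]
        rt_out[go & responded] = rt[go & responded]
        # no-go trials: commission errors from the withhold model
        nogo = ~is_target
        if task == "egonogo":
            logit = (acc_cfg.egonogo_nogo_base + acc_cfg.age_slope * age_c + subj_v
                     - (emo == POSITIVE) * acc_cfg.egonogo_pos_shift
                     - impul * (acc_cfg.nogo_adhd_slope
                                + (emo == POSITIVE) * acc_cfg.nogo_adhd_pos_slope)
                     - (emo == POSITIVE) * acc_cfg.nogo_sens_pos_slope * e_sens)
        else:
            logit = (acc_cfg.estroop_nogo_base + acc_cfg.age_slope * age_c + subj_v
                     - (emo == POSITIVE) * acc_cfg.estroop_pos_shift
                     - (emo == NEGATIVE) * acc_cfg.estroop_neg_shift
                     - impul * acc_cfg.estroop_nogo_adhd_slope
                     - emotional * acc_cfg.estroop_nogo_sens_slope * e_sens)
        withheld = rng.random(n) < _sigmoid(logit)
        commission = nogo & ~withheld & ~lapse
        responded[commission] = True
        correct[nogo] = ~commission[nogo]
        # commission touches land within the stimulus window
        window = design.nontarget_window_ms or 1500.0
        rt_out[commission] = rng.uniform(300.0, window, commission.sum())

    out = pd.DataFrame(
        {
            "participant_id": str(participant["participant_id"]),
            "task": task,
            "block": cond["block"].to_numpy(int),
            "trial_index": cond["trial_index"].to_numpy(int),
            "target_emotion": emo,
            "distractor_emotion": cond["distractor_emotion"].to_numpy(object),
            "color": cond["color"].to_numpy(object),
            "is_target": is_target,
            "responded": responded,
            "rt_ms": rt_out,
            "correct": correct,
            "timeout": timeout,
        }
    )
    return out[TRIAL_COLUMNS]


def _apply_dropout(
    session: pd.DataFrame, rng: np.random.Generator, threshold: int
) -> pd.DataFrame:
    """Disengage from a random main-phase trial onward (child stops touching).

    The start is chosen so that at least ``threshold`` response-required
    trials remain, guaranteeing a detectable miss run.
    """
    session = session.copy()
    main = session.index[session["block"] > 0]
    required = session.loc[main, "is_target"].to_numpy(bool)
    # latest possible start leaving `threshold` required trials
    req_positions = np.flatnonzero(required)
    if len(req_positions) < threshold:
        start_pos = 0
    else:
        latest = req_positions[len(req_positions) - threshold]
        start_pos = int(rng.integers(0, latest + 1))
    idx = main[start_pos:]
    session.loc[idx, "responded"] = False
    session.loc[idx, "rt_ms"] = np.nan
    req = session.loc[idx, "is_target"].to_numpy(bool)
    session.loc[idx, "timeout"] = req
    session.loc[idx, "correct"] = ~req  # withheld no-go trials score correct
    return session


@dataclass
class CohortData:
    """A simulated cohort: trial table, participant table, latent traits."""

    trials: pd.DataFrame
    participants: pd.DataFrame
    traits: pd.DataFrame
    config: SimConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "trials": write_trials(self.trials, out / "trials.csv"),
            "participants": write_participants(self.participants, out / "participants.csv"),
        }
        self.config.to_json(out / "sim_config.json")
        return paths


def simulate_cohort(
    config: SimConfig,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> CohortData:
    """Simulate the full cohort; optionally write trials/participants CSVs."""
    if seed is None:
        seed = config.seed
    root_ss = np.random.SeedSequence(seed)
    part_ss, session_ss, dropout_ss = root_ss.spawn(3)

    participants, traits = sample_participants(config, np.random.default_rng(part_ss))
    session_rngs = [np.random.default_rng(s) for s in session_ss.spawn(
        config.n_participants * len(TASKS))]
    dropout_rng = np.random.default_rng(dropout_ss)

    frames = []
    k = 0
    for i in range(config.n_participants):
        participant = participants.iloc[i]
        trait_row = traits.iloc[i]
        for task in TASKS:
            rng = session_rngs[k]
            k += 1
            schedule = make_schedule(task, rng)
            session = simulate_session(participant, trait_row, schedule, config, rng)
            if dropout_rng.random() < config.dropout_prob.get(task, 0.0):
                session = _apply_dropout(session, dropout_rng, config.dropout_threshold)
            frames.append(session)
    trials = pd.concat(frames, ignore_index=True)

    cohort = CohortData(trials=trials, participants=participants,
                        traits=traits, config=config)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
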