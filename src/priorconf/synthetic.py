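"""Synthetic dual-decision experiment generator.

Emulates the trial structure of the two dual-decision experiments: per trial
a lead and a target random-dot stimulus, the rule that a correct lead
response implies a rightward target, three coherence levels (L, M, H)
combined into Stronger-Lead / Stronger-Target conditions at three posterior
levels, adaptive staircasing of the coherence levels on the prior-free lead
decisions, and a prior-free control task used for psychometric calibration.

Main-task structure: 36-trial blocks in which the six (posterior level x
condition) cells each appear six times with balanced lead directions;
10 blocks per session, two sessions, i.e. 720 main trials per participant.
Control task: 90 single decisions per session at six fixed coherences
(30 per coherence across the two sessions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .observer import ObserverParams, simulate_trials

__all__ = [
    "StaircaseState",
    "ExperimentDesign",
    "staircase_update",
    "run_staircase",
    "build_design",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "read_external_table",
]

BLOCK_SIZE = 36
CONTROL_COHERENCES = (0.05, 0.10, 0.12, 0.15, 0.20, 0.30)
CONTROL_TRIALS_PER_COHERENCE = 30  # per participant, across sessions

#: condition cells: posterior level -> {condition -> (lead level, target level)}
CONDITION_CELLS = {
    "L_post": {"stronger_lead": ("M", "L"), "stronger_target": ("L", "M")},
    "M_post": {"stronger_lead": ("H", "L"), "stronger_target": ("L", "H")},
    "H_post": {"stronger_lead": ("H", "M"), "stronger_target": ("M", "H")},
}

MAIN_COLUMNS = [
    "participant", "session", "block", "trial",
    "posterior_level", "condition",
    "lead_level", "target_level", "lead_dir", "target_dir",
    "lead_coherence", "target_coherence",
    "lead_choice", "target_choice", "lead_correct", "target_correct",
    "conf_report", "r_lead", "r_target", "conf_model",
]


@dataclass
class StaircaseState:
    """One transformed up-down staircase.

    2-down-1-up converges to ~70.7% correct, 3-down-1-up to ~79.4%.
    The yoked rule tracks another staircase minus 5 percentage points of
    coherence and never updates itself.
    """

    rule: str = "two_down_one_up"  # two_down_one_up | three_down_one_up | yoked_minus_5pts
    coherence: float = 0.15
    consecutive_correct: int = 0
    step: float = 0.01
    bounds: tuple[float, float] = (0.01, 0.90)

    @property
    def n_down(self) -> int:
        return {"two_down_one_up": 2, "three_down_one_up": 3}[self.rule]


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Return the staircase state after one prior-free decision.

    Down (harder) after ``n_down`` consecutive correct responses; up (easier)
    after any error; the consecutive-correct counter resets after any step.
    Coherence saturates at the bounds.
    """
    if state.rule == "yoked_minus_5pts":
        return state  # yoked staircases never update on their own
    lo, hi = state.bounds
    coh = state.coherence
    if correct:
        streak = state.consecutive_correct + 1
        if streak >= state.n_down:
            return StaircaseState(state.rule, max(lo, coh - state.step), 0,
                                  state.step, state.bounds)
        return StaircaseState(state.rule, coh, streak, state.step, state.bounds)
    return StaircaseState(state.rule, min(hi, coh + state.step), 0,
                          state.step, state.bounds)


def run_staircase(params: ObserverParams, rule: str, n_trials: int,
                  seed=0, start: float = 0.15, step: float = 0.01,
                  bounds: tuple[float, float] = (0.01, 0.90)) -> pd.DataFrame:
    """Drive one staircase with prior-free single decisions of an observer.

    Each trial presents a stimulus of the current coherence in a random
    direction; the observer's response (internal noise, bias, lapse) feeds
    the staircase. Returns per-trial coherence and correctness, e.g. for
    checking the asymptotic percent correct the rule converges to
    (~70.7% for 2-down-1-up, ~79.4% for 3-down-1-up).
    """
    rng = np.random.default_rng(seed)
    state = StaircaseState(rule, start, step=step, bounds=bounds)
    rows = []
    for t in range(n_trials):
        direction = 1 if rng.random() < 0.5 else -1
        s = (direction * state.coherence - params.bias) / params.sigma
        r = rng.normal(s, 1.0)
        choice = 1 if r > 0 else -1
        if params.lapse > 0 and rng.random() < params.lapse:
            choice = 1 if rng.random() < 0.5 else -1
        correct = choice == direction
        rows.append((t + 1, state.coherence, direction, choice, correct))
        state = staircase_update(state, correct)
    return pd.DataFrame(rows, columns=["trial", "coherence", "direction",
                                       "choice", "correct"])


def yoked_coherence(medium_coherence: float, offset: float = 0.05,
                    floor: float = 0.01) -> float:
    """Low-level coherence: 5 percentage points below the medium staircase."""
    return max(floor, medium_coherence - offset)


@dataclass
class ExperimentDesign:
    """Sizes and schedule of one simulated experiment."""

    n_participants: int = 20
    sessions: int = 2
    blocks_per_session: int = 10
    trials_per_block: int = BLOCK_SIZE
    medium_start: float = 0.15
    high_start: float = 0.15
    staircase_step: float = 0.01
    staircase_bounds: tuple[float, float] = (0.01, 0.90)
    dropout_rate: float = 0.0  # random trial dropout hook (robustness tests)

    @property
    def trials_per_session(self) -> int:
        return self.blocks_per_session * self.trials_per_block

    @property
    def trials_per_participant(self) -> int:
        return self.sessions * self.trials_per_session


def build_design(n_trials_total: int, seed) -> pd.DataFrame:
    """Counterbalanced trial slots: (posterior level, condition, lead dir).

    Within each 36-trial block every (posterior level x condition) cell
    appears 6 times with 3 rightward and 3 leftward lead stimuli; order is
    shuffled with the given seed.
    """
    if n_trials_total % BLOCK_SIZE != 0:
        raise ValueError(
            f"n_trials_total must be divisible by {BLOCK_SIZE}, got {n_trials_total}"
        )
    rng = np.random.default_rng(seed)
    cells = [
        (post, cond, lead_dir)
        for post in CONDITION_CELLS
        for cond in ("stronger_lead", "stronger_target")
        for lead_dir in (1, -1)
        for _ in range(3)
    ]  # 36 slots per block
    rows = []
    for block in range(n_trials_total // BLOCK_SIZE):
        order = rng.permutation(len(cells))
        for k, idx in enumerate(order):
            post, cond, lead_dir = cells[idx]
            rows.append((block, k, post, cond, lead_dir))
    return pd.DataFrame(
        rows, columns=["block", "trial_in_block", "posterior_level", "condition",
                       "lead_dir"]
    )


def _simulate_participant(
    participant: str,
    params: ObserverParams,
    design: ExperimentDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Run one participant through all sessions with live staircases."""
    medium = StaircaseState("two_down_one_up", design.medium_start,
                            step=design.staircase_step, bounds=design.staircase_bounds)
    high = StaircaseState("three_down_one_up", design.high_start,
                          step=design.staircase_step, bounds=design.staircase_bounds)
    rows = []
    for session in range(1, design.sessions + 1):
        slots = build_design(design.trials_per_session, rng)
        for slot in slots.itertuples(index=False):
            level_coh = {
                "M": medium.coherence,
                "H": high.coherence,
                "L": yoked_coherence(medium.coherence),
            }
            post = slot.posterior_level
            lead_level, target_level = CONDITION_CELLS[post][slot.condition]
            lead_coh = level_coh[lead_level]
            target_coh = level_coh[target_level]

            sim = simulate_trials(
                params,
                np.array([slot.lead_dir]),
                np.array([lead_coh]),
                np.array([target_coh]),
                rng,
            )
            lead_correct = bool(sim["lead_correct"][0])
            # staircases are driven by the prior-free lead decisions
            if lead_level == "M":
                medium = staircase_update(medium, lead_correct)
            elif lead_level == "H":
                high = staircase_update(high, lead_correct)

            rows.append((
                participant, session, int(slot.block) + 1, int(slot.trial_in_block) + 1,
                post, slot.condition, lead_level, target_level,
                int(slot.lead_dir), int(sim["target_dir"][0]),
                lead_coh, target_coh,
                int(sim["lead_choice"][0]), int(sim["target_choice"][0]),
                lead_correct, bool(sim["target_correct"][0]),
                float(sim["conf_report"][0]),
                float(sim["r_lead"][0]), float(sim["r_target"][0]),
                float(sim["conf_model"][0]),
            ))
    df = pd.DataFrame(rows, columns=MAIN_COLUMNS)
    if design.dropout_rate > 0:
        keep = rng.random(len(df)) >= design.dropout_rate
        df = df.loc[keep].reset_index(drop=True)
    return df


def _simulate_control(
    participant: str,
    params: ObserverParams,
    design: ExperimentDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Prior-free single decisions at the six fixed control coherences."""
    per_session = CONTROL_TRIALS_PER_COHERENCE // design.sessions
    rows = []
    for session in range(1, design.sessions + 1):
        cohs = np.repeat(CONTROL_COHERENCES, per_session)
        dirs = rng.choice([-1, 1], size=cohs.size)
        order = rng.permutation(cohs.size)
        cohs, dirs = cohs[order], dirs[order]
        s = (dirs * cohs - params.bias) / params.sigma
        r = rng.normal(s, 1.0)
        choice = np.where(r > 0, 1, -1)
        if params.lapse > 0:
            flip = rng.random(cohs.size) < params.lapse
            choice = np.where(flip, rng.choice([-1, 1], size=cohs.size), choice)
        for k in range(cohs.size):
            rows.append((participant, session, k + 1, int(dirs[k]), float(cohs[k]),
                         int(choice[k]), bool(choice[k] == dirs[k])))
    return pd.DataFrame(
        rows,
        columns=["participant", "session", "trial", "direction", "coherence",
                 "choice", "correct"],
    )


def generate_dataset(
    params_per_participant: Sequence[ObserverParams],
    design: ExperimentDesign | None = None,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (main-task table, control-task table).

    Deterministic given the seed: each participant consumes an independent
    child stream spawned from the top-level seed.
    """
    design = design or ExperimentDesign(n_participants=len(params_per_participant))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(params_per_participant))
    mains, controls = [], []
    for i, (params, child) in enumerate(zip(params_per_participant, children)):
        pid = f"sim{i + 1:03d}"
        rng = np.random.default_rng(child)
        mains.append(_simulate_participant(pid, params, design, rng))
        controls.append(_simulate_control(pid, params, design, rng))
    return (pd.concat(mains, ignore_index=True),
            pd.concat(controls, ignore_index=True))


# ---------------------------------------------------------------------------
# Plain-text IO
# ---------------------------------------------------------------------------

def write_dataset(
    out_dir: str | Path,
    main: pd.DataFrame,
    control: pd.DataFrame,
    params_per_participant: Sequence[ObserverParams],
    seed,
    extra_manifest: dict | None = None,
) -> None:
    """Write trial tables as TSV plus a JSON manifest of true parameters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    main.to_csv(out_dir / "main_trials.tsv", sep="\t", index=False)
    control.to_csv(out_dir / "control_trials.tsv", sep="\t", index=False)
    manifest = {
        "seed": seed,
        "participants": {
            f"sim{i + 1:03d}": asdict(p) for i, p in enumerate(params_per_participant)
        },
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_dataset(out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    out_dir = Path(out_dir)
    main = pd.read_csv(out_dir / "main_trials.tsv", sep="\t")
    control = pd.read_csv(out_dir / "control_trials.tsv", sep="\t")
    return main, control


#: default column mapping for externally deposited trial tables
DEFAULT_COLUMN_MAP = {
    "participant": "participant",
    "session": "session",
    "lead_dir": "lead_dir",
    "target_dir": "target_dir",
    "lead_coherence": "lead_coherence",
    "target_coherence": "target_coherence",
    "lead_choice": "lead_choice",
    "target_choice": "target_choice",
    "conf_report": "conf_report",
}


def read_external_table(
    path: str | Path,
    column_map: dict | None = None,
    sep: str = ",",
    confidence_scale: float = 100.0,
) -> pd.DataFrame:
    """Read a deposited trial table into the internal column layout.

    ``column_map`` maps internal names to the file's column names. Confidence
    reported on a 50-100 scale is rescaled to [0.5, 1].
    """
    column_map = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    raw = pd.read_csv(path, sep=sep)
    df = pd.DataFrame({internal: raw[external]
                       for internal, external in column_map.items()
                       if external in raw.columns})
    if "conf_report" in df and df["conf_report"].max() > 1.5:
        df["conf_report"] = df["conf_report"] / confidence_scale
    for col in ("lead_correct", "target_correct"):
        if col not in df and {"lead_dir", "lead_choice"} <= set(df.columns):
            df["lead_correct"] = df["lead_dir"] == df["lead_choice"]
            df["target_correct"] = df["target_dir"] == df["target_choice"]
    return df
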