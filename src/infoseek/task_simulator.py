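"""Behavioural simulation of the information-seeking card-lottery task.

A session is 7 blocks of 16 trials.  On each trial the agent chooses
between an informative and a non-informative five-card stimulus at a
variable cost, watches the five cards, and then sees the lottery outcome
(20-cent win or 0-cent loss).  Roughly 10% of trials are catch trials in
which one card is replaced by a white X requiring a timed button press;
failing more than two catch trials fails the attention check.

Choices come from a logistic value-vs-cost agent:
``Pr(informative) = logistic(choice_noise * (info_value - cost))``,
so preference for information declines monotonically with its cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import task_model as tm

WIN = "win"
LOSS = "loss"

#: Cost levels in cents, uniformly interleaved across the session.
DEFAULT_COST_LEVELS = (0, 1, 2)


@dataclass(frozen=True)
class AgentParams:
    """Logistic choice agent.

    ``info_value`` is the subjective value of advance information in
    cents; ``choice_noise`` (inverse cents) scales the value-cost
    difference inside the logistic; ``catch_compliance`` is the
    probability of responding to a catch card in time.
    """

    info_value: float = 0.5
    choice_noise: float = 1.5
    catch_compliance: float = 0.98


@dataclass(frozen=True)
class TaskParams:
    """Session geometry and economy (defaults follow the task protocol)."""

    n_blocks: int = 7
    trials_per_block: int = 16
    cards_total: int = 5
    majority: int = 3
    win_amount: float = 20.0
    cost_levels: Sequence[float] = DEFAULT_COST_LEVELS
    catch_rate: float = 0.10
    catch_penalty: float = 100.0  # cents per failed catch trial
    winnings_cap: float = 1500.0  # cents, payment cap on reported winnings

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class Trial:
    block: int
    trial: int
    cost: float
    choice: str
    card_sequence: tuple[str, ...]
    is_catch: bool
    catch_position: int  # -1 when not a catch trial
    catch_responded: bool
    outcome: str
    payoff: float  # cents


@dataclass(frozen=True)
class Session:
    participant: str
    trials: tuple[Trial, ...]
    catch_failures: int
    total_winnings: float  # dollars, after catch penalties, uncapped
    reported_winnings: float  # dollars, capped at the payment cap
    agent: AgentParams
    task: TaskParams
    excluded: bool = False


def simulate_choice(
    cost: float, agent: AgentParams, rng: np.random.Generator
) -> str:
    """Stochastic informative/non-informative choice at the given cost."""
    if cost < 0:
        raise ValueError("cost must be non-negative")
    p_info = expit(agent.choice_noise * (agent.info_value - cost))
    return tm.INFORMATIVE if rng.random() < p_info else tm.NON_INFORMATIVE


def _cost_schedule(task: TaskParams, rng: np.random.Generator) -> np.ndarray:
    levels = np.asarray(task.cost_levels, dtype=float)
    reps = int(np.ceil(task.n_trials / len(levels)))
    costs = np.tile(levels, reps)[: task.n_trials]
    rng.shuffle(costs)
    return costs


def simulate_session(
    participant: str,
    agent: AgentParams | None = None,
    task: TaskParams | None = None,
    seed: int | np.random.Generator = 0,
) -> Session:
    """Simulate one full session, reproducibly for a given seed.

    Informative-choice outcomes are the majority colour of the drawn
    sequence; non-informative outcomes are an independent fair draw.
    The information cost is deducted on informative-choice wins only.
    """
    agent = agent or AgentParams()
    task = task or TaskParams()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    costs = _cost_schedule(task, rng)
    trials = []
    catch_failures = 0
    winnings = 0.0
    for i in range(task.n_trials):
        cost = float(costs[i])
        choice = simulate_choice(cost, agent, rng)
        seq = tuple(
            tm.BLACK if rng.random() < 0.5 else tm.RED
            for _ in range(task.cards_total)
        )
        if choice == tm.INFORMATIVE:
            won = sum(c == tm.BLACK for c in seq) >= task.majority
        else:
            won = rng.random() < 0.5
        is_catch = rng.random() < task.catch_rate
        catch_position = int(rng.integers(task.cards_total)) if is_catch else -1
        catch_responded = bool(
            rng.random() < agent.catch_compliance
        ) if is_catch else False
        if is_catch and not catch_responded:
            catch_failures += 1
        if won:
            payoff = task.win_amount - (cost if choice == tm.INFORMATIVE else 0.0)
        else:
            payoff = 0.0
        winnings += payoff
        trials.append(
            Trial(
                block=i // task.trials_per_block,
                trial=i,
                cost=cost,
                choice=choice,
                card_sequence=seq,
                is_catch=is_catch,
                catch_position=catch_position,
                catch_responded=catch_responded,
                outcome=WIN if won else LOSS,
                payoff=payoff,
            )
        )
    winnings -= catch_failures * task.catch_penalty
    return Session(
        participant=participant,
        trials=tuple(trials),
        catch_failures=catch_failures,
        total_winnings=winnings / 100.0,
        reported_winnings=min(winnings, task.winnings_cap) / 100.0,
        agent=agent,
        task=task,
        excluded=False,
    )


def simulate_cohort(
    n_participants: int = 20,
    seed: int = 0,
    agent: AgentParams | None = None,
    task: TaskParams | None = None,
    info_value_sd: float = 0.75,
) -> list[Session]:
    """Simulate a cohort with participant-level variation in info value."""
    base = agent or AgentParams()
    ss = np.random.SeedSequence(seed)
    sessions = []
    for i, child in enumerate(ss.spawn(n_participants)):
        rng = np.random.default_rng(child)
        value = base.info_value + info_value_sd * rng.standard_normal()
        sessions.append(
            simulate_session(
                participant=f"sub-{i + 1:02d}",
                agent=replace(base, info_value=value),
                task=task,
                seed=rng,
            )
        )
    return sessions


def apply_attention_exclusion(
    sessions: Sequence[Session], max_failures: int = 2
) -> list[Session]:
    """Flag sessions failing more than ``max_failures`` catch trials."""
    return [
        replace(s, excluded=s.catch_failures > max_failures) for s in sessions
    ]


def behavioural_summary(sessions: Sequence[Session]) -> dict:
    """Preference-by-cost table, per-participant cost slopes, group stats.

    Returns a dict with ``preference`` (participant x cost long table of
    Pr(informative)), ``slopes`` (per-participant OLS slope of preference
    on cost), and ``overall`` (per-participant Pr(informative) with group
    mean and range).
    """
    included = [s for s in sessions if not s.excluded]
    if not included:
        raise ValueError("all sessions excluded: no behavioural summary")
    pref_rows, slope_rows, overall_rows = [], [], []
    for s in included:
        df = pd.DataFrame(
            {
                "cost": [t.cost for t in s.trials],
                "informative": [
                    float(t.choice == tm.INFORMATIVE) for t in s.trials
                ],
            }
        )
        by_cost = df.groupby("cost")["informative"].mean()
        for cost, p in by_cost.items():
            pref_rows.append(
                {"participant": s.participant, "cost": cost, "pr_informative": p}
            )
        slope = float(np.polyfit(by_cost.index.values, by_cost.values, 1)[0])
        slope_rows.append({"participant": s.participant, "slope": slope})
        overall_rows.append(
            {
                "participant": s.participant,
                "pr_informative": float(df["informative"].mean()),
            }
        )
    overall = pd.DataFrame(overall_rows)
    return {
        "preference": pd.DataFrame(pref_rows),
        "slopes": pd.DataFrame(slope_rows),
        "overall": overall,
        "group_mean": float(overall["pr_informative"].mean()),
        "group_range": (
            float(overall["pr_informative"].min()),
            float(overall["pr_informative"].max()),
        ),
    }


@dataclass(frozen=True)
class TimingSpec:
    """Event timing in seconds (spacing >= half the default epoch window)."""

    lead_in: float = 2.0
    card_interval: float = 1.0
    outcome_delay: float = 1.0
    inter_trial: float = 1.5
    lead_out: float = 2.0
    event_duration: float = 0.5


def session_events(
    session: Session, timing: TimingSpec | None = None
) -> pd.DataFrame:
    """Per-event table (cards + outcome screens) with model annotations.

    Card events carry RPE/I/IPE labels from the task model, plus
    ``pseudo_*`` sign labels computed as though the stimulus had been
    informative (for informative trials these coincide with the true
    labels).  Catch trials contribute no card events: the hidden card
    takes the belief trajectory off the standard state graph, so their
    card epochs are not analysed.  Outcome-screen events are kept for
    all trials.
    """
    timing = timing or TimingSpec()
    task = session.task
    rows = []
    t = timing.lead_in
    for trial in session.trials:
        informative = trial.choice == tm.INFORMATIVE
        # walk the sequence as-if informative for the pseudo labels
        pseudo_state = tm.BeliefState(task.cards_total, 0, 0, tm.INFORMATIVE)
        true_state = tm.BeliefState(
            task.cards_total, 0, 0,
            tm.INFORMATIVE if informative else tm.NON_INFORMATIVE,
        )
        for idx, colour in enumerate(trial.card_sequence):
            onset = t + idx * timing.card_interval
            if not trial.is_catch:
                ev = tm.make_card_event(
                    true_state, colour, task.win_amount, task.majority
                )
                pseudo = tm.make_card_event(
                    pseudo_state, colour, task.win_amount, task.majority
                )
                rows.append(
                    {
                        "onset": onset,
                        "duration": timing.event_duration,
                        "event_class": "card",
                        "trial": trial.trial,
                        "card_index": idx,
                        "stimulus_kind": true_state.stimulus_kind,
                        "cost": trial.cost,
                        "colour": colour,
                        "pr_win_prior": tm.win_probability(
                            true_state, task.majority
                        ),
                        "pr_win_post": tm.win_probability(
                            ev.posterior, task.majority
                        ),
                        "rpe": ev.rpe,
                        "info": ev.info,
                        "expected_info": ev.expected_info,
                        "ipe": ev.ipe,
                        "rpe_sign": ev.rpe_sign,
                        "ipe_sign": ev.ipe_sign,
                        "info_sign": ev.info_sign,
                        "pseudo_rpe_sign": pseudo.rpe_sign,
                        "pseudo_ipe_sign": pseudo.ipe_sign,
                        "pseudo_info_sign": pseudo.info_sign,
                        "outcome": "",
                    }
                )
                true_state = ev.posterior
                pseudo_state = pseudo.posterior
        outcome_onset = (
            t
            + (task.cards_total - 1) * timing.card_interval
            + timing.outcome_delay
        )
        rows.append(
            {
                "onset": outcome_onset,
                "duration": timing.event_duration,
                "event_class": "outcome_screen",
                "trial": trial.trial,
                "card_index": -1,
                "stimulus_kind": (
                    tm.INFORMATIVE if informative else tm.NON_INFORMATIVE
                ),
                "cost": trial.cost,
                "colour": "",
                "pr_win_prior": np.nan,
                "pr_win_post": np.nan,
                "rpe": np.nan,
                "info": np.nan,
                "expected_info": np.nan,
                "ipe": np.nan,
                "rpe_sign": "",
                "ipe_sign": "",
                "info_sign": "",
                "pseudo_rpe_sign": "",
                "pseudo_ipe_sign": "",
                "pseudo_info_sign": "",
                "outcome": trial.outcome,
            }
        )
        t = outcome_onset + timing.inter_trial
    return pd.DataFrame(rows)


def write_bids_events(
    session: Session,
    tsv_path,
    json_path=None,
    timing: TimingSpec | None = None,
) -> pd.DataFrame:
    """Export a session as a BIDS-style events TSV plus JSON sidecar."""
    events = session_events(session, timing)
    events = events.assign(
        trial_type=events["event_class"].str.cat(
            events["stimulus_kind"], sep="/"
        )
    )
    cols = ["onset", "duration", "trial_type"] + [
        c for c in events.columns if c not in ("onset", "duration", "trial_type")
    ]
    events[cols].to_csv(tsv_path, sep="\t", index=False, na_rep="n/a")
    if json_path is not None:
        sidecar = {
            "participant": session.participant,
            "catch_failures": session.catch_failures,
            "excluded": session.excluded,
            "total_winnings_dollars": session.total_winnings,
            "reported_winnings_dollars": session.reported_winnings,
            "agent": {
                "info_value": session.agent.info_value,
                "choice_noise": session.agent.choice_noise,
                "catch_compliance": session.agent.catch_compliance,
            },
            "task": {
                "n_blocks": session.task.n_blocks,
                "trials_per_block": session.task.trials_per_block,
                "cost_levels": list(session.task.cost_levels),
                "win_amount": session.task.win_amount,
                "catch_rate": session.task.catch_rate,
            },
        }
        with open(json_path, "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)
    return events
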