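"""Computational variables of the five-card lottery task.

An informative stimulus reveals five cards one at a time; a majority of
black cards (>= 3 of 5 by default) means the lottery is won.  Each card
draw updates the belief over the win outcome, and from that update we
derive, per card:

* the reward prediction error (RPE), ``win_amount * (Pr(win)_post -
  Pr(win)_prior)`` in cents;
* the information content ``I = H(Pr(win)_prior) - H(Pr(win)_post)`` in
  bits, positive when the draw increases certainty about the outcome;
* the expected information ``E[I]``, the equiprobable average of the
  information the next card could convey; and
* the information prediction error ``IPE = I - E[I]``.

Non-informative stimuli are perceptually identical but carry no outcome
information: their win probability is 0.5 at every state, so RPE, I and
IPE are exactly zero.

Win probabilities for the fair (bias 0.5) task are computed in exact
rational arithmetic; entropies are binary entropies in bits.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Sequence, Union

import pandas as pd

BLACK = "black"
RED = "red"
COLOURS = (BLACK, RED)

INFORMATIVE = "informative"
NON_INFORMATIVE = "non_informative"

POS = "pos"
NEG = "neg"
ZERO = "zero"

#: Default tolerance below which a prediction error counts as exactly zero.
#: Every zero in the fair five-card task is analytically exact; the
#: tolerance only guards floating-point noise.
ZERO_TOLERANCE = 1e-9

Number = Union[int, float, Fraction]


def _default_majority(cards_total: int) -> int:
    return cards_total // 2 + 1


@dataclass(frozen=True)
class BeliefState:
    """Belief over the lottery outcome after some cards have been seen.

    Parameters
    ----------
    cards_total
        Number of cards in the stimulus (5 in the task).
    cards_drawn
        Cards revealed so far.
    n_black
        Black cards among those revealed.
    stimulus_kind
        ``"informative"`` or ``"non_informative"``.
    """

    cards_total: int = 5
    cards_drawn: int = 0
    n_black: int = 0
    stimulus_kind: str = INFORMATIVE

    def __post_init__(self) -> None:
        if self.cards_total < 1:
            raise ValueError("cards_total must be >= 1")
        if not 0 <= self.cards_drawn <= self.cards_total:
            raise ValueError("cards_drawn must lie in [0, cards_total]")
        if not 0 <= self.n_black <= self.cards_drawn:
            raise ValueError("n_black must lie in [0, cards_drawn]")
        if self.stimulus_kind not in (INFORMATIVE, NON_INFORMATIVE):
            raise ValueError(f"unknown stimulus_kind {self.stimulus_kind!r}")

    @property
    def cards_remaining(self) -> int:
        return self.cards_total - self.cards_drawn

    @property
    def n_red(self) -> int:
        return self.cards_drawn - self.n_black

    @property
    def is_terminal(self) -> bool:
        return self.cards_drawn == self.cards_total

    def successor(self, colour: str) -> "BeliefState":
        """State after one more card of the given colour."""
        if colour not in COLOURS:
            raise ValueError(f"unknown colour {colour!r}")
        if self.is_terminal:
            raise ValueError("terminal state has no successors")
        return replace(
            self,
            cards_drawn=self.cards_drawn + 1,
            n_black=self.n_black + (1 if colour == BLACK else 0),
        )


def required_black(n_black: int, majority: int = 3) -> int:
    """Additional black cards still needed for a black majority.

    ``max(majority - n_black, 0)``; negative inputs are rejected.
    """
    if n_black < 0:
        raise ValueError("n_black must be non-negative")
    if majority < 1:
        raise ValueError("majority must be >= 1")
    return max(majority - n_black, 0)


@lru_cache(maxsize=None)
def _pr_win_fair(n: int, n_req: int) -> Fraction:
    # Closed-form tail of the fair binomial: probability that at least
    # n_req of the n remaining cards are black.
    if n_req == 0:
        return Fraction(1)
    if n_req > n:
        return Fraction(0)
    below = sum(math.comb(n, k) for k in range(n_req))
    return 1 - Fraction(below, 2**n)


def win_probability_exact(state: BeliefState, majority: int | None = None) -> Fraction:
    """Win probability as an exact rational (fair card bias only)."""
    if state.stimulus_kind == NON_INFORMATIVE:
        return Fraction(1, 2)
    if majority is None:
        majority = _default_majority(state.cards_total)
    n_req = required_black(state.n_black, majority)
    return _pr_win_fair(state.cards_remaining, n_req)


def win_probability(
    state: BeliefState, majority: int | None = None, bias: float = 0.5
) -> float:
    """Probability of a win given the current belief state.

    Informative stimuli: probability that at least ``n_req`` of the
    remaining ``n`` cards are black, with per-card black probability
    ``bias``.  Non-informative stimuli: 0.5 at every state.
    """
    if state.stimulus_kind == NON_INFORMATIVE:
        return 0.5
    if bias == 0.5:
        return float(win_probability_exact(state, majority))
    if majority is None:
        majority = _default_majority(state.cards_total)
    n = state.cards_remaining
    n_req = required_black(state.n_black, majority)
    if n_req == 0:
        return 1.0
    if n_req > n:
        return 0.0
    return float(
        sum(
            math.comb(n, k) * bias**k * (1 - bias) ** (n - k)
            for k in range(n_req, n + 1)
        )
    )


def binary_entropy(p: Number) -> float:
    """Binary entropy H(p) in bits, with the convention 0*log2(0) = 0."""
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if p == 0.0 or p == 1.0:
        return 0.0
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)


def _check_transition(prior: BeliefState, posterior: BeliefState) -> None:
    ok = (
        posterior.cards_total == prior.cards_total
        and posterior.stimulus_kind == prior.stimulus_kind
        and posterior.cards_drawn == prior.cards_drawn + 1
        and posterior.n_black - prior.n_black in (0, 1)
    )
    if not ok:
        raise ValueError(f"{posterior} is not a legal successor of {prior}")


def information_content(
    prior: BeliefState, posterior: BeliefState, majority: int | None = None
) -> float:
    """Information conveyed by one card, in bits.

    Reduction of belief entropy, ``H(Pr(win)_prior) - H(Pr(win)_post)``:
    positive when the draw increases certainty about the outcome.
    """
    _check_transition(prior, posterior)
    if prior.stimulus_kind == NON_INFORMATIVE:
        return 0.0
    return binary_entropy(win_probability(prior, majority)) - binary_entropy(
        win_probability(posterior, majority)
    )


def expected_information(state: BeliefState, majority: int | None = None) -> float:
    """Expected information of the next card (equiprobable colour average)."""
    if state.is_terminal:
        raise ValueError("no cards remaining: expected information undefined")
    if state.stimulus_kind == NON_INFORMATIVE:
        return 0.0
    h_prior = binary_entropy(win_probability(state, majority))
    h_succ = [
        binary_entropy(win_probability(state.successor(c), majority)) for c in COLOURS
    ]
    return h_prior - 0.5 * (h_succ[0] + h_succ[1])


def reward_prediction_error(
    prior: BeliefState,
    posterior: BeliefState,
    win_amount: float = 20.0,
    majority: int | None = None,
) -> float:
    """RPE in cents: ``win_amount * (Pr(win)_post - Pr(win)_prior)``."""
    _check_transition(prior, posterior)
    if win_amount <= 0:
        raise ValueError("win_amount must be positive")
    if prior.stimulus_kind == NON_INFORMATIVE:
        return 0.0
    return win_amount * (
        win_probability(posterior, majority) - win_probability(prior, majority)
    )


def information_prediction_error(
    prior: BeliefState, posterior: BeliefState, majority: int | None = None
) -> float:
    """IPE in bits: information conveyed minus information expected."""
    _check_transition(prior, posterior)
    if prior.stimulus_kind == NON_INFORMATIVE:
        return 0.0
    return information_content(prior, posterior, majority) - expected_information(
        prior, majority
    )


def classify(value: float, zero_tolerance: float = ZERO_TOLERANCE) -> str:
    """Sign label for a prediction-error value: 'pos', 'neg' or 'zero'."""
    if abs(value) <= zero_tolerance:
        return ZERO
    return POS if value > 0 else NEG


@dataclass(frozen=True)
class CardEvent:
    """One card draw with its prediction-error annotations."""

    prior: BeliefState
    colour: str
    posterior: BeliefState
    rpe: float
    info: float
    expected_info: float
    ipe: float
    rpe_sign: str = field(default=ZERO)
    ipe_sign: str = field(default=ZERO)
    info_sign: str = field(default=ZERO)


def classify_event(
    event: CardEvent, zero_tolerance: float = ZERO_TOLERANCE
) -> CardEvent:
    """Return the event with sign labels recomputed from its numeric fields."""
    return replace(
        event,
        rpe_sign=classify(event.rpe, zero_tolerance),
        ipe_sign=classify(event.ipe, zero_tolerance),
        info_sign=classify(event.info, zero_tolerance),
    )


@lru_cache(maxsize=4096)
def make_card_event(
    prior: BeliefState,
    colour: str,
    win_amount: float = 20.0,
    majority: int | None = None,
    zero_tolerance: float = ZERO_TOLERANCE,
) -> CardEvent:
    """Compute the full annotated event for drawing ``colour`` at ``prior``."""
    posterior = prior.successor(colour)
    info = information_content(prior, posterior, majority)
    e_info = 0.0 if prior.stimulus_kind == NON_INFORMATIVE else expected_information(
        prior, majority
    )
    event = CardEvent(
        prior=prior,
        colour=colour,
        posterior=posterior,
        rpe=reward_prediction_error(prior, posterior, win_amount, majority),
        info=info,
        expected_info=e_info,
        ipe=info - e_info,
    )
    return classify_event(event, zero_tolerance)


@dataclass(frozen=True)
class StateGraph:
    """Complete annotated belief-state graph of the informative stimulus."""

    cards_total: int
    majority: int
    nodes: tuple[BeliefState, ...]
    edges: tuple[CardEvent, ...]

    def node_annotations(self) -> pd.DataFrame:
        rows = [
            {
                "cards_drawn": s.cards_drawn,
                "n_black": s.n_black,
                "pr_win": win_probability(s, self.majority),
                "entropy": binary_entropy(win_probability(s, self.majority)),
                "terminal": s.is_terminal,
            }
            for s in self.nodes
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        """JSON export (nodes, edges, annotations) for documentation/plots."""
        payload = {
            "cards_total": self.cards_total,
            "majority": self.majority,
            "nodes": self.node_annotations().to_dict(orient="records"),
            "edges": [
                {
                    "from": [e.prior.cards_drawn, e.prior.n_black],
                    "to": [e.posterior.cards_drawn, e.posterior.n_black],
                    "colour": e.colour,
                    "rpe": e.rpe,
                    "ipe": e.ipe,
                    "info": e.info,
                    "rpe_sign": e.rpe_sign,
                    "ipe_sign": e.ipe_sign,
                    "info_sign": e.info_sign,
                }
                for e in self.edges
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def enumerate_state_graph(
    cards_total: int = 5, majority: int | None = None, win_amount: float = 20.0
) -> StateGraph:
    """All reachable informative belief states and their card transitions."""
    if majority is None:
        majority = _default_majority(cards_total)
    if not 1 <= majority <= cards_total:
        raise ValueError("majority must lie in [1, cards_total]")
    nodes = tuple(
        BeliefState(cards_total, drawn, b)
        for drawn in range(cards_total + 1)
        for b in range(drawn + 1)
    )
    edges = tuple(
        make_card_event(s, colour, win_amount, majority)
        for s in nodes
        if not s.is_terminal
        for colour in COLOURS
    )
    return StateGraph(cards_total, majority, nodes, edges)


MAX_ORACLE_CARDS = 16


def exhaustive_oracle(
    cards_total: int = 5, majority: int | None = None, win_amount: float = 20.0
) -> pd.DataFrame:
    """Brute-force event table over every equiprobable card sequence.

    Win probabilities are obtained by frequency counting over all
    completions of the observed prefix (never via the closed-form tail
    sum), in exact rational arithmetic, so the table can serve as an
    independent oracle for the closed-form path.
    """
    if cards_total > MAX_ORACLE_CARDS:
        raise ValueError(
            f"cards_total={cards_total} exceeds the enumeration guard "
            f"({MAX_ORACLE_CARDS}); the oracle is 2^n in the card count"
        )
    if majority is None:
        majority = _default_majority(cards_total)

    @lru_cache(maxsize=None)
    def brute_pr_win(drawn: int, n_black: int) -> Fraction:
        n = cards_total - drawn
        wins = 0
        for completion in itertools.product((0, 1), repeat=n):
            if n_black + sum(completion) >= majority:
                wins += 1
        return Fraction(wins, 2**n)

    rows = []
    for seq_id, seq in enumerate(itertools.product(COLOURS, repeat=cards_total)):
        drawn, b = 0, 0
        for card_index, colour in enumerate(seq):
            p_prior = brute_pr_win(drawn, b)
            b_next = b + (1 if colour == BLACK else 0)
            p_post = brute_pr_win(drawn + 1, b_next)
            h_prior = binary_entropy(p_prior)
            info = h_prior - binary_entropy(p_post)
            # expected information over both brute-force successors
            e_info = h_prior - 0.5 * (
                binary_entropy(brute_pr_win(drawn + 1, b + 1))
                + binary_entropy(brute_pr_win(drawn + 1, b))
            )
            rows.append(
                {
                    "sequence": seq_id,
                    "card_index": card_index,
                    "colour": colour,
                    "cards_drawn_prior": drawn,
                    "n_black_prior": b,
                    "pr_win_prior": p_prior,
                    "pr_win_post": p_post,
                    "entropy_prior": h_prior,
                    "info": info,
                    "expected_info": e_info,
                    "rpe": win_amount * float(p_post - p_prior),
                    "ipe": info - e_info,
                }
            )
            drawn, b = drawn + 1, b_next
    return pd.DataFrame(rows)


EVENT_TABLE_COLUMNS = [
    "trial",
    "card_index",
    "stimulus_kind",
    "colour",
    "pr_win_prior",
    "pr_win_post",
    "rpe",
    "info",
    "expected_info",
    "ipe",
    "rpe_sign",
    "ipe_sign",
    "info_sign",
]


def events_to_frame(
    events: Iterable[CardEvent],
    trials: Sequence[int] | None = None,
    majority: int | None = None,
) -> pd.DataFrame:
    """Tabulate annotated card events in the canonical export layout."""
    events = list(events)
    if trials is None:
        trials = [0] * len(events)
    rows = []
    for trial, e in zip(trials, events):
        rows.append(
            {
                "trial": trial,
                "card_index": e.prior.cards_drawn,
                "stimulus_kind": e.prior.stimulus_kind,
                "colour": e.colour,
                "pr_win_prior": win_probability(e.prior, majority),
                "pr_win_post": win_probability(e.posterior, majority),
                "rpe": e.rpe,
                "info": e.info,
                "expected_info": e.expected_info,
                "ipe": e.ipe,
                "rpe_sign": e.rpe_sign,
                "ipe_sign": e.ipe_sign,
                "info_sign": e.info_sign,
            }
        )
    return pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS)


def write_event_table(frame: pd.DataFrame, path) -> None:
    """Write an event table as tab-separated values."""
    frame.to_csv(path, sep="\t", index=False)
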