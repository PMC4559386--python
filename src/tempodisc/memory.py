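"""Scoring of the episodic memory instruments.

Three scores are computed per participant:

* ``FNPA-PF`` — face-name paired-associates performance: hit proportion minus
  false-alarm proportion over the 20 intact and 20 recombined pairs, in [-1, 1].
* ``IGD-C1`` — autobiographical memory for personal events: events recalled
  (max 5 per each of 4 life episodes, so max 20) as a proportion of 20, plus
  the summed vividness/specificity/emotionality ratings (one rated event per
  episode, three 4-point scales scored 0-3, max 36) as a proportion of 36.
  Range [0, 2].
* ``IGD-C2`` — personal semantics (facts and dates): proportion of answered
  items answered "yes" plus the confidence ratings of the yes-answers as a
  proportion of their maximum (3 per yes-item). Range [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FNPA_N_CORRECT = 20
FNPA_N_FALSE = 20
C1_MAX_EVENTS = 20
C1_MAX_RATINGS = 36
C1_N_EPISODES = 4
C1_EVENTS_PER_EPISODE = 5
C1_RATING_MAX_PER_EPISODE = 9  # three 0-3 ratings of one event
C2_N_ITEMS = 64
C2_RATING_MAX = 3


def fnpa_pf(hits: int, false_alarms: int) -> float:
    """Hits minus false alarms, on the proportion scale (range [-1, 1])."""
    hits = int(hits)
    false_alarms = int(false_alarms)
    if not 0 <= hits <= FNPA_N_CORRECT:
        raise ValueError(f"hits must be in [0, {FNPA_N_CORRECT}], got {hits}")
    if not 0 <= false_alarms <= FNPA_N_FALSE:
        raise ValueError(
            f"false_alarms must be in [0, {FNPA_N_FALSE}], got {false_alarms}"
        )
    return hits / FNPA_N_CORRECT - false_alarms / FNPA_N_FALSE


def igd_c1(events_per_episode, episode_rating_sums) -> float:
    """Personal-events score: events/20 + ratings/36, in [0, 2].

    Parameters
    ----------
    events_per_episode : sequence of 4 ints
        Events recalled per life episode, each in [0, 5].
    episode_rating_sums : sequence of 4 ints
        Summed quality ratings (vividness + specificity + emotionality of the
        one rated event) per episode, each in [0, 9].
    """
    events = np.asarray(events_per_episode, dtype=float)
    ratings = np.asarray(episode_rating_sums, dtype=float)
    if events.shape != (C1_N_EPISODES,):
        raise ValueError(f"expected {C1_N_EPISODES} episode event counts")
    if ratings.shape != (C1_N_EPISODES,):
        raise ValueError(f"expected {C1_N_EPISODES} episode rating sums")
    if np.any(events < 0) or np.any(events > C1_EVENTS_PER_EPISODE):
        raise ValueError(f"event counts must be in [0, {C1_EVENTS_PER_EPISODE}]")
    if np.any(ratings < 0) or np.any(ratings > C1_RATING_MAX_PER_EPISODE):
        raise ValueError(f"rating sums must be in [0, {C1_RATING_MAX_PER_EPISODE}]")
    return float(events.sum() / C1_MAX_EVENTS + ratings.sum() / C1_MAX_RATINGS)


def igd_c2(answered: int, yes_count: int, confidence_sum: float) -> float:
    """Personal-semantics score: yes/answered + confidence proportion, in [0, 2].

    Confidence is rated 0-3 per yes-item, so the confidence proportion is
    ``confidence_sum / (3 * yes_count)`` (0 when nothing was answered yes).
    Items about inapplicable topics may be skipped, so ``answered`` can be
    below 64 but must be at least 1.
    """
    answered = int(answered)
    yes_count = int(yes_count)
    if not 1 <= answered <= C2_N_ITEMS:
        raise ValueError(f"answered must be in [1, {C2_N_ITEMS}], got {answered}")
    if not 0 <= yes_count <= answered:
        raise ValueError("yes_count must be in [0, answered]")
    max_conf = C2_RATING_MAX * yes_count
    if not 0 <= confidence_sum <= max(max_conf, 0):
        raise ValueError(f"confidence_sum must be in [0, {max_conf}]")
    conf_prop = confidence_sum / max_conf if yes_count > 0 else 0.0
    return yes_count / answered + float(conf_prop)


@dataclass
class FnpaResponses:
    hits: int
    false_alarms: int

    def score(self) -> float:
        return fnpa_pf(self.hits, self.false_alarms)


@dataclass
class IgdC1Responses:
    """Full C1 responses: per-episode event counts and the (4, 3) rating array."""

    events_per_episode: tuple
    ratings: tuple  # 4 episodes x 3 ratings, each 0-3

    def episode_rating_sums(self):
        ratings = np.asarray(self.ratings, dtype=float)
        if ratings.shape != (C1_N_EPISODES, 3):
            raise ValueError("ratings must be a 4x3 array")
        if np.any(ratings < 0) or np.any(ratings > 3):
            raise ValueError("each rating must be in [0, 3]")
        return ratings.sum(axis=1)

    def score(self) -> float:
        return igd_c1(self.events_per_episode, self.episode_rating_sums())


@dataclass
class IgdC2Responses:
    answered: int
    yes_count: int
    confidence_sum: float

    def score(self) -> float:
        return igd_c2(self.answered, self.yes_count, self.confidence_sum)


def score_memory_table(memory):
    """Score a raw-response table (one row per participant) into a copy with
    ``fnpa_pf``, ``igd_c1`` and ``igd_c2`` columns.

    Expected columns: ``fnpa_hits``, ``fnpa_fa``, ``c1_events_e1..e4``,
    ``c1_ratings_e1..e4``, ``c2_answered``, ``c2_yes``, ``c2_conf``.
    """
    scored = memory.copy()
    event_cols = [f"c1_events_e{i}" for i in range(1, 5)]
    rating_cols = [f"c1_ratings_e{i}" for i in range(1, 5)]
    scored["fnpa_pf"] = [
        fnpa_pf(h, f) for h, f in zip(memory["fnpa_hits"], memory["fnpa_fa"])
    ]
    scored["igd_c1"] = [
        igd_c1(ev, ra)
        for ev, ra in zip(
            memory[event_cols].to_numpy(), memory[rating_cols].to_numpy()
        )
    ]
    scored["igd_c2"] = [
        igd_c2(a, y, c)
        for a, y, c in zip(memory["c2_answered"], memory["c2_yes"], memory["c2_conf"])
    ]
    return scored
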