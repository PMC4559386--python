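"""Intertemporal choice task and face-name paired-associates (FNPA) layouts.

The choice task has 6 blocks of 18 binary trials. The later option is always
20 euros; the sooner option runs over 9 amounts (0 to 20 euros in 2.50 steps),
each presented twice per block. In blocks 1-4 the sooner option is available
"tomorrow" (encoded as a delay of 0 months) and the later option at 3, 6, 9 or
12 months; in blocks 5-6 the sooner option is itself delayed by 6 months with
the later option at 9 or 12 months. Trials offering 0 or 20 euros sooner have
a logically dominant option and serve as catch trials.

The FNPA task pairs 40 unique faces with names over 4 blocks; at retrieval,
half of the 10 pairs per block are shown intact and half recombined with
another name from the same block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sooner amounts in euros: 9 levels, 2.50-euro steps.
AMOUNT_LEVELS = np.round(np.arange(0.0, 20.0 + 1e-9, 2.5), 2)

#: Fixed later amount in euros.
LATER_AMOUNT = 20.0

#: block id -> (sooner delay, later delay) in months; 0 encodes "tomorrow".
BLOCK_DELAYS = {1: (0, 3), 2: (0, 6), 3: (0, 9), 4: (0, 12), 5: (6, 9), 6: (6, 12)}

#: Later-option delays (months) of the four tomorrow-anchored blocks used for
#: discount-model fitting.
FIT_DELAYS = (3, 6, 9, 12)

TRIAL_COLUMNS = [
    "participant_id",
    "block",
    "trial",
    "sooner_delay",
    "later_delay",
    "sooner_amount",
    "later_amount",
    "is_catch",
    "side_of_sooner",
    "choice",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def build_choice_design(participant_id, seed=None) -> pd.DataFrame:
    """Build the 108-trial choice design for one participant.

    Returns a DataFrame with one row per trial in presentation order: block
    order and within-block trial order are permuted under ``seed``, and the
    screen side of the sooner option is drawn uniformly per trial. The
    ``choice`` column is left unset (NaN).
    """
    rng = _as_rng(seed)
    block_order = rng.permutation(sorted(BLOCK_DELAYS))
    rows = []
    for block in block_order:
        sooner_delay, later_delay = BLOCK_DELAYS[block]
        amounts = np.repeat(AMOUNT_LEVELS, 2)
        rng.shuffle(amounts)
        sides = rng.choice(["left", "right"], size=amounts.size)
        for trial, (amount, side) in enumerate(zip(amounts, sides), start=1):
            rows.append(
                {
                    "participant_id": participant_id,
                    "block": int(block),
                    "trial": trial,
                    "sooner_delay": sooner_delay,
                    "later_delay": later_delay,
                    "sooner_amount": float(amount),
                    "later_amount": LATER_AMOUNT,
                    "is_catch": amount in (0.0, LATER_AMOUNT),
                    "side_of_sooner": side,
                    "choice": np.nan,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


@dataclass
class FnpaDesign:
    """Face-name paired-associates layout.

    ``layout`` has one row per retrieval trial with the encoded name and the
    name actually shown; ``is_correct_pair`` marks intact pairs.
    """

    n_blocks: int = 4
    retrieval_trials_per_block: int = 10
    fraction_correct_pairs: float = 0.5
    n_faces: int = 40
    layout: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.n_blocks * self.retrieval_trials_per_block != self.n_faces:
            raise ValueError("faces must partition exactly into blocks")


def build_fnpa_design(seed=None) -> FnpaDesign:
    """Assign 40 unique faces to 4 blocks and choose the 5 recombined pairs.

    Recombination permutes names only among the 5 false pairs of the same
    block (a derangement, so no "false" pair is accidentally intact).
    """
    rng = _as_rng(seed)
    design = FnpaDesign()
    faces = rng.permutation(design.n_faces)
    rows = []
    per_block = design.retrieval_trials_per_block
    for block in range(1, design.n_blocks + 1):
        block_faces = faces[(block - 1) * per_block : block * per_block]
        false_idx = rng.choice(per_block, size=per_block // 2, replace=False)
        is_false = np.zeros(per_block, dtype=bool)
        is_false[false_idx] = True
        shown = block_faces.copy()
        # derangement of the names of the false pairs within the block
        sub = block_faces[is_false]
        while True:
            perm = rng.permutation(sub.size)
            if not np.any(sub[perm] == sub):
                break
        shown[is_false] = sub[perm]
        for face, name_shown, false_pair in zip(block_faces, shown, is_false):
            rows.append(
                {
                    "block": block,
                    "face_id": int(face),
                    "encoded_name_id": int(face),
                    "shown_name_id": int(name_shown),
                    "is_correct_pair": not false_pair,
                }
            )
    order = rng.permutation(len(rows))
    design.layout = pd.DataFrame(rows).iloc[order].reset_index(drop=True)
    return design


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (UTF-8, comma separated, dot decimals)."""
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    trials = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    trials["is_catch"] = trials["is_catch"].astype(bool)
    return trials


def validate_design(trials: pd.DataFrame) -> None:
    """Raise if a trial table violates the task-design invariants."""
    for pid, sub in trials.groupby("participant_id"):
        if len(sub) != 108:
            raise ValueError(f"participant {pid}: expected 108 trials, got {len(sub)}")
        for block, block_trials in sub.groupby("block"):
            if len(block_trials) != 18:
                raise ValueError(f"participant {pid} block {block}: expected 18 trials")
            delays = BLOCK_DELAYS[int(block)]
            if not (
                (block_trials["sooner_delay"] == delays[0]).all()
                and (block_trials["later_delay"] == delays[1]).all()
            ):
                raise ValueError(f"participant {pid} block {block}: wrong delays")
    if not (trials["later_amount"] == LATER_AMOUNT).all():
        raise ValueError("later amount must be fixed at 20 euros")
    if not trials["sooner_amount"].isin(AMOUNT_LEVELS).all():
        raise ValueError("sooner amounts must lie on the 2.50-euro grid")
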