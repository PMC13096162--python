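"""Serial reaction-time session construction.

A session is one training block followed by seven experimental blocks.  Each
experimental block is the full generation 11 of the Fibonacci grammar (144
symbols); the training block is a 50-item pseudo-random sequence with the
same symbol frequencies as the grammatical blocks but containing
ungrammatical sub-sequences (00 and 111), so that no grammar-consistent
structure can be carried over from training.  Stimuli are coloured circles
(red = 0, blue = 1) answered with 'M' (red) and 'Z' (blue) at a fixed
500 ms inter-stimulus interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ambiguity
from .grammar import SymbolString, generate, validate_grammatical

__all__ = [
    "COLOR_OF_SYMBOL",
    "KEY_OF_SYMBOL",
    "ISI_MS",
    "N_EXPERIMENTAL_BLOCKS",
    "TRAINING_LENGTH",
    "EXPERIMENTAL_GENERATION",
    "SessionSpec",
    "build_training_block",
    "build_session",
    "export_trial_list",
    "read_trial_list",
]

COLOR_OF_SYMBOL = {0: "red", 1: "blue"}
KEY_OF_SYMBOL = {0: "M", 1: "Z"}
ISI_MS = 500
N_EXPERIMENTAL_BLOCKS = 7
TRAINING_LENGTH = 50
EXPERIMENTAL_GENERATION = 11

_ANNOT_COLS = ["ambiguity_level", "status"] + [
    f"class_at_level_{L}" for L in range(ambiguity.DEFAULT_MAX_LEVEL)
]


@dataclass
class SessionSpec:
    """An ordered trial table plus the seed and annotations that built it."""

    trials: pd.DataFrame
    seed: int
    annotations: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_blocks(self) -> int:
        return self.trials["block"].nunique()


def build_training_block(seed: int) -> SymbolString:
    """Draw the 50-item ungrammatical pseudo-random training sequence.

    Symbol frequencies match the grammatical blocks (89/144 ones, i.e. 31
    ones and 19 zeros out of 50); shuffles are redrawn until the sequence
    contains both forbidden sub-sequences 00 and 111, which guarantees it
    is not an output of the grammar.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n_ones = round(TRAINING_LENGTH * 89 / 144)  # 31
    base = np.array([1] * n_ones + [0] * (TRAINING_LENGTH - n_ones))
    while True:
        rng.shuffle(base)
        s = "".join(map(str, base))
        if "00" in s and "111" in s:
            return SymbolString(s, generation=None)


def build_session(seed: int, max_level: int = ambiguity.DEFAULT_MAX_LEVEL) -> SessionSpec:
    """Assemble the eight-block session with joined ambiguity annotations.

    Block 0 is the training sequence; blocks 1..7 each repeat generation 11.
    Each block is annotated independently (no cross-block context), so the
    experimental annotation is identical for every block.
    """
    training = build_training_block(seed)
    grammar_block = generate(n=EXPERIMENTAL_GENERATION)
    annot = ambiguity.assign_ambiguity_levels(grammar_block, max_level=max_level)

    frames = []
    train_df = pd.DataFrame(
        {
            "block": 0,
            "trial_in_block": np.arange(len(training)),
            "symbol": [int(c) for c in training],
        }
    )
    frames.append(train_df)
    for b in range(1, N_EXPERIMENTAL_BLOCKS + 1):
        df = annot.copy()
        df.insert(0, "block", b)
        df = df.rename(columns={"position": "trial_in_block"})
        frames.append(df)
    trials = pd.concat(frames, ignore_index=True)
    for col in _ANNOT_COLS:
        if col not in trials:
            trials[col] = pd.NA
    trials["color"] = trials["symbol"].map(COLOR_OF_SYMBOL)
    trials["expected_key"] = trials["symbol"].map(KEY_OF_SYMBOL)
    trials["isi_ms"] = ISI_MS
    trials["ambiguity_level"] = trials["ambiguity_level"].astype("Int64")
    order = ["block", "trial_in_block", "symbol", "color", "expected_key", "isi_ms"] + _ANNOT_COLS
    return SessionSpec(trials[order], seed=seed, annotations=annot)


def export_trial_list(session: SessionSpec, path, participant_id: str | None = None) -> None:
    """Write the trial list as CSV (one row per trial, lossless round-trip)."""
    df = session.trials.copy()
    df.insert(0, "participant_id", participant_id if participant_id is not None else "")
    df.to_csv(path, index=False)


def read_trial_list(path) -> pd.DataFrame:
    """Read a trial list written by :func:`export_trial_list`."""
    df = pd.read_csv(
        path,
        dtype={"participant_id": "string"},
        keep_default_na=True,
    )
    df["ambiguity_level"] = df["ambiguity_level"].astype("Int64")
    return df


def is_grammatical_block(symbols) -> bool:
    ok, _ = validate_grammatical(symbols)
    return ok
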