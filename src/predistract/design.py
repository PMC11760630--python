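"""Experiment-plan generation for the dual-stream auditory spatial n-back task.

The experiment crosses perceptual load (target-to-distractor SNR: 0 vs -10 dB),
working-memory load (1- vs 2-back) and distractor predictability (a repeating
four-number pattern vs a constrained pseudo-random sequence) into 16 blocks of
120 simultaneous target/distractor pairs (onset-to-onset 2 s).

Targets and distractors are spoken numbers 1-8, split into two disjoint groups
of four whose roles swap between the two repeats of each condition. In a
predictable block the distractor stream cycles through a fixed four-number
pattern (transition probability 1); in an unpredictable block each distractor
differs from the previous and penultimate one, so after the first two items any
next number is one of two admissible alternatives (transition probability 0.5,
and 1/3 for the second item).
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

ALL_NUMBERS = frozenset(range(1, 9))
SNR_LEVELS = (0, -10)
LOAD_LEVELS = (1, 2)
PREDICTABILITY_LEVELS = ("predictable", "unpredictable")
CONDITION_CELLS = tuple(itertools.product(SNR_LEVELS, LOAD_LEVELS, PREDICTABILITY_LEVELS))

N_BLOCKS = 16
TRIALS_PER_BLOCK = 120
ONSET_INTERVAL_S = 2.0
NBACK_RATE = 0.2


@dataclass(frozen=True)
class NumberGroups:
    """Random partition of the numbers 1-8 into two disjoint groups of four."""

    group_a: frozenset
    group_b: frozenset

    def __post_init__(self):
        if len(self.group_a) != 4 or len(self.group_b) != 4:
            raise ValueError("each group must contain 4 numbers")
        if self.group_a | self.group_b != ALL_NUMBERS or self.group_a & self.group_b:
            raise ValueError("groups must partition {1..8}")


@dataclass(frozen=True)
class TrialPair:
    trial_index: int          # 1-based position within the block
    target_number: int
    distractor_number: int
    is_nback: bool            # target matches the target n positions back
    onset_s: float


@dataclass
class BlockSpec:
    block_index: int          # 1-based position within the experiment
    attend_side: str          # "left" | "right"
    memory_load: int          # n of n-back: 1 | 2
    snr_db: int               # 0 | -10 (target re distractor)
    predictability: str       # "predictable" | "unpredictable"
    target_numbers: frozenset
    distractor_numbers: frozenset
    distractor_pattern: tuple | None = None   # predictable blocks only
    trials: list = field(default_factory=list)

    def validate(self) -> None:
        if self.target_numbers & self.distractor_numbers:
            raise ValueError("target and distractor number sets overlap")
        if self.predictability == "predictable":
            if self.distractor_pattern is None or set(self.distractor_pattern) != set(self.distractor_numbers):
                raise ValueError("distractor_pattern must permute the distractor set")
        for t in self.trials:
            if t.target_number not in self.target_numbers:
                raise ValueError("target number outside block target set")
            if t.distractor_number not in self.distractor_numbers:
                raise ValueError("distractor number outside block distractor set")
            if t.is_nback and t.trial_index <= self.memory_load:
                raise ValueError("is_nback flagged on an unscoreable trial")


@dataclass
class ExperimentPlan:
    """The full 16-block plan: each condition cell twice, 1920 trial pairs."""

    blocks: list
    seed: int

    @property
    def n_trials(self) -> int:
        return sum(len(b.trials) for b in self.blocks)

    def condition_census(self) -> Counter:
        return Counter((b.snr_db, b.memory_load, b.predictability) for b in self.blocks)

    def validate(self) -> None:
        census = self.condition_census()
        if set(census) != set(CONDITION_CELLS) or set(census.values()) != {2}:
            raise ValueError("each condition cell must occur exactly twice")
        n_left = sum(b.attend_side == "left" for b in self.blocks)
        if n_left != len(self.blocks) // 2:
            raise ValueError("attend_side must be left in exactly half of the blocks")
        for cell in CONDITION_CELLS:
            pair = [b for b in self.blocks if (b.snr_db, b.memory_load, b.predictability) == cell]
            if pair[0].target_numbers != pair[1].distractor_numbers:
                raise ValueError("number-group roles must swap between condition repeats")
        for b in self.blocks:
            b.validate()

    def to_frame(self) -> pd.DataFrame:
        """Long trial table: one row per target/distractor pair."""
        rows = []
        for b in self.blocks:
            for t in b.trials:
                rows.append({
                    "block": b.block_index,
                    "trial": t.trial_index,
                    "attend_side": b.attend_side,
                    "memory_load": b.memory_load,
                    "snr_db": b.snr_db,
                    "predictability": b.predictability,
                    "target": t.target_number,
                    "distractor": t.distractor_number,
                    "is_nback": t.is_nback,
                    "onset_s": t.onset_s,
                })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {"seed": self.seed, "blocks": []}
        for b in self.blocks:
            d = asdict(b)
            d["target_numbers"] = sorted(b.target_numbers)
            d["distractor_numbers"] = sorted(b.distractor_numbers)
            d["distractor_pattern"] = list(b.distractor_pattern) if b.distractor_pattern else None
            payload["blocks"].append(d)
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentPlan":
        payload = json.loads(text)
        blocks = []
        for d in payload["blocks"]:
            trials = [TrialPair(**t) for t in d.pop("trials")]
            d["target_numbers"] = frozenset(d["target_numbers"])
            d["distractor_numbers"] = frozenset(d["distractor_numbers"])
            if d["distractor_pattern"] is not None:
                d["distractor_pattern"] = tuple(d["distractor_pattern"])
            blocks.append(BlockSpec(trials=trials, **d))
        return cls(blocks=blocks, seed=payload["seed"])


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def split_number_groups(seed) -> NumberGroups:
    """Randomly sort the numbers 1-8 into two groups of four."""
    rng = _as_rng(seed)
    order = rng.permutation(sorted(ALL_NUMBERS))
    return NumberGroups(frozenset(order[:4].tolist()), frozenset(order[4:].tolist()))


def generate_target_sequence(numbers, n, n_trials=TRIALS_PER_BLOCK,
                             nback_rate=NBACK_RATE, seed=None):
    """Target stream with an exact share of n-back repeats.

    20% of the scoreable positions (trial index > n, where a comparison item
    exists) repeat the item n positions back; every other scoreable position is
    guaranteed NOT to match at lag n. Returns a list of (number, is_nback).

    Sampling is constructive: the n-back event positions are a uniform random
    subset of the scoreable positions, event positions copy the lag-n item, and
    every other position draws uniformly from the numbers that do not match at
    lag n. With four numbers this is always feasible.
    """
    numbers = sorted(set(numbers))
    if len(numbers) < 2:
        raise ValueError("need at least two distinct numbers")
    if n not in (1, 2):
        raise ValueError("memory load n must be 1 or 2")
    if not 0 <= nback_rate <= 1:
        raise ValueError(f"nback_rate {nback_rate} is not a proportion")
    rng = _as_rng(seed)
    scoreable = list(range(n, n_trials))           # 0-based indices with a lag-n partner
    n_events = int(round(nback_rate * len(scoreable)))
    if n_events > len(scoreable):
        raise ValueError("requested n-back rate is not achievable")
    event_at = np.zeros(n_trials, dtype=bool)
    if scoreable:
        event_at[rng.choice(scoreable, size=n_events, replace=False)] = True

    seq = []
    numbers_arr = np.array(numbers)
    for i in range(n_trials):
        if i < n:
            seq.append(int(rng.choice(numbers_arr)))
        elif event_at[i]:
            seq.append(seq[i - n])
        else:
            options = [x for x in numbers if x != seq[i - n]]
            seq.append(int(options[rng.integers(len(options))]))
    return [(x, bool(event_at[i])) for i, x in enumerate(seq)]


def generate_predictable_distractors(pattern, n_trials):
    """Cyclic repetition of a four-number pattern (transition probability 1)."""
    pattern = tuple(int(x) for x in pattern)
    if len(pattern) != 4 or len(set(pattern)) != 4:
        raise ValueError("pattern must contain 4 distinct numbers")
    return [pattern[i % 4] for i in range(n_trials)]


def generate_unpredictable_distractors(numbers, n_trials, seed=None):
    """Constrained random distractor stream.

    Each item differs from the previous and the penultimate item, leaving three
    admissible alternatives for the second item (p = 1/3 each) and two from the
    third item on (p = 1/2 each). With four numbers the constraint is always
    satisfiable.
    """
    numbers = sorted(set(numbers))
    if len(numbers) != 4:
        raise ValueError("unpredictable stream needs exactly 4 numbers")
    rng = _as_rng(seed)
    seq = [int(rng.choice(numbers))]
    for i in range(1, n_trials):
        forbidden = {seq[i - 1]} if i == 1 else {seq[i - 1], seq[i - 2]}
        options = [x for x in numbers if x not in forbidden]
        seq.append(int(options[rng.integers(len(options))]))
    return seq


def empirical_transition_stats(sequences, order=1, positions=None) -> pd.Series:
    """Conditional next-item frequencies over one or more sequences.

    Parameters
    ----------
    sequences : sequence of ints, or list thereof
    order : length of the conditioning context (1 = previous item,
        2 = previous and penultimate item)
    positions : optional iterable of 0-based positions to include (the position
        of the *next* item); defaults to every position >= order.

    Returns a Series indexed by (context..., next) holding conditional relative
    frequencies, which sum to 1 within each context.
    """
    if sequences and isinstance(sequences[0], (int, np.integer)):
        sequences = [sequences]
    counts: Counter = Counter()
    for seq in sequences:
        if len(seq) < order + 1:
            raise ValueError("sequence shorter than the conditioning order")
        idx = range(order, len(seq)) if positions is None else positions
        for i in idx:
            context = tuple(seq[i - order:i])
            counts[context + (seq[i],)] += 1
    s = pd.Series(counts).sort_index()
    totals = s.groupby(level=list(range(order))).transform("sum")
    return s / totals


def build_experiment(seed, n_trials_per_block=TRIALS_PER_BLOCK,
                     nback_rate=NBACK_RATE) -> ExperimentPlan:
    """Generate a full, validated experiment plan.

    Each of the eight condition cells occurs twice: once with number group A as
    targets and group B as distractors, once with the roles swapped; one of the
    two repeats is attend-left and the other attend-right (randomised per
    cell), so exactly half the blocks are attend-left. Block order is a seeded
    uniform permutation.
    """
    rng = _as_rng(seed)
    seed_value = seed if isinstance(seed, (int, np.integer)) else -1
    groups = split_number_groups(rng)
    blocks = []
    for snr_db, load, predictability in CONDITION_CELLS:
        sides = ["left", "right"]
        rng.shuffle(sides)
        for repeat, side in enumerate(sides):
            targets, distractors = (groups.group_a, groups.group_b) if repeat == 0 \
                else (groups.group_b, groups.group_a)
            target_seq = generate_target_sequence(targets, load, n_trials_per_block,
                                                  nback_rate, rng)
            if predictability == "predictable":
                pattern = tuple(int(x) for x in rng.permutation(sorted(distractors)))
                distractor_seq = generate_predictable_distractors(pattern, n_trials_per_block)
            else:
                pattern = None
                distractor_seq = generate_unpredictable_distractors(distractors,
                                                                    n_trials_per_block, rng)
            trials = [
                TrialPair(i + 1, tgt, dst, flag, i * ONSET_INTERVAL_S)
                for i, ((tgt, flag), dst) in enumerate(zip(target_seq, distractor_seq))
            ]
            blocks.append(BlockSpec(0, side, load, snr_db, predictability,
                                    targets, distractors, pattern, trials))
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]
    for pos, b in enumerate(blocks):
        b.block_index = pos + 1
    plan = ExperimentPlan(blocks=blocks, seed=int(seed_value))
    plan.validate()
    return plan
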