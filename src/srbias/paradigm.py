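"""Block structure of the noisy-letter experiment.

Six blocks per participant:

====== ========== ======= =====================================================
order  label      trials  content
====== ========== ======= =====================================================
0      practice   18      6 letters x 3 reps at an easy luminance (132), sigma=0
1      quest      50      staircase titration to 70% correct, sigma=0
2      block2     48      sigma=0, consonants frequent, base rates undisclosed
3      block3     48      sigma=0, base rates flipped toward the observed bias
                          and disclosed
4      block4     240     the noise ladder: 30 trials per level over eight
                          30-trial slots, the zero level holding two slots
5      block5     240     repeat of block4 with a fresh shuffle (60 trials per
                          nonzero level across blocks 4+5)
====== ========== ======= =====================================================

A 48-trial block cannot realize exactly 80/20 with equal per-letter counts
(48 x 0.8 = 38.4), so the closest equal-count split 39/9 (13 per frequent
letter, 3 per rare letter; effective base rate 81.25/18.75) is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import sdt
from .stimuli import CONSONANTS, VOWELS, LETTERS, NoiseLadder, make_noise_ladder

__all__ = ["BlockSpec", "ExperimentDesign", "build_design",
           "assign_frequent_category", "quest_rerun_rule", "exclusion_rule",
           "PRACTICE_INCREMENT", "default_ladder"]

#: Table-level "easy" practice luminance of 132 on the 127 background.
PRACTICE_INCREMENT = 5.0

BLOCK_ORDER = ("practice", "quest", "block2", "block3", "block4", "block5")


def default_ladder() -> NoiseLadder:
    """The experiment's ladder: 0, 0.25, 0.76, 2.30, 6.96, 21.11, 64."""
    return make_noise_ladder(0.25, 64.0, 6)


@dataclass(frozen=True)
class BlockSpec:
    label: str
    n_trials: int
    noise_conditions: tuple[tuple[float, int], ...]  # (sigma, n_trials_at_sigma)
    base_rate: float
    informed: bool
    increment_override: float | None = None

    def __post_init__(self) -> None:
        if self.label not in BLOCK_ORDER:
            raise ValueError(f"unknown block label {self.label!r}")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if sum(n for _, n in self.noise_conditions) != self.n_trials:
            raise ValueError("noise conditions must account for every trial")


@dataclass(frozen=True)
class ExperimentDesign:
    blocks: tuple[BlockSpec, ...]
    frequent_category: str
    letter_sequence: dict  # label -> list[(letter, sigma)]

    def block(self, label: str) -> BlockSpec:
        for b in self.blocks:
            if b.label == label:
                return b
        raise KeyError(label)


def _category_letters(category: str) -> tuple[str, ...]:
    return CONSONANTS if category == "consonant" else VOWELS


def _biased_letter_list(n_trials: int, base_rate: float,
                        frequent_category: str) -> list[str]:
    """Equal-count letter list realizing the base rate as closely as possible."""
    if n_trials % 3:
        raise ValueError("trial count per condition must be divisible by 3 "
                         "for equal per-letter counts")
    per_freq = round(n_trials * base_rate / 3)
    per_rare = n_trials // 3 - per_freq
    if per_rare < 1 or per_freq < 1:
        raise ValueError("base rate leaves a letter with no trials")
    freq = _category_letters(frequent_category)
    rare = _category_letters("vowel" if frequent_category == "consonant"
                             else "consonant")
    return [L for L in freq for _ in range(per_freq)] + \
           [L for L in rare for _ in range(per_rare)]


def build_design(rng_seed, frequent_category: str = "consonant",
                 ladder: NoiseLadder | None = None,
                 n_per_level: int = 30, quest_trials: int = 50,
                 bias_block_trials: int = 48) -> ExperimentDesign:
    """Full per-participant schedule; shuffling is seeded and only permutes order.

    Block 2 always presents consonants as frequent (the paper's undisclosed
    baseline); blocks 3-5 present ``frequent_category`` as frequent.  The
    noise block fills eight ``n_per_level``-trial slots over the seven ladder
    levels, the zero level taking two slots.
    """
    if frequent_category not in ("consonant", "vowel"):
        raise ValueError("frequent_category must be consonant or vowel")
    ladder = ladder or default_ladder()
    rng = np.random.default_rng(rng_seed)

    seq: dict[str, list[tuple[str, float]]] = {}
    blocks: list[BlockSpec] = []

    practice_letters = [L for L in LETTERS for _ in range(3)]
    rng.shuffle(practice_letters)
    seq["practice"] = [(L, 0.0) for L in practice_letters]
    blocks.append(BlockSpec("practice", 18, ((0.0, 18),), 0.5, False,
                            increment_override=PRACTICE_INCREMENT))

    quest_letters = [LETTERS[i] for i in rng.integers(0, 6, size=quest_trials)]
    seq["quest"] = [(L, 0.0) for L in quest_letters]
    blocks.append(BlockSpec("quest", quest_trials, ((0.0, quest_trials),),
                            0.5, False))

    for label, freq_cat, informed in (("block2", "consonant", False),
                                      ("block3", frequent_category, True)):
        letters = _biased_letter_list(bias_block_trials, 0.8, freq_cat)
        rng.shuffle(letters)
        seq[label] = [(L, 0.0) for L in letters]
        blocks.append(BlockSpec(label, bias_block_trials,
                                ((0.0, bias_block_trials),),
                                round(len([L for L in letters
                                           if sdt.LETTER_CATEGORY[L] == freq_cat])
                                      / bias_block_trials, 4),
                                informed))

    # noise blocks: eight slots of n_per_level trials; sigma=0 takes two
    conditions = [(0.0, 2 * n_per_level)] + \
                 [(s, n_per_level) for s in ladder.nonzero]
    n_noise = sum(n for _, n in conditions)
    for label in ("block4", "block5"):
        pairs: list[tuple[str, float]] = []
        for sigma, n in conditions:
            for L in _biased_letter_list(n, 0.8, frequent_category):
                pairs.append((L, sigma))
        order = rng.permutation(len(pairs))
        seq[label] = [pairs[i] for i in order]
        blocks.append(BlockSpec(label, n_noise, tuple(conditions), 0.8, True))

    return ExperimentDesign(blocks=tuple(blocks),
                            frequent_category=frequent_category,
                            letter_sequence=seq)


def assign_frequent_category(block2_records) -> str:
    """Category the participant over-responds with, by criterion sign.

    Block 2 presents consonants as frequent, so the criterion is computed
    with vowels as the rare category: positive c (under-reporting vowels)
    means a consonant bias, negative c a vowel bias.  A criterion of exactly
    zero defaults to consonant (the presented base rate).
    """
    records = list(block2_records)
    if not records:
        raise ValueError("block2 records are empty")
    counts = sdt.classify_responses(records, rare_category="vowel")
    hr, far, _ = sdt.rates(counts)
    return "consonant" if sdt.criterion(hr, far) >= 0 else "vowel"


def quest_rerun_rule(block2_accuracy: float) -> bool:
    """Rerun the staircase iff letter-exact accuracy strays beyond 70 +/- 10%.

    The boundary is inclusive: exactly 60% or 80% does not trigger a rerun.
    """
    if not (0.0 <= block2_accuracy <= 1.0):
        raise ValueError("accuracy must lie in [0, 1]")
    return abs(block2_accuracy - 0.70) > 0.10 + 1e-12


def exclusion_rule(block3_criterion: float) -> str:
    """Exclude participants without any bias toward the frequent stimuli."""
    return "include" if block3_criterion > 0 else "exclude"
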