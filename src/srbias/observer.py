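"""Synthetic observer: threshold transduction, template matching, biased choice.

The generator emulates a participant in the noisy-letter task.  Its mechanism
is the standard stochastic-resonance chain:

1. **Transduction.** Each frame's deviation from the grey background passes a
   hard threshold ``theta``; only super-threshold deviations contribute to the
   percept, which is the mean passed contribution over the integrated frames.
   A sub-threshold letter (increment < theta) is invisible at zero external
   noise unless noise pushes letter pixels over the threshold — adding a
   moderate amount of noise therefore *improves* letter transmission (the
   inverted-U signature), while strong noise swamps it.
2. **Internal noise.** Zero-mean Gaussian noise (SD ``internal_noise_sd``) is
   added per pixel per frame before thresholding, at every external-noise
   level.  This gives the observer a smooth psychometric function at zero
   external noise, so the QUEST staircase can titrate it to 70% correct while
   the letter stays sub-threshold; it plays the role of the sensory noise
   that real observers bring to the task.
3. **Template matching.** The percept map is compared against the six letter
   templates by normalized cross-correlation (mean-subtracted cosine).
4. **Decision noise.** Zero-mean Gaussian noise (SD ``decision_noise_sd``)
   perturbs each letter's evidence once per trial before the choice.  This
   late noise bounds the observer's efficiency: without it, template
   matching over thousands of pixels remains near-perfect even under severe
   external noise, whereas real observers fall to chance there.  It is what
   lets performance collapse at the top of the noise ladder.
5. **Biased decision.** Category base-rate knowledge enters as an additive
   log-prior bonus of strength ``w`` on each letter's evidence; the observer
   answers the argmax, lapsing to a uniformly random letter with probability
   ``lapse``.  ``w > 0`` yields the positive criterion toward the frequent
   category that the base-rate manipulation induces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .stimuli import (DEFAULT_BACKGROUND, DEFAULT_FIELD_SHAPE,
                      DEFAULT_GLYPH_HEIGHT, LETTERS, LETTER_CATEGORY,
                      LetterTemplate, StimulusFrames, compose_trial_frames,
                      embed_mask, render_letter_template)

__all__ = ["ObserverParams", "TemplateBank", "transduce", "letter_evidence",
           "decide", "simulate_trial", "simulate_participant"]


@dataclass(frozen=True)
class ObserverParams:
    """Synthetic-participant parameters.

    theta : hard transduction threshold (grey units above background).
    w : additive strength of the log category prior on letter evidence.
    lapse : probability of a uniformly random letter response.
    n_frames_integrated : frames averaged per trial (12 by default for
        desk-scale speed; the display refreshes at 60 Hz for 1 s).
    category_prior : probability the observer assigns to its preferred
        (frequent) category, split equally over that category's 3 letters.
    internal_noise_sd : per-pixel Gaussian sensory noise (grey units),
        present at every external-noise level.
    decision_noise_sd : per-trial Gaussian noise on each letter's evidence
        (evidence is a normalized correlation, so this is on a [-1, 1]
        scale); bounds the observer's template-matching efficiency.
    preferred_category : the category the observer is biased toward before
        any disclosure of base rates (the paradigm later makes it frequent).
    """

    theta: float = 50.0
    w: float = 0.05
    lapse: float = 0.02
    n_frames_integrated: int = 12
    category_prior: float = 0.8
    internal_noise_sd: float = 10.0
    decision_noise_sd: float = 0.15
    preferred_category: str = "consonant"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")
        if not (0.0 <= self.lapse <= 1.0):
            raise ValueError("lapse must lie in [0, 1]")
        if not (0.5 <= self.category_prior < 1.0):
            raise ValueError("category_prior must lie in [0.5, 1)")
        if self.w < 0:
            raise ValueError("w must be nonnegative")
        if self.internal_noise_sd < 0:
            raise ValueError("internal_noise_sd must be nonnegative")
        if self.decision_noise_sd < 0:
            raise ValueError("decision_noise_sd must be nonnegative")
        if self.preferred_category not in ("consonant", "vowel"):
            raise ValueError("preferred_category must be consonant or vowel")


class TemplateBank:
    """Embedded, mean-centred, unit-norm letter templates for fast matching."""

    def __init__(self, glyph_height: int = DEFAULT_GLYPH_HEIGHT,
                 shape: tuple[int, int] = DEFAULT_FIELD_SHAPE) -> None:
        self.shape = shape
        self.templates = {L: render_letter_template(L, glyph_height)
                          for L in LETTERS}
        mats = []
        for L in LETTERS:
            t = embed_mask(self.templates[L].mask, shape).ravel()
            t = t - t.mean()
            mats.append(t / np.linalg.norm(t))
        self.matrix = np.asarray(mats)          # (6, rows*cols)
        self.letters = LETTERS


def transduce(frames: StimulusFrames, theta: float,
              internal_noise_sd: float = 0.0, rng=None) -> np.ndarray:
    """Mean over frames of super-threshold deviations from background.

    A pixel contributes its deviation (pixel - background) on a frame only
    when that deviation exceeds ``theta``; otherwise it contributes zero.
    Optional internal noise is added to the deviation before thresholding.
    """
    x = frames.frames - frames.background
    if internal_noise_sd > 0:
        rng = np.random.default_rng(rng)
        x = x + rng.normal(0.0, internal_noise_sd, size=x.shape)
    return np.mean(np.where(x > theta, x, 0.0), axis=0)


def letter_evidence(percept_map: np.ndarray, templates) -> np.ndarray:
    """Normalized cross-correlation of the percept with each letter template.

    Returns one value per letter in the canonical order C, B, H, O, E, U.
    A zero (or constant) percept map carries no letter information and maps
    to the all-zero evidence vector.
    """
    if not isinstance(templates, TemplateBank):
        bank = object.__new__(TemplateBank)
        mats = []
        for L in LETTERS:
            t = np.asarray(templates[L].mask, dtype=float).ravel()
            t = t - t.mean()
            mats.append(t / np.linalg.norm(t))
        bank.matrix = np.asarray(mats)
        bank.letters = LETTERS
        templates = bank
    p = np.asarray(percept_map, dtype=float).ravel()
    p = p - p.mean()
    norm = np.linalg.norm(p)
    if norm == 0.0:
        return np.zeros(len(templates.letters))
    return templates.matrix @ (p / norm)


def decide(evidence: np.ndarray, frequent_category: str,
           params: ObserverParams, rng=None) -> str:
    """Prior-weighted argmax over letters, with lapses and uniform ties.

    Score_k = evidence_k + w * log prior(letter k), where the frequent
    category receives probability ``category_prior`` split equally over its
    three letters.
    """
    rng = np.random.default_rng(rng)
    if params.lapse > 0 and rng.random() < params.lapse:
        return LETTERS[rng.integers(len(LETTERS))]
    p_freq = params.category_prior / 3.0
    p_rare = (1.0 - params.category_prior) / 3.0
    log_prior = np.array([
        np.log(p_freq if LETTER_CATEGORY[L] == frequent_category else p_rare)
        for L in LETTERS])
    score = np.asarray(evidence, dtype=float) + params.w * log_prior
    best = np.flatnonzero(score == score.max())
    return LETTERS[int(rng.choice(best))]


def simulate_trial(letter: str, sigma: float, increment: float,
                   params: ObserverParams, bank: TemplateBank,
                   rng: np.random.Generator,
                   background: float = DEFAULT_BACKGROUND) -> str:
    """One presentation: compose frames, transduce, match, perturb, decide."""
    frames = compose_trial_frames(
        bank.templates[letter], increment, sigma,
        n_frames=params.n_frames_integrated, background=background,
        rng_seed=rng, shape=bank.shape)
    percept = transduce(frames, params.theta, params.internal_noise_sd, rng)
    ev = letter_evidence(percept, bank)
    if params.decision_noise_sd > 0:
        ev = ev + rng.normal(0.0, params.decision_noise_sd, size=ev.shape)
    return decide(ev, params.preferred_category, params, rng)


def simulate_participant(design, params: ObserverParams, increment: float,
                         bank: TemplateBank | None = None,
                         rng=None, participant_id: str = "sim") -> list:
    """Run every scheduled trial of a design at a fixed letter increment.

    Blocks may override the increment (the practice block's easy luminance).
    Returns the trial log as a list of :class:`srbias.sdt.TrialRecord`;
    identical seeds give identical logs.
    """
    from .sdt import TrialRecord

    if increment <= 0:
        raise ValueError("increment must be positive")
    if bank is None:
        bank = TemplateBank()
    rng = np.random.default_rng(params.rng_seed if rng is None else rng)
    records = []
    for block in design.blocks:
        inc = block.increment_override or increment
        seq = design.letter_sequence[block.label]
        for i, (letter, sigma) in enumerate(seq, start=1):
            resp = simulate_trial(letter, sigma, inc, params, bank, rng)
            records.append(TrialRecord(
                participant_id=participant_id, block=block.label,
                trial_index=i, sigma=sigma, letter_shown=letter,
                response_letter=resp, increment=inc))
    return records
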