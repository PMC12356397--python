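"""Noise ladder, letter templates and noisy stimulus frames.

The experiment shows one of six letters (C, B, H, O, E, U) on a uniform grey
background (grey level 127) inside a 100x100 pixel square, with dynamic
zero-mean Gaussian luminance noise added per pixel and refreshed on every
frame.  The external-noise standard deviation sigma is the independent
variable, stepped over a log-spaced ladder whose first level is exactly 0.

Letter glyphs are deterministic block-stroke bitmaps on a 5x5 stroke grid
(Sloan-like proportions, letter height == letter width).  The six glyphs are
designed so that each letter's nearest neighbour by pixel overlap is its
confusion partner from the opposite category: C<->O, E<->B, H<->U.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONSONANTS = ("C", "B", "H")
VOWELS = ("O", "E", "U")
LETTERS = CONSONANTS + VOWELS

#: Fixed letter -> category map.
LETTER_CATEGORY = {**{c: "consonant" for c in CONSONANTS},
                   **{v: "vowel" for v in VOWELS}}

#: 5x5 stroke-grid glyphs (1 = ink).  Nearest neighbour by Jaccard overlap
#: is the cross-category confusion partner: C<->O, E<->B, H<->U.
_GLYPHS = {
    "C": ["01110",
          "10000",
          "10000",
          "10000",
          "01110"],
    "O": ["01110",
          "10001",
          "10001",
          "10001",
          "01110"],
    "E": ["11111",
          "10000",
          "11110",
          "10000",
          "11111"],
    "B": ["11110",
          "10001",
          "11110",
          "10001",
          "11110"],
    "H": ["10001",
          "10001",
          "11111",
          "10001",
          "10001"],
    "U": ["10001",
          "10001",
          "10001",
          "10001",
          "11111"],
}

DEFAULT_FIELD_SHAPE = (100, 100)
DEFAULT_BACKGROUND = 127.0
DEFAULT_GLYPH_HEIGHT = 85
FRAME_RATE_HZ = 60


@dataclass(frozen=True)
class NoiseLadder:
    """Ordered external-noise levels (grey units), leading level exactly 0."""

    sigmas: tuple[float, ...]

    def __post_init__(self) -> None:
        s = self.sigmas
        if len(s) < 2 or s[0] != 0.0:
            raise ValueError("ladder must start with a zero level")
        nz = np.asarray(s[1:], dtype=float)
        if np.any(nz <= 0) or np.any(np.diff(nz) <= 0):
            raise ValueError("nonzero levels must be positive and strictly increasing")
        if len(nz) >= 3:
            ratios = nz[1:] / nz[:-1]
            if np.any(np.abs(ratios - ratios[0]) > 1e-9 * ratios[0]):
                raise ValueError("nonzero levels must be equally spaced in log space")

    @property
    def nonzero(self) -> tuple[float, ...]:
        return self.sigmas[1:]

    def rounded(self, ndigits: int = 2) -> tuple[float, ...]:
        """Display values (reporting only; full precision is used internally)."""
        return tuple(round(s, ndigits) for s in self.sigmas)

    def __len__(self) -> int:
        return len(self.sigmas)


@dataclass(frozen=True)
class LetterTemplate:
    """Binary pixel mask for one letter, row-major, origin top-left."""

    letter: str
    category: str
    mask: np.ndarray
    glyph_height: int

    def __post_init__(self) -> None:
        if self.letter not in LETTERS:
            raise ValueError(f"unknown letter {self.letter!r}")
        m = np.asarray(self.mask)
        if not np.isin(m, (0, 1)).all() or m.sum() == 0:
            raise ValueError("mask must be binary with at least one pixel set")


@dataclass(frozen=True)
class StimulusFrames:
    """Grey-level frame stack for one trial, values clipped to [0, 255]."""

    frames: np.ndarray          # (n_frames, rows, cols)
    background: float
    letter_increment: float
    sigma: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def make_noise_ladder(sigma_min: float, sigma_max: float,
                      n_nonzero: int) -> NoiseLadder:
    """Zero level followed by ``n_nonzero`` geometrically spaced sigmas.

    ``make_noise_ladder(0.25, 64, 6)`` reproduces the experiment's ladder
    0, 0.25, 0.76, 2.30, 6.96, 21.11, 64 (2 dp).
    """
    if sigma_min <= 0:
        raise ValueError("sigma_min must be positive")
    if sigma_max <= sigma_min:
        raise ValueError("sigma_max must exceed sigma_min")
    if int(n_nonzero) != n_nonzero or n_nonzero < 2:
        raise ValueError("n_nonzero must be an integer >= 2")
    nz = np.geomspace(sigma_min, sigma_max, int(n_nonzero))
    # exact endpoints, geometric interior
    nz[0], nz[-1] = sigma_min, sigma_max
    return NoiseLadder((0.0, *nz.tolist()))


def render_letter_template(letter: str,
                           glyph_height_px: int = DEFAULT_GLYPH_HEIGHT) -> LetterTemplate:
    """Scale the 5x5 stroke glyph to a square bitmap of the requested height."""
    if letter not in LETTERS:
        raise ValueError(f"unknown letter {letter!r}; expected one of {LETTERS}")
    if glyph_height_px < 8:
        raise ValueError("glyph_height_px must be >= 8")
    grid = np.array([[int(ch) for ch in row] for row in _GLYPHS[letter]],
                    dtype=np.uint8)
    # row/col band edges chosen so the scaled bounding box is exact
    edges = np.round(np.linspace(0, glyph_height_px, 6)).astype(int)
    reps = np.diff(edges)
    mask = np.repeat(np.repeat(grid, reps, axis=0), reps, axis=1)
    return LetterTemplate(letter=letter, category=LETTER_CATEGORY[letter],
                          mask=mask, glyph_height=glyph_height_px)


def pixel_overlap(a: LetterTemplate, b: LetterTemplate) -> float:
    """Jaccard overlap of two letter masks (same shape required)."""
    ma, mb = a.mask.astype(bool), b.mask.astype(bool)
    union = np.logical_or(ma, mb).sum()
    return float(np.logical_and(ma, mb).sum() / union)


def embed_mask(mask: np.ndarray,
               shape: tuple[int, int] = DEFAULT_FIELD_SHAPE) -> np.ndarray:
    """Centre a glyph mask in the presentation field (float array)."""
    rows, cols = shape
    gr, gc = mask.shape
    if gr > rows or gc > cols:
        raise ValueError("glyph larger than the presentation field")
    out = np.zeros(shape, dtype=np.float64)
    r0, c0 = (rows - gr) // 2, (cols - gc) // 2
    out[r0:r0 + gr, c0:c0 + gc] = mask
    return out


def generate_noise_field(sigma: float, shape=DEFAULT_FIELD_SHAPE,
                         rng_seed=None) -> np.ndarray:
    """Independent zero-mean Gaussian luminance noise, one deviate per pixel."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return np.zeros(shape, dtype=np.float64)
    rng = np.random.default_rng(rng_seed)
    return rng.normal(0.0, sigma, size=shape)


def compose_trial_frames(template: LetterTemplate, letter_increment: float,
                         sigma: float, n_frames: int = FRAME_RATE_HZ,
                         background: float = DEFAULT_BACKGROUND,
                         rng_seed=None,
                         shape: tuple[int, int] = DEFAULT_FIELD_SHAPE) -> StimulusFrames:
    """Letter-plus-noise frame stack: clip(bg + inc*mask + noise_t, 0, 255).

    The noise field is refreshed on every frame (60 Hz for a 1 s trial by
    default); with sigma=0 all frames are identical.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if not (0.0 <= background + letter_increment <= 255.0):
        raise ValueError("background + increment must lie in [0, 255]")
    base = background + letter_increment * embed_mask(template.mask, shape)
    if sigma == 0:
        frames = np.broadcast_to(base, (n_frames, *shape)).copy()
    else:
        rng = np.random.default_rng(rng_seed)
        noise = rng.normal(0.0, sigma, size=(n_frames, *shape))
        frames = np.clip(base[None] + noise, 0.0, 255.0)
    return StimulusFrames(frames=frames, background=background,
                          letter_increment=letter_increment, sigma=sigma)


def save_frames_png(frames: StimulusFrames, path_prefix: str) -> list[str]:
    """Optional PNG export of a frame stack for visual inspection."""
    from PIL import Image

    paths = []
    for i, frame in enumerate(frames.frames):
        p = f"{path_prefix}_{i:03d}.png"
        Image.fromarray(np.round(frame).astype(np.uint8), mode="L").save(p)
        paths.append(p)
    return paths
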