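"""Six-way sub-tile classification and four-class slide verdicts.

Each scored sub-tile lands in one of six categories, mirroring the
standard sharpness-map legend for histology QC:

=============  =====================================================
category       meaning
=============  =====================================================
sharp          in-focus tissue
sharp_bg       in-focus tissue with a high percentage of background
medium         tissue of intermediate focus score
blurred        defocused tissue
blurred_bg     defocused tissue with a high percentage of background
background     bare glass (almost no tissue)
=============  =====================================================

The slide as a whole is then graded **excellent / acceptable / review /
defective** from the fraction of tissue sub-tiles that are blurred.
Because no universal focus-score cut-offs exist (they depend on scanner,
stain, and measure), ``calibrate_thresholds`` derives ``t_sharp`` and
``t_blur`` from seeded synthetic textures at known defocus levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

from .errors import CalibrationError, SlideValidationError
from .focus import BackgroundParams, FocusParams, SubTileRecord

if TYPE_CHECKING:  # pragma: no cover
    from .mapper import SharpnessGrid

__all__ = [
    "CATEGORIES",
    "VERDICTS",
    "ClassifyThresholds",
    "SlideReport",
    "classify_sub_tile",
    "classify_slide",
    "coarse_label",
    "subtile_recovery",
    "calibrate_thresholds",
]

CATEGORIES = ("sharp", "sharp_bg", "medium", "blurred", "blurred_bg", "background")
VERDICTS = ("excellent", "acceptable", "review", "defective")

#: Default maximum blurred-tissue fraction for each verdict tier.
DEFAULT_SLIDE_EXCELLENT_MAX = 0.02
DEFAULT_SLIDE_ACCEPTABLE_MAX = 0.10
DEFAULT_SLIDE_REVIEW_MAX = 0.30


@dataclass(frozen=True)
class ClassifyThresholds:
    """Focus-score cut-offs and slide-level verdict bounds.

    Tissue with score >= ``t_sharp`` is sharp, < ``t_blur`` is blurred,
    in between is medium. ``slide_*_max`` are the largest blurred-tissue
    fractions still earning each verdict; anything above
    ``slide_review_max`` is defective.
    """

    t_sharp: float
    t_blur: float
    slide_excellent_max: float = DEFAULT_SLIDE_EXCELLENT_MAX
    slide_acceptable_max: float = DEFAULT_SLIDE_ACCEPTABLE_MAX
    slide_review_max: float = DEFAULT_SLIDE_REVIEW_MAX

    def __post_init__(self):
        if not (0.0 <= self.t_blur < self.t_sharp):
            raise SlideValidationError(
                f"need 0 <= t_blur < t_sharp, got t_blur={self.t_blur}, t_sharp={self.t_sharp}")
        if not (0.0 < self.slide_excellent_max < self.slide_acceptable_max
                < self.slide_review_max < 1.0):
            raise SlideValidationError(
                "slide verdict bounds must be strictly increasing within (0, 1)")

    def to_dict(self) -> dict:
        return {"t_sharp": self.t_sharp, "t_blur": self.t_blur,
                "slide_excellent_max": self.slide_excellent_max,
                "slide_acceptable_max": self.slide_acceptable_max,
                "slide_review_max": self.slide_review_max}

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifyThresholds":
        return cls(**{k: d[k] for k in
                      ("t_sharp", "t_blur", "slide_excellent_max",
                       "slide_acceptable_max", "slide_review_max") if k in d})


@dataclass
class SlideReport:
    """Slide-level summary: category counts, blurred fraction, verdict."""

    verdict: str
    counts: dict  # category -> int, all six keys present
    tissue_subtiles: int
    blurred_fraction: Optional[float]
    params_echo: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"verdict": self.verdict,
                "counts": dict(self.counts),
                "tissue_subtiles": self.tissue_subtiles,
                "blurred_fraction": self.blurred_fraction,
                "flags": list(self.flags),
                "params": self.params_echo}


def classify_sub_tile(record: SubTileRecord, th: ClassifyThresholds,
                      bp: BackgroundParams = BackgroundParams()) -> str:
    """Assign one of the six categories to a scored sub-tile.

    Pure background wins first (``bg_fraction >= bg_subtile_min``); then
    the focus score decides sharp / medium / blurred, with the high-
    background flag splitting sharp and blurred into their ``_bg``
    variants. Ties at thresholds resolve to the better class: ``>=`` at
    ``t_sharp`` and ``bg`` bounds, ``<`` at ``t_blur``.
    """
    if record.focus_score is None or record.bg_fraction is None:
        raise SlideValidationError("sub-tile record has unset score or bg_fraction")
    if record.bg_fraction >= bp.bg_subtile_min:
        return "background"
    high_bg = record.bg_fraction >= bp.bg_high_min
    if record.focus_score >= th.t_sharp:
        return "sharp_bg" if high_bg else "sharp"
    if record.focus_score < th.t_blur:
        return "blurred_bg" if high_bg else "blurred"
    return "medium"


def classify_slide(grid: "SharpnessGrid", th: ClassifyThresholds,
                   params_echo: Optional[dict] = None) -> SlideReport:
    """Grade a fully classified grid into one of the four slide classes.

    ``blurred_fraction = (blurred + blurred_bg) / tissue`` where tissue is
    everything but pure background (medium counts as tissue, not as
    blurred). A slide with no tissue at all cannot be vouched for and is
    sent to ``review`` with a flag.
    """
    counts = {c: 0 for c in CATEGORIES}
    n = 0
    for rec in grid.iter_records():
        if rec.category is None:
            raise SlideValidationError(
                f"sub-tile ({rec.grid_x},{rec.grid_y}) is unclassified")
        counts[rec.category] += 1
        n += 1
    if n == 0:
        raise SlideValidationError("empty grid")
    tissue = n - counts["background"]
    flags = []
    if tissue == 0:
        verdict = "review"
        blurred_fraction = None
        flags.append("no_tissue_detected")
    else:
        blurred_fraction = (counts["blurred"] + counts["blurred_bg"]) / tissue
        if blurred_fraction <= th.slide_excellent_max:
            verdict = "excellent"
        elif blurred_fraction <= th.slide_acceptable_max:
            verdict = "acceptable"
        elif blurred_fraction <= th.slide_review_max:
            verdict = "review"
        else:
            verdict = "defective"
    echo = dict(params_echo or {})
    echo.setdefault("thresholds", th.to_dict())
    return SlideReport(verdict=verdict, counts=counts, tissue_subtiles=tissue,
                       blurred_fraction=blurred_fraction, params_echo=echo,
                       flags=flags)


def coarse_label(record: SubTileRecord, th: ClassifyThresholds,
                 bp: BackgroundParams = BackgroundParams()) -> str:
    """Ternary sharp-tissue / blurred-tissue / background decision.

    The six-way map keeps an uncommitted ``medium`` band for
    visualization; when the coarse question must be answered (ground-
    truth recovery, QC triage), scores inside the band are resolved at
    its midpoint ``(t_sharp + t_blur) / 2``.
    """
    if record.bg_fraction >= bp.bg_subtile_min:
        return "background"
    mid = 0.5 * (th.t_sharp + th.t_blur)
    return "sharp_tissue" if record.focus_score >= mid else "blurred_tissue"


def subtile_recovery(grid, truth, th: ClassifyThresholds,
                     bp: BackgroundParams = BackgroundParams()) -> float:
    """Fraction of sub-tiles whose coarse label matches the ground truth."""
    n = ok = 0
    for rec in grid.iter_records():
        expected = truth.labels[rec.grid_y, rec.grid_x]
        ok += coarse_label(rec, th, bp) == expected
        n += 1
    if n == 0:
        raise SlideValidationError("empty grid")
    return ok / n


def calibrate_thresholds(generator_seed: int, n_textures: int = 50,
                         sigma_sharp: float = 0.0, sigma_blur: float = 3.0,
                         fparams: FocusParams = FocusParams(),
                         texture_side: int = 128) -> ClassifyThresholds:
    """Derive ``t_sharp``/``t_blur`` from seeded synthetic textures.

    Generates ``n_textures`` tissue textures, scores each in focus
    (``sigma_sharp``) and defocused (``sigma_blur`` Gaussian blur), and
    places ``t_sharp`` at the 25th percentile of the sharp-condition
    scores and ``t_blur`` at the 75th percentile of the blur-condition
    scores. If the two cross, both collapse to their midpoint and a
    warning is issued. Deterministic in ``generator_seed``.
    """
    from . import synth  # local import: synth depends on focus for its checks

    if n_textures < 10:
        raise SlideValidationError("n_textures must be >= 10 for stable percentiles")
    if sigma_blur <= sigma_sharp:
        raise SlideValidationError("sigma_blur must exceed sigma_sharp")
    sharp_scores = np.empty(n_textures)
    blur_scores = np.empty(n_textures)
    for i in range(n_textures):
        series = synth.generate_defocus_series(
            generator_seed + i, [sigma_sharp, sigma_blur],
            width_px=texture_side, height_px=texture_side)
        from .wsi_io import to_grayscale
        sharp_scores[i] = fparams.score(to_grayscale(series[0]))
        blur_scores[i] = fparams.score(to_grayscale(series[1]))
    if np.ptp(sharp_scores) == 0 and np.ptp(blur_scores) == 0:
        raise CalibrationError("degenerate score distributions: all scores equal")
    t_sharp = float(np.percentile(sharp_scores, 25))
    t_blur = float(np.percentile(blur_scores, 75))
    if t_blur >= t_sharp:
        mid = 0.5 * (t_sharp + t_blur)
        warnings.warn(
            "calibration conditions overlap; collapsing t_sharp and t_blur "
            f"to their midpoint {mid:.3g}", stacklevel=2)
        t_sharp = mid + 1e-9
        t_blur = mid
    return ClassifyThresholds(t_sharp=t_sharp, t_blur=t_blur)
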