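"""Muscle-referenced percent-density pipeline.

The measurement principle: the pectoralis major muscle, visible in the MLO
view, has a radiographic density close to that of fibroglandular tissue.
The median pixel intensity of an operator-placed rectangular ROI over the
muscle, multiplied by a calibration constant (default 0.72, the mean
muscle-to-gland intensity ratio estimated on an independent calibration
sample), gives the threshold separating dense from adipose tissue. The
threshold is then applied in the CC view — which is normally free of
muscle — after separating the breast from the exact-zero background, and
percent density is the dense-pixel fraction of the breast area.

All masks share the image shape; coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .images import MammogramImage, View

#: Default muscle-to-gland calibration constant.
DEFAULT_CONSTANT = 0.72

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular pectoral-muscle sampling region on the MLO view.

    Half-open, 0-based pixel ranges: rows ``[row_start, row_end)``,
    columns ``[col_start, col_end)``.
    """

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (self.row_start < self.row_end and self.col_start < self.col_end):
            raise ValueError("ROI must have positive area (start < end)")
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("ROI coordinates must be non-negative")

    def validate_on(self, image: MammogramImage) -> None:
        rows, cols = image.shape
        if self.row_end > rows or self.col_end > cols:
            raise ValueError(
                f"ROI {self} exceeds image bounds {rows}×{cols}"
            )

    @property
    def area(self) -> int:
        return (self.row_end - self.row_start) * (self.col_end - self.col_start)

    @classmethod
    def parse(cls, text: str) -> "RoiSpec":
        """Parse ``"R0,R1,C0,C1"`` into a spec."""
        parts = text.split(",")
        if len(parts) != 4:
            raise ValueError(f"expected R0,R1,C0,C1 — got {text!r}")
        r0, r1, c0, c1 = (int(p) for p in parts)
        return cls(r0, r1, c0, c1)


@dataclass
class BreastMask:
    """Boolean breast-area mask over a CC image."""

    mask: np.ndarray
    n_breast: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("breast mask must be 2D")
        self.n_breast = int(self.mask.sum())


@dataclass
class DensityResult:
    """Full output of one percent-density measurement."""

    muscle_median: float
    constant: float
    threshold: float
    n_breast: int
    n_dense: int
    percent_density: float
    reported_percent: int
    dense_mask: np.ndarray

    @property
    def birads(self) -> str:
        from .classify import classify_birads

        return classify_birads(self.percent_density).label

    @property
    def dense_flag(self) -> bool:
        from .classify import classify_dense

        return classify_dense(self.percent_density)

    def to_dict(self) -> dict:
        """JSON-ready summary (masks omitted)."""
        return {
            "muscle_median": self.muscle_median,
            "constant": self.constant,
            "threshold": self.threshold,
            "n_breast": self.n_breast,
            "n_dense": self.n_dense,
            "percent_density": self.percent_density,
            "reported_percent": self.reported_percent,
            "birads": self.birads,
            "dense_flag": self.dense_flag,
        }


def compute_roi_median(image: MammogramImage, roi: RoiSpec) -> float:
    """Median intensity of all pixels inside the muscle ROI (MLO view).

    Even pixel counts use the mean of the two central order statistics.
    All pixels in the rectangle contribute, including zeros.
    """
    if image.view is not View.MLO:
        raise ValueError(f"muscle ROI must be sampled on the MLO view, got {image.view.value}")
    roi.validate_on(image)
    block = image.pixels[roi.row_start : roi.row_end, roi.col_start : roi.col_end]
    return float(np.median(block))


def compute_threshold(muscle_median: float, constant: float = DEFAULT_CONSTANT) -> float:
    """Dense-tissue threshold: muscle median × calibration constant."""
    if constant <= 0:
        raise ValueError("constant must be positive")
    if muscle_median < 0:
        raise ValueError("muscle median must be non-negative")
    return muscle_median * constant


def segment_background(
    image: MammogramImage, mode: str = "literal"
) -> BreastMask:
    """Separate the breast from the zero-valued background (CC view).

    ``literal`` mode implements the definition exactly: background is the
    set of zero-valued pixels whose entire 8-neighbourhood is zero, with
    off-image neighbours treated as zero; the breast is the complement
    (so the one-pixel rim of zeros touching tissue counts as breast).

    ``component`` mode instead takes the largest border-touching
    zero-valued connected component as background, which is robust to
    isolated zero holes inside the breast.
    """
    zero = image.pixels == 0
    if mode == "literal":
        background = ndimage.binary_erosion(
            zero, structure=_EIGHT_CONN, border_value=1
        )
    elif mode == "component":
        labels, n = ndimage.label(zero, structure=_EIGHT_CONN)
        background = np.zeros_like(zero)
        if n:
            border_ids = np.unique(
                np.concatenate(
                    [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
                )
            )
            border_ids = border_ids[border_ids > 0]
            if border_ids.size:
                sizes = ndimage.sum_labels(zero, labels, border_ids)
                background = labels == border_ids[int(np.argmax(sizes))]
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    return BreastMask(~background)


def compute_dense_mask(
    image: MammogramImage, breast: BreastMask, threshold: float
) -> np.ndarray:
    """Dense-pixel mask: breast pixels whose value is ≥ the threshold."""
    if breast.mask.shape != image.shape:
        raise ValueError("breast mask shape does not match image")
    if threshold <= 0:
        raise ValueError(
            "threshold must be positive (a zero threshold would classify the "
            "background as dense)"
        )
    return breast.mask & (image.pixels >= threshold)


def compute_percent_density(
    breast: BreastMask, dense: np.ndarray
) -> tuple[float, int]:
    """Percent dense area and its 1–100 integer report.

    ``percent = 100 · n_dense / n_breast``. The integer report rounds half
    away from zero and is clamped to at least 1 whenever any dense pixel
    exists; it is 0 only for an empty dense set.
    """
    if breast.n_breast == 0:
        raise ValueError("no breast segmented (n_breast == 0)")
    n_dense = int(np.count_nonzero(dense))
    percent = 100.0 * n_dense / breast.n_breast
    reported = int(np.floor(percent + 0.5))  # half away from zero; percent ≥ 0
    if n_dense > 0:
        reported = max(reported, 1)
    return percent, reported


def make_overlay(
    image: MammogramImage,
    dense: np.ndarray,
    color: tuple[int, int, int] = (255, 64, 64),
) -> np.ndarray:
    """RGB visual feedback: dense pixels tinted, the rest grayscale.

    Non-dense pixels replicate the grayscale value in all three channels
    (rescaled to 8 bits when the source exceeds the 0–255 range); dense
    pixels are painted the highlight color exactly, so tinted-pixel counts
    equal dense-pixel counts.
    """
    dense = np.asarray(dense, dtype=bool)
    if dense.shape != image.shape:
        raise ValueError("dense mask shape does not match image")
    gray = image.pixels
    vmax = gray.max()
    if vmax > 255:
        gray = gray * (255.0 / vmax)
    gray8 = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    rgb = np.repeat(gray8[:, :, None], 3, axis=2)
    rgb[dense] = np.asarray(color, dtype=np.uint8)
    return rgb


def measure(
    mlo: MammogramImage,
    cc: MammogramImage,
    roi: RoiSpec,
    constant: float = DEFAULT_CONSTANT,
    background_mode: str = "literal",
) -> DensityResult:
    """Run the full pipeline on one MLO/CC pair.

    Deterministic: identical inputs give bit-identical results. Raises if
    the ROI median is zero (threshold would admit the background) or if no
    breast is segmented.
    """
    if mlo.view is not View.MLO:
        raise ValueError("first image must be the MLO view")
    if cc.view is not View.CC:
        raise ValueError("second image must be the CC view")
    muscle_median = compute_roi_median(mlo, roi)
    threshold = compute_threshold(muscle_median, constant)
    if threshold <= 0:
        raise ValueError(
            "ROI median is zero — the ROI appears to lie on background; "
            "reposition it over the pectoral muscle"
        )
    breast = segment_background(cc, mode=background_mode)
    dense = compute_dense_mask(cc, breast, threshold)
    percent, reported = compute_percent_density(breast, dense)
    return DensityResult(
        muscle_median=muscle_median,
        constant=constant,
        threshold=threshold,
        n_breast=breast.n_breast,
        n_dense=int(np.count_nonzero(dense)),
        percent_density=percent,
        reported_percent=reported,
        dense_mask=dense,
    )


def aggregate_subject(percents: "list[float]") -> float:
    """Per-subject summary over the (usually two) CC measurements: the mean."""
    if not percents:
        raise ValueError("no per-image percents supplied")
    return float(np.mean(percents))
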