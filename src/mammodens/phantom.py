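"""Synthetic MLO/CC mammogram phantoms with exact ground truth.

The phantom emulates just the features the density pipeline relies on:

* a background of exact zeros,
* a half-elliptical breast of uniform adipose-level intensity attached to
  the chest-wall edge,
* elliptical glandular blobs of higher intensity inside the breast,
  covering a controllable fraction of the breast area,
* on the MLO view only, a triangular pectoral-muscle wedge in the
  chest-wall corner whose intensity is ``muscle_gland_ratio`` times the
  glandular intensity (default 0.72, the calibration ratio),
* optional additive Gaussian noise inside tissue only, clipped at zero,
  so the exact-zero background definition remains valid.

Ground truth is bookkept under the pipeline's own background rule: the
breast-area truth includes the one-pixel rim of zero pixels that touch
tissue, because those are not "exclusively surrounded by zeros" and are
therefore breast by definition. With zero noise the pipeline recovers
``realized_dense_fraction`` exactly.

No attempt is made at parenchymal texture, scatter or compression realism:
the phantom exists to test the algorithm, not to imitate a detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .density import RoiSpec
from .images import Laterality, MammogramImage, Photometric, View

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic MLO/CC phantom pair.

    Intensities are on an arbitrary linear scale (defaults fit a 16-bit
    range). The defaults put adipose tissue (300) well below the working
    threshold ``ratio × constant × glandular`` (518.4 when the measurement
    constant equals the ratio 0.72) and glandular tissue (1000) well above
    it, leaving wide noise margins on both sides.
    """

    shape: tuple[int, int] = (256, 256)
    adipose_intensity: float = 300.0
    glandular_intensity: float = 1000.0
    muscle_gland_ratio: float = 0.72
    target_dense_fraction: float = 0.4
    n_blobs: int = 6
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 64 or cols < 64:
            raise ValueError("phantom shape must be at least 64×64")
        muscle = self.muscle_gland_ratio * self.glandular_intensity
        if not (0 < self.adipose_intensity < muscle < self.glandular_intensity):
            raise ValueError(
                "need 0 < adipose < ratio×glandular < glandular so the muscle "
                "reference separates adipose from glandular tissue"
            )
        if not 0 < self.target_dense_fraction < 1:
            raise ValueError("target_dense_fraction must be in (0, 1)")
        if self.n_blobs < 1:
            raise ValueError("n_blobs must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def muscle_intensity(self) -> float:
        return self.muscle_gland_ratio * self.glandular_intensity


@dataclass
class PhantomTruth:
    """A realized phantom pair plus its exact ground truth."""

    mlo: MammogramImage
    cc: MammogramImage
    roi: RoiSpec
    breast_mask_truth: np.ndarray  # breast-area truth on the CC view (incl. zero rim)
    dense_mask_truth: np.ndarray
    realized_dense_fraction: float
    spec: PhantomSpec

    @property
    def realized_percent(self) -> float:
        """Ground-truth percent density, computed with the identical
        count-ratio expression the pipeline uses (bit-exact comparable)."""
        return 100.0 * int(self.dense_mask_truth.sum()) / int(self.breast_mask_truth.sum())


def _breast_mask(rows: int, cols: int) -> np.ndarray:
    """Half-ellipse breast attached to the left (chest-wall) edge."""
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    cy = rows / 2.0
    a = 0.42 * rows  # vertical semi-axis
    b = 0.75 * cols  # horizontal semi-axis
    return ((r - cy) / a) ** 2 + (c / b) ** 2 <= 1.0


def _muscle_wedge(rows: int, cols: int) -> np.ndarray:
    """Top-left triangular pectoral wedge for the MLO view."""
    wedge_rows = int(0.5 * rows)
    wedge_cols = int(0.35 * cols)
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    return (r < wedge_rows) & (c < (1.0 - r / wedge_rows) * wedge_cols)


def _muscle_roi(rows: int, cols: int) -> RoiSpec:
    """A rectangle comfortably inside the muscle wedge."""
    return RoiSpec(
        row_start=int(0.10 * rows),
        row_end=int(0.25 * rows),
        col_start=int(0.05 * cols),
        col_end=int(0.15 * cols),
    )


def _ellipse(rows, cols, cy, cx, ry, rx) -> np.ndarray:
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    return ((r - cy) / ry) ** 2 + ((c - cx) / rx) ** 2 <= 1.0


def _place_blobs(
    breast: np.ndarray,
    n_breast_truth: int,
    target: float,
    n_blobs: int,
    rng: np.random.Generator,
    max_attempts: int = 500,
) -> np.ndarray:
    """Union of elliptical blobs covering ≈ target fraction of the breast.

    Blob areas are budgeted so the union reaches the target despite
    overlap: each placement draws semi-axes around the radius that would
    contribute the remaining area split over the remaining planned blobs,
    then small top-up blobs close any residual gap. Placement is rejection
    sampling of ellipses fully inside the breast.
    """
    rows, cols = breast.shape
    dense = np.zeros_like(breast)
    goal_px = target * n_breast_truth
    placed = 0
    attempts = 0
    breast_idx = np.argwhere(breast)
    while attempts < max_attempts:
        n_dense = int(dense.sum())
        remaining = goal_px - n_dense
        if remaining <= 0.005 * n_breast_truth:
            break
        if placed < n_blobs:
            area = remaining / (n_blobs - placed)
        else:
            area = min(remaining, 0.01 * n_breast_truth)
        r0 = max(2.0, np.sqrt(area / np.pi))
        ry = r0 * rng.uniform(0.7, 1.3)
        rx = area / (np.pi * ry)  # keep the product ≈ requested area
        rx = max(rx, 2.0)
        cy, cx = breast_idx[rng.integers(len(breast_idx))]
        blob = _ellipse(rows, cols, cy, cx, ry, rx)
        attempts += 1
        if not blob.any() or np.any(blob & ~breast):
            continue
        dense |= blob
        placed += 1
    if not dense.any():
        raise RuntimeError(
            "could not place any glandular blob inside the breast; "
            "the target fraction or geometry is unsatisfiable"
        )
    return dense


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate a reproducible MLO/CC phantom pair from a spec.

    Fully deterministic for a fixed ``spec`` (including its seed). Noise,
    when enabled, is added inside tissue only and clipped at zero; the
    realized dense fraction is recorded on the noise-free masks.
    """
    rows, cols = spec.shape
    rng = np.random.default_rng(spec.seed)

    breast = _breast_mask(rows, cols)
    # breast-area truth under the background rule: zeros touching tissue are
    # breast, i.e. the 3×3 dilation of the nonzero region
    breast_truth = ndimage.binary_dilation(breast, structure=_EIGHT_CONN)
    n_breast_truth = int(breast_truth.sum())

    dense = _place_blobs(
        breast, n_breast_truth, spec.target_dense_fraction, spec.n_blobs, rng
    )
    realized = float(dense.sum()) / n_breast_truth

    cc = np.zeros((rows, cols), dtype=np.float64)
    cc[breast] = spec.adipose_intensity
    cc[dense] = spec.glandular_intensity

    wedge = _muscle_wedge(rows, cols)
    mlo = np.zeros_like(cc)
    mlo[breast] = spec.adipose_intensity
    mlo[dense] = spec.glandular_intensity
    mlo[wedge] = spec.muscle_intensity

    if spec.noise_sd > 0:
        tissue_cc = cc > 0
        tissue_mlo = mlo > 0
        cc[tissue_cc] = np.clip(
            cc[tissue_cc] + rng.normal(0, spec.noise_sd, int(tissue_cc.sum())), 0, None
        )
        mlo[tissue_mlo] = np.clip(
            mlo[tissue_mlo] + rng.normal(0, spec.noise_sd, int(tissue_mlo.sum())),
            0,
            None,
        )

    roi = _muscle_roi(rows, cols)
    wedge_block = wedge[roi.row_start : roi.row_end, roi.col_start : roi.col_end]
    assert wedge_block.all(), "ROI must lie entirely inside the muscle wedge"

    mk = lambda px, view: MammogramImage(
        pixels=px,
        view=view,
        laterality=Laterality.UNKNOWN,
        bit_depth=16,
        source_photometric=Photometric.WHITE_IS_DENSE,
    )
    return PhantomTruth(
        mlo=mk(mlo, View.MLO),
        cc=mk(cc, View.CC),
        roi=roi,
        breast_mask_truth=breast_truth,
        dense_mask_truth=dense,
        realized_dense_fraction=realized,
        spec=spec,
    )
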