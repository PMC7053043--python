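import numpy as np
import pytest

from mammodens import MammogramImage, PhantomSpec, View, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Default noise-free phantom pair with known ground truth."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture()
def small_cc():
    """Tiny CC image with a hand-checkable layout."""
    px = np.zeros((5, 5))
    px[2, 2] = 80.0
    return MammogramImage(pixels=px, view=View.CC)


def brute_force_background(pixels: np.ndarray) -> np.ndarray:
    """Literal background rule by per-pixel double loop: a pixel is
    background iff it is zero and its whole 8-neighbourhood (off-image
    treated as zero) is zero."""
    rows, cols = pixels.shape
    out = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            if pixels[r, c] != 0:
                continue
            ok = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and pixels[rr, cc] != 0:
                        ok = False
            out[r, c] = ok
    return out


def brute_force_kappa(counts: np.ndarray) -> float:
    """Cohen's kappa straight from its definition by explicit loops."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    k = counts.shape[0]
    po = sum(counts[i, i] for i in range(k)) / n
    pe = 0.0
    for i in range(k):
        row = sum(counts[i, j] for j in range(k)) / n
        col = sum(counts[j, i] for j in range(k)) / n
        pe += row * col
    return (po - pe) / (1 - pe)
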