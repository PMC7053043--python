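"""mammodens: pectoral-muscle-referenced mammographic breast density.

Measures percent dense tissue on flat (2D) mammograms by thresholding the
CC view at the median pectoral-muscle intensity (sampled on the MLO view)
times a calibration constant, classifies the result into BI-RADS
4th-edition bands, and provides the method-comparison statistics
(Bland-Altman, ICC, Cohen's kappa) and synthetic phantoms needed to
validate such a measurement.
"""

from importlib import resources

__version__ = "0.1.0"

from .agreement import (
    AgreementReport,
    ConstantEstimate,
    ContingencyTable,
    KappaResult,
    PairedMeasurements,
    bland_altman,
    cohen_kappa,
    collapse_table,
    estimate_constant,
    icc,
)
from .classify import BiradsCategory, classify_birads, classify_dense
from .density import (
    DEFAULT_CONSTANT,
    BreastMask,
    DensityResult,
    RoiSpec,
    compute_dense_mask,
    compute_percent_density,
    compute_roi_median,
    compute_threshold,
    make_overlay,
    measure,
    segment_background,
)
from .images import Laterality, MammogramImage, Photometric, View, load_image, write_image
from .phantom import PhantomSpec, PhantomTruth, generate_phantom


def birads_agreement_table() -> ContingencyTable:
    """Packaged reference table: visual vs automated BI-RADS density
    categories for 291 screening mammograms, used as a regression fixture
    for the kappa statistics."""
    ref = resources.files("mammodens").joinpath("data/birads_agreement_291.csv")
    with resources.as_file(ref) as path:
        return ContingencyTable.from_csv(path)


__all__ = [
    "AgreementReport",
    "BiradsCategory",
    "BreastMask",
    "ConstantEstimate",
    "ContingencyTable",
    "DEFAULT_CONSTANT",
    "DensityResult",
    "KappaResult",
    "Laterality",
    "MammogramImage",
    "PairedMeasurements",
    "PhantomSpec",
    "PhantomTruth",
    "Photometric",
    "RoiSpec",
    "View",
    "birads_agreement_table",
    "bland_altman",
    "classify_birads",
    "classify_dense",
    "cohen_kappa",
    "collapse_table",
    "compute_dense_mask",
    "compute_percent_density",
    "compute_roi_median",
    "compute_threshold",
    "estimate_constant",
    "generate_phantom",
    "icc",
    "load_image",
    "make_overlay",
    "measure",
    "segment_background",
    "write_image",
]
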