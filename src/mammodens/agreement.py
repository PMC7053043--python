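"""Method-comparison statistics for paired density measurements.

Implements the validation toolkit for comparing an automated density
measurement against a reference (typically visual assessment by a
radiologist):

* Bland-Altman analysis — bias of the differences, its 95% CI, parametric
  95% limits of agreement (mean ± 1.96·SD), Shapiro-Wilk normality of the
  differences, one-sample t against zero bias, and the Pearson correlation
  of differences against pair means (proportional-bias check).
* Intraclass correlation — two-way random effects, absolute agreement,
  single measure (ICC(2,1)), with the Satterthwaite F-based 95% CI.
* Cohen's unweighted kappa on a K×K category table, with the large-sample
  null-hypothesis z statistic, plus category collapsing (e.g. the four
  density bands down to dense/non-dense).
* The muscle-to-gland calibration-constant estimator: mean per-image
  intensity ratio with a t-based 95% CI.

Differences are oriented *method_b − method_a*: with the reference in
``method_a`` and the automated method in ``method_b``, a positive bias
means the automated method reads higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# containers


@dataclass
class PairedMeasurements:
    """Equal-length paired vectors from two measurement methods."""

    method_a: np.ndarray
    method_b: np.ndarray

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=np.float64)
        self.method_b = np.asarray(self.method_b, dtype=np.float64)
        if self.method_a.ndim != 1 or self.method_b.ndim != 1:
            raise ValueError("paired measurements must be 1D vectors")
        if len(self.method_a) != len(self.method_b):
            raise ValueError("methods must have equal length")

    @property
    def n(self) -> int:
        return len(self.method_a)

    @classmethod
    def from_csv(cls, path) -> "PairedMeasurements":
        """Read a pairs CSV with columns ``method_a`` and ``method_b``
        (a leading ``subject`` column is allowed and ignored)."""
        df = pd.read_csv(path)
        missing = {"method_a", "method_b"} - set(df.columns)
        if missing:
            raise ValueError(f"pairs CSV lacks columns: {sorted(missing)}")
        return cls(df["method_a"].to_numpy(), df["method_b"].to_numpy())


@dataclass
class AgreementReport:
    """Bland-Altman summary of paired measurements (percentage points)."""

    n: int
    bias: float
    bias_ci: tuple[float, float]
    sd_diff: float
    loa_halfwidth: float
    loa: tuple[float, float]
    shapiro_stat: float
    shapiro_p: float
    t_stat: float
    t_p: float
    pearson_r: float
    pearson_p: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bias": self.bias,
            "bias_ci": list(self.bias_ci),
            "sd_diff": self.sd_diff,
            "loa_halfwidth": self.loa_halfwidth,
            "loa": list(self.loa),
            "shapiro_stat": self.shapiro_stat,
            "shapiro_p": self.shapiro_p,
            "t_stat": self.t_stat,
            "t_p": self.t_p,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
        }


@dataclass
class ContingencyTable:
    """Square K×K table of paired category counts (rows = method 1,
    columns = method 2)."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.labels = tuple(str(x) for x in self.labels)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match the labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_csv(cls, path) -> "ContingencyTable":
        """Read a labeled square table: first column = row labels,
        header = column labels (must match the row labels in order)."""
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError("row and column labels must match in order")
        return cls(df.to_numpy(), tuple(df.columns.astype(str)))


@dataclass
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    z: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "p_observed": self.p_observed,
            "p_expected": self.p_expected,
            "z": self.z,
            "p_value": self.p_value,
        }


@dataclass
class ConstantEstimate:
    mean_ratio: float
    ci: tuple[float, float] | None
    n: int

    def to_dict(self) -> dict:
        return {
            "mean_ratio": self.mean_ratio,
            "ci": list(self.ci) if self.ci is not None else None,
            "n": self.n,
        }


# ---------------------------------------------------------------------------
# Bland-Altman


def bland_altman(pairs: PairedMeasurements) -> AgreementReport:
    """Bland-Altman agreement analysis of two measurement methods.

    Differences ``d_i = b_i − a_i``; bias is their mean with a t-based 95%
    CI; limits of agreement are bias ± 1.96·SD(d) with the sample
    (n−1) standard deviation. The Pearson correlation of ``d_i`` with the
    pair means flags proportional bias. When the differences have zero
    variance (identical methods) the test statistics are undefined and
    returned as NaN.
    """
    if pairs.n < 3:
        raise ValueError("Bland-Altman requires at least 3 pairs")
    a, b = pairs.method_a, pairs.method_b
    d = b - a
    means = (a + b) / 2.0
    n = pairs.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    tcrit = stats.t.ppf(0.975, n - 1)
    se = sd / np.sqrt(n)
    bias_ci = (bias - tcrit * se, bias + tcrit * se)
    if np.ptp(means) == 0:
        raise ValueError("pair means have zero variance; correlation undefined")
    if sd == 0:
        sh_stat = sh_p = t_stat = t_p = r = r_p = float("nan")
    else:
        sh_stat, sh_p = stats.shapiro(d)
        t_stat, t_p = stats.ttest_1samp(d, 0.0)
        r, r_p = stats.pearsonr(d, means)
    return AgreementReport(
        n=n,
        bias=bias,
        bias_ci=(float(bias_ci[0]), float(bias_ci[1])),
        sd_diff=sd,
        loa_halfwidth=half,
        loa=(bias - half, bias + half),
        shapiro_stat=float(sh_stat),
        shapiro_p=float(sh_p),
        t_stat=float(t_stat),
        t_p=float(t_p),
        pearson_r=float(r),
        pearson_p=float(r_p),
    )


# ---------------------------------------------------------------------------
# intraclass correlation


def icc(pairs: PairedMeasurements, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares of the n×2 ratings matrix
    (subjects × methods); the CI is the standard F-based interval with
    Satterthwaite degrees of freedom. Raises on degenerate input where all
    subjects have identical values (no between-subject variance).
    """
    if pairs.n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    X = np.column_stack([pairs.method_a, pairs.method_b])
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    msr = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    resid = X - row_means[:, None] - col_means[None, :] + grand
    mse = float((resid**2).sum()) / ((n - 1) * (k - 1))
    if msr == 0:
        raise ValueError("degenerate ratings: no between-subject variance")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = (msr - mse) / denom

    if value >= 1.0 or mse == 0:
        # perfect agreement: the F-based interval collapses
        return float(value), (float(value), float(value))
    a_coef = k * value / (n * (1 - value))
    b_coef = 1 + k * value * (n - 1) / (n * (1 - value))
    v = (a_coef * msc + b_coef * mse) ** 2 / (
        (a_coef * msc) ** 2 / (k - 1) + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(value), (float(lower), float(upper))


# ---------------------------------------------------------------------------
# kappa


def cohen_kappa(table: ContingencyTable) -> KappaResult:
    """Unweighted Cohen's kappa with the large-sample H0 z statistic.

    ``kappa = (p_o − p_e) / (1 − p_e)`` with observed agreement ``p_o``
    (diagonal fraction) and chance agreement ``p_e`` (marginal products).
    The z statistic uses the null-hypothesis variance
    ``var0 = [p_e + p_e² − Σ_i p_{i·} p_{·i} (p_{i·} + p_{·i})] / [n (1 − p_e)²]``
    and the p-value is the two-sided normal tail.
    """
    counts = table.counts.astype(np.float64)
    n = counts.sum()
    p = counts / n
    po = float(np.trace(p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float((row * col).sum())
    if pe >= 1.0:
        raise ValueError("expected agreement is 1; kappa undefined")
    kappa = (po - pe) / (1 - pe)
    var0 = (pe + pe**2 - float((row * col * (row + col)).sum())) / (n * (1 - pe) ** 2)
    if var0 > 0:
        z = float(kappa / np.sqrt(var0))
        p_value = float(2 * stats.norm.sf(abs(z)))
    else:  # degenerate marginals: the H0 variance vanishes
        z = float("nan")
        p_value = float("nan")
    return KappaResult(
        kappa=float(kappa), p_observed=po, p_expected=pe, z=z, p_value=p_value
    )


def collapse_table(
    table: ContingencyTable, grouping: dict[str, str]
) -> ContingencyTable:
    """Merge categories by a label→group mapping, summing cells.

    Group order follows first appearance among the original labels. The
    grand total and grouped marginals are preserved. Every original label
    must be mapped.
    """
    missing = [lab for lab in table.labels if lab not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover labels: {missing}")
    groups: list[str] = []
    for lab in table.labels:
        g = grouping[lab]
        if g not in groups:
            groups.append(g)
    index = {g: i for i, g in enumerate(groups)}
    k = len(groups)
    out = np.zeros((k, k), dtype=np.int64)
    for i, li in enumerate(table.labels):
        for j, lj in enumerate(table.labels):
            out[index[grouping[li]], index[grouping[lj]]] += table.counts[i, j]
    return ContingencyTable(out, tuple(groups))


# ---------------------------------------------------------------------------
# calibration-constant estimator


def estimate_constant(
    muscle_medians, gland_medians, alpha: float = 0.05
) -> ConstantEstimate:
    """Mean muscle/gland intensity ratio with a t-based 95% CI.

    This is the procedure by which the default threshold constant is
    calibrated: per-image ratios ``r_i = muscle_i / gland_i``, their mean,
    and a Student-t interval. With a single pair the point estimate is
    returned and the CI is signalled as ``None``.
    """
    muscle = np.asarray(muscle_medians, dtype=np.float64)
    gland = np.asarray(gland_medians, dtype=np.float64)
    if muscle.shape != gland.shape or muscle.ndim != 1:
        raise ValueError("muscle and gland medians must be equal-length vectors")
    if muscle.size == 0:
        raise ValueError("no pairs supplied")
    if np.any(gland <= 0):
        raise ValueError("gland medians must be strictly positive")
    ratios = muscle / gland
    mean = float(ratios.mean())
    n = ratios.size
    if n < 2:
        return ConstantEstimate(mean_ratio=mean, ci=None, n=n)
    se = float(ratios.std(ddof=1)) / np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    return ConstantEstimate(
        mean_ratio=mean, ci=(mean - tcrit * se, mean + tcrit * se), n=n
    )
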