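"""Between-system agreement statistics and method-comparison plots.

Two kinds of comparison, mirroring common practice in concurrent-validity
studies of motion-capture systems:

* *time-series* parameters (angles, displacements, speeds over time) are
  compared per participant by Pearson's r and the mean absolute difference,
  then aggregated across participants by plain mean and SD;
* *scalar* parameters (peaks, smoothness) are compared across participants by
  the mean absolute error (MAE) and Bland-Altman analysis: bias = mean
  difference, limits of agreement (LoA) = bias +- 1.96 * SD of the
  differences, and a paired t-test on the bias.

Differences are oriented test - reference throughout (the sign of the bias
flips with the orientation; MAE, SDs and r do not). Sample SDs use the n-1
denominator. p-values are reported unadjusted.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PairedSeries", "AgreementRow", "pearson_r", "aggregate_r",
           "bland_altman", "make_plots", "LOA_FACTOR"]

#: Normal-quantile factor defining the ~95% limits of agreement.
LOA_FACTOR = 1.96


class ConstantSeriesError(ValueError):
    """Raised when Pearson's r is undefined because a series is constant."""


@dataclass(frozen=True)
class PairedSeries:
    """One parameter measured by two systems on a common timestamp grid,
    already reduced to frames valid in both."""

    x: np.ndarray
    y: np.ndarray
    participant_id: str
    parameter: str

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("paired series must be 1-D arrays of equal length")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class AgreementRow:
    """All agreement statistics for one parameter across participants."""

    parameter: str
    n: int
    mean_a: float
    mean_b: float
    mae: float
    mae_sd: float
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    p_bias: float
    r_mean: float | None = None
    r_sd: float | None = None
    degenerate_variance: bool = False


def pearson_r(pair: PairedSeries) -> float:
    """Product-moment correlation of the paired values.

    Requires >= 3 pairs and both series non-constant; a constant series makes
    the correlation undefined and raises :class:`ConstantSeriesError` so the
    caller can exclude (and report) the recording.
    """
    x, y = pair.x, pair.y
    if len(x) < 3:
        raise ValueError("Pearson's r requires at least 3 paired frames")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSeriesError(
            f"constant series for {pair.parameter!r} ({pair.participant_id}); "
            "correlation undefined"
        )
    return float(np.corrcoef(x, y)[0, 1])


def aggregate_r(r_values) -> tuple[float, float]:
    """Arithmetic mean and sample SD of per-participant correlations.

    No Fisher-z transform is applied: validity studies conventionally report
    the plain average r with its SD. A single value has SD 0.
    """
    r = np.asarray([v for v in r_values if np.isfinite(v)], dtype=float)
    if r.size == 0:
        raise ValueError("no finite correlation values to aggregate")
    sd = float(np.std(r, ddof=1)) if r.size > 1 else 0.0
    return float(r.mean()), sd


def bland_altman(a, b, parameter: str = "", r_mean: float | None = None,
                 r_sd: float | None = None) -> AgreementRow:
    """Bland-Altman statistics for paired scalar measurements.

    ``a`` is the test system, ``b`` the reference; differences d = a - b.
    Returns bias = mean(d), sd_diff = SD(d) (n-1), LoA = bias +- 1.96*sd_diff,
    MAE = mean(|d|) with its SD, and the two-sided paired t-test p-value of
    the bias against zero. With zero difference variance the t-test is
    degenerate: p is reported as 0 when the bias is nonzero (systematic
    offset certain) and 1 when all differences vanish, with a flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("Bland-Altman analysis requires at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        p = 0.0 if bias != 0.0 else 1.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    ad = np.abs(d)
    return AgreementRow(
        parameter=parameter, n=n,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        mae=float(ad.mean()), mae_sd=float(np.std(ad, ddof=1)),
        bias=bias, sd_diff=sd,
        loa_lower=bias - LOA_FACTOR * sd, loa_upper=bias + LOA_FACTOR * sd,
        p_bias=p, r_mean=r_mean, r_sd=r_sd, degenerate_variance=degenerate,
    )


def make_plots(rows, pairs, outdir):
    """Scatter (with line of equality) and Bland-Altman plot per parameter.

    ``rows`` is an iterable of :class:`AgreementRow`; ``pairs`` maps parameter
    name to ``(a, b)`` arrays (test, reference). Returns a dict per parameter
    with the file paths and the exact data table behind each plot, so tests
    can check the data layer rather than pixels. Parameters without pairs are
    skipped with a warning.
    """
    import warnings
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = {row.parameter: row for row in rows}
    out = {}
    for parameter, row in rows.items():
        if parameter not in pairs:
            warnings.warn(f"no paired values for {parameter!r}; skipping plots",
                          stacklevel=2)
            continue
        a, b = (np.asarray(v, dtype=float) for v in pairs[parameter])
        mean = 0.5 * (a + b)
        diff = a - b
        safe = parameter.replace("/", "_")

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(b, a, s=18, alpha=0.8)
        lims = [min(a.min(), b.min()), max(a.max(), b.max())]
        ax.plot(lims, lims, "k--", lw=1, label="x = y")
        ax.set_xlabel("reference")
        ax.set_ylabel("test")
        ax.set_title(parameter)
        ax.legend(frameon=False)
        scatter_path = outdir / f"{safe}_scatter.png"
        fig.savefig(scatter_path, dpi=110, bbox_inches="tight")
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(mean, diff, s=18, alpha=0.8)
        ax.axhline(row.bias, color="k", lw=1, label="bias")
        ax.axhline(row.loa_upper, color="k", lw=1, ls="--", label="LoA")
        ax.axhline(row.loa_lower, color="k", lw=1, ls="--")
        ax.set_xlabel("mean of methods")
        ax.set_ylabel("difference (test - reference)")
        ax.set_title(parameter)
        ax.legend(frameon=False)
        ba_path = outdir / f"{safe}_bland_altman.png"
        fig.savefig(ba_path, dpi=110, bbox_inches="tight")
        plt.close(fig)

        out[parameter] = {
            "scatter": scatter_path,
            "bland_altman": ba_path,
            "data": pd.DataFrame({
                "test": a, "reference": b, "mean": mean, "diff": diff,
                "bias": row.bias, "loa_lower": row.loa_lower,
                "loa_upper": row.loa_upper,
            }),
        }
    return out
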