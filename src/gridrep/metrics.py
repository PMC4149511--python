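"""Scoring a sample or interpolated surface against the population raster.

Three complementary measures:

* **representativeness** — two-sample Kolmogorov-Smirnov statistic D
  between the value distribution of a sample (or of all interpolated
  cells) and the distribution of all population cells.  Higher p means
  more similar distributions, i.e. a more representative sample.
* **similarity** — Pearson correlation between interpolated and true
  cell values (cell-wise, so defined only for interpolations).
* **accuracy** — root-mean-square error of the same cell-wise pairs.

Correlation with a zero-variance side is *undefined* and reported as
NaN, never coerced to 0: a constant area carries no similarity
information and would otherwise distort downstream trend fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .sampling import SampleValues
from .terrain import Raster

__all__ = [
    "MetricRecord",
    "ks_two_sample",
    "pearson_r",
    "rmse",
    "score",
    "histogram_report",
    "METRIC_COLUMNS",
]

#: Stable column order for MetricRecord tables written as CSV.
METRIC_COLUMNS = [
    "area_id",
    "sample_size",
    "iteration",
    "source",
    "ks_D",
    "ks_p",
    "pearson_r",
    "rmse",
    "area_sd",
]


@dataclass
class MetricRecord:
    """One evaluation of a sample or interpolation against a population.

    ``pearson_r`` and ``rmse`` are NaN for ``source='sample'`` (samples
    and population differ in length; both are cell-wise comparisons);
    ``pearson_r`` is also NaN (undefined) when either side has zero
    variance.
    """

    area_id: str
    sample_size: int
    iteration: int
    source: str  # "sample" | "interpolation"
    ks_D: float
    ks_p: float
    pearson_r: float
    rmse: float
    area_sd: float

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in METRIC_COLUMNS}


def ks_two_sample(a, b, method: str = "asymp") -> tuple[float, float]:
    """Exact two-sample KS statistic D with the asymptotic p-value.

    D is the supremum of |F_a - F_b| over the pooled sorted values
    (exact under ties).  With ``method="asymp"`` (default) the p-value
    is the asymptotic Kolmogorov survival function at
    ``sqrt(n_eff) * D`` with ``n_eff = n_a * n_b / (n_a + n_b)``,
    clamped to [0, 1] — the standard choice when one side is a raster
    population of thousands of cells.  ``method="exact"`` substitutes
    the small-sample exact p-value (D is unchanged).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    pooled = np.concatenate([a_sorted, b_sorted])
    cdf_a = np.searchsorted(a_sorted, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b_sorted, pooled, side="right") / b.size
    d = float(np.abs(cdf_a - cdf_b).max())
    if method == "asymp":
        n_eff = a.size * b.size / (a.size + b.size)
        p = float(special.kolmogorov(np.sqrt(n_eff) * d))
    elif method == "exact":
        from scipy import stats

        p = float(stats.ks_2samp(a, b, method="exact").pvalue)
    else:
        raise ValueError("method must be 'asymp' or 'exact'")
    return d, min(max(p, 0.0), 1.0)


def pearson_r(a, b) -> float:
    """Product-moment correlation; NaN (undefined) if either side is constant."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def rmse(a, b) -> float:
    """Root-mean-square difference of two equal-length value lists."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("length mismatch")
    if a.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def score(
    sample_or_surface,
    population: Raster,
    area_id: str = "",
    sample_size: int | None = None,
    iteration: int = 0,
) -> MetricRecord:
    """Score a :class:`SampleValues` or an interpolated :class:`Raster`.

    The KS comparison always runs the value list (sample values, or all
    interpolated cells) against *all* non-missing population cells.
    Correlation and RMSE are cell-wise and computed for interpolated
    surfaces only.
    """
    pop_vals = population.valid_values()
    area_sd = population.sd()
    if isinstance(sample_or_surface, SampleValues):
        sv = sample_or_surface
        d, p = ks_two_sample(sv.values, pop_vals)
        return MetricRecord(
            area_id=area_id or sv.source_area_id,
            sample_size=sample_size if sample_size is not None else sv.design.n,
            iteration=iteration,
            source="sample",
            ks_D=d,
            ks_p=p,
            pearson_r=float("nan"),
            rmse=float("nan"),
            area_sd=area_sd,
        )
    if isinstance(sample_or_surface, Raster):
        surf = sample_or_surface
        if surf.shape != population.shape or surf.cell_size != population.cell_size:
            raise ValueError("interpolated surface geometry must match population")
        mask = ~np.isnan(population.values)
        pred = surf.values[mask]
        true = population.values[mask]
        d, p = ks_two_sample(pred, true)
        return MetricRecord(
            area_id=area_id,
            sample_size=sample_size if sample_size is not None else -1,
            iteration=iteration,
            source="interpolation",
            ks_D=d,
            ks_p=p,
            pearson_r=pearson_r(pred, true),
            rmse=rmse(pred, true),
            area_sd=area_sd,
        )
    raise TypeError("expected SampleValues or Raster")


def histogram_report(
    values, population, bin_width: float = 20.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired histogram counts on shared bins for back-to-back plots.

    Bin edges are anchored at ``floor(min / bin_width) * bin_width`` and
    extend past the pooled maximum; the default 20 m width matches the
    conventional elevation-histogram binning.  Returns
    ``(edges, counts_values, counts_population)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(values, dtype=float).ravel()
    population = np.asarray(population, dtype=float).ravel()
    if values.size == 0 or population.size == 0:
        raise ValueError("empty input")
    lo = np.floor(min(values.min(), population.min()) / bin_width) * bin_width
    hi = max(values.max(), population.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width + 1e-12)))
    if lo + n_bins * bin_width <= hi:  # right edge must cover the max
        n_bins += 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    cv, _ = np.histogram(values, bins=edges)
    cp, _ = np.histogram(population, bins=edges)
    return edges, cv, cp
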