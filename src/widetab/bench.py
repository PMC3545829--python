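"""Benchmark harness: speed and scaling protocols plus regression fits.

Two protocols mirror the classic cluster benchmarks for this kind of
pipeline: processing time as a function of input size at fixed worker
count (expected linear — each record costs a constant amount plus a fixed
job lead time), and processing time as a function of worker count on the
full dataset (expected to follow a power law t = c·w^e, with e = −1 the
ideal linear speed-up).  Absolute wall-clock numbers are machine-dependent
and are never compared across machines; the analysis object is the fitted
relationship.

The power model is fit by ordinary least squares on log t vs log x, and
its R² is reported on that log scale.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .engine import TimingResult, run_pipeline
from .errors import (
    DegenerateDesignError,
    InvalidParamsError,
    NonPositiveValueError,
)
from .gff import GroupCatalog
from .synth import SynthDataset, default_catalog
from .transform import parse_aggspec

__all__ = [
    "RegressionFit",
    "fit_linear",
    "fit_power",
    "per_doubling_change",
    "run_speed_benchmark",
    "run_scaling_benchmark",
    "summarize",
    "fit_speed",
    "fit_scaling",
    "plot_benchmark",
]


@dataclass(frozen=True)
class RegressionFit:
    """A fitted benchmark model.

    ``model`` is "linear" (t = a·x + b, coefficients (a, b)) or "power"
    (t = c·x^e, coefficients (c, e)).  ``r_squared`` is on the fitting
    scale: raw for the linear model, log–log for the power model.
    """

    model: str
    coefficients: tuple[float, float]
    r_squared: float
    n_observations: int

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.model == "linear":
            a, b = self.coefficients
            return a * x + b
        c, e = self.coefficients
        return c * x ** e


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R²; R²=1 when residuals vanish
    on a zero-variance response."""
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    ss_res = float(np.dot(residuals, residuals))
    ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-20 * max(1.0, float(np.dot(y, y))) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def fit_linear(points) -> RegressionFit:
    """OLS fit of t = a·x + b to (x, t) points."""
    pts = [(float(x), float(t)) for x, t in points]
    if len({x for x, _ in pts}) < 2:
        raise DegenerateDesignError("linear fit needs ≥ 2 distinct x values")
    x = np.array([p[0] for p in pts])
    t = np.array([p[1] for p in pts])
    slope, intercept, r2 = _ols_line(x, t)
    return RegressionFit("linear", (slope, intercept), r2, len(pts))


def fit_power(points) -> RegressionFit:
    """Fit t = c·x^e by OLS on the log–log scale.

    All x and t must be strictly positive.  Coefficients come back as
    (c, e); R² is the log-scale coefficient of determination.
    """
    pts = [(float(x), float(t)) for x, t in points]
    if any(x <= 0 or t <= 0 for x, t in pts):
        raise NonPositiveValueError("power fit needs strictly positive values")
    if len({x for x, _ in pts}) < 2:
        raise DegenerateDesignError("power fit needs ≥ 2 distinct x values")
    log_x = np.log(np.array([p[0] for p in pts]))
    log_t = np.log(np.array([p[1] for p in pts]))
    exponent, log_c, r2 = _ols_line(log_x, log_t)
    return RegressionFit("power", (float(np.exp(log_c)), exponent), r2, len(pts))


def per_doubling_change(exponent: float) -> float:
    """Percentage decrease in predicted time per doubling of workers.

    Under t = c·w^e, doubling w multiplies t by 2^e, a decrease of
    (1 − 2^e) × 100 percent.  e = −1 gives 50 (ideal halving); e = 0
    gives 0 (no scaling).
    """
    return (1.0 - 2.0 ** float(exponent)) * 100.0


def _subsample(dataset: SynthDataset, fraction: float) -> SynthDataset:
    """Deterministic by-patient subsample: the first ⌈fraction·n⌉ subjects."""
    if not 0 < fraction <= 1:
        raise InvalidParamsError(f"fraction must be in (0, 1], got {fraction}")
    subjects = sorted({s.subject_id for s in dataset.summaries})
    keep = set(subjects[: max(1, round(fraction * len(subjects)))])
    return SynthDataset(
        summaries=[s for s in dataset.summaries if s.subject_id in keep],
        events=[e for e in dataset.events if e.subject_id in keep],
        courses=[c for c in dataset.courses if c.subject_id in keep],
        params=dataset.params,
    )


def _timed_pipeline(dataset: SynthDataset, catalog: GroupCatalog,
                    workers: int) -> float:
    aggspec = parse_aggspec("", catalog)  # COUNT every group
    t0 = time.perf_counter()
    run_pipeline(
        dataset.events,
        catalog,
        ("subject_id", "episode_id"),
        aggspec,
        summaries=dataset.summaries,
        workers=workers,
    )
    return time.perf_counter() - t0


def run_speed_benchmark(
    dataset: SynthDataset,
    fractions=(1.0, 0.5, 0.25, 0.125),
    reps: int = 3,
    workers: int = 1,
    catalog: GroupCatalog | None = None,
) -> list[TimingResult]:
    """Time the full pipeline on by-patient subsamples of the dataset.

    Each fraction is run ``reps`` times; the record count attached to each
    observation is the subsample's event count.
    """
    if reps < 1:
        raise InvalidParamsError(f"reps must be ≥ 1, got {reps}")
    catalog = catalog if catalog is not None else default_catalog(dataset.params)
    results = []
    for fraction in sorted(fractions):
        sub = _subsample(dataset, fraction)
        for rep in range(reps):
            elapsed = _timed_pipeline(sub, catalog, workers)
            results.append(TimingResult(
                records=len(sub.events),
                workers=workers,
                repetition=rep,
                elapsed_seconds=max(elapsed, 1e-9),
            ))
    return results


def run_scaling_benchmark(
    dataset: SynthDataset,
    worker_counts=(1, 2, 4, 8),
    reps: int = 3,
    catalog: GroupCatalog | None = None,
) -> list[TimingResult]:
    """Time the full pipeline at each worker count, ``reps`` times each."""
    if reps < 1:
        raise InvalidParamsError(f"reps must be ≥ 1, got {reps}")
    if any(w < 1 for w in worker_counts):
        raise InvalidParamsError("worker counts must be ≥ 1")
    catalog = catalog if catalog is not None else default_catalog(dataset.params)
    results = []
    for workers in worker_counts:
        for rep in range(reps):
            elapsed = _timed_pipeline(dataset, catalog, workers)
            results.append(TimingResult(
                records=len(dataset.events),
                workers=workers,
                repetition=rep,
                elapsed_seconds=max(elapsed, 1e-9),
            ))
    return results


def summarize(results, by: str = "records"):
    """Per-point mean/max/min table in the conventional benchmark layout.

    ``by`` is "records" for the speed protocol or "workers" for the
    scaling protocol; columns are the grouping variable then average, max
    and min processing time in seconds.
    """
    import pandas as pd

    if by not in ("records", "workers"):
        raise InvalidParamsError(f"summarize by {by!r}")
    frame = pd.DataFrame(
        {
            by: [getattr(r, by) for r in results],
            "elapsed": [r.elapsed_seconds for r in results],
        }
    )
    grouped = frame.groupby(by)["elapsed"].agg(["mean", "max", "min"])
    grouped = grouped.rename(columns={
        "mean": "average_time_s", "max": "max_time_s", "min": "min_time_s"
    })
    return grouped.reset_index()


def fit_speed(results) -> RegressionFit:
    """Linear fit of elapsed seconds vs record count."""
    return fit_linear([(r.records, r.elapsed_seconds) for r in results])


def fit_scaling(results) -> RegressionFit:
    """Power-law fit of elapsed seconds vs worker count."""
    return fit_power([(r.workers, r.elapsed_seconds) for r in results])


def plot_benchmark(results, fit: RegressionFit, path, by: str = "records"):
    """Scatter of observations with the fitted curve; requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([getattr(r, by) for r in results], dtype=float)
    t = np.array([r.elapsed_seconds for r in results])
    grid = np.linspace(x.min(), x.max(), 200)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(x, t, "o", label="observed")
    ax.plot(grid, fit.predict(grid), "-", label=f"{fit.model} fit")
    ax.set_xlabel(by)
    ax.set_ylabel("processing time (s)")
    if fit.model == "power":
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
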