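"""Extreme-value diagnostics for band-power features.

A recording whose 2-5 Hz band power is heavy-tailed (Weibull shape c < 1
above the 95th percentile) hosts genuine extreme events, and an outlier
detector is expected to find its seizures; a near-exponential tail
predicts failure.  The pipeline here is: subtract the global minimum,
optionally take local maxima of the dense series, split at the 95th
percentile, fit a Weibull law to the tail, and check the fit with a
chi-square goodness-of-fit test on equal-probability bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features import FeatureSeries


@dataclass
class WeibullFit:
    """Maximum-likelihood Weibull estimates plus goodness-of-fit metadata.

    ``c`` is the shape (c < 1 = heavy tail), ``l`` the location, ``s`` the
    scale, in the units of the fitted data.  ``converged`` is False when the
    optimizer failed or ran to a degenerate corner; such fits are flagged,
    never silently dropped.
    """

    c: float
    l: float
    s: float
    n: int
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)


@dataclass
class GofResult:
    chi2: float
    p: float
    dof: int
    H: int


@dataclass
class ExtremeReport:
    """Per-recording tail diagnostic: fit + classification."""

    fit: WeibullFit
    gof: GofResult | None
    n_tail: int
    percentile_cut: float
    heavy_tailed: bool
    series: str
    shape_threshold: float

    def to_dict(self) -> dict:
        return {
            "c": self.fit.c,
            "l": self.fit.l,
            "s": self.fit.s,
            "converged": self.fit.converged,
            "chi2": None if self.gof is None else self.gof.chi2,
            "p": None if self.gof is None else self.gof.p,
            "n_tail": self.n_tail,
            "percentile_cut": self.percentile_cut,
            "heavy_tailed": self.heavy_tailed,
            "series": self.series,
        }


def normalize_min(x: np.ndarray) -> np.ndarray:
    """Shift by the global minimum, so min(output) == 0 exactly."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return x - x.min()


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Values at strict local maxima; a plateau contributes its first point.

    An index i qualifies when the nearest differing neighbor on the left is
    smaller and the nearest differing neighbor on the right is smaller.
    Boundary points never qualify.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points to find local maxima")
    # scipy.signal.argrelmax misses plateaus; do the run-aware scan directly
    d = np.diff(x)
    rising = d > 0
    falling = d < 0
    # direction of the last nonzero step before each position / next after
    idx = []
    n = len(x)
    i = 0
    while i < n - 1:
        if rising[i]:
            j = i + 1
            while j < n - 1 and d[j] == 0:
                j += 1
            if j < n - 1 and falling[j]:
                idx.append(i + 1)  # first point of the (possibly flat) top
                i = j
                continue
            i = j
        else:
            i += 1
    return x[np.asarray(idx, dtype=int)] if idx else np.empty(0)


def tail_split(x: np.ndarray, q: float = 95.0) -> tuple[np.ndarray, np.ndarray, float]:
    """Split a sample at its q-th percentile (linear interpolation).

    Returns ``(below, above, cut)`` with ``above = {x > cut}``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 observations for a tail split")
    if np.ptp(x) == 0:
        raise ValueError("degenerate constant data: no tail to split")
    cut = float(np.percentile(x, q))
    above = x[x > cut]
    below = x[x <= cut]
    return below, above, cut


def fit_weibull(x: np.ndarray, fix_location: bool = False) -> WeibullFit:
    """Maximum-likelihood Weibull(c, l, s) fit.

    With ``fix_location`` the location is pinned: at 0 when all data are
    positive (the natural choice after min-normalization or for tail
    exceedances), otherwise just below the sample minimum.  The free
    3-parameter fit mirrors the classical protocol but has an unbounded
    likelihood for c < 1 as l approaches min(x); degenerate solutions are
    flagged via ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 observations to fit")
    if np.any(x < 0):
        raise ValueError("data must be nonnegative (normalize first)")
    diagnostics: dict = {"n_fitted_params": 2 if fix_location else 3}
    try:
        if fix_location:
            floc = 0.0 if x.min() > 0 else float(x.min()) - 1e-9 * max(np.ptp(x), 1.0)
            c, l, s = stats.weibull_min.fit(x, floc=floc)
        else:
            c, l, s = stats.weibull_min.fit(x)
    except Exception as exc:  # optimizer blew up: flag, don't raise
        diagnostics["error"] = str(exc)
        return WeibullFit(np.nan, np.nan, np.nan, x.size, converged=False, diagnostics=diagnostics)
    converged = bool(np.isfinite([c, l, s]).all() and c > 0 and s > 0)
    if converged and not fix_location:
        # degenerate corner: location pushed onto the smallest observation
        # with a tiny shape, where the likelihood is unbounded
        if c < 0.05 and abs(l - x.min()) < 1e-6 * max(np.ptp(x), 1.0):
            converged = False
            diagnostics["degenerate"] = "location at sample minimum with c -> 0"
    return WeibullFit(float(c), float(l), float(s), x.size, converged=converged, diagnostics=diagnostics)


def chi2_gof(x: np.ndarray, fit: WeibullFit, H: int | None = None) -> GofResult:
    """Chi-square goodness-of-fit of data against a fitted Weibull law.

    Bins are equal-probability under the fitted distribution, so expected
    counts are n/H; H defaults to the largest bin count (capped at 10)
    keeping expected counts >= 5.  Degrees of freedom are H - 1 - 2 for a
    pinned-location fit and H - 1 - 3 for a free fit.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    n_params = int(fit.diagnostics.get("n_fitted_params", 3))
    if H is None:
        H = min(10, n // 5)
    if H < 3:
        raise ValueError("too few observations for a chi-square test (need H >= 3, counts >= 5)")
    if n / H < 5:
        raise ValueError(f"expected count n/H = {n / H:.1f} < 5; reduce H")
    dist = stats.weibull_min(fit.c, loc=fit.l, scale=fit.s)
    edges = dist.ppf(np.linspace(0, 1, H + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    observed, _ = np.histogram(x, bins=edges)
    expected = np.full(H, n / H)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    dof = H - 1 - n_params
    p = float(stats.chi2.sf(chi2, dof)) if dof >= 1 else float("nan")
    return GofResult(chi2=chi2, p=p, dof=dof, H=H)


def extreme_report(
    features: FeatureSeries,
    series: str = "E",
    q: float = 95.0,
    shape_threshold: float = 1.0,
    fit_mode: str = "tail",
    fix_location: bool = True,
) -> ExtremeReport:
    """Tail diagnostic for one recording.

    ``series="E"`` analyzes local maxima of the min-normalized dense AWP;
    ``series="e"`` analyzes the min-normalized 60-s DAWP values directly.
    ``fit_mode="tail"`` fits the exceedances above the q-th percentile
    (peaks-over-threshold style); ``fit_mode="full"`` fits the whole sample.
    The recording is called heavy-tailed when the fit converged with shape
    below ``shape_threshold``.  The chi-square result is reported as an
    advisory fit-quality flag rather than a classification gate: its power
    grows with the recording length while the tail deviation it detects
    does not, so gating on it would make the label depend on how long the
    patient was monitored instead of on the tail itself.
    """
    if series == "E":
        data = local_maxima(normalize_min(features.E))
    elif series == "e":
        data = normalize_min(features.e)
    else:
        raise ValueError("series must be 'E' or 'e'")
    below, above, cut = tail_split(data, q)
    if fit_mode == "tail":
        sample = above - cut  # exceedances start at 0
    elif fit_mode == "full":
        sample = data
    else:
        raise ValueError("fit_mode must be 'tail' or 'full'")
    fit = fit_weibull(sample, fix_location=fix_location)
    gof: GofResult | None
    try:
        gof = chi2_gof(sample, fit) if fit.converged else None
    except ValueError:
        gof = None  # tail too small for a binned test; classification on shape only
    heavy = bool(fit.converged and fit.c < shape_threshold)
    return ExtremeReport(
        fit=fit,
        gof=gof,
        n_tail=int(above.size),
        percentile_cut=cut,
        heavy_tailed=heavy,
        series=series,
        shape_threshold=shape_threshold,
    )


def plot_tail_fit(report: ExtremeReport, data: np.ndarray, ax=None):
    """Histogram of the fitted sample with the Weibull density overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(data, bins=30, density=True, alpha=0.6, label="data")
    xs = np.linspace(data.min(), data.max(), 200)
    fit = report.fit
    ax.plot(xs, stats.weibull_min.pdf(xs, fit.c, fit.l, fit.s), "r-", label=f"Weibull c={fit.c:.2f}")
    ax.set_xlabel("band power")
    ax.set_ylabel("density")
    ax.legend()
    return ax
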