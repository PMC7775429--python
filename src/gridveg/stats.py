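"""Correlation screening with FDR control, BCa intervals and suitability rules.

The screen couples two scales: an area-averaged correlation per feature
(Pearson by default, Spearman as the rank-based alternative) whose p-values
are controlled across the whole catalog with the Benjamini-Hochberg step-up
rule at q = 0.05, and a per-pixel correlation map summarized as the
percentage of analyzed pixels with raw p <= 0.05.  A feature is *highly
suitable* when it survives the FDR screen and at least half of the analyzed
pixels are individually significant.  Uncertainty of the area correlation is
reported as a bias-corrected and accelerated (BCa) bootstrap interval with
2500 pairwise resamples.

Pixel-level p-values are deliberately not multiplicity-adjusted (the
area-level FDR screen carries the error control); an optional flag applies
per-pixel BH for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .anomalies import FeatureSeries, NdviAnomalySeries
from .cubes import ClassRaster, VEGETATION_CLASSES

logger = logging.getLogger(__name__)


class DegenerateSeriesError(ValueError):
    """Correlation undefined: one of the series has zero variance."""


@dataclass
class CorrelationRecord:
    """One catalog row: area test, BCa interval, pixel summary, suitability."""

    feature_id: str
    method: str
    r: float
    p: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    pct_significant_pixels: float = np.nan
    fdr_significant: bool = False
    highly_suitable: bool = False
    n_years: int = 0
    n_pixels: int = 0


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> tuple[float, float]:
    """Area correlation and two-sided p (t reference, df = n - 2).

    Spearman applies the same t-approximation to the rank correlation
    (midranks for ties).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired years")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateSeriesError("zero variance in one of the series")
    if method == "pearson":
        r = float(np.corrcoef(x, y)[0, 1])
    elif method == "spearman":
        r = float(np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1])
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return r, p


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``q``.

    Sort ascending, find the largest k with p_(k) <= k*q/m, reject the k
    smallest p-values.  Hand-rolled because this screen is the core decision
    rule of the pipeline; cross-checked against statsmodels in the tests.
    """
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    passing = np.flatnonzero(p[order] <= thresh)
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        k = passing[-1] + 1
        reject[order[:k]] = True
    return reject


# ---------------------------------------------------------------------------
# BCa bootstrap interval for a correlation
# ---------------------------------------------------------------------------

def _pearson_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r for matching (B, n) matrices; NaN if degenerate."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", Xc, Yc)
    den = np.sqrt(np.einsum("ij,ij->i", Xc, Xc) * np.einsum("ij,ij->i", Yc, Yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.clip(r, -1.0, 1.0)


def _jackknife_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out Pearson r via sufficient-statistic downdates."""
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    m = n - 1
    mean_x = (sx - x) / m
    mean_y = (sy - y) / m
    cov = (sxy - x * y) / m - mean_x * mean_y
    vx = (sxx - x * x) / m - mean_x**2
    vy = (syy - y * y) / m - mean_y**2
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    return np.clip(r, -1.0, 1.0)


def _regression_influence(idx: np.ndarray, boot: np.ndarray, n: int) -> np.ndarray:
    """Empirical influence values by regressing bootstrap replicates on the
    centered resampling frequencies (minimum-norm least squares, so the
    influence values sum to zero)."""
    B = idx.shape[0]
    freq = np.zeros((B, n))
    np.add.at(freq, (np.repeat(np.arange(B), idx.shape[1]), idx.ravel()), 1.0)
    X = freq / idx.shape[1] - 1.0 / n
    t = boot - boot.mean()
    L, *_ = np.linalg.lstsq(X, t, rcond=None)
    return L


def _norm_interpolated_quantile(sorted_vals: np.ndarray, q: float) -> float:
    """Order-statistic quantile with (B+1) positions, interpolated on the
    normal-quantile scale (the convention of the classic bootstrap codes);
    slightly wider in the tails than linear interpolation."""
    B = sorted_vals.size
    rk = q * (B + 1)
    k = int(np.floor(rk))
    if k <= 0:
        return float(sorted_vals[0])
    if k >= B:
        return float(sorted_vals[-1])
    z_q = sps.norm.ppf(q)
    z_k = sps.norm.ppf(k / (B + 1))
    z_k1 = sps.norm.ppf((k + 1) / (B + 1))
    frac = (z_q - z_k) / (z_k1 - z_k) if z_k1 != z_k else 0.0
    return float(sorted_vals[k - 1] + frac * (sorted_vals[k] - sorted_vals[k - 1]))


def bca_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 2500,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
    statistic: str = "pearson",
    accel: str = "regression",
) -> tuple[float, float]:
    """BCa bootstrap confidence interval for the correlation of paired years.

    Pairs are resampled with replacement ``n_boot`` times; the bias term z0
    comes from the fraction of bootstrap statistics below the observed value
    (ties counted half); the acceleration uses the third-moment formula on
    empirical influence values.  Influence values come, by default, from the
    linear regression of the bootstrap replicates on the resampling
    frequencies (the convention of the classic bootstrap packages, with
    visibly better small-sample coverage for correlations);
    ``accel="jackknife"`` switches to leave-one-out influence.  Endpoints are
    read at BCa-adjusted percentiles of the bootstrap distribution
    (interpolated on the normal-quantile scale) and clamped to [-1, 1].  A
    degenerate bootstrap distribution collapses the interval to the point
    estimate (warning).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 5 or len(np.unique(np.c_[x, y], axis=0)) < 5:
        raise ValueError("need at least 5 distinct pairs")
    rng = np.random.default_rng(rng)
    if statistic == "spearman":
        x, y = sps.rankdata(x), sps.rankdata(y)
    theta = _pearson_rows(x[None, :], y[None, :])[0]

    idx = rng.integers(0, n, size=(n_boot, n))
    boot_all = _pearson_rows(x[idx], y[idx])
    finite = np.isfinite(boot_all)
    idx, boot_all = idx[finite], boot_all[finite]
    boot = boot_all
    if boot.size == 0 or np.allclose(boot, boot[0]):
        if boot.size and not np.allclose(boot[0], theta):
            logger.warning("degenerate bootstrap distribution; collapsing CI")
        else:
            logger.warning("bootstrap distribution degenerate; CI collapsed to estimate")
        return float(theta), float(theta)

    below = np.sum(boot < theta) + 0.5 * np.sum(boot == theta)
    frac = min(max(below / boot.size, 1.0 / (2 * boot.size)), 1 - 1.0 / (2 * boot.size))
    z0 = sps.norm.ppf(frac)

    if accel == "regression":
        L = _regression_influence(idx, boot_all, n)
    elif accel == "jackknife":
        jack = _jackknife_pearson(x, y)
        jack = jack[np.isfinite(jack)]
        L = jack.mean() - jack
    else:
        raise ValueError(f"unknown acceleration estimator {accel!r}")
    denom = 6.0 * (np.sum(L * L) ** 1.5)
    a = float(np.sum(L**3) / denom) if denom > 0 else 0.0

    alpha = (1.0 - level) / 2.0
    lo_hi = []
    for z_alpha in (sps.norm.ppf(alpha), sps.norm.ppf(1 - alpha)):
        adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        lo_hi.append(float(sps.norm.cdf(adj)))
    srt = np.sort(boot)
    lo, hi = (_norm_interpolated_quantile(srt, q) for q in lo_hi)
    lo, hi = float(np.clip(lo, -1, 1)), float(np.clip(hi, -1, 1))
    lo = min(lo, float(theta))
    hi = max(hi, float(theta))
    return lo, hi


# ---------------------------------------------------------------------------
# Per-pixel analysis
# ---------------------------------------------------------------------------

@dataclass
class PixelResult:
    r: np.ndarray                # per analyzed pixel
    p: np.ndarray
    pct_significant: float
    n_analyzed: int
    analyzed_columns: np.ndarray  # indices into the pixel axis


def pixelwise_pearson(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r and two-sided p for (n_years, n_pixels) matrices."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0, keepdims=True)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    num = np.einsum("ij,ij->j", Xc, Yc)
    den = np.sqrt(np.einsum("ij,ij->j", Xc, Xc) * np.einsum("ij,ij->j", Yc, Yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip(num / den, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    return r, p


def per_pixel_analysis(
    feature: FeatureSeries,
    ndvi: NdviAnomalySeries,
    columns: np.ndarray | None = None,
    alpha: float = 0.05,
    adjust_fdr: bool = False,
) -> PixelResult:
    """Pearson r/p per analyzed pixel and the percent-significant summary.

    ``columns`` selects a subset of the NDVI pixel axis (e.g. one vegetation
    class).  Pixels with zero variance in either series are excluded from both
    numerator and denominator.  ``adjust_fdr`` switches the pixel decisions to
    a per-pixel BH screen (off by default: the raw threshold is the rule).
    """
    if feature.pixel_anomaly is None:
        raise ValueError("feature has no pixel anomalies")
    Xf = _feature_on_ndvi_columns(feature, ndvi)
    Y = ndvi.pixel_anomaly
    if feature.n_years != ndvi.n_years:
        ysel = np.isin(ndvi.years, feature.years)
        if ysel.sum() != feature.n_years:
            raise ValueError("feature years are not a subset of NDVI years")
        Y = Y[ysel]
    cols = np.arange(Y.shape[1]) if columns is None else np.asarray(columns)
    if cols.size == 0:
        raise ValueError("empty pixel mask")
    X, Y = Xf[:, cols], Y[:, cols]
    ok = (X.std(axis=0) > 0) & (Y.std(axis=0) > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("per-pixel analysis: excluded %d zero-variance pixels", n_dropped)
    X, Y, cols = X[:, ok], Y[:, ok], cols[ok]
    if cols.size == 0:
        raise ValueError("no analyzable pixels (all zero-variance)")
    r, p = pixelwise_pearson(X, Y)
    sig = bh_fdr(p, alpha) if adjust_fdr else (p <= alpha)
    pct = 100.0 * sig.sum() / cols.size
    return PixelResult(r=r, p=p, pct_significant=float(pct),
                       n_analyzed=int(cols.size), analyzed_columns=cols)


def _feature_on_ndvi_columns(feature: FeatureSeries, ndvi: NdviAnomalySeries) -> np.ndarray:
    """Align the feature's pixel-anomaly columns with the NDVI pixel axis."""
    if feature.pixel_mask is None:
        raise ValueError("feature has no pixel mask")
    if feature.pixel_mask.shape != ndvi.pixel_mask.shape:
        raise ValueError("feature and NDVI grids differ (regrid first)")
    if np.array_equal(feature.pixel_mask, ndvi.pixel_mask):
        return feature.pixel_anomaly
    # Scatter the feature columns onto the full raster, gather NDVI's columns.
    full = np.full((feature.pixel_anomaly.shape[0],) + feature.pixel_mask.shape, np.nan)
    full[:, feature.pixel_mask] = feature.pixel_anomaly
    out = full[:, ndvi.pixel_mask]
    if np.isnan(out).any():
        # pixels analyzed for NDVI but invalid for the feature: zero-variance
        # sentinel so they are excluded downstream
        out = np.nan_to_num(out, nan=0.0)
    return out


# ---------------------------------------------------------------------------
# Suitability classification and the full screen
# ---------------------------------------------------------------------------

def classify_highly_suitable(
    records: list[CorrelationRecord], pixel_pct_threshold: float = 50.0
) -> list[CorrelationRecord]:
    """Annotate and sort records (descending percent significant pixels).

    ``highly_suitable = fdr_significant and pct_significant_pixels >= 50``;
    assumes :func:`bh_fdr` was already applied across the full catalog.
    """
    out = []
    for rec in records:
        hs = bool(rec.fdr_significant) and rec.pct_significant_pixels >= pixel_pct_threshold
        out.append(replace(rec, highly_suitable=hs))
    out.sort(key=lambda r: (-r.pct_significant_pixels, r.p, r.feature_id))
    return out


def evaluate_features(
    features: list[FeatureSeries],
    ndvi: NdviAnomalySeries,
    method: str = "pearson",
    fdr_q: float = 0.05,
    pixel_alpha: float = 0.05,
    pixel_pct_threshold: float = 50.0,
    n_boot: int = 2500,
    seed: int | None = 0,
    columns: np.ndarray | None = None,
    with_ci: bool = True,
) -> list[CorrelationRecord]:
    """Run the full dual-scale screen for one catalog (one BH family).

    ``columns`` restricts the per-pixel stage (and the area series, which is
    recomputed as the mean over those pixel columns) to a subset of analyzed
    pixels, which is how per-class analyses are run.
    """
    rng = np.random.default_rng(seed)
    records: list[CorrelationRecord] = []
    pvals = []
    for feat in features:
        x = feat.anomaly
        y = ndvi.anomaly
        if columns is not None:
            Xf = _feature_on_ndvi_columns(feat, ndvi)[:, columns]
            Yp = ndvi.pixel_anomaly[:, columns]
            x = Xf.mean(axis=1)
            x = x - x.mean()
            y = Yp.mean(axis=1)
            y = y - y.mean()
        if feat.n_years != ndvi.n_years:
            ysel = np.isin(ndvi.years, feat.years)
            y = y[ysel]
        r, p = correlate(x, y, method=method)
        ci = bca_ci(x, y, n_boot=n_boot, rng=rng, statistic=method) if with_ci else (np.nan, np.nan)
        px = per_pixel_analysis(feat, ndvi, columns=columns, alpha=pixel_alpha)
        records.append(CorrelationRecord(
            feature_id=feat.feature_id, method=method, r=r, p=p,
            ci_low=ci[0], ci_high=ci[1],
            pct_significant_pixels=px.pct_significant,
            n_years=feat.n_years, n_pixels=px.n_analyzed,
        ))
        pvals.append(p)
    reject = bh_fdr(np.array(pvals), q=fdr_q)
    records = [replace(rec, fdr_significant=bool(rej)) for rec, rej in zip(records, reject)]
    return classify_highly_suitable(records, pixel_pct_threshold)


def autocorrelation_check(
    series: NdviAnomalySeries | FeatureSeries, lags: int | None = None
) -> dict:
    """Ljung-Box + ACF-bounds screen of the annual anomaly series.

    ``lags`` defaults to ``min(10, n // 5)`` (at least 1).  Pass requires the
    Ljung-Box p above 0.05 and no ACF value outside +-1.96/sqrt(n).
    A constant series is reported as not applicable.
    """
    from statsmodels.stats.diagnostic import acorr_ljungbox
    from statsmodels.tsa.stattools import acf

    y = np.asarray(series.anomaly, float)
    n = y.size
    if n < 8:
        raise ValueError("need at least 8 years for the autocorrelation check")
    if np.std(y) == 0:
        return {"applicable": False, "passed": None, "statistic": np.nan,
                "p": np.nan, "acf": None, "bound": np.nan}
    if lags is None:
        lags = max(1, min(10, n // 5))
    lb = acorr_ljungbox(y, lags=[lags], return_df=True)
    stat = float(lb["lb_stat"].iloc[0])
    p = float(lb["lb_pvalue"].iloc[0])
    rho = acf(y, nlags=lags, fft=False)[1:]
    bound = 1.96 / np.sqrt(n)
    passed = bool(p > 0.05 and np.all(np.abs(rho) <= bound))
    return {"applicable": True, "passed": passed, "statistic": stat, "p": p,
            "acf": rho, "bound": bound, "lags": lags}


def per_class_analysis(
    features: list[FeatureSeries],
    ndvi: NdviAnomalySeries,
    classes: ClassRaster,
    class_names: tuple[str, ...] = VEGETATION_CLASSES[:3],
    min_pixels: int = 2,
    **kwargs,
) -> dict[str, list[CorrelationRecord]]:
    """Re-run the full screen with the pixel mask restricted to each class.

    BH is applied within each class's own catalog (one family per class).
    Classes with fewer than ``min_pixels`` analyzed pixels are skipped.
    """
    flat_class = classes.class_id[ndvi.pixel_mask]
    out: dict[str, list[CorrelationRecord]] = {}
    for name in class_names:
        cid = VEGETATION_CLASSES.index(name)
        cols = np.flatnonzero(flat_class == cid)
        if cols.size < min_pixels:
            logger.warning("class %s: only %d pixels, skipped", name, cols.size)
            continue
        out[name] = evaluate_features(features, ndvi, columns=cols, **kwargs)
    return out
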