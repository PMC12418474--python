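"""Tiered per-protein linear modelling of plasma on serum NPX.

For each protein measured in matched serum and plasma aliquots, an ordinary
least-squares line ``plasma = intercept + slope * serum`` is fitted.  The
slope is the candidate *transformation factor*: because NPX is log2-scale,
multiplying a serum NPX value by the slope rescales it onto the plasma axis
(a power-law relation on the linear concentration scale).  The intercept
captures cohort-specific offsets and is reported for provenance only.

A protein is **modelable** when its fit reaches R-squared >= 0.5.  Gross
outlier samples (haemolysis, handling artefacts) can destroy an otherwise
clean linear relationship, so fitting proceeds in three tiers:

* Tier 1 -- all complete (serum, plasma) pairs.
* Tier 2 -- the top ``ceil(0.10 n)`` samples by Cook's distance removed
  (2 samples at n = 19).
* Tier 3 -- the top ``ceil(0.15 n)`` samples removed (3 at n = 19); a
  superset of the Tier-2 removals.

Cook's distances are computed on the Tier-1 fit and rank the removals for
both lower tiers, so the scheme is deterministic and a protein only falls to
a lower tier when every tier above it failed the R-squared threshold.  The
precision of an accepted slope is summarised by the half-width of its 95%
t-based confidence interval, ``t(1 - alpha/2, n_used - 2) * slope_se``; the
downstream catalog gate operates on this half-width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateFitError, ParameterError
from .npx_io import MatchedCohort

R2_THRESHOLD_DEFAULT = 0.5


@dataclass(frozen=True)
class TierScheme:
    """Parameters of the tiered modelling scheme.

    Attributes
    ----------
    r2_threshold : float
        Minimum R-squared for a fit to be accepted (modelability call).
    pearson_threshold : float
        Signed Pearson-r threshold of the descriptive screen.
    removal_fractions : (float, float, float)
        Fraction of samples removed at tiers 1-3; counts are ``ceil(f * n)``.
        The defaults (0, 0.10, 0.15) give removals of 0/2/3 at n = 19.
    fixed_counts : (int, int, int), optional
        When set, overrides the fractions with absolute removal counts.
    rerank_per_tier : bool
        If True, Tier-3 removals beyond the Tier-2 set are ranked by Cook's
        distances recomputed on the Tier-2 fit instead of the Tier-1 fit.
    alpha : float
        Significance level of the slope confidence interval (default 95% CI).
    """

    r2_threshold: float = R2_THRESHOLD_DEFAULT
    pearson_threshold: float = 0.5
    removal_fractions: tuple = (0.0, 0.10, 0.15)
    fixed_counts: tuple | None = None
    rerank_per_tier: bool = False
    alpha: float = 0.05

    def removal_counts(self, n_total: int) -> tuple:
        """Per-tier removal counts for a protein with ``n_total`` pairs."""
        if self.fixed_counts is not None:
            counts = tuple(int(k) for k in self.fixed_counts)
        else:
            counts = tuple(math.ceil(f * n_total) for f in self.removal_fractions)
        if not (counts[0] <= counts[1] <= counts[2]):
            raise ParameterError(f"removal counts must be non-decreasing, got {counts}")
        return counts


@dataclass
class OLSFit:
    """Simple-regression fit of y on x with influence quantities."""

    slope: float
    intercept: float
    slope_se: float
    r2: float
    residuals: np.ndarray
    leverages: np.ndarray
    n: int
    sigma2: float  # SSE / (n - 2)
    degenerate_y: bool = False


@dataclass
class TierFit:
    """Per-protein result of the tiered fitting scheme.

    ``tier`` is 1, 2 or 3 for a modelable protein and None otherwise; a
    non-modelable protein carries its Tier-1 fit so diagnostics remain
    available.  ``ci_halfwidth`` is the half-width of the
    ``(1 - alpha)`` t-confidence interval of the slope.
    """

    protein_id: object
    tier: int | None
    slope: float
    intercept: float
    slope_se: float
    r2: float
    pearson_r: float
    n_total: int
    n_used: int
    excluded_samples: list = field(default_factory=list)
    ci_halfwidth: float = float("nan")
    degenerate: bool = False

    @property
    def modelable(self) -> bool:
        return self.tier is not None


def fit_ols(x: np.ndarray, y: np.ndarray) -> OLSFit:
    """Ordinary least squares of ``y`` on ``x`` (simple regression).

    Returns the slope, intercept, slope standard error
    ``s / sqrt(Sxx)`` with ``s^2 = SSE / (n - 2)``, the coefficient of
    determination ``1 - SSE/SStot``, raw residuals and hat-matrix diagonals.

    A constant ``x`` admits no slope and raises
    :class:`~npxfactor.exceptions.DegenerateFitError`; a constant ``y`` is
    returned as a flagged degenerate fit with slope 0 and R-squared 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise DegenerateFitError(f"need >= 3 pairs, got {n}")
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0.0:
        raise DegenerateFitError("predictor has zero variance")
    leverages = 1.0 / n + (x - xbar) ** 2 / sxx
    if float(np.var(y)) == 0.0:
        return OLSFit(
            slope=0.0, intercept=float(y.mean()), slope_se=0.0, r2=0.0,
            residuals=np.zeros(n), leverages=leverages, n=n, sigma2=0.0,
            degenerate_y=True,
        )
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    residuals = y - fitted
    sse = float((residuals ** 2).sum())
    sstot = float(((y - y.mean()) ** 2).sum())
    return OLSFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r2=1.0 - sse / sstot,
        residuals=residuals,
        leverages=leverages,
        n=n,
        sigma2=sse / (n - 2),
    )


def cooks_distance(fit: OLSFit) -> np.ndarray:
    """Cook's distance of every sample under a simple-regression fit.

    ``D_i = e_i^2 / (p s^2) * h_ii / (1 - h_ii)^2`` with p = 2 estimated
    parameters; equivalently the scaled sum of squared changes in all fitted
    values when sample i is deleted.  A perfectly interpolated sample set
    (all residuals zero) yields all-zero distances; a sample with leverage 1
    is reported as +inf.
    """
    p = 2
    h = fit.leverages
    e = fit.residuals
    with np.errstate(divide="ignore", invalid="ignore"):
        if fit.sigma2 == 0.0:
            return np.zeros(fit.n)
        d = (e ** 2 / (p * fit.sigma2)) * (h / (1.0 - h) ** 2)
    d = np.where(h >= 1.0, np.inf, d)
    return d


def rank_outliers(distances: np.ndarray, k: int, sample_ids=None) -> list:
    """Indices (or IDs) of the ``k`` largest Cook's distances, descending.

    Ties are broken by input order (earlier sample wins), deterministically.
    """
    distances = np.asarray(distances, dtype=float)
    n = distances.size
    if not 0 <= k <= n:
        raise ParameterError(f"cannot select {k} of {n} samples")
    order = np.argsort(-distances, kind="stable")[:k]
    if sample_ids is None:
        return list(order)
    sample_ids = list(sample_ids)
    return [sample_ids[i] for i in order]


def slope_ci(slope_se: float, n_used: int, alpha: float = 0.05) -> float:
    """Half-width of the (1 - alpha) t-confidence interval of the slope."""
    if n_used <= 2:
        raise ParameterError("confidence interval undefined for n <= 2")
    return float(stats.t.ppf(1.0 - alpha / 2.0, n_used - 2) * slope_se)


def _complete_pairs(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray, sample_ids=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    ids = np.asarray(list(sample_ids) if sample_ids is not None else np.arange(x.size), dtype=object)
    return x[mask], y[mask], ids[mask]


def tiered_fit(x, y, scheme: TierScheme | None = None, sample_ids=None, protein_id=None) -> TierFit:
    """Run the three-tier fitting scheme on one protein.

    ``x`` is the serum NPX vector, ``y`` the matched plasma vector; pairs
    with either side missing are excluded up front (``n_total`` is the
    complete-pair count).  Tier 1 fits all pairs; if it misses the
    R-squared threshold the top-k2 / top-k3 samples ranked by the *Tier-1*
    Cook's distances are removed and the model refitted.  The returned
    :class:`TierFit` carries the accepted tier's fit, or the Tier-1 fit
    with ``tier=None`` when no tier reaches the threshold.
    """
    scheme = scheme or TierScheme()
    x, y, ids = _complete_pairs(x, y, sample_ids)
    n_total = x.size

    def _nonmodelable(**kw) -> TierFit:
        base = dict(
            protein_id=protein_id, tier=None, slope=float("nan"),
            intercept=float("nan"), slope_se=float("nan"), r2=float("nan"),
            pearson_r=float("nan"), n_total=n_total, n_used=n_total,
            excluded_samples=[], ci_halfwidth=float("nan"), degenerate=True,
        )
        base.update(kw)
        return TierFit(**base)

    if n_total < 3:
        return _nonmodelable()
    try:
        tier1 = fit_ols(x, y)
    except DegenerateFitError:
        return _nonmodelable()
    if tier1.degenerate_y:
        pearson_r = float("nan")
    else:
        pearson_r = float(stats.pearsonr(x, y).statistic)

    def _result(fit: OLSFit, tier: int | None, excluded: list) -> TierFit:
        n_used = fit.n
        return TierFit(
            protein_id=protein_id,
            tier=tier,
            slope=fit.slope,
            intercept=fit.intercept,
            slope_se=fit.slope_se,
            r2=fit.r2,
            pearson_r=pearson_r,
            n_total=n_total,
            n_used=n_used,
            excluded_samples=list(excluded),
            ci_halfwidth=slope_ci(fit.slope_se, n_used, scheme.alpha),
            degenerate=fit.degenerate_y,
        )

    if tier1.r2 >= scheme.r2_threshold:
        return _result(tier1, 1, [])

    _, k2, k3 = scheme.removal_counts(n_total)
    d1 = cooks_distance(tier1)
    order = np.argsort(-d1, kind="stable")

    def _refit_without(idx_removed: np.ndarray) -> OLSFit | None:
        keep = np.setdiff1d(np.arange(n_total), idx_removed, assume_unique=True)
        if keep.size < 3:
            return None
        try:
            return fit_ols(x[keep], y[keep])
        except DegenerateFitError:
            return None

    # Tier 2
    if 0 < k2 < n_total - 2:
        idx2 = order[:k2]
        tier2 = _refit_without(idx2)
        if tier2 is not None and tier2.r2 >= scheme.r2_threshold:
            return _result(tier2, 2, [ids[i] for i in idx2])
    else:
        idx2 = order[:0]
        tier2 = None

    # Tier 3: removals are a superset of Tier 2's
    if 0 < k3 < n_total - 2 and k3 > k2:
        if scheme.rerank_per_tier and tier2 is not None:
            keep2 = np.setdiff1d(np.arange(n_total), idx2, assume_unique=True)
            d2 = cooks_distance(tier2)
            extra_local = np.argsort(-d2, kind="stable")[: k3 - k2]
            idx3 = np.concatenate([idx2, keep2[extra_local]])
        else:
            idx3 = order[:k3]
        tier3 = _refit_without(idx3)
        if tier3 is not None and tier3.r2 >= scheme.r2_threshold:
            return _result(tier3, 3, [ids[i] for i in idx3])

    return _result(tier1, None, [])


def pearson_screen(cohort: MatchedCohort, threshold: float | None = None) -> pd.DataFrame:
    """Descriptive per-protein Pearson screen between serum and plasma.

    Returns a frame indexed by protein with columns ``pearson_r``,
    ``n_pairs`` and ``passes`` (signed r >= threshold).  Proteins with fewer
    than 3 complete pairs or zero variance in either medium get an undefined
    (NaN) correlation and fail.  The screen is descriptive only: tiered
    fitting is applied to all proteins regardless.
    """
    thr = TierScheme().pearson_threshold if threshold is None else threshold
    records = []
    for protein in cohort.protein_ids:
        x, y, _ = _complete_pairs(
            cohort.serum.values[protein], cohort.plasma.values[protein]
        )
        n = x.size
        if n < 3 or np.var(x) == 0.0 or np.var(y) == 0.0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(x, y).statistic)
        records.append({
            "protein_id": protein,
            "pearson_r": r,
            "n_pairs": n,
            "passes": bool(r >= thr) if not math.isnan(r) else False,
        })
    return pd.DataFrame(records).set_index("protein_id")


def fit_cohort(cohort: MatchedCohort, scheme: TierScheme | None = None) -> list:
    """Tiered fit of every protein in a matched cohort, in panel order."""
    scheme = scheme or TierScheme()
    subject_ids = cohort.subject_ids
    return [
        tiered_fit(
            cohort.serum.values[p], cohort.plasma.values[p],
            scheme=scheme, sample_ids=subject_ids, protein_id=p,
        )
        for p in cohort.protein_ids
    ]


def fits_to_frame(fits) -> pd.DataFrame:
    """Tabulate a TierFit collection (one row per protein)."""
    rows = []
    for f in fits:
        rows.append({
            "protein_id": f.protein_id,
            "tier": -1 if f.tier is None else f.tier,
            "modelable": f.modelable,
            "slope": f.slope,
            "intercept": f.intercept,
            "slope_se": f.slope_se,
            "ci_halfwidth": f.ci_halfwidth,
            "r2": f.r2,
            "pearson_r": f.pearson_r,
            "n_total": f.n_total,
            "n_used": f.n_used,
            "excluded_samples": ";".join(map(str, f.excluded_samples)),
        })
    return pd.DataFrame(rows).set_index("protein_id")


def variance_diagnostics(cohort: MatchedCohort, fits) -> pd.DataFrame:
    """Per-protein variance/expression diagnostics joined to fit outcomes.

    Supports the two standard checks on a fitted cohort: modelability tracks
    per-protein variance (low-variance proteins rarely reach R² >= 0.5), and
    mean NPX level does not determine modelability.
    """
    by_protein = {f.protein_id: f for f in fits}
    rows = []
    for protein in cohort.protein_ids:
        s = cohort.serum.values[protein]
        p = cohort.plasma.values[protein]
        f = by_protein.get(protein)
        rows.append({
            "protein_id": protein,
            "serum_variance": float(s.var(ddof=1)),
            "plasma_variance": float(p.var(ddof=1)),
            "serum_mean_npx": float(s.mean()),
            "plasma_mean_npx": float(p.mean()),
            "r2": float("nan") if f is None else f.r2,
            "tier": -1 if (f is None or f.tier is None) else f.tier,
            "modelable": bool(f is not None and f.modelable),
        })
    return pd.DataFrame(rows).set_index("protein_id")
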