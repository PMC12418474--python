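"""Transformation-factor catalogs: gating, summarising and applying slopes.

A fitted slope only becomes a *transformation factor* once its 95%
confidence half-width passes the gate (default <= 0.3, inclusive): a slope
known no better than +/-0.3 would propagate unacceptable error into
downstream group comparisons (see :mod:`npxfactor.sensitivity`).  Applying a
catalog multiplies each protein's NPX by its slope; intercepts are stored
for provenance but excluded from conversion because they reflect
cohort-specific offsets.  NPX is log2-scale, so the multiplication is a
power-law relation on the linear concentration scale -- there is
deliberately no linear-scale mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import IntegrityError, ParameterError, UsageError
from .npx_io import NPXMatrix
from .tiered import TierFit

GATE_DEFAULT = 0.3

_DIRECTIONS = ("serum_to_plasma", "plasma_to_serum")
_SOURCE_MEDIUM = {"serum_to_plasma": "serum", "plasma_to_serum": "plasma"}
_TARGET_MEDIUM = {"serum_to_plasma": "plasma", "plasma_to_serum": "serum"}


@dataclass
class TransformationFactor:
    """A gated, provenance-tagged slope converting NPX between media."""

    protein_id: object
    slope: float
    intercept: float
    slope_se: float
    ci_halfwidth: float
    r2: float
    tier: int
    n_used: int
    excluded_samples: list = field(default_factory=list)
    cohort_label: str = ""
    direction: str = "serum_to_plasma"

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ParameterError(f"direction must be one of {_DIRECTIONS}")
        if not np.isfinite(self.slope):
            raise ParameterError(f"{self.protein_id}: slope must be finite")


@dataclass
class FactorCatalog:
    """A collection of transformation factors, one per protein."""

    factors: list = field(default_factory=list)
    gate_threshold: float | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for f in self.factors:
            if f.protein_id in seen:
                raise IntegrityError(f"duplicate factor for protein {f.protein_id!r}")
            seen.add(f.protein_id)

    def __len__(self) -> int:
        return len(self.factors)

    def __iter__(self):
        return iter(self.factors)

    def __contains__(self, protein_id) -> bool:
        return any(f.protein_id == protein_id for f in self.factors)

    def __getitem__(self, protein_id) -> TransformationFactor:
        for f in self.factors:
            if f.protein_id == protein_id:
                return f
        raise KeyError(protein_id)

    @property
    def protein_ids(self) -> list:
        return [f.protein_id for f in self.factors]

    def slopes(self) -> pd.Series:
        return pd.Series({f.protein_id: f.slope for f in self.factors}, name="slope")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "protein_id": f.protein_id, "slope": f.slope, "intercept": f.intercept,
            "slope_se": f.slope_se, "ci_halfwidth": f.ci_halfwidth, "r2": f.r2,
            "tier": f.tier, "n_used": f.n_used, "cohort_label": f.cohort_label,
            "direction": f.direction,
        } for f in self.factors]).set_index("protein_id") if self.factors else pd.DataFrame(
            columns=["slope", "intercept", "slope_se", "ci_halfwidth", "r2",
                     "tier", "n_used", "cohort_label", "direction"])


def factor_from_fit(fit: TierFit, cohort_label: str = "",
                    direction: str = "serum_to_plasma") -> TransformationFactor:
    if not fit.modelable:
        raise ParameterError(f"{fit.protein_id}: non-modelable fit has no factor")
    return TransformationFactor(
        protein_id=fit.protein_id, slope=fit.slope, intercept=fit.intercept,
        slope_se=fit.slope_se, ci_halfwidth=fit.ci_halfwidth, r2=fit.r2,
        tier=fit.tier, n_used=fit.n_used,
        excluded_samples=list(fit.excluded_samples),
        cohort_label=cohort_label, direction=direction,
    )


def gate_by_ci(fits, max_halfwidth: float = GATE_DEFAULT, cohort_label: str = "",
               direction: str = "serum_to_plasma") -> FactorCatalog:
    """Gate modelable fits on their slope-CI half-width (inclusive boundary).

    Non-modelable fits are ignored; a modelable fit enters the catalog iff
    ``ci_halfwidth <= max_halfwidth``.
    """
    if max_halfwidth < 0:
        raise ParameterError("gate threshold must be non-negative")
    factors = [
        factor_from_fit(f, cohort_label=cohort_label, direction=direction)
        for f in fits
        if f.modelable and f.ci_halfwidth <= max_halfwidth
    ]
    return FactorCatalog(
        factors=factors, gate_threshold=max_halfwidth,
        provenance=[cohort_label] if cohort_label else [],
    )


def slope_distribution(slopes, bin_edges) -> pd.Series:
    """Histogram of slopes over ``bin_edges``.

    Bins are closed on the left and open on the right except the final bin,
    which is closed on both ends (numpy's convention), so every slope inside
    the covered range is counted exactly once.
    """
    if isinstance(slopes, FactorCatalog):
        values = slopes.slopes().to_numpy()
    else:
        values = np.asarray([f.slope if isinstance(f, (TierFit, TransformationFactor)) else f
                             for f in slopes], dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ParameterError("bin_edges must be strictly increasing with >= 2 entries")
    counts, _ = np.histogram(values[~np.isnan(values)], bins=edges)
    labels = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    labels[-1] = labels[-1][:-1] + "]"
    return pd.Series(counts, index=labels, name="count")


def count_in_interval(slopes, lo: float, hi: float) -> int:
    """Count slopes in the closed interval [lo, hi] (both bounds inclusive)."""
    if isinstance(slopes, FactorCatalog):
        values = slopes.slopes().to_numpy()
    else:
        values = np.asarray([f.slope if isinstance(f, (TierFit, TransformationFactor)) else f
                             for f in slopes], dtype=float)
    return int(np.sum((values >= lo) & (values <= hi)))


def apply_transform(matrix: NPXMatrix, catalog: FactorCatalog,
                    mode: str = "strict", affine: bool = False) -> NPXMatrix:
    """Convert an NPX matrix between media using a factor catalog.

    Each catalogued protein's NPX is multiplied by its slope (``affine=True``
    additionally adds the intercept, for within-cohort use only).  In
    ``strict`` mode uncatalogued proteins are dropped so downstream analyses
    never mix transformed and untransformed scales; ``passthrough`` copies
    them unchanged.  The input's medium must match the catalog direction's
    source medium (an ``unknown`` medium is accepted).
    """
    if mode not in ("strict", "passthrough"):
        raise ParameterError(f"mode must be 'strict' or 'passthrough', got {mode!r}")
    if len(catalog) == 0:
        raise IntegrityError("empty factor catalog")
    directions = {f.direction for f in catalog}
    if len(directions) > 1:
        raise UsageError(f"catalog mixes directions {sorted(directions)}")
    direction = directions.pop()
    source = _SOURCE_MEDIUM[direction]
    if matrix.medium not in ("unknown", source):
        raise UsageError(
            f"matrix medium {matrix.medium!r} does not match catalog source {source!r}"
        )
    shared = [p for p in matrix.protein_ids if p in set(catalog.protein_ids)]
    if mode == "strict" and not shared:
        raise IntegrityError("no catalogued protein present in the input matrix")
    out = matrix.values.copy()
    for f in catalog:
        if f.protein_id in out.columns:
            out[f.protein_id] = out[f.protein_id] * f.slope + (f.intercept if affine else 0.0)
    if mode == "strict":
        out = out[shared]
    return NPXMatrix(values=out, medium=_TARGET_MEDIUM[direction], transformed=True)


def select_best_factor(candidates) -> FactorCatalog:
    """Merge factor collections from several cohorts by best R-squared.

    ``candidates`` is a sequence of :class:`FactorCatalog` (cohort order
    matters).  For a protein present in several catalogs the factor with the
    highest R-squared wins; ties fall to the larger ``n_used``, then to the
    earlier-listed cohort.  Provenance lists every contributing cohort.
    """
    candidates = list(candidates)
    gates = {c.gate_threshold for c in candidates}
    best: dict = {}
    provenance: list = []
    for cohort_rank, catalog in enumerate(candidates):
        for label in (catalog.provenance or []):
            if label not in provenance:
                provenance.append(label)
        for f in catalog:
            key = f.protein_id
            if key not in best:
                best[key] = (cohort_rank, f)
            else:
                rank0, f0 = best[key]
                if (f.r2, f.n_used, -cohort_rank) > (f0.r2, f0.n_used, -rank0):
                    best[key] = (cohort_rank, f)
    factors = [f for _, f in best.values()]
    gate = gates.pop() if len(gates) == 1 else None
    return FactorCatalog(factors=factors, gate_threshold=gate, provenance=provenance)
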