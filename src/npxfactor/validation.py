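"""Cross-cohort validation of transformation factors.

Reproducibility of a factor is judged by refitting the catalogued proteins
in an independent matched cohort and comparing slopes: two cohorts agree on
a protein when both call it modelable and the absolute slope difference is
at most the concordance tolerance (default 0.3, the same magnitude as the
CI gate).  Proteins modelable in only one cohort are reported with their
per-medium variances attached, since loss of modelability in a more
homogeneous cohort is typically a low-variance effect; no automatic
variance cutoff is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .catalog import FactorCatalog
from .exceptions import IntegrityError, ParameterError
from .npx_io import MatchedCohort
from .tiered import TierScheme, fit_cohort, tiered_fit

CONCORDANCE_TOLERANCE_DEFAULT = 0.3


@dataclass
class ConcordanceReport:
    """Per-protein slope agreement between two fitted cohorts."""

    per_protein: pd.DataFrame  # slope_a, slope_b, abs_delta, modelable_a/b, concordant
    tolerance: float

    @property
    def n_overlap_modelable(self) -> int:
        m = self.per_protein
        return int((m.modelable_a & m.modelable_b).sum())

    @property
    def n_concordant(self) -> int:
        return int(self.per_protein.concordant.sum())

    @property
    def concordant_fraction(self) -> float:
        n = self.n_overlap_modelable
        return float("nan") if n == 0 else self.n_concordant / n

    @property
    def n_a_only(self) -> int:
        m = self.per_protein
        return int((m.modelable_a & ~m.modelable_b).sum())

    @property
    def n_b_only(self) -> int:
        m = self.per_protein
        return int((~m.modelable_a & m.modelable_b).sum())

    def concordant_proteins(self) -> list:
        return list(self.per_protein.index[self.per_protein.concordant])


def refit_cohort(catalog: FactorCatalog, cohort: MatchedCohort,
                 scheme: TierScheme | None = None):
    """Tiered refit of catalogued proteins in an independent cohort.

    Returns ``(fits, untestable)``: fits for the proteins present in the
    cohort panel, and the list of catalogued proteins the cohort does not
    measure.
    """
    scheme = scheme or TierScheme()
    panel = set(cohort.protein_ids)
    testable = [p for p in catalog.protein_ids if p in panel]
    untestable = [p for p in catalog.protein_ids if p not in panel]
    if not testable:
        raise IntegrityError("no catalogued protein measured in the validation cohort")
    subject_ids = cohort.subject_ids
    fits = [
        tiered_fit(cohort.serum.values[p], cohort.plasma.values[p],
                   scheme=scheme, sample_ids=subject_ids, protein_id=p)
        for p in testable
    ]
    return fits, untestable


def slope_concordance(fits_a, fits_b, tolerance: float = CONCORDANCE_TOLERANCE_DEFAULT,
                      cohort_a: MatchedCohort | None = None,
                      cohort_b: MatchedCohort | None = None) -> ConcordanceReport:
    """Compare two fit collections protein-by-protein.

    A protein is concordant iff it is modelable in both collections and
    ``|slope_a - slope_b| <= tolerance`` (inclusive).  When the underlying
    cohorts are supplied, proteins lost in one cohort are annotated with
    that cohort's per-medium variances.
    """
    if tolerance < 0:
        raise ParameterError("tolerance must be non-negative")
    a = {f.protein_id: f for f in fits_a}
    b = {f.protein_id: f for f in fits_b}
    rows = []
    for protein in list(a) + [p for p in b if p not in a]:
        fa, fb = a.get(protein), b.get(protein)
        slope_a = fa.slope if fa is not None else float("nan")
        slope_b = fb.slope if fb is not None else float("nan")
        mod_a = bool(fa is not None and fa.modelable)
        mod_b = bool(fb is not None and fb.modelable)
        delta = abs(slope_a - slope_b) if (mod_a and mod_b) else float("nan")
        row = {
            "protein_id": protein,
            "slope_a": slope_a, "slope_b": slope_b, "abs_delta": delta,
            "modelable_a": mod_a, "modelable_b": mod_b,
            "concordant": bool(mod_a and mod_b and delta <= tolerance),
        }
        for label, cohort in (("a", cohort_a), ("b", cohort_b)):
            if cohort is not None and protein in set(cohort.protein_ids):
                row[f"serum_variance_{label}"] = float(cohort.serum.values[protein].var(ddof=1))
                row[f"plasma_variance_{label}"] = float(cohort.plasma.values[protein].var(ddof=1))
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("protein_id")
    return ConcordanceReport(per_protein=frame, tolerance=tolerance)


def overlap_sets(modelable_sets: dict) -> tuple[pd.DataFrame, dict]:
    """Membership table and Venn-region counts for >= 2 modelable-protein sets.

    ``modelable_sets`` maps a cohort label to its set of modelable protein
    IDs.  Returns a boolean membership frame (union of proteins x labels)
    and a dict mapping each non-empty label combination (a tuple of labels,
    meaning 'in exactly these') to its region count; counts sum to the size
    of the union.
    """
    labels = list(modelable_sets)
    universe = sorted(set().union(*modelable_sets.values()) if labels else set(), key=str)
    membership = pd.DataFrame(
        {lab: [p in modelable_sets[lab] for p in universe] for lab in labels},
        index=universe,
    )
    regions = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            in_all = np.ones(len(universe), dtype=bool)
            for lab in labels:
                col = membership[lab].to_numpy() if len(universe) else np.array([], bool)
                in_all &= col if lab in combo else ~col
            count = int(in_all.sum())
            if count:
                regions[combo] = count
    return membership, regions


def validate_catalog(catalog: FactorCatalog, cohort: MatchedCohort,
                     scheme: TierScheme | None = None,
                     tolerance: float = CONCORDANCE_TOLERANCE_DEFAULT,
                     cohort_for_variance: MatchedCohort | None = None) -> ConcordanceReport:
    """Refit a catalog in a validation cohort and report slope concordance.

    The catalog side contributes its stored slopes as pseudo-fits (always
    modelable by construction); the cohort side contributes fresh tiered
    fits.
    """
    from .tiered import TierFit

    fits_b, untestable = refit_cohort(catalog, cohort, scheme)
    fits_a = []
    for f in catalog:
        if f.protein_id in untestable:
            continue
        fits_a.append(TierFit(
            protein_id=f.protein_id, tier=f.tier, slope=f.slope,
            intercept=f.intercept, slope_se=f.slope_se, r2=f.r2,
            pearson_r=float("nan"), n_total=f.n_used, n_used=f.n_used,
            excluded_samples=list(f.excluded_samples), ci_halfwidth=f.ci_halfwidth,
        ))
    return slope_concordance(fits_a, fits_b, tolerance=tolerance, cohort_b=cohort)
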