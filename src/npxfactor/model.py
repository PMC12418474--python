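"""Statsmodels-style modelling interface.

:class:`SerumPlasmaModel` wraps a matched serum/plasma cohort; ``fit()``
runs the Pearson screen and the tiered per-protein regressions and returns a
:class:`SerumPlasmaResults` holding the fits, their uncertainties and
diagnostics.  Gating, validation against another cohort, transformation and
plotting all hang off the results object:

>>> from npxfactor import SerumPlasmaModel, simulate
>>> cohort, truth = simulate.gen_matched_cohort()
>>> res = SerumPlasmaModel(cohort).fit()
>>> catalog = res.gate(0.3)
>>> print(res.summary())                            # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import npx_io
from .catalog import FactorCatalog, gate_by_ci
from .npx_io import MatchedCohort, NPXMatrix, pair_matched
from .tiered import (
    TierScheme,
    fit_cohort,
    fits_to_frame,
    pearson_screen,
    variance_diagnostics,
)
from .validation import ConcordanceReport, slope_concordance


class SerumPlasmaModel:
    """Per-protein linear model of plasma NPX on serum NPX.

    Parameters
    ----------
    cohort : MatchedCohort
        Matched serum/plasma aliquots aligned on subjects.
    scheme : TierScheme, optional
        Tiered-fitting parameters (thresholds, removal counts, CI level).
    """

    def __init__(self, cohort: MatchedCohort, scheme: TierScheme | None = None):
        self.cohort = cohort
        self.scheme = scheme or TierScheme()

    @classmethod
    def from_frames(cls, serum: pd.DataFrame, plasma: pd.DataFrame,
                    subject_map=None, cohort_label: str = "",
                    scheme: TierScheme | None = None) -> "SerumPlasmaModel":
        """Build from two wide samples-x-proteins DataFrames."""
        cohort = pair_matched(
            NPXMatrix(serum, medium="serum"),
            NPXMatrix(plasma, medium="plasma"),
            subject_map=subject_map, cohort_label=cohort_label,
        )
        return cls(cohort, scheme)

    @classmethod
    def from_long_files(cls, serum_path, plasma_path, subject_map=None,
                        cohort_label: str = "", columns=None,
                        scheme: TierScheme | None = None) -> "SerumPlasmaModel":
        """Build from two long-format NPX files."""
        serum = npx_io.read_npx_long(serum_path, medium="serum", columns=columns)
        plasma = npx_io.read_npx_long(plasma_path, medium="plasma", columns=columns)
        cohort = pair_matched(serum, plasma, subject_map=subject_map,
                              cohort_label=cohort_label)
        return cls(cohort, scheme)

    def fit(self) -> "SerumPlasmaResults":
        """Run the Pearson screen and tiered fits for every protein."""
        fits = fit_cohort(self.cohort, self.scheme)
        screen = pearson_screen(self.cohort, self.scheme.pearson_threshold)
        return SerumPlasmaResults(self, fits, screen)


class SerumPlasmaResults:
    """Fitted per-protein transformation models for one cohort."""

    def __init__(self, model: SerumPlasmaModel, fits: list, screen: pd.DataFrame):
        self.model = model
        self.cohort = model.cohort
        self.scheme = model.scheme
        self.fits = fits
        self.pearson = screen

    # -- accessors ---------------------------------------------------------

    @property
    def fits_frame(self) -> pd.DataFrame:
        return fits_to_frame(self.fits)

    @property
    def modelable_fits(self) -> list:
        return [f for f in self.fits if f.modelable]

    @property
    def modelable_proteins(self) -> set:
        return {f.protein_id for f in self.fits if f.modelable}

    def tier_counts(self) -> dict:
        counts = {1: 0, 2: 0, 3: 0, None: 0}
        for f in self.fits:
            counts[f.tier] += 1
        return counts

    # -- downstream operations --------------------------------------------

    def gate(self, max_halfwidth: float = 0.3,
             direction: str = "serum_to_plasma") -> FactorCatalog:
        """CI-gate the modelable fits into a transformation-factor catalog."""
        return gate_by_ci(self.fits, max_halfwidth=max_halfwidth,
                          cohort_label=self.cohort.cohort_label,
                          direction=direction)

    def variance_diagnostics(self) -> pd.DataFrame:
        return variance_diagnostics(self.cohort, self.fits)

    def concordance_with(self, other: "SerumPlasmaResults",
                         tolerance: float = 0.3) -> ConcordanceReport:
        """Slope concordance of this cohort's fits against another's."""
        return slope_concordance(self.fits, other.fits, tolerance=tolerance,
                                 cohort_a=self.cohort, cohort_b=other.cohort)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fitting summary (counts, slope and CI quantiles)."""
        counts = self.tier_counts()
        n = len(self.fits)
        n_model = len(self.modelable_fits)
        n_pass = int(self.pearson["passes"].sum())
        slopes = np.array([f.slope for f in self.modelable_fits])
        cis = np.array([f.ci_halfwidth for f in self.modelable_fits])
        lines = [
            "Serum-plasma transformation model",
            "=" * 46,
            f"Cohort:               {self.cohort.cohort_label or '(unlabelled)'}",
            f"Subjects:             {self.cohort.n_subjects}",
            f"Proteins:             {n}",
            f"Pearson r >= {self.scheme.pearson_threshold:g}:     "
            f"{n_pass} ({0 if n == 0 else 100 * n_pass / n:.0f}%)",
            f"Modelable (R2 >= {self.scheme.r2_threshold:g}): {n_model} "
            f"({0 if n == 0 else 100 * n_model / n:.0f}%)",
            f"  Tier 1:             {counts[1]}",
            f"  Tier 2:             {counts[2]}",
            f"  Tier 3:             {counts[3]}",
            f"Non-modelable:        {counts[None]}",
        ]
        if n_model:
            q = np.percentile(slopes, [25, 50, 75])
            lines += [
                f"Slope quartiles:      {q[0]:.3f} / {q[1]:.3f} / {q[2]:.3f}",
                f"Median CI half-width: {np.median(cis):.3f}",
            ]
        return "\n".join(lines)

    def plot_slope_hist(self, bins=20, ax=None):
        """Histogram of modelable-protein slopes (matplotlib Axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist([f.slope for f in self.modelable_fits], bins=bins,
                edgecolor="black")
        ax.set_xlabel("slope (transformation factor)")
        ax.set_ylabel("proteins")
        ax.set_title("Modelable-protein slope distribution")
        return ax

    def plot_ci_hist(self, bins=20, ax=None):
        """Histogram of slope 95% CI half-widths for modelable proteins."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist([f.ci_halfwidth for f in self.modelable_fits], bins=bins,
                edgecolor="black")
        ax.set_xlabel("slope CI half-width")
        ax.set_ylabel("proteins")
        return ax
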