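"""Synthetic matched serum/plasma cohorts and two-group studies.

Every pipeline stage can be exercised against known ground truth: the
generator draws per-protein serum NPX levels, produces plasma as a linear
response ``plasma = intercept + slope * serum + noise``, plants a small
number of gross plasma-side outlier samples in a subset of proteins, and
returns a truth table alongside the cohort.  Residuals are Gaussian on the
NPX (log2) scale.  A low-variance protein stratum emulates the homogeneous
analytes that defeat cross-medium modelling in real panels.

Defaults mirror a 19-subject matched cohort with heterogeneous per-protein
variance: true slopes uniform on [0.6, 1.3], serum means uniform on
[2, 10] NPX, 15% of proteins in a near-zero-variance stratum, residual SD
set to half of ``slope * serum_sd`` (a typical modelable protein then has an
expected R-squared near 0.8) but floored at a 0.2 NPX technical noise level
-- which is precisely what renders the low-variance stratum non-modelable --
and 10% of proteins receiving two +8 NPX plasma outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .npx_io import MatchedCohort, NPXMatrix


@dataclass
class SimConfig:
    """Configuration of a synthetic matched serum/plasma cohort."""

    n_subjects: int = 19
    n_proteins: int = 200
    slope_range: tuple = (0.6, 1.3)
    true_slopes: np.ndarray | None = None      # overrides slope_range
    true_intercepts: np.ndarray | None = None  # default all 0
    serum_mean_range: tuple = (2.0, 10.0)
    serum_sd_range: tuple = (0.5, 1.5)
    low_variance_fraction: float = 0.15
    low_variance_sd_range: tuple = (0.02, 0.10)
    noise_sd: np.ndarray | float | None = None  # default slope * serum_sd / 2, floored
    assay_noise_floor: float = 0.2   # technical NPX noise independent of biology
    outlier_fraction: float = 0.10   # fraction of proteins with planted outliers
    n_outliers: int = 2              # outlier samples per affected protein
    outlier_shift: float = 8.0       # plasma displacement, NPX units
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ParameterError("n_subjects must be >= 4")
        if self.n_proteins < 1:
            raise ParameterError("n_proteins must be >= 1")
        for name in ("low_variance_fraction", "outlier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.n_outliers < 0 or self.n_outliers > self.n_subjects - 3:
            raise ParameterError("n_outliers must leave >= 3 clean samples")


@dataclass
class TwoGroupConfig:
    """Configuration of a synthetic two-group study for the DEA sweep."""

    n_per_group: int = 20
    n_proteins: int = 200
    n_de: int = 30
    de_effect: float = 1.2       # |group difference| in NPX units, random sign
    within_sd: float = 0.3
    baseline_range: tuple = (2.0, 10.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if not 0 <= self.n_de <= self.n_proteins:
            raise ParameterError("n_de must be in [0, n_proteins]")
        if self.within_sd < 0:
            raise ParameterError("within_sd must be >= 0")


def _protein_ids(n: int) -> list:
    width = len(str(n))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _subject_ids(n: int, prefix: str = "S") -> list:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_p = config.n_proteins
    slopes = (np.asarray(config.true_slopes, float) if config.true_slopes is not None
              else rng.uniform(*config.slope_range, size=n_p))
    intercepts = (np.asarray(config.true_intercepts, float)
                  if config.true_intercepts is not None else np.zeros(n_p))
    means = rng.uniform(*config.serum_mean_range, size=n_p)
    sds = rng.uniform(*config.serum_sd_range, size=n_p)
    low_var = rng.random(n_p) < config.low_variance_fraction
    sds[low_var] = rng.uniform(*config.low_variance_sd_range, size=int(low_var.sum()))
    if config.noise_sd is None:
        noise_sd = np.maximum(np.abs(slopes) * sds / 2.0, config.assay_noise_floor)
    else:
        noise_sd = np.broadcast_to(np.asarray(config.noise_sd, float), (n_p,)).copy()
    has_outliers = rng.random(n_p) < config.outlier_fraction
    return pd.DataFrame({
        "protein_id": _protein_ids(n_p),
        "slope": slopes, "intercept": intercepts,
        "serum_mean": means, "serum_sd": sds, "noise_sd": noise_sd,
        "low_variance": low_var, "has_outliers": has_outliers,
    }).set_index("protein_id")


def _realise_cohort(truth: pd.DataFrame, config: SimConfig,
                    rng: np.random.Generator, n_subjects: int,
                    subject_prefix: str, cohort_label: str):
    subjects = _subject_ids(n_subjects, subject_prefix)
    n_p = len(truth)
    serum = (truth["serum_mean"].to_numpy()
             + rng.standard_normal((n_subjects, n_p)) * truth["serum_sd"].to_numpy())
    plasma = (truth["intercept"].to_numpy()
              + truth["slope"].to_numpy() * serum
              + rng.standard_normal((n_subjects, n_p)) * truth["noise_sd"].to_numpy())
    outlier_ids = []
    for j, protein in enumerate(truth.index):
        if truth["has_outliers"].iloc[j] and config.n_outliers > 0:
            picks = rng.choice(n_subjects, size=config.n_outliers, replace=False)
            plasma[picks, j] += config.outlier_shift
            outlier_ids.append(";".join(subjects[i] for i in sorted(picks)))
        else:
            outlier_ids.append("")
    truth = truth.copy()
    truth["outlier_samples"] = outlier_ids
    proteins = list(truth.index)
    serum_m = NPXMatrix(pd.DataFrame(serum, index=subjects, columns=proteins),
                        medium="serum")
    plasma_m = NPXMatrix(pd.DataFrame(plasma, index=subjects, columns=proteins),
                         medium="plasma")
    cohort = MatchedCohort(serum=serum_m, plasma=plasma_m,
                           subject_map=[(s, s) for s in subjects],
                           cohort_label=cohort_label)
    return cohort, truth


def gen_matched_cohort(config: SimConfig | None = None,
                       cohort_label: str = "synthetic"):
    """Generate a matched cohort plus its ground-truth table.

    Returns ``(MatchedCohort, truth)`` where ``truth`` is indexed by protein
    and records the true slope/intercept, the serum level law, the residual
    SD and the planted outlier subjects (semicolon-joined, empty if none).
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    return _realise_cohort(truth, config, rng, config.n_subjects, "S", cohort_label)


def gen_paired_cohorts(config: SimConfig | None = None, n2: int = 40):
    """Two cohorts sharing true slopes but with independent subjects/noise.

    Emulates an original cohort plus an independent validation cohort of a
    different size; returns ``(cohort_a, cohort_b, truth)``.
    """
    config = config or SimConfig()
    config.validate()
    if n2 < 4:
        raise ParameterError("n2 must be >= 4")
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    cohort_a, truth_a = _realise_cohort(truth, config, rng, config.n_subjects,
                                        "A", "synthetic-a")
    cohort_b, truth_b = _realise_cohort(truth, config, rng, n2, "B", "synthetic-b")
    truth = truth_a.copy()
    truth = truth.rename(columns={"outlier_samples": "outlier_samples_a"})
    truth["outlier_samples_b"] = truth_b["outlier_samples"]
    return cohort_a, cohort_b, truth


def gen_two_group_study(config: TwoGroupConfig | None = None):
    """Generate a two-group NPX study with a known differential set.

    Returns ``(NPXMatrix, labels, truth)``: labels is a Series mapping each
    sample to ``"A"`` or ``"B"``; truth is indexed by protein with the true
    group-B-minus-A effect (0 for non-differential proteins) and a boolean
    ``is_de`` column.
    """
    config = config or TwoGroupConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_p = config.n_proteins
    proteins = _protein_ids(n_p)
    baselines = rng.uniform(*config.baseline_range, size=n_p)
    effects = np.zeros(n_p)
    de_idx = rng.choice(n_p, size=config.n_de, replace=False)
    effects[de_idx] = config.de_effect * rng.choice([-1.0, 1.0], size=config.n_de)
    n = config.n_per_group
    samples = _subject_ids(2 * n, "G")
    labels = pd.Series(["A"] * n + ["B"] * n, index=samples, name="group")
    values = baselines + rng.standard_normal((2 * n, n_p)) * config.within_sd
    values[n:, :] += effects
    matrix = NPXMatrix(pd.DataFrame(values, index=samples, columns=proteins),
                       medium="unknown")
    truth = pd.DataFrame({
        "protein_id": proteins,
        "true_effect": effects,
        "is_de": np.isin(np.arange(n_p), de_idx),
    }).set_index("protein_id")
    return matrix, labels, truth
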