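"""Sensitivity of differential-expression conclusions to factor error.

A transformation factor that is off by some multiplicative amount rescales
every NPX value of a protein and therefore its group-difference estimate.
This module quantifies how such mis-scaling propagates into a two-group
differential expression analysis (DEA): the original DEA is run once, the
matrix is rescaled by each factor on a grid (default 0.6 ... 1.4 in steps of
0.1), the DEA is re-run, and each originally- or newly-significant protein
is classified:

* **TP** -- significant in both runs with the same direction of change;
* **FP** -- significant only in the rescaled run, or significant in both
  with a flipped direction;
* **FN** -- significant in the original run but not retained (lost
  significance, or flipped direction).

``retention = TP / (TP + FN)`` is the fraction of original findings
preserved.  Significance uses the compound rule adjusted p <= 0.05 AND
|group mean difference| >= 1 NPX (NPX is log2-scale, so 1 NPX is a
two-fold change).  The test statistic is Welch's two-sample t by default,
with Benjamini-Hochberg adjustment across scored proteins; a rank-sum
alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import IntegrityError, ParameterError
from .npx_io import NPXMatrix

P_THRESHOLD_DEFAULT = 0.05
EFFECT_THRESHOLD_DEFAULT = 1.0  # NPX units; log2 scale, so fold-change 2
FACTOR_GRID_DEFAULT = (0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)


@dataclass
class SensitivityRecord:
    """TP/FP/FN counts at one perturbation factor."""

    factor: float
    n_tp: int
    n_fp: int
    n_fn: int

    @property
    def retention(self) -> float:
        orig = self.n_tp + self.n_fn
        return float("nan") if orig == 0 else self.n_tp / orig

    @property
    def fp_fraction(self) -> float:
        sig = self.n_tp + self.n_fp
        return 0.0 if sig == 0 else self.n_fp / sig


def _split_groups(matrix: NPXMatrix, group_labels, groups=None):
    labels = pd.Series(group_labels)
    if not labels.index.isin(matrix.sample_ids).all() and len(labels) == matrix.n_samples:
        labels.index = matrix.sample_ids
    labels = labels.reindex(matrix.sample_ids)
    uniq = list(pd.unique(labels.dropna()))
    if groups is None:
        if len(uniq) != 2:
            raise ParameterError(f"need exactly 2 groups, got {uniq}")
        groups = tuple(uniq)
    a_ids = labels.index[labels == groups[0]]
    b_ids = labels.index[labels == groups[1]]
    return matrix.values.loc[a_ids], matrix.values.loc[b_ids], groups


def run_dea(matrix: NPXMatrix, group_labels, p_threshold: float = P_THRESHOLD_DEFAULT,
            effect_threshold: float = EFFECT_THRESHOLD_DEFAULT,
            groups=None, test: str = "welch") -> pd.DataFrame:
    """Two-group differential expression analysis on NPX values.

    ``group_labels`` maps samples to two group labels (a dict, Series, or a
    sequence aligned with the matrix rows).  The effect is
    ``mean(group2) - mean(group1)`` in NPX units (a log2 fold-change);
    ``direction`` is ``up`` for a positive effect.  A protein is significant
    iff its BH-adjusted p-value is <= ``p_threshold`` AND the absolute
    effect reaches ``effect_threshold``.  Proteins with fewer than 2 values
    in either group, or constant in both groups, get an undefined p-value
    and are never significant.
    """
    a, b, groups = _split_groups(matrix, group_labels, groups)
    a_arr, b_arr = a.to_numpy(float), b.to_numpy(float)
    n_a = np.sum(~np.isnan(a_arr), axis=0)
    n_b = np.sum(~np.isnan(b_arr), axis=0)
    scored = (n_a >= 2) & (n_b >= 2)
    mean_a = np.nanmean(np.where(np.isnan(a_arr), np.nan, a_arr), axis=0)
    mean_b = np.nanmean(np.where(np.isnan(b_arr), np.nan, b_arr), axis=0)
    effect = mean_b - mean_a
    pvals = np.full(matrix.n_proteins, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        if test == "welch":
            res = stats.ttest_ind(b_arr, a_arr, axis=0, equal_var=False,
                                  nan_policy="omit")
            pvals = np.asarray(res.pvalue, dtype=float)
        elif test == "ranksum":
            for j in range(matrix.n_proteins):
                if scored[j]:
                    xa = a_arr[:, j][~np.isnan(a_arr[:, j])]
                    xb = b_arr[:, j][~np.isnan(b_arr[:, j])]
                    pvals[j] = stats.mannwhitneyu(xb, xa, alternative="two-sided").pvalue
        else:
            raise ParameterError(f"unknown test {test!r}")
    pvals = np.where(scored, pvals, np.nan)
    adj = np.full_like(pvals, np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    significant = ok & (adj <= p_threshold) & (np.abs(effect) >= effect_threshold)
    return pd.DataFrame({
        "effect": effect,
        "p_value": pvals,
        "adj_p_value": adj,
        "significant": significant,
        "direction": np.where(effect >= 0, "up", "down"),
        "scored": scored,
    }, index=matrix.protein_ids)


def scale_values(matrix: NPXMatrix, factor: float, proteins=None) -> NPXMatrix:
    """Multiply the NPX of the named proteins (default: all) by ``factor``."""
    if not factor > 0:
        raise ParameterError(f"scale factor must be positive, got {factor}")
    out = matrix.values.copy()
    cols = list(out.columns) if proteins is None else [p for p in out.columns if p in set(proteins)]
    out[cols] = out[cols] * factor
    return NPXMatrix(values=out, medium=matrix.medium, transformed=matrix.transformed)


def classify_tp_fp_fn(original: pd.DataFrame, modified: pd.DataFrame) -> tuple[int, int, int]:
    """Classify proteins by significance status before vs after rescaling.

    Returns ``(n_tp, n_fp, n_fn)``.  A protein significant in both runs but
    with a flipped direction counts as both FP (spuriously 'new' finding)
    and FN (its original finding is not retained), so
    ``TP + FN == |originally significant|`` always holds.
    """
    if set(original.index) != set(modified.index):
        raise IntegrityError("original and modified DEA cover different proteins")
    mod = modified.reindex(original.index)
    sig_o = original["significant"].to_numpy(bool)
    sig_m = mod["significant"].to_numpy(bool)
    same_dir = (original["direction"].to_numpy() == mod["direction"].to_numpy())
    tp = int((sig_o & sig_m & same_dir).sum())
    fp = int(((~sig_o & sig_m) | (sig_o & sig_m & ~same_dir)).sum())
    fn = int(((sig_o & ~sig_m) | (sig_o & sig_m & ~same_dir)).sum())
    return tp, fp, fn


def classify_labels(original: pd.DataFrame, modified: pd.DataFrame) -> pd.Series:
    """Per-protein TP/FP/FN label for one original-vs-rescaled DEA pair.

    Direction flips are labelled ``FP|FN`` (they count in both tallies);
    proteins significant in neither run get an empty label.
    """
    if set(original.index) != set(modified.index):
        raise IntegrityError("original and modified DEA cover different proteins")
    mod = modified.reindex(original.index)
    sig_o = original["significant"].to_numpy(bool)
    sig_m = mod["significant"].to_numpy(bool)
    same = original["direction"].to_numpy() == mod["direction"].to_numpy()
    labels = np.full(len(original), "", dtype=object)
    labels[sig_o & sig_m & same] = "TP"
    labels[~sig_o & sig_m] = "FP"
    labels[sig_o & ~sig_m] = "FN"
    labels[sig_o & sig_m & ~same] = "FP|FN"
    return pd.Series(labels, index=original.index, name="label")


def sensitivity_sweep(matrix: NPXMatrix, group_labels, factors=FACTOR_GRID_DEFAULT,
                      proteins_to_scale=None, p_threshold: float = P_THRESHOLD_DEFAULT,
                      effect_threshold: float = EFFECT_THRESHOLD_DEFAULT,
                      groups=None, test: str = "welch") -> list:
    """Run the DEA perturbation sweep over a grid of scale factors.

    The original DEA is computed once; for each factor the matrix is
    rescaled, the DEA re-run with identical settings, and TP/FP/FN recorded.
    Records are returned ordered by factor.
    """
    for f in factors:
        if not f > 0:
            raise ParameterError(f"factors must be positive, got {f}")
    original = run_dea(matrix, group_labels, p_threshold, effect_threshold,
                       groups=groups, test=test)
    records = []
    for factor in sorted(factors):
        scaled = scale_values(matrix, factor, proteins_to_scale)
        modified = run_dea(scaled, group_labels, p_threshold, effect_threshold,
                           groups=groups, test=test)
        tp, fp, fn = classify_tp_fp_fn(original, modified)
        records.append(SensitivityRecord(factor=float(factor), n_tp=tp, n_fp=fp, n_fn=fn))
    return records


def retention_curve(records) -> pd.DataFrame:
    """Tabulate retention and FP rates per factor for reporting.

    ``fp_fraction`` uses the rescaled run's significant set as denominator,
    ``fp_over_original`` the original significant count; both are reported
    because either convention is defensible.
    """
    if not records:
        raise ParameterError("no sensitivity records")
    return pd.DataFrame([{
        "factor": r.factor, "n_tp": r.n_tp, "n_fp": r.n_fp, "n_fn": r.n_fn,
        "retention": r.retention, "fp_fraction": r.fp_fraction,
        "fp_over_original": (float("nan") if r.n_tp + r.n_fn == 0
                             else r.n_fp / (r.n_tp + r.n_fn)),
    } for r in records]).set_index("factor")
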