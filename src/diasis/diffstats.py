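"""Across-sample ratios, differential abundance, and evaluation curves.

Fold changes are reported in log2 while the quantification pipeline works in
log10; the conversion ``log2FC = (log10 difference) * log2(10)`` is applied
exactly once, here at the statistics boundary.

Differential abundance uses a two-sided two-sample Student t-test (equal
variance) on the per-replicate log abundances of the two samples, without
multiple-testing correction; a protein is called significant when
``p < 0.01`` and ``|log2FC| > 1`` (both strict). Precision-recall curves for
a dilution benchmark are built from proteins with negative fold changes
only, since the diluted species can only go down.
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .benchmark import species_of_series
from .quantify import AbundanceMatrix
from .report_io import DesignSpec

__all__ = [
    "LOG2_PER_LOG10",
    "across_sample_ratios",
    "ttest_diff",
    "bh_adjust",
    "classify_hits",
    "differential_abundance",
    "precision_recall",
    "missingness_summary",
    "restrict_to_reference_set",
]

#: log2(10): converts a log10 difference into a log2 fold change.
LOG2_PER_LOG10 = math.log2(10.0)


def across_sample_ratios(matrix: AbundanceMatrix, design: DesignSpec) -> pd.DataFrame:
    """Per-protein, per-comparison replicate log2 fold changes and their mean.

    For each comparison (S vs reference) and replicate k,
    ``log2FC_k = (abundance(S,k) − abundance(ref,k)) * log2(10)``. A protein
    contributes to a comparison only when it is quantified in *all*
    replicates of both samples; proteins with any missing replicate are
    ignored for that comparison.

    Returns columns ``protein_group, comparison, replicate, log2fc`` (long,
    one row per replicate) with the summary accessible via
    :func:`replicate_means`.
    """
    data = matrix.data
    rows = []
    for sample, ref in design.comparisons:
        name = design.comparison_name(sample, ref)
        pairs = design.replicate_pairs(sample, ref)
        runs = [r for _, run_s, run_ref in pairs for r in (run_s, run_ref)]
        runs = [r for r in runs if r in data.columns]
        complete = data[runs].notna().all(axis=1)
        for rep, run_s, run_ref in pairs:
            diff = (data.loc[complete, run_s] - data.loc[complete, run_ref]) * LOG2_PER_LOG10
            rows.append(
                pd.DataFrame(
                    {
                        "protein_group": diff.index,
                        "comparison": name,
                        "replicate": rep,
                        "log2fc": diff.to_numpy(),
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["protein_group", "comparison", "replicate", "log2fc"])
    return pd.concat(rows, ignore_index=True)


def replicate_means(ratios: pd.DataFrame) -> pd.DataFrame:
    """Mean log2FC and replicate count per (protein, comparison)."""
    if ratios.empty:
        return pd.DataFrame(columns=["protein_group", "comparison", "mean_log2fc", "n_pairs"])
    out = (
        ratios.groupby(["protein_group", "comparison"])
        .agg(mean_log2fc=("log2fc", "mean"), n_pairs=("log2fc", "size"))
        .reset_index()
    )
    out["n_pairs"] = out["n_pairs"].astype(int)
    return out


def ttest_diff(group_a: np.ndarray, group_b: np.ndarray, test: str = "two_sample") -> float:
    """Two-sided Student t-test p-value for two replicate groups.

    Equal-variance (classic Student) by default; ``test='welch'`` switches to
    the unequal-variance form. Requires at least two values per group. When
    the pooled variance is zero the p-value is undefined and NaN is returned
    — never 0, even if the group means differ.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.var(a) == 0 and np.var(b) == 0:
        return float("nan")
    res = stats.ttest_ind(a, b, equal_var=(test != "welch"))
    return float(res.pvalue)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaN inputs stay NaN."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return out
    order = np.argsort(p[ok], kind="mergesort")
    ranked = p[ok][order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    vals = np.empty(m)
    vals[order] = adj
    out[ok] = vals
    return out


def classify_hits(results: pd.DataFrame, p_cut: float = 0.01, fc_cut: float = 1.0) -> pd.DataFrame:
    """Flag significantly differentially abundant proteins.

    Strict cutoffs: ``p < p_cut`` and ``|mean_log2fc| > fc_cut``; an
    undefined (NaN) p-value is never significant.
    """
    out = results.copy()
    p = out["p_value"]
    out["significant"] = (
        p.notna() & (p < p_cut) & (out["mean_log2fc"].abs() > fc_cut)
    )
    return out


def differential_abundance(
    matrix: AbundanceMatrix,
    design: DesignSpec,
    p_cut: float = 0.01,
    fc_cut: float = 1.0,
    test: str = "two_sample",
    correction: str | None = None,
) -> pd.DataFrame:
    """Full differential-abundance table for every configured comparison.

    Combines the replicate-paired ratio summaries with a two-group t-test on
    the per-replicate log abundances of the two samples (the same proteins
    that have a complete ratio; a t-test p-value is scale-invariant, so it is
    computed on the log10 values directly). Output columns:
    ``protein_group, comparison, mean_log2fc, n_pairs, p_value, species,
    significant``.
    """
    means = replicate_means(across_sample_ratios(matrix, design))
    data = matrix.data
    pval_frames = []
    for sample, ref in design.comparisons:
        name = design.comparison_name(sample, ref)
        runs_s = [r for r in design.runs_of(sample).values() if r in data.columns]
        runs_r = [r for r in design.runs_of(ref).values() if r in data.columns]
        prots = means.loc[means["comparison"] == name, "protein_group"]
        if prots.empty:
            continue
        a = data.loc[prots, runs_s].to_numpy(dtype=float)
        b = data.loc[prots, runs_r].to_numpy(dtype=float)
        # complete-ratio proteins have no NaN in these runs by construction
        with np.errstate(invalid="ignore", divide="ignore"):
            p = stats.ttest_ind(a, b, axis=1, equal_var=(test != "welch")).pvalue
        degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
        p = np.where(degenerate, np.nan, p)
        pval_frames.append(
            pd.DataFrame({"protein_group": prots.to_numpy(), "comparison": name, "p_value": p})
        )
    if pval_frames:
        means = means.merge(pd.concat(pval_frames, ignore_index=True), on=["protein_group", "comparison"], how="left")
    else:
        means["p_value"] = np.nan
    if correction == "bh":
        # off by default: the standard workflow reports uncorrected p-values
        means["p_value"] = (
            means.groupby("comparison")["p_value"].transform(lambda s: bh_adjust(s.to_numpy()))
        )
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    means["species"] = species_of_series(
        means["protein_group"], design.species_rules, design.species_table
    ).to_numpy()
    return classify_hits(means, p_cut=p_cut, fc_cut=fc_cut)


def precision_recall(
    results: pd.DataFrame,
    positives: Iterable[str],
    ranking: str = "log2fc",
) -> pd.DataFrame:
    """Precision-recall curve over proteins with negative fold changes.

    In a dilution benchmark the diluted species (the positives) can only be
    depleted, so the curve is built from proteins with ``mean_log2fc < 0``
    only. Proteins are ranked by increasing log2FC (most depleted first) or
    by increasing p-value; thresholds sweep the distinct scores, tied scores
    entering together. The recall denominator is the number of true
    positives in the restricted set.

    Returns columns ``ranking, threshold, recall, precision``.
    """
    if ranking not in ("log2fc", "pvalue"):
        raise ValueError(f"unknown ranking {ranking!r}")
    pos = set(positives)
    sub = results[results["mean_log2fc"] < 0].copy()
    if ranking == "log2fc":
        sub["score"] = sub["mean_log2fc"]
    else:
        sub["score"] = sub["p_value"]
        sub = sub[sub["score"].notna()]
    sub["is_positive"] = sub["protein_group"].isin(pos)
    n_pos = int(sub["is_positive"].sum())
    if n_pos == 0:
        raise ValueError("no true positives among proteins with negative fold change")
    sub = sub.sort_values("score", kind="mergesort")
    scores = sub["score"].to_numpy()
    is_pos = sub["is_positive"].to_numpy()
    tp_cum = np.cumsum(is_pos)
    n_cum = np.arange(1, len(sub) + 1)
    # last index of each distinct score: tied scores enter together
    last_of_tie = np.r_[scores[1:] != scores[:-1], True]
    idx = np.flatnonzero(last_of_tie)
    return pd.DataFrame(
        {
            "ranking": ranking,
            "threshold": scores[idx],
            "recall": tp_cum[idx] / n_pos,
            "precision": tp_cum[idx] / n_cum[idx],
        }
    )


def missingness_summary(
    matrix: AbundanceMatrix,
    design: DesignSpec,
    reference_proteins: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Fraction of proteins without a complete across-sample ratio.

    For each comparison and species: the denominator is the reference protein
    set (by default every protein in the matrix; configurable to e.g. the
    union of proteins seen by any method under comparison), the numerator the
    proteins lacking a value in at least one replicate of either sample.
    Returns ``comparison, species, n_reference, n_complete,
    missing_fraction``.
    """
    data = matrix.data
    if reference_proteins is None:
        reference = pd.Index(data.index)
    else:
        reference = pd.Index(sorted(set(reference_proteins)))
    species = species_of_series(
        pd.Series(reference, index=reference), design.species_rules, design.species_table
    )
    rows = []
    for sample, ref in design.comparisons:
        name = design.comparison_name(sample, ref)
        runs = [
            r
            for _, run_s, run_ref in design.replicate_pairs(sample, ref)
            for r in (run_s, run_ref)
        ]
        present = data.reindex(reference)[[c for c in runs if c in data.columns]]
        complete = present.notna().all(axis=1) if len(present.columns) == len(runs) else pd.Series(False, index=reference)
        for sp in sorted(species.unique()):
            members = reference[species == sp]
            n_ref = len(members)
            n_complete = int(complete.loc[members].sum()) if n_ref else 0
            rows.append(
                {
                    "comparison": name,
                    "species": sp,
                    "n_reference": n_ref,
                    "n_complete": n_complete,
                    "missing_fraction": 1.0 - n_complete / n_ref if n_ref else float("nan"),
                }
            )
    return pd.DataFrame(rows)


class RestrictedResults(NamedTuple):
    results: pd.DataFrame
    n_before: int
    n_after: int


def restrict_to_reference_set(
    results: pd.DataFrame, reference_proteins: Iterable[str]
) -> RestrictedResults:
    """Intersect a result table with a reference protein set.

    Used to make label-free and spike-in analyses comparable by reducing both
    to proteins found in any spike-in sample. Reports counts before/after.
    """
    ref = set(reference_proteins)
    keep = results["protein_group"].isin(ref)
    return RestrictedResults(
        results.loc[keep].reset_index(drop=True), int(len(results)), int(keep.sum())
    )
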