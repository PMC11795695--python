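"""Scoring quantification output against two-species ground truth.

In the mixed-species benchmark the anchor species is present at equal
amounts everywhere (its true fold change is always 1:1) while the second
species is diluted by known factors; every protein therefore carries a
ground-truth label. Scoring counts misclassified anchor proteins (false
positives), recovered diluted proteins (true positives), and summarizes the
bias and spread of the recovered ratios per true-fold-change tier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "species_of",
    "species_of_series",
    "completeness",
    "score_against_truth",
    "BenchmarkReport",
]


def species_of(
    protein_group: str,
    rules: Sequence[tuple[str, str]] = (),
    table: Mapping[str, str] | None = None,
) -> str:
    """Species label of a protein group.

    Each accession of the (semicolon-joined) group is looked up in the
    explicit ``table`` first, then matched against the ordered ``(regex,
    species)`` rules. An unmapped group is ``"unknown"``; a group whose
    members map to more than one species is ``"mixed"`` — both are excluded
    from scoring, with counts reported.
    """
    labels = set()
    for acc in protein_group.split(";"):
        label = None
        if table and acc in table:
            label = table[acc]
        else:
            for pattern, sp in rules:
                if re.search(pattern, acc):
                    label = sp
                    break
        if label is not None:
            labels.add(label)
    if not labels:
        return "unknown"
    if len(labels) > 1:
        return "mixed"
    return labels.pop()


def species_of_series(
    groups: pd.Series,
    rules: Sequence[tuple[str, str]] = (),
    table: Mapping[str, str] | None = None,
) -> pd.Series:
    uniq = {g: species_of(g, rules, table) for g in groups.unique()}
    return groups.map(uniq)


def completeness(quant, design, rules=None, table=None) -> pd.DataFrame:
    """Per-sample, per-species counts of proteins found in 1..n replicates.

    ``quant`` may be an abundance matrix (object with a wide ``.data``
    frame) or a protein quant table with ``protein_group``/``run_id``
    columns. The bins partition the detected protein set of each sample: a
    protein detected in k of the sample's replicates counts once in bin k,
    and a protein absent from the sample entirely is not counted.
    """
    rules = design.species_rules if rules is None else rules
    table = design.species_table if table is None else table
    if hasattr(quant, "data"):
        presence = quant.data.notna()
    else:
        presence = (
            quant.assign(one=True)
            .pivot_table(index="protein_group", columns="run_id", values="one", aggfunc="any")
            .fillna(False)
        )
    species = species_of_series(
        pd.Series(presence.index, index=presence.index), rules, table
    )
    rows = []
    for sample in design.samples:
        runs = [r for r in design.runs_of(sample).values() if r in presence.columns]
        if not runs:
            continue
        n_detected = presence[runs].sum(axis=1)
        for sp in sorted(species.unique()):
            counts = n_detected[species == sp]
            for k in range(1, len(runs) + 1):
                rows.append(
                    {
                        "sample": sample,
                        "species": sp,
                        "n_replicates": k,
                        "n_proteins": int((counts == k).sum()),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class BenchmarkReport:
    """Summary of a scored benchmark run.

    ``fp_count``: anchor/negative-label proteins flagged significant.
    ``tp_count``: positive-label proteins flagged significant.
    ``tier_stats``: per (comparison, species, true log2FC) median bias
    (observed − expected log2FC) and MAD spread.
    ``n_excluded``: proteins skipped because their species was unknown or
    spanned two species.
    """

    fp_count: int
    tp_count: int
    n_positives: int
    n_negatives: int
    tier_stats: pd.DataFrame
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        head = pd.DataFrame(
            {
                "metric": ["fp_count", "tp_count", "n_positives", "n_negatives", "n_excluded"],
                "value": [
                    self.fp_count,
                    self.tp_count,
                    self.n_positives,
                    self.n_negatives,
                    self.n_excluded,
                ],
            }
        )
        return head


def score_against_truth(results: pd.DataFrame, truth: pd.DataFrame) -> BenchmarkReport:
    """Score a differential-abundance table against ground truth.

    ``results`` needs columns ``protein_group, comparison, mean_log2fc,
    significant``; ``truth`` needs ``protein_group, comparison, species,
    true_log2fc, is_positive``. Counting uses the significance flags as-is;
    proteins whose truth species is ``unknown`` or ``mixed`` are excluded
    with a count. Invariant to protein ordering.
    """
    merged = results.drop(columns=["species"], errors="ignore").merge(
        truth[["protein_group", "comparison", "species", "true_log2fc", "is_positive"]],
        on=["protein_group", "comparison"],
        how="inner",
    )
    excluded = merged["species"].isin(["unknown", "mixed"])
    n_excluded = int(excluded.sum())
    merged = merged[~excluded]

    is_pos = merged["is_positive"].astype(bool)
    sig = merged["significant"].astype(bool)
    fp = int((sig & ~is_pos).sum())
    tp = int((sig & is_pos).sum())

    merged = merged.assign(bias=merged["mean_log2fc"] - merged["true_log2fc"])
    tier_stats = (
        merged.groupby(["comparison", "species", "true_log2fc"])
        .agg(
            n=("bias", "size"),
            median_bias=("bias", "median"),
            mad_spread=("bias", lambda x: float(np.median(np.abs(x - np.median(x))))),
        )
        .reset_index()
    )
    return BenchmarkReport(
        fp_count=fp,
        tp_count=tp,
        n_positives=int(is_pos.sum()),
        n_negatives=int((~is_pos).sum()),
        tier_stats=tier_stats,
        n_excluded=n_excluded,
    )
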