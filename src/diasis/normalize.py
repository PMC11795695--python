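"""Normalization schemes for reconstructed abundances and L/H ratios.

Two schemes, used for two different study designs:

Anchor normalization (two-species benchmark)
    The anchor species is held at constant amount in every sample, so its
    theoretical across-sample ratio is 1:1. For each non-reference run the
    observed median anchor log-ratio against the paired reference run is
    subtracted from every abundance of that run; reference runs are never
    shifted. After the shift the anchor median across-sample log ratio is 0
    by construction.

Run-median shift (super-SILAC / clinical-tissue designs)
    Without a constant-amount species, each run's protein log10 L/H ratios
    are centered by subtracting the run median before abundances are
    reconstructed.

Both operations are idempotent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .benchmark import species_of_series
from .quantify import AbundanceMatrix
from .report_io import DesignSpec

__all__ = ["anchor_normalize", "median_shift_normalize"]


def anchor_normalize(
    matrix: AbundanceMatrix,
    design: DesignSpec,
    pooled: bool = False,
) -> AbundanceMatrix:
    """Shift each non-reference run so the anchor species is centered on 1:1.

    The shift for run (sample S, replicate k) is the median, over
    anchor-species proteins quantified in both runs, of
    ``abundance(p, S, k) − abundance(p, ref, k)``. With ``pooled=True`` one
    shift per sample is computed from all replicate pairs jointly instead of
    one per replicate pair.

    Raises if a run pair shares no anchor-species protein.
    """
    species = species_of_series(
        pd.Series(matrix.data.index, index=matrix.data.index),
        design.species_rules,
        design.species_table,
    )
    anchor_idx = matrix.data.index[species == design.anchor_species]
    out = matrix.copy()
    data = out.data

    for sample in design.samples:
        if sample == design.reference_sample:
            continue
        pairs = design.replicate_pairs(sample)
        shifts = {}
        diffs_pooled = []
        for rep, run_s, run_ref in pairs:
            if run_s not in data.columns or run_ref not in data.columns:
                continue
            diff = data.loc[anchor_idx, run_s] - data.loc[anchor_idx, run_ref]
            diff = diff.dropna()
            if diff.empty:
                raise ValueError(
                    f"no anchor-species protein shared between runs "
                    f"{run_s!r} and {run_ref!r}"
                )
            shifts[run_s] = float(diff.median())
            diffs_pooled.append(diff)
        if pooled and diffs_pooled:
            shift = float(pd.concat(diffs_pooled).median())
            for run_s in shifts:
                data[run_s] = data[run_s] - shift
        else:
            for run_s, shift in shifts.items():
                data[run_s] = data[run_s] - shift

    out.normalized = True
    return out


def median_shift_normalize(pq: pd.DataFrame) -> pd.DataFrame:
    """Center each run's protein log10 L/H ratios on their median.

    Operates on a protein quant table (columns ``protein_group, run_id,
    log10_lh_protein, ...``); after the shift every run's protein-ratio
    median is exactly 0. Raises on a run without any ratio (cannot occur in
    tables built by the rollup, which emits no empty runs).
    """
    if pq.empty:
        raise ValueError("cannot median-shift an empty quant table")
    out = pq.copy()
    medians = out.groupby("run_id")["log10_lh_protein"].transform("median")
    if medians.isna().any():
        bad = out.loc[medians.isna(), "run_id"].iloc[0]
        raise ValueError(f"run {bad!r} has no protein ratios")
    out["log10_lh_protein"] = out["log10_lh_protein"] - medians
    return out
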