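"""Channel pairing, L/H ratio rollup, and light-abundance reconstruction.

The spike-in SILAC quantification model: every sample receives an identical
heavy-labeled reference proteome, so the light/heavy (L/H) intensity ratio of
a precursor is an internally calibrated measure of the light amount.

Per precursor and run, log10 L/H ratios are computed from the Ms1-level and
the fragment-level intensity column independently (a column contributes only
when both channel values are present and > 0). Per protein and run, the
protein log10 L/H ratio is the median over all of its precursor ratios, both
columns pooled. The protein's global heavy intensity is the median over runs
of log10(summed heavy precursor intensity), and the reconstructed light
abundance is, in log10 space::

    abundance(p, run) = log10_lh_protein(p, run) + log10_heavy_global(p)

Because the heavy reference is identical in every run, any global rescaling
of the spike-in amount cancels between the two terms: light abundances are
invariant to the spike-in excess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import FilterPolicy, channel_pass, translated_valid

__all__ = [
    "AbundanceMatrix",
    "pair_channels",
    "precursor_log_ratios",
    "protein_log_ratio",
    "global_heavy_intensity",
    "light_abundances",
    "lfq_abundances",
    "sis_quantify",
]

_SIDE_COLUMNS = [
    "ms1_translated",
    "precursor_translated",
    "global_pg_qvalue",
    "channel_qvalue",
]


@dataclass
class AbundanceMatrix:
    """Protein x run matrix of log10 light abundances (or log10 LFQ values).

    ``data`` is wide: index ``protein_group``, one column per run, NaN where
    the protein was not quantified in that run. ``method`` records the
    provenance (``sis`` or ``lfq``); ``normalized`` whether a normalization
    scheme has been applied.
    """

    data: pd.DataFrame
    method: str = "sis"
    normalized: bool = False

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.method, self.normalized)

    def to_frame_with_meta(self):
        frame = self.data.reset_index()
        meta = {
            "kind": "abundance_matrix",
            "method": self.method,
            "normalized": str(self.normalized),
        }
        return frame, meta

    @classmethod
    def from_frame_with_meta(cls, frame: pd.DataFrame, meta: dict) -> "AbundanceMatrix":
        data = frame.set_index("protein_group")
        return cls(data, meta.get("method", "sis"), meta.get("normalized") == "True")


def pair_channels(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot records into one row per (run, precursor) with L and H sides.

    Output columns: ``run_id, protein_group, precursor_key, precursor_charge,
    is_contaminant, has_L, has_H`` plus per-side intensity and q-value columns
    (``L_ms1_translated`` etc.). Orphan light records (no heavy partner)
    appear with ``has_H=False`` and are dropped by pair selection.

    Raises on duplicate records for one (run, precursor_key, channel).
    """
    key = ["run_id", "protein_group", "precursor_key"]
    dup = records.duplicated(["run_id", "precursor_key", "channel"], keep=False)
    if dup.any():
        first = records.loc[dup, ["run_id", "precursor_key", "channel"]].iloc[0]
        raise ValueError(f"duplicate channel record for {tuple(first)}")

    wide = records.pivot(
        index=key + ["precursor_charge", "is_contaminant"],
        columns="channel",
        values=_SIDE_COLUMNS,
    )
    wide.columns = [f"{ch}_{col}" for col, ch in wide.columns]
    wide = wide.reset_index()
    for ch in ("L", "H"):
        for col in _SIDE_COLUMNS:
            if f"{ch}_{col}" not in wide.columns:
                wide[f"{ch}_{col}"] = np.nan
    # presence means a record row existed for that channel, even if all its
    # intensity cells were empty — missing is distinct from absent
    counts = (
        records.assign(one=1)
        .pivot_table(index=key, columns="channel", values="one", aggfunc="size")
        .reindex(columns=["L", "H"])
    )
    present = counts.notna().reset_index().rename(columns={"L": "has_L", "H": "has_H"})
    out = wide.merge(present, on=key, how="left")
    out["has_L"] = out["has_L"].astype(bool)
    out["has_H"] = out["has_H"].astype(bool)
    return out


def precursor_log_ratios(pairs: pd.DataFrame, policy: FilterPolicy) -> pd.DataFrame:
    """Per-precursor log10(L/H) ratios from the two quantification columns.

    Each side of a pair must satisfy the configured translated-validity rule;
    a column then yields a ratio only where both its L and H value are
    present and > 0 (zero, negative or missing values suppress that column's
    ratio, they are never imputed). Output: long table with columns
    ``run_id, protein_group, precursor_key, source_column, log10_lh,
    rescued``.
    """
    rule = policy.translated_validity
    valid = translated_valid(pairs, rule, side="L") & translated_valid(pairs, rule, side="H")
    rescued = pairs["rescued"] if "rescued" in pairs else pd.Series(False, index=pairs.index)

    frames = []
    for source, col in (("ms1", "ms1_translated"), ("precursor", "precursor_translated")):
        lv, hv = pairs[f"L_{col}"], pairs[f"H_{col}"]
        ok = valid & lv.notna() & hv.notna() & (lv > 0) & (hv > 0)
        if not ok.any():
            continue
        sub = pairs.loc[ok, ["run_id", "protein_group", "precursor_key"]].copy()
        sub["source_column"] = source
        sub["log10_lh"] = np.log10(lv[ok].to_numpy() / hv[ok].to_numpy())
        sub["rescued"] = rescued[ok].to_numpy()
        frames.append(sub)
    if not frames:
        return pd.DataFrame(
            columns=["run_id", "protein_group", "precursor_key", "source_column", "log10_lh", "rescued"]
        )
    return pd.concat(frames, ignore_index=True)


def protein_log_ratio(ratios: pd.DataFrame) -> pd.DataFrame:
    """Protein-level rollup: median of all precursor log10 L/H ratios.

    Both source columns are pooled into one ratio list per (protein, run);
    the median uses the mean-of-central-pair convention for even counts.
    Returns columns ``protein_group, run_id, log10_lh_protein, n_ratios,
    rescued_fraction``; a (protein, run) without any ratio yields no row.
    """
    if ratios.empty:
        return pd.DataFrame(
            columns=["protein_group", "run_id", "log10_lh_protein", "n_ratios", "rescued_fraction"]
        )
    grouped = ratios.groupby(["protein_group", "run_id"], sort=True)
    out = grouped.agg(
        log10_lh_protein=("log10_lh", "median"),
        n_ratios=("log10_lh", "size"),
        rescued_fraction=("rescued", "mean"),
    ).reset_index()
    out["n_ratios"] = out["n_ratios"].astype(int)
    return out


def global_heavy_intensity(records: pd.DataFrame, policy: FilterPolicy) -> pd.DataFrame:
    """Per-protein global heavy intensity from confident heavy records.

    Heavy records passing :func:`channel_pass` are summed per (protein, run)
    over both quantification columns (a missing column counts as 0 inside the
    sum); the global value is the median over runs of log10(sum), excluding
    runs whose sum is 0. Proteins with no positive heavy sum anywhere are
    dropped. Returns ``protein_group, log10_heavy_global, n_samples_used``.
    """
    heavy = records[(records["channel"] == "H") & channel_pass(records, policy)]
    if heavy.empty:
        return pd.DataFrame(columns=["protein_group", "log10_heavy_global", "n_samples_used"])
    sums = (
        heavy.assign(
            total=heavy["ms1_translated"].fillna(0) + heavy["precursor_translated"].fillna(0)
        )
        .groupby(["protein_group", "run_id"])["total"]
        .sum()
    )
    sums = sums[sums > 0]
    logged = np.log10(sums)
    out = (
        logged.groupby("protein_group")
        .agg(log10_heavy_global="median", n_samples_used="size")
        .reset_index()
    )
    out["n_samples_used"] = out["n_samples_used"].astype(int)
    return out


def light_abundances(pq: pd.DataFrame, gh: pd.DataFrame) -> AbundanceMatrix:
    """Reconstruct light abundances: protein L/H ratio + global heavy, in log10.

    Every protein in the quant table must be present in the global heavy
    index; otherwise an error lists the missing proteins.
    """
    missing = sorted(set(pq["protein_group"]) - set(gh["protein_group"]))
    if missing:
        shown = ", ".join(missing[:10])
        raise ValueError(
            f"{len(missing)} protein(s) missing from the global heavy index: {shown}"
        )
    merged = pq.merge(gh[["protein_group", "log10_heavy_global"]], on="protein_group")
    merged["abundance"] = merged["log10_lh_protein"] + merged["log10_heavy_global"]
    wide = merged.pivot(index="protein_group", columns="run_id", values="abundance")
    wide.columns.name = None
    return AbundanceMatrix(wide, method="sis", normalized=False)


def lfq_abundances(records: pd.DataFrame) -> AbundanceMatrix:
    """Label-free abundance matrix from the report's MaxLFQ column.

    The MaxLFQ protein value is constant within a (protein, run); conflicting
    values raise. Nonpositive values are dropped (the count is recorded in
    ``matrix.data.attrs['n_dropped_nonpositive']``); abundances are log10.
    """
    sub = records.dropna(subset=["pg_maxlfq"])
    uniq = sub.groupby(["protein_group", "run_id"])["pg_maxlfq"].nunique()
    conflict = uniq[uniq > 1]
    if not conflict.empty:
        pg, run = conflict.index[0]
        raise ValueError(
            f"conflicting PG.MaxLFQ values for protein {pg!r} in run {run!r}"
        )
    vals = sub.groupby(["protein_group", "run_id"])["pg_maxlfq"].first()
    n_bad = int((vals <= 0).sum())
    vals = vals[vals > 0]
    wide = np.log10(vals).unstack("run_id")
    wide.columns.name = None
    out = AbundanceMatrix(wide, method="lfq", normalized=False)
    out.data.attrs["n_dropped_nonpositive"] = n_bad
    return out


def sis_quantify(records: pd.DataFrame, policy: FilterPolicy):
    """Full spike-in quantification of a contaminant-flagged record table.

    Chains channel pairing, pair selection under the policy's mode,
    precursor ratio computation, median rollup, global heavy intensity and
    abundance reconstruction. Returns ``(protein_quant, abundance_matrix)``.
    """
    from .filtering import select_sis_pairs

    pairs = select_sis_pairs(pair_channels(records), policy)
    ratios = precursor_log_ratios(pairs, policy)
    pq = protein_log_ratio(ratios)
    gh = global_heavy_intensity(records, policy)
    pq = pq[pq["protein_group"].isin(set(gh["protein_group"]))].reset_index(drop=True)
    return pq, light_abundances(pq, gh)
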