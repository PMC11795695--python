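"""Confidence filtering of multiplexed report records.

Three modes mirror the three quantification strategies:

``lfq``
    Label-free: contaminants removed, charge > 1, Lib.PG.Q.Value < 0.01 and
    Lib.Q.Value < 0.01.
``sis_basic``
    Spike-in SILAC: contaminants removed, charge > 1, Global.PG.Q.Value < 0.01
    and Channel.Q.Value < 0.03 on *both* the light and heavy channel.
``sis_requant``
    As ``sis_basic`` for the heavy channel, but a light precursor whose heavy
    partner passed is rescued even if its own q-values fail. Rationale: the
    light and heavy species co-elute, so a confident heavy detection certifies
    the measurement window of the light partner.

All thresholds are strict inequalities; a record sitting exactly at a
threshold is excluded. A missing q-value fails the corresponding filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterPolicy",
    "apply_lfq_filters",
    "channel_pass",
    "select_sis_pairs",
    "translated_valid",
]


@dataclass
class FilterPolicy:
    """Thresholds and mode of the record-level filters.

    ``min_charge_exclusive`` is the exclusive lower bound on the precursor
    charge (default 1, i.e. charge > 1 is kept). ``translated_validity``
    selects the intensity-validity rule: ``both`` requires Ms1-level and
    fragment-level intensities to both be present and > 0; ``any`` accepts a
    record when at least one of them is (used for sparse low-input data).
    """

    mode: str = "sis_basic"  # lfq | sis_basic | sis_requant
    global_pg_q_max: float = 0.01
    channel_q_max: float = 0.03
    lib_pg_q_max: float = 0.01
    lib_q_max: float = 0.01
    min_charge_exclusive: int = 1
    translated_validity: str = "both"  # both | any

    def __post_init__(self) -> None:
        if self.mode not in ("lfq", "sis_basic", "sis_requant"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.translated_validity not in ("both", "any"):
            raise ValueError(
                f"unknown translated-validity rule {self.translated_validity!r}"
            )
        for name in ("global_pg_q_max", "channel_q_max", "lib_pg_q_max", "lib_q_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.min_charge_exclusive < 0:
            raise ValueError("min_charge_exclusive must be >= 0")


def _lt(series: pd.Series, threshold: float) -> pd.Series:
    """Strict less-than where NaN fails the filter."""
    return series.notna() & (series < threshold)


def apply_lfq_filters(records: pd.DataFrame, policy: FilterPolicy) -> pd.DataFrame:
    """Label-free record filter.

    Keeps non-contaminant rows with charge above the exclusive minimum and
    both library-level q-values strictly below their thresholds. Rows with a
    missing tested q-value are removed.
    """
    if policy.mode != "lfq":
        raise ValueError("apply_lfq_filters requires mode == 'lfq'")
    keep = (
        ~records["is_contaminant"]
        & (records["precursor_charge"] > policy.min_charge_exclusive)
        & _lt(records["lib_pg_qvalue"], policy.lib_pg_q_max)
        & _lt(records["lib_qvalue"], policy.lib_q_max)
    )
    return records.loc[keep].reset_index(drop=True)


def channel_pass(records: pd.DataFrame, policy: FilterPolicy, side: str | None = None) -> pd.Series:
    """Channel-level confidence filter for spike-in modes.

    True iff non-contaminant, charge above the minimum, Global.PG.Q.Value and
    Channel.Q.Value strictly below their thresholds. With ``side`` given
    ("L"/"H") the per-side columns of a paired table are tested instead
    (shared columns ``is_contaminant``/``precursor_charge`` apply to both
    sides of a pair).
    """
    if policy.mode not in ("sis_basic", "sis_requant"):
        raise ValueError("channel_pass requires a spike-in mode")
    if side is None:
        gq, cq = records["global_pg_qvalue"], records["channel_qvalue"]
    else:
        gq, cq = records[f"{side}_global_pg_qvalue"], records[f"{side}_channel_qvalue"]
    return (
        ~records["is_contaminant"]
        & (records["precursor_charge"] > policy.min_charge_exclusive)
        & _lt(gq, policy.global_pg_q_max)
        & _lt(cq, policy.channel_q_max)
    )


def select_sis_pairs(pairs: pd.DataFrame, policy: FilterPolicy) -> pd.DataFrame:
    """Retain channel pairs according to the spike-in mode.

    ``pairs`` is the wide table from :func:`diasis.quantify.pair_channels`.
    In every mode the heavy side must be present and pass
    :func:`channel_pass` — the spike-in is the confident reference. In
    ``sis_basic`` the light side must pass too. In ``sis_requant`` a light
    record that exists but fails its q-value filters is rescued and marked
    ``rescued=True``; a light record entirely absent from the report is never
    invented.

    The retained set under ``sis_requant`` is always a superset of the set
    under ``sis_basic``, and shared pairs carry identical values.
    """
    if policy.mode not in ("sis_basic", "sis_requant"):
        raise ValueError("select_sis_pairs requires a spike-in mode")
    h_ok = pairs["has_H"] & channel_pass(pairs, policy, side="H")
    l_ok = pairs["has_L"] & channel_pass(pairs, policy, side="L")
    if policy.mode == "sis_basic":
        keep = h_ok & l_ok
        rescued = pd.Series(False, index=pairs.index)
    else:
        keep = h_ok & pairs["has_L"]
        rescued = keep & ~l_ok
    out = pairs.loc[keep].copy()
    out["rescued"] = rescued.loc[keep].to_numpy()
    return out.reset_index(drop=True)


def translated_valid(records: pd.DataFrame, rule: str, side: str | None = None) -> pd.Series:
    """Intensity-validity rule on the two quantification columns.

    ``both``: Ms1-level and fragment-level intensity both present and > 0.
    ``any``: at least one of the two present and > 0.
    """
    if rule not in ("both", "any"):
        raise ValueError(f"unknown translated-validity rule {rule!r}")
    if side is None:
        ms1, prec = records["ms1_translated"], records["precursor_translated"]
    else:
        ms1, prec = records[f"{side}_ms1_translated"], records[f"{side}_precursor_translated"]
    ms1_ok = ms1.notna() & (ms1 > 0)
    prec_ok = prec.notna() & (prec > 0)
    return (ms1_ok & prec_ok) if rule == "both" else (ms1_ok | prec_ok)
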