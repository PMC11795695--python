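"""Reading and writing DIA-NN-style multiplexed reports and pipeline tables.

A multiplexed DIA-NN ``report.tsv`` holds one row per precursor x run x
channel, where the channel is the isotope state of the precursor: L (light,
the sample) or H (heavy, the spike-in reference). This module parses such
reports into a canonical long-format :class:`pandas.DataFrame`, flags
contaminant protein groups, reads/writes the experimental design, and
round-trips every tabular artifact the pipeline produces.

Canonical record columns
------------------------
run_id, protein_group, precursor_key, channel, precursor_charge,
ms1_translated, precursor_translated, global_pg_qvalue, channel_qvalue,
lib_pg_qvalue, lib_qvalue, pg_maxlfq, is_contaminant

``precursor_key`` is the label-stripped modified sequence joined with the
charge, so that the light and heavy partners of one precursor share a key.
Missing intensities stay missing (NaN) and are never conflated with 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DesignSpec",
    "ReportSchemaError",
    "DIANN_COLUMN_MAP",
    "RECORD_COLUMNS",
    "read_report",
    "flag_contaminants",
    "read_contaminant_list",
    "write_table",
    "read_table",
]


class ReportSchemaError(ValueError):
    """A report file does not conform to the expected dialect schema."""


#: DIA-NN dialect header -> canonical column name.
DIANN_COLUMN_MAP = {
    "Run": "run_id",
    "Protein.Group": "protein_group",
    "Precursor.Id": "precursor_id",
    "Modified.Sequence": "modified_sequence",
    "Precursor.Charge": "precursor_charge",
    "Ms1.Translated": "ms1_translated",
    "Precursor.Translated": "precursor_translated",
    "Global.PG.Q.Value": "global_pg_qvalue",
    "Channel.Q.Value": "channel_qvalue",
    "Lib.PG.Q.Value": "lib_pg_qvalue",
    "Lib.Q.Value": "lib_qvalue",
    "PG.MaxLFQ": "pg_maxlfq",
}

RECORD_COLUMNS = [
    "run_id",
    "protein_group",
    "precursor_key",
    "channel",
    "precursor_charge",
    "ms1_translated",
    "precursor_translated",
    "global_pg_qvalue",
    "channel_qvalue",
    "lib_pg_qvalue",
    "lib_qvalue",
    "pg_maxlfq",
    "is_contaminant",
]

_NUMERIC_COLUMNS = [
    "precursor_charge",
    "ms1_translated",
    "precursor_translated",
    "global_pg_qvalue",
    "channel_qvalue",
    "lib_pg_qvalue",
    "lib_qvalue",
    "pg_maxlfq",
]

_QVALUE_COLUMNS = [
    "global_pg_qvalue",
    "channel_qvalue",
    "lib_pg_qvalue",
    "lib_qvalue",
]

#: Removes isotope-label decorations such as ``(SILAC-K-H)`` from a modified
#: sequence so L/H partners key identically.
DEFAULT_LABEL_STRIP_REGEX = r"\(SILAC[^)]*\)"

#: Fallback: infer the channel from the label decoration when no dedicated
#: channel column is present.
DEFAULT_CHANNEL_REGEX = r"\(SILAC-[A-Z]+-([LH])\)"


# ---------------------------------------------------------------------------
# Experimental design


@dataclass
class DesignSpec:
    """Maps runs to samples/replicates and names the comparison structure.

    Parameters
    ----------
    samples:
        Sample identifiers (e.g. ``["S1", "S2", "S3"]``).
    run_to_sample:
        ``run_id -> (sample, replicate index)``; every run maps to exactly one
        pair, and replicates pair by index across samples.
    comparisons:
        ``(sample, reference sample)`` pairs; the reference is always the
        denominator of an across-sample ratio.
    anchor_species:
        Species whose across-sample ratio is theoretically 1:1 (the species
        held at constant amount in every sample).
    reference_sample:
        The sample that is never shifted by anchor normalization.
    species_rules:
        Ordered ``(regex, species)`` rules applied to each accession of a
        protein group, or an explicit ``accession -> species`` table.
    """

    samples: list[str]
    run_to_sample: dict[str, tuple[str, int]]
    comparisons: list[tuple[str, str]]
    anchor_species: str
    reference_sample: str
    species_rules: list[tuple[str, str]] = field(default_factory=list)
    species_table: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for run, (sample, rep) in self.run_to_sample.items():
            if sample not in self.samples:
                raise ValueError(f"run {run!r} maps to unknown sample {sample!r}")
            key = (sample, int(rep))
            if key in seen:
                raise ValueError(
                    f"runs {seen[key]!r} and {run!r} both map to {key}"
                )
            seen[key] = run
        for sample, ref in self.comparisons:
            if ref != self.reference_sample:
                raise ValueError(
                    f"comparison ({sample}, {ref}) does not use the reference "
                    f"sample {self.reference_sample!r} as denominator"
                )
        if self.reference_sample not in self.samples:
            raise ValueError(f"unknown reference sample {self.reference_sample!r}")

    def runs_of(self, sample: str) -> dict[int, str]:
        """Replicate index -> run id for one sample."""
        return {
            rep: run
            for run, (s, rep) in self.run_to_sample.items()
            if s == sample
        }

    def replicate_pairs(self, sample: str, reference: str | None = None) -> list[tuple[int, str, str]]:
        """(replicate, sample run, reference run) for replicates present in both."""
        reference = reference or self.reference_sample
        mine = self.runs_of(sample)
        theirs = self.runs_of(reference)
        return [(k, mine[k], theirs[k]) for k in sorted(mine.keys() & theirs.keys())]

    def comparison_name(self, sample: str, reference: str | None = None) -> str:
        return f"{sample}_vs_{reference or self.reference_sample}"

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "samples": list(self.samples),
            "reference_sample": self.reference_sample,
            "anchor_species": self.anchor_species,
            "comparisons": [list(c) for c in self.comparisons],
            "runs": {
                run: {"sample": s, "replicate": int(rep)}
                for run, (s, rep) in self.run_to_sample.items()
            },
            "species_rules": [
                {"pattern": pat, "species": sp} for pat, sp in self.species_rules
            ],
            "species_table": dict(self.species_table),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignSpec":
        return cls(
            samples=list(d["samples"]),
            run_to_sample={
                run: (v["sample"], int(v["replicate"]))
                for run, v in d["runs"].items()
            },
            comparisons=[tuple(c) for c in d["comparisons"]],
            anchor_species=d["anchor_species"],
            reference_sample=d["reference_sample"],
            species_rules=[
                (r["pattern"], r["species"]) for r in d.get("species_rules", [])
            ],
            species_table=dict(d.get("species_table", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Report reading


def _strip_label(seq: pd.Series, label_strip_regex: str) -> pd.Series:
    return seq.str.replace(label_strip_regex, "", regex=True)


def _coerce_numeric(df: pd.DataFrame, column: str) -> pd.Series:
    raw = df[column]
    if raw.dtype.kind in "fiu":
        return raw.astype(float)
    as_str = raw.astype("string")
    blank = as_str.isna() | (as_str.str.strip() == "")
    coerced = pd.to_numeric(as_str.where(~blank), errors="coerce")
    bad = coerced.isna() & ~blank
    if bad.any():
        # +2: one for the header line, one for 0- vs 1-based indexing
        line = int(df.index[bad][0]) + 2
        raise ReportSchemaError(
            f"unparseable numeric value {as_str[bad].iloc[0]!r} in column "
            f"{column!r} at line {line}"
        )
    return coerced.astype(float)


def read_report(
    path: str | Path,
    dialect: str = "diann",
    channel_column: str = "Channel",
    channel_regex: str = DEFAULT_CHANNEL_REGEX,
    label_strip_regex: str = DEFAULT_LABEL_STRIP_REGEX,
) -> pd.DataFrame:
    """Read a multiplexed report into canonical long format.

    The channel is taken from ``channel_column`` if present; otherwise it is
    inferred from the label decoration on ``Modified.Sequence`` via
    ``channel_regex`` (an undecorated sequence is light). Missing or empty
    numeric cells become NaN — never 0.

    Raises
    ------
    ReportSchemaError
        If a required column is absent, a numeric cell cannot be parsed
        (reported with its line number), a channel value is unrecognized, a
        q-value lies outside [0, 1], or ``(run, precursor_key, channel)`` is
        duplicated.
    """
    if dialect != "diann":
        raise ValueError(f"unknown report dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in DIANN_COLUMN_MAP if c not in raw.columns]
    if missing:
        raise ReportSchemaError(
            f"report {path} is missing required column(s): {', '.join(missing)}"
        )

    df = raw.rename(columns=DIANN_COLUMN_MAP)
    for col in _NUMERIC_COLUMNS:
        df[col] = _coerce_numeric(df, col)

    if channel_column in raw.columns:
        channel = raw[channel_column].str.strip()
    else:
        extracted = df["modified_sequence"].str.extract(channel_regex, expand=False)
        channel = extracted.fillna("L")
    bad_channel = ~channel.isin(["L", "H"])
    if bad_channel.any():
        raise ReportSchemaError(
            f"unrecognized channel value {channel[bad_channel].iloc[0]!r} "
            f"at line {int(channel.index[bad_channel][0]) + 2}"
        )
    df["channel"] = channel.to_numpy()

    for col in _QVALUE_COLUMNS:
        vals = df[col]
        out = vals.notna() & ((vals < 0) | (vals > 1))
        if out.any():
            raise ReportSchemaError(
                f"q-value column {col!r} outside [0, 1] at line "
                f"{int(df.index[out][0]) + 2}"
            )

    if (df["precursor_charge"].fillna(0) < 1).any():
        raise ReportSchemaError("precursor_charge must be >= 1")
    df["precursor_charge"] = df["precursor_charge"].astype(int)

    stripped = _strip_label(df["modified_sequence"], label_strip_regex)
    df["precursor_key"] = stripped + "/" + df["precursor_charge"].astype(str)

    dup = df.duplicated(["run_id", "precursor_key", "channel"], keep=False)
    if dup.any():
        first = df.loc[dup, ["run_id", "precursor_key", "channel"]].iloc[0]
        raise ReportSchemaError(
            "duplicate (run, precursor, channel) record: "
            f"{tuple(first)} (and possibly others)"
        )

    df["is_contaminant"] = False
    return df[RECORD_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Contaminants


def read_contaminant_list(path: str | Path) -> set[str]:
    """Plain-text accession list, one per line; blank lines and # comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def flag_contaminants(
    records: pd.DataFrame,
    contaminant_ids: Iterable[str] | None = None,
    prefix: str | None = None,
) -> pd.DataFrame:
    """Set ``is_contaminant`` where any accession of the group matches.

    A protein group is a semicolon-joined accession list; the group is flagged
    if *any* member is in ``contaminant_ids`` or carries ``prefix``. No rows
    are removed (removal happens during filtering). Idempotent and
    order-independent.
    """
    ids = set(contaminant_ids) if contaminant_ids else set()

    def _hit(group: str) -> bool:
        for acc in group.split(";"):
            if acc in ids:
                return True
            if prefix and acc.startswith(prefix):
                return True
        return False

    out = records.copy()
    groups = out["protein_group"].unique()
    flagged = {g: _hit(g) for g in groups}
    out["is_contaminant"] = out["protein_group"].map(flagged).astype(bool)
    return out


# ---------------------------------------------------------------------------
# Generic table I/O

_META_PREFIX = "#diasis\t"


def write_table(table, path: str | Path) -> None:
    """Write a pipeline table as TSV (UTF-8, '.' decimal separator).

    Accepts a plain DataFrame or an object exposing ``to_frame_with_meta()``
    (e.g. :class:`diasis.quantify.AbundanceMatrix`); metadata is stored on a
    leading comment line so that :func:`read_table` restores the full object.
    Round-trips without value loss.
    """
    path = Path(path)
    meta = None
    if hasattr(table, "to_frame_with_meta"):
        frame, meta = table.to_frame_with_meta()
    else:
        frame = table
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if meta is not None:
            fh.write(_META_PREFIX + "\t".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path):
    """Read a table written by :func:`write_table`.

    Returns a DataFrame, or the typed object when a metadata line announces
    one (currently ``kind=abundance_matrix``).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        meta: dict[str, str] = {}
        if first.startswith(_META_PREFIX):
            for kv in first[len(_META_PREFIX):].strip("\n").split("\t"):
                k, _, v = kv.partition("=")
                meta[k] = v
        else:
            fh.seek(0)
        frame = pd.read_csv(fh, sep="\t")
    if meta.get("kind") == "abundance_matrix":
        from .quantify import AbundanceMatrix

        return AbundanceMatrix.from_frame_with_meta(frame, meta)
    return frame
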