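"""Synthetic two-species spike-in benchmark generator.

Emulates the mixed-species dilution benchmark: an anchor species (human-like)
held at constant amount in every sample, a second species (E. coli-like)
diluted by known factors down to 1:50, and a heavy spike-in reference added
at a configurable excess over the maximum light amount. The generator writes
a DIA-NN-style multiplexed report (one row per precursor x run x channel)
plus a ground-truth table, so the whole pipeline can be validated without
any external data.

Generative model, per protein:

- baseline log10 intensity ~ Normal(mean, sd); per-precursor response offset
  ~ Normal(0, sd).
- light true intensity in run (sample, rep) = 10^(baseline+offset) x the
  sample's light amount for the species; heavy true intensity =
  10^(baseline+offset) x spike_excess x max light amount (identical in every
  run — the premise of a spike-in reference).
- measured Ms1-level and fragment-level intensities are correlated noisy
  replicates: each gets lognormal noise of sd ``measurement_noise_sd`` (log10
  scale) sharing a common component with correlation ``column_correlation``.
- a record is present with logistic probability in its true log10 intensity
  (heavier spike-in -> more detectable), reproducing intensity-dependent
  missingness; absent records produce no row.
- channel q-values: a fraction of IDs is "bad" and draws Channel.Q.Value ~
  Uniform(0,1); good IDs draw Beta(1, 99). Library/global q-values are small
  for all simulated proteins.
- contaminant entries (constant amount, ``Cont_`` accessions) are injected.

Randomness: per-protein substreams are spawned from the master seed, so
changing the replicate count or adding proteins does not reshuffle earlier
baselines, and a fixed seed yields a byte-identical report.

An optional interference term (additive background proportional to the mean
signal of a run x channel) models ratio compression; it is off by default,
in which case light abundances are exactly invariant to the spike excess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .report_io import DesignSpec

__all__ = ["SimulationConfig", "default_design", "simulate_report", "ground_truth"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic benchmark generator.

    ``species_amounts`` maps species -> sample -> relative light amount; the
    anchor species is constant at 1 and the diluted species runs down to the
    1:50 extreme. ``spike_excess`` is the heavy amount relative to the
    species' maximum light amount (printed sweep values: 2, 5, 20).
    ``precursors_per_protein`` is an inclusive (min, max) range.
    ``detection_midpoint`` is the log10 intensity of 50% detection
    probability (None disables the detection model: every record present).
    """

    n_proteins_per_species: int = 500
    species_amounts: dict = field(
        default_factory=lambda: {
            "human": {"S1": 1.0, "S2": 1.0, "S3": 1.0},
            "ecoli": {"S1": 1.0 / 50.0, "S2": 1.0 / 10.0, "S3": 1.0},
        }
    )
    anchor_species: str = "human"
    spike_excess: float = 2.0
    n_replicates: int = 4
    precursors_per_protein: tuple[int, int] = (1, 20)
    baseline_log10_mean: float = 5.5
    baseline_log10_sd: float = 0.8
    precursor_log10_sd: float = 0.5
    measurement_noise_sd: float = 0.1
    column_correlation: float = 0.7
    detection_midpoint: float | None = 3.0
    detection_slope: float = 2.0
    fraction_bad: float = 0.02
    good_channel_q_beta: tuple[float, float] = (1.0, 99.0)
    good_lib_q_max: float = 0.008
    contaminant_fraction: float = 0.02
    charge_one_fraction: float = 0.05
    column_dropout: float = 0.0
    interference_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_bad", "contaminant_fraction", "charge_one_fraction",
                     "column_dropout", "column_correlation"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.spike_excess <= 0:
            raise ValueError("spike_excess must be positive")
        lo, hi = self.precursors_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("precursors_per_protein must be an inclusive range >= 1")

    def n_contaminants(self) -> int:
        return int(round(self.contaminant_fraction * len(self.species_amounts) * self.n_proteins_per_species))


def default_design(config: SimulationConfig) -> DesignSpec:
    """Design matching the generator's sample layout: runs ``<sample>_r<k>``."""
    samples = sorted(next(iter(config.species_amounts.values())).keys())
    reference = samples[-1]
    runs = {
        f"{s}_r{k}": (s, k)
        for s in samples
        for k in range(1, config.n_replicates + 1)
    }
    rules = [("_HUMAN$", "human"), ("_ECOLI$", "ecoli"), ("^Cont_", "contaminant")]
    return DesignSpec(
        samples=samples,
        run_to_sample=runs,
        comparisons=[(s, reference) for s in samples if s != reference],
        anchor_species=config.anchor_species,
        reference_sample=reference,
        species_rules=rules,
    )


def _protein_roster(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for species in config.species_amounts:
        tag = "HSIM" if species == config.anchor_species else "ESIM"
        suffix = "_HUMAN" if species == config.anchor_species else "_ECOLI"
        for i in range(config.n_proteins_per_species):
            rows.append((f"{tag}{i:04d}{suffix}", species))
    for i in range(config.n_contaminants()):
        rows.append((f"Cont_KRT{i:03d}", "contaminant"))
    return pd.DataFrame(rows, columns=["protein_group", "species"])


def ground_truth(design: DesignSpec, config: SimulationConfig) -> pd.DataFrame:
    """Expected log2 fold change and positive/negative label per protein.

    The anchor species (and contaminants) have true log2FC 0 and a negative
    label in every comparison; a diluted protein's true log2FC is
    ``log2(amount_sample / amount_reference)``, labeled positive when the
    amounts differ. Deterministic — derives from the configuration only.
    """
    roster = _protein_roster(config)
    rows = []
    for sample, ref in design.comparisons:
        name = design.comparison_name(sample, ref)
        for _, p in roster.iterrows():
            amounts = config.species_amounts.get(p["species"])
            if amounts is None:  # contaminants: constant
                fc = 0.0
            else:
                fc = float(np.log2(amounts[sample] / amounts[ref]))
            rows.append(
                {
                    "protein_group": p["protein_group"],
                    "species": p["species"],
                    "comparison": name,
                    "true_log2fc": fc,
                    "is_positive": bool(fc != 0.0),
                }
            )
    return pd.DataFrame(rows)


def _simulate_protein(
    rng: np.random.Generator,
    pid: str,
    pidx: int,
    species: str,
    config: SimulationConfig,
    design: DesignSpec,
) -> pd.DataFrame:
    lo, hi = config.precursors_per_protein
    n_prec = int(rng.integers(lo, hi + 1))
    baseline = rng.normal(config.baseline_log10_mean, config.baseline_log10_sd)
    offsets = rng.normal(0.0, config.precursor_log10_sd, n_prec)
    charges = np.where(
        rng.random(n_prec) < config.charge_one_fraction,
        1,
        rng.integers(2, 4, n_prec),
    )
    amounts = config.species_amounts.get(species, {s: 1.0 for s in design.samples})
    heavy_amount = config.spike_excess * max(amounts.values())

    runs = sorted(design.run_to_sample)
    n_runs = len(runs)
    run_samples = [design.run_to_sample[r][0] for r in runs]
    light_factor = np.array([amounts[s] for s in run_samples])

    base = 10.0 ** (baseline + offsets)  # (n_prec,)
    # true intensity, shape (n_prec, n_runs, 2 channels [L, H])
    true = np.empty((n_prec, n_runs, 2))
    true[:, :, 0] = base[:, None] * light_factor[None, :]
    true[:, :, 1] = base[:, None] * heavy_amount

    shape = true.shape
    sd = config.measurement_noise_sd
    rho = config.column_correlation
    z_shared = rng.standard_normal(shape)
    z_ms1 = rng.standard_normal(shape)
    z_prec = rng.standard_normal(shape)
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
    noise_ms1 = sd * (a * z_shared + b * z_ms1)
    noise_prec = sd * (a * z_shared + b * z_prec)

    u_detect = rng.random(shape)
    u_bad = rng.random(shape)
    q_good = rng.beta(*config.good_channel_q_beta, shape)
    q_bad = rng.random(shape)
    channel_q = np.where(u_bad < config.fraction_bad, q_bad, q_good)
    u_drop_ms1 = rng.random(shape)
    u_drop_prec = rng.random(shape)

    lib_q = np.where(
        rng.random(n_prec) < config.fraction_bad,
        rng.random(n_prec),
        rng.uniform(0, config.good_lib_q_max, n_prec),
    )
    global_pg_q = rng.uniform(0, config.good_lib_q_max)
    lib_pg_q = rng.uniform(0, config.good_lib_q_max)
    lfq_noise = rng.normal(0.0, sd if sd > 0 else 0.0, n_runs)

    seqs = np.array([f"PEP{pidx:05d}X{j:02d}K" for j in range(n_prec)])

    prec_idx, run_idx, ch_idx = np.meshgrid(
        np.arange(n_prec), np.arange(n_runs), np.arange(2), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "protein_group": pid,
            "species": species,
            "prec": prec_idx.ravel(),
            "run_idx": run_idx.ravel(),
            "channel": np.where(ch_idx.ravel() == 0, "L", "H"),
            "true_intensity": true.ravel(),
            "noise_ms1": noise_ms1.ravel(),
            "noise_prec": noise_prec.ravel(),
            "u_detect": u_detect.ravel(),
            "channel_qvalue": channel_q.ravel(),
            "u_drop_ms1": u_drop_ms1.ravel(),
            "u_drop_prec": u_drop_prec.ravel(),
        }
    )
    df["run_id"] = np.array(runs)[df["run_idx"]]
    df["sequence"] = seqs[df["prec"]]
    df["precursor_charge"] = charges[df["prec"]]
    df["lib_qvalue"] = lib_q[df["prec"]]
    df["global_pg_qvalue"] = global_pg_q
    df["lib_pg_qvalue"] = lib_pg_q
    # per-run light sum for the MaxLFQ column (label-free comparator)
    light_sum = true[:, :, 0].sum(axis=0) * 10.0 ** lfq_noise
    df["pg_maxlfq"] = light_sum[df["run_idx"]]
    return df


def simulate_report(
    design: DesignSpec | None, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a DIA-NN-dialect report and its ground-truth table.

    Returns ``(report, truth)`` where ``report`` has the diann dialect
    columns (one row per detected precursor x run x channel) and ``truth``
    is the output of :func:`ground_truth`. Fully deterministic under
    ``config.seed``.
    """
    if design is None:
        design = default_design(config)
    roster = _protein_roster(config)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(roster))

    frames = []
    for pidx, (child, (_, p)) in enumerate(zip(children, roster.iterrows())):
        rng = np.random.default_rng(child)
        frames.append(
            _simulate_protein(rng, p["protein_group"], pidx, p["species"], config, design)
        )
    sim = pd.concat(frames, ignore_index=True)

    # optional interference: additive background per run x channel,
    # proportional to the mean true signal there (models ratio compression)
    if config.interference_fraction > 0:
        bg = (
            sim.groupby(["run_id", "channel"])["true_intensity"].transform("mean")
            * config.interference_fraction
        )
        sim["true_intensity"] = sim["true_intensity"] + bg

    measured_ms1 = sim["true_intensity"] * 10.0 ** sim["noise_ms1"]
    measured_prec = sim["true_intensity"] * 10.0 ** sim["noise_prec"]
    if config.column_dropout > 0:
        measured_ms1 = measured_ms1.where(sim["u_drop_ms1"] >= config.column_dropout)
        measured_prec = measured_prec.where(sim["u_drop_prec"] >= config.column_dropout)
    sim["ms1"] = measured_ms1
    sim["prec_int"] = measured_prec

    if config.detection_midpoint is None:
        present = np.ones(len(sim), dtype=bool)
    else:
        logint = np.log10(sim["true_intensity"].to_numpy())
        p_detect = 1.0 / (
            1.0 + np.exp(-config.detection_slope * (logint - config.detection_midpoint))
        )
        present = sim["u_detect"].to_numpy() < p_detect
    sim = sim.loc[present]

    heavy = sim["channel"] == "H"
    modseq = sim["sequence"].where(~heavy, sim["sequence"] + "(SILAC-K-H)")
    report = pd.DataFrame(
        {
            "Run": sim["run_id"],
            "Protein.Group": sim["protein_group"],
            "Precursor.Id": sim["sequence"] + sim["precursor_charge"].astype(str),
            "Modified.Sequence": modseq,
            "Precursor.Charge": sim["precursor_charge"],
            "Channel": sim["channel"],
            "Ms1.Translated": sim["ms1"],
            "Precursor.Translated": sim["prec_int"],
            "Global.PG.Q.Value": sim["global_pg_qvalue"],
            "Channel.Q.Value": sim["channel_qvalue"],
            "Lib.PG.Q.Value": sim["lib_pg_qvalue"],
            "Lib.Q.Value": sim["lib_qvalue"],
            "PG.MaxLFQ": sim["pg_maxlfq"],
        }
    ).sort_values(["Run", "Protein.Group", "Precursor.Id", "Channel"], kind="mergesort")
    report = report.reset_index(drop=True)
    truth = ground_truth(design, config)
    return report, truth


def write_simulation(
    design: DesignSpec | None, config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write ``report.tsv``, ``truth.tsv`` and a ``design.yaml`` echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if design is None:
        design = default_design(config)
    report, truth = simulate_report(design, config)
    paths = {
        "report": out / "report.tsv",
        "truth": out / "truth.tsv",
        "design": out / "design.yaml",
    }
    report.to_csv(paths["report"], sep="\t", index=False, lineterminator="\n")
    truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    design.to_yaml(paths["design"])
    return paths
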