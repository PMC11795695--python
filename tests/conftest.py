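import numpy as np
import pandas as pd
import pytest

from diasis.report_io import RECORD_COLUMNS
from diasis.simulate import SimulationConfig, default_design, simulate_report

_DEFAULTS = {
    "run_id": "r1",
    "protein_group": "P1_HUMAN",
    "precursor_key": "PEPK/2",
    "channel": "L",
    "precursor_charge": 2,
    "ms1_translated": 100.0,
    "precursor_translated": 100.0,
    "global_pg_qvalue": 0.001,
    "channel_qvalue": 0.001,
    "lib_pg_qvalue": 0.001,
    "lib_qvalue": 0.001,
    "pg_maxlfq": np.nan,
    "is_contaminant": False,
}


def rec(**kw) -> dict:
    """One canonical precursor record with overridable defaults."""
    out = dict(_DEFAULTS)
    out.update(kw)
    return out


def records(*rows) -> pd.DataFrame:
    """Canonical record table from `rec()` dicts."""
    return pd.DataFrame(list(rows), columns=RECORD_COLUMNS)


def lh_pair(key="PEPK/2", run="r1", protein="P1_HUMAN", L=None, H=None) -> list[dict]:
    """A light+heavy record pair sharing one precursor key."""
    L = L or {}
    H = H or {}
    return [
        rec(run_id=run, protein_group=protein, precursor_key=key, channel="L", **L),
        rec(run_id=run, protein_group=protein, precursor_key=key, channel="H", **H),
    ]


@pytest.fixture(scope="session")
def small_sim():
    """A modest noisy two-species simulation shared across tests."""
    config = SimulationConfig(
        n_proteins_per_species=60,
        precursors_per_protein=(3, 6),
        n_replicates=3,
        measurement_noise_sd=0.1,
        seed=7,
    )
    design = default_design(config)
    report, truth = simulate_report(design, config)
    return config, design, report, truth


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free, fully detected simulation: exact recovery expected."""
    config = SimulationConfig(
        n_proteins_per_species=40,
        precursors_per_protein=(2, 4),
        n_replicates=3,
        measurement_noise_sd=0.0,
        detection_midpoint=None,
        fraction_bad=0.0,
        contaminant_fraction=0.0,
        seed=11,
    )
    design = default_design(config)
    report, truth = simulate_report(design, config)
    return config, design, report, truth


def report_to_records(report: pd.DataFrame, tmp_path, prefix="Cont_") -> pd.DataFrame:
    """Round-trip a simulated report through the reader, flagging contaminants."""
    from diasis.report_io import flag_contaminants, read_report

    path = tmp_path / "report.tsv"
    report.to_csv(path, sep="\t", index=False)
    return flag_contaminants(read_report(path), prefix=prefix)
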