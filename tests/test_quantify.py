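"""Ratio computation, median rollup, and abundance reconstruction."""

import math

import numpy as np
import pandas as pd
import pytest

from diasis.filtering import FilterPolicy, select_sis_pairs
from diasis.quantify import (
    global_heavy_intensity,
    lfq_abundances,
    light_abundances,
    pair_channels,
    precursor_log_ratios,
    protein_log_ratio,
    sis_quantify,
)

from conftest import lh_pair, rec, records, report_to_records

POLICY = FilterPolicy(mode="sis_basic")


class TestPairChannels:
    def test_lh_pair_forms_one_pair(self):
        pairs = pair_channels(records(*lh_pair()))
        assert len(pairs) == 1
        assert pairs["has_L"].iloc[0] and pairs["has_H"].iloc[0]

    def test_orphan_light_has_no_heavy_side(self):
        pairs = pair_channels(records(rec(channel="L")))
        assert len(pairs) == 1 and not pairs["has_H"].iloc[0]
        assert select_sis_pairs(pairs, POLICY).empty

    def test_duplicate_channel_record_errors(self):
        df = records(rec(channel="H"), rec(channel="H"))
        with pytest.raises(ValueError, match="duplicate"):
            pair_channels(df)


class TestPrecursorRatios:
    def _ratios(self, L, H, rule="both"):
        policy = FilterPolicy(mode="sis_basic", translated_validity=rule)
        pairs = pair_channels(records(*lh_pair(L=L, H=H)))
        pairs["rescued"] = False
        return precursor_log_ratios(pairs, policy)

    def test_two_columns_two_ratios(self):
        out = self._ratios(
            {"ms1_translated": 300.0, "precursor_translated": 200.0},
            {"ms1_translated": 100.0, "precursor_translated": 100.0},
        )
        got = dict(zip(out["source_column"], out["log10_lh"]))
        assert got["ms1"] == pytest.approx(math.log10(3), abs=1e-12)
        assert got["precursor"] == pytest.approx(math.log10(2), abs=1e-12)

    def test_zero_suppresses_column_under_any_rule(self):
        out = self._ratios(
            {"ms1_translated": 100.0, "precursor_translated": 0.0},
            {"ms1_translated": 100.0, "precursor_translated": 50.0},
            rule="any",
        )
        assert list(out["source_column"]) == ["ms1"]
        assert out["log10_lh"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_column_invalidates_side_under_both_rule(self):
        out = self._ratios(
            {"ms1_translated": 100.0, "precursor_translated": 0.0},
            {"ms1_translated": 100.0, "precursor_translated": 50.0},
            rule="both",
        )
        assert out.empty

    def test_identical_channels_give_zero_ratios(self):
        out = self._ratios(
            {"ms1_translated": 80.0, "precursor_translated": 60.0},
            {"ms1_translated": 80.0, "precursor_translated": 60.0},
        )
        assert np.allclose(out["log10_lh"], 0.0, atol=1e-12) and len(out) == 2


class TestProteinRollup:
    @pytest.mark.parametrize(
        "values,expected",
        [([0.2, 0.4, 0.9], 0.4), ([0.1, 0.3], 0.2), ([0.7], 0.7)],
    )
    def test_median_conventions(self, values, expected):
        ratios = pd.DataFrame(
            {
                "protein_group": "P",
                "run_id": "r1",
                "precursor_key": [f"k{i}/2" for i in range(len(values))],
                "source_column": "ms1",
                "log10_lh": values,
                "rescued": False,
            }
        )
        out = protein_log_ratio(ratios)
        assert out["log10_lh_protein"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert out["n_ratios"].iloc[0] == len(values)

    def test_rollup_matches_sort_based_oracle(self):
        """Pooled-median rollup equals a brute-force sorted median on 1000 draws."""
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = int(rng.integers(1, 9))
            vals = rng.normal(0, 1, n)
            ratios = pd.DataFrame(
                {
                    "protein_group": "P",
                    "run_id": "r",
                    "precursor_key": [f"k{i}" for i in range(n)],
                    "source_column": "ms1",
                    "log10_lh": vals,
                    "rescued": False,
                }
            )
            got = protein_log_ratio(ratios)["log10_lh_protein"].iloc[0]
            s = np.sort(vals)
            oracle = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
            assert got == pytest.approx(oracle, abs=1e-12)

    def test_rescued_fraction(self):
        ratios = pd.DataFrame(
            {
                "protein_group": "P",
                "run_id": "r1",
                "precursor_key": ["a", "b", "c", "d"],
                "source_column": "ms1",
                "log10_lh": [0.1, 0.2, 0.3, 0.4],
                "rescued": [True, False, False, True],
            }
        )
        assert protein_log_ratio(ratios)["rescued_fraction"].iloc[0] == 0.5


class TestGlobalHeavy:
    def _records(self, sums_by_run):
        rows = []
        for run, total in sums_by_run.items():
            rows.append(
                rec(
                    run_id=run,
                    channel="H",
                    ms1_translated=total / 2,
                    precursor_translated=total / 2,
                )
            )
        return records(*rows)

    def test_median_of_log10_sums(self):
        gh = global_heavy_intensity(self._records({"r1": 100, "r2": 1000, "r3": 10000}), POLICY)
        assert gh["log10_heavy_global"].iloc[0] == pytest.approx(3.0, abs=1e-12)
        assert gh["n_samples_used"].iloc[0] == 3

    def test_single_run(self):
        gh = global_heavy_intensity(self._records({"r1": 500}), POLICY)
        assert gh["log10_heavy_global"].iloc[0] == pytest.approx(math.log10(500), abs=1e-12)

    def test_zero_sum_run_excluded(self):
        gh = global_heavy_intensity(self._records({"r1": 0, "r2": 100}), POLICY)
        assert gh["log10_heavy_global"].iloc[0] == pytest.approx(2.0, abs=1e-12)
        assert gh["n_samples_used"].iloc[0] == 1

    def test_missing_column_counts_as_zero_in_sum(self):
        df = records(
            rec(channel="H", ms1_translated=100.0, precursor_translated=np.nan)
        )
        gh = global_heavy_intensity(df, POLICY)
        assert gh["log10_heavy_global"].iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_only_confident_heavy_rows_used(self):
        df = records(
            rec(channel="H", channel_qvalue=0.5, ms1_translated=1e6, precursor_translated=0.0),
            rec(channel="H", run_id="r2", ms1_translated=100.0, precursor_translated=0.0),
        )
        gh = global_heavy_intensity(df, POLICY)
        assert gh["log10_heavy_global"].iloc[0] == pytest.approx(2.0, abs=1e-12)


class TestAbundances:
    def test_log_space_addition(self):
        pq = pd.DataFrame(
            {
                "protein_group": ["P", "P"],
                "run_id": ["r1", "r2"],
                "log10_lh_protein": [0.3010, 0.0],
                "n_ratios": 1,
                "rescued_fraction": 0.0,
            }
        )
        gh = pd.DataFrame({"protein_group": ["P"], "log10_heavy_global": [5.0], "n_samples_used": [2]})
        m = light_abundances(pq, gh)
        assert m.data.loc["P", "r1"] == pytest.approx(5.3010, abs=1e-12)
        assert m.data.loc["P", "r2"] == pytest.approx(5.0, abs=1e-12)
        assert m.method == "sis" and not m.normalized

    def test_protein_missing_from_heavy_index_errors(self):
        pq = pd.DataFrame(
            {
                "protein_group": ["P"],
                "run_id": ["r1"],
                "log10_lh_protein": [0.0],
                "n_ratios": 1,
                "rescued_fraction": 0.0,
            }
        )
        gh = pd.DataFrame(columns=["protein_group", "log10_heavy_global", "n_samples_used"])
        with pytest.raises(ValueError, match="P"):
            light_abundances(pq, gh)

    def test_lfq_log10_and_conflict(self):
        df = records(
            rec(pg_maxlfq=10000.0),
            rec(precursor_key="other/2", pg_maxlfq=10000.0),
        )
        m = lfq_abundances(df)
        assert m.data.loc["P1_HUMAN", "r1"] == pytest.approx(4.0, abs=1e-12)
        assert m.method == "lfq"
        bad = records(rec(pg_maxlfq=1.0), rec(precursor_key="o/2", pg_maxlfq=2.0))
        with pytest.raises(ValueError, match="conflicting"):
            lfq_abundances(bad)

    def test_lfq_nonpositive_dropped_with_count(self):
        df = records(rec(pg_maxlfq=0.0))
        m = lfq_abundances(df)
        assert m.data.empty
        assert m.data.attrs["n_dropped_nonpositive"] == 1


@pytest.fixture(scope="module")
def base(small_sim, tmp_path_factory):
    _, design, report, _ = small_sim
    tmp = tmp_path_factory.mktemp("inv")
    records_df = report_to_records(report, tmp)
    return design, records_df


class TestAlgebraicInvariances:
    """Exact scaling laws of the ratio/abundance algebra on simulated data."""

    @staticmethod
    def _quant(records_df):
        policy = FilterPolicy(mode="sis_basic")
        return sis_quantify(records_df, policy)

    @staticmethod
    def _scale(records_df, factor, run=None, channel=None):
        out = records_df.copy()
        mask = pd.Series(True, index=out.index)
        if run is not None:
            mask &= out["run_id"] == run
        if channel is not None:
            mask &= out["channel"] == channel
        for col in ("ms1_translated", "precursor_translated"):
            out.loc[mask, col] = out.loc[mask, col] * factor
        return out

    def test_channel_balance_invariance(self, base):
        """Scaling both channels of one run leaves its protein ratios unchanged."""
        _, records_df = base
        run = records_df["run_id"].iloc[0]
        pq0, _ = self._quant(records_df)
        pq1, _ = self._quant(self._scale(records_df, 7.3, run=run))
        merged = pq0.merge(pq1, on=["protein_group", "run_id"], suffixes=("_0", "_1"))
        sub = merged[merged["run_id"] == run]
        assert len(sub) > 10
        assert np.allclose(sub["log10_lh_protein_0"], sub["log10_lh_protein_1"], atol=1e-12)

    def test_light_scaling_equivariance(self, base):
        """Scaling only the light channel of one run shifts its ratios by log10 c."""
        _, records_df = base
        run = records_df["run_id"].iloc[0]
        c = 4.7
        pq0, _ = self._quant(records_df)
        pq1, _ = self._quant(self._scale(records_df, c, run=run, channel="L"))
        merged = pq0.merge(pq1, on=["protein_group", "run_id"], suffixes=("_0", "_1"))
        sub = merged[merged["run_id"] == run]
        assert np.allclose(
            sub["log10_lh_protein_1"] - sub["log10_lh_protein_0"], math.log10(c), atol=1e-12
        )
        other = merged[merged["run_id"] != run]
        assert np.allclose(other["log10_lh_protein_0"], other["log10_lh_protein_1"], atol=1e-12)

    def test_heavy_excess_invariance_of_abundances(self, base):
        """Scaling all heavy intensities globally cancels out of light abundances."""
        _, records_df = base
        _, m0 = self._quant(records_df)
        _, m1 = self._quant(self._scale(records_df, 10.0, channel="H"))
        common = m0.data.index.intersection(m1.data.index)
        assert len(common) > 10
        a0 = m0.data.loc[common].to_numpy()
        a1 = m1.data.loc[common].to_numpy()
        assert np.allclose(a0, a1, atol=1e-12, equal_nan=True)

    def test_abundance_differences_equal_ratio_differences(self, base):
        """The global heavy term cancels from across-sample abundance differences."""
        _, records_df = base
        pq, m = self._quant(records_df)
        wide = pq.pivot(index="protein_group", columns="run_id", values="log10_lh_protein")
        runs = list(m.data.columns[:2])
        d_ab = m.data[runs[0]] - m.data[runs[1]]
        d_lh = wide[runs[0]] - wide[runs[1]]
        joined = pd.concat([d_ab, d_lh], axis=1, keys=["ab", "lh"]).dropna()
        assert np.allclose(joined["ab"], joined["lh"], atol=1e-12)
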