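"""Repertoire summary indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ighrep.metrics import (
    MetricsError,
    cdr3_length_stats,
    gene_usage,
    germline_index,
    isotype_usage,
    kyte_doolittle_index,
    load_hydropathy_table,
    profile_sample,
    profiles_to_frame,
    sample_gi,
    shannon_index,
    shm_rate,
    simpson_index,
    usage_matrix,
)


def _table(rows):
    base = {
        "sequence_id": "x", "v_call": "IGHV1-1", "d_call": "IGHD1-1",
        "j_call": "IGHJ1", "c_call": "IGHM", "junction": "TGTGCTTGG",
        "junction_aa": "CAW", "junction_status": "ok", "productive": True,
        "duplicate_count": 1, "v_mutations": 0, "v_region_length": 200,
        "germline_junction_nt": 9, "sequence_aa": "MCAW",
    }
    return pd.DataFrame([{**base, **r} for r in rows])


class TestDiversity:
    @pytest.mark.parametrize("s", [2, 4, 8, 16, 64])
    def test_uniform_closed_forms(self, s):
        counts = [5] * s
        assert shannon_index(counts) == pytest.approx(np.log2(s), abs=1e-12)
        assert simpson_index(counts) == pytest.approx(s, abs=1e-12)

    def test_single_species(self):
        assert shannon_index([17]) == 0.0
        assert simpson_index([17]) == 1.0

    def test_direct_small_example(self):
        assert shannon_index([1, 1, 2]) == pytest.approx(1.5)
        assert simpson_index([1, 1, 2]) == pytest.approx(1 / 0.375)

    def test_nonpositive_counts_rejected(self):
        for bad in ([], [0, 1], [-1, 2]):
            with pytest.raises(MetricsError):
                shannon_index(bad)
            with pytest.raises(MetricsError):
                simpson_index(bad)

    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=40))
    def test_bounds_with_equality_iff_uniform(self, counts):
        s = len(counts)
        sh, si = shannon_index(counts), simpson_index(counts)
        assert sh <= np.log2(s) + 1e-9
        assert 1.0 - 1e-9 <= si <= s + 1e-9
        if len(set(counts)) == 1:
            assert sh == pytest.approx(np.log2(s))
            assert si == pytest.approx(s)
        elif len(set(counts)) > 1:
            assert sh < np.log2(s)
            assert si < s


class TestHydrophobicity:
    @pytest.mark.parametrize("aa,value", [("III", 1.0), ("RRR", -1.0), ("IR", 0.0)])
    def test_normalized_kyte_doolittle(self, aa, value):
        assert kyte_doolittle_index(aa) == pytest.approx(value)

    def test_non_standard_residue_names_position(self):
        with pytest.raises(MetricsError, match="position 2"):
            kyte_doolittle_index("CAXW")

    def test_alternative_residue_table_file(self, tmp_path):
        path = tmp_path / "scale.tsv"
        path.write_text("# toy scale\nA\t4.5\nC\t-4.5\n")
        table = load_hydropathy_table(path)
        assert kyte_doolittle_index("AC", table) == pytest.approx(0.0)

    def test_values_stay_in_unit_interval(self):
        table = load_hydropathy_table()
        for aa in table:
            assert -1.0 <= kyte_doolittle_index(aa * 3) <= 1.0


class TestUsage:
    def test_degenerate_single_gene(self):
        t = _table([{}, {}])
        assert gene_usage(t, "V") == {"IGHV1-1": 1.0}

    def test_family_rollup(self):
        t = _table([{"v_call": "IGHV3-23"}, {"v_call": "IGHV3-7"}])
        assert gene_usage(t, "V", level="family") == {"IGHV3": 1.0}

    def test_clonotype_vs_read_weighting(self):
        t = _table([
            {"v_call": "IGHV1-1", "duplicate_count": 9},
            {"v_call": "IGHV2-2", "duplicate_count": 1},
        ])
        assert gene_usage(t, "V", weighting="clonotype") == {
            "IGHV1-1": 0.5, "IGHV2-2": 0.5,
        }
        assert gene_usage(t, "V", weighting="read") == pytest.approx(
            {"IGHV1-1": 0.9, "IGHV2-2": 0.1}
        )

    def test_empty_table_is_an_error(self):
        with pytest.raises(MetricsError, match="no annotated records"):
            gene_usage(_table([]).iloc[0:0], "V")

    def test_isotype_usage_collapses_subclasses(self):
        t = _table([{"c_call": "IGHG1"}, {"c_call": "IGHG4"}, {"c_call": "IGHM"},
                    {"c_call": "IGHM"}])
        assert isotype_usage(t) == pytest.approx({"IGHG": 0.5, "IGHM": 0.5})


class TestShmAndGi:
    def test_mutation_free_sample_rate_zero(self):
        assert shm_rate(_table([{}, {}])) == 0.0

    def test_pooled_ratio(self):
        t = _table([
            {"v_mutations": 2, "v_region_length": 200},
            {"v_mutations": 4, "v_region_length": 200},
        ])
        assert shm_rate(t) == pytest.approx(1.5)

    def test_zero_length_is_an_error(self):
        with pytest.raises(MetricsError):
            shm_rate(_table([{"v_region_length": 0}]))

    def test_germline_index_values(self):
        assert germline_index(9, 9) == 1.0
        assert germline_index(12, 15) == pytest.approx(0.8)
        with pytest.raises(MetricsError):
            germline_index(16, 15)
        with pytest.raises(MetricsError):
            germline_index(3, 0)

    def test_sample_gi_weighted_mean(self):
        t = _table([
            {"germline_junction_nt": 9, "junction": "TGTGCTTGG"},
            {"germline_junction_nt": 3, "junction": "TGTGCTTGG", "duplicate_count": 3},
        ])
        assert sample_gi(t, weighting="clonotype") == pytest.approx((1.0 + 1 / 3) / 2)
        assert sample_gi(t, weighting="read") == pytest.approx((1.0 + 3 / 3) / 4)


class TestCdr3Lengths:
    def test_uniform_length(self):
        t = _table([{"junction_aa": "CARW"}, {"junction_aa": "CGGW"}])
        dist, mean = cdr3_length_stats(t)
        assert dist == {4: 1.0} and mean == 4.0

    def test_mean_of_two_lengths(self):
        t = _table([
            {"junction_aa": "C" * 10}, {"junction_aa": "C" * 20},
        ])
        _dist, mean = cdr3_length_stats(t)
        assert mean == 15.0

    def test_distribution_normalized(self, sim_bundle):
        productive = sim_bundle["collapsed"]
        dist, _mean = cdr3_length_stats(productive)
        assert sum(dist.values()) == pytest.approx(1.0)


class TestProfiles:
    def test_profile_on_simulated_sample(self, sim_bundle):
        prof = profile_sample(sim_bundle["collapsed"], "fix")
        assert prof.clonotype_count == len(sim_bundle["collapsed"])
        assert prof.read_count == sim_bundle["collapsed"]["duplicate_count"].sum()
        assert 0.0 <= prof.gi <= 1.0
        assert -1.0 <= prof.hydrophobicity <= 1.0
        assert prof.shannon >= 0 and prof.simpson >= 1
        for seg_class in ("V", "J", "C"):
            assert sum(prof.usage[seg_class].values()) == pytest.approx(1.0)
        assert sum(prof.family_usage.values()) == pytest.approx(1.0)

    def test_merging_two_identical_samples_changes_nothing(self, sim_bundle):
        from ighrep.annotate import collapse_duplicates

        table = sim_bundle["collapsed"]
        merged = collapse_duplicates(pd.concat([table, table], ignore_index=True))
        assert len(merged) == len(table)
        a = profile_sample(table, "s").features()
        b = profile_sample(merged, "s").features()
        for key, value in a.items():
            assert b[key] == pytest.approx(value, nan_ok=True), key

    def test_feature_frame_zero_fills_absent_segments(self):
        t1 = _table([{"v_call": "IGHV1-1"}])
        t2 = _table([{"v_call": "IGHV2-2"}])
        frame = profiles_to_frame([profile_sample(t1, "s1"), profile_sample(t2, "s2")])
        assert frame.loc["s1", "usage:IGHV2-2"] == 0.0
        assert frame.loc["s2", "usage:IGHV1-1"] == 0.0

    def test_usage_matrix_shape(self, sim_bundle):
        prof = profile_sample(sim_bundle["collapsed"], "fix")
        mat = usage_matrix([prof], "V")
        assert mat.shape[0] == 1
        assert set(mat.columns) == set(prof.usage["V"])
        assert mat.loc["fix"].sum() == pytest.approx(1.0)
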