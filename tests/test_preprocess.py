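import math

import numpy as np
import pandas as pd
import pytest

from pulsedcaf.errors import NumericalError
from pulsedcaf.io_formats import IntensityTable, ProteinGroupRecord
from pulsedcaf.preprocess import (
    MEC,
    POV,
    classify_missing,
    filter_missing,
    filter_protein_groups,
    impute_detquantile,
    impute_slsa,
    max_pov_allowed,
    median_normalize,
    preprocess_table,
)
from tests.conftest import make_table


def rec(pid, up=5, rev=False, cont=False, site=False):
    return ProteinGroupRecord(
        protein_ids=(pid,), unique_peptides=up,
        reverse_flag=rev, contaminant_flag=cont, site_only_flag=site,
    )


class TestFilterProteinGroups:
    def test_min_unique_peptides_rule(self):
        kept, rejected = filter_protein_groups([rec("A", up=1)])
        assert kept == []
        assert rejected == [("A", "min unique peptides")]

    def test_boundary_two_peptides_retained(self):
        kept, rejected = filter_protein_groups([rec("A", up=2)])
        assert len(kept) == 1 and rejected == []

    def test_one_of_each_flag_fixture(self):
        records = [
            rec("A", rev=True),
            rec("B", cont=True),
            rec("C", site=True),
            rec("D", up=1),
            rec("E"),
        ]
        kept, rejected = filter_protein_groups(records)
        assert [r.protein_id for r in kept] == ["E"]
        assert dict(rejected) == {
            "A": "reverse",
            "B": "contaminant",
            "C": "only identified by site",
            "D": "min unique peptides",
        }

    def test_first_matching_rule_wins(self):
        kept, rejected = filter_protein_groups([rec("A", rev=True, cont=True, up=1)])
        assert rejected == [("A", "contaminant")]

    def test_order_insensitive(self):
        records = [rec("A"), rec("B", rev=True), rec("C")]
        kept_fwd, _ = filter_protein_groups(records)
        kept_rev, _ = filter_protein_groups(records[::-1])
        assert {r.protein_id for r in kept_fwd} == {r.protein_id for r in kept_rev}


class TestClassifyMissing:
    def test_pov_with_one_missing(self):
        t = make_table([[1, 2, 3, np.nan]], ["a", "b", "c", "d"])
        labels = classify_missing(t, {"cond": ["a", "b", "c", "d"]})
        lab = labels.label("P001", "cond")
        assert lab.status == POV and lab.n_missing == 1

    def test_mec_all_missing(self):
        t = make_table([[np.nan] * 4], ["a", "b", "c", "d"])
        lab = classify_missing(t, {"cond": ["a", "b", "c", "d"]}).label("P001", "cond")
        assert lab.status == MEC

    def test_complete_n2(self):
        t = make_table([[1.0, 2.0]], ["a", "b"])
        lab = classify_missing(t, {"cond": ["a", "b"]}).label("P001", "cond")
        assert lab.status == "complete"


class TestFilterMissing:
    def test_two_missing_of_four_removed(self):
        t = make_table(
            [[1, 2, np.nan, np.nan, 5, 6, 7, 8]],
            [f"s{i}" for i in range(8)],
        )
        groups = {"c1": ["s0", "s1", "s2", "s3"], "c2": ["s4", "s5", "s6", "s7"]}
        out = filter_missing(t, classify_missing(t, groups))
        assert out.proteins == []

    def test_n2_pov_removed(self):
        t = make_table([[1, np.nan, 3, 4]], ["a", "b", "c", "d"])
        groups = {"c1": ["a", "b"], "c2": ["c", "d"]}
        out = filter_missing(t, classify_missing(t, groups))
        assert out.proteins == []

    def test_n2_complete_plus_mec_retained(self):
        t = make_table([[1, 2, np.nan, np.nan]], ["a", "b", "c", "d"])
        groups = {"c1": ["a", "b"], "c2": ["c", "d"]}
        out = filter_missing(t, classify_missing(t, groups))
        assert out.proteins == ["P001"]

    @pytest.mark.parametrize("n,allowed", [(2, 0), (4, 1), (3, 0), (8, 2)])
    def test_generic_allowance(self, n, allowed):
        assert max_pov_allowed(n) == allowed


class TestMedianNormalize:
    def test_fixed_point(self):
        t = make_table([[1, 1], [2, 2], [3, 3]], ["a", "b"])
        out = median_normalize(t)
        np.testing.assert_allclose(out.values.to_numpy(), t.values.to_numpy(), atol=1e-12)

    def test_two_sample_shifts(self):
        # medians 10 and 12 -> grand median 11 -> shifts +1 / -1
        t = make_table([[9, 11], [10, 12], [11, 13]], ["a", "b"])
        out = median_normalize(t)
        np.testing.assert_allclose(out.values["a"], [10, 11, 12])
        np.testing.assert_allclose(out.values["b"], [10, 11, 12])

    def test_shift_invariance_up_to_anchor(self):
        # the grand-median anchor moves with the shift, so normalizing a
        # shifted table equals normalizing the original up to one global
        # constant; every between-sample contrast is identical
        t = make_table([[9, 11], [10, 12], [11, 13]], ["a", "b"])
        shifted = t.copy()
        shifted.values["a"] = shifted.values["a"] + 5.0
        n1 = median_normalize(t).values.to_numpy()
        n2 = median_normalize(shifted).values.to_numpy()
        diff = n2 - n1
        np.testing.assert_allclose(diff, diff[0, 0], atol=1e-12)

    def test_all_missing_sample_errors(self):
        t = make_table([[1, np.nan], [2, np.nan]], ["a", "b"])
        with pytest.raises(NumericalError, match="b"):
            median_normalize(t)


class TestImputeDetQuantile:
    def test_one_percent_of_1_to_100(self):
        values = np.column_stack(
            [np.arange(1.0, 102.0), np.arange(1.0, 102.0)]
        )
        values[100] = [np.nan, np.nan]  # MEC protein in a 2-sample condition
        t = make_table(values, ["a", "b"])
        labels = classify_missing(t, {"cond": ["a", "b"]})
        out = impute_detquantile(t, labels, quantile=0.01)
        # observed values are 1..100 -> linear-interpolated 1% quantile = 1.99
        assert out.values.at["P101", "a"] == pytest.approx(1.99)

    def test_quantile_to_zero_approaches_minimum(self):
        values = np.column_stack([np.arange(1.0, 102.0), np.arange(1.0, 102.0)])
        values[100] = [np.nan, np.nan]
        t = make_table(values, ["a", "b"])
        labels = classify_missing(t, {"cond": ["a", "b"]})
        out = impute_detquantile(t, labels, quantile=1e-9)
        assert out.values.at["P101", "a"] == pytest.approx(1.0, abs=1e-6)

    def test_no_mec_is_noop(self):
        t = make_table([[1, 2], [3, 4]], ["a", "b"])
        labels = classify_missing(t, {"cond": ["a", "b"]})
        out = impute_detquantile(t, labels)
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_scope_all_touches_povs(self):
        values = np.column_stack([np.arange(1.0, 11.0)] * 4)
        values[0, 0] = np.nan  # POV
        t = make_table(values, ["a", "b", "c", "d"])
        labels = classify_missing(t, {"cond": ["a", "b", "c", "d"]})
        mec_only = impute_detquantile(t, labels, scope="mec")
        assert math.isnan(mec_only.values.at["P001", "a"])
        all_mode = impute_detquantile(t, labels, scope="all")
        assert not math.isnan(all_mode.values.at["P001", "a"])


class TestImputeSlsa:
    def test_zero_offsets_give_protein_mean(self):
        # constant anchor rows -> all sample offsets are exactly zero
        values = np.array(
            [[5.0, 7.0, 6.0, np.nan], [1.0, 1.0, 1.0, 1.0],
             [3.0, 3.0, 3.0, 3.0], [8.0, 8.0, 8.0, 8.0]]
        )
        t = make_table(values, ["a", "b", "c", "d"])
        labels = classify_missing(t, {"cond": ["a", "b", "c", "d"]})
        out = impute_slsa(t, labels)
        assert out.values.at["P001", "d"] == pytest.approx(6.0)

    def test_rank1_recovery(self, rng):
        a = rng.normal(10, 2, size=12)
        b = rng.normal(0, 1, size=4)
        full = a[:, None] + b[None, :]
        values = full.copy()
        values[0, 2] = np.nan
        t = make_table(values, ["a", "b", "c", "d"])
        labels = classify_missing(t, {"cond": ["a", "b", "c", "d"]})
        out = impute_slsa(t, labels)
        assert out.values.iat[0, 2] == pytest.approx(full[0, 2], abs=1e-9)

    def test_idempotent_second_pass(self, rng):
        values = rng.normal(20, 1, size=(6, 4))
        values[1, 0] = np.nan
        t = make_table(values, ["a", "b", "c", "d"])
        labels = classify_missing(t, {"cond": ["a", "b", "c", "d"]})
        once = impute_slsa(t, labels)
        labels2 = classify_missing(once, {"cond": ["a", "b", "c", "d"]})
        twice = impute_slsa(once, labels2)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_observed_never_modified(self, rng):
        values = rng.normal(20, 1, size=(6, 4))
        values[1, 0] = np.nan
        t = make_table(values, ["a", "b", "c", "d"])
        labels = classify_missing(t, {"cond": ["a", "b", "c", "d"]})
        out = impute_slsa(t, labels)
        mask = ~np.isnan(values)
        np.testing.assert_array_equal(out.values.to_numpy()[mask], values[mask])


class TestFullChain:
    def _records(self, rng, n=30):
        records = []
        for i in range(n):
            r = ProteinGroupRecord(protein_ids=(f"P{i:03d}",), unique_peptides=3)
            for cond in ("A", "B"):
                for repl in range(1, 5):
                    v = float(2.0 ** rng.normal(20, 2))
                    if rng.random() < 0.08:
                        v = float("nan")
                    r.intensity_light[f"{cond}_r{repl}"] = v
            records.append(r)
        return records

    def _design(self):
        rows = []
        for cond, role in (("A", "test"), ("B", "reference")):
            for repl in range(1, 5):
                rows.append(
                    {"sample_id": f"{cond}_r{repl}", "condition": cond,
                     "replicate": repl, "timepoint_h": 16.0,
                     "channel": "light", "role": role}
                )
        from pulsedcaf.io_formats import ExperimentDesign

        return ExperimentDesign(pd.DataFrame(rows))

    def test_no_missing_after_chain(self, rng):
        table, _, _ = preprocess_table(self._records(rng), self._design())
        assert not table.values.isna().any().any()

    def test_relabeling_commutes(self, rng):
        records = self._records(rng)
        design = self._design()
        out1, _, _ = preprocess_table(records, design)
        renamed = []
        for r in records:
            import dataclasses

            renamed.append(dataclasses.replace(r, protein_ids=(f"X{r.protein_id}",)))
        out2, _, _ = preprocess_table(renamed, design)
        np.testing.assert_allclose(out1.values.to_numpy(), out2.values.to_numpy())
        assert [f"X{p}" for p in out1.proteins] == out2.proteins
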