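"""Randomized exact matching and the paired log-difference estimate."""

import numpy as np
import pandas as pd
import pytest

import theatreflow as tf
from theatreflow.matched import (
    match_pairs,
    paired_effect,
    per_procedure_matched,
    stratified_matched,
)

from conftest import code_raw, make_raw


def coded_frame(rows: list[dict]) -> pd.DataFrame:
    """Hand-built coded frame (bypasses list reconstruction)."""
    defaults = {
        "procedure_code": "LC",
        "age_group": "45-54",
        "asa_grade": "II",
        "duration_min": 60.0,
        "absolute_list_no": 1,
        "procedure_specific_list_no": 1,
        "switch": False,
    }
    out = []
    for i, r in enumerate(rows):
        out.append({"record_id": f"m{i}", **defaults, **r})
    return pd.DataFrame(out)


def min_count_oracle(coded: pd.DataFrame, k: int = 1) -> int:
    """Counting oracle: pairs per cell = min(#position-k, #position-k+1)."""
    cells = ["procedure_code", "age_group", "asa_grade"]
    s = coded["procedure_specific_list_no"]
    n1 = coded[s == k].groupby(cells).size()
    n2 = coded[s == k + 1].groupby(cells).size()
    both = pd.concat([n1.rename("a"), n2.rename("b")], axis=1).fillna(0)
    return int(both.min(axis=1).sum())


class TestMatchPairs:
    def test_unique_compatible_candidates_all_matched(self):
        rows = []
        for i, age in enumerate(["19-24", "35-44", "65-75"]):
            rows.append({"age_group": age, "procedure_specific_list_no": 1})
            rows.append({"age_group": age, "procedure_specific_list_no": 2})
        for seed in (0, 1, 99):
            res = match_pairs(coded_frame(rows), seed=seed)
            assert res.n_matched == 3

    def test_disjoint_cells_no_pairs(self):
        rows = [
            {"age_group": "19-24", "procedure_specific_list_no": 1},
            {"age_group": "65-75", "procedure_specific_list_no": 2},
        ]
        res = match_pairs(coded_frame(rows))
        assert res.n_matched == 0

    def test_empty_input_empty_result(self):
        res = match_pairs(coded_frame([{}]).iloc[0:0])
        assert res.n_matched == 0

    def test_surplus_pool1_case_selected_uniformly(self):
        # 2 candidates at position 1, 1 at position 2: exactly one pair per
        # seed, and each position-1 case is chosen about half the time
        rows = [
            {"procedure_specific_list_no": 1},
            {"procedure_specific_list_no": 1},
            {"procedure_specific_list_no": 2},
        ]
        df = coded_frame(rows)
        chosen = []
        for seed in range(400):
            res = match_pairs(df, seed=seed)
            assert res.n_matched == 1
            chosen.append(res.pairs["record_id_first"].iloc[0])
        frac = np.mean([c == "m0" for c in chosen])
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 400)

    def test_no_record_in_two_pairs(self, small_dataset):
        res = match_pairs(small_dataset, seed=5)
        ids = pd.concat([res.pairs["record_id_first"], res.pairs["record_id_second"]])
        assert ids.is_unique

    def test_members_share_cell_exactly(self, small_dataset):
        res = match_pairs(small_dataset, seed=5)
        merged = res.pairs.merge(
            small_dataset[["record_id", "procedure_code", "age_group", "asa_grade"]],
            left_on="record_id_second",
            right_on="record_id",
            suffixes=("", "_2"),
        )
        assert (merged["procedure_code"] == merged["procedure_code_2"]).all()
        assert (merged["age_group"] == merged["age_group_2"]).all()
        assert (merged["asa_grade"] == merged["asa_grade_2"]).all()

    @pytest.mark.parametrize("seed", [0, 3, 17])
    def test_pair_count_equals_min_count_oracle(self, small_dataset, seed):
        res = match_pairs(small_dataset, seed=seed)
        assert res.n_matched == min_count_oracle(small_dataset)

    def test_same_seed_identical_pairs(self, small_dataset):
        a = match_pairs(small_dataset, seed=11).pairs
        b = match_pairs(small_dataset, seed=11).pairs
        pd.testing.assert_frame_equal(a, b)

    def test_k_parameterized(self, small_dataset):
        res = match_pairs(small_dataset, k=2, seed=0)
        assert res.n_matched == min_count_oracle(small_dataset, k=2)
        with pytest.raises(ValueError):
            match_pairs(small_dataset, k=0)


class TestPairedEffect:
    def test_equal_durations_give_zero(self):
        rows = [
            {"procedure_specific_list_no": s, "age_group": a}
            for a in ("19-24", "35-44")
            for s in (1, 2)
        ]
        res = match_pairs(coded_frame(rows))
        eff = paired_effect(res)
        assert eff.beta == 0.0
        assert eff.pct == 0.0

    def test_exact_multiplicative_shift(self):
        # every second duration is exp(-0.0618) times its partner
        rows = []
        for i, age in enumerate(tf.AGE_GROUPS):
            rows.append({"age_group": age, "procedure_specific_list_no": 1, "duration_min": 50.0 + i})
            rows.append(
                {
                    "age_group": age,
                    "procedure_specific_list_no": 2,
                    "duration_min": (50.0 + i) * np.exp(-0.0618),
                }
            )
        eff = paired_effect(match_pairs(coded_frame(rows)))
        assert eff.beta == pytest.approx(-0.0618, abs=1e-12)
        assert eff.se < 1e-12
        assert eff.ci_high - eff.ci_low < 1e-10

    def test_fewer_than_two_pairs_signalled(self):
        rows = [{"procedure_specific_list_no": 1}, {"procedure_specific_list_no": 2}]
        res = match_pairs(coded_frame(rows))
        with pytest.raises(ValueError):
            paired_effect(res)

    def test_rescaling_invariance(self, small_dataset):
        res = match_pairs(small_dataset, seed=2)
        eff = paired_effect(res)
        scaled = small_dataset.assign(duration_min=small_dataset["duration_min"] * 3.0)
        eff2 = paired_effect(match_pairs(scaled, seed=2))
        assert eff2.beta == pytest.approx(eff.beta, abs=1e-12)
        assert eff2.se == pytest.approx(eff.se, abs=1e-12)


class TestPerProcedureAndStratified:
    def test_single_code_agrees_with_pooled(self, small_dataset):
        one = small_dataset[small_dataset["procedure_code"] == "P01"]
        effs, _ = per_procedure_matched(one, seed=4)
        pooled = paired_effect(match_pairs(one, seed=4))
        assert effs["P01"].beta == pytest.approx(pooled.beta, abs=1e-12)

    def test_absent_code_absent_from_output(self, small_dataset):
        effs, skipped = per_procedure_matched(small_dataset, seed=0)
        assert "NOPE" not in effs
        assert set(effs) | set(skipped) == set(small_dataset["procedure_code"].unique())

    def test_single_stratum_equals_pooled(self, small_dataset):
        one_method = small_dataset[small_dataset["method"] == "open"]
        effs, _, _ = stratified_matched(one_method, "method", seed=9)
        pooled = paired_effect(match_pairs(one_method, seed=9))
        assert effs["open"].beta == pytest.approx(pooled.beta, abs=1e-12)

    def test_unclassified_records_excluded_and_counted(self, small_dataset):
        df = small_dataset.copy()
        df.loc[df.index[:50], "method"] = "unclassified"
        _, _, n_uncl = stratified_matched(df, "method", seed=0)
        assert n_uncl == 50

    def test_unknown_stratifier_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            stratified_matched(small_dataset, "surgeon", seed=0)

    def test_equal_effects_across_strata_consistent(self):
        # generator applies one common repetition effect; method strata
        # should give overlapping CIs
        cfg = tf.GeneratorConfig(
            n_lists=3000,
            beta_abs=0.0,
            beta_switch=0.0,
            beta_spec=float(np.log1p(-0.0618)),
            p_same=1.0,
            tau=0.15,
            sigma=0.3,
            p_missing_surgeon=0.0,
            p_missing_start=0.0,
            p_duplicate=0.0,
            seed=41,
        )
        from theatreflow.synthetic import catalogue_mapping

        coded = code_raw(tf.generate_dataset(cfg))
        coded = tf.classify(coded, catalogue_mapping(cfg.catalogue))
        effs, _, _ = stratified_matched(coded, "method", seed=6)
        (a, b) = (effs["open"], effs["minimally_invasive"])
        assert a.ci_low <= b.ci_high and b.ci_low <= a.ci_high
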