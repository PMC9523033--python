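"""Design-matrix encoding: branch rules, flags, widths, invariants."""

import numpy as np
import pandas as pd
import pytest

from decliner import build_design_matrix, generate_cohort, CohortSpec
from decliner.cohort import CLINICAL_MATRIX, CohortTable, Missing, VariableSchema
from decliner.encoding import (
    decode_binary,
    encode_binary,
    encode_continuous,
    encode_multicategorical,
    encode_ordinal,
    make_missing_flag,
)
from decliner.errors import DegenerateFeatureError, SchemaError


class TestBinary:
    def test_paper_rule(self):
        col = encode_binary(["yes", "no", None])
        assert list(col.values) == [-1.0, 1.0, 0.0]  # lexicographic: no->+1, yes->-1
        assert set(np.abs(col.values[:2])) == {1.0}
        assert col.values[2] == 0.0

    def test_all_missing_is_all_zero(self):
        col = encode_binary([None, None, None])
        assert list(col.values) == [0.0, 0.0, 0.0]

    def test_invertibility(self):
        raw = ["yes", "no", None, "yes"]
        assert decode_binary(encode_binary(raw)) == ["yes", "no", None, "yes"]

    def test_three_levels_rejected(self):
        with pytest.raises(SchemaError):
            encode_binary(["a", "b", "c"])


class TestMulticategorical:
    def test_member_plus_one_others_minus_one(self):
        mat, _ = encode_multicategorical(["b"], ["a", "b", "c"])
        assert list(mat[0]) == [-1.0, 1.0, -1.0]

    def test_missing_row_all_zero(self):
        mat, miss = encode_multicategorical([None], ["a", "b", "c"])
        assert list(mat[0]) == [0.0, 0.0, 0.0]
        assert miss[0]

    @pytest.mark.parametrize("K", [2, 3, 4, 5, 6])
    def test_row_sum_identity(self, K):
        cats = [f"c{i}" for i in range(K)]
        mat, _ = encode_multicategorical(cats, cats)
        assert np.allclose(mat.sum(axis=1), 2 - K)

    def test_unseen_level_rejected(self):
        with pytest.raises(SchemaError):
            encode_multicategorical(["z"], ["a", "b"])


class TestContinuous:
    def test_hand_computed_zscores(self):
        col = encode_continuous([2.0, 4.0, None, 6.0])
        sd = np.sqrt(8 / 3)  # population SD of {2,4,6}
        assert col.values == pytest.approx([-2 / sd, 0.0, 0.0, 2 / sd])

    def test_idempotent_on_standardized_input(self):
        x = np.array([-1.2247448, 0.0, 1.2247448])
        col = encode_continuous(list(x))
        assert col.values == pytest.approx(x, abs=1e-7)

    def test_constant_column_degenerate(self):
        with pytest.raises(DegenerateFeatureError):
            encode_continuous([5.0, 5.0, 5.0])


class TestOrdinal:
    def test_rank_then_zscore(self):
        col = encode_ordinal(["never", "sometimes", "daily"], ["never", "sometimes", "daily"])
        sd = np.sqrt(2 / 3)
        assert col.values == pytest.approx([-1 / sd, 0.0, 1 / sd])

    def test_order_preserving_relabel_invariance(self):
        a = encode_ordinal(["lo", "mid", "hi", "mid"], ["lo", "mid", "hi"])
        b = encode_ordinal(["x1", "x2", "x3", "x2"], ["x1", "x2", "x3"])
        assert np.allclose(a.values, b.values)

    def test_single_level_degenerate(self):
        with pytest.raises(DegenerateFeatureError):
            encode_ordinal(["mid", "mid"], ["lo", "mid", "hi"])

    def test_unseen_level_rejected(self):
        with pytest.raises(SchemaError):
            encode_ordinal(["huge"], ["lo", "mid", "hi"])


class TestMissingFlag:
    def test_three_states(self):
        flag = make_missing_flag([Missing.PRESENT, Missing.TYPE1, Missing.TYPE2])
        assert list(flag) == [-1.0, 1.0, 0.0]

    def test_all_present(self):
        assert list(make_missing_flag([Missing.PRESENT] * 3)) == [-1.0] * 3

    def test_flag_reconstructs_missingness_type(self):
        codes = [Missing.PRESENT, Missing.TYPE1, Missing.TYPE2, Missing.PRESENT]
        flag = make_missing_flag(codes)
        back = [
            Missing.PRESENT if f == -1 else (Missing.TYPE1 if f == 1 else Missing.TYPE2)
            for f in flag
        ]
        assert back == codes


def _tiny_cohort():
    n = 6
    clinical = pd.DataFrame(
        {
            "sex": ["m", "f", "m", "f", "m", "f"],
            "grade": ["a", "b", "c", "a", "b", "c"],
        }
    )
    vals = pd.DataFrame(
        {"met1": [1.0, 2.0, np.nan, 4.0, 5.0, np.nan], "met2": [2.0, np.nan, 3.0, 1.0, 6.0, 5.0]}
    )
    codes = pd.DataFrame(
        {
            "met1": [0, 0, 1, 0, 0, 2],
            "met2": [0, 2, 0, 0, 0, 0],
        },
        dtype=np.int8,
    )
    schema = {
        "sex": VariableSchema("sex", "binary", CLINICAL_MATRIX),
        "grade": VariableSchema("grade", "multicategorical", CLINICAL_MATRIX, categories=["a", "b", "c"]),
        "met1": VariableSchema("met1", "metabolite", "plasma"),
        "met2": VariableSchema("met2", "metabolite", "plasma"),
    }
    return CohortTable(
        sample_ids=[f"S{i}" for i in range(n)],
        clinical=clinical,
        metabolites={"plasma": vals},
        missing_codes={"plasma": codes},
        schema=schema,
    )


class TestBuildDesignMatrix:
    def test_width_formula_combined(self):
        # 2 metabolites (value+flag) + 1 binary + 1 multicategorical K=3
        em = build_design_matrix(_tiny_cohort(), dataset_tag="combined")
        assert em.width == 2 * 2 + 1 + 3

    def test_width_clinical_only(self):
        em = build_design_matrix(_tiny_cohort(), dataset_tag="clinical")
        assert em.width == 4

    def test_width_additivity(self):
        c = _tiny_cohort()
        wm = build_design_matrix(c, dataset_tag="metabolomic").width
        wc = build_design_matrix(c, dataset_tag="clinical").width
        assert build_design_matrix(c, dataset_tag="combined").width == wm + wc

    def test_empty_metabolite_block(self):
        c = _tiny_cohort()
        c.metabolites, c.missing_codes = {}, {}
        c.schema = {k: v for k, v in c.schema.items() if v.matrix == CLINICAL_MATRIX}
        em = build_design_matrix(c, dataset_tag="metabolomic")
        assert em.width == 0

    def test_schema_mismatch_lists_names(self):
        c = _tiny_cohort()
        del c.schema["met2"]
        with pytest.raises(SchemaError, match="met2"):
            build_design_matrix(c, dataset_tag="combined")

    def test_missing_cells_encode_to_zero(self):
        em = build_design_matrix(_tiny_cohort(), dataset_tag="combined")
        assert np.all(em.values[em.missing_mask] == 0.0)

    def test_flag_column_values(self):
        em = build_design_matrix(_tiny_cohort(), dataset_tag="metabolomic")
        flag = em.column("Missing flag for P-met1")
        assert list(flag) == [-1.0, -1.0, 1.0, -1.0, -1.0, 0.0]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_encoded_invariants_on_generated_cohorts(seed):
    spec = CohortSpec(
        n_samples=50, n_plasma_metab=8, n_urine_metab=8, n_clinical=8,
        missing_rate_type1=0.25, missing_rate_type2=0.05, seed=seed,
    )
    cohort, _, _ = generate_cohort(spec)
    em = build_design_matrix(cohort, dataset_tag="combined")
    em.check_invariants()
    kinds = np.asarray(em.feature_kinds)
    # z-scored columns: mean ~0, SD ~1 over non-imputed entries
    for j in np.flatnonzero(np.isin(kinds, ["continuous", "ordinal"])):
        obs = em.values[~em.missing_mask[:, j], j]
        assert obs.mean() == pytest.approx(0.0, abs=1e-9)
        assert obs.std() == pytest.approx(1.0, abs=1e-9)
    # imputation neutrality: missing cells contribute exactly 0 to any weighted sum
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(em.width)
    masked = em.values.copy()
    masked[em.missing_mask] = rng.standard_normal(int(em.missing_mask.sum())) * 0
    assert np.allclose(em.values @ w, masked @ w)
    assert np.all(em.values[em.missing_mask] == 0)
    # one-hot groups: at most one +1 per row
    for src in set(np.asarray(em.source_variables)[kinds == "onehot"]):
        group = em.values[:, (np.asarray(em.source_variables) == src) & (kinds == "onehot")]
        assert np.all((group == 1).sum(axis=1) <= 1)
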