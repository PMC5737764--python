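"""Per-gene training-pool sampling, -1/+1 encoding and class-weighted
imputation."""

import numpy as np
import pytest

from moipred.annotate import AnnotationRecord, Consequence, Variant
from moipred.catalogue import BOOLEAN, CATEGORICAL, NUMERIC, Feature, FeatureCatalogue
from moipred.errors import ContractError, ValidationError
from moipred.features import (
    EQUAL_CLASS,
    FeatureMatrix,
    LabeledPool,
    apply_imputation,
    encode,
    fit_imputation,
    impute,
    read_matrix,
    sample_training_pool,
    write_matrix,
)


def _record(gene, pos, longest=True, **feats):
    cons = Consequence(
        variant=Variant("chr1", pos, "A", "G"),
        transcript_id=f"{gene}.t1",
        gene=gene,
        effect="nonsynonymous",
        protein_pos=1,
        aa_ref="K",
        aa_alt="E",
    )
    feats.setdefault("is_longest_isoform", longest)
    return AnnotationRecord(consequence=cons, features=feats)


def _pool(label, gene_sizes):
    records, pos = [], 1
    for gene, n in gene_sizes.items():
        for _ in range(n):
            records.append(_record(gene, pos))
            pos += 1
    return LabeledPool(label=label, records=records)


class TestSampleTrainingPool:
    def test_two_per_gene_on_balanced_pool(self):
        """598 records over 119 genes, two per gene -> 238 selected."""
        sizes = {f"G{i}": 5 for i in range(118)}
        sizes["G118"] = 8  # 118*5 + 8 = 598
        pool = _pool("dominant", sizes)
        assert len(pool) == 598
        assert len(sample_training_pool(pool, 2, 1)) == 238

    def test_one_per_gene_on_benign_style_pool(self):
        rng = np.random.default_rng(0)
        counts = rng.multinomial(1024 - 292, np.ones(292) / 292) + 1
        pool = _pool("benign", {f"G{i}": int(c) for i, c in enumerate(counts)})
        assert len(pool) == 1024
        assert len(sample_training_pool(pool, 1, 2)) == 292

    def test_min_clamp_single_record_gene(self):
        pool = _pool("dominant", {"G0": 1})
        assert len(sample_training_pool(pool, 2, 3)) == 1

    def test_selected_count_formula_against_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            sizes = {f"G{i}": int(rng.integers(1, 6)) for i in range(rng.integers(2, 15))}
            per_gene = int(rng.integers(1, 4))
            pool = _pool("recessive", sizes)
            expected = sum(min(per_gene, n) for n in sizes.values())
            assert len(sample_training_pool(pool, per_gene, 5)) == expected

    def test_restricted_to_longest_transcript_records(self):
        records = [_record("G0", 1, longest=False), _record("G0", 2, longest=True)]
        pool = LabeledPool(label="benign", records=records)
        [chosen] = sample_training_pool(pool, 1, 0)
        assert chosen.variant.pos == 2

    def test_reproducible_and_seed_sensitive(self):
        pool = _pool("benign", {f"G{i}": 4 for i in range(30)})
        pick = lambda s: [r.row_id() for r in sample_training_pool(pool, 1, s)]
        assert pick(11) == pick(11)
        assert pick(11) != pick(12)

    def test_empty_pool_rejected(self):
        pool = LabeledPool(label="benign", records=[])
        with pytest.raises(ValidationError, match="empty"):
            sample_training_pool(pool, 1, 0)


TOY = FeatureCatalogue(
    [
        Feature("gerp_score", NUMERIC),
        Feature("in_pfam", BOOLEAN),
        Feature("affects_all_isoforms", CATEGORICAL, ("full", "partial")),
    ]
)


class TestEncode:
    def test_boolean_to_plus_minus_one(self):
        recs = [
            _record("G0", 1, gerp_score=3.2, in_pfam=True, affects_all_isoforms="full"),
            _record("G1", 2, gerp_score=-1.0, in_pfam=False, affects_all_isoforms="partial"),
        ]
        m = encode(recs, TOY)
        assert m.columns == ["gerp_score", "in_pfam", "affects_all_isoforms"]
        assert m.values[0].tolist() == [3.2, 1.0, 1.0]
        assert m.values[1].tolist() == [-1.0, -1.0, -1.0]

    def test_missing_values_stay_missing(self):
        m = encode([_record("G0", 1, gerp_score=None, in_pfam=True)], TOY)
        assert np.isnan(m.values[0, 0])
        assert np.isnan(m.values[0, 2])  # categorical absent

    def test_unknown_level_rejected(self):
        rec = _record("G0", 1, affects_all_isoforms="sideways")
        with pytest.raises(ContractError, match="affects_all_isoforms.*sideways"):
            encode([rec], TOY)

    def test_multilevel_categorical_one_column_per_level(self):
        wide = FeatureCatalogue([Feature("color", CATEGORICAL, ("red", "green", "blue"))])
        m = encode([_record("G0", 1, color="green")], wide)
        assert m.columns == ["color=red", "color=green", "color=blue"]
        assert m.values[0].tolist() == [-1.0, 1.0, -1.0]


def _labelled_matrix(values, labels, columns=("f",)):
    return FeatureMatrix(
        row_ids=[(f"r{i}",) for i in range(len(values))],
        columns=list(columns),
        values=np.asarray(values, dtype=float),
        labels=list(labels),
    )


class TestImpute:
    def test_weighted_average_is_pooled_mean_over_observed(self):
        """Class means 0/1/2 observed in 292/238/409 rows -> fill 1.1246."""
        values = [[0.0]] * 292 + [[1.0]] * 238 + [[2.0]] * 409 + [[np.nan]]
        labels = (
            ["benign"] * 292 + ["dominant"] * 238 + ["recessive"] * 409 + ["benign"]
        )
        m = _labelled_matrix(values, labels)
        fills = fit_imputation(m)
        assert fills["f"] == pytest.approx((292 * 0 + 238 * 1 + 409 * 2) / 939, abs=1e-4)
        assert fills["f"] == pytest.approx(1.1246, abs=1e-4)

    def test_no_missing_leaves_matrix_unchanged_but_records_fill(self):
        m = _labelled_matrix([[1.0], [3.0]], ["benign", "dominant"])
        out = impute(m)
        assert out.values.tolist() == m.values.tolist()
        assert out.imputation == {"f": 2.0}

    def test_equal_class_means_give_that_mean(self):
        values = [[4.0], [4.0], [4.0], [np.nan]]
        labels = ["benign", "dominant", "recessive", "benign"]
        out = impute(_labelled_matrix(values, labels))
        assert out.values[3, 0] == pytest.approx(4.0)

    def test_equal_class_weighting_switch(self):
        values = [[0.0], [0.0], [3.0], [np.nan]]
        labels = ["benign", "benign", "dominant", "recessive"]
        m = _labelled_matrix(values, labels)
        assert fit_imputation(m)["f"] == pytest.approx(1.0)  # pooled
        assert fit_imputation(m, weighting=EQUAL_CLASS)["f"] == pytest.approx(1.5)

    def test_feature_missing_everywhere_is_an_error(self):
        m = _labelled_matrix([[np.nan], [np.nan]], ["benign", "dominant"])
        with pytest.raises(ValidationError, match="f"):
            fit_imputation(m)

    def test_heldout_observed_values_never_altered(self):
        rng = np.random.default_rng(4)
        train = _labelled_matrix(
            rng.normal(size=(30, 1)), ["benign", "dominant", "recessive"] * 10
        )
        fills = fit_imputation(train)
        held = rng.normal(size=(10, 1))
        held[3, 0] = np.nan
        held_m = FeatureMatrix(
            row_ids=[(f"h{i}",) for i in range(10)], columns=["f"], values=held.copy()
        )
        out = apply_imputation(held_m, fills)
        observed = ~np.isnan(held)
        assert np.array_equal(out.values[observed], held[observed])
        assert out.values[3, 0] == pytest.approx(fills["f"])

    def test_encode_impute_leaves_no_missing_and_valid_encodings(self, small_pools, catalogue):
        records = [r for pool in small_pools.values() for r in pool.records]
        labels = [p.label for p in small_pools.values() for _ in p.records]
        raw = encode(records, catalogue, labels=labels)
        m = impute(raw)
        assert not m.has_missing()
        for col in m.encoding:
            j = m.column_index(col)
            observed = ~np.isnan(raw.values[:, j])
            # observed descriptive values are exactly -1/+1; imputed entries
            # are weighted averages and stay inside the interval
            assert set(np.unique(m.values[observed, j])) <= {-1.0, 1.0}
            assert np.all(np.abs(m.values[:, j]) <= 1.0)


def test_matrix_round_trip(tmp_path, small_pools, catalogue):
    records = small_pools["benign"].records[:10]
    m = impute(encode(records, catalogue, labels=["benign"] * 10))
    write_matrix(m, tmp_path / "m.tsv")
    back = read_matrix(tmp_path / "m.tsv")
    assert back.columns == m.columns
    assert back.labels == m.labels
    assert np.allclose(back.values, m.values)
    assert back.imputation.keys() == m.imputation.keys()
    assert back.catalogue_digest == m.catalogue_digest
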