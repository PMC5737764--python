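"""Feature kernels (heterozygosity, entropy, network distance, densities,
isoform flags) and whole-record annotation behavior."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moipred.annotate import (
    annotate_variant,
    average_heterozygosity,
    expression_entropy,
    shortest_path_to_set,
    snp_density,
    transcript_flags,
)
from moipred.errors import ValidationError
from moipred.fixtures import FixtureConfig, generate_fixture_set


class TestAverageHeterozygosity:
    def test_single_snp(self):
        assert average_heterozygosity([(0.5, 0.5)], 1000) == pytest.approx(5e-4)

    def test_empty_list(self):
        assert average_heterozygosity([], 500) == 0.0

    def test_two_snps_hand_sum(self):
        # (2*0.1*0.9 + 2*0.2*0.8) / 100 = (0.18 + 0.32) / 100
        assert average_heterozygosity([(0.1, 0.9), (0.2, 0.8)], 100) == pytest.approx(
            0.005
        )

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValidationError):
            average_heterozygosity([(0.1, 0.9)], 0)

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 0.5, allow_nan=False), st.floats(0, 1, allow_nan=False)
            ),
            max_size=20,
        ),
        st.lists(
            st.tuples(
                st.floats(0, 0.5, allow_nan=False), st.floats(0, 1, allow_nan=False)
            ),
            max_size=20,
        ),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_additive_over_disjoint_snp_lists(self, a, b):
        l = 300
        combined = average_heterozygosity(a + b, l)
        assert combined == pytest.approx(
            average_heterozygosity(a, l) + average_heterozygosity(b, l), abs=1e-12
        )


class TestSnpDensity:
    @pytest.mark.parametrize(
        "count,l,expected", [(5, 1000, 0.005), (0, 500, 0.0), (3, 300, 0.01)]
    )
    def test_examples(self, count, l, expected):
        assert snp_density(count, l) == pytest.approx(expected)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValidationError):
            snp_density(3, -1)


class TestExpressionEntropy:
    def test_uniform_25_tissues_is_log2_25(self):
        assert expression_entropy([1.0] * 25) == pytest.approx(math.log2(25))

    def test_single_tissue_is_zero(self):
        assert expression_entropy([0.0] * 24 + [5.0]) == pytest.approx(0.0)

    def test_two_equal_tissues_is_one_bit(self):
        assert expression_entropy([3.0, 3.0] + [0.0] * 23) == pytest.approx(1.0)

    def test_all_zero_is_missing(self):
        assert expression_entropy([0.0] * 25) is None

    def test_negative_expression_rejected(self):
        with pytest.raises(ValidationError):
            expression_entropy([1.0, -0.5])

    @given(
        st.lists(st.floats(0.01, 100, allow_nan=False), min_size=2, max_size=25),
        st.floats(0.1, 50, allow_nan=False),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_invariant_to_positive_rescaling(self, expr, scale):
        assert expression_entropy(expr) == pytest.approx(
            expression_entropy([v * scale for v in expr]), rel=1e-9
        )

    @given(st.lists(st.floats(0.01, 100, allow_nan=False), min_size=2, max_size=25))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_maximized_by_uniform_vector(self, expr):
        assert expression_entropy(expr) <= math.log2(len(expr)) + 1e-9


class TestShortestPathToSet:
    def test_member_gene_is_zero(self):
        g = nx.path_graph(["A", "B", "C"])
        assert shortest_path_to_set("A", {"A"}, g) == 0

    def test_path_length_two_by_bfs(self):
        g = nx.path_graph(["A", "B", "C"])
        assert shortest_path_to_set("A", {"C"}, g) == 2

    def test_disconnected_gene_is_missing(self):
        g = nx.Graph([("A", "B"), ("X", "Y")])
        assert shortest_path_to_set("A", {"X"}, g) is None
        assert shortest_path_to_set("ZZ", {"X"}, g) is None

    def test_equals_min_over_single_pair_paths(self):
        """Oracle: minimum over members of all-pairs shortest paths."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
            members = {f"N{i}" for i in rng.choice(12, size=3, replace=False)}
            lengths = dict(nx.all_pairs_shortest_path_length(g))
            for node in g.nodes:
                expected = (
                    0
                    if node in members
                    else min(
                        (lengths[node][m] for m in members if m in lengths[node]),
                        default=None,
                    )
                )
                assert shortest_path_to_set(node, members, g) == expected


class TestTranscriptFlags:
    def test_single_isoform_is_longest_and_full(self, small_fixture_set):
        fs = small_fixture_set
        single = next(
            g for g in fs.models.genes() if len(fs.models.gene_isoforms(g)) == 1
        )
        variant = next(
            v
            for pool in fs.variant_pools.values()
            for v in pool
            if fs.models.overlapping(v.chrom, v.pos0)
            and fs.models.overlapping(v.chrom, v.pos0)[0].gene == single
        )
        from moipred.annotate import call_consequence

        [cons] = [
            c
            for c in call_consequence(variant, fs.models, fs.genome)
            if c.gene == single
        ]
        assert transcript_flags(cons, fs.models.gene_isoforms(single)) == (True, "full")

    def test_partial_when_variant_misses_one_isoform(self, small_fixture_set):
        """A variant in the skipped exon is partial; one in shared exons full."""
        from moipred.annotate import call_consequence

        fs = small_fixture_set
        seen_partial = seen_full_short = False
        for pool in fs.variant_pools.values():
            for v in pool:
                hits = fs.models.overlapping(v.chrom, v.pos0)
                gene = hits[0].gene
                isoforms = fs.models.gene_isoforms(gene)
                if len(isoforms) != 2:
                    continue
                conss = [
                    c for c in call_consequence(v, fs.models, fs.genome) if c.gene == gene
                ]
                for cons in conss:
                    is_longest, fp = transcript_flags(cons, isoforms)
                    in_all = all(m.contains(v.pos0) for m in isoforms)
                    assert fp == ("full" if in_all else "partial")
                    if fp == "partial":
                        seen_partial = True
                    if fp == "full" and not is_longest:
                        seen_full_short = True
        assert seen_partial and seen_full_short


class TestAnnotateVariant:
    def test_no_missing_fields_without_missingness(self):
        cfg = FixtureConfig(
            n_genes={"benign": 4, "dominant": 3, "recessive": 4},
            n_variants={"benign": 8, "dominant": 6, "recessive": 8},
            missingness=0.0,
        )
        fs = generate_fixture_set(cfg, seed=21)
        catalogue = cfg.annotation.catalogue()
        n_records = 0
        for pool in fs.variant_pools.values():
            for v in pool:
                for rec in annotate_variant(
                    v, fs.bundle, fs.models, fs.genome, cfg.annotation
                ):
                    n_records += 1
                    missing = [
                        f.name for f in catalogue if rec.features.get(f.name) is None
                    ]
                    # mean-GERP summaries are undefined for SNP-free classes
                    allowed = {
                        "syn_mean_gerp",
                        "nonsyn_mean_gerp",
                        "pct_syn_in_gerp_element",
                        "pct_nonsyn_in_gerp_element",
                    }
                    assert set(missing) <= allowed, (v, missing)
        assert n_records > 0

    def test_unknown_sites_yield_missing_but_computed_fields_populated(
        self, small_fixture_set
    ):
        """A variant absent from every site table still gets entropy/density."""
        fs = small_fixture_set
        variant = next(iter(fs.variant_pools["benign"]))
        import copy

        from moipred.resources import SiteTable

        bundle = copy.copy(fs.bundle)
        bundle.gerp_sites = SiteTable(fs.bundle.gerp_sites.schema)
        bundle.allele_freqs = SiteTable(fs.bundle.allele_freqs.schema)
        bundle.splice_scores = SiteTable(fs.bundle.splice_scores.schema)
        [rec] = [
            r
            for r in annotate_variant(
                variant, bundle, fs.models, fs.genome, fs.config.annotation
            )
            if r.is_longest_isoform
        ]
        assert rec.features["gerp_score"] is None
        assert rec.features["af_1kg"] is None
        assert rec.features["splice_score"] is None
        assert rec.features["expression_entropy"] is not None
        assert rec.features["syn_snp_density"] is not None
        assert rec.features["transcript_length"] is not None

    def test_synonymous_only_variant_yields_no_records(self, small_fixture_set):
        from moipred.annotate import SYNONYMOUS, Variant, call_consequence

        fs = small_fixture_set
        # scan for a site where some substitution is synonymous on all transcripts
        found = None
        for model in fs.models.models:
            cds = model.cds_sequence(fs.genome)
            for codon_idx in range(1, len(cds) // 3 - 1):
                for within in range(3):
                    from moipred.fixtures import _cds_to_genomic

                    pos0 = _cds_to_genomic(model, codon_idx * 3 + within)
                    ref = fs.genome.base(model.chrom, pos0)
                    for alt in "ACGT":
                        if alt == ref:
                            continue
                        v = Variant(model.chrom, pos0 + 1, ref, alt)
                        calls = call_consequence(v, fs.models, fs.genome)
                        if all(c.effect == SYNONYMOUS for c in calls):
                            found = v
                            break
                    if found:
                        break
                if found:
                    break
            if found:
                break
        assert found is not None
        assert (
            annotate_variant(
                found, fs.bundle, fs.models, fs.genome, fs.config.annotation
            )
            == []
        )

    def test_annotation_is_deterministic_and_order_independent(self, small_fixture_set):
        from moipred.annotate import annotate_variants, records_to_frame

        fs = small_fixture_set
        catalogue = fs.config.annotation.catalogue()
        variants = list(fs.variant_pools["dominant"])[:10]
        a = records_to_frame(
            annotate_variants(variants, fs.bundle, fs.models, fs.genome, fs.config.annotation),
            catalogue,
        )
        b = records_to_frame(
            annotate_variants(
                variants[::-1], fs.bundle, fs.models, fs.genome, fs.config.annotation
            ),
            catalogue,
        )
        b = b.sort_values(["chrom", "pos", "alt", "transcript"]).reset_index(drop=True)
        a = a.sort_values(["chrom", "pos", "alt", "transcript"]).reset_index(drop=True)
        assert a.equals(b)


def test_annotation_table_round_trip(tmp_path, small_fixture_set):
    from moipred.annotate import (
        read_annotation_table,
        records_to_frame,
        write_annotation_table,
    )

    fs = small_fixture_set
    catalogue = fs.config.annotation.catalogue()
    records = fs.labeled_pools()["benign"].records[:12]
    path = tmp_path / "anno.tsv"
    write_annotation_table(records, catalogue, path)
    loaded = read_annotation_table(path, catalogue)
    a = records_to_frame(records, catalogue)
    b = records_to_frame(loaded, catalogue)
    import pandas as pd

    for col in a.columns:
        for x, y in zip(a[col], b[col]):
            x_missing = x is None or (isinstance(x, float) and pd.isna(x))
            y_missing = y is None or (isinstance(y, float) and pd.isna(y))
            if x_missing or y_missing:
                assert x_missing and y_missing
            elif isinstance(x, float):
                assert y == pytest.approx(x, rel=1e-5)
            else:
                assert x == y
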