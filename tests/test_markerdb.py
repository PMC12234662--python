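"""Marker integration: conflict resolution, specificity, weights, concordance."""

import math

import numpy as np
import pandas as pd
import pytest

from markerscore import (
    MarkerTable,
    Scope,
    build_weighted_markers,
    compute_evidence_consistency,
    compute_specificity,
    database_concordance,
    jaccard_index,
    regularize_scores,
    summarize_database,
)
from markerscore.markerdb import (
    MarkerTableError,
    NoCommonCellTypesError,
    ScopeError,
)

from conftest import marker_record, random_marker_frame


def _as_map(resolved):
    return {
        (r.gene, r.celltype_id): (r.polarity, r.ECs)
        for r in resolved.itertuples()
    }


class TestEvidenceConsistency:
    def test_conflict_resolution_outcomes(self, conflict_table, blood_scope):
        got = _as_map(compute_evidence_consistency(conflict_table, blood_scope))
        assert got[("CD19", "B cell")] == ("positive", 3)
        assert got[("CD3E", "B cell")] == ("positive", 2)  # 3 pos - 1 neg
        assert ("NKG7", "B cell") not in got  # 2 - 2 cancels
        assert got[("CD19", "plasma cell")] == ("negative", 1)

    def test_duplicate_records_collapse_before_counting(self, blood_scope):
        rows = [marker_record("CD19", "B cell", "positive", "s1")] * 4
        table = MarkerTable(pd.DataFrame(rows))
        assert len(table) == 1
        got = _as_map(compute_evidence_consistency(table, blood_scope))
        assert got[("CD19", "B cell")] == ("positive", 1)

    def test_empty_scope_raises_naming_scope(self, conflict_table):
        scope = Scope("mouse", "brain", "physiological")
        with pytest.raises(ScopeError, match="mouse"):
            compute_evidence_consistency(conflict_table, scope)

    def test_conflict_antisymmetry(self, blood_scope):
        """Swapping all polarity labels flips every resolved polarity and
        preserves every ECs."""
        rng = np.random.default_rng(7)
        df = random_marker_frame(rng)
        flipped = df.copy()
        flipped["polarity"] = flipped["polarity"].map(
            {"positive": "negative", "negative": "positive"}
        )
        fwd = _as_map(
            compute_evidence_consistency(MarkerTable(df), blood_scope)
        )
        rev = _as_map(
            compute_evidence_consistency(MarkerTable(flipped), blood_scope)
        )
        assert set(fwd) == set(rev)
        swap = {"positive": "negative", "negative": "positive"}
        for key, (pol, ecs) in fwd.items():
            assert rev[key] == (swap[pol], ecs)


class TestSpecificity:
    def test_per_polarity_counts(self, blood_scope):
        rows = []
        # GATA1 positive for 1 cell type; SPINK2 positive for 4
        rows.append(marker_record("GATA1", "erythroid", "positive"))
        for ct in ("CT1", "CT2", "CT3", "CT4"):
            rows.append(marker_record("SPINK2", ct, "positive"))
        # MIXED: positive for 2, negative for 3 cell types
        for ct in ("CT1", "CT2"):
            rows.append(marker_record("MIXED", ct, "positive"))
        for ct in ("CT3", "CT4", "CT5"):
            rows.append(marker_record("MIXED", ct, "negative"))
        resolved = compute_evidence_consistency(
            MarkerTable(pd.DataFrame(rows)), blood_scope
        )
        spec = compute_specificity(resolved).set_index(["gene", "polarity"])
        assert spec.loc[("GATA1", "positive"), "SPs"] == 1.0
        assert spec.loc[("SPINK2", "positive"), "SPs"] == 0.25
        assert spec.loc[("MIXED", "positive"), "SPs"] == 0.5
        assert spec.loc[("MIXED", "negative"), "SPs"] == pytest.approx(1 / 3)
        assert ("GATA1", "negative") not in spec.index


class TestRegularization:
    def test_ecs_reg_closed_form(self):
        resolved = pd.DataFrame(
            {
                "gene": ["A", "B", "C"],
                "celltype_id": ["X", "X", "X"],
                "polarity": ["positive"] * 3,
                "ECs": [1, 10, 23],
            }
        )
        spec = compute_specificity(resolved)
        out = regularize_scores(resolved, spec, ecs_max=23).set_index("gene")
        assert out.loc["A", "ECs_reg"] == 1.0
        assert out.loc["B", "ECs_reg"] == 2.0
        assert out.loc["C", "ECs_reg"] == pytest.approx(
            1 + math.log10(23), abs=1e-9
        )

    def test_specificity_reverse_scaling_endpoints(self):
        # genes spanning N in {1..5}: most specific maps to 1+log10(ECs_max),
        # least specific to 1.0
        rows = []
        for i, n_ct in enumerate([1, 2, 3, 4, 5]):
            for j in range(n_ct):
                rows.append(
                    {
                        "gene": f"G{i}",
                        "celltype_id": f"CT{j}",
                        "polarity": "positive",
                        "ECs": 1,
                    }
                )
        resolved = pd.DataFrame(rows)
        spec = compute_specificity(resolved)
        out = regularize_scores(resolved, spec, ecs_max=23)
        by_gene = out.groupby("gene")["SPs_reg"].first()
        assert by_gene["G0"] == pytest.approx(1 + math.log10(23), abs=1e-9)
        assert by_gene["G4"] == pytest.approx(1.0, abs=1e-12)
        # monotone: fewer cell types -> higher SPs_reg
        assert by_gene.is_monotonic_decreasing

    def test_uniform_specificity_not_penalized(self):
        resolved = pd.DataFrame(
            {
                "gene": ["A", "B"],
                "celltype_id": ["X", "Y"],
                "polarity": ["positive"] * 2,
                "ECs": [5, 5],
            }
        )
        spec = compute_specificity(resolved)
        out = regularize_scores(resolved, spec, ecs_max=5)
        assert out["SPs_reg"].tolist() == pytest.approx(
            [1 + math.log10(5)] * 2
        )

    def test_ecs_below_one_rejected(self):
        resolved = pd.DataFrame(
            {
                "gene": ["A"],
                "celltype_id": ["X"],
                "polarity": ["positive"],
                "ECs": [0],
            }
        )
        with pytest.raises(ValueError, match="ECs"):
            regularize_scores(
                resolved, compute_specificity(resolved), ecs_max=5
            )


def brute_force_weighted(df, scope, max_n_marker=None):
    """Independent per-(gene, celltype) enumeration oracle."""
    sub = df[
        (df.species == scope.species)
        & (df.tissue == scope.tissue)
        & (df.category == scope.category)
    ].drop_duplicates(
        subset=[
            "species",
            "tissue",
            "celltype_id",
            "gene",
            "polarity",
            "source_id",
        ]
    )
    resolved = {}
    for (gene, ct), grp in sub.groupby(["gene", "celltype_id"]):
        pos = grp[grp.polarity == "positive"]["source_id"].nunique()
        neg = grp[grp.polarity == "negative"]["source_id"].nunique()
        d = pos - neg
        if d != 0:
            resolved[(gene, ct)] = (
                "positive" if d > 0 else "negative",
                abs(d),
            )
    if not resolved:
        return {}
    ecs_max = max(e for _, e in resolved.values())
    # N per (gene, polarity)
    n_ct = {}
    for (gene, ct), (pol, _) in resolved.items():
        n_ct[(gene, pol)] = n_ct.get((gene, pol), 0) + 1
    out = {}
    for pol in ("positive", "negative"):
        ns = [v for (g, p), v in n_ct.items() if p == pol]
        if not ns:
            continue
        n_min, n_max = min(ns), max(ns)
        for (gene, ct), (p, ecs) in resolved.items():
            if p != pol:
                continue
            n = n_ct[(gene, pol)]
            if n_max == n_min:
                m = ecs_max
            else:
                r = n_max + n_min - n
                m = 1 + (r - n_min) * (ecs_max - 1) / (n_max - n_min)
            ecs_reg = 1 + math.log10(ecs)
            sps_reg = 1 + math.log10(m)
            out[(gene, ct)] = (pol, ecs, ecs_reg * sps_reg)
    if max_n_marker is not None:
        kept = {}
        by_ct_pol = {}
        for (gene, ct), (pol, ecs, w) in out.items():
            by_ct_pol.setdefault((ct, pol), []).append((gene, w))
        for (ct, pol), items in by_ct_pol.items():
            items.sort(key=lambda t: (-t[1], t[0]))
            for gene, w in items[:max_n_marker]:
                kept[(gene, ct)] = out[(gene, ct)]
        out = kept
    return out


class TestBuildWeightedMarkers:
    def test_weight_endpoints_match_printed_range(self, blood_scope):
        """ECs=23 + maximal specificity gives (1+log10 23)^2 ~ 5.58 (prints
        as 5.6); ECs=1 + minimal specificity gives exactly 1."""
        rows = []
        for s in range(23):
            rows.append(
                marker_record("SPECIFIC", "CT_A", "positive", f"s{s}")
            )
        for ct in ("CT1", "CT2", "CT3", "CT4", "CT5"):
            rows.append(marker_record("BROAD", ct, "positive", "s0"))
        wmt = build_weighted_markers(
            MarkerTable(pd.DataFrame(rows)), blood_scope
        )
        assert wmt.ecs_max == 23
        top = wmt.markers.set_index("gene")
        assert top.loc["SPECIFIC", "weight"] == pytest.approx(
            (1 + math.log10(23)) ** 2, abs=1e-9
        )
        assert round(top.loc["SPECIFIC", "weight"], 1) == 5.6
        assert (top.loc["BROAD", "weight"] == 1.0).all()

    def test_weight_bounds_invariant(self, blood_scope):
        rng = np.random.default_rng(11)
        for trial in range(5):
            df = random_marker_frame(rng, n_records=45)
            try:
                wmt = build_weighted_markers(MarkerTable(df), blood_scope)
            except ScopeError:
                continue
            upper = (1 + math.log10(wmt.ecs_max)) ** 2
            assert (wmt.markers["weight"] >= 1.0 - 1e-12).all()
            assert (wmt.markers["weight"] <= upper + 1e-12).all()

    def test_matches_brute_force_oracle(self, blood_scope):
        rng = np.random.default_rng(3)
        for trial in range(8):
            df = random_marker_frame(rng, n_records=50)
            expected = brute_force_weighted(df, blood_scope)
            if not expected:
                continue
            wmt = build_weighted_markers(MarkerTable(df), blood_scope)
            got = {
                (r.gene, r.celltype_id): (r.polarity, r.ECs, r.weight)
                for r in wmt.markers.itertuples()
            }
            assert set(got) == set(expected)
            for key in expected:
                pol_e, ecs_e, w_e = expected[key]
                pol_g, ecs_g, w_g = got[key]
                assert (pol_g, ecs_g) == (pol_e, ecs_e)
                assert w_g == pytest.approx(w_e, abs=1e-12)

    def test_top_n_selection_and_ties(self, blood_scope):
        rows = []
        # three positive markers with weights ordered by ECs {4, 2, 1}
        for gene, n_src in (("AAA", 4), ("BBB", 2), ("CCC", 1)):
            for s in range(n_src):
                rows.append(marker_record(gene, "CT_X", "positive", f"s{s}"))
        wmt = build_weighted_markers(
            MarkerTable(pd.DataFrame(rows)), blood_scope, max_n_marker=2
        )
        assert list(wmt.markers["gene"]) == ["AAA", "BBB"]

    def test_top_n_independent_per_polarity(self, blood_scope):
        rows = []
        for gene in ("P1", "P2", "P3"):
            rows.append(marker_record(gene, "CT_X", "positive", "s1"))
        for gene in ("N1", "N2", "N3"):
            rows.append(marker_record(gene, "CT_X", "negative", "s1"))
        wmt = build_weighted_markers(
            MarkerTable(pd.DataFrame(rows)), blood_scope, max_n_marker=2
        )
        assert len(wmt.markers_for("CT_X", "positive")) == 2
        assert len(wmt.markers_for("CT_X", "negative")) == 2

    def test_positive_negative_sets_disjoint(self, conflict_table, blood_scope):
        wmt = build_weighted_markers(conflict_table, blood_scope)
        for ct in wmt.celltypes:
            pos = set(wmt.markers_for(ct, "positive")["gene"])
            neg = set(wmt.markers_for(ct, "negative")["gene"])
            assert not (pos & neg)

    def test_invalid_max_n_marker(self, conflict_table, blood_scope):
        with pytest.raises(ValueError, match="max_n_marker"):
            build_weighted_markers(conflict_table, blood_scope, max_n_marker=0)


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
            ({"A", "B"}, {"A", "B"}, 1.0),
            ({"A"}, {"B"}, 0.0),
            (set(), set(), 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert jaccard_index(a, b) == expected

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(5)
        universe = [f"G{i}" for i in range(12)]
        for _ in range(25):
            a = set(rng.choice(universe, rng.integers(0, 10), replace=False))
            b = set(rng.choice(universe, rng.integers(0, 10), replace=False))
            j = jaccard_index(a, b)
            assert j == jaccard_index(b, a)
            assert 0.0 <= j <= 1.0


class TestConcordance:
    def _db(self, mapping):
        rows = [
            marker_record(g, ct, source=src)
            for ct, genes in mapping.items()
            for src, g in enumerate(genes)
        ]
        return MarkerTable(pd.DataFrame(rows))

    def test_average_over_common_celltypes(self):
        db_a = self._db({"T": ["A", "B", "C"], "B": ["X", "Y"], "only_a": ["Q"]})
        db_b = self._db({"T": ["B", "C", "D"], "B": ["X", "Y", "Z", "W"]})
        matrix, avg = database_concordance(db_a, db_b)
        assert matrix.loc["T", "T"] == 0.5
        assert matrix.loc["B", "B"] == 0.5
        assert avg == 0.5

    def test_toy_example_average(self):
        db_a = self._db({"T": ["A", "B"], "B": ["X", "Y", "Z"]})
        db_b = self._db({"T": ["A", "B", "C", "D"], "B": ["X", "P", "Q", "R", "S", "U", "V", "W", "T2", "T3", "T4"]})
        # per-type Jaccard: T: 2/4 = 0.5; B: 1/13 ... construct directly:
        matrix, avg = database_concordance(db_a, db_b)
        assert avg == pytest.approx(
            (matrix.loc["T", "T"] + matrix.loc["B", "B"]) / 2
        )

    def test_self_concordance_is_one(self, conflict_table):
        _, avg = database_concordance(conflict_table, conflict_table)
        assert avg == 1.0

    def test_symmetric_scalar(self):
        db_a = self._db({"T": ["A", "B", "C"], "B": ["X", "Y"]})
        db_b = self._db({"T": ["B", "C", "D"], "B": ["Y", "Z"]})
        _, ab = database_concordance(db_a, db_b)
        _, ba = database_concordance(db_b, db_a)
        assert ab == ba

    def test_no_common_celltypes_errors(self):
        db_a = self._db({"T": ["A"]})
        db_b = self._db({"NK": ["A"]})
        with pytest.raises(NoCommonCellTypesError, match="no common cell types"):
            database_concordance(db_a, db_b)


class TestSummarize:
    def test_toy_counts(self):
        rows = [
            marker_record("G1", "CT1"),
            marker_record("G2", "CT1"),
            marker_record("G3", "CT2"),
        ]
        out = summarize_database(MarkerTable(pd.DataFrame(rows)))
        row = out.loc[("human", "physiological")]
        assert row["n_marker_genes"] == 3
        assert row["n_celltypes"] == 2
        assert row["n_tissues"] == 1
        assert row["n_associations"] == 3

    def test_invariant_to_order_and_duplicates(self):
        rng = np.random.default_rng(13)
        df = random_marker_frame(rng, n_records=30)
        base = summarize_database(MarkerTable(df))
        shuffled = df.sample(frac=1.0, random_state=1)
        doubled = pd.concat([shuffled, shuffled.head(10)])
        again = summarize_database(MarkerTable(doubled))
        pd.testing.assert_frame_equal(base, again)


class TestValidation:
    def test_invalid_polarity_rejected(self):
        df = pd.DataFrame([marker_record("G1", "CT1", polarity="pos+")])
        with pytest.raises(MarkerTableError, match="polarity"):
            MarkerTable(df)

    def test_missing_column_rejected(self):
        df = pd.DataFrame([marker_record("G1", "CT1")]).drop(columns=["gene"])
        with pytest.raises(MarkerTableError, match="gene"):
            MarkerTable(df)

    def test_case_insensitive_flag(self, blood_scope):
        df = pd.DataFrame(
            [
                marker_record("cd19", "B cell", source="s1"),
                marker_record("CD19", "B cell", source="s2"),
            ]
        )
        default = compute_evidence_consistency(MarkerTable(df), blood_scope)
        assert len(default) == 2  # case-sensitive: two distinct genes
        folded = compute_evidence_consistency(
            MarkerTable(df, case_insensitive=True), blood_scope
        )
        assert len(folded) == 1
        assert folded.iloc[0]["ECs"] == 2
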