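"""Core scoring statistic: normalization, filtering, hub boundary, scores."""

import numpy as np
import pandas as pd
import pytest

from hubsig.interactome import PathwayMap
from hubsig.score import (
    class_norm_counts,
    class_score,
    filter_to_pathways,
    hub_boundary_search,
    norm_connections,
    variance_filter,
)
from hubsig.synthcohort import SampleProfile


def make_profiles(spec):
    """spec: list of (class, cancer_type, n_samples, {gene: count_upregulated}).

    Gene g appears in the first count samples of the group.
    """
    profiles = []
    for cls, ctype, n, gene_counts in spec:
        for i in range(n):
            genes = frozenset(g for g, c in gene_counts.items() if i < c)
            profiles.append(SampleProfile(f"{ctype}_{i}", ctype, cls, genes))
    return profiles


class TestFilterToPathways:
    def test_no_overlap_empties_profiles(self):
        profiles = make_profiles([("H", "T1", 2, {"g1": 2}),
                                  ("L", "T2", 2, {"g1": 1})])
        filtered, summary = filter_to_pathways(
            profiles, PathwayMap({"P": {"other"}})
        )
        assert all(not p.genes for p in filtered)
        assert (summary.total, summary.h_only, summary.l_only,
                summary.shared) == (0, 0, 0, 0)

    def test_toy_partition(self):
        profiles = make_profiles([
            ("H", "T1", 2, {"h_only": 1, "shared": 2}),
            ("L", "T2", 2, {"l_only": 2, "shared": 1}),
        ])
        pw = PathwayMap({"P": {"h_only", "l_only", "shared"}})
        _, summary = filter_to_pathways(profiles, pw)
        assert (summary.total, summary.h_only, summary.l_only,
                summary.shared) == (3, 1, 1, 1)

    def test_identity_pathways_leave_profiles_unchanged(self):
        profiles = make_profiles([("H", "T1", 3, {"a": 2, "b": 1}),
                                  ("L", "T2", 2, {"a": 1})])
        universe = {"a", "b"}
        filtered, _ = filter_to_pathways(profiles, PathwayMap({"P": universe}))
        for orig, new in zip(profiles, filtered):
            assert orig.genes == new.genes

    def test_empty_pathways_rejected(self):
        profiles = make_profiles([("H", "T1", 1, {"a": 1})])
        with pytest.raises(ValueError):
            filter_to_pathways(profiles, PathwayMap({}))


class TestClassNormCounts:
    def test_one_in_125_is_0_008(self):
        profiles = make_profiles([("H", "T1", 125, {"ABL1": 1}),
                                  ("L", "T2", 135, {"other": 1})])
        stats = class_norm_counts(profiles)
        row = stats[(stats.gene == "ABL1") & (stats.group == "H")].iloc[0]
        assert row["n"] == 1
        assert row["norm_count"] == pytest.approx(0.008)

    def test_full_presence_is_one_and_absence_zero(self):
        profiles = make_profiles([("H", "T1", 10, {"g": 10}),
                                  ("L", "T2", 7, {"x": 3})])
        stats = class_norm_counts(profiles)
        get = lambda g, grp: stats[(stats.gene == g) & (stats.group == grp)].iloc[0]
        assert get("g", "H")["norm_count"] == 1.0
        assert get("g", "L")["norm_count"] == 0.0  # null imputation
        assert get("g", "L")["n"] == 0

    def test_scale_invariance_under_duplication(self, cohort):
        profiles, _ = cohort
        doubled = profiles + [
            SampleProfile(p.sample_id + "_dup", p.cancer_type, p.class_label,
                          p.genes)
            for p in profiles
        ]
        a = class_norm_counts(profiles).set_index(["gene", "group"])
        b = class_norm_counts(doubled).set_index(["gene", "group"])
        pd.testing.assert_series_equal(a["norm_count"], b["norm_count"])

    def test_grouping_by_cancer_type(self):
        profiles = make_profiles([("H", "T1", 4, {"g": 2}),
                                  ("H", "T2", 8, {"g": 2})])
        stats = class_norm_counts(profiles, group_by="cancer_type")
        vals = stats.set_index("group")["norm_count"]
        assert vals["T1"] == 0.5 and vals["T2"] == 0.25


class TestNormConnections:
    def test_table3_reference_rows(self):
        """Printed per-gene normalized connections: (n / class size) x degree."""
        profiles = make_profiles([
            ("H", "T1", 125, {"CTNNB1": 81, "GRB2": 54}),
            ("L", "T2", 135, {"CTNNB1": 62, "GRB2": 36}),
        ])
        degrees = {"CTNNB1": 444, "GRB2": 753}
        stats = norm_connections(class_norm_counts(profiles), degrees)
        get = lambda g, grp: stats[(stats.gene == g) & (stats.group == grp)].iloc[0]
        assert get("CTNNB1", "H")["norm_connections"] == pytest.approx(287.7, abs=0.05)
        assert get("CTNNB1", "L")["norm_connections"] == pytest.approx(203.9, abs=0.05)
        assert get("GRB2", "H")["norm_connections"] == pytest.approx(325.3, abs=0.05)

    def test_degree_zero_gives_zero(self):
        profiles = make_profiles([("H", "T1", 2, {"g": 2}),
                                  ("L", "T2", 2, {"g": 1})])
        stats = norm_connections(class_norm_counts(profiles), {"g": 0})
        assert (stats["norm_connections"] == 0).all()

    def test_missing_gene_excluded(self, caplog):
        profiles = make_profiles([("H", "T1", 2, {"known": 2, "unknown": 1}),
                                  ("L", "T2", 2, {"known": 1})])
        stats = norm_connections(class_norm_counts(profiles), {"known": 5})
        assert set(stats["gene"]) == {"known"}
        assert stats.attrs["n_missing_degree"] == 1

    def test_bounds_invariant(self, cohort, interactome500):
        profiles, _ = cohort
        stats = norm_connections(class_norm_counts(profiles), interactome500)
        assert ((stats["norm_count"] >= 0) & (stats["norm_count"] <= 1)).all()
        assert (stats["norm_connections"] <= stats["degree"] + 1e-12).all()


class TestVarianceFilter:
    @staticmethod
    def stats_from(rows):
        return pd.DataFrame(
            rows, columns=["gene", "group", "n", "norm_count", "degree",
                           "norm_connections"]
        )

    def test_identical_values_excluded(self):
        stats = self.stats_from([
            ("g", "H", 5, 0.5, 10, 5.0), ("g", "L", 5, 0.5, 10, 5.0),
        ])
        assert variance_filter(stats) == set()

    def test_class_exclusive_always_selected(self):
        stats = self.stats_from([
            ("g", "H", 5, 0.5, 10, 5.0), ("g", "L", 0, 0.0, 10, 0.0),
        ])
        assert variance_filter(stats) == {"g"}

    def test_two_value_variance_arithmetic(self):
        # unbiased sample variance of (0.1, 0.3) is (0.2)^2 / 2 = 0.02
        stats = self.stats_from([
            ("g", "H", 1, 0.3, 10, 3.0), ("g", "L", 1, 0.1, 10, 1.0),
        ])
        assert variance_filter(stats, threshold=0.005) == {"g"}
        assert variance_filter(stats, threshold=0.02) == set()  # strict >

    def test_threshold_monotonicity(self, cohort, interactome500):
        profiles, _ = cohort
        stats = norm_connections(class_norm_counts(profiles), interactome500)
        prev = None
        for thr in (0.0, 0.002, 0.005, 0.02, 0.1):
            sel = variance_filter(stats, threshold=thr)
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_variance_on_connections_switch(self):
        stats = self.stats_from([
            ("g", "H", 2, 0.20, 100, 20.0), ("g", "L", 1, 0.19, 100, 19.0),
        ])
        # tiny frequency variance, large connection-weighted variance
        assert variance_filter(stats, on="norm_count") == set()
        assert variance_filter(stats, on="norm_connections") == {"g"}


def brute_force_boundary(stats_h, stats_l):
    """Independent exhaustive search over all observed (c, f) pairs."""
    h = stats_h[stats_h["n"] > 0]
    l = stats_l[stats_l["n"] > 0]
    best = (0, -np.inf, -np.inf, [])  # count, c, f, genes
    for c in h["norm_connections"]:
        for f in h["norm_count"]:
            l_hit = ((l["norm_connections"] >= c) & (l["norm_count"] >= f)).any()
            if l_hit:
                continue
            mask = (h["norm_connections"] >= c) & (h["norm_count"] >= f)
            cand = (int(mask.sum()), c, f, sorted(h.loc[mask, "gene"]))
            if cand[0] > 0 and (cand[0], cand[1], cand[2]) > (
                best[0], best[1], best[2]
            ):
                best = cand
    return best


class TestHubBoundary:
    @staticmethod
    def table(rows):
        return pd.DataFrame(
            [(g, grp, n, f, d, f * d) for g, grp, n, f, d in rows],
            columns=["gene", "group", "n", "norm_count", "degree",
                     "norm_connections"],
        )

    def test_planted_boundary_recovered_exactly(self):
        h_rows = [(f"hub{i}", "H", 10, 0.80, 40, ) for i in range(9)]
        h_rows += [(f"lo{i}", "H", 10, 0.50, 20) for i in range(5)]
        l_rows = [(f"lg{i}", "L", 10, 0.60, 30) for i in range(5)]
        stats_h, stats_l = self.table(h_rows), self.table(l_rows)
        res = hub_boundary_search(stats_h, stats_l)
        assert len(res.genes) == 9
        assert set(res.genes) == {f"hub{i}" for i in range(9)}
        assert res.c_star == pytest.approx(0.80 * 40)
        assert res.f_star == pytest.approx(0.80)

    def test_identical_tables_give_empty_set(self):
        rows = [(f"g{i}", "H", 5, 0.5, 10) for i in range(5)]
        stats_h = self.table(rows)
        stats_l = self.table([(g, "L", n, f, d) for g, _, n, f, d in rows])
        res = hub_boundary_search(stats_h, stats_l)
        assert res.genes == []
        assert res.objective == 0

    def test_matches_brute_force_on_random_tables(self, cohort,
                                                  interactome500):
        profiles, _ = cohort
        stats = norm_connections(class_norm_counts(profiles), interactome500)
        h = stats[stats.group == "H"].head(200)
        l = stats[stats.group == "L"].head(200)
        res = hub_boundary_search(h, l)
        count, c, f, genes = brute_force_boundary(h, l)
        assert res.objective == count
        assert res.genes == genes
        assert (res.c_star, res.f_star) == (pytest.approx(c), pytest.approx(f))


class TestClassScore:
    TABLE3 = {  # gene: (degree, n_H, n_L); class sizes 125 / 135
        "GRB2": (753, 54, 36), "CTNNB1": (444, 81, 62), "SKP1": (234, 63, 25),
        "CSNK2A1": (284, 70, 24), "PRKDC": (110, 66, 19),
        "HDAC1": (257, 39, 22), "YWHAZ": (522, 109, 67),
        "YWHAB": (310, 83, 33), "PSMD2": (132, 53, 0), "EGFR": (464, 56, 43),
    }

    def stats(self):
        profiles = make_profiles([
            ("H", "T1", 125, {g: v[1] for g, v in self.TABLE3.items()}),
            ("L", "T2", 135, {g: v[2] for g, v in self.TABLE3.items()}),
        ])
        degrees = {g: v[0] for g, v in self.TABLE3.items()}
        return norm_connections(class_norm_counts(profiles), degrees)

    def test_reference_totals_and_relative_difference(self):
        totals, rel = class_score(self.stats(), list(self.TABLE3))
        assert totals["H"] == pytest.approx(1953.1, abs=0.05)
        assert totals["L"] == pytest.approx(1038.5, abs=0.05)
        assert round(rel) == 47

    def test_single_absent_gene_scores_zero(self):
        totals, _ = class_score(self.stats(), ["PSMD2"])
        assert totals["L"] == 0.0
        assert totals["H"] == pytest.approx(132 * 53 / 125)

    def test_additivity_over_disjoint_lists(self):
        stats = self.stats()
        genes = list(self.TABLE3)
        a, b = genes[:4], genes[4:]
        t_all, _ = class_score(stats, genes)
        t_a, _ = class_score(stats, a)
        t_b, _ = class_score(stats, b)
        for cls in ("H", "L"):
            assert t_all[cls] == pytest.approx(t_a[cls] + t_b[cls])

    def test_empty_gene_list(self):
        totals, rel = class_score(self.stats(), [])
        assert totals["H"] == totals["L"] == 0.0
        assert np.isnan(rel)
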