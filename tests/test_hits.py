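"""Consensus hit calling, selectivity, summaries, encoding and clustering."""

import numpy as np
import pandas as pd
import pytest

from qhtscreen.errors import InvalidArgumentError, LookupFailure
from qhtscreen.hits import (
    ActivityMatrix,
    ConsensusHit,
    call_selectivity,
    cluster_profiles,
    consensus_hits,
    dendrogram_newick,
    efficacy_difference,
    encode_outcomes,
    flat_clusters,
    fold_shift,
    summarize,
)

CLL = [f"CLL-{i}" for i in range(1, 7)]
NORMAL = [f"N-{i}" for i in range(1, 6)]


def make_matrix(rows):
    """rows: (compound, sample, category, ic50)"""
    return ActivityMatrix(
        pd.DataFrame(
            [
                {
                    "compound_id": c,
                    "sample_id": s,
                    "category": cat,
                    "curve_class": {"active": "1.1", "inactive": "4"}.get(cat, "2.2"),
                    "ac50_uM": ic50,
                    "efficacy_pct": 90.0 if cat == "active" else 10.0,
                }
                for c, s, cat, ic50 in rows
            ]
        )
    )


def full_grid(spec):
    """spec: compound -> dict sample -> (category, ic50); absent cells are untested."""
    rows = []
    for cid, per_sample in spec.items():
        for sid in CLL + NORMAL:
            if sid not in per_sample:
                continue
            cat, ic50 = per_sample[sid]
            rows.append((cid, sid, cat, ic50))
    return make_matrix(rows)


def pan_active(ic50_cll=1.0, ic50_normal=1.0):
    d = {s: ("active", ic50_cll) for s in CLL}
    d.update({s: ("active", ic50_normal) for s in NORMAL})
    return d


class TestConsensus:
    def test_active_everywhere_included(self):
        m = full_grid({"A": pan_active(1.0)})
        hits = consensus_hits(m, CLL)
        assert [h.compound_id for h in hits] == ["A"]
        assert hits[0].gm_ic50_uM == pytest.approx(1.0)

    def test_five_of_six_excluded(self):
        spec = pan_active(1.0)
        spec["CLL-3"] = ("inconclusive", 2.0)
        m = full_grid({"A": spec})
        assert consensus_hits(m, CLL) == []

    def test_single_ic50_above_gate_excluded(self):
        spec = pan_active(1.0)
        spec["CLL-2"] = ("active", 35.0)
        m = full_grid({"A": spec})
        assert consensus_hits(m, CLL) == []
        assert len(consensus_hits(m, CLL, ic50_gate_uM=40.0)) == 1

    def test_sorted_by_geometric_mean(self):
        m = full_grid({"A": pan_active(5.0), "B": pan_active(0.2)})
        assert [h.compound_id for h in consensus_hits(m, CLL)] == ["B", "A"]

    def test_unknown_sample_rejected(self):
        m = full_grid({"A": pan_active()})
        with pytest.raises(LookupFailure):
            consensus_hits(m, CLL + ["CLL-99"])

    def test_anti_monotone_in_samples(self):
        # a hit list can only shrink (or persist) as CLL samples are added
        spec_a = pan_active(1.0)
        spec_b = pan_active(1.0)
        spec_b["CLL-6"] = ("inactive", np.nan)
        m = full_grid({"A": spec_a, "B": spec_b})
        for k in range(1, len(CLL) + 1):
            sub = {h.compound_id for h in consensus_hits(m, CLL[:k])}
            full = {h.compound_id for h in consensus_hits(m, CLL)}
            assert full <= sub


class TestFoldShift:
    def test_idarubicin_style_shift(self):
        assert fold_shift(0.1, 3.2) == pytest.approx(32.0)

    def test_no_shift(self):
        assert fold_shift(4.2, 4.2) == 1.0

    def test_doxorubicin_style_shift(self):
        assert fold_shift(4.5, 14.4) == pytest.approx(3.2)
        assert round(fold_shift(4.5, 14.4)) == 3

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fold_shift(0.0, 1.0)


def curves_for(compound_id, cll_resp, normal_resp, concs=(19.0, 57.0)):
    rows = []
    for conc, (rc, rn) in zip(concs, zip(*[cll_resp, normal_resp])):
        for s in CLL:
            rows.append((compound_id, s, conc, rc))
        for s in NORMAL:
            rows.append((compound_id, s, conc, rn))
    return pd.DataFrame(rows, columns=["compound_id", "sample_id", "conc_uM", "response"])


class TestEfficacyDifference:
    def test_stated_rule_arithmetic(self):
        curves = curves_for("A", (-90.0, -95.0), (-20.0, -25.0))
        assert efficacy_difference(curves, "A", CLL, NORMAL) == pytest.approx(70.0)

    def test_identical_groups_zero(self):
        curves = curves_for("A", (-50.0, -60.0), (-50.0, -60.0))
        assert efficacy_difference(curves, "A", CLL, NORMAL) == 0.0

    def test_threshold_boundary(self):
        curves = curves_for("A", (-80.0, -80.0), (-38.0, -38.0))
        assert efficacy_difference(curves, "A", CLL, NORMAL) == pytest.approx(42.0)

    def test_missing_compound(self):
        with pytest.raises(LookupFailure):
            efficacy_difference(curves_for("A", (-1, -1), (-1, -1)), "B", CLL, NORMAL)


class TestSelectivity:
    def hit(self, cid, gm):
        return ConsensusHit(cid, (gm,) * 6, gm, gm, gm)

    def test_potency_shift_clause(self):
        m = full_grid({"A": pan_active(ic50_cll=0.1, ic50_normal=3.0)})
        res = call_selectivity(m, [self.hit("A", 0.1)], NORMAL)[0]
        assert res.fold_shift == pytest.approx(30.0)
        assert res.selective

    def test_comparable_potency_not_selective(self):
        m = full_grid({"A": pan_active(ic50_cll=1.0, ic50_normal=1.1)})
        res = call_selectivity(m, [self.hit("A", 1.0)], NORMAL)[0]
        assert not res.selective

    def test_majority_inactive_clause_with_undefined_ratio(self):
        spec = pan_active(1.0)
        for s in NORMAL[:3]:
            spec[s] = ("inactive", np.nan)
        for s in NORMAL[3:]:
            spec[s] = ("inactive", np.nan)
        m = full_grid({"A": spec})
        res = call_selectivity(m, [self.hit("A", 1.0)], NORMAL)[0]
        assert np.isnan(res.fold_shift)
        assert res.n_normal_inactive == 5
        assert res.selective

    def test_majority_clause_three_of_five(self):
        spec = pan_active(1.0, ic50_normal=1.0)
        for s in NORMAL[:3]:
            spec[s] = ("inconclusive", np.nan)
        m = full_grid({"A": spec})
        res = call_selectivity(m, [self.hit("A", 1.0)], NORMAL)[0]
        assert res.n_normal_inactive == 3
        assert res.selective

    def test_efficacy_clause(self):
        m = full_grid({"A": pan_active(1.0, 1.2)})
        curves = curves_for("A", (-90.0, -95.0), (-20.0, -25.0))
        res = call_selectivity(m, [self.hit("A", 1.0)], NORMAL, curves=curves,
                               cll_samples=CLL)[0]
        assert res.efficacy_diff == pytest.approx(70.0)
        assert res.selective

    def test_empty_consensus_rejected(self):
        m = full_grid({"A": pan_active()})
        with pytest.raises(InvalidArgumentError):
            call_selectivity(m, [], NORMAL)


class TestSummarize:
    def test_counts_and_percentages(self):
        spec = {f"C{i}": pan_active(1.0) for i in range(5)}
        spec["D"] = {s: ("inactive", np.nan) for s in CLL + NORMAL}
        spec["E"] = {s: ("inconclusive", np.nan) for s in CLL + NORMAL}
        m = full_grid(spec)
        hits = consensus_hits(m, CLL)
        sel = call_selectivity(m, hits, NORMAL)
        summary = summarize(m, hits, sel, CLL)
        assert summary["n_tested"] == 7
        assert summary["per_sample"]["CLL-1"]["n_active"] == 5
        assert summary["per_sample"]["CLL-1"]["pct_active"] == 71.4
        assert summary["n_consensus"] == 5
        assert summary["pct_consensus"] == 71.4
        assert summary["n_inactive_all_cll"] == 2
        # category counts partition every sample's tested compounds
        for sid, d in summary["per_sample"].items():
            assert d["n_active"] + d["n_inconclusive"] + d["n_inactive"] == 7

    def test_zero_actives(self):
        spec = {"A": {s: ("inactive", np.nan) for s in CLL + NORMAL}}
        m = full_grid(spec)
        summary = summarize(m, [], [], CLL)
        assert summary["per_sample"]["CLL-1"]["pct_active"] == 0.0
        assert summary["pct_consensus"] == 0.0


class TestEncoding:
    def test_codes(self):
        m = full_grid({
            "A": pan_active(1.0),
            "B": {s: ("inactive", np.nan) for s in CLL + NORMAL},
            "C": {s: ("inconclusive", np.nan) for s in CLL},  # untested in normals
        })
        codes = encode_outcomes(m)
        assert (codes.loc["A"] == 1).all()
        assert (codes.loc["B"] == 3).all()
        assert (codes.loc["C", CLL] == 2).all()
        assert (codes.loc["C", NORMAL] == 4).all()


class TestClustering:
    def test_identical_profiles_adjacent(self):
        codes = pd.DataFrame(
            [[1, 1, 1], [3, 3, 3], [1, 1, 1]],
            index=["A", "B", "C"],
            columns=["s1", "s2", "s3"],
        )
        result = cluster_profiles(codes)
        pos = {cid: i for i, cid in enumerate(result.order)}
        assert abs(pos["A"] - pos["C"]) == 1

    def test_maximal_disagreement_distance(self):
        from qhtscreen.hits import _profile_distance

        codes = np.array([[1, 1, 1], [3, 3, 3]])
        assert _profile_distance(codes)[0] == 1.0

    def test_untested_cells_excluded_from_distance(self):
        from qhtscreen.hits import _profile_distance

        codes = np.array([[1, 1, 4], [1, 3, 3]])
        # one shared tested assay agrees, one disagrees
        assert _profile_distance(codes)[0] == pytest.approx(0.5)

    def test_single_row_trivial(self):
        codes = pd.DataFrame([[1, 2]], index=["A"], columns=["s1", "s2"])
        result = cluster_profiles(codes)
        assert result.order == ["A"]

    def test_planted_groups_recovered(self, rng):
        profiles = {"g1": [1] * 8, "g2": [3] * 8, "g3": [1] * 4 + [3] * 4, "g4": [2] * 8}
        rows, ids, labels = [], [], []
        for g, base in profiles.items():
            for i in range(5):
                row = list(base)
                j = rng.integers(0, 8)
                row[j] = int(rng.integers(1, 4))  # one noisy assay
                rows.append(row)
                ids.append(f"{g}-{i}")
                labels.append(g)
        codes = pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(8)])
        result = cluster_profiles(codes)
        flat = flat_clusters(result, 4)
        truth = pd.Series(labels, index=ids).sort_index()
        # each recovered cluster should be dominated by one planted group
        purity = (
            pd.DataFrame({"flat": flat, "truth": truth})
            .groupby("flat")["truth"]
            .agg(lambda s: s.value_counts().iloc[0] / len(s))
        )
        assert (purity >= 0.8).all()

    def test_newick_export_contains_all_leaves(self):
        codes = pd.DataFrame(
            [[1, 1], [3, 3], [1, 3]], index=["A", "B", "C"], columns=["s1", "s2"]
        )
        nwk = dendrogram_newick(cluster_profiles(codes))
        assert nwk.endswith(";")
        for leaf in "ABC":
            assert leaf in nwk
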