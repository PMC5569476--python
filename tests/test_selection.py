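"""Array-design pipeline: filter cascade, score rule, spacing, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from snparray.selection import (
    FilterConfig,
    STAGE_ORDER,
    annotate_snp_context,
    apply_design_score_rule,
    apply_hard_filters,
    average_spacing_kb,
    select_spaced_markers,
    share_percent,
    summarize_panel,
)


def _cand(id, chrom="c1", pos=1000, maf=0.3, het=0.05, acc=0.999,
          score=0.95, multi=False, region="intergenic", feature="none"):
    return {"id": id, "chrom": chrom, "pos": pos, "ref": "A", "alt": "G",
            "maf": maf, "het_rate": het, "accuracy": acc, "design_score": score,
            "multi_mapped": multi, "region_class": region, "feature": feature}


@pytest.fixture
def five_snps():
    """One clean SNP and four violating exactly one rule each."""
    return pd.DataFrame([
        _cand("s1", pos=1_000),
        _cand("s2", pos=50_000),              # inside repeat interval
        _cand("s3", pos=100_000),             # InDel 40 bp away
        _cand("s4", pos=150_000, het=0.20),   # heterozygosity too high
        _cand("s5", pos=200_000, maf=0.08),   # MAF too low
    ])


class TestHardFilters:
    def test_each_rule_removes_its_planted_violation(self, five_snps):
        mask = pd.DataFrame([{"chrom": "c1", "start": 49_900, "end": 50_100}])
        neigh = pd.DataFrame([{"chrom": "c1", "pos": 100_040}])
        survivors, report = apply_hard_filters(five_snps, FilterConfig(), mask, neigh)
        assert list(survivors["id"]) == ["s1"]
        removed = dict(zip(report["stage"], report["n_removed"]))
        assert removed == {"maf": 1, "accuracy": 0, "repeat": 1,
                           "flanking": 1, "heterozygosity": 1, "uniqueness": 0}

    def test_empty_input_yields_all_zero_report(self):
        empty = pd.DataFrame(columns=["id", "chrom", "pos", "maf", "het_rate",
                                      "accuracy", "multi_mapped"])
        survivors, report = apply_hard_filters(empty, FilterConfig())
        assert survivors.empty
        assert (report[["n_input", "n_removed", "n_surviving"]] == 0).all().all()
        assert list(report["stage"]) == list(STAGE_ORDER)

    def test_counts_conserve_at_every_stage(self, five_snps):
        mask = pd.DataFrame([{"chrom": "c1", "start": 49_900, "end": 50_100}])
        _, report = apply_hard_filters(five_snps, FilterConfig(), mask)
        assert (report["n_input"] == report["n_removed"] + report["n_surviving"]).all()
        # each stage's survivors feed the next stage
        assert (report["n_surviving"].values[:-1] == report["n_input"].values[1:]).all()

    def test_cascade_is_idempotent(self, five_snps):
        mask = pd.DataFrame([{"chrom": "c1", "start": 49_900, "end": 50_100}])
        neigh = pd.DataFrame([{"chrom": "c1", "pos": 100_040}])
        once, _ = apply_hard_filters(five_snps, FilterConfig(), mask, neigh)
        twice, _ = apply_hard_filters(once, FilterConfig(), mask, neigh)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))

    def test_survivors_independent_of_batching(self, five_snps):
        mask = pd.DataFrame([{"chrom": "c1", "start": 49_900, "end": 50_100}])
        neigh = pd.DataFrame([{"chrom": "c1", "pos": 100_040}])
        whole, _ = apply_hard_filters(five_snps, FilterConfig(), mask, neigh)
        parts = [apply_hard_filters(five_snps.iloc[i:i + 2], FilterConfig(),
                                    mask, neigh,
                                    known_chromosomes={"c1"})[0]
                 for i in range(0, len(five_snps), 2)]
        rejoined = pd.concat(parts).reset_index(drop=True)
        pd.testing.assert_frame_equal(whole.reset_index(drop=True), rejoined)

    def test_unknown_chromosome_in_mask_is_named(self, five_snps):
        mask = pd.DataFrame([{"chrom": "cX", "start": 1, "end": 10}])
        with pytest.raises(ValueError, match="cX"):
            apply_hard_filters(five_snps, FilterConfig(), mask)

    def test_malformed_interval_rejected(self, five_snps):
        mask = pd.DataFrame([{"chrom": "c1", "start": 100, "end": 50}])
        with pytest.raises(ValueError, match="malformed"):
            apply_hard_filters(five_snps, FilterConfig(), mask)


class TestDesignScoreRule:
    def test_genic_threshold(self):
        df = pd.DataFrame([_cand("a", region="genic", score=0.71),
                           _cand("b", pos=2000, region="genic", score=0.69)])
        kept = apply_design_score_rule(df)
        assert list(kept["id"]) == ["a"]

    def test_intergenic_threshold_is_stricter(self):
        df = pd.DataFrame([_cand("a", region="intergenic", score=0.89)])
        assert apply_design_score_rule(df).empty

    def test_perfect_scores_all_kept(self):
        df = pd.DataFrame([_cand(f"x{i}", pos=1000 * (i + 1), score=1.0,
                                 region="genic" if i % 2 else "intergenic")
                           for i in range(6)])
        assert len(apply_design_score_rule(df)) == 6

    def test_missing_score_lists_offenders(self):
        df = pd.DataFrame([_cand("a"), _cand("b", pos=2000, score=np.nan)])
        with pytest.raises(ValueError, match="b"):
            apply_design_score_rule(df)


def _dp_max_spaced(positions, gap):
    """DP oracle: maximum number of positions with all pairwise gaps > gap."""
    pos = sorted(positions)
    n = len(pos)
    if n == 0:
        return 0
    best = [1] * n
    for i in range(n):
        for j in range(i):
            if pos[i] - pos[j] > gap and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
    return max(best)


class TestSpacing:
    def test_hand_example(self):
        df = pd.DataFrame([_cand(f"p{p}", pos=p) for p in [100, 1500, 2700, 5000]])
        panel = select_spaced_markers(df, 2100, mode="max_count")
        assert list(panel["pos"]) == [100, 2700, 5000]

    def test_single_candidate_kept(self):
        df = pd.DataFrame([_cand("only")])
        assert len(select_spaced_markers(df, 2100)) == 1

    def test_score_priority_keeps_best_in_window(self):
        df = pd.DataFrame([_cand("a", pos=100, score=0.8),
                           _cand("b", pos=600, score=0.95),
                           _cand("c", pos=1100, score=0.9),
                           _cand("d", pos=1600, score=0.85)])
        panel = select_spaced_markers(df, 2100, mode="score_priority")
        assert list(panel["id"]) == ["b"]

    def test_duplicate_position_rejected(self):
        df = pd.DataFrame([_cand("a", pos=100), _cand("b", pos=100)])
        with pytest.raises(ValueError, match="duplicate"):
            select_spaced_markers(df, 2100)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(min_value=1, max_value=50_000),
                    min_size=1, max_size=20, unique=True),
           st.integers(min_value=100, max_value=5000))
    def test_max_count_matches_dp_oracle(self, positions, gap):
        df = pd.DataFrame([_cand(f"p{p}", pos=p) for p in positions])
        panel = select_spaced_markers(df, gap, mode="max_count")
        assert len(panel) == _dp_max_spaced(positions, gap)
        assert (np.diff(panel["pos"]) > gap).all()


class TestAnnotation:
    @pytest.fixture
    def features(self):
        return pd.DataFrame([
            {"chrom": "c1", "start": 1000, "end": 6000, "ftype": "gene", "gene_id": "g1"},
            {"chrom": "c1", "start": 1000, "end": 1200, "ftype": "UTR", "gene_id": "g1"},
            {"chrom": "c1", "start": 1201, "end": 2000, "ftype": "exon", "gene_id": "g1"},
        ])

    @pytest.mark.parametrize("pos,region,feature", [
        (1500, "genic", "exon"),
        (1100, "genic", "UTR"),
        (3000, "genic", "intron"),
        (9000, "intergenic", "none"),
    ])
    def test_precedence(self, features, pos, region, feature):
        df = pd.DataFrame([_cand("x", pos=pos)]).drop(columns=["region_class", "feature"])
        out = annotate_snp_context(df, features)
        assert out.loc[0, "region_class"] == region
        assert out.loc[0, "feature"] == feature

    def test_feature_outside_parent_gene_warns_and_is_ignored(self, features):
        bad = pd.concat([features, pd.DataFrame([
            {"chrom": "c1", "start": 8000, "end": 9000, "ftype": "exon",
             "gene_id": "g1"}])], ignore_index=True)
        df = pd.DataFrame([_cand("x", pos=8500)]).drop(columns=["region_class", "feature"])
        with pytest.warns(UserWarning, match="outside its parent"):
            out = annotate_snp_context(df, bad)
        assert out.loc[0, "region_class"] == "intergenic"


class TestSummaries:
    def test_average_spacing_definition(self):
        # one marker on a chromosome of length L -> average distance L
        assert average_spacing_kb(1, 1234.5) == 1234.5
        assert np.isnan(average_spacing_kb(0, 1000.0))

    def test_summary_shares_and_counts(self, rng):
        layout = pd.DataFrame({"chrom": ["c1", "c2"],
                               "length_bp": [1_000_000, 500_000],
                               "subgenome": ["At", "Dt"]})
        rows = []
        for chrom, n in (("c1", 30), ("c2", 20)):
            pos = np.sort(rng.choice(np.arange(1000, 500_000, 100), n, replace=False))
            for i, p in enumerate(pos):
                rows.append(_cand(f"{chrom}_{i}", chrom=chrom, pos=int(p),
                                  region="genic" if i % 3 == 0 else "intergenic",
                                  feature="exon" if i % 3 == 0 else "none"))
        panel = pd.DataFrame(rows)
        summ = summarize_panel(panel, layout)
        assert summ.n_total == 50
        assert summ.per_chromosome["n_snps"].sum() == summ.n_total
        assert abs(summ.subgenomes["share_pct"].sum() - 100.0) < 0.02
        assert abs(summ.regions["share_pct"].sum() - 100.0) < 0.02
        assert abs(summ.gap_histogram["share_pct"].sum() - 100.0) < 0.02
        c1 = summ.per_chromosome.set_index("chrom")
        assert c1.loc["c1", "avg_distance_kb"] == round(1000.0 / 30, 1)

    def test_zero_marker_chromosome_is_nan_not_error(self):
        layout = pd.DataFrame({"chrom": ["c1", "c2"],
                               "length_bp": [1_000_000, 500_000],
                               "subgenome": ["At", "Dt"]})
        panel = pd.DataFrame([_cand("a", chrom="c1", pos=10)])
        summ = summarize_panel(panel, layout)
        row = summ.per_chromosome.set_index("chrom").loc["c2"]
        assert np.isnan(row["avg_distance_kb"])

    def test_share_percent(self):
        assert share_percent(45183, 77774) == 58.10
        assert np.isnan(share_percent(1, 0))
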