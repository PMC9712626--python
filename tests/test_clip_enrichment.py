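import numpy as np
import pandas as pd
import pytest
from scipy import stats


from irtax.clip_enrichment import (
    REGION_NAMES,
    SCOPES,
    ClipError,
    build_hit_matrix,
    cluster_groups,
    define_regions,
    group_enrichment,
    per_intron_enrichment,
    significant_rbps,
)
from irtax.types import CrosslinkTrack, IntronRecord


def _intron(start=1000, end=1200, strand="+", chrom="chr1", iid="i1", gene="g1"):
    return IntronRecord(iid, gene, chrom, start, end, strand, start - 60, end + 60)


class TestDefineRegions:
    def test_plus_strand_hand_computed(self):
        rs = define_regions(_intron())
        assert rs.regions == {
            "R1": (970, 1000),
            "R2": (1000, 1030),
            "R3": (1085, 1115),
            "R4": (1170, 1200),
            "R5": (1200, 1230),
        }
        assert all(rs.valid.values())

    def test_short_intron_intronic_regions_invalid(self):
        rs = define_regions(_intron(end=1060))
        assert not rs.valid["R2"] and not rs.valid["R3"] and not rs.valid["R4"]
        assert rs.valid["R1"] and rs.valid["R5"]

    def test_short_flanking_exon_invalidates_exonic_region(self):
        iv = IntronRecord("i1", "g1", "chr1", 1000, 1200, "+", 980, 1260)
        rs = define_regions(iv)
        assert not rs.valid["R1"] and rs.valid["R5"]

    def test_minus_strand_is_mirror_of_plus(self):
        """Regions of a minus-strand intron equal the coordinate-flipped plus-strand ones."""
        L = 2000  # mirror the plus-strand locus through x -> L - x
        plus = _intron()
        minus = IntronRecord(
            "i1", "g1", "chr1", L - plus.end, L - plus.start, "-",
            L - plus.downstream_exon_end, L - plus.upstream_exon_start,
        )
        rp, rm = define_regions(plus), define_regions(minus)
        for name in REGION_NAMES:
            ps, pe = rp.regions[name]
            ms, me = rm.regions[name]
            # R3 centring uses floor(), so the mirror may shift by the width parity
            assert (ms, me) == (L - pe, L - ps) or name == "R3"
        ms, me = rm.regions["R3"]
        ps, pe = rp.regions["R3"]
        assert abs(ms - (L - pe)) <= 1 and abs(me - (L - ps)) <= 1

    def test_region_widths_always_30(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            start = int(rng.integers(100, 5000))
            length = int(rng.integers(91, 800))
            strand = "+" if rng.random() < 0.5 else "-"
            rs = define_regions(_intron(start, start + length, strand))
            for name in REGION_NAMES:
                if rs.valid[name]:
                    lo, hi = rs.regions[name]
                    assert hi - lo == 30
            # R2/R4 abut the splice sites exactly
            iv_start, iv_end = start, start + length
            if strand == "+":
                assert rs.regions["R2"][0] == iv_start and rs.regions["R4"][1] == iv_end
            else:
                assert rs.regions["R2"][1] == iv_end and rs.regions["R4"][0] == iv_start


class TestHitMatrix:
    def test_single_event_in_r2(self):
        iv = _intron()
        track = CrosslinkTrack("RBPA", {("chr1", 1010, "+")})
        hits = build_hit_matrix([track], [define_regions(iv)], [iv])
        got = {s: bool(hits.hits[0, 0, SCOPES.index(s)]) for s in SCOPES}
        assert got == {
            "R1": False, "R2": True, "R3": False, "R4": False, "R5": False,
            "whole_intron": True,
        }

    def test_opposite_strand_event_ignored(self):
        iv = _intron()
        track = CrosslinkTrack("RBPA", {("chr1", 1010, "-")})
        hits = build_hit_matrix([track], [define_regions(iv)], [iv])
        assert not hits.hits.any()

    def test_unknown_chromosome_warned_and_counted(self):
        iv = _intron()
        track = CrosslinkTrack("RBPA", {("chrUn", 1010, "+")})
        with pytest.warns(UserWarning, match="unknown"):
            hits = build_hit_matrix([track], [define_regions(iv)], [iv])
        assert hits.skipped_events == 1

    def test_whole_intron_implied_by_intronic_region_hits(self):
        rng = np.random.default_rng(1)
        introns = [_intron(1000 + 3000 * k, 1000 + 3000 * k + 300, iid=f"i{k}") for k in range(10)]
        tracks = [
            CrosslinkTrack(
                f"R{j}",
                {("chr1", int(rng.integers(0, 32000)), "+") for _ in range(200)},
            )
            for j in range(3)
        ]
        hits = build_hit_matrix(tracks, [define_regions(iv) for iv in introns], introns)
        for r in ("R2", "R3", "R4"):
            idx = SCOPES.index(r)
            implied = hits.hits[:, :, idx] & ~hits.hits[:, :, SCOPES.index("whole_intron")]
            assert not implied.any()

    def test_matches_membership_loop_oracle(self):
        rng = np.random.default_rng(2)
        # random introns on two chromosomes, random strands
        introns = []
        for k in range(15):
            start = int(rng.integers(100, 20000))
            introns.append(
                _intron(start, start + int(rng.integers(91, 500)),
                        "+" if rng.random() < 0.5 else "-",
                        chrom=f"chr{rng.integers(1, 3)}", iid=f"i{k}")
            )
        events = {
            (f"chr{rng.integers(1, 3)}", int(rng.integers(0, 21000)),
             "+" if rng.random() < 0.5 else "-")
            for _ in range(1000)
        }
        track = CrosslinkTrack("RBPA", events)
        region_sets = [define_regions(iv) for iv in introns]
        hits = build_hit_matrix([track], region_sets, introns)
        for i, (iv, rs) in enumerate(zip(introns, region_sets)):
            for name in REGION_NAMES:
                win = rs.regions[name]
                if win is None:
                    continue
                expected = any(
                    c == iv.chrom and s == iv.strand and win[0] <= p < win[1]
                    for c, p, s in events
                )
                assert bool(hits.hits[i, 0, SCOPES.index(name)]) == expected
            expected_whole = sum(
                1 for c, p, s in events
                if c == iv.chrom and s == iv.strand and iv.start <= p < iv.end
            )
            assert hits.whole_intron_counts[i, 0] == expected_whole


def _toy_hits(flags, rbp="RBPA"):
    """HitMatrix with given whole-intron booleans for one RBP."""
    n = len(flags)
    ids = [f"i{k}" for k in range(n)]
    hits = np.zeros((n, 1, len(SCOPES)), dtype=bool)
    hits[:, 0, SCOPES.index("whole_intron")] = flags
    valid = pd.DataFrame(True, index=ids, columns=list(REGION_NAMES))
    from irtax.clip_enrichment import HitMatrix

    return HitMatrix(ids, [rbp], hits, np.zeros((n, 1), int), valid)


class TestGroupEnrichment:
    def test_group_equals_background_is_one(self):
        hm = _toy_hits([True] * 4 + [False] * 6)
        rows = group_enrichment(hm, set(hm.intron_ids), set(hm.intron_ids), "whole_intron")
        assert rows[0].enrichment == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        flags = [True] * 4 + [False] * 6 + [True] * 16 + [False] * 74
        hm = _toy_hits(flags)
        group = set(hm.intron_ids[:10])
        rows = group_enrichment(hm, group, set(hm.intron_ids), "whole_intron")
        assert rows[0].fraction_group == pytest.approx(0.4)
        assert rows[0].fraction_background == pytest.approx(0.2)
        assert rows[0].enrichment == pytest.approx(2.0)

    def test_zero_background_fraction_undefined(self):
        hm = _toy_hits([False] * 10)
        rows = group_enrichment(hm, set(hm.intron_ids[:3]), set(hm.intron_ids), "whole_intron")
        assert np.isnan(rows[0].enrichment)

    def test_group_not_subset_rejected(self):
        hm = _toy_hits([True] * 5)
        with pytest.raises(ClipError, match="subset"):
            group_enrichment(hm, {"zz"}, set(hm.intron_ids), "whole_intron")

    def test_fisher_matches_hypergeometric_enumeration(self):
        """One-sided Fisher p equals the exact hypergeometric tail on small tables."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(6, 31))
            flags = rng.random(n) < rng.uniform(0.2, 0.8)
            hm = _toy_hits(list(flags))
            gsize = int(rng.integers(2, n - 1))
            group = set(hm.intron_ids[:gsize])
            row = group_enrichment(hm, group, set(hm.intron_ids), "whole_intron")[0]
            k = int(flags[:gsize].sum())
            K = int(flags.sum())
            # tail enumeration: P(X >= k), X ~ Hypergeom(n, K, gsize)
            expected = sum(
                stats.hypergeom.pmf(x, n, K, gsize)
                for x in range(k, min(K, gsize) + 1)
            )
            assert row.p_value == pytest.approx(expected, abs=1e-9)


class TestPerIntronEnrichment:
    def test_equal_rates_give_one(self):
        retained = _intron(1000, 1100, iid="r1")
        other = _intron(2000, 2200, iid="nr1")
        events = {("chr1", 1000 + p, "+") for p in range(0, 100, 10)}  # 10 in 100 nt
        events |= {("chr1", 2000 + p, "+") for p in range(0, 200, 10)}  # 20 in 200 nt
        track = CrosslinkTrack("A", events)
        assert per_intron_enrichment([track], retained, [other]) == pytest.approx(1.0)

    def test_double_rate_gives_two(self):
        retained = _intron(1000, 1100, iid="r1")
        other = _intron(2000, 2200, iid="nr1")
        events = {("chr1", 1000 + p, "+") for p in range(0, 100, 5)}  # rate 0.2
        events |= {("chr1", 2000 + p, "+") for p in range(0, 200, 10)}  # rate 0.1
        assert per_intron_enrichment([CrosslinkTrack("A", events)], retained, [other]) == pytest.approx(2.0)

    def test_no_nonretained_introns_undefined(self):
        with pytest.raises(ClipError, match="nonretained"):
            per_intron_enrichment([], _intron(), [])

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(4)
        retained = _intron(500, 900, iid="r1")
        others = [_intron(2000, 2300, iid="nr1"), _intron(4000, 4500, iid="nr2")]
        events = {("chr1", int(rng.integers(0, 5000)), "+") for _ in range(400)}
        track = CrosslinkTrack("A", events)
        n_r = sum(1 for c, p, s in events if 500 <= p < 900 and s == "+")
        n_b = sum(1 for c, p, s in events if 2000 <= p < 2300 or 4000 <= p < 4500)
        expected = (n_r / 400) / (n_b / 800)
        assert per_intron_enrichment([track], retained, others) == pytest.approx(expected)


class TestSignificantAndClustering:
    def test_significant_rbps_excludes_depletion(self):
        from irtax.clip_enrichment import EnrichmentRow

        rows = [
            EnrichmentRow("g", "A", "whole_intron", 0.3, 0.2, 1.5, 0.005, 10, 100),
            EnrichmentRow("g", "B", "whole_intron", 0.1, 0.2, 0.5, 0.005, 10, 100),
            EnrichmentRow("g", "C", "whole_intron", 0.3, 0.2, 1.5, 0.05, 10, 100),
        ]
        assert significant_rbps(rows, alpha=0.01) == {"A"}

    @staticmethod
    def _table(profiles):
        rows = []
        for g, vec in profiles.items():
            for j, (rbp, scope) in enumerate(
                [(r, s) for r in ("X", "Y") for s in ("R1", "R2", "R3")]
            ):
                rows.append(
                    {"group": g, "rbp": rbp, "scope": scope, "enrichment": vec[j]}
                )
        return pd.DataFrame(rows)

    def test_identical_groups_merge_first_at_zero(self):
        table = self._table({"A": [1, 2, 3, 1, 2, 3], "B": [1, 2, 3, 1, 2, 3], "C": [9] * 6})
        linkage, groups = cluster_groups(table, scopes=("R1", "R2", "R3"))
        assert sorted([groups[int(linkage[0, 0])], groups[int(linkage[0, 1])]]) == ["A", "B"]
        assert linkage[0, 2] == pytest.approx(0.0)

    def test_planted_pair_merges_before_outlier(self):
        table = self._table(
            {"A": [1, 1, 1, 1, 1, 1], "B": [1.1] * 6, "C": [5] * 6}
        )
        linkage, groups = cluster_groups(table, scopes=("R1", "R2", "R3"))
        first = sorted([groups[int(linkage[0, 0])], groups[int(linkage[0, 1])]])
        assert first == ["A", "B"]

    def test_input_order_invariant_topology(self):
        profiles = {"A": [1, 2, 1, 2, 1, 2], "B": [1, 2, 1.2, 2, 1, 2], "C": [4, 0, 4, 0, 4, 0],
                    "D": [4.1, 0, 4, 0.1, 4, 0]}
        t1 = self._table(profiles)
        t2 = self._table(dict(reversed(list(profiles.items()))))
        l1, g1 = cluster_groups(t1, scopes=("R1", "R2", "R3"))
        l2, g2 = cluster_groups(t2, scopes=("R1", "R2", "R3"))
        assert g1 == g2  # groups sorted by label first
        assert np.allclose(l1, l2)

    def test_single_group_rejected(self):
        table = self._table({"A": [1] * 6})
        with pytest.raises(ClipError, match=">= 2"):
            cluster_groups(table, scopes=("R1", "R2", "R3"))
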