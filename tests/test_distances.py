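"""K2P distance engine, haplotype collapsing, distance summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import barcodelim as bl
from barcodelim.core_io import ValidationError
from barcodelim.distances import NoOverlapError, SitePairCounts

from tests.conftest import make_aln, make_dm


def naive_k2p_pair(seq_a, seq_b):
    """Per-pair site loop: the independent oracle for pairwise_k2p."""
    pur = set("AG")
    ts = tv = n = 0
    for x, y in zip(seq_a, seq_b):
        if x in "N-" or y in "N-":
            continue
        n += 1
        if x == y:
            continue
        if (x in pur) == (y in pur):
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    a, b = 1 - 2 * P - Q, 1 - 2 * Q
    if a <= 0 or b <= 0:
        return float("nan"), n
    return -0.5 * math.log(a * math.sqrt(b)), n


class TestClosedForm:
    @pytest.mark.parametrize(
        "P,Q,expected",
        [
            (0.0, 0.0, 0.0),
            (0.1, 0.05, 0.17018116514034713),  # -1/2 ln(0.75 sqrt(0.9))
        ],
    )
    def test_values(self, P, Q, expected):
        got = bl.k2p_distance(SitePairCounts(P, Q, 600))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_saturation_is_nan(self):
        assert np.isnan(bl.k2p_distance(SitePairCounts(0.5, 0.0, 600)))
        assert np.isnan(bl.k2p_distance(SitePairCounts(0.2, 0.5, 600)))

    def test_no_overlap_rejected(self):
        with pytest.raises(NoOverlapError):
            SitePairCounts(0.1, 0.1, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0, 0.45), st.floats(0, 0.45))
    def test_correction_dominates_p_distance(self, P, Q):
        """Multiple-hit correction can only increase the raw proportion."""
        if 1 - 2 * P - Q <= 1e-9 or 1 - 2 * Q <= 1e-9 or P + Q > 1:
            return
        d = bl.k2p_distance(SitePairCounts(P, Q, 600))
        assert d >= P + Q - 1e-12


class TestPairwise:
    def test_identical_sequences(self):
        aln = make_aln({"a": "ACGT" * 150, "b": "ACGT" * 150})
        dm = bl.pairwise_k2p(aln)
        assert dm.d[0, 1] == 0.0
        assert dm.comparable_sites[0, 1] == 600

    def test_three_transitions_hand_count(self):
        base = list("ACGT" * 150)
        mut = base.copy()
        for pos in (0, 8, 16):  # A -> G transitions
            assert mut[pos] == "A"
            mut[pos] = "G"
        dm = bl.pairwise_k2p(make_aln({"a": "".join(base), "b": "".join(mut)}))
        expected = bl.k2p_distance(SitePairCounts(3 / 600, 0.0, 600))
        assert dm.d[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_all_n_sequence_is_no_overlap(self):
        aln = make_aln({"a": "ACGT" * 3, "b": "N" * 12})
        with pytest.raises(NoOverlapError, match="b"):
            bl.pairwise_k2p(aln)

    def test_matches_site_loop_oracle(self, rng):
        """Vectorized engine vs naive per-pair loop on random alignments."""
        bases = np.array(list("ACGTN-"))
        for _ in range(5):
            probs = [0.22, 0.22, 0.22, 0.22, 0.06, 0.06]
            seqs = {
                f"s{i}": "".join(rng.choice(bases, size=100, p=probs))
                for i in range(10)
            }
            # ensure pairwise overlap
            for k in seqs:
                seqs[k] = "ACGT" + seqs[k][4:]
            aln = make_aln(seqs)
            dm = bl.pairwise_k2p(aln)
            for i, (ida, sa) in enumerate(aln.records):
                for j in range(i + 1, len(aln)):
                    idb, sb = aln.records[j]
                    want, n = naive_k2p_pair(sa, sb)
                    assert dm.comparable_sites[i, j] == n
                    if np.isnan(want):
                        assert np.isnan(dm.d[i, j])
                    else:
                        assert dm.d[i, j] == pytest.approx(want, abs=1e-12)


class TestHaplotypes:
    def test_all_distinct_identity(self):
        seqs = {f"s{i}": "ACGT" * 2 + "ACGT"[i % 4] * 4 for i in range(4)}
        collapsed, mapping = bl.collapse_haplotypes(make_aln(seqs))
        assert len(collapsed) == 4
        assert all(mapping[k] == [k] for k in mapping)

    def test_groups_collapse_to_smallest_id(self):
        seqs = {"c": "AAAA", "a": "AAAA", "b": "AAAA", "e": "CCCC", "d": "CCCC"}
        collapsed, mapping = bl.collapse_haplotypes(make_aln(seqs))
        assert sorted(collapsed.ids) == ["a", "d"]
        assert mapping == {"a": ["a", "b", "c"], "d": ["d", "e"]}
        # expansion recovers the original specimen set exactly
        assert sorted(x for v in mapping.values() for x in v) == \
            sorted(seqs)

    def test_n_differences_not_collapsed(self):
        collapsed, _ = bl.collapse_haplotypes(
            make_aln({"a": "ACGT", "b": "ACNT"})
        )
        assert len(collapsed) == 2

    def test_expand_partition_total(self):
        seqs = {"a": "AAAA", "b": "AAAA", "c": "CCCC"}
        collapsed, mapping = bl.collapse_haplotypes(make_aln(seqs))
        part = bl.Partition({h: "g1" for h in collapsed.ids}, method="GMYC")
        full = bl.expand_partition(part, mapping)
        assert set(full.assignment) == {"a", "b", "c"}


class TestSummaries:
    def test_hand_example(self):
        dm = make_dm(
            ["A", "B", "C"],
            [[0, 0.01, 0.2], [0.01, 0, 0.2], [0.2, 0.2, 0]],
        )
        p = bl.Partition({"A": "c1", "B": "c1", "C": "c2"}, method="NJ2")
        s = bl.distance_summaries(dm, p)
        assert s.within_by_cluster["c1"] == pytest.approx(0.01)
        assert s.within_by_cluster["c2"] is None  # singleton: n/a, never 0
        assert s.mean_between == pytest.approx(0.2)
        assert s.n_singletons == 1

    def test_single_cluster_no_between(self):
        dm = make_dm(["A", "B"], [[0, 0.1], [0.1, 0]])
        p = bl.Partition({"A": "c1", "B": "c1"}, method="NJ2")
        s = bl.distance_summaries(dm, p)
        assert s.between_by_pair == {}
        assert s.mean_between is None

    def test_brute_force_oracle_random(self, rng):
        for _ in range(5):
            n = int(rng.integers(4, 12))
            d = rng.uniform(0.001, 0.3, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            ids = [f"s{i}" for i in range(n)]
            dm = make_dm(ids, d)
            labels = {sid: f"c{rng.integers(3)}" for sid in ids}
            p = bl.Partition(labels, method="NJ2")
            s = bl.distance_summaries(dm, p)
            within, between = [], []
            for i in range(n):
                for j in range(i + 1, n):
                    (within if labels[ids[i]] == labels[ids[j]]
                     else between).append(d[i, j])
            if within:
                assert s.mean_within == pytest.approx(np.mean(within))
            if between:
                assert s.mean_between == pytest.approx(np.mean(between))

    def test_clade_matrix_layout(self):
        dm = make_dm(
            ["A", "B", "C", "D"],
            [
                [0, 0.01, 0.2, 0.21],
                [0.01, 0, 0.19, 0.2],
                [0.2, 0.19, 0, 0.02],
                [0.21, 0.2, 0.02, 0],
            ],
        )
        p = bl.Partition({s: s for s in dm.ids}, method="NJ2")
        clades = {"A": "c1", "B": "c1", "C": "c2", "D": "c2"}
        m = bl.distance_summaries(dm, p, clades).clade_matrix
        assert m.loc["c1", "c1"] == pytest.approx(0.01)  # diagonal: within
        assert m.loc["c2", "c1"] == pytest.approx(0.2)   # below: between mean
        vals = [0.2, 0.21, 0.19, 0.2]
        se = np.std(vals, ddof=1) / 2.0
        assert m.loc["c1", "c2"] == pytest.approx(se)    # above: std error

    def test_partition_must_cover(self):
        dm = make_dm(["A", "B"], [[0, 0.1], [0.1, 0]])
        with pytest.raises(ValidationError):
            bl.distance_summaries(dm, bl.Partition({"A": "c"}, method="NJ2"))
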