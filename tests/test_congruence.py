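"""Pattern A-D classification and final OTU consensus."""

import itertools

import pytest

import barcodelim as bl
from barcodelim.congruence import (
    classify_patterns,
    cluster_agrees,
    method_count_table,
    pattern_percentages,
)
from barcodelim.core_io import Partition, ValidationError


def part(method, **clusters):
    """Partition from cluster_id -> members shorthand."""
    assignment = {}
    for cid, members in clusters.items():
        for m in members:
            assignment[m] = cid
    return Partition(assignment, method=method)


class TestClusterAgrees:
    def test_exact_match(self):
        other = part("ABGD", x="abc", y="de")
        assert cluster_agrees(frozenset("abc"), other)

    def test_split_is_disagreement(self):
        other = part("ABGD", x="ab", y="c", z="de")
        assert not cluster_agrees(frozenset("abc"), other)

    def test_merge_is_disagreement(self):
        other = part("ABGD", x="abcd", y="e")
        assert not cluster_agrees(frozenset("abc"), other)


class TestClassify:
    def test_all_identical_is_full_match(self):
        p = part("NJ2", c1="abc", c2="de", c3="f")
        report = classify_patterns(
            p,
            part("ABGD", c1="abc", c2="de", c3="f"),
            part("GMYC", c1="abc", c2="de", c3="f"),
            part("BIN", c1="abc", c2="de", c3="f"),
        )
        assert report.pattern_counts() == (3, 0, 0, 0)
        assert report.n_final_otus == 3
        assert pattern_percentages(report) == (100.0, 0.0, 0.0, 0.0)

    def test_pattern_b_two_agree(self):
        nj = part("NJ2", c1="abc", c2="de")
        abgd = part("ABGD", c1="abc", c2="de")
        gmyc = part("GMYC", c1="abc", c2="de")
        bin_ = part("BIN", x="ab", y="c", c2="de")  # splits c1
        report = classify_patterns(nj, abgd, gmyc, bin_)
        verdict = next(v for v in report.per_cluster.values()
                       if v.members == frozenset("abc"))
        assert verdict.pattern == "B"
        assert set(verdict.agreeing_methods) == {"ABGD", "GMYC"}

    def test_pattern_d_keeps_nj_cluster(self):
        nj = part("NJ2", c1="abcd")
        abgd = part("ABGD", x="ab", y="cd")
        gmyc = part("GMYC", x="abc", y="d")
        bin_ = part("BIN", x="a", y="bcd")
        report = classify_patterns(nj, abgd, gmyc, bin_)
        v = next(iter(report.per_cluster.values()))
        assert v.pattern == "D"
        assert v.final_otus == [frozenset("abcd")]

    def test_shared_split_adopted(self):
        """Two methods splitting an initial cluster the same way outvote it,
        so the final OTU count can exceed the initial cluster count."""
        nj = part("NJ2", c1="abcd", c2="ef")
        abgd = part("ABGD", x="ab", y="cd", c2="ef")
        gmyc = part("GMYC", x="ab", y="cd", c2="ef")
        bin_ = part("BIN", c1="abcd", c2="ef")
        report = classify_patterns(nj, abgd, gmyc, bin_)
        v = next(v for v in report.per_cluster.values()
                 if v.members == frozenset("abcd"))
        assert v.pattern == "C"  # only BIN agrees with NJ
        assert set(v.final_otus) == {frozenset("ab"), frozenset("cd")}
        assert set(v.split_adopted_from) == {"ABGD", "GMYC"}
        assert report.n_final_otus == 3

    def test_method_order_invariance(self):
        nj = part("NJ2", c1="abc", c2="de", c3="fg")
        others = {
            "ABGD": part("ABGD", c1="abc", x="d", y="e", c3="fg"),
            "GMYC": part("GMYC", c1="abc", c2="de", x="f", y="g"),
            "BIN": part("BIN", c1="abc", c2="de", c3="fg"),
        }
        baseline = None
        for order in itertools.permutations(["ABGD", "GMYC", "BIN"]):
            relabeled = {
                "ABGD": Partition(others[order[0]].assignment, "ABGD"),
                "GMYC": Partition(others[order[1]].assignment, "GMYC"),
                "BIN": Partition(others[order[2]].assignment, "BIN"),
            }
            report = classify_patterns(
                nj, relabeled["ABGD"], relabeled["GMYC"], relabeled["BIN"]
            )
            counts = report.pattern_counts()
            if baseline is None:
                baseline = counts
            assert counts == baseline

    def test_final_otus_partition_universe(self):
        aln, truth = bl.simulate_dataset(
            bl.SimConfig(n_species=8, n_clades=2, seed=6,
                         min_species_split=0.12)
        )
        dm = bl.pairwise_k2p(aln)
        nj = bl.threshold_clusters(dm, 0.02, method="NJ2")
        abgd = list(bl.abgd_partition(dm).values())[0]
        gmyc_part = Partition(dict(truth.species_partition.assignment),
                              "GMYC")
        report = classify_patterns(nj, abgd, gmyc_part,
                                   bl.bin_partition(dm))
        universe = set(aln.ids)
        assert set(report.final_partition.assignment) == universe
        counted = sum(
            len(o) for v in report.per_cluster.values() for o in v.final_otus
        )
        assert counted == len(universe)

    def test_coverage_violation_names_specimens(self):
        nj = part("NJ2", c1="abc")
        abgd = part("ABGD", c1="ab")
        with pytest.raises(ValidationError, match="c"):
            classify_patterns(nj, abgd, part("GMYC", c1="abc"))

    def test_partial_bin_abstains(self):
        """A cluster with <50% BIN coverage is scored from ABGD+GMYC only;
        the best attainable pattern is then B."""
        nj = part("NJ2", c1="abcd", c2="ef")
        abgd = part("ABGD", c1="abcd", c2="ef")
        gmyc = part("GMYC", c1="abcd", c2="ef")
        bin_ = part("BIN", x="a", c2="ef")  # covers 1/4 of c1
        report = classify_patterns(nj, abgd, gmyc, bin_)
        v = next(v for v in report.per_cluster.values()
                 if v.members == frozenset("abcd"))
        assert v.bin_abstained and v.pattern == "B"
        v2 = next(v for v in report.per_cluster.values()
                  if v.members == frozenset("ef"))
        assert not v2.bin_abstained and v2.pattern == "A"

    def test_absent_bin(self):
        nj = part("NJ2", c1="abc")
        report = classify_patterns(nj, part("ABGD", c1="abc"),
                                   part("GMYC", c1="abc"), None)
        assert next(iter(report.per_cluster.values())).pattern == "B"


class TestPercentages:
    def test_paper_arithmetic(self):
        """Counts (63, 41, 17, 4) over 125 OTUs give the published
        percentage split 50.4 / 32.8 / 13.6 / 3.2."""
        nj_clusters = {}
        sid = 0
        expected = []
        for pat, count in zip("ABCD", (63, 41, 17, 4)):
            for _ in range(count):
                nj_clusters[f"c{sid}"] = [f"s{sid}a", f"s{sid}b", f"s{sid}c"]
                expected.append(pat)
                sid += 1
        nj = part("NJ2", **nj_clusters)
        # build method partitions realizing each cluster's target pattern;
        # disagreeing methods split differently from each other so the
        # shared-split adoption rule never fires
        parts = {"ABGD": {}, "GMYC": {}, "BIN": {}}
        agree_sets = {"A": ("ABGD", "GMYC", "BIN"), "B": ("ABGD", "GMYC"),
                      "C": ("ABGD",), "D": ()}
        splits = {
            "ABGD": [[0], [1, 2]],
            "GMYC": [[0, 1], [2]],
            "BIN": [[0], [1], [2]],
        }
        for (cid, members), pat in zip(nj_clusters.items(), expected):
            for m in parts:
                if m in agree_sets[pat]:
                    for x in members:
                        parts[m][x] = cid
                else:
                    for g, idxs in enumerate(splits[m]):
                        for k in idxs:
                            parts[m][members[k]] = f"{cid}_{g}"
        report = classify_patterns(
            nj, Partition(parts["ABGD"], "ABGD"),
            Partition(parts["GMYC"], "GMYC"), Partition(parts["BIN"], "BIN"),
        )
        assert report.pattern_counts() == (63, 41, 17, 4)
        assert pattern_percentages(report) == (50.4, 32.8, 13.6, 3.2)

    def test_single_pattern(self):
        p = part("NJ2", **{f"c{i}": [f"s{i}", f"t{i}"] for i in range(5)})
        report = classify_patterns(
            p, Partition(p.assignment, "ABGD"),
            Partition(p.assignment, "GMYC"), Partition(p.assignment, "BIN"),
        )
        assert pattern_percentages(report) == (100.0, 0.0, 0.0, 0.0)

    def test_sums_to_hundred(self):
        counts = (63, 41, 17, 4)
        assert abs(sum((100.0 * c / 125) for c in counts) - 100.0) < 0.1


class TestMethodCounts:
    def test_single_partition_no_clades(self):
        p = part("NJ2", **{f"c{i}": [f"s{i}"] for i in range(7)})
        table = method_count_table([p])
        assert table.loc["all", "NJ2"] == 7

    def test_per_clade_counts(self):
        p = part("NJ2", c1="ab", c2="cd", c3="ef")
        clades = {x: ("cladeA" if x in "abcd" else "cladeB") for x in "abcdef"}
        table = method_count_table([p], clades)
        assert table.loc["cladeA", "NJ2"] == 2
        assert table.loc["cladeB", "NJ2"] == 1
        assert table.loc["all", "NJ2"] == 3
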