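"""Congruence classification of initial clusters and final OTU consensus.

Each initial 2%-cutoff cluster is tested against the three alternative
delimitations (ABGD, GMYC, BIN-style). A method *agrees* with a cluster when
that exact specimen set appears as one whole cluster of the method (same
members, nothing added, nothing removed). The number of agreeing methods
gives the pattern: 3 -> A (full match), 2 -> B, 1 -> C (partial matches),
0 -> D (discordant, in which case the OTU is the 2%-cutoff cluster itself).

Final OTUs: when at least two methods cleanly split an initial cluster into
the same sub-partition (every part being a whole cluster of each method),
that shared split is adopted; otherwise the initial cluster stands. The
adopted OTUs inherit the cluster's pattern label. BIN coverage may be
partial (records absent from the BIN analysis): uncovered specimens are
ignored in the BIN comparison, and when fewer than half of a cluster's
specimens are covered BIN abstains — the pattern is then the best
attainable from the remaining methods (2 agreements -> B, 1 -> C, 0 -> D).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core_io import Partition, ValidationError

logger = logging.getLogger("barcodelim")

PATTERNS = ("A", "B", "C", "D")


@dataclass
class ClusterVerdict:
    nj_cluster_id: str
    members: frozenset[str]
    pattern: str
    agreeing_methods: tuple[str, ...]
    bin_abstained: bool
    final_otus: list[frozenset[str]]
    split_adopted_from: tuple[str, ...] = ()


@dataclass
class CongruenceReport:
    per_cluster: dict[str, ClusterVerdict]
    totals: dict[str, int]
    method_counts: dict[str, int]
    n_final_otus: int
    final_partition: Partition = field(repr=False)

    def pattern_counts(self) -> tuple[int, int, int, int]:
        """Final-OTU counts per pattern (each adopted sub-OTU counts once)."""
        counts = dict.fromkeys(PATTERNS, 0)
        for verdict in self.per_cluster.values():
            counts[verdict.pattern] += len(verdict.final_otus)
        return tuple(counts[p] for p in PATTERNS)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, v in sorted(self.per_cluster.items()):
            rows.append({
                "nj_cluster_id": cid,
                "n_specimens": len(v.members),
                "pattern": v.pattern,
                "agreeing_methods": ",".join(v.agreeing_methods),
                "bin_abstained": v.bin_abstained,
                "n_final_otus": len(v.final_otus),
                "split_adopted_from": ",".join(v.split_adopted_from),
            })
        return pd.DataFrame(rows)


def cluster_agrees(nj_cluster: frozenset[str], other: Partition) -> bool:
    """True iff the specimen set is exactly one whole cluster of ``other``.

    Specimens the other partition does not cover are ignored; if nothing is
    covered the method cannot agree.
    """
    covered = nj_cluster & set(other.assignment)
    if not covered:
        return False
    labels = {other.assignment[s] for s in covered}
    if len(labels) != 1:
        return False
    label = labels.pop()
    other_members = {
        s for s, c in other.assignment.items() if c == label
    }
    return other_members == set(covered)


def _restriction(cluster: frozenset[str], other: Partition
                 ) -> list[frozenset[str]] | None:
    """The other method's sub-partition of the cluster, or None if any of
    its clusters straddles the boundary (not a clean split)."""
    covered = cluster & set(other.assignment)
    if covered != cluster:
        return None
    labels = {other.assignment[s] for s in cluster}
    parts = []
    for label in labels:
        members = frozenset(
            s for s, c in other.assignment.items() if c == label
        )
        if not members <= cluster:
            return None
        parts.append(members)
    return sorted(parts, key=min)


def classify_patterns(
    nj: Partition,
    abgd: Partition,
    gmyc: Partition,
    bin_: Partition | None = None,
) -> CongruenceReport:
    """Classify every initial cluster and assemble the final OTU table."""
    universe = set(nj.assignment)
    for name, part in (("ABGD", abgd), ("GMYC", gmyc)):
        missing = universe - set(part.assignment)
        if missing:
            raise ValidationError(
                f"{name} partition missing specimens: {sorted(missing)}"
            )

    methods: dict[str, Partition] = {"ABGD": abgd, "GMYC": gmyc}
    if bin_ is not None:
        methods["BIN"] = bin_

    per_cluster: dict[str, ClusterVerdict] = {}
    final_assignment: dict[str, str] = {}
    otu_no = 0
    for cid, members in sorted(nj.clusters().items(), key=lambda kv: min(kv[1])):
        active: dict[str, Partition] = {}
        bin_abstained = bin_ is None
        for name, part in methods.items():
            if name == "BIN":
                covered = members & set(part.assignment)
                if len(covered) < 0.5 * len(members):
                    bin_abstained = True
                    continue
            active[name] = part
        agreeing = tuple(
            name for name, part in active.items()
            if cluster_agrees(members, part)
        )
        if bin_abstained:
            # max attainable pattern from the two remaining methods
            pattern = {2: "B", 1: "C", 0: "D"}[len(agreeing)]
        else:
            pattern = {3: "A", 2: "B", 1: "C", 0: "D"}[len(agreeing)]

        if pattern == "D":
            # discordant: the OTU is the 2%-cutoff cluster itself
            final_otus, adopted_from = [members], ()
        else:
            final_otus, adopted_from = _final_otus(members, active, agreeing)
        for otu in final_otus:
            label = f"OTU{otu_no:04d}"
            otu_no += 1
            for sid in otu:
                final_assignment[sid] = label
        per_cluster[cid] = ClusterVerdict(
            nj_cluster_id=cid,
            members=members,
            pattern=pattern,
            agreeing_methods=agreeing,
            bin_abstained=bin_abstained,
            final_otus=final_otus,
            split_adopted_from=adopted_from,
        )

    final_partition = Partition(assignment=final_assignment, method="OTU")
    if set(final_assignment) != universe:
        raise ValidationError("final OTUs do not cover the specimen set")

    totals = dict.fromkeys(PATTERNS, 0)
    for v in per_cluster.values():
        totals[v.pattern] += len(v.final_otus)
    method_counts = {"NJ2": nj.n_clusters, "ABGD": abgd.n_clusters,
                     "GMYC": gmyc.n_clusters}
    if bin_ is not None:
        method_counts["BIN"] = bin_.n_clusters
    return CongruenceReport(
        per_cluster=per_cluster,
        totals=totals,
        method_counts=method_counts,
        n_final_otus=len(set(final_assignment.values())),
        final_partition=final_partition,
    )


def _final_otus(
    members: frozenset[str],
    active: dict[str, Partition],
    agreeing: tuple[str, ...],
) -> tuple[list[frozenset[str]], tuple[str, ...]]:
    """Adoption rule: a shared clean split by >=2 methods replaces the
    cluster; otherwise the cluster itself is the OTU."""
    splits: dict[tuple[frozenset[str], ...], list[str]] = {}
    for name, part in active.items():
        if name in agreeing:
            continue
        restriction = _restriction(members, part)
        if restriction is not None and len(restriction) > 1:
            splits.setdefault(tuple(restriction), []).append(name)
    for restriction, names in sorted(
        splits.items(), key=lambda kv: (-len(kv[1]), kv[1])
    ):
        if len(names) >= 2:
            logger.debug(
                "adopting %d-way split of cluster %s supported by %s",
                len(restriction), sorted(members)[0], names,
            )
            return list(restriction), tuple(sorted(names))
    return [members], ()


def pattern_percentages(report: CongruenceReport) -> tuple[float, float, float, float]:
    """Percent of final OTUs per pattern, to one decimal (sums to ~100)."""
    if report.n_final_otus == 0:
        raise ValidationError("empty report")
    counts = report.pattern_counts()
    return tuple(
        round(100.0 * c / report.n_final_otus, 1) for c in counts
    )


def method_count_table(
    partitions: list[Partition],
    clade_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Cluster counts per method, for all data and per clade when labelled.

    A cluster counts toward a clade row when at least one of its specimens
    carries that clade label; clusters spanning clades are logged.
    """
    if not partitions:
        raise ValidationError("need at least one partition")
    rows: dict[str, dict[str, int]] = {"all": {}}
    for part in partitions:
        rows["all"][part.method] = part.n_clusters
        if clade_labels:
            spanning = 0
            for clade in sorted({c for c in clade_labels.values() if c}):
                ids = {s for s, c in clade_labels.items() if c == clade}
                seen = {
                    cid for sid, cid in part.assignment.items() if sid in ids
                }
                rows.setdefault(clade, {})[part.method] = len(seen)
            for cid, members in part.clusters().items():
                clades_hit = {clade_labels.get(s) for s in members} - {None}
                if len(clades_hit) > 1:
                    spanning += 1
            if spanning:
                logger.info(
                    "%s: %d clusters span clade boundaries", part.method,
                    spanning,
                )
    return pd.DataFrame(rows).T.fillna(0).astype(int)
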