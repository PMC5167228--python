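"""Shared data model and file IO for the barcode delimitation pipeline.

The pipeline's raw input is an aligned set of COI barcode sequences plus a
specimen metadata table (nominal species, locality, optional clade label).
Intermediate artifacts are plain text: FASTA alignments, TSV metadata and
partitions, newick trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("barcodelim")

VALID_METHODS = ("NJ2", "ABGD", "GMYC", "BIN", "TRUTH", "OTU")

#: IUPAC ambiguity codes (other than N) collapsed to N on read; K2P treats N
#: as missing, so partial information in R/Y/... is deliberately discarded.
AMBIGUITY_CODES = set("RYSWKMBDHV")


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


@dataclass(frozen=True)
class SpecimenMeta:
    nominal_species: str
    locality: str
    clade_label: Optional[str] = None


@dataclass
class BarcodeAlignment:
    """Aligned barcode sequences with per-specimen metadata.

    Invariants (enforced by :meth:`validate`): equal sequence lengths, unique
    specimen ids, and a one-to-one correspondence between sequence records
    and metadata rows.
    """

    records: list[tuple[str, str]]
    metadata: dict[str, SpecimenMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, specimen_id: str) -> str:
        for sid, seq in self.records:
            if sid == specimen_id:
                return seq
        raise KeyError(specimen_id)

    def validate(self) -> None:
        ids = self.ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate specimen ids: {dupes}")
        if self.records:
            ref_len = len(self.records[0][1])
            for sid, seq in self.records:
                if len(seq) != ref_len:
                    raise ValidationError(
                        f"ragged alignment: record {sid!r} has length "
                        f"{len(seq)}, expected {ref_len}"
                    )
                bad = set(seq) - set("ACGTN-")
                if bad:
                    raise ValidationError(
                        f"record {sid!r} contains invalid symbols {sorted(bad)}"
                    )
        if self.metadata:
            fasta_ids, meta_ids = set(ids), set(self.metadata)
            if fasta_ids != meta_ids:
                missing = sorted(fasta_ids ^ meta_ids)
                raise ValidationError(
                    "FASTA/metadata specimen id mismatch (symmetric "
                    f"difference): {missing}"
                )

    def subset(self, keep_ids: list[str]) -> "BarcodeAlignment":
        keep = set(keep_ids)
        return BarcodeAlignment(
            records=[(s, q) for s, q in self.records if s in keep],
            metadata={s: m for s, m in self.metadata.items() if s in keep},
        )


@dataclass
class Partition:
    """A labeling of specimens into clusters, one per delimitation method."""

    assignment: dict[str, str]
    method: str

    def __post_init__(self) -> None:
        if self.method not in VALID_METHODS:
            raise ValidationError(
                f"unknown method {self.method!r}; expected one of {VALID_METHODS}"
            )
        for sid, cid in self.assignment.items():
            if not cid:
                raise ValidationError(f"empty cluster id for specimen {sid!r}")

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[str, frozenset[str]]:
        """cluster_id -> frozenset of member specimen ids."""
        out: dict[str, set[str]] = {}
        for sid, cid in self.assignment.items():
            out.setdefault(cid, set()).add(sid)
        return {cid: frozenset(m) for cid, m in out.items()}

    def cluster_sets(self) -> set[frozenset[str]]:
        return set(self.clusters().values())

    def singletons(self) -> list[str]:
        return sorted(
            next(iter(m)) for m in self.clusters().values() if len(m) == 1
        )

    def restrict(self, ids: set[str]) -> "Partition":
        return Partition(
            {s: c for s, c in self.assignment.items() if s in ids}, self.method
        )


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths; thin wrapper around a dendropy Tree.

    ``is_ultrametric`` is always computed from the branch lengths (relative
    tolerance 1e-9 on root-to-tip depths), never trusted from the source.
    """

    tree: dendropy.Tree
    is_ultrametric: bool = field(init=False)

    REL_TOL = 1e-9

    def __post_init__(self) -> None:
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(
                    f"negative branch length {edge.length} on edge to "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else 'internal node'}"
                )
        self.is_ultrametric = self._check_ultrametric()

    def _check_ultrametric(self) -> bool:
        depths = list(self.leaf_depths().values())
        if not depths:
            return False
        dmax = max(depths)
        if dmax == 0:
            return True
        return (dmax - min(depths)) <= self.REL_TOL * dmax

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-tip path length per leaf label."""
        out: dict[str, float] = {}
        for node in self.tree.preorder_node_iter():
            parent_depth = getattr(node.parent_node, "_bl_depth", 0.0) if node.parent_node else 0.0
            node._bl_depth = parent_depth + (node.edge.length or 0.0)
            if node.is_leaf():
                out[node.taxon.label] = node._bl_depth
        return out

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _clean_sequence(raw: str, counter: dict[str, int]) -> str:
    seq = raw.upper().replace("U", "T")
    out = []
    for ch in seq:
        if ch in AMBIGUITY_CODES:
            counter["ambiguous"] = counter.get("ambiguous", 0) + 1
            ch = "N"
        out.append(ch)
    return "".join(out)


def read_alignment(fasta_path: str | Path, metadata_path: str | Path) -> BarcodeAlignment:
    """Read an aligned FASTA plus its specimen metadata TSV.

    Sequences are uppercased, U mapped to T and non-N ambiguity codes mapped
    to N (count logged). The metadata TSV must have a header with columns
    ``specimen_id``, ``nominal_species``, ``locality`` and optionally
    ``clade_label``; it is the single source of species labels (FASTA header
    text beyond the id token is ignored).
    """
    counter: dict[str, int] = {}
    records = [
        (rec.id, _clean_sequence(str(rec.seq), counter))
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    if counter.get("ambiguous"):
        logger.info(
            "mapped %d ambiguous bases (non-N IUPAC codes) to N",
            counter["ambiguous"],
        )
    df = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"specimen_id", "nominal_species", "locality"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"metadata TSV missing columns {sorted(required - set(df.columns))}"
        )
    if df["specimen_id"].duplicated().any():
        dupes = sorted(df.loc[df["specimen_id"].duplicated(), "specimen_id"])
        raise ValidationError(f"duplicate specimen ids in metadata: {dupes}")
    has_clade = "clade_label" in df.columns
    metadata = {
        row.specimen_id: SpecimenMeta(
            nominal_species=row.nominal_species,
            locality=row.locality,
            clade_label=(getattr(row, "clade_label", None) if has_clade else None),
        )
        for row in df.itertuples()
    }
    return BarcodeAlignment(records=records, metadata=metadata)


def write_alignment(aln: BarcodeAlignment, fasta_path: str | Path,
                    metadata_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for sid, seq in aln.records:
            fh.write(f">{sid}\n{seq}\n")
    rows = []
    for sid in aln.ids:
        m = aln.metadata[sid]
        rows.append(
            {"specimen_id": sid, "nominal_species": m.nominal_species,
             "locality": m.locality, "clade_label": m.clade_label or ""}
        )
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def read_tree(newick_path: str | Path) -> PhyloTree:
    """Read a newick tree; branch lengths required, is_ultrametric computed."""
    text = Path(newick_path).read_text()
    return tree_from_newick(text)


def tree_from_newick(text: str) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"unparseable newick: {exc}") from exc
    return PhyloTree(tree)


def write_tree(ptree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(ptree.newick() + "\n")


def read_partition(path: str | Path) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"specimen_id", "cluster_id", "method"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"partition TSV missing columns {sorted(required - set(df.columns))}"
        )
    if df["specimen_id"].duplicated().any():
        dupes = sorted(df.loc[df["specimen_id"].duplicated(), "specimen_id"])
        raise ValidationError(f"specimen listed more than once: {dupes}")
    methods = df["method"].unique()
    if len(methods) != 1:
        raise ValidationError(f"partition file mixes methods: {sorted(methods)}")
    return Partition(
        assignment=dict(zip(df["specimen_id"], df["cluster_id"])),
        method=methods[0],
    )


def write_partition(p: Partition, path: str | Path) -> None:
    rows = [
        {"specimen_id": sid, "cluster_id": cid, "method": p.method}
        for sid, cid in sorted(p.assignment.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
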