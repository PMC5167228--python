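"""Kimura 2-parameter distances, haplotype collapsing and distance summaries.

K2P distinguishes transitions (A<->G, C<->T) from transversions and corrects
the raw proportions P (transitions) and Q (transversions) for multiple hits:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries N or a gap are excluded pairwise
(pairwise deletion). When a log argument is non-positive the pair is
saturated and the distance is undefined; undefined cells are carried as NaN
and treated as "always split" (+inf) by the clustering stages, never
silently zeroed or capped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import BarcodeAlignment, Partition, ValidationError

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

# integer encoding: A=0, G=1 (purines), C=2, T=3 (pyrimidines), missing=4
_ENCODE = {"A": 0, "G": 1, "C": 2, "T": 3, "N": 4, "-": 4}


class NoOverlapError(ValidationError):
    """A sequence pair shares zero comparable sites."""


@dataclass(frozen=True)
class SitePairCounts:
    """Transition/transversion proportions for one sequence pair."""

    P: float
    Q: float
    n_comparable: int

    def __post_init__(self) -> None:
        if self.n_comparable <= 0:
            raise NoOverlapError("pair has no comparable sites")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValidationError(f"invalid proportions P={self.P}, Q={self.Q}")


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix in substitutions/site.

    ``d`` holds NaN wherever the K2P correction is undefined (saturation);
    ``comparable_sites[i, j]`` is the number of sites both sequences resolve.
    """

    ids: list[str]
    d: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.comparable_sites.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(np.diagonal(self.d), 0.0):
            raise ValidationError("nonzero diagonal")
        # symmetry with NaN-aware comparison
        if not np.array_equal(self.d, self.d.T, equal_nan=True):
            raise ValidationError("distance matrix not symmetric")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_undefined(self) -> int:
        n = len(self.ids)
        return int(np.isnan(self.d[np.triu_indices(n, k=1)]).sum())

    def index(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def submatrix(self, keep_ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in keep_ids]
        return DistanceMatrix(
            ids=list(keep_ids),
            d=self.d[np.ix_(idx, idx)].copy(),
            comparable_sites=self.comparable_sites[np.ix_(idx, idx)].copy(),
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        n = len(self.ids)
        return self.d[np.triu_indices(n, k=1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="specimen_id")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(i) for i in df.index]
        d = df.to_numpy(dtype=float)
        ncomp = np.full_like(d, -1, dtype=int)  # unknown after round-trip
        return cls(ids=ids, d=d, comparable_sites=ncomp)


def k2p_distance(counts: SitePairCounts) -> float:
    """K2P distance from transition/transversion proportions.

    Returns NaN when the correction is undefined (saturated pair), i.e. when
    1 - 2P - Q <= 0 or 1 - 2Q <= 0.
    """
    a = 1.0 - 2.0 * counts.P - counts.Q
    b = 1.0 - 2.0 * counts.Q
    if a <= 0.0 or b <= 0.0:
        return float("nan")
    return -0.5 * np.log(a * np.sqrt(b))


def encode_alignment(aln: BarcodeAlignment) -> np.ndarray:
    """(n_specimens, n_sites) int8 matrix in the A/G/C/T/missing code."""
    lut = np.full(128, 4, dtype=np.int8)
    for ch, code in _ENCODE.items():
        lut[ord(ch)] = code
    rows = [
        lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        for _, seq in aln.records
    ]
    return np.vstack(rows) if rows else np.empty((0, 0), dtype=np.int8)


def pairwise_k2p(aln: BarcodeAlignment) -> DistanceMatrix:
    """All-pairs K2P distances with pairwise deletion of N/gap sites.

    Vectorized over the alignment: per-pair transition, transversion and
    comparable-site counts come from indicator-matrix products, so the cost
    is a handful of (n x L) @ (L x n) multiplications.
    """
    if len(aln) < 2:
        raise ValidationError("need >=2 records for pairwise distances")
    enc = encode_alignment(aln)
    valid = (enc < 4).astype(np.float32)
    onehot = [(enc == b).astype(np.float32) for b in range(4)]  # A,G,C,T

    comparable = valid @ valid.T
    matches = sum(x @ x.T for x in onehot)
    pu = onehot[0] + onehot[1]
    py = onehot[2] + onehot[3]
    tv = pu @ py.T + py @ pu.T
    ts = comparable - matches - tv

    comparable = np.round(comparable).astype(np.int64)
    ts = np.round(ts).astype(np.int64)
    tv = np.round(tv).astype(np.int64)

    no_overlap = (comparable == 0)
    np.fill_diagonal(no_overlap, False)
    if no_overlap.any():
        i, j = np.argwhere(no_overlap)[0]
        raise NoOverlapError(
            f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts / comparable
        Q = tv / comparable
        a = 1.0 - 2.0 * P - Q
        b = 1.0 - 2.0 * Q
        d = np.where((a > 0) & (b > 0), -0.5 * np.log(a * np.sqrt(np.abs(b))), np.nan)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(ids=aln.ids, d=d, comparable_sites=comparable)


def collapse_haplotypes(
    aln: BarcodeAlignment,
) -> tuple[BarcodeAlignment, dict[str, list[str]]]:
    """Collapse byte-identical sequences to one representative each.

    The representative is the lexicographically smallest specimen id of its
    group. Sequences differing only at an N are distinct haplotypes (exact
    string identity, mirroring exact-duplicate removal tools). Returns the
    collapsed alignment plus a total mapping haplotype_id -> member ids.
    """
    groups: dict[str, list[str]] = {}
    for sid, seq in aln.records:
        groups.setdefault(seq, []).append(sid)
    mapping: dict[str, list[str]] = {}
    reps: dict[str, str] = {}
    for seq, members in groups.items():
        rep = min(members)
        mapping[rep] = sorted(members)
        reps[rep] = seq
    kept = sorted(mapping)
    collapsed = BarcodeAlignment(
        records=[(sid, reps[sid]) for sid in kept],
        metadata={sid: aln.metadata[sid] for sid in kept} if aln.metadata else {},
    )
    return collapsed, mapping


def expand_partition(p: Partition, mapping: dict[str, list[str]]) -> Partition:
    """Map a haplotype-level partition back onto all specimens."""
    assignment = {}
    for hap_id, cid in p.assignment.items():
        for sid in mapping[hap_id]:
            assignment[sid] = cid
    return Partition(assignment=assignment, method=p.method)


# ---------------------------------------------------------------------------
# Summaries (within/between cluster means, clade matrix, singletons)
# ---------------------------------------------------------------------------

@dataclass
class DistanceSummary:
    within_by_cluster: dict[str, float | None]   # None = singleton (n/a)
    mean_within: float | None
    between_by_pair: dict[tuple[str, str], float]
    mean_between: float | None
    n_singletons: int
    clade_matrix: pd.DataFrame | None

    def to_frames(self) -> dict[str, pd.DataFrame]:
        within = pd.DataFrame(
            [
                {"cluster": c, "mean_within": ("n/a" if v is None else v)}
                for c, v in sorted(self.within_by_cluster.items())
            ]
        )
        between = pd.DataFrame(
            [
                {"cluster_a": a, "cluster_b": b, "mean_between": v}
                for (a, b), v in sorted(self.between_by_pair.items())
            ]
        )
        overall = pd.DataFrame(
            [
                {
                    "mean_within": self.mean_within,
                    "mean_between": self.mean_between,
                    "n_singletons": self.n_singletons,
                }
            ]
        )
        out = {"within": within, "between": between, "overall": overall}
        if self.clade_matrix is not None:
            out["clade_matrix"] = self.clade_matrix
        return out


def _nanmean_or_none(values: np.ndarray) -> float | None:
    values = values[~np.isnan(values)]
    return float(values.mean()) if values.size else None


def distance_summaries(
    dm: DistanceMatrix,
    p: Partition,
    clade_labels: dict[str, str] | None = None,
) -> DistanceSummary:
    """Mean within/between cluster distances, clade matrix, singleton count.

    Singleton clusters report a within-mean of n/a (``None``), never 0.
    Saturated (NaN) distances are excluded from every mean. The clade matrix
    follows the barcoding convention: within-clade means on the diagonal,
    between-clade means below the diagonal and standard errors of those means
    above it.
    """
    missing = set(dm.ids) - set(p.assignment)
    if missing:
        raise ValidationError(f"partition does not cover: {sorted(missing)}")
    idx = {sid: k for k, sid in enumerate(dm.ids)}
    clusters = p.restrict(set(dm.ids)).clusters()

    within_by_cluster: dict[str, float | None] = {}
    within_all: list[np.ndarray] = []
    for cid, members in clusters.items():
        ix = np.array(sorted(idx[s] for s in members))
        if len(ix) < 2:
            within_by_cluster[cid] = None
            continue
        vals = dm.d[np.ix_(ix, ix)][np.triu_indices(len(ix), k=1)]
        within_by_cluster[cid] = _nanmean_or_none(vals)
        within_all.append(vals)

    between_by_pair: dict[tuple[str, str], float] = {}
    between_all: list[np.ndarray] = []
    cids = sorted(clusters)
    for i, ca in enumerate(cids):
        ia = np.array(sorted(idx[s] for s in clusters[ca]))
        for cb in cids[i + 1:]:
            ib = np.array(sorted(idx[s] for s in clusters[cb]))
            vals = dm.d[np.ix_(ia, ib)].ravel()
            m = _nanmean_or_none(vals)
            if m is not None:
                between_by_pair[(ca, cb)] = m
            between_all.append(vals)

    clade_matrix = None
    if clade_labels:
        clade_matrix = _clade_matrix(dm, clade_labels, idx)

    return DistanceSummary(
        within_by_cluster=within_by_cluster,
        mean_within=_nanmean_or_none(
            np.concatenate(within_all) if within_all else np.array([])
        ),
        between_by_pair=between_by_pair,
        mean_between=_nanmean_or_none(
            np.concatenate(between_all) if between_all else np.array([])
        ),
        n_singletons=sum(1 for m in clusters.values() if len(m) == 1),
        clade_matrix=clade_matrix,
    )


def _clade_matrix(
    dm: DistanceMatrix, clade_labels: dict[str, str], idx: dict[str, int]
) -> pd.DataFrame:
    clades = sorted({c for c in clade_labels.values() if c})
    mat = pd.DataFrame(np.nan, index=clades, columns=clades)
    members = {
        c: np.array(sorted(idx[s] for s, lab in clade_labels.items()
                           if lab == c and s in idx))
        for c in clades
    }
    for i, ca in enumerate(clades):
        ia = members[ca]
        if len(ia) >= 2:
            vals = dm.d[np.ix_(ia, ia)][np.triu_indices(len(ia), k=1)]
            mat.loc[ca, ca] = _nanmean_or_none(vals)
        for cb in clades[i + 1:]:
            ib = members[cb]
            vals = dm.d[np.ix_(ia, ib)].ravel()
            vals = vals[~np.isnan(vals)]
            if vals.size:
                # below diagonal: mean; above: standard error of that mean
                mat.loc[cb, ca] = float(vals.mean())
                mat.loc[ca, cb] = float(vals.std(ddof=1) / np.sqrt(vals.size)) \
                    if vals.size > 1 else 0.0
    return mat
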