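"""Fixed-cutoff distance clustering (the initial 2% NJ-stage delimitation).

Clusters are the connected components of the graph with an edge wherever
d(i, j) < cutoff (strict: pairs at exactly the cutoff are split, matching
"divergence greater than 2%" being a split). Saturated/undefined distances
are non-edges. An optional mode cuts at patristic distances on the NJ tree
instead of raw K2P distances.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core_io import Partition, ValidationError
from .distances import DistanceMatrix


def _component_partition(dm: DistanceMatrix, cutoff: float, method: str,
                         prefix: str) -> Partition:
    d = dm.d
    adj = (d < cutoff) & ~np.isnan(d)
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    # stable naming: components numbered by first specimen in input order
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    assignment = {
        sid: f"{prefix}{order[lab]:04d}" for sid, lab in zip(dm.ids, labels)
    }
    return Partition(assignment=assignment, method=method)


def threshold_clusters(
    dm: DistanceMatrix,
    cutoff: float,
    method: str | None = None,
    prefix: str = "C",
) -> Partition:
    """Single-linkage clusters at a fixed distance cutoff.

    The method tag defaults to NJ2 at the canonical 2% cutoff and BIN at the
    2.2% BIN pre-stage; any other cutoff needs an explicit tag.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    if method is None:
        method = "NJ2" if abs(cutoff - 0.02) < 1e-12 else "TRUTH"
    return _component_partition(dm, cutoff, method, prefix)


def tree_cut_clusters(dm: DistanceMatrix, cutoff: float,
                      method: str = "NJ2") -> Partition:
    """Alternative mode: single linkage on NJ-tree patristic distances."""
    from .trees import neighbor_joining, patristic_matrix

    pat = patristic_matrix(neighbor_joining(dm))
    return _component_partition(pat, cutoff, method, prefix="T")
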