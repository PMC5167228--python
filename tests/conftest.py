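import numpy as np
import pytest

from barcodelim import BarcodeAlignment, DistanceMatrix, SpecimenMeta


def make_dm(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(ids=list(ids), d=d,
                          comparable_sites=np.full(d.shape, 600, dtype=int))


def make_aln(seqs, species=None):
    """BarcodeAlignment from {id: sequence}, with minimal metadata."""
    meta = {
        sid: SpecimenMeta(
            nominal_species=(species or {}).get(sid, "spX"),
            locality="loc",
        )
        for sid in seqs
    }
    return BarcodeAlignment(records=sorted(seqs.items()), metadata=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def three_taxon_dm():
    return make_dm(
        ["A", "B", "C"],
        [[0.0, 0.2, 0.3], [0.2, 0.0, 0.4], [0.3, 0.4, 0.0]],
    )


def random_additive_tree(n_leaves, rng):
    """Random binary tree as (children dict, edge lengths, leaf names) plus
    its exact leaf-to-leaf path-length matrix — an independent oracle for
    distance-based reconstruction."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    lengths = {}
    active = list(nodes)
    children = {}
    counter = 0
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent = f"N{counter}"
        counter += 1
        children[parent] = (a, b)
        lengths[a] = rng.uniform(0.05, 1.0)
        lengths[b] = rng.uniform(0.05, 1.0)
        active = [x for k, x in enumerate(active) if k not in (i, j)]
        active.append(parent)
    root = active[0]

    # leaf depth paths via root-to-leaf traversal
    paths = {}

    def walk(node, acc):
        if node in children:
            for ch in children[node]:
                walk(ch, acc + [ch])
        else:
            paths[node] = acc

    walk(root, [])
    d = np.zeros((n_leaves, n_leaves))
    for x in range(n_leaves):
        for y in range(x + 1, n_leaves):
            px, py = paths[nodes[x]], paths[nodes[y]]
            shared = 0
            for u, v in zip(px, py):
                if u == v:
                    shared += 1
                else:
                    break
            dist = sum(lengths[e] for e in px[shared:]) + \
                sum(lengths[e] for e in py[shared:])
            d[x, y] = d[y, x] = dist
    return nodes, d
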