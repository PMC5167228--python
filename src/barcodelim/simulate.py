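"""Synthetic COI barcode datasets with known truth.

The generator emulates the statistical structure of a large barcoding
survey of a species-rich fish genus: a handful of deep clades, many species
per clade (a Yule species tree), a Kingman coalescent inside each species,
and sequences evolved under Kimura's two-parameter process. Branch lengths
are in expected substitutions per site, so the K2P estimator is calibrated
directly against the generating tree:

* the species tree is rescaled so the realized sample-weighted mean
  cross-clade tip-pair path length equals ``target_inter`` (default 18.8%);
* within a species the pair coalescence time has mean ``target_intra / 2``,
  giving mean within-species pair distance ``target_intra`` (default 0.44%).

Defaults mirror the study conditions: 633 bp, five clades, ~0.44% within /
~18.8% between divergence, a fixed fraction of singleton species, and a
tunable rate of exactly duplicated haplotypes. No indels and no stop-codon
logic (the data this emulates had none). Everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import dendropy
import numpy as np

from .core_io import (
    BarcodeAlignment,
    Partition,
    PhyloTree,
    SpecimenMeta,
    ValidationError,
)

_LOCALITIES = (
    "upper-basin", "lower-basin", "coastal-drainage", "highland-creek",
    "floodplain",
)


@dataclass(frozen=True)
class SimConfig:
    n_species: int
    mean_specimens_per_species: float = 5.0
    singleton_fraction: float = 0.25
    seq_length: int = 633
    target_intra: float = 0.0044
    target_inter: float = 0.188
    min_species_split: float = 0.044
    ts_tv_ratio: float = 2.0
    n_clades: int = 5
    duplicate_haplotype_rate: float = 0.0
    n_mask_rate: float = 0.0
    mutation_scale: float = 1.0
    max_within_tmrca: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or not (1 <= self.n_clades <= self.n_species):
            raise ValidationError("need n_species >= n_clades >= 1")
        for name in ("singleton_fraction", "duplicate_haplotype_rate",
                     "n_mask_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.seq_length < 1:
            raise ValidationError("seq_length must be positive")
        if not (0 < self.target_intra < self.target_inter):
            raise ValidationError("need 0 < target_intra < target_inter")
        if not (self.target_intra < self.min_species_split < self.target_inter):
            raise ValidationError(
                "need target_intra < min_species_split < target_inter"
            )
        if self.ts_tv_ratio <= 0 or self.mutation_scale < 0:
            raise ValidationError("invalid rate parameters")
        if self.max_within_tmrca is not None and self.max_within_tmrca <= 0:
            raise ValidationError("max_within_tmrca must be positive")
        f = self.singleton_fraction
        if f < 1.0 and (self.mean_specimens_per_species - f) / (1 - f) < 2:
            raise ValidationError(
                "mean_specimens_per_species too small for the requested "
                "singleton fraction (non-singleton species need >=2)"
            )


@dataclass
class SimTruth:
    species_partition: Partition
    clade_labels: dict[str, str]   # species name -> clade label
    true_tree: PhyloTree


def paper_scale_profile(seed: int = 0) -> SimConfig:
    """Desk-scale analogue of the study: 124 species in five clades, 633 bp,
    a 31/124 singleton fraction, 0.44% within / 18.8% between divergence."""
    return SimConfig(
        n_species=124,
        mean_specimens_per_species=5.0,
        singleton_fraction=31 / 124,
        seq_length=633,
        target_intra=0.0044,
        target_inter=0.188,
        min_species_split=0.12,
        ts_tv_ratio=2.0,
        n_clades=5,
        duplicate_haplotype_rate=0.2,
        max_within_tmrca=0.005,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Genealogy simulators (ages in arbitrary units; rescaled by callers)
# ---------------------------------------------------------------------------

def _yule_ages_topology(n: int, rng: np.random.Generator):
    """Forward Yule simulation conditioned on n tips.

    Returns (root_node, ages dict) with tips at age 0; ages include the
    usual extra Exp(n * lambda) stretch from the last split to the present.
    """
    if n == 1:
        leaf = dendropy.Node()
        return leaf, {leaf: 0.0}
    root = dendropy.Node()
    split_time: dict[dendropy.Node, float] = {root: 0.0}
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append(child)
    t = 0.0
    k = 2
    while k < n:
        t += rng.exponential(1.0 / k)
        victim = active.pop(rng.integers(len(active)))
        split_time[victim] = t
        for _ in range(2):
            child = dendropy.Node()
            victim.add_child(child)
            active.append(child)
        k += 1
    t_total = t + rng.exponential(1.0 / n)
    ages = {node: t_total - s for node, s in split_time.items()}
    for leaf in active:
        ages[leaf] = 0.0
    return root, ages


def _coalescent_ages_topology(tips: list[dendropy.Node],
                              rng: np.random.Generator, mean_pair_time: float):
    """Kingman coalescent over the given tip nodes.

    Times are scaled so a specific pair of lineages coalesces after an
    exponential time with the given mean; the mean tip-pair path length is
    therefore 2 * mean_pair_time.
    """
    ages: dict[dendropy.Node, float] = {tip: 0.0 for tip in tips}
    active = list(tips)
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1))) * mean_pair_time
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(active[i])
        parent.add_child(active[j])
        ages[parent] = t
        active = [a for m, a in enumerate(active) if m not in (i, j)]
        active.append(parent)
    return active[0], ages


def _assign_edge_lengths(root: dendropy.Node,
                         ages: dict[dendropy.Node, float]) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        for child in node.child_nodes():
            child.edge.length = ages[node] - ages[child]
            stack.append(child)
    root.edge.length = None


def simulate_yule_tree(n_tips: int, seed: int, birth_rate: float = 1.0
                       ) -> PhyloTree:
    """Pure-birth tree conditioned on n tips (tips at time 0)."""
    rng = np.random.default_rng(seed)
    root, ages = _yule_ages_topology(n_tips, rng)
    if birth_rate != 1.0:
        ages = {n: a / birth_rate for n, a in ages.items()}
    taxa = dendropy.TaxonNamespace()
    for i, leaf in enumerate(_leaves(root)):
        leaf.taxon = taxa.new_taxon(f"t{i:03d}")
    _assign_edge_lengths(root, ages)
    return PhyloTree(dendropy.Tree(taxon_namespace=taxa, seed_node=root))


def simulate_coalescent_tree(n_tips: int, seed: int,
                             mean_pair_time: float = 1.0) -> PhyloTree:
    """Single-population coalescent genealogy (null model for GMYC tests)."""
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tips = []
    for i in range(n_tips):
        taxon = taxa.new_taxon(f"t{i:03d}")
        tips.append(dendropy.Node(taxon=taxon))
    root, ages = _coalescent_ages_topology(tips, rng, mean_pair_time)
    _assign_edge_lengths(root, ages)
    return PhyloTree(dendropy.Tree(taxon_namespace=taxa, seed_node=root))


def _affine_map_ages(ages: dict, lo: float, hi: float) -> dict:
    """Map internal-node ages onto [lo, hi] preserving order (tips stay 0).

    This pins both the deepest and the shallowest split, so the separation
    between the species process and the within-species process is a design
    parameter rather than a tail event of the Yule draw.
    """
    internal = [a for n, a in ages.items() if a > 0]
    amin, amax = min(internal), max(internal)
    if amax == amin:
        return {n: (hi if a > 0 else 0.0) for n, a in ages.items()}
    return {
        n: (lo + (a - amin) / (amax - amin) * (hi - lo) if a > 0 else 0.0)
        for n, a in ages.items()
    }


def simulate_species_coalescent_tree(
    n_species: int,
    samples_per_species: int,
    seed: int,
    species_depth: float = 1.0,
    coal_mean: float = 0.01,
    min_split_frac: float = 0.5,
) -> tuple[PhyloTree, list[frozenset[str]]]:
    """Yule species tree with coalescent tip clusters (GMYC truth fixture).

    ``species_depth / coal_mean`` sets the separation of the two processes
    (the study-style regime is two orders of magnitude); species split ages
    span [min_split_frac, 1] x species_depth so every speciation respects
    that separation. Returns the glued ultrametric tree and the true entity
    sets.
    """
    rng = np.random.default_rng(seed)
    sp_root, sp_ages = _yule_ages_topology(n_species, rng)
    sp_ages = _affine_map_ages(sp_ages, min_split_frac * species_depth,
                               species_depth)
    taxa = dendropy.TaxonNamespace()
    truth: list[frozenset[str]] = []
    for s, sp_tip in enumerate(list(_leaves(sp_root))):
        labels = [f"sp{s:03d}_{i:02d}" for i in range(samples_per_species)]
        tips = [dendropy.Node(taxon=taxa.new_taxon(lab)) for lab in labels]
        g_root, g_ages = _coalescent_ages_topology(tips, rng, coal_mean)
        parent_age = sp_ages[sp_tip.parent_node]
        if g_ages[g_root] >= parent_age:
            shrink = 0.9 * parent_age / g_ages[g_root]
            g_ages = {n: a * shrink for n, a in g_ages.items()}
        _graft(sp_tip, g_root)
        sp_ages.update(g_ages)
        truth.append(frozenset(labels))
    _assign_edge_lengths(sp_root, sp_ages)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=sp_root)
    return PhyloTree(tree), truth


def _leaves(root: dendropy.Node):
    for node in root.preorder_iter():
        if node.is_leaf():
            yield node


def _graft(species_tip: dendropy.Node, genealogy_root: dendropy.Node) -> None:
    """Replace a species-tree tip with a within-species genealogy."""
    if genealogy_root is species_tip:
        return
    parent = species_tip.parent_node
    if parent is None:  # single-species tree: genealogy is the whole tree
        return
    parent.remove_child(species_tip)
    parent.add_child(genealogy_root)


# ---------------------------------------------------------------------------
# Sequence evolution under the two-parameter process
# ---------------------------------------------------------------------------

def _k2p_mask_probs(t: float, kappa: float) -> np.ndarray:
    """Probabilities of (identity, transition, each transversion) after a
    branch of t expected substitutions/site at ts/tv rate ratio kappa."""
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    return np.array([1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv, p_tv])


def _evolve(root: dendropy.Node, length: int, kappa: float, scale: float,
            rng: np.random.Generator) -> dict[dendropy.Node, np.ndarray]:
    """Site-independent simulation; bases coded A=0, G=1, C=2, T=3 so that
    XOR 1 is the transition partner and XOR 2 / XOR 3 the transversions."""
    seqs: dict[dendropy.Node, np.ndarray] = {
        root: rng.integers(0, 4, size=length).astype(np.int8)
    }
    for node in root.preorder_iter():
        if node is root:
            continue
        t = (node.edge.length or 0.0) * scale
        probs = _k2p_mask_probs(t, kappa)
        masks = rng.choice(4, size=length, p=probs).astype(np.int8)
        seqs[node] = seqs[node.parent_node] ^ masks
    return seqs


_DECODE = np.array(list("AGCT"))


def simulate_dataset(cfg: SimConfig) -> tuple[BarcodeAlignment, SimTruth]:
    """Generate an aligned barcode dataset plus its generating truth."""
    rng = np.random.default_rng(cfg.seed)
    S = cfg.n_species

    # --- specimen counts: exact singleton quota, Poisson bulk --------------
    n_singletons = int(round(cfg.singleton_fraction * S))
    counts = np.full(S, 1, dtype=int)
    non_single = rng.permutation(S)[n_singletons:]
    if len(non_single):
        f = n_singletons / S
        bulk_mean = (cfg.mean_specimens_per_species - f) / (1 - f) if f < 1 else 2.0
        counts[non_single] = 2 + rng.poisson(max(bulk_mean - 2.0, 0.0),
                                             size=len(non_single))

    # --- species tree, clades, inter-clade calibration ---------------------
    sp_root, sp_ages = _yule_ages_topology(S, rng)
    sp_tips = list(_leaves(sp_root))
    species_names = [f"sp{s:03d}" for s in range(S)]
    clade_of = _cut_clades(sp_root, sp_ages, sp_tips, cfg.n_clades)
    sp_ages = _calibrate_species_ages(sp_root, sp_ages, sp_tips, clade_of,
                                      counts, cfg)

    # --- within-species coalescents ---------------------------------------
    taxa = dendropy.TaxonNamespace()
    assignment: dict[str, str] = {}
    species_of_specimen: dict[str, str] = {}
    for s, sp_tip in enumerate(sp_tips):
        name = species_names[s]
        labels = [f"{name}_{i:02d}" for i in range(counts[s])]
        for lab in labels:
            assignment[lab] = name
            species_of_specimen[lab] = name
        tips = [dendropy.Node(taxon=taxa.new_taxon(lab)) for lab in labels]
        if len(tips) == 1:
            g_root, g_ages = tips[0], {tips[0]: 0.0}
        else:
            g_root, g_ages = _coalescent_ages_topology(
                tips, rng, cfg.target_intra / 2.0
            )
            # bound the within-species depth (cluster-defined species: the
            # emulated groups have all within distances under the cutoff)
            cap = cfg.max_within_tmrca
            if cap is not None and g_ages[g_root] > cap:
                shrink = 0.98 * cap / g_ages[g_root]
                g_ages = {n: a * shrink for n, a in g_ages.items()}
        parent = sp_tip.parent_node
        if parent is not None and g_ages[g_root] >= sp_ages[parent]:
            shrink = 0.9 * sp_ages[parent] / g_ages[g_root]
            g_ages = {n: a * shrink for n, a in g_ages.items()}
        if parent is None:
            sp_root = g_root  # single-species dataset
            sp_ages = dict(g_ages)
        else:
            if g_root is not sp_tip:
                parent.remove_child(sp_tip)
                parent.add_child(g_root)
            sp_ages.update(g_ages)
    _assign_edge_lengths(sp_root, sp_ages)
    true_tree = PhyloTree(dendropy.Tree(taxon_namespace=taxa, seed_node=sp_root))

    # --- sequences ---------------------------------------------------------
    seqs = _evolve(sp_root, cfg.seq_length, cfg.ts_tv_ratio,
                   cfg.mutation_scale, rng)
    seq_of: dict[str, np.ndarray] = {
        node.taxon.label: seqs[node] for node in _leaves(sp_root)
    }

    # duplicated haplotypes: overwrite with a copy of an earlier conspecific
    if cfg.duplicate_haplotype_rate > 0:
        for s in range(S):
            labels = [f"{species_names[s]}_{i:02d}" for i in range(counts[s])]
            for i, lab in enumerate(labels[1:], start=1):
                if rng.random() < cfg.duplicate_haplotype_rate:
                    donor = labels[rng.integers(i)]
                    seq_of[lab] = seq_of[donor].copy()

    records = []
    for lab in sorted(seq_of):
        letters = _DECODE[seq_of[lab]]
        if cfg.n_mask_rate > 0:
            mask = rng.random(cfg.seq_length) < cfg.n_mask_rate
            letters = letters.copy()
            letters[mask] = "N"
        records.append((lab, "".join(letters)))

    metadata = {
        lab: SpecimenMeta(
            nominal_species=species_of_specimen[lab],
            locality=_LOCALITIES[
                int(rng.integers(len(_LOCALITIES)))
            ],
            clade_label=clade_of[species_of_specimen[lab]],
        )
        for lab, _ in records
    }
    aln = BarcodeAlignment(records=records, metadata=metadata)
    truth = SimTruth(
        species_partition=Partition(assignment=assignment, method="TRUTH"),
        clade_labels=clade_of,
        true_tree=true_tree,
    )
    return aln, truth


def _cut_clades(root, ages, tips, n_clades: int) -> dict[str, str]:
    """Clade labels from cutting the species tree below its deepest splits."""
    names = [f"sp{s:03d}" for s in range(len(tips))]
    if n_clades == 1 or len(tips) == 1:
        return {n: "clade1" for n in names}
    internal_ages = sorted(
        (a for n, a in ages.items() if not n.is_leaf()), reverse=True
    )
    cut_age = (
        (internal_ages[n_clades - 2] + internal_ages[n_clades - 1]) / 2.0
        if len(internal_ages) >= n_clades
        else internal_ages[-1] / 2.0
    )
    label_of: dict[str, str] = {}
    clade_no = 0

    def walk(node) -> None:
        nonlocal clade_no
        age = 0.0 if node.is_leaf() else ages[node]
        if age <= cut_age:
            clade_no += 1
            for leaf in _leaves(node):
                label_of[names[tips.index(leaf)]] = f"clade{clade_no}"
        else:
            for child in node.child_nodes():
                walk(child)

    walk(root)
    return label_of


def _calibrate_species_ages(root, ages, tips, clade_of, counts, cfg: SimConfig):
    """Affine-map species split ages so the shallowest split sits at
    min_species_split / 2 and the sample-weighted mean cross-clade tip-pair
    path equals target_inter.

    Analytic K2P calibration: path lengths are expected substitutions/site,
    which the K2P distance estimates without bias, so matching path lengths
    matches expected distances. Mapped ages a' = L + r(a) * (U - L) with
    r(a) the rank-preserving normalization of a; the calibration pair mean
    is linear in U, so U has a closed form.
    """
    if len(tips) < 2:
        return ages
    names = [f"sp{s:03d}" for s in range(len(tips))]
    L = cfg.min_species_split / 2.0
    target_age = cfg.target_inter / 2.0
    internal = [a for n, a in ages.items() if a > 0]
    amin, amax = min(internal), max(internal)
    if amax == amin:
        return _affine_map_ages(ages, target_age, target_age)

    mrca_age = _pairwise_mrca_ages(root, ages, tips)
    cross_clade = len(set(clade_of.values())) >= 2
    num = 0.0
    den = 0.0
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            if cross_clade and clade_of[names[i]] == clade_of[names[j]]:
                continue
            w = counts[i] * counts[j]
            num += w * (mrca_age[i, j] - amin) / (amax - amin)
            den += w
    r_bar = num / den
    if r_bar <= 0:
        return _affine_map_ages(ages, L, target_age)
    U = L + (target_age - L) / r_bar
    return _affine_map_ages(ages, L, max(U, L * (1 + 1e-9)))


def _pairwise_mrca_ages(root, ages, tips) -> np.ndarray:
    index = {tip: k for k, tip in enumerate(tips)}
    n = len(tips)
    out = np.zeros((n, n))

    def walk(node) -> list[int]:
        if node.is_leaf():
            return [index[node]]
        child_sets = [walk(c) for c in node.child_nodes()]
        age = ages[node]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        out[i, j] = out[j, i] = age
        return [i for cs in child_sets for i in cs]

    walk(root)
    return out


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=seed)
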