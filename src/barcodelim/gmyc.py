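"""Single-threshold generalized mixed Yule-coalescent (GMYC) delimitation.

An ultrametric tree of unique haplotypes is modelled as a speciation (Yule)
process older than a threshold time T and independent within-species
coalescent processes younger than T. The data are the waiting times between
branching events; between consecutive events the total branching rate is

    b = lambda_yule * n^p_yule + lambda_coal * sum_j (n_j (n_j - 1))^p_coal

with n the number of species-level lineages and n_j the lineage count
inside species j. Each inter-event interval of duration x contributes
log(b) - b * x (the waiting time is exponential at the prevailing total
rate). The threshold is profiled over candidate times (midpoints between
node ages), the null model is a single coalescent over the whole tree, and
the likelihood-ratio statistic is referred to chi-square with 2 degrees of
freedom.

Times before present are reported negative (threshold_time = -T), matching
the sign convention of the R 'splits' output this mirrors.

Numerics: per candidate the four parameters (log rates, exponents) are
maximized with L-BFGS-B from three starts; the central start sets each rate
to its per-component Poisson estimate at unit exponents. Exponents are
bounded to [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .core_io import Partition, PhyloTree, ValidationError
from .trees import node_ages

P_BOUNDS = (0.0, 2.0)
LOG_RATE_BOUNDS = (-30.0, 30.0)
_START_OFFSETS = [
    (0.0, 0.0, 0.0, 0.0),
    (1.0, -1.0, 0.5, -0.5),
    (-1.0, 1.0, -0.5, 0.5),
]
_OPT_TOL = 1e-8
CI_DELTA = 2.0  # log-likelihood units for the entity confidence set


@dataclass(frozen=True)
class _Stats:
    """Sufficient statistics of one candidate threshold.

    Interval and event rates depend only on the species-lineage count n and
    the multiset of within-species pair counts v = n_j (n_j - 1); the
    multisets are stored as count matrices over the distinct v values so a
    likelihood evaluation is a couple of small matrix-vector products.
    """

    n_entities: int
    ev_n: np.ndarray        # species-lineage count during each event's interval
    ev_C: np.ndarray        # (n_events, n_distinct_v) pair-count multiplicities
    int_x: np.ndarray       # interval durations
    int_n: np.ndarray       # species-lineage count per interval
    int_C: np.ndarray       # (n_intervals, n_distinct_v)
    v: np.ndarray           # distinct pair-count values

    def loglik(self, lambda_yule: float, lambda_coal: float,
               p_yule: float, p_coal: float) -> float:
        vp = self.v ** p_coal
        b_events = lambda_yule * self.ev_n ** p_yule + lambda_coal * (self.ev_C @ vp)
        if np.any(b_events <= 0):
            return -np.inf
        exposure = (
            lambda_yule * float(np.sum(self.int_x * self.int_n ** p_yule))
            + lambda_coal * float(np.sum(self.int_x * (self.int_C @ vp)))
        )
        return float(np.sum(np.log(b_events))) - exposure


@dataclass
class GmycFit:
    threshold_time: float        # negative: time before present
    n_entities: int
    lambda_yule: float
    lambda_coal: float
    p_yule: float
    p_coal: float
    logL_mixed: float
    logL_null: float
    LR: float
    p_value: float
    ci_entities: tuple[int, int]
    converged: bool
    entity_sets: list[frozenset[str]] = field(default_factory=list)
    candidates: list[tuple[float, int, float]] = field(default_factory=list)
    # (threshold_time, n_entities, logL) per candidate, for diagnostics

    def partition(self) -> Partition:
        assignment = {}
        for k, members in enumerate(
            sorted(self.entity_sets, key=lambda m: min(m))
        ):
            for sid in members:
                assignment[sid] = f"G{k:04d}"
        return Partition(assignment=assignment, method="GMYC")


def _tree_events(ptree: PhyloTree):
    ages = node_ages(ptree)
    return ages, max(ages.values())


def _candidate_stats(ptree: PhyloTree, ages: dict, T: float
                     ) -> tuple[_Stats, list[frozenset[str]]]:
    """Classify nodes for threshold age T (positive, before present) and
    sweep the timeline from the tips toward the root."""
    root = ptree.tree.seed_node
    yule_ages: list[float] = []
    coal_events: list[tuple[float, int]] = []
    species_tips: list[frozenset[str]] = []

    def collect_species(node) -> None:
        sp = len(species_tips)
        tips = []
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur.is_leaf():
                tips.append(cur.taxon.label)
            else:
                coal_events.append((ages[cur], sp))
                stack.extend(cur.child_nodes())
        species_tips.append(frozenset(tips))

    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf() or ages[node] <= T:
            collect_species(node)
        else:
            yule_ages.append(ages[node])
            stack.extend(node.child_nodes())
    n_entities = len(species_tips)

    events = sorted(
        [(a, 0, sp) for a, sp in coal_events] + [(a, 1, -1) for a in yule_ages]
    )
    nj = np.array([len(t) for t in species_tips], dtype=np.int64)
    coal_mult: dict[int, int] = {}
    for c in nj:
        if c >= 2:
            v = int(c * (c - 1))
            coal_mult[v] = coal_mult.get(v, 0) + 1

    n_sp = n_entities
    t_prev = 0.0
    ev_n: list[int] = []
    ev_rows: list[dict[int, int]] = []
    int_x: list[float] = []
    int_n: list[int] = []
    int_rows: list[dict[int, int]] = []
    for age, kind, sp in events:
        x = age - t_prev
        if x > 0:
            int_x.append(x)
            int_n.append(n_sp)
            int_rows.append(dict(coal_mult))
        ev_n.append(n_sp)
        ev_rows.append(dict(coal_mult))
        if kind == 1:  # species-level (Yule) event
            n_sp -= 1
        else:          # coalescence inside species sp
            v = int(nj[sp] * (nj[sp] - 1))
            coal_mult[v] -= 1
            if coal_mult[v] == 0:
                del coal_mult[v]
            nj[sp] -= 1
            if nj[sp] >= 2:
                v2 = int(nj[sp] * (nj[sp] - 1))
                coal_mult[v2] = coal_mult.get(v2, 0) + 1
        t_prev = age

    distinct = sorted({v for row in ev_rows + int_rows for v in row}) or [2]
    v_arr = np.array(distinct, dtype=float)
    col = {v: k for k, v in enumerate(distinct)}

    def as_matrix(rows: list[dict[int, int]]) -> np.ndarray:
        out = np.zeros((len(rows), len(distinct)))
        for r, row in enumerate(rows):
            for v, m in row.items():
                out[r, col[v]] = m
        return out

    stats = _Stats(
        n_entities=n_entities,
        ev_n=np.array(ev_n, dtype=float),
        ev_C=as_matrix(ev_rows),
        int_x=np.array(int_x, dtype=float),
        int_n=np.array(int_n, dtype=float),
        int_C=as_matrix(int_rows),
        v=v_arr,
    )
    return stats, species_tips


def _central_start(stats: _Stats) -> np.ndarray:
    """Per-component Poisson rate estimates at unit exponents."""
    m = stats.ev_n.size
    E_y = float(np.sum(stats.int_x * stats.int_n))
    E_c = float(np.sum(stats.int_x * (stats.int_C @ stats.v)))
    lam_y = m / E_y if E_y > 0 else 1e-10
    lam_c = m / E_c if E_c > 0 else 1e-10
    return np.array([
        np.clip(np.log(lam_y), *LOG_RATE_BOUNDS),
        np.clip(np.log(lam_c), *LOG_RATE_BOUNDS),
        1.0,
        1.0,
    ])


def _maximize(stats: _Stats) -> tuple[float, float, float, float, float, bool]:
    """Best (logL, lambda_yule, lambda_coal, p_yule, p_coal, converged)."""

    def neg(q: np.ndarray) -> float:
        return -stats.loglik(np.exp(q[0]), np.exp(q[1]), q[2], q[3])

    center = _central_start(stats)
    best = None
    ok = False
    for off in _START_OFFSETS:
        x0 = center + np.array(off)
        x0[2:] = np.clip(x0[2:], *P_BOUNDS)
        x0[:2] = np.clip(x0[:2], *LOG_RATE_BOUNDS)
        res = minimize(neg, x0, method="L-BFGS-B",
                       bounds=[LOG_RATE_BOUNDS, LOG_RATE_BOUNDS,
                               P_BOUNDS, P_BOUNDS],
                       options={"ftol": _OPT_TOL, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    lam_y, lam_c = np.exp(best.x[0]), np.exp(best.x[1])
    return (-best.fun, float(lam_y), float(lam_c),
            float(best.x[2]), float(best.x[3]), ok)


def gmyc_loglik(
    ptree: PhyloTree,
    threshold_T: float,
    lambda_yule: float,
    lambda_coal: float,
    p_yule: float,
    p_coal: float,
) -> float:
    """Mixed Yule-coalescent log-likelihood at explicit parameter values.

    ``threshold_T`` is negative (time before present) and must lie strictly
    between the root time and 0.
    """
    if lambda_yule < 0 or lambda_coal < 0:
        raise ValidationError("rates must be non-negative")
    ages, root_age = _tree_events(ptree)
    if not (-root_age < threshold_T < 0):
        raise ValidationError(
            f"threshold {threshold_T} outside (root time {-root_age}, 0)"
        )
    stats, _ = _candidate_stats(ptree, ages, -threshold_T)
    return stats.loglik(lambda_yule, lambda_coal, p_yule, p_coal)


def gmyc_fit(ptree: PhyloTree) -> GmycFit:
    """Fit the single-threshold model by profiling candidate thresholds.

    Candidates are the midpoints between consecutive internal-node ages,
    plus a just-younger-than-the-youngest-node boundary (every haplotype its
    own entity) and a just-older-than-the-root boundary (one entity; this is
    also the null single-coalescent model). The confidence set collects the
    entity counts of candidates within 2 log-likelihood units of the best.
    Duplicate haplotypes must be collapsed before fitting.
    """
    if len(ptree.leaf_labels) < 3:
        raise ValidationError("GMYC needs >=3 leaves")
    ages, root_age = _tree_events(ptree)
    u = np.sort(np.array(list(ages.values())))
    cand_T = [u[0] / 2.0]
    cand_T += [(u[k] + u[k + 1]) / 2.0 for k in range(u.size - 1)]
    cand_T.append(root_age * (1.0 + 1e-9) + 1e-300)

    results = []
    best_idx, best_logL = 0, -np.inf
    for k, T in enumerate(cand_T):
        stats, species = _candidate_stats(ptree, ages, T)
        logL, lam_y, lam_c, p_y, p_c, ok = _maximize(stats)
        results.append((T, stats.n_entities, logL, lam_y, lam_c, p_y, p_c,
                        ok, species))
        if logL > best_logL:
            best_logL, best_idx = logL, k

    logL_null = results[-1][2]  # just-older-than-root candidate
    T, n_ent, logL, lam_y, lam_c, p_y, p_c, ok, species = results[best_idx]
    LR = max(2.0 * (logL - logL_null), 0.0)
    in_ci = [r[1] for r in results if r[2] >= logL - CI_DELTA]
    return GmycFit(
        threshold_time=-float(T),
        n_entities=n_ent,
        lambda_yule=lam_y,
        lambda_coal=lam_c,
        p_yule=p_y,
        p_coal=p_c,
        logL_mixed=logL,
        logL_null=logL_null,
        LR=LR,
        p_value=float(chi2.sf(LR, df=2)),
        ci_entities=(min(in_ci), max(in_ci)),
        converged=ok,
        entity_sets=list(species),
        candidates=[(-r[0], r[1], r[2]) for r in results],
    )
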