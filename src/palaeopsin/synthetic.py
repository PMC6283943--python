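"""Synthetic dated trees, duplication histories and posterior-style CIs.

This module emulates, at summary level, the outputs of the two Bayesian
dating analyses the inference consumes: a dated species tree with fossil
tips (a forward birth–death simulation with Poisson fossil recovery and
extant subsampling, the generative analogue of a fossilised birth–death
sampled tree) and noisy node-age posteriors summarised as equal-tailed
credibility intervals.  No likelihoods are computed; the goal is
plausible, calibrated dating output so that every pipeline stage is
testable end to end without external data.

Default scales emulate the shape of the empirical ecdysozoan dataset:
root age ~ Gamma(mean 600 Ma, sd 26 Ma), on the order of ten extant and
fifty fossil tips, posterior CIs ~20–25 Ma wide, four duplications along
a backbone lineage with five focal divergences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .chronology import ComplementTable, infer_all
from .dated_trees import CredibleInterval, DatedNode, DatedTree
from .datasets import ecdysozoan_fixture  # re-exported: the in-package worked example
from .errors import SimulationError
from .nomenclature import (
    DuplicationEvent,
    GeneLineageTree,
    NamePrecedence,
    build_gene_lineage_tree,
)

__all__ = [
    "SimulationConfig",
    "simulate_species_tree",
    "scatter_fossils",
    "simulate_duplications",
    "DuplicationHistory",
    "simulate_age_posteriors",
    "perturb_tree_ages",
    "TruthBundle",
    "FocusTruth",
    "simulate_truth_bundle",
    "evaluate_recovery",
    "RecoveryMetrics",
    "run_recovery_experiment",
    "ecdysozoan_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Rates are per lineage per Ma.  ``rho`` is the probability that an
    extant lineage is sampled; ``psi`` the Poisson fossil-recovery rate.
    ``age_rel_sd`` is the relative standard deviation of the lognormal
    posterior-age emulation (0 gives degenerate intervals).
    """

    birth_rate: float = 0.011
    death_rate: float = 0.008
    rho: float = 1.0
    psi: float = 0.015
    root_age_mean: float = 600.0
    root_age_sd: float = 26.0
    n_duplications: int = 4
    duplication_times: tuple[float, ...] | None = None
    duplication_rate: float | None = None
    n_foci: int = 5
    min_focus_gap: float = 20.0
    age_rel_sd: float = 0.01
    n_posterior_samples: int = 500
    ci_level: float = 0.95
    seed: int = 0
    min_sampled_extant: int = 2
    max_tries: int = 500

    def __post_init__(self):
        if min(self.birth_rate, self.death_rate, self.psi) < 0:
            raise SimulationError("rates must be non-negative")
        if not (0 < self.rho <= 1):
            raise SimulationError(f"rho must be in (0, 1]; got {self.rho}")
        if not (0 < self.ci_level < 1):
            raise SimulationError(f"ci_level must be in (0, 1); got {self.ci_level}")
        if self.age_rel_sd < 0:
            raise SimulationError("age_rel_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# species-tree simulation
# ---------------------------------------------------------------------------


def _simulate_complete(rng: np.random.Generator, birth: float, death: float, root_age: float) -> DatedNode:
    """Complete (extinct lineages included) birth-death tree from a root split."""
    root = DatedNode(age=root_age)
    # each stack entry: (parent node, start age of the lineage)
    stack = [(root, root_age), (root, root_age)]
    total = birth + death
    while stack:
        parent, t = stack.pop()
        while True:
            wait = rng.exponential(1.0 / total) if total > 0 else math.inf
            t_next = t - wait
            if t_next <= 0:
                parent.add_child(DatedNode(age=0.0))
                break
            if rng.random() < (birth / total):
                node = parent.add_child(DatedNode(age=t_next))
                stack.append((node, t_next))
                parent, t = node, t_next
            else:
                parent.add_child(DatedNode(age=t_next))  # extinction: tip above present
                break
    return root


def scatter_fossils(
    root: DatedNode, psi: float, rng: np.random.Generator
) -> dict[int, list[float]]:
    """Poisson(psi × branch duration) fossilisation events per branch.

    Returns a map from ``id(node)`` to fossil ages on the branch above that
    node (uniform within the branch's age span).
    """
    out: dict[int, list[float]] = {}
    if psi <= 0:
        return out
    for nd in root.preorder():
        if nd.parent is None:
            continue
        span = nd.parent.age - nd.age
        if span <= 0:
            continue
        k = rng.poisson(psi * span)
        if k:
            ages = nd.age + (nd.parent.age - nd.age) * rng.random(k)
            out[id(nd)] = sorted(ages.tolist(), reverse=True)
    return out


def _prune_sampled(
    root: DatedNode,
    sampled: set[int],
    fossils: dict[int, list[float]],
) -> DatedNode | None:
    """Reduce a complete tree to the sampled tree (extant samples + fossils)."""

    contributes: dict[int, bool] = {}
    for nd in root.postorder():
        own = (id(nd) in sampled) or bool(fossils.get(id(nd)))
        contributes[id(nd)] = own or any(contributes[id(c)] for c in nd.children)

    def rebuild(nd: DatedNode):
        """Returns (top node of rebuilt subtree, fossil ages pending on its branch)."""
        pending = list(fossils.get(id(nd), []))
        kept = [rebuild(c) for c in nd.children if contributes[id(c)]]
        if not nd.children:
            if id(nd) in sampled:
                return DatedNode(age=nd.age), pending
            if pending:
                youngest = pending.pop()  # lineage observed up to its last fossil
                return DatedNode(age=youngest), pending
            return None, pending
        if not kept:
            if pending:
                youngest = pending.pop()
                return DatedNode(age=youngest), pending
            return None, pending
        if len(kept) == 1:
            top, child_pending = kept[0]
            return top, child_pending + pending
        me = DatedNode(age=nd.age)
        for top, child_pending in kept:
            me.add_child(_attach_fossil_chain(top, child_pending))
        return me, pending

    top, pending = rebuild(root)
    if top is None:
        return None
    return _attach_fossil_chain(top, pending)


def _attach_fossil_chain(top: DatedNode, pending: list[float]) -> DatedNode:
    """Insert fossil side-tips along the branch above ``top`` (oldest outermost)."""
    current = top
    for age in sorted(pending):  # youngest first: wrapped innermost
        holder = DatedNode(age=age)
        holder.add_child(DatedNode(age=age))  # the fossil tip itself (zero-length)
        holder.add_child(current)
        # reorder so the continuation comes first, fossil second
        holder.children.reverse()
        for c in holder.children:
            c.parent = holder
        current = holder
    return current


def simulate_species_tree(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> DatedTree:
    """Forward-simulated dated species tree with fossil tips.

    Birth–death simulation from a root split at a Gamma-distributed root
    age, extant lineages retained with probability ``rho``, fossils
    scattered as a Poisson process on all branches (extinct subtrees
    included, as in a sampled fossilised-birth-death tree), then pruned to
    the sampled tree.  Conditioned on at least ``min_sampled_extant``
    sampled extant tips and on the root split being observed.
    """
    rng = config.rng() if rng is None else rng
    shape = (config.root_age_mean / config.root_age_sd) ** 2
    scale = config.root_age_sd**2 / config.root_age_mean
    for _ in range(config.max_tries):
        root_age = rng.gamma(shape, scale)
        complete = _simulate_complete(rng, config.birth_rate, config.death_rate, root_age)
        extant = [nd for nd in complete.preorder() if nd.is_leaf and nd.age == 0.0]
        sampled = {id(nd) for nd in extant if rng.random() < config.rho}
        if len(sampled) < config.min_sampled_extant:
            continue
        fossils = scatter_fossils(complete, config.psi, rng)
        pruned = _prune_sampled(complete, sampled, fossils)
        if pruned is None or pruned.is_leaf:
            continue
        if abs(pruned.age - root_age) > 1e-9:
            continue  # root split unobserved; condition on a sampled root
        n_extant = n_fossil = 0
        for leaf in pruned.leaves():
            if leaf.age > 1e-9:
                n_fossil += 1
                leaf.label = f"F{n_fossil}"
            else:
                n_extant += 1
                leaf.label = f"T{n_extant}"
        return DatedTree(pruned)
    raise SimulationError(
        f"no surviving sampled tree in {config.max_tries} attempts; "
        "increase birth_rate, rho or max_tries, or lower death_rate"
    )


# ---------------------------------------------------------------------------
# duplication histories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplicationHistory:
    """True duplication times on a backbone lineage, as a named chain.

    ``times`` are strictly decreasing (oldest first); ``glt`` is the
    corresponding gene lineage tree with degenerate CIs at the true times,
    a caterpillar over auto-named terminals g1..g(k+1).
    """

    times: tuple[float, ...]
    glt: GeneLineageTree
    backbone_tip: str | None = None

    @property
    def precedence(self) -> NamePrecedence:
        return self.glt.precedence


def _caterpillar_events(
    times: Sequence[float], cis: Sequence[CredibleInterval] | None = None
) -> tuple[list[DuplicationEvent], NamePrecedence]:
    k = len(times)
    terminals = [f"g{i}" for i in range(1, k + 2)]
    precedence = NamePrecedence(terminals)
    events = []
    for i, t in enumerate(times):
        ci = cis[i] if cis is not None else CredibleInterval(t, t)
        events.append(
            DuplicationEvent(
                frozenset({terminals[i]}), frozenset(terminals[i + 1 :]), ci
            )
        )
    return events, precedence


def backbone_path(tree: DatedTree, tip_label: str) -> list[DatedNode]:
    """Internal nodes from the root down to (excluding) the named tip."""
    tip = tree.tip(tip_label)
    path = [nd for nd in tip.ancestors()]
    path.reverse()
    return path


def default_backbone_tip(tree: DatedTree) -> str:
    """The extant tip subtended by the largest number of internal nodes."""
    best, best_n = None, -1
    for leaf in tree.leaves():
        if leaf.tip_kind != "extant":
            continue
        n = sum(1 for _ in leaf.ancestors())
        if n > best_n:
            best, best_n = leaf.label, n
    if best is None:
        raise SimulationError("tree has no extant tip to anchor the backbone")
    return best


def simulate_duplications(
    tree: DatedTree,
    backbone: str | None = None,
    times: Sequence[float] | None = None,
    rate: float | None = None,
    rng: np.random.Generator | None = None,
) -> DuplicationHistory:
    """Place duplication events on the backbone lineage of a dated tree.

    Either explicit ``times`` (strictly decreasing, within the backbone's
    age span) or a Poisson ``rate`` per Ma along the span.  With no events
    the history is a single ancestral gene.
    """
    tip_label = backbone or default_backbone_tip(tree)
    tip = tree.tip(tip_label)
    old = tree.root.age
    young = tip.age if tip.age is not None else 0.0
    if times is not None:
        times = [float(t) for t in times]
        for t in times:
            if not (young <= t <= old):
                raise SimulationError(
                    f"duplication time {t} outside backbone span ({young}, {old})"
                )
        if any(b >= a for a, b in zip(times, times[1:])):
            raise SimulationError(f"explicit duplication times must strictly decrease: {times}")
    else:
        rate = rate or 0.0
        if rate < 0:
            raise SimulationError("duplication rate must be >= 0")
        if rate == 0:
            times = []
        else:
            rng = np.random.default_rng() if rng is None else rng
            k = rng.poisson(rate * (old - young))
            times = sorted((young + (old - young) * rng.random(k)).tolist(), reverse=True)
    if not times:
        glt = build_gene_lineage_tree([], terminals=["g1"], precedence=NamePrecedence(["g1"]))
        return DuplicationHistory((), glt, tip_label)
    events, precedence = _caterpillar_events(times)
    glt = build_gene_lineage_tree(events, precedence)
    return DuplicationHistory(tuple(times), glt, tip_label)


# ---------------------------------------------------------------------------
# posterior-age emulation
# ---------------------------------------------------------------------------


def simulate_age_posteriors(
    times: Sequence[float],
    rel_sd: float,
    n_samples: int = 500,
    rng: np.random.Generator | None = None,
    ci_level: float = 0.95,
    parents: Sequence[int | None] | None = None,
    lower_bounds: Sequence[float] | None = None,
) -> tuple[list[float], list[CredibleInterval]]:
    """Emulated posterior summaries (point age + equal-tailed CI) per event.

    For each true age ``t`` a posterior centre is drawn lognormally around
    ``t`` with relative sd ``rel_sd``, then ``n_samples`` posterior draws
    are taken around that centre; the CI is the equal-tailed interval of
    the draws.  Drawing the centre itself is what makes the intervals
    *calibrated*: the truth falls inside the 95% CI ~95% of the time.
    With ``rel_sd = 0`` every CI is degenerate at the truth.

    ``parents[i]`` (an index, or None for a root event) imposes
    child-older-than-parent truncation sample-wise; ``lower_bounds[i]``
    clamps from below (e.g. the oldest fossil tip beneath a node).
    """
    if rel_sd < 0:
        raise SimulationError("rel_sd must be >= 0")
    times = [float(t) for t in times]
    n = len(times)
    if parents is None:
        parents = [None] * n
    if lower_bounds is None:
        lower_bounds = [0.0] * n
    if rel_sd == 0:
        return list(times), [CredibleInterval(t, t) for t in times]

    rng = np.random.default_rng() if rng is None else rng
    alpha = (1.0 - ci_level) / 2.0
    samples: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    centers: list[float] = [0.0] * n
    cis: list[CredibleInterval] = [None] * n  # type: ignore[list-item]

    order = _topological_order(parents)
    for i in order:
        t = times[i]
        center = t * math.exp(rel_sd * rng.standard_normal())
        draws = center * np.exp(rel_sd * rng.standard_normal(n_samples))
        p = parents[i]
        if p is not None:
            draws = np.minimum(draws, samples[p])
            center = min(center, centers[p])
        lb = float(lower_bounds[i])
        if lb > 0:
            draws = np.maximum(draws, lb)
            center = max(center, lb)
        samples[i] = draws
        lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
        center = min(max(center, lo), hi)
        centers[i] = center
        cis[i] = CredibleInterval.of(float(lo), float(hi))
    return centers, cis


def _topological_order(parents: Sequence[int | None]) -> list[int]:
    n = len(parents)
    order: list[int] = []
    state = [0] * n  # 0 unvisited, 1 done

    def visit(i: int) -> None:
        if state[i]:
            return
        p = parents[i]
        if p is not None:
            visit(p)
        state[i] = 1
        order.append(i)

    for i in range(n):
        visit(i)
    return order


def perturb_tree_ages(
    tree: DatedTree,
    rel_sd: float,
    n_samples: int = 500,
    rng: np.random.Generator | None = None,
    ci_level: float = 0.95,
    nodes: Iterable[DatedNode] | None = None,
) -> DatedTree:
    """Observed version of a true dated tree: noisy CIs on internal nodes.

    Tip ages are kept exact (they play the role of known tip
    calibrations).  Internal nodes outside ``nodes`` (default: all
    internal nodes) lose their point age rather than carrying a stale true
    value.
    """
    out = tree.copy()
    targets = (
        {nd.id for nd in out.internal_nodes()}
        if nodes is None
        else {(nd if isinstance(nd, str) else nd.id) for nd in nodes}
    )
    internal = [nd for nd in out.preorder() if not nd.is_leaf]
    index = {nd.id: i for i, nd in enumerate(internal)}
    times = [nd.age for nd in internal]
    parents = [
        index[nd.parent.id] if (nd.parent is not None and nd.parent.id in index) else None
        for nd in internal
    ]
    bounds = []
    for nd in internal:
        tip_ages = [lf.age or 0.0 for lf in nd.leaves()]
        bounds.append(max(tip_ages) if tip_ages else 0.0)
    centers, cis = simulate_age_posteriors(
        times, rel_sd, n_samples=n_samples, rng=rng, ci_level=ci_level,
        parents=parents, lower_bounds=bounds,
    )
    for nd, center, ci in zip(internal, centers, cis):
        if nd.id in targets:
            nd.age = center
            nd.ci = ci
        else:
            nd.age = None
            nd.ci = None
    out.validate()
    return out


# ---------------------------------------------------------------------------
# the bundled end-to-end scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FocusTruth:
    """A focal divergence: its node, true age, and observed interval."""

    label: str
    node_id: str
    true_age: float
    observed_ci: CredibleInterval
    observed_age: float


@dataclass(frozen=True)
class TruthBundle:
    """Everything a recovery experiment needs: truth plus observations."""

    config: SimulationConfig
    species_true: DatedTree
    species_observed: DatedTree
    history: DuplicationHistory
    glt_observed: GeneLineageTree
    foci: tuple[FocusTruth, ...]

    @property
    def backbone_tip(self) -> str:
        return self.history.backbone_tip


def _select_foci(tree: DatedTree, tip_label: str, n_foci: int, min_gap: float) -> list[DatedNode]:
    path = backbone_path(tree, tip_label)[1:]  # exclude the root: foci are
    # divergences below the origin of the gene family
    chosen: list[DatedNode] = []
    last_age = math.inf
    for nd in path:  # oldest first
        if nd.age is None:
            continue
        if last_age - nd.age >= min_gap or not chosen:
            chosen.append(nd)
            last_age = nd.age
        if len(chosen) == n_foci:
            break
    return chosen


def simulate_truth_bundle(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TruthBundle:
    """Simulate one full synthetic study: tree, duplications, noisy CIs.

    The default scenario mirrors the empirical design: four duplications
    along the backbone lineage, placed midway between five focal
    divergences (so each focus truly inherits one more paralogue than the
    one above it), then observed through calibrated noisy intervals.
    """
    rng = config.rng() if rng is None else rng
    for _ in range(config.max_tries):
        tree = simulate_species_tree(config, rng)
        tip = default_backbone_tip(tree)
        foci_nodes = _select_foci(tree, tip, config.n_foci, config.min_focus_gap)
        if len(foci_nodes) < config.n_foci:
            continue
        ages = [nd.age for nd in foci_nodes]
        if config.duplication_times is not None:
            dup_times = list(config.duplication_times)
        elif config.duplication_rate is not None:
            history = simulate_duplications(tree, tip, rate=config.duplication_rate, rng=rng)
            dup_times = list(history.times)
        else:
            upstream = [tree.root.age] + ages[:-1]
            dup_times = [0.5 * (a + b) for a, b in zip(upstream, ages)][: config.n_duplications]
        history = simulate_duplications(tree, tip, times=dup_times)

        # observed duplication chain: noisy CIs, chain-truncated
        if history.times:
            parents = [None] + list(range(len(history.times) - 1))
            _, dup_cis = simulate_age_posteriors(
                history.times,
                config.age_rel_sd,
                n_samples=config.n_posterior_samples,
                rng=rng,
                ci_level=config.ci_level,
                parents=parents,
            )
            events, precedence = _caterpillar_events(history.times, dup_cis)
            glt_observed = build_gene_lineage_tree(events, precedence)
        else:
            glt_observed = history.glt

        species_observed = perturb_tree_ages(
            tree,
            config.age_rel_sd,
            n_samples=config.n_posterior_samples,
            rng=rng,
            ci_level=config.ci_level,
            nodes=foci_nodes,
        )
        foci = []
        for nd in foci_nodes:
            obs = species_observed.node(nd.id)
            foci.append(
                FocusTruth(
                    label=nd.label or nd.id,
                    node_id=nd.id,
                    true_age=nd.age,
                    observed_ci=obs.ci,
                    observed_age=obs.age,
                )
            )
        return TruthBundle(
            config=config,
            species_true=tree,
            species_observed=species_observed,
            history=history,
            glt_observed=glt_observed,
            foci=tuple(foci),
        )
    raise SimulationError(
        f"could not assemble a scenario with {config.n_foci} well-separated foci in "
        f"{config.max_tries} attempts; lower min_focus_gap or n_foci"
    )


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryMetrics:
    """Aggregate recovery of true complements from noisy intervals."""

    n_compared: int
    n_exact: int
    n_overclaim: int
    n_underclaim: int

    @property
    def exact_rate(self) -> float:
        return self.n_exact / self.n_compared if self.n_compared else float("nan")

    @property
    def overclaim_rate(self) -> float:
        return self.n_overclaim / self.n_compared if self.n_compared else float("nan")

    @property
    def underclaim_rate(self) -> float:
        return self.n_underclaim / self.n_compared if self.n_compared else float("nan")

    def __add__(self, other: "RecoveryMetrics") -> "RecoveryMetrics":
        return RecoveryMetrics(
            self.n_compared + other.n_compared,
            self.n_exact + other.n_exact,
            self.n_overclaim + other.n_overclaim,
            self.n_underclaim + other.n_underclaim,
        )

    def as_dict(self) -> dict:
        return {
            "n_compared": self.n_compared,
            "n_exact": self.n_exact,
            "n_overclaim": self.n_overclaim,
            "n_underclaim": self.n_underclaim,
            "exact_rate": self.exact_rate,
            "overclaim_rate": self.overclaim_rate,
            "underclaim_rate": self.underclaim_rate,
        }


def infer_observed_complements(bundle: TruthBundle) -> ComplementTable:
    """Run the interval-comparison inference on the observed bundle."""
    foci = [(f.label, f.observed_ci) for f in bundle.foci]
    return infer_all(None, bundle.glt_observed, foci)


def evaluate_recovery(
    bundle: TruthBundle, inferred: ComplementTable | None = None
) -> RecoveryMetrics:
    """Compare inferred complements against the exact time-cut truth.

    Per focus: *overclaim* when the inferred set contains paralogues whose
    true duplication postdates the true divergence (some inferred gene is
    a strict descendant of a gene on the true frontier); *underclaim* when
    an ancestral gene was kept although its duplication truly precedes the
    divergence; *exact* otherwise.  The conservative interval rule makes
    overclaims the error the construction is designed to bound.
    """
    from .chronology import infer_complement  # local import to avoid cycles
    from .nomenclature import split_name

    if inferred is None:
        inferred = infer_observed_complements(bundle)
    n = n_exact = n_over = n_under = 0
    for focus in bundle.foci:
        truth = infer_complement(
            bundle.history.glt, CredibleInterval(focus.true_age, focus.true_age)
        )
        row = inferred[focus.label]
        got = {split_name(g) for g in row.genes}
        want = {split_name(g) for g in truth}
        n += 1
        if got == want:
            n_exact += 1
            continue
        over = any(g < w for g in got for w in want)
        under = any(w < g for g in got for w in want)
        if over:
            n_over += 1
        if under:
            n_under += 1
    return RecoveryMetrics(n, n_exact, n_over, n_under)


def run_recovery_experiment(
    config: SimulationConfig, n_replicates: int, seed: int | None = None
) -> RecoveryMetrics:
    """Aggregate recovery metrics over independent replicate studies."""
    base_seed = config.seed if seed is None else seed
    children = np.random.SeedSequence(base_seed).spawn(n_replicates)
    total = RecoveryMetrics(0, 0, 0, 0)
    for ss in children:
        rng = np.random.default_rng(ss)
        bundle = simulate_truth_bundle(config, rng)
        total = total + evaluate_recovery(bundle)
    return total
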