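"""Neutral coalescent simulation engine.

Simulates gene genealogies under panmictic, island-model, stepping-stone,
exponentially growing, and metapopulation (extinction–recolonization)
demographies, drops infinite-sites mutations on them (either at a scaled
rate theta = 4*N*mu or conditioned on an observed number of segregating
sites), and assembles diploid individuals from haplotype pools under
partial self-fertilization.

Time is measured in units of 2N generations, so with k lineages in a deme
of relative size 1 the coalescence rate is C(k,2) and E[TMRCA] for a pair
is 1.  Selfing is modeled at the diploidization step through the
equilibrium autozygosity probability F = s/(2-s); the within-genealogy
effective-size reduction 1/(1+F) can additionally be switched on with
``scale_by_selfing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DemographyModel",
    "CoalescentTree",
    "SimulatedLocus",
    "DiploidAssignment",
    "simulate_tree",
    "drop_mutations",
    "drop_fixed_s",
    "diploidize",
    "equilibrium_inbreeding",
    "write_ms_like",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def equilibrium_inbreeding(selfing_rate: float) -> float:
    """Equilibrium inbreeding coefficient F = s/(2-s) under selfing rate s."""
    if not 0.0 <= selfing_rate <= 1.0:
        raise ValueError(f"selfing rate must be in [0, 1], got {selfing_rate}")
    return selfing_rate / (2.0 - selfing_rate)


@dataclass
class DemographyModel:
    """Demographic scenario for the structured coalescent.

    Parameters
    ----------
    n_demes : int
        Number of demes.
    deme_sizes : sequence of float, optional
        Relative deme sizes (default all 1).
    migration_rate : float
        Scaled migration rate 4Nm; each lineage migrates at total rate
        ``migration_rate / 2`` under the island model.
    growth_rate : float
        Scaled exponential growth rate alpha >= 0 (0 = constant size);
        looking backward in time the coalescence rate is multiplied by
        ``exp(alpha * t)``.
    selfing_rate : float
        Selfing rate s in [0, 1]; consumed by :func:`diploidize` and, when
        ``scale_by_selfing`` is set, by the genealogy via Ne -> Ne/(1+F).
    topology : {"island", "stepping_stone"}
        Migration topology when no explicit matrix is given.
    migration_matrix : ndarray (n_demes, n_demes), optional
        Scaled deme-to-deme rates 4Nm[i, j]; overrides topology.
    extinction_rate : float
        Per-deme rate of extinction–recolonization events (metapopulation
        propagule model); on an event all lineages in the deme descend from
        at most ``n_founders`` founders drawn from one random source deme.
    n_founders : int
        Propagule size for recolonization.
    scale_by_selfing : bool
        Apply the 1/(1+F) effective-size reduction inside the genealogy.
    """

    n_demes: int = 1
    deme_sizes: list | None = None
    migration_rate: float = 0.0
    growth_rate: float = 0.0
    selfing_rate: float = 0.0
    topology: str = "island"
    migration_matrix: np.ndarray | None = None
    extinction_rate: float = 0.0
    n_founders: int = 1
    scale_by_selfing: bool = False

    def __post_init__(self):
        if self.n_demes < 1:
            raise ValueError("n_demes must be >= 1")
        if self.migration_rate < 0 or self.extinction_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must be in [0, 1]")
        if self.deme_sizes is None:
            self.deme_sizes = [1.0] * self.n_demes
        self.deme_sizes = list(map(float, self.deme_sizes))
        if len(self.deme_sizes) != self.n_demes:
            raise ValueError("deme_sizes length must equal n_demes")
        if self.migration_matrix is not None:
            self.migration_matrix = np.asarray(self.migration_matrix, float)
            if self.migration_matrix.shape != (self.n_demes, self.n_demes):
                raise ValueError("migration_matrix shape mismatch")

    def rate_matrix(self) -> np.ndarray:
        """Per-lineage migration rate matrix (rate from deme i to deme j)."""
        d = self.n_demes
        if self.migration_matrix is not None:
            M = self.migration_matrix / 2.0
        elif d == 1 or self.migration_rate == 0.0:
            M = np.zeros((d, d))
        elif self.topology == "stepping_stone":
            M = np.zeros((d, d))
            for i in range(d):
                for j in (i - 1, i + 1):
                    if 0 <= j < d:
                        M[i, j] = self.migration_rate / 4.0
        else:  # island: total per-lineage rate m/2 split over other demes
            M = np.full((d, d), self.migration_rate / (2.0 * (d - 1)))
        np.fill_diagonal(M, 0.0)
        return M


@dataclass
class CoalescentTree:
    """Binary (or multifurcation-free, zero-length-resolved) genealogy.

    Nodes ``0 .. n_leaves-1`` are leaves at time 0; internal nodes are
    appended in coalescence order.  ``parent[root] == -1``.
    """

    n_leaves: int
    parent: np.ndarray
    time: np.ndarray
    leaf_deme: np.ndarray | None = None
    _leaf_lists: list | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        bl = self.branch_lengths()
        return [
            (int(c), int(p), float(bl[c]))
            for c, p in enumerate(self.parent)
            if p >= 0
        ]

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    @property
    def tmrca(self) -> float:
        return float(self.time.max())

    def n_descendants(self) -> np.ndarray:
        """Number of leaf descendants below (and including) each node."""
        counts = np.zeros(self.n_nodes, dtype=int)
        counts[: self.n_leaves] = 1
        # children coalesce before parents, so node order is postorder-safe
        for c in np.argsort(self.time, kind="stable"):
            p = self.parent[c]
            if p >= 0:
                counts[p] += counts[c]
        return counts

    def leaf_lists(self) -> list[np.ndarray]:
        """Leaf indices below each node (cached)."""
        if self._leaf_lists is None:
            lists: list[list[int] | np.ndarray] = [[i] for i in range(self.n_leaves)]
            lists += [[] for _ in range(self.n_nodes - self.n_leaves)]
            for c in np.argsort(self.time, kind="stable"):
                p = self.parent[c]
                if p >= 0:
                    lists[p] = list(lists[p]) + list(lists[c])
            self._leaf_lists = [np.asarray(x, dtype=int) for x in lists]
        return self._leaf_lists

    def external_length(self) -> float:
        return float(self.branch_lengths()[: self.n_leaves].sum())


@dataclass
class SimulatedLocus:
    """Infinite-sites haplotypes simulated on a genealogy."""

    haplotypes: np.ndarray  # (n_leaves, S) uint8
    positions: np.ndarray  # sorted uniform(0,1)
    tree: CoalescentTree
    mutation_nodes: np.ndarray | None = None  # node below each mutated branch

    @property
    def n_segregating(self) -> int:
        return self.haplotypes.shape[1]

    def derived_counts(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)


def _sample_sizes_per_deme(n, model, sample_demes):
    if sample_demes is None:
        if model.n_demes == 1:
            return np.asarray([n], dtype=int)
        base = n // model.n_demes
        sizes = np.full(model.n_demes, base, dtype=int)
        sizes[: n - base * model.n_demes] += 1
        return sizes
    sizes = np.asarray(sample_demes, dtype=int)
    if sizes.sum() != n or len(sizes) != model.n_demes:
        raise ValueError("sample_demes must sum to n over n_demes entries")
    return sizes


def simulate_tree(n: int, model: DemographyModel | None = None, seed=None,
                  sample_demes=None) -> CoalescentTree:
    """Simulate one genealogy for *n* haploid lineages.

    ``sample_demes`` gives the number of sampled lineages per deme (defaults
    to spreading *n* as evenly as possible).  Raises if samples span demes
    that can never share an ancestor (zero migration, no recolonization).
    """
    if n < 2:
        raise ValueError("need at least 2 lineages")
    model = model or DemographyModel()
    rng = _rng(seed)
    sizes = _sample_sizes_per_deme(n, model, sample_demes)

    M = model.rate_matrix()
    row_rate = M.sum(axis=1)
    occupied = np.flatnonzero(sizes > 0)
    if (
        len(occupied) > 1
        and row_rate[occupied].max() == 0.0
        and model.extinction_rate == 0.0
    ):
        raise ValueError(
            "samples span multiple demes with zero migration and no "
            "recolonization: no common ancestor in finite expected time"
        )

    g = float(model.growth_rate)
    coal_scale = 1.0 + equilibrium_inbreeding(model.selfing_rate) if model.scale_by_selfing else 1.0

    # active lineages per deme (node ids)
    demes: list[list[int]] = [[] for _ in range(model.n_demes)]
    node = 0
    leaf_deme = np.zeros(n, dtype=int)
    for d, k in enumerate(sizes):
        for _ in range(k):
            demes[d].append(node)
            leaf_deme[node] = d
            node += 1

    parent = [-1] * n
    time = [0.0] * n
    t = 0.0
    n_active = n

    def new_node(tt):
        nonlocal node
        parent.append(-1)
        time.append(tt)
        node += 1
        return node - 1

    while n_active > 1:
        # candidate coalescence time per deme (inhomogeneous when growing)
        best_dt = np.inf
        best_event = None  # ("coal", d) | ("mig",) | ("ext",)
        for d in range(model.n_demes):
            k = len(demes[d])
            if k < 2:
                continue
            lam0 = coal_scale * k * (k - 1) / 2.0 / model.deme_sizes[d]
            e = rng.exponential()
            if g == 0.0:
                dt = e / lam0
            else:
                dt = np.log(np.exp(g * t) + g * e / lam0) / g - t
            if dt < best_dt:
                best_dt, best_event = dt, ("coal", d)
        mig_rate = sum(len(demes[d]) * row_rate[d] for d in range(model.n_demes))
        if mig_rate > 0:
            dt = rng.exponential() / mig_rate
            if dt < best_dt:
                best_dt, best_event = dt, ("mig",)
        if model.extinction_rate > 0:
            dt = rng.exponential() / (model.extinction_rate * model.n_demes)
            if dt < best_dt:
                best_dt, best_event = dt, ("ext",)
        if not np.isfinite(best_dt):
            raise RuntimeError("no feasible event; disconnected configuration")
        t += best_dt

        kind = best_event[0]
        if kind == "coal":
            d = best_event[1]
            i, j = rng.choice(len(demes[d]), size=2, replace=False)
            a, b = demes[d][i], demes[d][j]
            anc = new_node(t)
            parent[a] = parent[b] = anc
            for x in sorted((i, j), reverse=True):
                demes[d].pop(x)
            demes[d].append(anc)
            n_active -= 1
        elif kind == "mig":
            weights = np.array([len(demes[d]) * row_rate[d] for d in range(model.n_demes)])
            d = rng.choice(model.n_demes, p=weights / weights.sum())
            i = rng.integers(len(demes[d]))
            lin = demes[d].pop(i)
            dest = rng.choice(model.n_demes, p=M[d] / M[d].sum())
            demes[dest].append(lin)
        else:  # extinction–recolonization
            d = rng.integers(model.n_demes)
            lineages = demes[d]
            if lineages:
                founders: dict[int, int] = {}
                survivors = []
                for lin in lineages:
                    slot = int(rng.integers(model.n_founders))
                    if slot in founders:
                        anc = new_node(t)
                        parent[lin] = anc
                        parent[founders[slot]] = anc
                        founders[slot] = anc
                        n_active -= 1
                    else:
                        founders[slot] = lin
                survivors = list(founders.values())
                demes[d] = []
                if model.n_demes > 1:
                    src = int(rng.integers(model.n_demes - 1))
                    if src >= d:
                        src += 1
                else:
                    src = d
                demes[src].extend(survivors)

    return CoalescentTree(
        n_leaves=n,
        parent=np.asarray(parent, dtype=int),
        time=np.asarray(time, dtype=float),
        leaf_deme=leaf_deme if model.n_demes > 1 else None,
    )


def _build_locus(tree: CoalescentTree, mutated_nodes: np.ndarray, rng) -> SimulatedLocus:
    s = len(mutated_nodes)
    haps = np.zeros((tree.n_leaves, s), dtype=np.uint8)
    if s:
        lists = tree.leaf_lists()
        for j, nd in enumerate(mutated_nodes):
            haps[lists[nd], j] = 1
    pos = np.sort(rng.uniform(size=s))
    return SimulatedLocus(haplotypes=haps, positions=pos, tree=tree,
                          mutation_nodes=np.asarray(mutated_nodes, dtype=int))


def _sample_branches(tree: CoalescentTree, size: int, rng) -> np.ndarray:
    bl = tree.branch_lengths()
    total = bl.sum()
    if total <= 0:
        raise ValueError("tree has zero total length")
    return rng.choice(tree.n_nodes, size=size, p=bl / total)


def drop_mutations(tree: CoalescentTree, theta: float, seed=None) -> SimulatedLocus:
    """Poisson infinite-sites mutations at scaled rate theta = 4*N*mu.

    The expected number of segregating sites is ``theta * L_total / 2``
    where L_total is the tree length in units of 2N generations, i.e.
    E[S] = theta * sum_{i<n} 1/i for a constant-size panmictic genealogy.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = _rng(seed)
    s = rng.poisson(theta * tree.total_length / 2.0)
    nodes = _sample_branches(tree, s, rng) if s else np.empty(0, dtype=int)
    return _build_locus(tree, nodes, rng)


def drop_fixed_s(tree: CoalescentTree, s_obs: int, seed=None) -> SimulatedLocus:
    """Place exactly ``s_obs`` mutations, branches chosen proportional to length.

    This is the fixed-S conditioning convention used by DnaSP-style null
    distributions for Tajima's D and related statistics.
    """
    if s_obs < 0:
        raise ValueError("s_obs must be >= 0")
    rng = _rng(seed)
    nodes = _sample_branches(tree, s_obs, rng) if s_obs else np.empty(0, dtype=int)
    return _build_locus(tree, nodes, rng)


@dataclass
class DiploidAssignment:
    """Pairing of pool haplotypes into diploid individuals.

    ``pairs[i] = (a, b)`` are the two haplotype rows of individual *i*
    (``a == b`` when the individual is autozygous); ``genotypes`` is the
    dosage matrix when the pool carried sequence data.
    """

    pairs: np.ndarray  # (n_ind, 2) indices into the pool
    autozygous: np.ndarray  # (n_ind,) bool
    genotypes: np.ndarray | None = None  # (n_ind, S) dosage


def diploidize(haplotype_pool, selfing_rate: float, seed=None,
               n_individuals: int | None = None) -> DiploidAssignment:
    """Assemble diploids from a haplotype pool under partial selfing.

    With probability F = s/(2-s) an individual is autozygous and carries one
    pool haplotype duplicated; otherwise it receives two distinct haplotypes.
    Assignment consumes a shuffled pool sequentially, so the pool must hold
    at least ``2 * n_individuals`` rows.  Realized FIS converges to F.
    """
    rng = _rng(seed)
    F = equilibrium_inbreeding(selfing_rate)
    if isinstance(haplotype_pool, SimulatedLocus):
        pool = haplotype_pool.haplotypes
        n_pool = pool.shape[0]
    elif np.isscalar(haplotype_pool):
        pool, n_pool = None, int(haplotype_pool)
    else:
        pool = np.asarray(haplotype_pool)
        n_pool = pool.shape[0]
    if n_individuals is None:
        n_individuals = n_pool // 2
    if 2 * n_individuals > n_pool:
        raise ValueError("haplotype pool too small for requested individuals")
    order = rng.permutation(n_pool)
    auto = rng.random(n_individuals) < F
    pairs = np.empty((n_individuals, 2), dtype=int)
    cursor = 0
    for i in range(n_individuals):
        a = order[cursor]
        cursor += 1
        if auto[i]:
            pairs[i] = (a, a)
        else:
            pairs[i] = (a, order[cursor])
            cursor += 1
    genotypes = None
    if pool is not None and pool.ndim == 2:
        genotypes = pool[pairs[:, 0]].astype(np.int8) + pool[pairs[:, 1]].astype(np.int8)
    return DiploidAssignment(pairs=pairs, autozygous=auto, genotypes=genotypes)


def write_ms_like(loci: list[SimulatedLocus], path, command: str = "ivypop") -> None:
    """Write segregating-sites output in the ms text format for cross-checks."""
    with open(path, "w") as fh:
        n = loci[0].haplotypes.shape[0] if loci else 0
        fh.write(f"{command} {n} {len(loci)}\n\n")
        for locus in loci:
            fh.write("//\n")
            fh.write(f"segsites: {locus.n_segregating}\n")
            if locus.n_segregating:
                fh.write("positions: " + " ".join(f"{p:.5f}" for p in locus.positions) + "\n")
                for row in locus.haplotypes:
                    fh.write("".join(map(str, row)) + "\n")
            fh.write("\n")
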