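"""Synthetic Y-STR data with known ground truth.

Haplotypes evolve under the symmetric single-step stepwise mutation model
(SMM): at each locus and generation a mutation occurs with probability mu
and shifts the repeat count by +1 or -1 with equal probability.  This is
the idealization under which the ASD clock is exactly unbiased
(E[squared displacement after t generations] = mu * t); no multi-step
mutations or allele-range constraints are modeled.

Three generators are provided: independent lineages radiating from a
founder (``simulate_star``), a Kingman coalescent genealogy
(``simulate_coalescent``) and a full two-population regional scenario
(``simulate_region_scenario``) with old cross-population clusters plus
young and single-population decoys — the synthetic stand-in for a
substrate-screening study, with every sample's cluster and true age
recorded in a :class:`ScenarioTruth`.

By default mutation counts per (lineage, locus) are drawn
Poisson(mu * t) with signed random-walk steps — equivalent in
distribution to per-generation simulation for mu * t << 1 and far
faster; the exact per-generation mode is available via
``exact_per_generation=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

from .io import Haplotype, HaplotypeSet, LocusPanel, default_panel

#: population-label -> population-group mapping used by the regional scenario
GROUP_OF = {
    "Ryazan-Russian": "Slavic",
    "Erzya": "Finnic",
    "Moksha": "Finnic",
    "Shoksha": "Finnic",
}

FINNIC_POPULATIONS = ("Erzya", "Moksha", "Shoksha")
#: relative sizes of the three Finnic-speaking subgroups (Erzya-heavy)
FINNIC_WEIGHTS = (0.60, 0.29, 0.11)

#: search-group labels the scenario's cluster branches are assigned to
SEARCH_GROUPS = ("Y3910", "Y33(xY1390)", "Y35(xY33)", "CTS1211(xY35)", "Z92")


@dataclass
class SimulationConfig:
    """Configuration of a single-cluster simulation."""

    panel: LocusPanel
    founder: dict | Sequence[float]
    genealogy: str = "star"  # "star" | "coalescent"
    T_years: float = 2000.0  # true TMRCA (star) ...
    Ne: float = 500.0        # ... or haploid effective size (coalescent)
    n: int = 25
    generation_interval: float = 31.5
    seed: int = 0
    population: str = "pop"
    exact_per_generation: bool = False

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.T_years < 0:
            raise ValueError("T_years must be non-negative")
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")


@dataclass
class ClusterTruth:
    label: str
    search_group: str
    founder: dict
    age_years: float
    informative: bool
    populations: dict[str, int] = field(default_factory=dict)
    samples: list[str] = field(default_factory=list)


@dataclass
class ScenarioTruth:
    """Ground truth of a generated scenario: per-cluster founders/ages and
    the sample -> cluster assignment."""

    clusters: list[ClusterTruth]
    sample_cluster: dict[str, str]
    seed: int = 0
    provenance: str = ""

    def informative_labels(self) -> set[str]:
        return {c.label for c in self.clusters if c.informative}

    def to_yaml(self, path) -> None:
        doc = {
            "seed": self.seed,
            "provenance": self.provenance,
            "clusters": [asdict(c) for c in self.clusters],
            "sample_cluster": dict(self.sample_cluster),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioTruth":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        clusters = [ClusterTruth(**c) for c in doc["clusters"]]
        return cls(clusters=clusters, sample_cluster=doc["sample_cluster"],
                   seed=doc.get("seed", 0), provenance=doc.get("provenance", ""))


# ---------------------------------------------------------------------------
# SMM machinery

def _encode_founder(panel: LocusPanel, founder) -> np.ndarray:
    vec = panel.encode(founder) if isinstance(founder, dict) else np.asarray(founder, dtype=float)
    if np.isnan(vec).any():
        raise ValueError("founder must be fully typed on the panel")
    return vec


def _smm_drift(rng: np.random.Generator, shape: tuple, mu: np.ndarray,
               t_gen: int, exact: bool) -> np.ndarray:
    """Net signed repeat displacement for each (lineage, column)."""
    if exact:
        hits = rng.random((t_gen, *shape)) < mu
        signs = rng.integers(0, 2, size=(t_gen, *shape)) * 2 - 1
        return (hits * signs).sum(axis=0)
    k = rng.poisson(mu * t_gen, size=shape)
    # net of k symmetric unit steps: 2*Binomial(k, 1/2) - k
    return 2 * rng.binomial(k, 0.5) - k


def _evolve_star(rng, founder_vec, mu, t_gen, n, exact=False) -> np.ndarray:
    drift = _smm_drift(rng, (n, founder_vec.size), mu, t_gen, exact)
    return founder_vec[None, :] + drift


def _states_to_haplotypes(panel, states, sample_ids, populations,
                          snp_branch="", districts=None) -> list[Haplotype]:
    out = []
    for i, sid in enumerate(sample_ids):
        out.append(Haplotype(
            sample_id=sid,
            repeats=panel.decode(states[i]),
            population=populations[i],
            district=districts[i] if districts else "",
            snp_branch=snp_branch,
        ))
    return out


# ---------------------------------------------------------------------------
# generators

def simulate_star(cfg: SimulationConfig) -> tuple[HaplotypeSet, ScenarioTruth]:
    """Evolve n independent lineages from the founder for T_years.

    Every lineage accumulates SMM mutations over
    ``round(T_years / generation_interval)`` generations.  Deterministic
    given the seed.
    """
    if cfg.genealogy != "star":
        raise ValueError("simulate_star requires genealogy='star'")
    panel = cfg.panel
    rng = np.random.default_rng(cfg.seed)
    fvec = _encode_founder(panel, cfg.founder)
    t_gen = int(round(cfg.T_years / cfg.generation_interval))
    states = _evolve_star(rng, fvec, panel.column_mu, t_gen, cfg.n,
                          cfg.exact_per_generation)
    ids = [f"S{i:04d}" for i in range(cfg.n)]
    haps = _states_to_haplotypes(panel, states, ids, [cfg.population] * cfg.n)
    hs = HaplotypeSet(panel, haps, provenance=f"simulate_star(seed={cfg.seed})")
    truth = ScenarioTruth(
        clusters=[ClusterTruth(label="star", search_group="", founder=panel.decode(fvec),
                               age_years=float(t_gen * cfg.generation_interval),
                               informative=False,
                               populations={cfg.population: cfg.n}, samples=ids)],
        sample_cluster={sid: "star" for sid in ids},
        seed=cfg.seed, provenance=hs.provenance,
    )
    return hs, truth


def simulate_coalescent(cfg: SimulationConfig) -> tuple[HaplotypeSet, dict]:
    """Simulate haplotypes on a Kingman coalescent genealogy.

    Haploid scaling: with k extant lineages the coalescence rate is
    k(k-1)/2 per Ne generations, so waiting times are
    Exp(mean = 2*Ne / (k(k-1))) generations and E[TMRCA] = Ne generations
    for n = 2.  SMM mutations are dropped on branches as Poisson(mu * length)
    per locus.  Returns the haplotype set and the true genealogy
    (parent map, branch lengths in generations, per-branch mutation counts,
    root time).
    """
    if cfg.genealogy != "coalescent":
        raise ValueError("simulate_coalescent requires genealogy='coalescent'")
    panel = cfg.panel
    rng = np.random.default_rng(cfg.seed)
    fvec = _encode_founder(panel, cfg.founder)
    n = cfg.n

    # Kingman tree: node ids 0..n-1 tips, internal nodes appended
    times = {i: 0.0 for i in range(n)}
    parent: dict[int, int] = {}
    active = list(range(n))
    t = 0.0
    next_id = n
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1) / 2.0 / cfg.Ne  # per generation
        t += rng.exponential(1.0 / rate)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        times[next_id] = t
        parent[a] = parent[b] = next_id
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    root = active[0]

    # drop mutations root -> tips
    states = {root: fvec.copy()}
    mutations: dict[int, int] = {}
    children: dict[int, list[int]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    order = [root]
    for node in order:
        for c in sorted(children.get(node, [])):
            blen = times[node] - times[c]
            k_mut = rng.poisson(panel.column_mu * blen)
            drift = 2 * rng.binomial(k_mut, 0.5) - k_mut
            states[c] = states[node] + drift
            mutations[c] = int(k_mut.sum())
            order.append(c)

    ids = [f"S{i:04d}" for i in range(n)]
    haps = _states_to_haplotypes(panel, [states[i] for i in range(n)], ids,
                                 [cfg.population] * n)
    hs = HaplotypeSet(panel, haps, provenance=f"simulate_coalescent(seed={cfg.seed})")
    genealogy = {
        "parent": parent,
        "times_generations": times,
        "branch_mutations": mutations,
        "tmrca_generations": times[root],
        "tmrca_years": times[root] * cfg.generation_interval,
        "root": root,
    }
    return hs, genealogy


# ---------------------------------------------------------------------------
# regional scenario

@dataclass
class RegionScenarioConfig:
    """The default regional scenario: ~400 haplotypes on a 37-value panel,
    one Slavic-labeled group and three Finnic-labeled subgroups, ten old
    cross-population clusters (true ages 1600-2900 y) plus two young mixed
    and two old single-population decoy clusters, founders at least
    ``min_founder_sep`` mutation steps apart."""

    panel: Optional[LocusPanel] = None
    n_informative: int = 10
    n_young_decoys: int = 2
    n_single_pop_decoys: int = 2
    age_range: tuple[float, float] = (1600.0, 2900.0)
    young_age_range: tuple[float, float] = (150.0, 550.0)
    informative_size_range: tuple[int, int] = (15, 45)
    decoy_size_range: tuple[int, int] = (15, 35)
    slavic_frac_range: tuple[float, float] = (0.30, 0.60)
    min_founder_sep: int = 6
    base_repeat: int = 14
    generation_interval: float = 31.5
    seed: int = 0

    def __post_init__(self):
        if self.panel is None:
            self.panel = default_panel()
        if self.n_informative < 1:
            raise ValueError("need at least one informative cluster")
        if self.n_young_decoys + self.n_single_pop_decoys < 1:
            raise ValueError("need at least one decoy cluster")


def _draw_founders(rng, panel, k, sep, base) -> np.ndarray:
    """k founder states pairwise >= sep unweighted steps apart."""
    L = panel.L
    if sep > 2 * L:
        raise ValueError("infeasible founder separation for panel size")
    base_vec = np.full(L, float(base))
    founders = []
    for _ in range(k):
        for _attempt in range(1000):
            cand = base_vec.copy()
            cols = rng.choice(L, size=sep, replace=False)
            cand[cols] += rng.integers(0, 2, size=sep) * 2 - 1
            # extra scatter so founders do not sit on a tight shell
            extra = rng.integers(0, sep // 2 + 1)
            if extra:
                cols2 = rng.choice(L, size=extra, replace=False)
                cand[cols2] += rng.integers(0, 2, size=extra) * 2 - 1
            if all(np.abs(cand - f).sum() >= sep for f in founders):
                founders.append(cand)
                break
        else:
            raise ValueError("infeasible founder separation for panel size")
    return np.vstack(founders)


def _assign_populations(rng, n, slavic_frac, mode) -> list[str]:
    """mode: 'mixed' (both groups guaranteed), 'slavic', 'finnic'."""
    if mode == "slavic":
        return ["Ryazan-Russian"] * n
    if mode == "finnic":
        pops = list(rng.choice(FINNIC_POPULATIONS, size=n, p=FINNIC_WEIGHTS))
        return [str(p) for p in pops]
    pops = []
    for i in range(n):
        if i == 0:
            pops.append("Ryazan-Russian")
        elif i == 1:
            pops.append(str(rng.choice(FINNIC_POPULATIONS, p=FINNIC_WEIGHTS)))
        elif rng.random() < slavic_frac:
            pops.append("Ryazan-Russian")
        else:
            pops.append(str(rng.choice(FINNIC_POPULATIONS, p=FINNIC_WEIGHTS)))
    return pops


def simulate_region_scenario(cfg: Optional[RegionScenarioConfig] = None,
                             ) -> tuple[HaplotypeSet, ScenarioTruth]:
    """Generate the two-population regional scenario with known truth.

    Each cluster is a star radiation from its own founder; cluster branch
    labels are distributed over five search groups.  The truth records each
    cluster's founder, true age, population mix and whether it was planted
    as informative (old AND cross-population).
    """
    cfg = cfg or RegionScenarioConfig()
    panel = cfg.panel
    rng = np.random.default_rng(cfg.seed)

    k_total = cfg.n_informative + cfg.n_young_decoys + cfg.n_single_pop_decoys
    founders = _draw_founders(rng, panel, k_total, cfg.min_founder_sep, cfg.base_repeat)

    specs = []  # (label, age, size, mode, informative)
    for i in range(cfg.n_informative):
        age = float(rng.uniform(*cfg.age_range))
        size = int(rng.integers(cfg.informative_size_range[0],
                                cfg.informative_size_range[1] + 1))
        specs.append((f"B{i + 1:02d}", age, size, "mixed", True))
    for i in range(cfg.n_young_decoys):
        age = float(rng.uniform(*cfg.young_age_range))
        size = int(rng.integers(cfg.decoy_size_range[0], cfg.decoy_size_range[1] + 1))
        specs.append((f"B{cfg.n_informative + i + 1:02d}", age, size, "mixed", False))
    for i in range(cfg.n_single_pop_decoys):
        age = float(rng.uniform(*cfg.age_range))
        size = int(rng.integers(cfg.decoy_size_range[0], cfg.decoy_size_range[1] + 1))
        mode = "slavic" if i % 2 == 0 else "finnic"
        specs.append((f"B{cfg.n_informative + cfg.n_young_decoys + i + 1:02d}",
                      age, size, mode, False))

    haps: list[Haplotype] = []
    clusters: list[ClusterTruth] = []
    sample_cluster: dict[str, str] = {}
    sid = 0
    for ci, (label, age, size, mode, informative) in enumerate(specs):
        t_gen = int(round(age / cfg.generation_interval))
        states = _evolve_star(rng, founders[ci], panel.column_mu, t_gen, size)
        slavic_frac = float(rng.uniform(*cfg.slavic_frac_range))
        pops = _assign_populations(rng, size, slavic_frac, mode)
        ids = [f"S{sid + i:04d}" for i in range(size)]
        sid += size
        search_group = SEARCH_GROUPS[ci % len(SEARCH_GROUPS)]
        haps.extend(_states_to_haplotypes(panel, states, ids, pops, snp_branch=label))
        pop_counts: dict[str, int] = {}
        for p in pops:
            pop_counts[p] = pop_counts.get(p, 0) + 1
        clusters.append(ClusterTruth(
            label=label, search_group=search_group,
            founder=panel.decode(founders[ci]),
            age_years=float(t_gen * cfg.generation_interval),
            informative=informative, populations=pop_counts, samples=ids))
        sample_cluster.update({s: label for s in ids})

    hs = HaplotypeSet(panel, haps,
                      provenance=f"simulate_region_scenario(seed={cfg.seed})")
    truth = ScenarioTruth(clusters=clusters, sample_cluster=sample_cluster,
                          seed=cfg.seed, provenance=hs.provenance)
    return hs, truth


def branch_search_group_map(truth: ScenarioTruth) -> dict[str, str]:
    """Branch-label -> search-group map recorded in a scenario truth."""
    return {c.label: c.search_group for c in truth.clusters}
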