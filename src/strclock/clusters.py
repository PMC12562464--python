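"""Partitioning, cluster delimitation and the informative-cluster screen.

A cluster is "informative" for substrate detection when it simultaneously
(1) contains members of every required population group (by default one
Slavic-labeled and one Finnic-labeled group) and (2) predates the reference
colonization horizon — its age, taken conservatively as the minimum of the
ASD and rho point estimates, exceeds ``min_age_ybp`` (default 1000 years).
Clusters failing either requirement are flagged non-informative with the
reason recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io import HaplotypeSet
from .network import MJNetwork, ParsimonyTree, infer_founder
from .simulate import GROUP_OF

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class FilterCriteria:
    """The two-criterion informative-cluster screen."""

    required_groups: tuple[str, ...] = ("Slavic", "Finnic")
    min_age_ybp: float = 1000.0

    def __post_init__(self):
        if self.min_age_ybp <= 0:
            raise ValueError("min_age_ybp must be positive")
        if len(self.required_groups) < 2:
            raise ValueError("need at least two required population groups")


@dataclass
class Cluster:
    """A set of samples with an inferred founder and per-method ages."""

    label: str
    sample_ids: list[str]
    populations: dict[str, int] = field(default_factory=dict)
    founder: Optional[dict] = None
    ages: dict = field(default_factory=dict)  # method -> TmrcaEstimate
    informative: Optional[bool] = None
    reason: str = ""

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def min_age_ybp(self) -> float:
        if not self.ages:
            raise ValueError(f"cluster {self.label} has no age estimates")
        return min(est.t_years for est in self.ages.values())


def partition_by_snp(hs: HaplotypeSet,
                     branch_map: Optional[Mapping[str, str]] = None
                     ) -> dict[str, HaplotypeSet]:
    """Disjoint exhaustive partition of a haplotype set by Y-SNP branch.

    ``branch_map`` optionally maps fine branch labels onto coarser search
    groups (exclusion syntax "A(xB)" — carries A, lacks B — is treated as an
    opaque label).  Samples with an empty branch label go into an
    "unassigned" bin with a warning.
    """
    bins: dict[str, list] = {}
    n_unassigned = 0
    for h in hs.haplotypes:
        label = h.snp_branch.strip()
        if not label:
            label = UNASSIGNED
            n_unassigned += 1
        elif branch_map is not None:
            label = branch_map.get(label, label)
        bins.setdefault(label, []).append(h)
    if n_unassigned:
        logger.warning("%d samples without a Y-SNP branch collected into %r",
                       n_unassigned, UNASSIGNED)
    return {label: replace(hs, haplotypes=haps, provenance=hs.provenance)
            for label, haps in sorted(bins.items())}


def delimit_clusters(hs: HaplotypeSet, *, mode: str = "snp",
                     net: Optional[MJNetwork] = None,
                     tree: Optional[ParsimonyTree] = None,
                     min_subtree_size: int = 3) -> list[Cluster]:
    """Delimit clusters within one search group.

    ``mode="snp"`` (default): clusters are the samples sharing a terminal
    Y-SNP branch label — the primary rule, validated against the SNP
    phylogeny.  ``mode="subtree"``: for data without fine SNP labels,
    clusters are the maximal subtrees hanging off the branches adjacent to
    the root of the group's parsimony tree (requires ``net``; unless a
    ``tree`` is supplied, the tree is rooted at its centroid — the balance
    point that keeps distinct radiations in distinct subtrees).
    """
    if mode == "snp":
        groups: dict[str, list] = {}
        for h in hs.haplotypes:
            groups.setdefault(h.snp_branch.strip() or UNASSIGNED, []).append(h)
        return [_make_cluster(label, haps) for label, haps in sorted(groups.items())]

    if mode != "subtree":
        raise ValueError(f"unknown mode {mode!r}")
    if net is None:
        raise ValueError("subtree mode requires the group's network")
    if tree is None:
        from .network import extract_parsimony_tree, tree_centroid
        rough = extract_parsimony_tree(net, infer_founder(net))
        tree = extract_parsimony_tree(net, tree_centroid(rough))
    by_sample = {h.sample_id: h for h in hs.haplotypes}
    kids: dict = {}
    for k, p in tree.parent.items():
        if p is not None:
            kids.setdefault(p, []).append(k)
    children = sorted(kids.get(tree.root, []),
                      key=lambda k: tuple(-1 if v is None else v for v in k))
    subtrees: list[list[str]] = []
    for child in children:
        samples: list[str] = []
        stack = [child]
        while stack:
            node = stack.pop()
            samples.extend(tree.tree.nodes[node].get("samples", []))
            stack.extend(kids.get(node, []))
        subtrees.append(sorted(samples))
    # the root's own radiation: its samples plus any sub-minimum subtree
    # (small root-adjacent offshoots belong to the radiation around the root,
    # not to a separate cluster)
    root_samples = list(tree.tree.nodes[tree.root].get("samples", []))
    clusters = []
    i = 0
    for samples in subtrees:
        if len(samples) < min_subtree_size:
            root_samples.extend(samples)
        elif samples:
            i += 1
            clusters.append(_make_cluster(f"subtree{i:02d}",
                                          [by_sample[s] for s in samples]))
    if root_samples:
        clusters.insert(0, _make_cluster("root", [by_sample[s]
                                                  for s in sorted(root_samples)]))
    return clusters


def _make_cluster(label, haps) -> Cluster:
    pops: dict[str, int] = {}
    for h in haps:
        pops[h.population] = pops.get(h.population, 0) + 1
    return Cluster(label=label, sample_ids=[h.sample_id for h in haps],
                   populations=pops)


def filter_informative(clusters: Sequence[Cluster], crit: FilterCriteria,
                       group_of: Mapping[str, str] = GROUP_OF) -> list[Cluster]:
    """Apply the two-criterion screen; returns clusters with flags set.

    informative <=> every required group is represented by at least one
    member AND the minimum of the per-method point ages exceeds
    ``crit.min_age_ybp``.  The screen is monotone: lowering the age
    threshold or dropping a required group never removes a cluster from the
    informative set.
    """
    out = []
    for c in clusters:
        age = c.min_age_ybp()  # raises if ages absent
        groups = {group_of.get(p, p) for p, n in c.populations.items() if n > 0}
        missing = [g for g in crit.required_groups if g not in groups]
        if missing:
            flag, reason = False, "single-group"
        elif age <= crit.min_age_ybp:
            flag, reason = False, "too young"
        else:
            flag, reason = True, "ok"
        out.append(replace(c, informative=flag, reason=reason))
    return out


def share_pct(k: int, n: int) -> float:
    """Percentage share k/n (NA-safe handled by caller)."""
    if n == 0:
        raise ValueError("denominator is zero")
    return 100.0 * k / n


def population_share_pct(carrier_share_pct: float, haplogroup_freq_pct: float) -> float:
    """Population-level share: in-cluster share among carriers times the
    haplogroup's frequency in the population (both in percent)."""
    return carrier_share_pct * haplogroup_freq_pct / 100.0


def membership_summary(clusters: Sequence[Cluster], hs: HaplotypeSet,
                       group_of: Mapping[str, str] = GROUP_OF,
                       haplogroup_freq_pct: Optional[Mapping[str, float]] = None
                       ) -> pd.DataFrame:
    """Per population group: carriers inside informative clusters, totals,
    percentages, and (when the haplogroup's population frequency is given)
    the derived population-level share."""
    if any(c.informative is None for c in clusters):
        raise ValueError("informative flags not set; run filter_informative first")
    informative_samples = {s for c in clusters if c.informative for s in c.sample_ids}
    totals: dict[str, int] = {}
    inside: dict[str, int] = {}
    for h in hs.haplotypes:
        g = group_of.get(h.population, h.population)
        totals[g] = totals.get(g, 0) + 1
        if h.sample_id in informative_samples:
            inside[g] = inside.get(g, 0) + 1
    rows = []
    for g in sorted(totals):
        n, k = totals[g], inside.get(g, 0)
        pct = share_pct(k, n) if n else float("nan")
        row = {"group": g, "in_informative": k, "total": n, "pct": pct}
        if haplogroup_freq_pct and g in haplogroup_freq_pct:
            row["population_share_pct"] = population_share_pct(pct, haplogroup_freq_pct[g])
        rows.append(row)
    return pd.DataFrame(rows)
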