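"""Cluster dating by two independent Y-STR molecular clocks.

Both estimators convert observed repeat-unit variation around a founder
haplotype into an age:

* **ASD** — the average squared distance between member haplotypes and the
  founder.  Under the symmetric single-step mutation model the expected
  squared displacement per locus after t generations is exactly ``mu * t``,
  so ``t = ASD / mu`` is unbiased regardless of multiple hits.
* **rho** — the mean number of mutational steps from the root to each
  sampled haplotype on a rooted parsimony tree, with
  ``t = rho / (L * mu)``.  rho counts *observed* steps, so back mutations
  hidden by the single-step process make it increasingly conservative
  (younger) for old clusters; see the methods note.

Ages are reported in generations and calendar years (years before the
analysis date; no calibration offset is applied).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import Haplotype, LocusPanel
from .network import ParsimonyTree


@dataclass(frozen=True)
class ClockParams:
    """Molecular-clock constants: the marker panel (carrying per-locus
    mutation rates) and the generation interval in years."""

    panel: LocusPanel
    generation_interval: float = 31.5

    def __post_init__(self):
        if self.generation_interval <= 0:
            raise ValueError("generation interval must be positive")


@dataclass(frozen=True)
class TmrcaEstimate:
    """A point age with its standard error, tagged by estimation method."""

    method: str  # "ASD" | "rho"
    t_generations: float
    se_generations: float
    n: int
    generation_interval: float
    rho: Optional[float] = None

    @property
    def t_years(self) -> float:
        return self.t_generations * self.generation_interval

    @property
    def se_years(self) -> float:
        return self.se_generations * self.generation_interval


def _encode_members(members: Sequence, panel: LocusPanel) -> np.ndarray:
    rows = []
    for m in members:
        if isinstance(m, Haplotype):
            rows.append(panel.encode(m.repeats))
        else:
            rows.append(np.asarray(m, dtype=float))
    return np.vstack(rows)


def _column_mean(sq: np.ndarray) -> np.ndarray:
    """Column means ignoring NaN; NaN for columns with no data."""
    counts = (~np.isnan(sq)).sum(axis=0)
    out = np.full(sq.shape[1], np.nan)
    has = counts > 0
    out[has] = np.nansum(sq[:, has], axis=0) / counts[has]
    return out


def asd_tmrca(members: Sequence, founder, clock: ClockParams, *,
              n_boot: int = 1000, seed: int = 0,
              pairwise: bool = False) -> TmrcaEstimate:
    """Date a cluster by average squared distance to its founder.

    ``ASD = (1/L') * sum over compared loci of mean over members of
    (repeat - founder repeat)^2`` where L' counts loci typed in the founder
    and at least one member; the age is ``ASD / mean(mu)`` generations.  The
    standard error comes from a seeded bootstrap over loci (columns).

    With ``pairwise=True`` the founder is ignored and ASD is computed as
    half the mean pairwise squared difference — a comparison variant; the
    founder-based form is the primary estimator.
    """
    panel = clock.panel
    X = _encode_members(members, panel)
    if X.shape[0] == 0:
        raise ValueError("members must be non-empty")

    if pairwise:
        n = X.shape[0]
        sq = (X[:, None, :] - X[None, :, :]) ** 2
        iu = np.triu_indices(n, 1)
        col_mean = _column_mean(sq[iu]) / 2.0 if n > 1 else np.zeros(panel.L)
    else:
        f = panel.encode(founder) if isinstance(founder, dict) else np.asarray(founder, dtype=float)
        if np.all(np.isnan(f)):
            raise ValueError("founder state is missing at all loci")
        sq = (X - f) ** 2  # NaN wherever member or founder missing
        col_mean = _column_mean(sq)

    used = ~np.isnan(col_mean)
    if not used.any():
        raise ValueError("no loci compared between members and founder")
    mu = panel.column_mu[used]
    vals = col_mean[used]
    asd = float(vals.mean())
    t_gen = asd / float(mu.mean())

    rng = np.random.default_rng(seed)
    k = vals.size
    idx = rng.integers(0, k, size=(n_boot, k))
    boot_t = vals[idx].mean(axis=1) / mu[idx].mean(axis=1)
    se_gen = float(boot_t.std(ddof=1)) if n_boot > 1 else 0.0

    return TmrcaEstimate(method="ASD", t_generations=float(t_gen),
                         se_generations=se_gen, n=X.shape[0],
                         generation_interval=clock.generation_interval)


def rho_tmrca(tree: ParsimonyTree, clock: ClockParams) -> TmrcaEstimate:
    """Date a cluster by the rho statistic on a rooted parsimony tree.

    ``rho`` is the multiplicity-weighted mean mutation count on root-to-tip
    paths; its variance follows the genealogy-based (Saillard-type)
    estimator ``sigma_rho^2 = (1/n^2) * sum over branches m_b * n_b^2``
    with ``m_b`` mutations on branch b and ``n_b`` samples below it.  The
    age is ``rho / (L * mean(mu))`` generations.
    """
    if tree.root is None or tree.root not in tree.tree:
        raise ValueError("tree must be rooted at a founder node")
    panel = clock.panel
    tips = [(k, d["multiplicity"]) for k, d in tree.tree.nodes(data=True)
            if d.get("observed") and d.get("multiplicity", 0) > 0]
    n = sum(m for _, m in tips)
    if n == 0:
        raise ValueError("tree carries no sampled haplotypes")

    rho = sum(m * tree.path_mutations(k) for k, m in tips) / n

    below = tree.tips_below()
    var = 0.0
    for node, par in tree.parent.items():
        if par is None:
            continue
        m_b = tree.tree.edges[node, par]["mutations"]
        var += m_b * below[node] ** 2
    sigma_rho = (var / n ** 2) ** 0.5

    scale = panel.L * panel.mean_mu  # expected mutations per haplotype per generation
    return TmrcaEstimate(method="rho", t_generations=rho / scale,
                         se_generations=sigma_rho / scale, n=int(n),
                         generation_interval=clock.generation_interval, rho=float(rho))
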