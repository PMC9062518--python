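"""Alpha, beta, and gamma diversity labels for vegetation plots.

For each focal plot we locate its N nearest neighboring plots (Euclidean
distance in equal-area projected meters) and derive three labels:

* **alpha** — species richness of the focal plot itself;
* **gamma** — richness of the union of species lists over the focal plot and
  its N neighbors;
* **beta** — the multiple-site Sørensen dissimilarity βsor over the same
  N + 1 plots,

  .. math::

     \\beta_{sor} = \\frac{A + B}{2\\,(\\sum_i S_i - S_T) + A + B},

  where the pair sums run over each (neighbor i, focal j) pair,
  ``A = Σ min(b_ij, b_ji)`` and ``B = Σ max(b_ij, b_ji)`` with ``b_ij`` /
  ``b_ji`` the counts of species found only in site i / only in site j,
  ``S_i`` the per-site richness summed over all N + 1 sites, and ``S_T`` the
  union richness. With a single neighbor this reduces to the classical
  pairwise Sørensen dissimilarity ``1 − 2|X ∩ Y| / (|X| + |Y|)``.

The radius of the focal-centered circle encompassing the N neighbors (the
distance to the Nth nearest neighbor) is kept as a feature: it is the spatial
scale at which the gamma label was measured, which lets a downstream model
learn the species–area relationship.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree


def normalize_name(name: str) -> str:
    """Canonical species-name string: trimmed, whitespace-collapsed, case-folded."""
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class PlotRecord:
    """One vegetation plot: id, projected coordinates (m), area (m²), species set."""

    plot_id: str
    x: float
    y: float
    area: float
    species: frozenset[str]

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"plot {self.plot_id}: area must be positive")
        object.__setattr__(
            self, "species", frozenset(normalize_name(s) for s in self.species)
        )


@dataclass(frozen=True)
class DiversitySite:
    """Diversity labels of one focal plot and the neighborhood they refer to."""

    plot_id: str
    alpha: int
    beta: float
    gamma: int
    radius: float
    neighbor_ids: tuple[str, ...]
    N: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta {self.beta} outside [0, 1]")
        if self.gamma < self.alpha:
            raise ValueError("gamma cannot be below alpha")
        if len(self.neighbor_ids) != self.N:
            raise ValueError("neighbor_ids length must equal N")


@dataclass(frozen=True)
class PairwiseTerms:
    """Intermediate set-arithmetic terms of the multiple-site Sørensen index."""

    A: int
    B: int
    sum_S: int
    S_T: int


def find_neighbors(focal: PlotRecord, plots: Sequence[PlotRecord], N: int):
    """N nearest plots to ``focal`` (excluded from candidates) and the radius.

    Returns ``(neighbor_ids, radius)`` where ``radius`` is the distance to the
    Nth nearest neighbor — the smallest focal-centered circle encompassing all
    N. Ties at identical distance are broken by ascending plot id.
    """
    candidates = [p for p in plots if p.plot_id != focal.plot_id]
    if len(candidates) < N:
        raise ValueError(
            f"need {N} neighbors for plot {focal.plot_id} but only "
            f"{len(candidates)} other plots exist"
        )
    if N < 1:
        raise ValueError("N must be at least 1")
    xy = np.array([(p.x, p.y) for p in candidates])
    dist = np.hypot(xy[:, 0] - focal.x, xy[:, 1] - focal.y)
    order = sorted(range(len(candidates)), key=lambda i: (dist[i], candidates[i].plot_id))
    chosen = order[:N]
    return tuple(candidates[i].plot_id for i in chosen), float(dist[chosen[-1]])


def compute_alpha(plot: PlotRecord) -> int:
    """Species richness of a single plot (cardinality of its species set)."""
    return len(plot.species)


def compute_gamma(focal: PlotRecord, neighbors: Sequence[PlotRecord]) -> int:
    """Union richness over the focal plot and all neighbors."""
    if not neighbors:
        raise ValueError("neighbor sequence must be non-empty")
    union: set[str] = set(focal.species)
    for p in neighbors:
        union |= p.species
    return len(union)


def pairwise_terms(focal: PlotRecord, neighbors: Sequence[PlotRecord]) -> PairwiseTerms:
    """A, B, ΣS_i and S_T for the multiple-site Sørensen index."""
    A = 0
    B = 0
    for p in neighbors:
        b_ij = len(p.species - focal.species)   # only in neighbor i
        b_ji = len(focal.species - p.species)   # only in focal j
        A += min(b_ij, b_ji)
        B += max(b_ij, b_ji)
    sum_S = len(focal.species) + sum(len(p.species) for p in neighbors)
    S_T = compute_gamma(focal, neighbors) if neighbors else len(focal.species)
    return PairwiseTerms(A=A, B=B, sum_S=sum_S, S_T=S_T)


def compute_beta_sorensen(focal: PlotRecord, neighbors: Sequence[PlotRecord]) -> float:
    """Multiple-site Sørensen dissimilarity βsor over focal + neighbors.

    The per-site richness sum in the denominator runs over all N + 1 sites
    including the focal one; only with that convention does the single-neighbor
    case reduce to the classical pairwise Sørensen dissimilarity.
    """
    if not neighbors:
        raise ValueError("neighbor sequence must be non-empty")
    t = pairwise_terms(focal, neighbors)
    denom = 2 * (t.sum_S - t.S_T) + t.A + t.B
    if denom == 0:
        # denom == 0 implies every site is empty (no shared and no one-sided species)
        raise ValueError("beta diversity undefined: all sites are empty")
    return (t.A + t.B) / denom


def label_all_sites(plots: Sequence[PlotRecord], N: int) -> list[DiversitySite]:
    """Compute DiversitySite labels (alpha, beta, gamma, radius) for every plot.

    Neighbor search uses a KD-tree over all plots at once; within the returned
    neighbor set, ordering ties at equal distance are resolved by plot id.
    """
    if len(plots) < N + 1:
        raise ValueError(f"need at least {N + 1} plots for N={N}, got {len(plots)}")
    xy = np.array([(p.x, p.y) for p in plots])
    tree = cKDTree(xy)
    dist, idx = tree.query(xy, k=N + 1)
    sites = []
    for j, focal in enumerate(plots):
        # drop the focal plot itself from its own neighbor list
        mask = idx[j] != j
        if mask.sum() == N + 1:  # exact-duplicate coordinates: drop the last
            mask[-1] = False
        nbr_idx = idx[j][mask][:N]
        nbr_dist = dist[j][mask][:N]
        order = sorted(range(N), key=lambda i: (nbr_dist[i], plots[nbr_idx[i]].plot_id))
        nbr_idx = nbr_idx[order]
        neighbors = [plots[i] for i in nbr_idx]
        alpha = compute_alpha(focal)
        gamma = compute_gamma(focal, neighbors)
        beta = compute_beta_sorensen(focal, neighbors)
        sites.append(
            DiversitySite(
                plot_id=focal.plot_id,
                alpha=alpha,
                beta=beta,
                gamma=gamma,
                radius=float(nbr_dist[order[-1]]),
                neighbor_ids=tuple(plots[i].plot_id for i in nbr_idx),
                N=N,
            )
        )
    return sites
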