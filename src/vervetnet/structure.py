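"""Dominance hierarchy and cluster/community structure.

David's Scores turn a directed win/loss matrix from agonistic bouts into
a cardinal dominance index; Ward-linkage clustering with cophenetic
validation and Newman modularity describe how a cooperation (or foraging)
network splits into sub-units of preferred partners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .core import DyadicMatrix, ValidationError

__all__ = [
    "DominanceResult",
    "Dendrogram",
    "CommunityPartition",
    "davids_score",
    "ward_dendrogram",
    "cophenetic_coefficient",
    "newman_communities",
    "modularity",
]


# ---------------------------------------------------------------------------
# David's Score
# ---------------------------------------------------------------------------


@dataclass
class DominanceResult:
    """David's Scores for the scored individuals.

    ``ds`` is the raw score (sums to zero over the scored set);
    ``normalized_ds`` maps it onto 0..n-1 via (DS + n(n-1)/2)/n.  Scores
    are kept at full precision; rounding to integers for display is a
    formatting choice only.  Note the ordering is not guaranteed stable
    under adding an individual with no interactions.
    """

    ids: list[str]
    ds: np.ndarray
    normalized_ds: np.ndarray
    n_interactions: int
    method: str

    def ranking(self) -> list[str]:
        """Ids from most to least dominant."""
        return [self.ids[i] for i in np.argsort(-self.ds, kind="stable")]


def davids_score(wins: DyadicMatrix, method: str = "Pij") -> DominanceResult:
    """David's Score from a directed win-count matrix.

    For each dyad with n_ij = w_ij + w_ji > 0 interactions the win
    proportion is P_ij = w_ij / n_ij (zero for unobserved dyads).  Then

        w_i  = sum_j P_ij          l_i  = sum_j P_ji
        w2_i = sum_j P_ij * w_j    l2_i = sum_j P_ji * l_j
        DS_i = w_i + w2_i - l_i - l2_i

    ``method="Dij"`` applies the chance-corrected proportion
    P_ij - (P_ij - 0.5) / (n_ij + 1), which shrinks small-sample
    proportions toward one half.
    """
    w = np.asarray(wins.values, dtype=float)
    if (w < 0).any():
        raise ValidationError("win counts must be nonnegative")
    n = wins.n
    nij = w + w.T
    if nij.sum() == 0:
        warnings.warn("all-zero agonistic matrix; all David's Scores are 0",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(nij > 0, w / np.where(nij > 0, nij, 1), 0.0)
    if method == "Dij":
        p = np.where(nij > 0, p - (p - 0.5) / (nij + 1), 0.0)
    elif method != "Pij":
        raise ValidationError(f"unknown method {method!r}")
    np.fill_diagonal(p, 0.0)
    wsum = p.sum(axis=1)
    lsum = p.sum(axis=0)
    w2 = p @ wsum
    l2 = p.T @ lsum
    ds = wsum + w2 - lsum - l2
    normalized = (ds + n * (n - 1) / 2) / n
    return DominanceResult(
        ids=list(wins.ids),
        ds=ds,
        normalized_ds=normalized,
        n_interactions=int(nij.sum() // 2),
        method=method,
    )


# ---------------------------------------------------------------------------
# Ward clustering + cophenetic validation
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Agglomerative merge tree under Ward's minimum-variance objective.

    ``merges`` follows the scipy linkage convention (cluster k created at
    step k-n merges ``merges[k-n]``); ``heights`` are the Ward objective
    increments, i.e. the increase in total within-cluster sum of squares
    caused by each merge, non-decreasing along the tree.
    """

    ids: list[str]
    merges: np.ndarray
    heights: np.ndarray
    linkage: np.ndarray  # scipy-format matrix for plotting / export

    @property
    def n(self) -> int:
        return len(self.ids)

    def leaf_sets(self) -> list[frozenset]:
        """Member set of every internal cluster, in merge order."""
        clusters: dict[int, frozenset] = {
            i: frozenset([self.ids[i]]) for i in range(self.n)
        }
        out = []
        for k, (a, b) in enumerate(self.merges):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[self.n + k] = merged
            out.append(merged)
        return out

    def merge_pairs(self) -> list[frozenset]:
        """The unordered pair of clusters merged at each step."""
        clusters: dict[int, frozenset] = {
            i: frozenset([self.ids[i]]) for i in range(self.n)
        }
        out = []
        for k, (a, b) in enumerate(self.merges):
            ca, cb = clusters[int(a)], clusters[int(b)]
            out.append(frozenset([ca, cb]))
            clusters[self.n + k] = ca | cb
        return out

    def cophenetic_matrix(self) -> np.ndarray:
        """Dyadic matrix of cophenetic distances: the height (Ward
        increment) of the lowest merge joining each pair."""
        z = self.linkage.copy()
        z[:, 2] = self.heights
        return squareform(sch.cophenet(z))

    def to_newick(self) -> str:
        """Newick string with Ward increments as node heights (branch
        length = parent height - child height)."""
        heights = {i: 0.0 for i in range(self.n)}
        names: dict[int, str] = {i: self.ids[i] for i in range(self.n)}
        for k, (a, b) in enumerate(self.merges):
            node = self.n + k
            h = float(self.heights[k])
            heights[node] = h
            la = h - heights[int(a)]
            lb = h - heights[int(b)]
            names[node] = f"({names[int(a)]}:{la:g},{names[int(b)]}:{lb:g})"
        return names[2 * self.n - 2] + ";"


def profile_distances(rates: DyadicMatrix) -> np.ndarray:
    """Euclidean distances between individuals' rate profiles (rows of the
    rate matrix, undefined cells and the diagonal treated as 0) — the
    geometry Ward's objective assumes."""
    v = np.nan_to_num(np.asarray(rates.values, dtype=float))
    np.fill_diagonal(v, 0.0)
    diff = v[:, None, :] - v[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def ward_dendrogram(rates: DyadicMatrix, metric: str = "profile") -> Dendrogram:
    """Ward-linkage merge tree of a dyadic rate/similarity matrix.

    ``metric="profile"`` (default) embeds each individual as its row of
    the rate matrix and runs Ward on the Euclidean distances between
    profiles, which satisfies Ward's geometric assumptions.
    ``metric="distance"`` treats the matrix itself as distances and
    applies the Ward update directly (with the usual caveat that Ward is
    only exact for Euclidean-embeddable distances).  Heights are Ward
    objective increments (within-cluster sum-of-squares increases).
    """
    if rates.n < 2:
        raise ValidationError("clustering needs at least 2 individuals")
    if metric == "profile":
        dist = profile_distances(rates)
    elif metric == "distance":
        dist = np.nan_to_num(np.asarray(rates.values, dtype=float))
        np.fill_diagonal(dist, 0.0)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    z = sch.linkage(squareform(dist, checks=False), method="ward")
    # scipy's ward merge distance h relates to the SS increase by h^2 / 2
    heights = z[:, 2] ** 2 / 2.0
    return Dendrogram(
        ids=list(rates.ids),
        merges=z[:, :2].astype(int),
        heights=heights,
        linkage=z,
    )


def cophenetic_coefficient(dend: Dendrogram, d: DyadicMatrix | np.ndarray) -> float:
    """Cophenetic correlation: Pearson correlation between the
    dendrogram's cophenetic distances and the input distances over all
    dyads.  1.0 means the tree reproduces the distances perfectly; 0.8 is
    conventionally taken as a good fit.
    """
    if isinstance(d, DyadicMatrix):
        if d.ids != dend.ids:
            d = d.reorder(dend.ids)
        dv = d.values
    else:
        dv = np.asarray(d, dtype=float)
    iu = np.triu_indices(dend.n, 1)
    x = dend.cophenetic_matrix()[iu]
    y = dv[iu]
    if np.ptp(y) == 0:
        raise ValidationError("constant input distances; coefficient undefined")
    return float(np.corrcoef(x, y)[0, 1])


def good_cophenetic_fit(coefficient: float, threshold: float = 0.8) -> bool:
    """Conventional reading: a cophenetic coefficient of at least 0.8
    indicates the dendrogram represents the data faithfully."""
    return coefficient >= threshold


# ---------------------------------------------------------------------------
# Newman modularity communities
# ---------------------------------------------------------------------------


@dataclass
class CommunityPartition:
    """A node partition with its weighted Newman modularity Q."""

    ids: list[str]
    assignment: np.ndarray  # community label per individual
    Q: float

    def communities(self) -> list[set]:
        return [
            {self.ids[i] for i in np.flatnonzero(self.assignment == c)}
            for c in np.unique(self.assignment)
        ]


def _adjacency(rates: DyadicMatrix) -> np.ndarray:
    a = np.nan_to_num(np.asarray(rates.values, dtype=float))
    np.fill_diagonal(a, 0.0)
    if (a < 0).any():
        raise ValidationError("modularity needs nonnegative weights")
    return a


def modularity(rates: DyadicMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity of a partition:
    Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j), with node
    strength in place of degree."""
    a = _adjacency(rates) if isinstance(rates, DyadicMatrix) else np.asarray(rates)
    labels = np.asarray(labels)
    k = a.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValidationError("empty network: total edge weight is zero")
    same = labels[:, None] == labels[None, :]
    return float(((a - np.outer(k, k) / two_m) * same).sum() / two_m)


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities in first-appearance order, so equal partitions
    compare equal and ties break deterministically."""
    out = np.empty(len(labels), dtype=int)
    mapping: dict = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label vectors."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, n_used: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(n_used + 1):
            labels[i] = c
            yield from rec(i + 1, max(n_used, c + 1))

    yield from rec(1, 1)


def newman_communities(
    rates: DyadicMatrix, exact_max: int = 8, tol: float = 1e-12
) -> CommunityPartition:
    """Partition maximising weighted Newman modularity.

    Study groups are small, so for networks of up to ``exact_max`` nodes
    the optimum is found exactly by enumerating every partition.  Larger
    networks use Newman's leading-eigenvector bipartitioning with
    Kernighan-Lin-style single-node refinement, applied recursively while
    a split improves Q.  Ties between equal-Q partitions break toward the
    lexicographically smallest canonical label vector.
    """
    a = _adjacency(rates)
    n = rates.n
    if a.sum() == 0:
        raise ValidationError("empty network: total edge weight is zero")
    if n <= exact_max:
        best_labels, best_q = None, -np.inf
        for labels in _set_partitions(n):
            q = modularity(a, labels)
            if q > best_q + tol or (
                abs(q - best_q) <= tol
                and best_labels is not None
                and tuple(labels) < tuple(best_labels)
            ):
                best_q, best_labels = q, labels.copy()
        labels = _canonical(best_labels)
        return CommunityPartition(list(rates.ids), labels, modularity(a, labels))
    labels = _spectral_partition(a)
    labels = _canonical(labels)
    return CommunityPartition(list(rates.ids), labels, modularity(a, labels))


def _spectral_partition(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    k = a.sum(axis=1)
    two_m = k.sum()
    b = a - np.outer(k, k) / two_m
    labels = np.zeros(n, dtype=int)
    next_label = [1]

    def split(members: np.ndarray) -> None:
        if len(members) < 2:
            return
        # generalized modularity matrix of the subgraph
        bg = b[np.ix_(members, members)].copy()
        bg -= np.diag(bg.sum(axis=1))
        vals, vecs = np.linalg.eigh(bg)
        lead = vecs[:, -1]
        if vals[-1] <= 1e-12:
            return
        s = np.where(lead >= 0, 1.0, -1.0)
        s = _kl_refine(bg, s)
        dq = float(s @ bg @ s) / (2 * two_m)
        if dq <= 1e-12 or len(set(s)) < 2:
            return
        side_b = members[s < 0]
        lab = next_label[0]
        next_label[0] += 1
        labels[side_b] = lab
        split(members[s > 0])
        split(side_b)

    split(np.arange(n))
    return labels


def _kl_refine(bg: np.ndarray, s: np.ndarray, max_sweeps: int = 10) -> np.ndarray:
    """Greedy single-node moves improving s' B s, vertex-by-vertex."""
    s = s.copy()
    for _ in range(max_sweeps):
        improved = False
        for i in range(len(s)):
            delta = -4 * s[i] * (bg[i] @ s - bg[i, i] * s[i])
            if delta > 1e-12:
                s[i] = -s[i]
                improved = True
        if not improved:
            break
    return s
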