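"""Community-structure comparison engine.

Shared by OTU count tables and gel lane profiles: any sample can be
represented as a numeric feature profile (OTU counts or densitometric
intensities), and samples are compared by the pairwise Pearson correlation,
which is invariant to per-sample positive rescaling and therefore suitable
for samples with different numbers of reads.

On top of the similarity matrix this module provides

* UPGMA clustering (average linkage with cluster-size weights) with a
  deterministic lexicographic tie-break,
* bootstrap cluster supports (features resampled with replacement; the
  support of a node is the percent of replicates in which exactly its
  sample set reappears as a cluster),
* the percent-dissimilarity statistic d = mean within-group similarity
  minus mean between-group similarity, and
* a permutation test for d over reassignments of samples to two groups of
  the original sizes (exhaustive when the number of distinct unordered
  partitions is small, Monte-Carlo otherwise, optionally stratified, e.g.
  permuting treatment labels within each soil).
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .otu_report import OtuTable

EXHAUSTIVE_CAP = 10_000


class DegenerateProfileError(ValueError):
    """A profile with zero variance has no defined Pearson correlation."""


def _as_profile_frame(profiles) -> pd.DataFrame:
    """Accept an OtuTable or a feature x sample DataFrame/array."""
    if isinstance(profiles, OtuTable):
        return profiles.counts
    if isinstance(profiles, pd.DataFrame):
        return profiles
    arr = np.asarray(profiles, dtype=float)
    return pd.DataFrame(arr, columns=[f"S{i}" for i in range(arr.shape[1])])


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise Pearson similarity in percent (r x 100)."""

    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("similarity matrix shape does not match sample ids")
        self.values = v

    def loc(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def subset(self, ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)])


def pearson_similarity(profiles) -> SimilarityMatrix:
    """Pairwise Pearson similarity (percent) between sample profiles.

    Accepts an :class:`~soilshift.otu_report.OtuTable` or a feature x sample
    DataFrame.  Raises :class:`DegenerateProfileError` for any constant
    profile, naming the sample.
    """
    frame = _as_profile_frame(profiles)
    arr = frame.to_numpy(dtype=float)
    sds = arr.std(axis=0)
    if np.any(sds == 0):
        bad = frame.columns[np.flatnonzero(sds == 0)[0]]
        raise DegenerateProfileError(f"profile of sample {bad!r} is constant")
    r = np.corrcoef(arr, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix([str(c) for c in frame.columns], 100.0 * r)


# -- UPGMA ---------------------------------------------------------------------


@dataclass
class Dendrogram:
    """UPGMA merge tree over samples.

    ``clusters`` maps each internal node's sample set to its merge height
    (half the merge dissimilarity, so the tree is ultrametric);
    ``supports`` optionally maps the same sets to bootstrap percentages.
    """

    tree: TreeNode = field(repr=False)
    clusters: dict[frozenset, float]
    supports: dict[frozenset, float] | None = None
    n_discarded_replicates: int = 0

    @property
    def sample_ids(self) -> list[str]:
        return sorted(leaf.name for leaf in self.tree.tips())

    def height_of(self, samples: Iterable[str]) -> float:
        return self.clusters[frozenset(samples)]

    def _annotated_tree(self) -> TreeNode:
        t = self.tree.copy()
        if self.supports is not None:
            for node in t.non_tips(include_self=True):
                key = frozenset(l.name for l in node.tips())
                if key in self.supports:
                    node.name = f"{self.supports[key]:.0f}"
        return t

    def to_newick(self) -> str:
        buf = io.StringIO()
        self._annotated_tree().write(buf, format="newick")
        return buf.getvalue()

    def write_newick(self, path) -> None:
        self._annotated_tree().write(str(path), format="newick")


def upgma(similarity: SimilarityMatrix) -> Dendrogram:
    """UPGMA dendrogram on the dissimilarity 100 - similarity.

    Average linkage weighted by cluster sizes; merge height is half the
    merge dissimilarity so leaf-to-node path lengths are equal
    (ultrametric).  Ties are broken by the lexicographically smallest
    combined member list, which makes the tree platform-independent.
    """
    ids = list(similarity.sample_ids)
    if len(ids) < 2:
        raise ValueError("need at least two samples")
    dis = 100.0 - similarity.values
    # active clusters: key -> (sorted member tuple, TreeNode, height, size)
    members: dict[int, tuple[tuple[str, ...], TreeNode, float, int]] = {
        i: ((ids[i],), TreeNode(name=ids[i]), 0.0, 1) for i in range(len(ids))
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): float(dis[i, j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    }
    clusters: dict[frozenset, float] = {}
    next_key = len(ids)
    while len(members) > 1:
        best_pair = None
        best = math.inf
        for (i, j), d in dist.items():
            key = tuple(sorted(members[i][0] + members[j][0]))
            if d < best - 1e-12 or (
                abs(d - best) <= 1e-12
                and (best_pair is None or key < best_pair[2])
            ):
                best = d
                best_pair = (i, j, key)
        i, j, _ = best_pair
        mi, ni, hi, si = members[i]
        mj, nj, hj, sj = members[j]
        h = best / 2.0
        ni.length = h - hi
        nj.length = h - hj
        node = TreeNode(children=[ni, nj])
        merged = tuple(sorted(mi + mj))
        clusters[frozenset(merged)] = h
        del members[i], members[j]
        new_dist = {}
        for (a, b), d in dist.items():
            if a in (i, j) or b in (i, j):
                continue
            new_dist[(a, b)] = d
        for k, (mk, nk, hk, sk) in members.items():
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dist[(min(next_key, k), max(next_key, k))] = (
                si * dik + sj * djk
            ) / (si + sj)
        members[next_key] = (merged, node, h, si + sj)
        dist = new_dist
        next_key += 1
    (_, root, _, _) = next(iter(members.values()))
    root.length = None
    return Dendrogram(tree=root, clusters=clusters)


def bootstrap_support(
    profiles, n_boot: int = 500, seed: int = 0
) -> Dendrogram:
    """UPGMA dendrogram with bootstrap cluster supports.

    Features (OTUs or gel positions) are resampled with replacement
    ``n_boot`` times; the support of each internal node of the original
    tree is the percent of replicates whose UPGMA tree contains exactly
    that node's sample set as a cluster.  Replicates in which a resampled
    profile becomes constant are discarded but still counted in the
    denominator (``n_discarded_replicates`` records how many).
    """
    frame = _as_profile_frame(profiles)
    base = upgma(pearson_similarity(frame))
    counts = {key: 0 for key in base.clusters}
    rng = np.random.default_rng(seed)
    n_feat = frame.shape[0]
    arr = frame.to_numpy(dtype=float)
    discarded = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n_feat, size=n_feat)
        sub = arr[idx]
        if np.any(sub.std(axis=0) == 0):
            discarded += 1
            continue
        r = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(r, 1.0)
        sim = SimilarityMatrix([str(c) for c in frame.columns], 100.0 * r)
        rep = upgma(sim)
        for key in counts:
            if key in rep.clusters:
                counts[key] += 1
    supports = {key: 100.0 * c / n_boot for key, c in counts.items()}
    return Dendrogram(
        tree=base.tree,
        clusters=base.clusters,
        supports=supports,
        n_discarded_replicates=discarded,
    )


# -- percent dissimilarity d ---------------------------------------------------


@dataclass
class DissimilarityD:
    """Percent dissimilarity between two sample groups:
    d = mean within-group pairwise similarity (pooled over both groups)
    minus mean between-group pairwise similarity."""

    d: float
    mean_within: float
    mean_between: float
    n_a: int
    n_b: int


def dissimilarity_d(
    similarity: SimilarityMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pooled_within: bool = True,
) -> DissimilarityD:
    """Percent dissimilarity d between two groups of samples.

    ``pooled_within=True`` (default) averages all within-group pairs of both
    groups together; ``False`` averages each group's mean separately and
    then averages the two means.
    """
    a = list(group_a)
    b = list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    if set(a) & set(b):
        raise ValueError("groups overlap")
    wa = [similarity.loc(x, y) for x, y in itertools.combinations(a, 2)]
    wb = [similarity.loc(x, y) for x, y in itertools.combinations(b, 2)]
    between = [similarity.loc(x, y) for x in a for y in b]
    if pooled_within:
        mean_within = float(np.mean(wa + wb))
    else:
        mean_within = float((np.mean(wa) + np.mean(wb)) / 2.0)
    mean_between = float(np.mean(between))
    return DissimilarityD(
        d=mean_within - mean_between,
        mean_within=mean_within,
        mean_between=mean_between,
        n_a=len(a),
        n_b=len(b),
    )


# -- permutation test ----------------------------------------------------------


@dataclass
class PermutationResult:
    """Permutation test of d over two-group reassignments."""

    observed_d: float
    null_d: np.ndarray = field(repr=False)
    p_value: float
    n_partitions: int
    mode: str  # "exhaustive" or "monte_carlo"
    seed: int | None
    min_attainable_p: float


def n_distinct_partitions(
    n_a: int, n_b: int, strata_sizes: Sequence[tuple[int, int]] | None = None
) -> int:
    """Number of distinct unordered assignments of samples to two groups of
    fixed sizes (optionally with per-stratum sizes fixed)."""
    if strata_sizes is None:
        total = math.comb(n_a + n_b, n_a)
        return total // 2 if n_a == n_b else total
    total = math.prod(math.comb(a + b, a) for a, b in strata_sizes)
    symmetric = all(a == b for a, b in strata_sizes)
    return total // 2 if symmetric else total


def _partition_d(sim: np.ndarray, masks: np.ndarray, pooled_within: bool) -> np.ndarray:
    """Vectorized d for P partitions given as boolean masks (P x n, True=A)."""
    n = sim.shape[0]
    m = masks.astype(float)
    c = 1.0 - m
    n_a = m.sum(axis=1)
    n_b = c.sum(axis=1)
    q_a = np.einsum("pi,ij,pj->p", m, sim, m)
    q_b = np.einsum("pi,ij,pj->p", c, sim, c)
    s_a = (q_a - 100.0 * n_a) / 2.0
    s_b = (q_b - 100.0 * n_b) / 2.0
    pairs_a = n_a * (n_a - 1) / 2.0
    pairs_b = n_b * (n_b - 1) / 2.0
    total = (sim.sum() - 100.0 * n) / 2.0
    s_between = total - s_a - s_b
    if pooled_within:
        mean_within = (s_a + s_b) / (pairs_a + pairs_b)
    else:
        mean_within = (s_a / pairs_a + s_b / pairs_b) / 2.0
    mean_between = s_between / (n_a * n_b)
    return mean_within - mean_between


def permutation_test_d(
    profiles,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_perm: int = 9999,
    seed: int | None = 0,
    strata: dict[str, str] | None = None,
    pooled_within: bool = True,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> PermutationResult:
    """One-sided permutation test of d (large d = treatment effect).

    The null reassigns the samples to two groups of the original sizes.
    When the number of distinct unordered partitions is at most
    ``exhaustive_cap`` all of them are enumerated (the observed partition
    included); otherwise ``n_perm`` Monte-Carlo reassignments are drawn and
    the observed partition is added.  In both cases
    p = #(null d >= observed d, observed included) / #(partitions evaluated).

    ``strata`` optionally maps each sample to a stratum label (e.g. its
    soil); reassignments then preserve the per-stratum group sizes, i.e.
    treatment labels are permuted within soils only.
    """
    a = list(group_a)
    b = list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    frame = _as_profile_frame(profiles)
    samples = a + b
    sim = pearson_similarity(frame[samples]).values
    idx_a = np.arange(len(a))
    observed_mask = np.zeros(len(samples), dtype=bool)
    observed_mask[idx_a] = True

    if strata is not None:
        labels = [strata[s] for s in samples]
        strata_names = sorted(set(labels))
        per_stratum = [
            (
                [i for i, l in enumerate(labels) if l == st and observed_mask[i]],
                [i for i, l in enumerate(labels) if l == st and not observed_mask[i]],
            )
            for st in strata_names
        ]
        sizes = [(len(ia), len(ib)) for ia, ib in per_stratum]
        n_part = n_distinct_partitions(len(a), len(b), strata_sizes=sizes)
    else:
        per_stratum = [(list(range(len(a))), list(range(len(a), len(samples))))]
        sizes = [(len(a), len(b))]
        n_part = n_distinct_partitions(len(a), len(b))

    symmetric = all(na == nb for na, nb in sizes)

    if n_part <= exhaustive_cap:
        masks = []
        choices_per_stratum = []
        for ia, ib in per_stratum:
            pool = sorted(ia + ib)
            choices_per_stratum.append(
                list(itertools.combinations(pool, len(ia)))
            )
        seen = set()
        for combo in itertools.product(*choices_per_stratum):
            chosen = frozenset(itertools.chain.from_iterable(combo))
            if symmetric:
                comp = frozenset(range(len(samples))) - chosen
                key = min(tuple(sorted(chosen)), tuple(sorted(comp)))
                if key in seen:
                    continue
                seen.add(key)
            mask = np.zeros(len(samples), dtype=bool)
            mask[list(chosen)] = True
            masks.append(mask)
        masks = np.array(masks)
        assert masks.shape[0] == n_part
        null_d = _partition_d(sim, masks, pooled_within)
        obs_row = np.flatnonzero((masks == observed_mask).all(axis=1))
        if len(obs_row) == 0:  # symmetric dedup may have kept the complement
            obs_row = np.flatnonzero((masks == ~observed_mask).all(axis=1))
        observed = float(null_d[obs_row[0]])
        p = float(np.sum(null_d >= observed - 1e-12) / n_part)
        mode = "exhaustive"
        n_evaluated = n_part
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_perm, len(samples)), dtype=bool)
        for r in range(n_perm):
            for ia, ib in per_stratum:
                pool = np.array(ia + ib)
                pick = rng.choice(pool, size=len(ia), replace=False)
                masks[r, pick] = True
        null_d = _partition_d(sim, masks, pooled_within)
        observed = float(
            _partition_d(sim, observed_mask[None, :], pooled_within)[0]
        )
        p = float((1 + np.sum(null_d >= observed - 1e-12)) / (1 + n_perm))
        mode = "monte_carlo"
        n_evaluated = n_perm + 1
    return PermutationResult(
        observed_d=observed,
        null_d=np.asarray(null_d),
        p_value=p,
        n_partitions=n_evaluated,
        mode=mode,
        seed=seed,
        min_attainable_p=1.0 / n_evaluated,
    )
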