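"""Hierarchical clustering of study presence/absence profiles.

Studies are clustered on their binary gene-detection vectors with the
asymmetric binary (Jaccard) distance and average linkage (UPGMA), and each
internal node receives bootstrap support from multiscale resampling of
genes: the ordinary bootstrap probability (BP) at scale 1 and the
approximately-unbiased (AU) p-value estimated from the scale dependence of
BP, following Shimodaira's signed-distance/curvature fit as popularized by
pvclust.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))


def to_binary_matrix(entries, study_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Genes x studies 0/1 matrix from compendium entries."""
    entries = list(entries)
    if not entries:
        raise ValidationError("empty compendium")
    if study_ids is None:
        study_ids = list(entries[0].study_flags)
    data = {
        e.gene_key.symbol: [e.study_flags.get(s, 0) for s in study_ids] for e in entries
    }
    matrix = pd.DataFrame.from_dict(data, orient="index", columns=list(study_ids)).astype(np.int8)
    return matrix.sort_index()


def binary_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise asymmetric binary distance between study columns.

    d(i, j) = (# discordant genes) / (# genes present in at least one of
    the two studies); rows where both are absent carry no information.
    A pair of all-zero columns gets distance 0 with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need at least two study columns")
    X = matrix.to_numpy(dtype=bool)
    labels = list(matrix.columns)
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = int(np.sum(X[:, i] | X[:, j]))
            if union == 0:
                logger.warning("studies %s and %s share no detected genes; distance set to 0",
                               labels[i], labels[j])
                d = 0.0
            else:
                d = int(np.sum(X[:, i] ^ X[:, j])) / union
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=labels, columns=labels)


@dataclass
class DendrogramNode:
    members: frozenset[str]
    height: float
    children: tuple = ()  # pair of DendrogramNode or leaf labels (str)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    """Binary merge tree over studies with non-decreasing merge heights."""

    root: DendrogramNode
    leaves: list[str]
    merges: list[DendrogramNode] = field(default_factory=list)  # in merge order

    def internal_member_sets(self) -> list[frozenset[str]]:
        """Member sets of internal nodes, root included, in merge order."""
        return [node.members for node in self.merges]

    def to_newick(self, support: Optional[dict[frozenset[str], str]] = None) -> str:
        def render(node: DendrogramNode, parent_height: float) -> str:
            length = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{next(iter(node.members))}:{length:.6g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            label = (support or {}).get(node.members, "")
            return f"({inner}){label}:{length:.6g}"

        root = self.root
        inner = ",".join(render(c, root.height) for c in root.children)
        label = (support or {}).get(root.members, "")
        return f"({inner}){label};"


def _upgma_merges(dist: np.ndarray, labels: Sequence[str]) -> list[tuple[frozenset, float, int, int]]:
    """Core UPGMA loop; ties break on the lexicographically smallest pair.

    Returns (members, height, i, j) per merge over a growing node list.
    """
    n = len(labels)
    active: list[int] = list(range(n))
    members: list[frozenset] = [frozenset([l]) for l in labels]
    minlab: list[str] = [str(l) for l in labels]
    sizes: list[int] = [1] * n
    # distance bookkeeping over node indices
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = dist[i, j]
    out = []
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = D[(min(i, j), max(i, j))]
                a, b = minlab[i], minlab[j]
                tie_key = (a, b) if a <= b else (b, a)
                cand = (d, tie_key, i, j)
                if best is None or cand < best:
                    best = cand
        d, _, i, j = best
        new = len(members)
        members.append(members[i] | members[j])
        minlab.append(min(minlab[i], minlab[j]))
        sizes.append(sizes[i] + sizes[j])
        for k in active:
            if k in (i, j):
                continue
            dik = D[(min(i, k), max(i, k))]
            djk = D[(min(j, k), max(j, k))]
            D[(k, new)] = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        active = [k for k in active if k not in (i, j)] + [new]
        out.append((members[new], d, i, j))
    return out


def average_linkage(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA dendrogram from a symmetric distance matrix over studies."""
    D = dist.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValidationError("distance matrix must be square and symmetric")
    if (D < -1e-12).any():
        raise ValidationError("distance matrix has negative entries")
    labels = [str(c) for c in dist.columns]
    merges = _upgma_merges(D, labels)
    nodes: dict[frozenset, DendrogramNode] = {
        frozenset([l]): DendrogramNode(members=frozenset([l]), height=0.0) for l in labels
    }
    all_nodes: list[DendrogramNode] = [nodes[frozenset([l])] for l in labels]
    merge_nodes = []
    for members, height, i, j in merges:
        node = DendrogramNode(members=members, height=height,
                              children=(all_nodes[i], all_nodes[j]))
        all_nodes.append(node)
        merge_nodes.append(node)
    return Dendrogram(root=merge_nodes[-1], leaves=labels, merges=merge_nodes)


def _bootstrap_member_sets(dist: np.ndarray, labels: Sequence[str]) -> set[frozenset]:
    return {members for members, _, _, _ in _upgma_merges(dist, labels)}


@dataclass
class BootstrapSupport:
    """Per-node BP (scale 1) and AU support plus the per-scale BP table."""

    node_members: list[frozenset[str]]
    bp: dict[frozenset, float]
    au: dict[frozenset, Optional[float]]
    bp_by_scale: pd.DataFrame  # index: node order, columns: scales
    n_samplings: int
    scales: tuple[float, ...]
    seed: int

    def table(self) -> pd.DataFrame:
        rows = []
        for members in self.node_members:
            au = self.au[members]
            rows.append(
                {
                    "members": "|".join(sorted(members)),
                    "bp": self.bp[members],
                    "au": "" if au is None else au,
                    "n_samplings": self.n_samplings,
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)


def _fit_au(scales: np.ndarray, bp: np.ndarray, n_samplings: int) -> Optional[float]:
    """AU from the multiscale BP curve.

    Fits z(r) = v*sqrt(r) + c/sqrt(r) to z_r = qnorm(1 - BP_r) by weighted
    least squares (binomial information weights) and returns
    AU = 1 - Phi(v - c). Needs at least two scales with non-degenerate BP.
    """
    eps = 0.5 / n_samplings
    usable = (bp > 0) & (bp < 1)
    if usable.sum() < 2:
        return None
    r = scales[usable]
    p = np.clip(bp[usable], eps, 1 - eps)
    z = norm.ppf(1 - p)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    w = n_samplings * norm.pdf(z) ** 2 / (p * (1 - p))
    W = np.sqrt(w)
    try:
        coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
    except np.linalg.LinAlgError:
        return None
    v, c = coef
    return float(np.clip(1.0 - norm.cdf(v - c), 0.0, 1.0))


def bootstrap_support(
    matrix: pd.DataFrame,
    tree: Dendrogram,
    n_samplings: int = 5000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int = 0,
) -> BootstrapSupport:
    """Multiscale bootstrap of genes (rows) assessing each original clade.

    At each scale ``r``, ``n_samplings`` resamples of ``round(r * n_genes)``
    genes are drawn with replacement, the studies are re-clustered, and a
    clade counts as recovered when its exact member set reappears. BP is
    the recovery fraction at scale 1; AU comes from the across-scale fit.
    """
    if n_samplings < 100:
        logger.warning("n_samplings=%d is very small; support values will be noisy", n_samplings)
    scales = tuple(float(s) for s in scales)
    if 1.0 not in scales:
        raise ValidationError("scales must include 1.0 (BP is defined at scale 1)")
    X = matrix.to_numpy(dtype=bool)
    labels = [str(c) for c in matrix.columns]
    n_genes, n_studies = X.shape
    node_sets = tree.internal_member_sets()
    # root reappears in every replicate by construction; keep it for reporting
    pair_idx = [(i, j) for i in range(n_studies) for j in range(i + 1, n_studies)]
    XOR = np.empty((n_genes, len(pair_idx)), dtype=np.float64)
    OR = np.empty_like(XOR)
    for p, (i, j) in enumerate(pair_idx):
        XOR[:, p] = X[:, i] ^ X[:, j]
        OR[:, p] = X[:, i] | X[:, j]
    rng = np.random.default_rng(seed)
    prob = np.full(n_genes, 1.0 / n_genes)
    counts = {s: np.zeros(len(node_sets), dtype=np.int64) for s in scales}
    dist = np.zeros((n_studies, n_studies))
    for s in scales:
        m = max(2, int(round(s * n_genes)))
        draws = rng.multinomial(m, prob, size=n_samplings).astype(np.float64)
        num = draws @ XOR
        den = draws @ OR
        with np.errstate(invalid="ignore", divide="ignore"):
            dvals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        for b in range(n_samplings):
            for p, (i, j) in enumerate(pair_idx):
                dist[i, j] = dist[j, i] = dvals[b, p]
            found = _bootstrap_member_sets(dist, labels)
            for t, members in enumerate(node_sets):
                if members in found:
                    counts[s][t] += 1
    bp_by_scale = pd.DataFrame(
        {s: counts[s] / n_samplings for s in scales},
        index=["|".join(sorted(ms)) for ms in node_sets],
    )
    scale_arr = np.array(scales)
    bp = {}
    au = {}
    for t, members in enumerate(node_sets):
        curve = np.array([counts[s][t] / n_samplings for s in scales])
        bp[members] = float(curve[scale_arr == 1.0][0])
        au_val = _fit_au(scale_arr, curve, n_samplings)
        if au_val is None:
            logger.info("AU undefined for node {%s}: degenerate BP curve",
                        ", ".join(sorted(members)))
        au[members] = au_val
    return BootstrapSupport(
        node_members=node_sets,
        bp=bp,
        au=au,
        bp_by_scale=bp_by_scale,
        n_samplings=n_samplings,
        scales=scales,
        seed=seed,
    )
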