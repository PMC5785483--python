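"""Between-sample (beta) diversity: UniFrac distances, PCoA, PERMANOVA.

UniFrac is computed over a branch x sample incidence/abundance matrix derived
from the rooted phylogeny, so pairwise distance matrices over a whole study
cost a single tree traversal.  PCoA uses Gower double-centering with negative
eigenvalues dropped (and logged).  PERMANOVA is the one-factor permutation
test on squared distances; the four-group habitat x disease design is handled
as pairwise one-factor contrasts by the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_tables import DistanceMatrix, OtuTable, PhyloTree, ValidationError

__all__ = [
    "RANKS",
    "PcoaResult",
    "PermanovaResult",
    "aggregate",
    "unweighted_unifrac",
    "weighted_unifrac",
    "distance_matrix",
    "pcoa",
    "permanova",
]

logger = logging.getLogger(__name__)

RANKS = ("phylum", "class", "order", "family", "genus", "species", "otu")


def aggregate(table: OtuTable, rank: str) -> OtuTable:
    """Collapse an OTU table to taxa at ``rank`` by summing counts.

    Rows sharing the same lineage prefix up to ``rank`` merge; OTUs whose
    lineage is absent or too shallow pool under ``"unclassified"``.  Column
    sums are invariant.
    """
    if rank not in RANKS:
        raise ValidationError(f"rank {rank!r} not in {RANKS}")
    if rank == "otu":
        return table
    depth = RANKS.index(rank) + 1
    groups: dict[str, np.ndarray] = {}
    for i, otu in enumerate(table.otu_ids):
        lineage = table.taxonomy.get(otu, "")
        parts = [p for p in lineage.split(";") if p] if lineage else []
        key = ";".join(parts[:depth]) if len(parts) >= depth else "unclassified"
        if key in groups:
            groups[key] = groups[key] + table.counts[i]
        else:
            groups[key] = table.counts[i].copy()
    taxa = list(groups)
    counts = np.vstack([groups[t] for t in taxa])
    taxonomy = {t: t for t in taxa if t != "unclassified"}
    return OtuTable(taxa, table.sample_ids, counts, taxonomy)


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------


def _branch_abundance(tree: PhyloTree, counts: dict | "np.ndarray", otu_ids=None):
    """lengths (B,) and per-branch subtree totals for one or more samples."""
    if otu_ids is None:
        # mapping input: keys define the OTU order
        items = dict(counts)
        otu_ids = list(items)
        vec = np.array([float(items[o]) for o in otu_ids])[:, None]
    else:
        vec = np.asarray(counts, dtype=float)
        if vec.ndim == 1:
            vec = vec[:, None]
    lengths, inc = tree.branch_leaf_matrix(otu_ids)
    return lengths, inc.astype(float) @ vec


def _pair_profiles(tree: PhyloTree, counts_a, counts_b):
    a = dict(counts_a)
    b = dict(counts_b)
    otu_ids = sorted(set(a) | set(b))
    vecs = np.array(
        [[float(a.get(o, 0.0)), float(b.get(o, 0.0))] for o in otu_ids]
    )
    lengths, inc = tree.branch_leaf_matrix(otu_ids)
    return lengths, inc.astype(float) @ vecs


def unweighted_unifrac(tree: PhyloTree, counts_a, counts_b) -> float:
    """Presence/absence UniFrac: unshared branch length over total covered.

    ``sum l_b |I_A(b) - I_B(b)| / sum l_b max(I_A, I_B)`` with ``I_X(b) = 1``
    iff any leaf below branch ``b`` is present in sample ``X``.
    """
    lengths, totals = _pair_profiles(tree, counts_a, counts_b)
    if totals[:, 0].sum() == 0 or totals[:, 1].sum() == 0:
        raise ValidationError("empty sample in unweighted UniFrac")
    pres = totals > 0
    num = float((lengths * (pres[:, 0] ^ pres[:, 1])).sum())
    den = float((lengths * (pres[:, 0] | pres[:, 1])).sum())
    return num / den if den > 0 else 0.0


def weighted_unifrac(tree: PhyloTree, counts_a, counts_b, normalized: bool = True) -> float:
    """Abundance-weighted UniFrac.

    Raw form ``sum l_b |p_A(b) - p_B(b)|`` where ``p_X(b)`` is the fraction of
    sample X's reads below branch ``b``; the normalized form divides by
    ``sum l_b (p_A(b) + p_B(b))``, bounding the distance to [0, 1].
    """
    lengths, totals = _pair_profiles(tree, counts_a, counts_b)
    tot_a, tot_b = totals[:, 0], totals[:, 1]
    na = float(np.asarray(list(dict(counts_a).values()), dtype=float).sum())
    nb = float(np.asarray(list(dict(counts_b).values()), dtype=float).sum())
    if na == 0 or nb == 0:
        raise ValidationError("empty sample in weighted UniFrac")
    pa, pb = tot_a / na, tot_b / nb
    raw = float((lengths * np.abs(pa - pb)).sum())
    if not normalized:
        return raw
    den = float((lengths * (pa + pb)).sum())
    return raw / den if den > 0 else 0.0


def distance_matrix(table: OtuTable, tree: PhyloTree, metric: str) -> DistanceMatrix:
    """All-pairs UniFrac over the table's samples (one traversal, vectorized).

    ``metric`` is ``"uw-unifrac"`` or ``"w-unifrac"`` (normalized weighted).
    """
    if metric not in ("uw-unifrac", "w-unifrac"):
        raise ValidationError(f"unknown metric {metric!r}")
    lengths, inc = tree.branch_leaf_matrix(table.otu_ids)
    branch_counts = inc.astype(float) @ table.counts.astype(float)  # B x S
    n = table.n_samples
    data = np.zeros((n, n))
    if metric == "uw-unifrac":
        pres = branch_counts > 0
        for i in range(n):
            diff = pres[:, i : i + 1] ^ pres[:, i + 1 :]
            union = pres[:, i : i + 1] | pres[:, i + 1 :]
            num = lengths @ diff
            den = lengths @ union
            with np.errstate(invalid="ignore"):
                d = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
            data[i, i + 1 :] = d
    else:
        totals = table.counts.sum(axis=0).astype(float)
        frac = branch_counts / totals  # B x S
        for i in range(n):
            num = lengths @ np.abs(frac[:, i : i + 1] - frac[:, i + 1 :])
            den = lengths @ (frac[:, i : i + 1] + frac[:, i + 1 :])
            d = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
            data[i, i + 1 :] = d
    data = data + data.T
    return DistanceMatrix(table.sample_ids, data)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # descending, positive only
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, eps: float = 1e-10) -> PcoaResult:
    """Classical (metric) multidimensional scaling.

    Gower double-centering of ``-D**2 / 2``, eigendecomposition, coordinates
    scaled by the square roots of the eigenvalues.  Negative eigenvalues are
    dropped with a log message (no correction applied).
    """
    d = dm.data
    n = d.shape[0]
    a = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_neg = int((eigvals < -eps * max(abs(eigvals[0]), 1.0)).sum())
    if n_neg:
        logger.info("pcoa: dropping %d negative eigenvalue(s)", n_neg)
    keep = eigvals > eps * max(abs(eigvals[0]), 1.0)
    eigvals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(eigvals)
    total = eigvals.sum()
    proportions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PcoaResult(list(dm.sample_ids), coords, eigvals, proportions)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, uniq: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(len(uniq)):
        mask = codes == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    a = len(uniq)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix, labels, n_permutations: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-factor permutational MANOVA on a distance matrix.

    Pseudo-F from total and within-group sums of squared distances;
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` under
    seed-deterministic label permutations.
    """
    labels = np.asarray(list(labels))
    if len(labels) != len(dm.sample_ids):
        raise ValidationError("label count does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    sizes = {str(u): int((codes == i).sum()) for i, u in enumerate(uniq)}
    if min(sizes.values()) < 2:
        raise ValidationError(f"every group needs >= 2 samples, got {sizes}")
    d2 = dm.data**2
    f_obs = _pseudo_f(d2, codes, uniq)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, uniq) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), n_permutations, sizes)
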