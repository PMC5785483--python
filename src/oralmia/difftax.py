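"""Differential-abundance screening and clinical covariate correlation.

Relative abundances are compared between disease and control groups per
habitat with the two-sided Wilcoxon rank-sum test (exact enumeration for
small untied samples, tie- and continuity-corrected normal approximation
otherwise), followed by Benjamini-Hochberg FDR within each (habitat, rank)
family.  A taxon is significant iff p < 0.05 and q < 0.05.

Clinical correlation uses Spearman's rho on pairwise-complete observations
with heatmap-style row/column orderings from average-linkage hierarchical
clustering on 1 - rho distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .betadiv import aggregate
from .io_tables import CLINICAL_VARIABLES, OtuTable, ValidationError

__all__ = [
    "DiffResult",
    "ClinicalCorrelationResult",
    "relative_abundance",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "differential_screen",
    "diff_frame",
    "clinical_correlation",
]

P_THRESHOLD = 0.05
Q_THRESHOLD = 0.05


@dataclass
class DiffResult:
    """One taxon's differential-abundance test between disease and control."""

    taxon_id: str
    rank: str
    habitat: str
    mean_rel_abund_asd: float
    mean_rel_abund_control: float
    direction: str  # "ASD-enriched" | "control-enriched"
    p_value: float
    q_value: float
    significant: bool


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1, zeros preserved)."""
    counts = table.counts.astype(float)
    return pd.DataFrame(
        counts / counts.sum(axis=0), index=table.otu_ids, columns=table.sample_ids
    )


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by enumeration when both samples have <= 8 observations and no
    ties; otherwise the normal approximation with tie and continuity
    corrections.  Returns ``(W, p)`` where W is the rank sum of ``x``.
    If every value in both samples is identical, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValidationError("each group needs >= 3 observations")
    n1 = len(x)
    w_stat = float(stats.rankdata(np.concatenate([x, y]))[:n1].sum())
    if np.ptp(np.concatenate([x, y])) == 0:
        return w_stat, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto",
                             use_continuity=True)
    return w_stat, float(res.pvalue)


def bh_fdr(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (Benjamini-Yekutieli via ``"by"``).

    ``q(i) = min_{j >= i} p(j) * m / j`` over the sorted p-values, restored to
    the input order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    if method == "by":
        ranked *= np.sum(1.0 / np.arange(1, m + 1))
    elif method != "bh":
        raise ValidationError(f"unknown FDR method {method!r}")
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_screen(
    table: OtuTable,
    metadata: pd.DataFrame,
    rank: str = "otu",
    habitat: str | None = None,
    fdr_method: str = "bh",
) -> list[DiffResult]:
    """Wilcoxon + FDR screen of every taxon at ``rank``, per habitat.

    The FDR family is all taxa of one rank within one habitat.  Direction
    follows the sign of the group mean relative-abundance difference.
    """
    habitats = [habitat] if habitat else sorted(metadata["habitat"].unique())
    results: list[DiffResult] = []
    for hab in habitats:
        sample_ids = [
            s
            for s in table.sample_ids
            if s in metadata.index and metadata.loc[s, "habitat"] == hab
        ]
        if not sample_ids:
            raise ValidationError(f"no samples for habitat {hab!r}")
        sub = aggregate(table.select_samples(sample_ids), rank)
        rel = relative_abundance(sub)
        groups = metadata.loc[sample_ids, "group"]
        asd_cols = groups[groups == "ASD"].index
        ctrl_cols = groups[groups == "control"].index
        rows = []
        for taxon in sub.otu_ids:
            x = rel.loc[taxon, asd_cols].to_numpy()
            y = rel.loc[taxon, ctrl_cols].to_numpy()
            _, p = wilcoxon_rank_sum(x, y)
            rows.append((taxon, float(x.mean()), float(y.mean()), p))
        q_values = bh_fdr([r[3] for r in rows], method=fdr_method)
        for (taxon, mean_asd, mean_ctrl, p), q in zip(rows, q_values):
            direction = "ASD-enriched" if mean_asd >= mean_ctrl else "control-enriched"
            results.append(
                DiffResult(
                    taxon_id=taxon,
                    rank=rank,
                    habitat=hab,
                    mean_rel_abund_asd=mean_asd,
                    mean_rel_abund_control=mean_ctrl,
                    direction=direction,
                    p_value=float(p),
                    q_value=float(q),
                    significant=bool(p < P_THRESHOLD and q < Q_THRESHOLD),
                )
            )
    return results


def diff_frame(results: list[DiffResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


@dataclass
class ClinicalCorrelationResult:
    """Spearman correlations of top taxa against clinical variables.

    ``rho``/``p_value``/``n_pairs`` are taxa x variables frames (rho is NaN
    where either vector is constant or fewer than 3 complete pairs exist);
    ``row_order``/``col_order`` are the clustering-derived display orders.
    """

    rho: pd.DataFrame
    p_value: pd.DataFrame
    n_pairs: pd.DataFrame
    row_order: list[str]
    col_order: list[str]

    def to_long(self) -> pd.DataFrame:
        rows = []
        for otu in self.rho.index:
            for var in self.rho.columns:
                rows.append(
                    {
                        "otu_id": otu,
                        "variable": var,
                        "spearman_rho": self.rho.loc[otu, var],
                        "p_value": self.p_value.loc[otu, var],
                        "n_pairs": int(self.n_pairs.loc[otu, var]),
                    }
                )
        return pd.DataFrame(rows)


def _cluster_order(dist: np.ndarray, labels: list[str]) -> list[str]:
    if len(labels) < 3:
        return list(labels)
    condensed = dist[np.triu_indices(len(labels), 1)]
    linkage = hierarchy.average(condensed)
    return [labels[i] for i in hierarchy.leaves_list(linkage)]


def clinical_correlation(
    table: OtuTable,
    metadata: pd.DataFrame,
    top_k: int = 50,
    variables: tuple[str, ...] = CLINICAL_VARIABLES,
) -> ClinicalCorrelationResult:
    """Correlate the ``top_k`` most abundant OTUs with clinical variables.

    Spearman rho with average ranks for ties, computed on pairwise-complete
    observations.  Rows and columns are ordered by average-linkage
    hierarchical clustering on 1 - rho distances.
    """
    rel = relative_abundance(table)
    order = rel.mean(axis=1).sort_values(ascending=False, kind="mergesort")
    top = list(order.index[: min(top_k, len(order))])
    meta = metadata.loc[rel.columns]

    rho = pd.DataFrame(index=top, columns=list(variables), dtype=float)
    pval = pd.DataFrame(index=top, columns=list(variables), dtype=float)
    npairs = pd.DataFrame(0, index=top, columns=list(variables), dtype=int)
    for var in variables:
        v = pd.to_numeric(meta[var], errors="coerce").to_numpy(dtype=float)
        complete = np.isfinite(v)
        n = int(complete.sum())
        for otu in top:
            a = rel.loc[otu].to_numpy(dtype=float)[complete]
            npairs.loc[otu, var] = n
            if n < 3 or np.ptp(v[complete]) == 0 or np.ptp(a) == 0:
                continue  # rho undefined: left NaN, n_pairs recorded
            r, p = stats.spearmanr(a, v[complete])
            rho.loc[otu, var] = float(r)
            pval.loc[otu, var] = float(p)

    # display orders: correlation-based distances among rows / columns
    abund = rel.loc[top].to_numpy(dtype=float)
    row_rho = stats.spearmanr(abund, axis=1).statistic if len(top) > 2 else np.ones((len(top), len(top)))
    row_rho = np.atleast_2d(np.nan_to_num(row_rho, nan=0.0))
    row_order = _cluster_order(1.0 - row_rho, top)
    col_fill = rho.fillna(0.0).to_numpy(dtype=float).T
    col_dist = 1.0 - np.nan_to_num(np.corrcoef(col_fill), nan=0.0)
    col_order = _cluster_order(col_dist, list(variables))
    return ClinicalCorrelationResult(rho, pval, npairs, row_order, col_order)
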