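"""Rarefaction and within-sample (alpha) diversity indices.

Implements subsampling without replacement, Shannon diversity/evenness in
natural log units, the abundance-based coverage estimator (ACE) of richness,
Good's coverage, expected rarefaction curves and a Welch t-test group
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import OtuTable, ValidationError

__all__ = [
    "AlphaResult",
    "rarefy",
    "shannon",
    "shannoneven",
    "ace",
    "goods_coverage",
    "rarefaction_curve",
    "compare_alpha",
    "alpha_summary",
    "compare_groups",
]

logger = logging.getLogger(__name__)


@dataclass
class AlphaResult:
    """Per-sample diversity summary at a common rarefaction depth."""

    sample_id: str
    observed_otus: int
    ace: float
    shannon: float
    shannoneven: float
    goods_coverage: float
    rarefaction_depth: int


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValidationError("expected a 1-D count vector")
    if (arr < 0).any():
        raise ValidationError("negative counts")
    return arr


def rarefy(sample_counts, depth: int, seed: int) -> np.ndarray:
    """Subsample a count vector to exactly ``depth`` reads without replacement.

    Multivariate-hypergeometric draw; deterministic for a given seed.  Raises
    if ``depth`` exceeds the sample total (callers decide whether to drop the
    sample instead).
    """
    counts = _as_counts(sample_counts)
    total = int(counts.sum())
    if depth > total:
        raise ValidationError(f"depth {depth} exceeds sample total {total}")
    if depth == total:
        return counts.astype(np.int64).copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over nonzero p_i (nats by default)."""
    counts = _as_counts(counts)
    nz = counts[counts > 0]
    if nz.size == 0:
        raise ValidationError("all-zero count vector")
    p = nz / nz.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def shannoneven(counts) -> float:
    """Shannon evenness H / ln(S_obs); defined as 0 for a single-species sample."""
    counts = _as_counts(counts)
    s_obs = int((counts > 0).sum())
    if s_obs == 0:
        raise ValidationError("all-zero count vector")
    if s_obs == 1:
        return 0.0
    return shannon(counts) / float(np.log(s_obs))


def ace(counts, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator of species richness.

    ``S_abund + S_rare / C_ace + (F1 / C_ace) * gamma^2`` with
    ``C_ace = 1 - F1 / N_rare`` and the squared coefficient of variation
    ``gamma^2`` floored at 0.  Falls back to Chao1 when every rare read is a
    singleton (``C_ace = 0``).
    """
    counts = _as_counts(counts)
    nz = counts[counts > 0].astype(np.int64)
    if nz.size == 0:
        raise ValidationError("all-zero count vector")
    rare = nz[nz <= rare_threshold]
    s_abund = int((nz > rare_threshold).sum())
    s_rare = int(rare.size)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f = np.bincount(rare, minlength=rare_threshold + 1)
    f1 = int(f[1])
    if n_rare == f1:
        # all rare reads are singletons: C_ace = 0, use Chao1
        f2 = int(f[2]) if len(f) > 2 else 0
        return float(nz.size + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    c_ace = 1.0 - f1 / n_rare
    i = np.arange(1, rare_threshold + 1)
    sum_iif = float((i * (i - 1) * f[1:]).sum())
    gamma2 = max(
        (s_rare / c_ace) * sum_iif / (n_rare * (n_rare - 1.0)) - 1.0, 0.0
    )
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N (F1 = singleton OTUs, N = total reads)."""
    counts = _as_counts(counts)
    total = int(counts.sum())
    if total < 1:
        raise ValidationError("sample has no reads")
    f1 = int((counts == 1).sum())
    return 1.0 - f1 / total


def rarefaction_curve(
    sample_counts, depths: Sequence[int], replicates: int, seed: int
) -> pd.Series:
    """Mean observed OTUs at each subsampling depth over ``replicates`` draws."""
    counts = _as_counts(sample_counts)
    rng = np.random.default_rng(seed)
    means = []
    for depth in depths:
        obs = [
            int(
                (
                    rarefy(counts, int(depth), seed=int(rng.integers(0, 2**31)))
                    > 0
                ).sum()
            )
            for _ in range(replicates)
        ]
        means.append(float(np.mean(obs)))
    return pd.Series(means, index=list(depths), name="observed_otus")


def compare_alpha(values_a, values_b, equal_var: bool = False):
    """Two-sample t-test on per-sample index values (Welch by default).

    Returns ``(t, p)``.
    """
    res = stats.ttest_ind(np.asarray(values_a, float), np.asarray(values_b, float),
                          equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def alpha_summary(
    table: OtuTable, depth: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Rarefy every sample to a common depth and compute all alpha indices.

    ``depth=None`` uses the minimum per-sample total.  Samples below ``depth``
    are dropped with a warning rather than failing the run.
    """
    totals = table.counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "dropping %d sample(s) below rarefaction depth %d: %s",
            len(dropped), depth, dropped,
        )
    rng = np.random.default_rng(seed)
    rows = []
    for j, sid in enumerate(table.sample_ids):
        if not keep[j]:
            continue
        col = rarefy(table.counts[:, j], depth, seed=int(rng.integers(0, 2**31)))
        rows.append(
            AlphaResult(
                sample_id=sid,
                observed_otus=int((col > 0).sum()),
                ace=ace(col),
                shannon=shannon(col),
                shannoneven=shannoneven(col),
                goods_coverage=goods_coverage(col),
                rarefaction_depth=depth,
            ).__dict__
        )
    return pd.DataFrame(rows).set_index("sample_id")


def compare_groups(
    alpha: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Welch t-tests of each index between ASD and control, per habitat."""
    rows = []
    meta = metadata.loc[alpha.index]
    for habitat in sorted(meta["habitat"].unique()):
        mask = meta["habitat"] == habitat
        asd = alpha[mask & (meta["group"] == "ASD")]
        ctrl = alpha[mask & (meta["group"] == "control")]
        for index_name in ("observed_otus", "ace", "shannon", "shannoneven"):
            t, p = compare_alpha(asd[index_name], ctrl[index_name])
            rows.append(
                {
                    "habitat": habitat,
                    "index": index_name,
                    "mean_asd": float(asd[index_name].mean()),
                    "mean_control": float(ctrl[index_name].mean()),
                    "t": t,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
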