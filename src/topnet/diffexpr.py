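"""Differential-expression filters feeding the TPS and early-marker steps.

Two-class contrasts use a Welch t-test on log2 intensities with linear-scale
fold change ``2 ** (mean_A - mean_B)``; multi-class contrasts use one-way
ANOVA. Adjusted p-values are Benjamini-Hochberg. A permutation-based FDR
(label shuffling on the t statistic) is available in place of SAM's
d-statistic, which is deliberately not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ExpressionStudy

__all__ = [
    "DEGRecord",
    "DEGConfig",
    "two_class_test",
    "multi_class_anova",
    "is_deg",
    "bh_adjust",
]


@dataclass
class DEGRecord:
    gene: str
    contrast: str
    p: float
    p_adj: float
    fc: float
    perm_fdr: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")
        if self.p_adj < self.p - 1e-12:
            raise ValueError("p_adj must be >= p")
        if self.fc <= 0:
            raise ValueError("fold change must be positive")


@dataclass
class DEGConfig:
    p_threshold: float = 0.05
    p_adj_threshold: float = 0.05
    fc_threshold: float = 1.5
    perm_fdr_threshold: float = 0.001
    n_permutations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_threshold", "p_adj_threshold", "perm_fdr_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must be > 1")


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistic for two genes x samples blocks."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(denom == 0, 0.0, t)


def two_class_test(
    study: ExpressionStudy,
    groupA_samples: list[str],
    groupB_samples: list[str],
    config: DEGConfig | None = None,
    contrast: str | None = None,
    equal_var: bool = False,
) -> list[DEGRecord]:
    """Per-gene two-sample t-test (Welch by default) of A vs B.

    Fold change is ``2 ** (mean_log2_A - mean_log2_B)``. When
    ``config.n_permutations`` > 0, a permutation FDR is attached per gene:
    the expected number of null |t| values at least as large as the gene's
    (over seeded group-label shufflings) divided by the observed count.
    """
    config = config or DEGConfig()
    if set(groupA_samples) & set(groupB_samples):
        raise ValueError("groups must be disjoint")
    if len(groupA_samples) < 2 or len(groupB_samples) < 2:
        raise ValueError("each group needs >= 2 samples")
    sub = study.subset_samples(list(groupA_samples) + list(groupB_samples))
    na = len(groupA_samples)
    a, b = sub.values[:, :na], sub.values[:, na:]
    if contrast is None:
        sa = {study.design[s] for s in groupA_samples}
        sb = {study.design[s] for s in groupB_samples}
        contrast = f"{'+'.join(sorted(sa))}_vs_{'+'.join(sorted(sb))}"

    res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
    fc = 2.0 ** (a.mean(axis=1) - b.mean(axis=1))
    p_adj = bh_adjust(p)

    perm_fdr = None
    if config.n_permutations > 0:
        t_obs = np.abs(_welch_t(a, b))
        pooled = sub.values
        rng = np.random.default_rng(config.seed)
        n_tot = pooled.shape[1]
        exceed = np.zeros(len(t_obs))
        for _ in range(config.n_permutations):
            perm = rng.permutation(n_tot)
            pa, pb = pooled[:, perm[:na]], pooled[:, perm[na:]]
            t_null = np.sort(np.abs(_welch_t(pa, pb)))
            exceed += len(t_null) - np.searchsorted(t_null, t_obs, side="left")
        null_mean = exceed / config.n_permutations
        order = np.sort(t_obs)
        obs_count = len(order) - np.searchsorted(order, t_obs, side="left")
        with np.errstate(divide="ignore", invalid="ignore"):
            perm_fdr = np.clip(null_mean / np.maximum(obs_count, 1), 0.0, 1.0)

    records = []
    for i, gene in enumerate(sub.genes):
        records.append(
            DEGRecord(
                gene=gene,
                contrast=contrast,
                p=float(min(p[i], 1.0)),
                p_adj=float(p_adj[i]),
                fc=float(fc[i]),
                perm_fdr=float(perm_fdr[i]) if perm_fdr is not None else None,
            )
        )
    return records


def multi_class_anova(
    study: ExpressionStudy, states: list[str] | None = None
) -> list[DEGRecord]:
    """Per-gene one-way ANOVA across >= 3 states, BH-adjusted.

    The record's ``fc`` slot is the linear fold change between the highest
    and lowest state means (always >= 1), kept for bookkeeping only.
    """
    states = states or study.states
    if len(states) < 3:
        raise ValueError(f"need >= 3 states for ANOVA, got {len(states)}")
    groups = []
    for st in states:
        cols = [study.samples.index(s) for s in study.state_samples(st)]
        if len(cols) < 2:
            raise ValueError(f"state {st!r} needs >= 2 samples")
        groups.append(study.values[:, cols])
    res = stats.f_oneway(*groups, axis=1)
    p = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
    p_adj = bh_adjust(p)
    means = np.stack([g.mean(axis=1) for g in groups], axis=1)
    fc = 2.0 ** (means.max(axis=1) - means.min(axis=1))
    contrast = "anova_" + "+".join(states)
    return [
        DEGRecord(
            gene=g, contrast=contrast, p=float(min(p[i], 1.0)),
            p_adj=float(p_adj[i]), fc=float(fc[i]),
        )
        for i, g in enumerate(study.genes)
    ]


def is_deg(record: DEGRecord, config: DEGConfig | None = None, mode: str = "tps") -> bool:
    """DEG predicates.

    ``tps``: adjusted p below threshold and fold change > fc_threshold or
    < 1/fc_threshold (both regulation arms). ``signature``: raw p below
    threshold, permutation FDR below its threshold, and fold change above
    fc_threshold.
    """
    config = config or DEGConfig()
    if mode == "tps":
        return record.p_adj < config.p_adj_threshold and (
            record.fc > config.fc_threshold or record.fc < 1.0 / config.fc_threshold
        )
    if mode == "signature":
        if record.perm_fdr is None:
            raise ValueError("signature mode needs a permutation FDR on the record")
        return (
            record.p < config.p_threshold
            and record.perm_fdr < config.perm_fdr_threshold
            and record.fc > config.fc_threshold
        )
    raise ValueError(f"unknown mode {mode!r}")
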