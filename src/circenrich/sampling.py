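"""Platform-weighted sampling null (the Hindorff-style comparison method).

Random background SNP sets of the same size as the trait-associated set are
drawn from the catalog, with per-platform-group counts proportional to the
group composition of the real trait-associated SNPs.  Inference is
theoretical: Wald confidence intervals and normal-approximation p-values on
the log odds ratio, contrasting with the empirical inference of the
circular-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SnpCatalog
from .stats import (
    ContingencyTable,
    EnrichmentResult,
    fold_enrichment,
    odds_ratio,
    wald_ci,
    wald_pvalue,
)

__all__ = [
    "SamplingConfig",
    "group_weights_from_catalog",
    "allocate_counts",
    "sample_background",
    "sampling_enrichment",
    "run_sampling",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Parameters of the platform-weighted sampling null.

    ``group_weights`` maps platform-group label → proportion of the sample
    drawn from that group (must sum to 1).  When empty, weights are derived
    from the group composition of the real trait-associated SNP set.
    ``exclude_associated`` removes trait-associated SNPs from the sampling
    pool (off by default; the background may contain them).
    """

    n_samples: int = 100
    seed: int = 0
    group_weights: dict[str, float] = field(default_factory=dict)
    exclude_associated: bool = False

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.group_weights:
            total = sum(self.group_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"group weights sum to {total}, expected 1")


def group_weights_from_catalog(catalog: SnpCatalog, assoc_mask: np.ndarray) -> dict[str, float]:
    """Group proportions among the associated SNPs (multi-group SNPs count
    once per group; proportions normalized over group-membership counts)."""
    counts: dict[str, int] = {}
    for groups in catalog.df.loc[np.asarray(assoc_mask, dtype=bool), "platform_groups"]:
        for g in groups:
            counts[g] = counts.get(g, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no associated SNPs to derive group weights from")
    return {g: c / total for g, c in sorted(counts.items())}


def allocate_counts(weights: dict[str, float], size: int) -> dict[str, int]:
    """Largest-remainder (Hamilton) apportionment of ``size`` across groups.

    Each group gets floor(size·w); remaining units go to the groups with
    the largest fractional remainders, ties broken by group label.
    """
    groups = sorted(weights)
    raw = {g: size * weights[g] for g in groups}
    base = {g: int(raw[g]) for g in groups}
    left = size - sum(base.values())
    by_remainder = sorted(groups, key=lambda g: (-(raw[g] - base[g]), g))
    for g in by_remainder[:left]:
        base[g] += 1
    return base


def sample_background(
    catalog: SnpCatalog,
    cfg: SamplingConfig,
    size: int,
    assoc_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> set[str]:
    """One background SNP set of ``size``, platform-group weighted.

    Groups are processed in a fixed (sorted) order; a SNP belonging to
    several groups is eligible for each but drawn at most once, because
    SNPs sampled by earlier groups are removed from later pools.  Sampling
    within a group is without replacement.  Raises when a group's pool is
    smaller than its allocation, naming the group.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    weights = cfg.group_weights
    if not weights:
        if assoc_mask is None:
            raise ValueError("need assoc_mask to derive default group weights")
        weights = group_weights_from_catalog(catalog, assoc_mask)
    alloc = allocate_counts(weights, size)
    df = catalog.df
    eligible = np.ones(len(df), dtype=bool)
    if cfg.exclude_associated:
        if assoc_mask is None:
            raise ValueError("exclude_associated requires assoc_mask")
        eligible &= ~np.asarray(assoc_mask, dtype=bool)
    chosen: set[str] = set()
    taken = np.zeros(len(df), dtype=bool)
    group_sets = df["platform_groups"].to_numpy()
    ids = catalog.snp_ids
    for g in sorted(alloc):
        want = alloc[g]
        if want == 0:
            continue
        pool = np.flatnonzero(
            eligible & ~taken & np.fromiter((g in s for s in group_sets), bool, len(df))
        )
        if len(pool) < want:
            raise ValueError(
                f"platform group {g!r} exhausted: need {want}, have {len(pool)}"
            )
        pick = rng.choice(pool, size=want, replace=False)
        taken[pick] = True
        chosen.update(ids[pick])
    return chosen


def sampling_enrichment(
    annotation: str,
    observed_hits: int,
    n_assoc: int,
    sample_hit_counts,
    sample_size: int,
) -> EnrichmentResult:
    """Wald-based enrichment of the observation against sampled backgrounds.

    The null cell is the mean hit count over the samples; CI and p come
    from the Wald normal approximation on ln OR.
    """
    counts = np.asarray(sample_hit_counts, dtype=float)
    if ((counts < 0) | (counts > sample_size)).any():
        raise ValueError("sample hit counts must lie in [0, sample_size]")
    mean = float(counts.mean())
    table = ContingencyTable(observed_hits, n_assoc - observed_hits,
                             mean, sample_size - mean)
    point = odds_ratio(table)
    ci_low, ci_high = wald_ci(table)
    p = wald_pvalue(table)
    fe = fold_enrichment(observed_hits, mean) if mean > 0 else np.inf
    return EnrichmentResult(
        annotation=annotation,
        table=table,
        odds_ratio=point,
        ci_low=ci_low,
        ci_high=ci_high,
        pvalue=p,
        pvalue_is_bound=False,
        fold_enrichment=fe,
        method="sampling",
    )


def run_sampling(
    matrix,
    catalog: SnpCatalog,
    assoc_mask: np.ndarray,
    cfg: SamplingConfig,
) -> list[EnrichmentResult]:
    """Full sampling null over every annotation in an overlap matrix.

    Background SNPs reuse the precomputed LD-expanded incidence rows: their
    LD partners are ascertained exactly as for the real trait-associated
    SNPs.
    """
    assoc_mask = np.asarray(assoc_mask, dtype=bool)
    n_assoc = int(assoc_mask.sum())
    if n_assoc == 0:
        raise ValueError("no associated SNPs")
    rng = np.random.default_rng(cfg.seed)
    row_of = {sid: i for i, sid in enumerate(matrix.snp_ids)}
    hit_counts = np.zeros((cfg.n_samples, matrix.values.shape[1]), dtype=np.int64)
    for s in range(cfg.n_samples):
        ids = sample_background(catalog, cfg, n_assoc, assoc_mask, rng)
        rows = np.fromiter((row_of[i] for i in ids), dtype=np.int64, count=len(ids))
        hit_counts[s] = matrix.values[rows].sum(axis=0)
    observed = matrix.values[assoc_mask].sum(axis=0)
    return [
        sampling_enrichment(
            matrix.annotations[j], int(observed[j]), n_assoc, hit_counts[:, j], n_assoc
        )
        for j in range(matrix.values.shape[1])
    ]
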