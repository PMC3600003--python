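"""Synthetic genomes with the statistical structure the real inputs have.

The generator emulates, at toy scale, what makes annotation-enrichment
inference hard on real data: SNP positions cluster (genotyping platforms
and HapMap density are far from uniform), LD comes in blocks with a hard
distance cap, annotation intervals cluster rather than sprinkle, platform
membership varies per SNP, and association labels can be planted with a
chosen odds ratio towards a designated track.  Every stage of the pipeline
is therefore testable offline against a known ground truth.

All randomness flows through one seeded ``numpy`` generator, consumed in
the order: SNP positions (per chromosome), platform flags, LD blocks,
annotation tracks (in listed order), association labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotationTrack, LdConfig, LdMap, SnpCatalog, Status
from .overlap import OverlapMatrix
from .stats import ContingencyTable, DegenerateTableError, odds_ratio

__all__ = [
    "TrackSpec",
    "SimConfig",
    "simulate_genome",
    "simulate_ld_blocks",
    "simulate_annotations",
    "plant_associations",
    "simulate_study",
]


@dataclass(frozen=True)
class TrackSpec:
    """One synthetic annotation track.

    ``target_coverage`` is the fraction of the genome the track should
    cover (realized within ±10% relative); ``mean_length`` the mean
    interval length in bp; ``clustering`` the mean number of intervals per
    cluster (1 = unclustered).
    """

    name: str
    target_coverage: float = 0.05
    mean_length: int = 2_000
    clustering: float = 4.0

    def __post_init__(self):
        if not 0 < self.target_coverage < 1:
            raise ValueError("target_coverage must be in (0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic genome.

    Defaults give a 3-chromosome × 20,000-SNP toy genome, 10 clustered
    tracks and a rare associated set — the same shape as the real study
    (clustered SNPs, block LD under a 250 kb cap, clustered annotations,
    platform-group structure) at desk scale.
    """

    n_chromosomes: int = 3
    snps_per_chromosome: int = 20_000
    chromosome_length: int = 60_000_000
    cluster_size_mean: float = 8.0  # mean SNPs per cluster
    cluster_spread: int = 5_000  # geometric mean offset from cluster center, bp
    ld_block_length: int = 20_000  # mean block length, bp
    within_block_r2: tuple[float, float] = (0.5, 1.0)  # uniform range
    tracks: tuple[TrackSpec, ...] = tuple(
        TrackSpec(name=f"track{i:02d}", target_coverage=c, mean_length=2_000, clustering=4.0)
        for i, c in enumerate((0.02, 0.05, 0.05, 0.1, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4))
    )
    n_assoc: int = 200
    planted_or: dict[str, float] = field(default_factory=dict)
    platform_groups: tuple[tuple[str, float], ...] = (
        ("affymetrix", 0.55),
        ("illumina", 0.60),
        ("hapmap", 1.0),
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_assoc > 0 and self.n_assoc >= self.n_chromosomes * self.snps_per_chromosome:
            raise ValueError("n_assoc must be smaller than the total SNP count")
        for tr, or_ in self.planted_or.items():
            if or_ <= 0:
                raise ValueError(f"planted OR for {tr!r} must be positive")


def _clustered_positions(n: int, length: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Poisson-cluster SNP positions: uniform cluster centers, geometric offsets."""
    if n == 0:
        return np.array([], dtype=np.int64)
    if n > length:
        raise ValueError(f"cannot place {n} distinct SNPs on a {length} bp chromosome")
    positions: set[int] = set()
    # draw clusters until enough distinct positions accumulate
    while len(positions) < n:
        n_clusters = max(1, int(np.ceil((n - len(positions)) / cfg.cluster_size_mean)))
        centers = rng.integers(1, length + 1, size=n_clusters)
        sizes = rng.geometric(1.0 / cfg.cluster_size_mean, size=n_clusters)
        for c, k in zip(centers, sizes):
            offs = rng.geometric(1.0 / cfg.cluster_spread, size=k) * rng.choice(
                [-1, 1], size=k
            )
            for p in c + offs:
                if 1 <= p <= length:
                    positions.add(int(p))
    pos = np.array(sorted(positions), dtype=np.int64)
    if len(pos) > n:
        pos = np.sort(rng.choice(pos, size=n, replace=False))
    return pos


def simulate_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> SnpCatalog:
    """Clustered SNP catalog with platform-group flags; no statuses yet."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rows = []
    fallback = cfg.platform_groups[0][0] if cfg.platform_groups else "default"
    for c in range(cfg.n_chromosomes):
        chrom = str(c + 1)
        pos = _clustered_positions(cfg.snps_per_chromosome, cfg.chromosome_length, cfg, rng)
        flags = {
            label: rng.random(len(pos)) < prob for label, prob in cfg.platform_groups
        }
        for i, p in enumerate(pos):
            groups = frozenset(lbl for lbl in flags if flags[lbl][i])
            if not groups:
                groups = frozenset({fallback})
            rows.append((f"rs{chrom}_{i}", chrom, int(p), groups))
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "platform_groups"])
    if df.empty:
        df = pd.DataFrame(
            {"snp_id": pd.Series(dtype=str), "chrom": pd.Series(dtype=str),
             "pos": pd.Series(dtype=np.int64), "platform_groups": pd.Series(dtype=object)}
        )
    return SnpCatalog(df)


def simulate_ld_blocks(
    catalog: SnpCatalog,
    cfg: SimConfig,
    ld_cfg: LdConfig | None = None,
    rng: np.random.Generator | None = None,
) -> LdMap:
    """Block-cartoon LD: chromosomes tiled into exponential-length blocks,
    every intra-block pair assigned an r² from ``within_block_r2``; only
    pairs passing the LdConfig filters (strict r² threshold, distance cap)
    enter the map.  No cross-block partners."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if ld_cfg is None:
        ld_cfg = LdConfig()
    lo, hi = cfg.within_block_r2
    partners: dict[str, set[str]] = {}
    pos = catalog.positions()
    ids = catalog.snp_ids
    for chrom, sl in catalog.chrom_slices().items():
        p = pos[sl]
        sid = ids[sl]
        # tile the chromosome into blocks
        edge = 0.0
        edges = [0.0]
        while edge < cfg.chromosome_length:
            edge += rng.exponential(cfg.ld_block_length)
            edges.append(edge)
        block_of = np.searchsorted(np.asarray(edges), p, side="right")
        for b in np.unique(block_of):
            members = np.flatnonzero(block_of == b)
            for i_idx in range(len(members)):
                for j_idx in range(i_idx + 1, len(members)):
                    i, j = members[i_idx], members[j_idx]
                    r2 = rng.uniform(lo, hi)
                    if r2 > ld_cfg.r2_threshold and abs(int(p[i]) - int(p[j])) <= ld_cfg.max_pair_distance:
                        partners.setdefault(sid[i], set()).add(sid[j])
    return LdMap(partners)


def _clustered_intervals(
    spec: TrackSpec, chrom_lengths: dict[str, int], rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    total = sum(chrom_lengths.values())
    target = spec.target_coverage * total
    intervals: list[tuple[str, int, int]] = []
    covered = 0.0
    chroms = list(chrom_lengths)
    if spec.target_coverage > 0.95:
        raise ValueError("coverage target too high to realize with clustered intervals")
    # add clusters of intervals until the (approximate) covered length reaches target
    while covered < target:
        chrom = chroms[rng.integers(len(chroms))]
        length = chrom_lengths[chrom]
        center = int(rng.integers(0, length))
        k = int(rng.geometric(1.0 / spec.clustering))
        for _ in range(k):
            span = max(1, int(rng.exponential(spec.mean_length)))
            start = center + int(rng.normal(0, spec.mean_length * 4))
            start = max(0, min(start, length - 1))
            end = min(length, start + span)
            if end > start:
                intervals.append((chrom, start, end))
                covered += end - start
            if covered >= target:
                break
    return intervals


def simulate_annotations(
    cfg: SimConfig, chrom_lengths: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> list[AnnotationTrack]:
    """Clustered annotation tracks hitting each coverage target within ±10%.

    Interval overlap within a track makes naive length-summing overshoot;
    each track is rebuilt with a shrinking correction until the realized
    (merged) coverage lands inside the tolerance.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    if chrom_lengths is None:
        chrom_lengths = {
            str(c + 1): cfg.chromosome_length for c in range(cfg.n_chromosomes)
        }
    total = sum(chrom_lengths.values())
    tracks = []
    for spec in cfg.tracks:
        track = None
        spec_eff = spec
        for _ in range(20):
            candidate = AnnotationTrack(spec.name, _clustered_intervals(spec_eff, chrom_lengths, rng))
            realized = candidate.total_bases() / total
            if abs(realized - spec.target_coverage) <= 0.10 * spec.target_coverage:
                track = candidate
                break
            # overlap made the union fall short: inflate the raw target
            scale = spec.target_coverage / max(realized, 1e-9)
            new_cov = min(0.95, spec_eff.target_coverage * scale)
            spec_eff = TrackSpec(spec.name, new_cov, spec.mean_length, spec.clustering)
        if track is None:
            raise ValueError(f"could not realize coverage target for track {spec.name!r}")
        tracks.append(track)
    return tracks


def plant_associations(
    matrix: OverlapMatrix,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict[str, ContingencyTable]]:
    """Association labels planted at target odds ratios towards tracks.

    Labels are sampled without replacement with per-SNP weight
    ``prod_t planted_or[t] ** incidence[snp, t]`` (exponential tilting), so
    the realized conditional odds ratio approaches the target as the
    associated fraction stays rare.  Returns the boolean label vector and
    the realized ground-truth 2×2 table per planted track — acceptance
    checks compare against realized, not nominal, ORs.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    n = len(matrix.snp_ids)
    if cfg.n_assoc > n:
        raise ValueError("n_assoc exceeds number of SNPs")
    logw = np.zeros(n)
    for tr, or_ in cfg.planted_or.items():
        logw += np.log(or_) * matrix.column(tr).astype(float)
    # Efraimidis–Spirakis weighted sampling without replacement
    keys = rng.exponential(1.0, size=n) / np.exp(logw)
    chosen = np.argpartition(keys, cfg.n_assoc)[: cfg.n_assoc] if cfg.n_assoc else np.array([], dtype=int)
    status = np.zeros(n, dtype=bool)
    status[chosen] = True
    tables: dict[str, ContingencyTable] = {}
    for tr in cfg.planted_or:
        inc = matrix.column(tr)
        tables[tr] = ContingencyTable(
            hits_real=int((status & inc).sum()),
            nonhits_real=int((status & ~inc).sum()),
            hits_null=int((~status & inc).sum()),
            nonhits_null=int((~status & ~inc).sum()),
        )
    return status, tables


def plant_clustered_associations(
    catalog: SnpCatalog,
    n_assoc: int,
    mean_cluster: float = 5.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Association labels planted in positional clusters, independent of
    any annotation.

    Mimics the clustering of real GWAS hits (one causal signal tags a run
    of neighbouring SNPs through LD): random seed SNPs are chosen and a
    geometric-length run of consecutive catalog neighbours is labelled with
    them, until ``n_assoc`` labels are placed.  Because the labels ignore
    every annotation, enrichment tests on them exercise pure null
    behaviour — but with the positional clustering that a
    position-ignorant background-sampling null does not model.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(catalog)
    if n_assoc > n:
        raise ValueError("n_assoc exceeds number of SNPs")
    status = np.zeros(n, dtype=bool)
    slices = list(catalog.chrom_slices().values())
    while status.sum() < n_assoc:
        sl = slices[rng.integers(len(slices))]
        size = sl.stop - sl.start
        start = sl.start + int(rng.integers(size))
        run = int(rng.geometric(1.0 / mean_cluster))
        run = min(run, n_assoc - int(status.sum()) + int(status[start:start + run].sum()))
        status[start:min(sl.stop, start + run)] = True
    # trim overshoot deterministically from the end of the label list
    extra = int(status.sum()) - n_assoc
    if extra > 0:
        status[np.flatnonzero(status)[-extra:]] = False
    return status


def realized_or(table: ContingencyTable) -> float:
    """Ground-truth odds ratio of a planted 2×2 table."""
    try:
        return odds_ratio(table)
    except DegenerateTableError:
        return float("nan")


def simulate_study(cfg: SimConfig, ld_cfg: LdConfig | None = None):
    """Full synthetic study: catalog, LD map, tracks, matrix, labels, truth.

    Consumes independent seeded substreams per stage (seed, seed+1, ...),
    so stages stay reproducible when rerun in isolation.
    """
    from .overlap import compute_overlap_matrix

    catalog = simulate_genome(cfg)
    ld = simulate_ld_blocks(catalog, cfg, ld_cfg)
    tracks = simulate_annotations(cfg)
    matrix = compute_overlap_matrix(catalog, ld, tracks)
    status, truth = plant_associations(matrix, cfg)
    df = catalog.df.copy()
    df["status"] = np.where(status, Status.SIGNIFICANT, Status.BACKGROUND)
    df["pvalue"] = np.where(status, 1e-9, 0.5)
    catalog = SnpCatalog(df)
    return catalog, ld, tracks, matrix, status, truth
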