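"""Core data types and readers/writers for the formats the tool touches.

Coordinate conventions
----------------------
SNP positions are 1-based (dbSNP/VCF convention).  Annotation intervals are
0-based half-open BED intervals ``[start, end)``.  A 1-based position ``p``
lies inside ``[start, end)`` iff ``start < p <= end``.

Chromosome names are canonicalized by stripping a leading ``chr`` prefix, so
``chr1`` and ``1`` refer to the same chromosome.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Status",
    "StatusConfig",
    "LdConfig",
    "SnpCatalog",
    "LdMap",
    "AnnotationTrack",
    "canonical_chrom",
    "read_annotation_bed",
    "read_snp_table",
    "write_snp_table",
    "read_ld_pairs",
    "assign_association_status",
    "write_enrichment_table",
    "read_enrichment_table",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def canonical_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix so 'chr1' and '1' compare equal."""
    name = str(name).strip()
    return name[3:] if name.lower().startswith("chr") else name


class Status(enum.Enum):
    """Trait-association status of a SNP."""

    SIGNIFICANT = "significant"
    SUGGESTIVE = "suggestive"
    BACKGROUND = "background"


@dataclass(frozen=True)
class StatusConfig:
    """Thresholds and exclusions used to assign association status.

    ``genomewide_threshold`` is the genome-wide significance level
    (p < 5e-8); p-values in ``[genomewide_threshold, suggestive_upper)``
    are suggestive.  Suggestive SNPs in LD (r² above
    ``prune_suggestive_r2``) with a significant SNP are demoted to
    background.  SNPs on ``excluded_chromosomes`` are removed entirely.
    """

    genomewide_threshold: float = 5e-8
    suggestive_upper: float = 5e-5
    excluded_chromosomes: frozenset[str] = frozenset({"Y", "Un"})
    prune_suggestive_r2: float = 0.9

    def __post_init__(self) -> None:
        if not self.genomewide_threshold < self.suggestive_upper:
            raise ValueError("genomewide_threshold must be < suggestive_upper")
        object.__setattr__(
            self,
            "excluded_chromosomes",
            frozenset(canonical_chrom(c) for c in self.excluded_chromosomes),
        )


@dataclass(frozen=True)
class LdConfig:
    """Filters defining which SNP pairs count as LD partners.

    Pairs are retained when r² is strictly above ``r2_threshold`` and the
    positional distance is at most ``max_pair_distance`` base pairs
    (250 kb per side by default, so partners of one SNP may span 500 kb).
    """

    r2_threshold: float = 0.9
    max_pair_distance: int = 250_000

    def __post_init__(self) -> None:
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.max_pair_distance <= 0:
            raise ValueError("max_pair_distance must be positive")


class SnpCatalog:
    """Ordered per-chromosome list of SNPs: the substrate every null permutes.

    Backed by a DataFrame with columns ``snp_id``, ``chrom``, ``pos``,
    ``platform_groups`` (frozenset of labels), ``pvalue`` (float, NaN when
    absent) and ``status`` (:class:`Status`), sorted by (chrom, pos) with
    chromosome order = first-appearance order of the sorted label set.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"snp_id", "chrom", "pos", "platform_groups"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        df = df.copy()
        df["chrom"] = df["chrom"].map(canonical_chrom)
        if "pvalue" not in df.columns:
            df["pvalue"] = np.nan
        if "status" not in df.columns:
            df["status"] = Status.BACKGROUND
        if df["snp_id"].duplicated().any():
            dupes = df.loc[df["snp_id"].duplicated(), "snp_id"].head(3).tolist()
            raise ValueError(f"duplicate snp_id values, e.g. {dupes}")
        if (df["pos"] <= 0).any():
            raise ValueError("SNP positions must be positive (1-based)")
        if df.duplicated(subset=["chrom", "pos", "snp_id"]).any():
            raise ValueError("duplicate (chrom, pos, snp_id) triples")
        for groups in df["platform_groups"]:
            if not groups:
                raise ValueError("every SNP must belong to >=1 platform group")
        # stable chromosome order: numeric autosomes first, then X etc.
        df = df.sort_values(
            ["chrom", "pos"], key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s
        ).reset_index(drop=True)
        self._df = df
        self._index = pd.Index(df["snp_id"])

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def snp_ids(self) -> np.ndarray:
        return self._df["snp_id"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in catalog order."""
        return list(dict.fromkeys(self._df["chrom"]))

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def row_of(self, snp_id: str) -> int:
        """Positional row index of a SNP in catalog order."""
        i = self._index.get_indexer([snp_id])[0]
        if i < 0:
            raise KeyError(f"unknown SNP id: {snp_id!r}")
        return int(i)

    def positions(self) -> np.ndarray:
        return self._df["pos"].to_numpy(dtype=np.int64)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome, in catalog order."""
        out: dict[str, slice] = {}
        chroms = self._df["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def status_array(self, which: Status) -> np.ndarray:
        """Boolean per-SNP vector marking SNPs with the given status."""
        return (self._df["status"] == which).to_numpy()


def _chrom_sort_key(name: str):
    try:
        return (0, int(name), "")
    except ValueError:
        return (1, 0, name)


class LdMap:
    """Symmetric SNP → LD-partner mapping, filtered by r² and distance."""

    def __init__(self, partners: dict[str, set[str]]):
        # enforce symmetry on construction
        sym: dict[str, set[str]] = {k: set(v) for k, v in partners.items()}
        for a, ps in list(sym.items()):
            for b in ps:
                sym.setdefault(b, set()).add(a)
        self._partners = sym

    def partners(self, snp_id: str) -> frozenset[str]:
        return frozenset(self._partners.get(snp_id, ()))

    def __len__(self) -> int:
        return sum(len(v) for v in self._partners.values()) // 2

    def items(self):
        return self._partners.items()


@dataclass(frozen=True)
class AnnotationTrack:
    """A named set of genomic intervals (0-based half-open).

    Construction normalizes: intervals sorted per chromosome, overlapping
    or touching intervals merged, so the stored set is disjoint.
    """

    name: str
    intervals: tuple[tuple[str, int, int], ...]

    def __init__(self, name: str, intervals) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "intervals", _normalize(intervals))

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome (n, 2) arrays of [start, end) pairs."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.intervals:
            out.setdefault(chrom, []).append((s, e))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def _normalize(intervals) -> tuple[tuple[str, int, int], ...]:
    cleaned = []
    for chrom, start, end in intervals:
        start, end = int(start), int(end)
        if not 0 <= start < end:
            raise ValueError(f"invalid interval [{start}, {end}) on {chrom}")
        cleaned.append((canonical_chrom(chrom), start, end))
    cleaned.sort(key=lambda t: (_chrom_sort_key(t[0]), t[1], t[2]))
    merged: list[list] = []
    for chrom, s, e in cleaned:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([chrom, s, e])
    return tuple((c, s, e) for c, s, e in merged)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_annotation_bed(path, name: str) -> AnnotationTrack:
    """Read a BED file (>=3 columns) into a normalized AnnotationTrack.

    Header lines starting with ``browser``, ``track`` or ``#`` are skipped;
    extra BED columns are ignored.  Raises :class:`ParseError` naming the
    offending line for non-integer or inverted coordinates.
    """
    intervals = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "browser", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom, s_raw, e_raw = fields[0], fields[1], fields[2]
            try:
                start, end = int(s_raw), int(e_raw)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates {s_raw!r}, {e_raw!r}"
                ) from None
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            intervals.append((chrom, start, end))
    return AnnotationTrack(name, intervals)


def read_tss_bed(path, name: str = "tss") -> pd.DataFrame:
    """Read a stranded BED (chrom, start, end, name, score, strand).

    Returns a DataFrame with columns chrom, pos (1-based TSS point: start+1
    for + strand, end for - strand) and strand.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "browser", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: stranded BED needs >=6 fields")
            chrom, start, end, strand = fields[0], int(fields[1]), int(fields[2]), fields[5]
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            pos = start + 1 if strand == "+" else end
            rows.append((canonical_chrom(chrom), pos, strand))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


def read_snp_table(path) -> SnpCatalog:
    """Read a tab-separated SNP table into a sorted :class:`SnpCatalog`.

    Required header columns: ``snp_id``, ``chrom``, ``pos``,
    ``platform_groups`` (comma-joined labels); ``pvalue`` is optional and
    missing/empty values leave the SNP as background pending assignment.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"snp_id", "chrom", "pos", "platform_groups"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    try:
        pos = df["pos"].astype(np.int64)
    except (ValueError, TypeError):
        bad = df.index[~df["pos"].str.fullmatch(r"-?\d+", na=False)]
        raise ParseError(
            f"{path}: non-integer pos at data row(s) {bad[:3].tolist()}"
        ) from None
    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"],
            "chrom": df["chrom"],
            "pos": pos,
            "platform_groups": [
                frozenset(g.strip() for g in str(x).split(",") if g.strip())
                for x in df["platform_groups"]
            ],
        }
    )
    if "pvalue" in df.columns:
        out["pvalue"] = pd.to_numeric(df["pvalue"], errors="coerce")
    return SnpCatalog(out)


def write_snp_table(catalog: SnpCatalog, path) -> None:
    df = catalog.df.copy()
    df["platform_groups"] = df["platform_groups"].map(lambda s: ",".join(sorted(s)))
    df["status"] = df["status"].map(lambda s: s.value)
    df.to_csv(path, sep="\t", index=False)


def read_ld_pairs(path, cfg: LdConfig, catalog: SnpCatalog) -> LdMap:
    """Read (snpA, snpB, r2) rows and build a filtered, symmetric LdMap.

    Pairs are kept when r² > ``cfg.r2_threshold`` (strict), both SNPs lie
    on the same chromosome, and their distance is within
    ``cfg.max_pair_distance``.  Pairs naming SNPs absent from the catalog,
    or crossing chromosomes, are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    df.columns = [c.lower() for c in df.columns]
    cols = list(df.columns)
    a_col = next((c for c in ("snpa", "snp_a", "snp_1") if c in cols), cols[0])
    b_col = next((c for c in ("snpb", "snp_b", "snp_2") if c in cols), cols[1])
    r2_col = next((c for c in ("r2", "r^2", "rsq") if c in cols), cols[-1])
    return build_ld_map(
        df[a_col].to_numpy(), df[b_col].to_numpy(),
        df[r2_col].to_numpy(dtype=float), cfg, catalog,
    )


def build_ld_map(snp_a, snp_b, r2, cfg: LdConfig, catalog: SnpCatalog) -> LdMap:
    """Filter raw LD pairs against the catalog and LdConfig (see read_ld_pairs)."""
    r2 = np.asarray(r2, dtype=float)
    if ((r2 < 0) | (r2 > 1)).any():
        raise ValueError("r2 values must lie in [0, 1]")
    cat = catalog.df
    lookup = pd.Series(np.arange(len(cat)), index=cat["snp_id"])
    ia = lookup.reindex(snp_a).to_numpy()
    ib = lookup.reindex(snp_b).to_numpy()
    known = ~(np.isnan(ia) | np.isnan(ib))
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.info("dropped %d LD pairs referencing unknown SNPs", n_unknown)
    ia, ib, r2 = ia[known].astype(int), ib[known].astype(int), r2[known]
    chrom = cat["chrom"].to_numpy()
    pos = cat["pos"].to_numpy()
    same_chrom = chrom[ia] == chrom[ib]
    if (~same_chrom).any():
        logger.warning("dropped %d cross-chromosome LD pairs", int((~same_chrom).sum()))
    keep = (
        same_chrom
        & (r2 > cfg.r2_threshold)
        & (np.abs(pos[ia] - pos[ib]) <= cfg.max_pair_distance)
        & (ia != ib)
    )
    ids = cat["snp_id"].to_numpy()
    partners: dict[str, set[str]] = {}
    for a, b in zip(ids[ia[keep]], ids[ib[keep]]):
        partners.setdefault(a, set()).add(b)
    return LdMap(partners)


def assign_association_status(
    catalog: SnpCatalog, cfg: StatusConfig, ld: LdMap
) -> SnpCatalog:
    """Assign significant / suggestive / background status from p-values.

    SNPs on excluded chromosomes (Y and unassigned by default) are removed.
    ``pvalue < genomewide_threshold`` → significant;
    ``genomewide_threshold <= pvalue < suggestive_upper`` → suggestive,
    except that suggestive SNPs in LD with any significant SNP are demoted
    to background (they tag the same signal); everything else background.
    Idempotent: statuses are recomputed from p-values each call.
    """
    df = catalog.df.copy()
    df = df[~df["chrom"].isin(cfg.excluded_chromosomes)].reset_index(drop=True)
    p = df["pvalue"].to_numpy(dtype=float)
    sig = p < cfg.genomewide_threshold
    sug = (~sig) & (p < cfg.suggestive_upper)
    sig_ids = set(df.loc[sig, "snp_id"])
    status = np.full(len(df), Status.BACKGROUND, dtype=object)
    status[sig] = Status.SIGNIFICANT
    for i in np.flatnonzero(sug):
        if ld.partners(df.at[i, "snp_id"]) & sig_ids:
            continue  # tags a significant signal; demoted
        status[i] = Status.SUGGESTIVE
    df["status"] = status
    return SnpCatalog(df)


_ENRICH_COLS = [
    "annotation",
    "hits_obs",
    "n_assoc",
    "null_mean",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "pvalue",
    "pvalue_is_bound",
    "fold_enrichment",
    "significant_after_bonferroni",
]


def _fmt(x) -> str:
    if isinstance(x, float):
        if math.isinf(x):
            return "Infinity" if x > 0 else "-Infinity"
        if math.isnan(x):
            return "NA"
        return f"{x:.8g}"
    return str(x)


def write_enrichment_table(results, path, *, bonferroni_alpha: float | None = None,
                           n_tests: int | None = None) -> None:
    """Write EnrichmentResults as a TSV; unbounded CIs rendered "Infinity".

    When ``bonferroni_alpha`` and ``n_tests`` are given, the
    ``significant_after_bonferroni`` column thresholds each p-value at
    alpha/n_tests; otherwise it is NA.
    """
    results = list(results)
    if not results:
        raise ValueError("results must be non-empty")
    thresh = None
    if bonferroni_alpha is not None and n_tests is not None:
        thresh = bonferroni_alpha / n_tests
    rows = []
    for r in results:
        sig = "NA" if thresh is None else str(r.pvalue <= thresh)
        rows.append(
            [
                r.annotation,
                r.table.hits_real,
                r.table.hits_real + r.table.nonhits_real,
                r.table.hits_null,
                r.odds_ratio,
                r.ci_low,
                r.ci_high,
                r.pvalue,
                r.pvalue_is_bound,
                r.fold_enrichment,
                sig,
            ]
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_ENRICH_COLS) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def read_enrichment_table(path) -> pd.DataFrame:
    """Parse a written enrichment TSV back; "Infinity" becomes float inf."""
    df = pd.read_csv(path, sep="\t")
    for col in ("null_mean", "odds_ratio", "ci_low", "ci_high", "pvalue", "fold_enrichment"):
        df[col] = df[col].map(
            lambda v: float("inf") if v == "Infinity"
            else float("-inf") if v == "-Infinity"
            else float(v)
        )
    return df
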