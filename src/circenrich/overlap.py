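"""LD-expanded SNP-vs-annotation incidence and interval arithmetic.

The central object is the :class:`OverlapMatrix`: one boolean per
(SNP, annotation) cell, true when the SNP *or any of its LD partners* lies
inside the annotation.  SNPs without LD partners are assessed on their own.
The matrix is computed once; every null (circular permutation, platform
sampling) is then a relabelling of its rows, never a re-overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AnnotationTrack, LdMap, SnpCatalog, canonical_chrom

__all__ = [
    "IntervalIndex",
    "OverlapMatrix",
    "build_interval_index",
    "expand_with_ld",
    "compute_overlap_matrix",
    "subtract_tracks",
]


class IntervalIndex:
    """Binary-searchable point-membership index over a normalized track.

    Intervals within a chromosome are disjoint and sorted, so membership of
    a 1-based position ``p`` reduces to locating the interval whose start
    is the greatest start < p and checking ``p <= end``.
    """

    def __init__(self, track: AnnotationTrack):
        self.name = track.name
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, arr in track.by_chrom().items():
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    def contains(self, chrom: str, positions) -> np.ndarray:
        """Vectorized membership of 1-based positions on one chromosome."""
        positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        chrom = canonical_chrom(chrom)
        starts = self._starts.get(chrom)
        if starts is None:
            return np.zeros(positions.shape, dtype=bool)
        ends = self._ends[chrom]
        # 1-based p in [start, end) (0-based)  <=>  start < p <= end
        idx = np.searchsorted(starts, positions, side="left") - 1
        ok = idx >= 0
        hit = np.zeros(positions.shape, dtype=bool)
        hit[ok] = positions[ok] <= ends[idx[ok]]
        return hit

    def contains_point(self, chrom: str, position: int) -> bool:
        return bool(self.contains(chrom, [position])[0])


def build_interval_index(track: AnnotationTrack) -> IntervalIndex:
    """Build an :class:`IntervalIndex` for point queries on a track."""
    return IntervalIndex(track)


def expand_with_ld(snp_id: str, ld: LdMap, catalog: SnpCatalog | None = None) -> frozenset[str]:
    """The SNP together with its LD partners; never empty.

    SNPs without partners expand to themselves alone.
    """
    if catalog is not None and snp_id not in catalog:
        raise KeyError(f"unknown SNP id: {snp_id!r}")
    return frozenset({snp_id}) | ld.partners(snp_id)


@dataclass(frozen=True)
class OverlapMatrix:
    """Boolean SNP × annotation incidence in catalog row order.

    ``values[i, j]`` is true when SNP ``i`` or one of its LD partners lies
    inside track ``j``.  Immutable once built; nulls recount its rows.
    """

    snp_ids: tuple[str, ...]
    annotations: tuple[str, ...]
    values: np.ndarray  # bool, shape (n_snps, n_tracks)

    def __post_init__(self):
        if self.values.shape != (len(self.snp_ids), len(self.annotations)):
            raise ValueError("matrix shape does not match labels")
        self.values.setflags(write=False)

    def column(self, annotation: str) -> np.ndarray:
        try:
            j = self.annotations.index(annotation)
        except ValueError:
            raise KeyError(f"unknown annotation: {annotation!r}") from None
        return self.values[:, j]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("snp_id\t" + "\t".join(self.annotations) + "\n")
            for sid, row in zip(self.snp_ids, self.values.astype(int)):
                fh.write(sid + "\t" + "\t".join(map(str, row)) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "OverlapMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col="snp_id")
        return cls(
            snp_ids=tuple(df.index),
            annotations=tuple(df.columns),
            values=df.to_numpy().astype(bool),
        )


def _own_incidence(catalog: SnpCatalog, index: IntervalIndex) -> np.ndarray:
    """Per-SNP membership of the SNP's own position in one track."""
    out = np.zeros(len(catalog), dtype=bool)
    pos = catalog.positions()
    for chrom, sl in catalog.chrom_slices().items():
        out[sl] = index.contains(chrom, pos[sl])
    return out


def compute_overlap_matrix(
    catalog: SnpCatalog, ld: LdMap, tracks: list[AnnotationTrack]
) -> OverlapMatrix:
    """LD-expanded incidence of every catalog SNP against every track.

    A cell is true iff any member of the SNP's LD expansion (itself plus
    partners) has its position inside the track.  Partners absent from the
    catalog are an error: the overlap rule needs their positions.
    """
    n = len(catalog)
    ids = catalog.snp_ids
    row_of = {sid: i for i, sid in enumerate(ids)}

    # CSR-style partner arrays: for each SNP row, the rows of its partners
    heads = [np.array([i], dtype=np.int64) for i in range(n)]
    for sid, partners in ld.items():
        if sid not in row_of:
            continue  # partner map may cover SNPs outside this catalog
        i = row_of[sid]
        prow = []
        for p in partners:
            if p not in row_of:
                raise KeyError(f"LD partner {p!r} of {sid!r} absent from catalog")
            prow.append(row_of[p])
        if prow:
            heads[i] = np.concatenate([heads[i], np.asarray(prow, dtype=np.int64)])
    counts = np.array([len(h) for h in heads])
    flat = np.concatenate(heads)
    offsets = np.concatenate([[0], np.cumsum(counts)])[:-1]

    values = np.zeros((n, len(tracks)), dtype=bool)
    for j, track in enumerate(tracks):
        own = _own_incidence(catalog, build_interval_index(track))
        member = own[flat]
        # any() over each SNP's expansion segment
        values[:, j] = np.logical_or.reduceat(member, offsets)
    return OverlapMatrix(
        snp_ids=tuple(ids), annotations=tuple(t.name for t in tracks), values=values
    )


def subtract_tracks(base: AnnotationTrack, exclusions: list[AnnotationTrack],
                    name: str | None = None) -> AnnotationTrack:
    """Base minus the union of exclusion tracks (normalized interval algebra).

    Used to derive a negative-control track: e.g. intergenic regions with
    every genic, regulatory and evolutionary annotation carved out.
    """
    if name is None:
        name = f"{base.name}_minus_" + "+".join(t.name for t in exclusions) if exclusions else base.name
    union = AnnotationTrack("_union", [iv for t in exclusions for iv in t.intervals])
    excl = union.by_chrom()
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in base.intervals:
        cuts = excl.get(chrom)
        if cuts is None:
            out.append((chrom, s, e))
            continue
        cur = s
        for cs, ce in cuts:
            if ce <= cur or cs >= e:
                continue
            if cs > cur:
                out.append((chrom, cur, cs))
            cur = max(cur, ce)
            if cur >= e:
                break
        if cur < e:
            out.append((chrom, cur, e))
    return AnnotationTrack(name, out)
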