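"""Nucleosome map calling, occupancy tracks, linkers and map matching.

The unique map is produced by a greedy caller: repeatedly take the
highest-scoring NCP position at least ``min_spacing`` (default 120 bp)
from every previously selected dyad, then retain the top 90% of calls by
score.  The redundant map is every position whose NCP score is at least
the minimum score found in the unique map.  Occupancy is the redundant
map's scores smoothed with a Gaussian kernel (sigma 20 bp) normalized to
unit mass over its truncation window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import FragmentSet, GenomicInterval, ValidationError
from .ncp_scoring import NcpTrack

NUC_SIZE = 147

__all__ = [
    "NucleosomeMap",
    "OccupancyTrack",
    "LinkerSet",
    "call_unique_map",
    "build_redundant_map",
    "occupancy_track",
    "mnase_occupancy_track",
    "linker_lengths",
    "match_maps",
]


@dataclass
class NucleosomeMap:
    flavor: str  # "unique" or "redundant"
    positions: dict[str, np.ndarray]  # sorted per chromosome
    scores: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    @property
    def n(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def min_score(self) -> float:
        mins = [s.min() for s in self.scores.values() if len(s)]
        if not mins:
            raise ValidationError("empty nucleosome map")
        return float(min(mins))

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.positions:
                for p, s in zip(self.positions[c], self.scores[c]):
                    fh.write(f"{c}\t{p}\t{p + 1}\t{self.flavor}\t{s:.6g}\t+\n")


@dataclass
class OccupancyTrack:
    values: dict[str, np.ndarray]
    sigma: float = 20.0
    halfwidth: int = 73

    @property
    def chroms(self) -> list[str]:
        return list(self.values)


@dataclass
class LinkerSet:
    """Linker lengths (center-to-center spacing minus 147 bp), with group
    labels; negative linkers from closely spaced calls are kept as-is."""

    lengths: np.ndarray
    chroms: np.ndarray
    midpoints: np.ndarray
    groups: dict[str, np.ndarray] = field(default_factory=dict)  # name -> bool

    def in_group(self, name: str) -> np.ndarray:
        return self.lengths[self.groups[name]]


def _gaussian_kernel(sigma: float, halfwidth: int) -> np.ndarray:
    d = np.arange(-halfwidth, halfwidth + 1)
    k = np.exp(-d.astype(float) ** 2 / (2 * sigma ** 2))
    return k / k.sum()


def call_unique_map(ncp: NcpTrack, min_spacing: int = 120,
                    keep_frac: float = 0.90) -> NucleosomeMap:
    """Greedy unique-map caller with top-``keep_frac`` retention.

    Ties at equal NCP score go to the leftmost position; retention keeps
    the floor(keep_frac * n) highest-scoring calls, ties at the boundary
    again breaking leftmost-first.
    """
    if min_spacing < 1:
        raise ValidationError("min_spacing must be >= 1")
    if not (0 < keep_frac <= 1):
        raise ValidationError("keep_frac must be in (0, 1]")
    calls: list[tuple[float, str, int]] = []
    for chrom in ncp.chroms:
        s = ncp.scores[chrom]
        cand = np.flatnonzero((s > 0) & ncp.mask[chrom])
        if cand.size == 0:
            continue
        order = cand[np.lexsort((cand, -s[cand]))]
        blocked = np.zeros(len(s), dtype=bool)
        for p in order:
            if blocked[p]:
                continue
            calls.append((float(s[p]), chrom, int(p)))
            blocked[max(0, p - (min_spacing - 1)): p + min_spacing] = True
    if not calls:
        warnings.warn("all-zero NCP track; unique map is empty")
        return NucleosomeMap("unique", {c: np.empty(0, np.int64) for c in ncp.chroms},
                             {c: np.empty(0) for c in ncp.chroms},
                             {"min_spacing": min_spacing, "keep_frac": keep_frac})
    n_keep = int(np.floor(keep_frac * len(calls)))
    calls.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept = calls[:n_keep]
    positions = {c: [] for c in ncp.chroms}
    scores = {c: [] for c in ncp.chroms}
    for s, chrom, p in kept:
        positions[chrom].append(p)
        scores[chrom].append(s)
    pos_arr, sc_arr = {}, {}
    for c in ncp.chroms:
        order = np.argsort(positions[c])
        pos_arr[c] = np.asarray(positions[c], dtype=np.int64)[order]
        sc_arr[c] = np.asarray(scores[c], dtype=float)[order]
    return NucleosomeMap("unique", pos_arr, sc_arr,
                         {"min_spacing": min_spacing, "keep_frac": keep_frac})


def build_redundant_map(ncp: NcpTrack, unique: NucleosomeMap) -> NucleosomeMap:
    """All positions with NCP >= the minimum unique-map score (a superset
    of the unique map)."""
    if unique.n == 0:
        raise ValidationError("unique map is empty")
    threshold = unique.min_score()
    positions, scores = {}, {}
    for chrom in ncp.chroms:
        s = ncp.scores[chrom]
        sel = np.flatnonzero((s >= threshold) & ncp.mask[chrom])
        positions[chrom] = sel.astype(np.int64)
        scores[chrom] = s[sel]
    return NucleosomeMap("redundant", positions, scores,
                         {"threshold": threshold,
                          "source": unique.provenance})


def occupancy_track(redundant: NucleosomeMap,
                    lengths: dict[str, int],
                    sigma: float = 20.0, halfwidth: int = 73
                    ) -> OccupancyTrack:
    """Center-weighted occupancy: redundant NCP scores convolved with a
    unit-mass truncated Gaussian kernel."""
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    kernel = _gaussian_kernel(sigma, halfwidth)
    values = {}
    for chrom, L in lengths.items():
        arr = np.zeros(L)
        pos = redundant.positions.get(chrom)
        if pos is not None and len(pos):
            arr[pos] = redundant.scores[chrom]
        values[chrom] = np.convolve(arr, kernel, mode="same")
    return OccupancyTrack(values, sigma, halfwidth)


def mnase_occupancy_track(fragments: FragmentSet, lengths: dict[str, int],
                          sigma: float = 20.0, halfwidth: int = 73
                          ) -> OccupancyTrack:
    """MNase analogue of the occupancy track: fragment-midpoint counts
    (midpoint = start + floor((len-1)/2)) smoothed with the same kernel."""
    if fragments.n == 0:
        raise ValidationError("no fragments")
    kernel = _gaussian_kernel(sigma, halfwidth)
    values = {}
    for chrom, L in lengths.items():
        arr = np.zeros(L)
        s = fragments.starts.get(chrom)
        if s is not None and len(s):
            e = fragments.ends[chrom]
            mids = s + (e - s - 1) // 2
            mids = mids[(mids >= 0) & (mids < L)]
            arr = np.bincount(mids, minlength=L).astype(float)
        values[chrom] = np.convolve(arr, kernel, mode="same")
    return OccupancyTrack(values, sigma, halfwidth)


def linker_lengths(nmap: NucleosomeMap,
                   groupings: dict[str, list[GenomicInterval]] | None = None,
                   anchor_windows: dict[str, tuple[list, int]] | None = None
                   ) -> LinkerSet:
    """Adjacent-dyad linkers (spacing - 147 bp) from a unique map.

    Each linker is assigned to a group when its midpoint falls inside any
    of the group's intervals, or within +/-flank of any of the group's
    anchors (``anchor_windows`` maps name -> (anchors, flank)).
    """
    if nmap.flavor != "unique":
        raise ValidationError("linkers are defined on unique maps")
    lengths, chroms, mids = [], [], []
    for chrom in nmap.chroms:
        pos = nmap.positions[chrom]
        if len(pos) < 2:
            continue
        d = np.diff(pos)
        lengths.append(d - NUC_SIZE)
        chroms.append(np.full(len(d), chrom, dtype=object))
        mids.append((pos[:-1] + pos[1:]) // 2)
    if not lengths:
        return LinkerSet(np.empty(0, np.int64), np.empty(0, object),
                         np.empty(0, np.int64))
    lengths = np.concatenate(lengths)
    chroms = np.concatenate(chroms)
    mids = np.concatenate(mids)
    groups: dict[str, np.ndarray] = {}
    if groupings:
        for name, ivs in groupings.items():
            sel = np.zeros(len(lengths), dtype=bool)
            for iv in ivs:
                sel |= (chroms == iv.chrom) & (mids >= iv.start) & (mids < iv.end)
            groups[name] = sel
    if anchor_windows:
        for name, (anchors, flank) in anchor_windows.items():
            sel = np.zeros(len(lengths), dtype=bool)
            for a in anchors:
                chrom, pos = (a.chrom, a.pos) if hasattr(a, "pos") else a
                sel |= ((chroms == chrom) & (mids >= pos - flank)
                        & (mids <= pos + flank))
            groups[name] = sel
    return LinkerSet(lengths, chroms, mids, groups)


def match_maps(map_a: NucleosomeMap, map_b: NucleosomeMap, max_dist: int = 73):
    """Mutual-nearest-neighbour dyad matching within ``max_dist`` bp.

    Returns (pairs, distances, fraction_identical) where distance =
    posB - posA and fraction identical = (#distance 0) / min(|A|, |B|).
    """
    for m in (map_a, map_b):
        if m.flavor != "unique":
            raise ValidationError("matching is defined on unique maps")
        if m.n == 0:
            raise ValidationError("empty map")
    pairs = []
    distances = []
    for chrom in map_a.chroms:
        a = map_a.positions.get(chrom)
        b = map_b.positions.get(chrom)
        if a is None or b is None or len(a) == 0 or len(b) == 0:
            continue
        # nearest b for each a
        ib = np.searchsorted(b, a)
        left = np.clip(ib - 1, 0, len(b) - 1)
        right = np.clip(ib, 0, len(b) - 1)
        nb = np.where(np.abs(b[right] - a) < np.abs(a - b[left]), right, left)
        ia = np.searchsorted(a, b)
        lefta = np.clip(ia - 1, 0, len(a) - 1)
        righta = np.clip(ia, 0, len(a) - 1)
        na = np.where(np.abs(a[righta] - b) < np.abs(b - a[lefta]),
                      righta, lefta)
        for i in range(len(a)):
            j = nb[i]
            if na[j] == i and abs(int(b[j]) - int(a[i])) <= max_dist:
                pairs.append((chrom, int(a[i]), int(b[j])))
                distances.append(int(b[j]) - int(a[i]))
    distances = np.asarray(distances, dtype=np.int64)
    denom = min(map_a.n, map_b.n)
    frac_identical = float((distances == 0).sum()) / denom if denom else 0.0
    return pairs, distances, frac_identical
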