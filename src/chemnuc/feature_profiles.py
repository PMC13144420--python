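"""Anchor-centered profile aggregation and site-level analyses.

Covers metagene-style aggregation of any dense signal around point
anchors (TSS, enhancer centers, CTCF motif centers, exon boundaries),
expression stratification, K-means clustering of per-site profiles,
unique-nucleosome count differences between conditions, dinucleotide
periodicity around dyads, spectral periodicity detection, and refinement
of peak centers by position-weight-matrix scanning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend

from .io_formats import (
    GenomeSequence,
    GenomicInterval,
    PointAnchor,
    ValidationError,
)

__all__ = [
    "ProfileMatrix",
    "PositionWeightMatrix",
    "anchor_profile",
    "stratify_by_expression",
    "kmeans_profiles",
    "unique_count_difference",
    "dinucleotide_profile",
    "detect_periodicity",
    "refine_motif_centers",
]


@dataclass
class ProfileMatrix:
    """Per-site signal in relative coordinates -flank..+flank.

    Minus-strand rows are reversed when built strand-aware, so column j
    always means "j bp downstream in reading direction".
    """

    matrix: np.ndarray          # n_sites x (2*flank+1)
    valid: np.ndarray           # same shape, bool
    flank: int
    anchors: list = field(default_factory=list)
    n_dropped: int = 0          # anchors with out-of-genome windows
    row_meta: dict = field(default_factory=dict)

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def mean_profile(self) -> np.ndarray:
        out = np.full(self.matrix.shape[1], np.nan)
        counts = self.valid.sum(axis=0)
        ok = counts > 0
        vals = np.where(self.valid, self.matrix, 0.0)
        out[ok] = vals.sum(axis=0)[ok] / counts[ok]
        return out


def anchor_profile(values: dict[str, np.ndarray], anchors: list[PointAnchor],
                   flank: int, strand_aware: bool = True,
                   mask: dict[str, np.ndarray] | None = None) -> ProfileMatrix:
    """Extract per-anchor signal vectors and their mean profile.

    Anchors whose window leaves the genome are dropped (counted in
    ``n_dropped``); masked positions are excluded from the mean per column.
    """
    if not anchors:
        raise ValidationError("no anchors given")
    width = 2 * flank + 1
    rows, valids, kept = [], [], []
    for a in anchors:
        if a.chrom not in values:
            continue
        arr = values[a.chrom]
        lo, hi = a.pos - flank, a.pos + flank + 1
        if lo < 0 or hi > len(arr):
            continue
        row = arr[lo:hi].astype(float)
        v = (mask[a.chrom][lo:hi].copy() if mask is not None
             else np.ones(width, dtype=bool))
        if strand_aware and a.strand == "-":
            row = row[::-1]
            v = v[::-1]
        rows.append(row)
        valids.append(v)
        kept.append(a)
    if not rows:
        raise ValidationError("all anchors out of range")
    return ProfileMatrix(np.vstack(rows), np.vstack(valids), flank,
                         kept, len(anchors) - len(rows))


def stratify_by_expression(anchors: list[PointAnchor],
                           fpkm: dict[str, float],
                           scheme: str = "quartiles"):
    """Expression groups: "no_expression" for FPKM 0, else quartiles of the
    expressed (FPKM > 0) genes; boundary ties go to the lower group.

    Anchor labels are used as gene ids; anchors without an FPKM entry are
    excluded and counted.  Returns (labels, n_missing, group_sizes).
    """
    if scheme != "quartiles":
        raise ValidationError(f"unknown scheme {scheme!r}")
    values, keep = [], []
    n_missing = 0
    for a in anchors:
        if a.label not in fpkm:
            n_missing += 1
            keep.append(False)
            continue
        keep.append(True)
        values.append(fpkm[a.label])
    values = np.asarray(values)
    expressed = values[values > 0]
    if expressed.size == 0:
        raise ValidationError("no expressed genes; quartiles undefined")
    q = np.quantile(expressed, [0.25, 0.5, 0.75])
    names = ["Q1", "Q2", "Q3", "Q4"]
    labels = []
    i = 0
    for k in keep:
        if not k:
            labels.append(None)
            continue
        v = values[i]
        i += 1
        if v == 0:
            labels.append("no_expression")
        else:
            labels.append(names[int(np.searchsorted(q, v, side="left"))])
    sizes = {g: sum(1 for x in labels if x == g)
             for g in ["no_expression"] + names}
    return labels, n_missing, sizes


def kmeans_profiles(profile: ProfileMatrix, k: int,
                    window: tuple[int, int] | None = None,
                    seed: int = 0, normalize: bool = False):
    """K-means clustering of per-site profiles (k-means++, fixed seed).

    ``window`` restricts the features to relative offsets [lo, hi]
    (e.g. (-150, 250) for TSS profiles).  Rows with any invalid value in
    the window are dropped and counted.  Centroids are returned in
    decreasing cluster-size order; labels use the reordered ids (-1 for
    dropped rows).  Rows are not z-normalized unless ``normalize``.
    """
    from sklearn.cluster import KMeans

    offs = profile.offsets
    if window is not None:
        sel = (offs >= window[0]) & (offs <= window[1])
    else:
        sel = np.ones(len(offs), dtype=bool)
    X = profile.matrix[:, sel]
    ok = profile.valid[:, sel].all(axis=1)
    Xok = X[ok]
    if Xok.shape[0] < k:
        raise ValidationError(f"only {Xok.shape[0]} usable rows for k={k}")
    if normalize:
        mu = Xok.mean(axis=1, keepdims=True)
        sd = Xok.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Xok = (Xok - mu) / sd
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                random_state=seed)
    raw = km.fit_predict(Xok)
    sizes = np.bincount(raw, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = np.full(profile.matrix.shape[0], -1, dtype=int)
    labels[ok] = remap[raw]
    centroids = km.cluster_centers_[order]
    return labels, centroids, int((~ok).sum())


def unique_count_difference(map_a, map_b, anchors: list[PointAnchor],
                            flank: int = 1000):
    """Per-anchor difference in unique-dyad counts within [pos-flank,
    pos+flank] (closed on both ends): count_A - count_B.

    Returns (deltas, histogram dict, mean).
    """
    deltas = []
    for a in anchors:
        lo, hi = a.pos - flank, a.pos + flank
        ca = cb = 0
        pa = map_a.positions.get(a.chrom)
        pb = map_b.positions.get(a.chrom)
        if pa is not None:
            ca = int(np.searchsorted(pa, hi, side="right")
                     - np.searchsorted(pa, lo, side="left"))
        if pb is not None:
            cb = int(np.searchsorted(pb, hi, side="right")
                     - np.searchsorted(pb, lo, side="left"))
        deltas.append(ca - cb)
    deltas = np.asarray(deltas, dtype=np.int64)
    values, counts = (np.unique(deltas, return_counts=True)
                      if len(deltas) else (np.array([]), np.array([])))
    hist = {int(v): int(c) for v, c in zip(values, counts)}
    mean = float(deltas.mean()) if len(deltas) else np.nan
    return deltas, hist, mean


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def dinucleotide_profile(genome: GenomeSequence,
                         dyads: dict[str, np.ndarray], flank: int,
                         dinucs: set[str] = frozenset({"AA", "TT", "AT", "TA"})
                         ) -> np.ndarray:
    """Fraction of dyads whose reference-strand dinucleotide starting at
    dyad+j is in the set, for j in [-flank, flank-1]."""
    target = np.zeros(16, dtype=bool)
    for dn in dinucs:
        target[4 * _CODE[ord(dn[0])] + _CODE[ord(dn[1])]] = True
    offsets = np.arange(-flank, flank)
    num = np.zeros(len(offsets))
    den = 0
    for chrom, pos in dyads.items():
        seq = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        codes = _CODE[seq]
        n = len(codes)
        valid_dinuc = np.zeros(n, dtype=bool)
        okpos = (codes[:-1] < 4) & (codes[1:] < 4)
        ids = np.where(okpos, 4 * codes[:-1] + codes[1:], 0)
        valid_dinuc[:-1] = okpos & target[ids]
        pos = np.asarray(pos)
        pos = pos[(pos - flank >= 0) & (pos + flank < n)]
        if len(pos) == 0:
            continue
        den += len(pos)
        for j, off in enumerate(offsets):
            num[j] += valid_dinuc[pos + off].sum()
    if den == 0:
        raise ValidationError("no dyads with a full in-range flank")
    return num / den


def detect_periodicity(series: np.ndarray, period_range=(5.0, 25.0),
                       x: np.ndarray | None = None, pad_to: int = 4096,
                       ratio_threshold: float = 4.0):
    """Dominant period/phase of a (roughly evenly sampled) profile.

    The series is linearly detrended and Fourier-analysed on a zero-padded
    grid; the dominant period is the power argmax within ``period_range``,
    the phase comes from the complex coefficient (for a profile peaked at
    x = phase mod period), and the power ratio is peak power over the
    median power across frequencies.  ``significant`` is False for
    near-flat series (ratio below ``ratio_threshold``).

    Returns dict with period, phase, power_ratio, significant.
    """
    y = np.asarray(series, dtype=float)
    if x is None:
        x = np.arange(len(y))
    x = np.asarray(x, dtype=float)
    if len(y) < 3 * period_range[0]:
        raise ValidationError("series too short for the candidate periods")
    raw_scale = max(float(np.abs(y).max()) ** 2 * len(y), 1e-300)
    y = detrend(y, type="linear")
    n = max(pad_to, len(y))
    spec = np.fft.rfft(y, n=n)
    freqs = np.fft.rfftfreq(n, d=1.0)
    power = np.abs(spec) ** 2
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / freqs, np.inf)
    in_range = (periods >= period_range[0]) & (periods <= period_range[1])
    if not in_range.any():
        raise ValidationError("period range outside the resolvable band")
    j = np.flatnonzero(in_range)[np.argmax(power[in_range])]
    period = float(periods[j])
    # coefficient phase, shifted to the x origin of the series
    coeff = np.sum(y * np.exp(-2j * np.pi * (x - x[0]) / period))
    phase = float((-np.angle(coeff) * period / (2 * np.pi) + x[0]) % period)
    baseline = np.median(power[freqs > 0])
    if power[j] / raw_scale < 1e-12 or baseline <= 0:
        ratio = 1.0  # numerically flat series: no detectable periodicity
    else:
        ratio = float(power[j] / baseline)
    return {"period": period, "phase": phase, "power_ratio": ratio,
            "significant": bool(ratio >= ratio_threshold)}


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}  # A<->T, C<->G


@dataclass
class PositionWeightMatrix:
    """4xL log2-odds matrix over rows A, C, G, T."""

    log_odds: np.ndarray
    background: np.ndarray
    name: str = "motif"

    def __post_init__(self):
        if self.log_odds.ndim != 2 or self.log_odds.shape[0] != 4 \
                or self.log_odds.shape[1] < 1:
            raise ValidationError("PWM must be 4 x L with L >= 1")
        if not np.isfinite(self.log_odds).all():
            raise ValidationError("PWM entries must be finite")

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @classmethod
    def from_pfm(cls, counts: np.ndarray, pseudocount: float = 0.8,
                 background: np.ndarray | None = None, name: str = "motif"):
        """Counts -> log2 odds with a pseudocount split by background."""
        counts = np.asarray(counts, dtype=float)
        bg = (np.full(4, 0.25) if background is None
              else np.asarray(background, dtype=float))
        adj = counts + pseudocount * bg[:, None]
        probs = adj / adj.sum(axis=0, keepdims=True)
        return cls(np.log2(probs / bg[:, None]), bg, name)

    def reverse_complement(self) -> np.ndarray:
        rc = np.empty_like(self.log_odds)
        for b, comp in _COMPLEMENT.items():
            rc[comp] = self.log_odds[b][::-1]
        return rc


def refine_motif_centers(peaks: list[GenomicInterval], genome: GenomeSequence,
                         pwm: PositionWeightMatrix) -> list[PointAnchor]:
    """Best PWM hit per peak window on either strand; the refined center is
    start + floor(L/2) of the winning placement.

    Ties resolve to the leftmost start, + strand first.  Peaks narrower
    than the motif are skipped with a warning.
    """
    L = pwm.length
    fwd = pwm.log_odds
    rev = pwm.reverse_complement()
    out = []
    skipped = 0
    for peak in peaks:
        seq = genome.fetch(peak.chrom, peak.start, peak.end)
        codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        n = len(codes)
        if n < L:
            skipped += 1
            continue
        n_pos = n - L + 1
        idx = np.arange(L)
        windows = codes[np.arange(n_pos)[:, None] + idx]
        ok = (windows < 4).all(axis=1)
        safe = np.where(windows < 4, windows, 0)
        score_f = fwd[safe, idx].sum(axis=1)
        score_r = rev[safe, idx].sum(axis=1)
        score_f[~ok] = -np.inf
        score_r[~ok] = -np.inf
        top = max(score_f.max(), score_r.max())
        if not np.isfinite(top):
            skipped += 1
            continue
        # ties (within float tolerance) resolve leftmost, + strand first
        tol = 1e-9 * max(1.0, abs(top))
        best_start, best_strand = None, "+"
        for start in range(n_pos):
            if score_f[start] >= top - tol:
                best_start, best_strand = start, "+"
                break
            if score_r[start] >= top - tol:
                best_start, best_strand = start, "-"
                break
        center = peak.start + best_start + L // 2
        out.append(PointAnchor(peak.chrom, center, best_strand, peak.name))
    if skipped:
        warnings.warn(f"{skipped} peaks narrower than the motif (or all-N) "
                      "were skipped")
    return out
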