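"""Genome-wide comparison of two occupancy tracks.

Sliding-window local Pearson correlation (501 bp, 1-bp step), ECDF
summaries, 1-kb bin classification at a 0.15 threshold, region-of-interest
enrichment as odds ratios with chi-square tests, and Wald tests on
differences of short-linker log odds ratios between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval, ValidationError
from .nucleosome_maps import LinkerSet, OccupancyTrack

__all__ = [
    "CorrelationTrack",
    "TwoByTwoResult",
    "local_correlation",
    "Ecdf",
    "ecdf",
    "bin_and_classify",
    "roi_enrichment",
    "short_linker_wald",
    "two_by_two",
]


@dataclass
class CorrelationTrack:
    r: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]
    window: int

    @property
    def chroms(self) -> list[str]:
        return list(self.r)

    def values(self) -> np.ndarray:
        """All valid correlation values, concatenated."""
        return np.concatenate([self.r[c][self.valid[c]] for c in self.chroms])


@dataclass
class TwoByTwoResult:
    a: float  # low & ROI   (or short & condition A)
    b: float  # high & ROI  (or long & condition A)
    c: float  # low & BG    (or short & condition B)
    d: float  # high & BG   (or long & condition B)
    odds_ratio: float
    log_or: float       # natural log
    log2_or: float
    se_log_or: float
    chi2: float
    p_chi2: float
    corrected: bool = False  # Haldane-Anscombe +0.5 applied
    flagged: bool = False    # degenerate table

    @classmethod
    def from_counts(cls, a, b, c, d, correction: str = "haldane"):
        raw = np.array([a, b, c, d], dtype=float)
        flagged = False
        corrected = False
        cells = raw.copy()
        if (cells == 0).any():
            if correction == "haldane":
                cells = cells + 0.5
                corrected = True
            flagged = True
        aa, bb, cc, dd = cells
        if bb == 0 or cc == 0 or dd == 0 or aa == 0:
            orr = np.nan
            flagged = True
        else:
            orr = (aa / bb) / (cc / dd)
        log_or = float(np.log(orr)) if np.isfinite(orr) and orr > 0 else np.nan
        se = float(np.sqrt((1 / cells).sum())) if (cells > 0).all() else np.nan
        chi2, p = _chi2_2x2(*raw)
        return cls(float(a), float(b), float(c), float(d),
                   float(orr), log_or,
                   log_or / np.log(2) if np.isfinite(log_or) else np.nan,
                   se, chi2, p, corrected, flagged)


def _chi2_2x2(a, b, c, d):
    """Uncorrected chi-square (df=1): N(ad-bc)^2 / product of margins."""
    n = a + b + c + d
    m = (a + b) * (c + d) * (a + c) * (b + d)
    if m == 0 or n == 0:
        return np.nan, np.nan
    chi2 = n * (a * d - b * c) ** 2 / m
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Local correlation
# ---------------------------------------------------------------------------

def _sliding_pearson(x: np.ndarray, y: np.ndarray, window: int):
    """Centered sliding-window Pearson r via cumulative sums."""
    n = len(x)
    half = window // 2
    r = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    if n < window:
        return r, valid

    def winsum(a):
        cs = np.concatenate(([0.0], np.cumsum(a)))
        return cs[window:] - cs[:-window]  # sum over each full window

    sx, sy = winsum(x), winsum(y)
    sxx, syy = winsum(x * x), winsum(y * y)
    sxy = winsum(x * y)
    w = float(window)
    varx = sxx - sx * sx / w
    vary = syy - sy * sy / w
    cov = sxy - sx * sy / w
    denom = varx * vary
    centers = np.arange(half, n - half)
    tol = 1e-12 * np.maximum(1.0, np.maximum(sxx, syy))
    ok = (varx > tol) & (vary > tol)
    rw = np.full(len(sx), np.nan)
    rw[ok] = cov[ok] / np.sqrt(denom[ok])
    r[centers] = np.clip(rw, -1.0, 1.0)
    valid[centers] = ok
    return r, valid


def local_correlation(occ_a: OccupancyTrack, occ_b: OccupancyTrack,
                      window: int = 501, step: int = 1) -> CorrelationTrack:
    """Sliding-window Pearson correlation of two occupancy tracks.

    Positions whose window is edge-truncated, or where either window has
    (numerically) zero variance, are invalid.
    """
    if set(occ_a.chroms) != set(occ_b.chroms):
        raise ValidationError("occupancy tracks cover different chromosomes")
    rs, valids = {}, {}
    for chrom in occ_a.chroms:
        x, y = occ_a.values[chrom], occ_b.values[chrom]
        if len(x) != len(y):
            raise ValidationError(f"length mismatch on {chrom}")
        r, valid = _sliding_pearson(x, y, window)
        if step > 1:
            keep = np.zeros(len(r), dtype=bool)
            keep[::step] = True
            valid = valid & keep
        rs[chrom], valids[chrom] = r, valid
    return CorrelationTrack(rs, valids, window)


# ---------------------------------------------------------------------------
# ECDF
# ---------------------------------------------------------------------------

class Ecdf:
    """Right-continuous empirical distribution function."""

    def __init__(self, values):
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValidationError("ECDF needs at least one finite value")
        self.sorted = np.sort(v)
        self.n = v.size

    def __call__(self, x) -> float:
        return float(np.searchsorted(self.sorted, x, side="right") / self.n)

    def fraction_ge(self, x) -> float:
        """Fraction of values >= x, i.e. 1 - F(x-)."""
        return float(1 - np.searchsorted(self.sorted, x, side="left") / self.n)

    def quantile(self, q) -> float:
        return float(np.quantile(self.sorted, q))


def ecdf(values) -> Ecdf:
    return Ecdf(values)


# ---------------------------------------------------------------------------
# Binning and enrichment
# ---------------------------------------------------------------------------

def bin_and_classify(occ_a: OccupancyTrack, occ_b: OccupancyTrack,
                     bin_size: int = 1000, threshold: float = 0.15
                     ) -> pd.DataFrame:
    """Per-bin Pearson correlation and low/high classification.

    Bins tile each chromosome (only full bins are scored); a bin is valid
    iff both tracks have nonzero variance within it.  ``low`` is r <=
    threshold.  Columns: chrom, start, end, r, valid, low.
    """
    if bin_size < 2:
        raise ValidationError("bin_size must be >= 2")
    rows = []
    for chrom in occ_a.chroms:
        x, y = occ_a.values[chrom], occ_b.values[chrom]
        n_bins = len(x) // bin_size
        if n_bins == 0:
            continue
        xb = x[: n_bins * bin_size].reshape(n_bins, bin_size)
        yb = y[: n_bins * bin_size].reshape(n_bins, bin_size)
        xm = xb - xb.mean(axis=1, keepdims=True)
        ym = yb - yb.mean(axis=1, keepdims=True)
        vx = (xm * xm).sum(axis=1)
        vy = (ym * ym).sum(axis=1)
        cov = (xm * ym).sum(axis=1)
        tol_x = 1e-12 * np.maximum(1.0, (xb * xb).sum(axis=1))
        tol_y = 1e-12 * np.maximum(1.0, (yb * yb).sum(axis=1))
        valid = (vx > tol_x) & (vy > tol_y)
        r = np.full(n_bins, np.nan)
        r[valid] = np.clip(cov[valid] / np.sqrt(vx[valid] * vy[valid]), -1, 1)
        starts = np.arange(n_bins) * bin_size
        for i in range(n_bins):
            rows.append((chrom, int(starts[i]), int(starts[i] + bin_size),
                         float(r[i]), bool(valid[i]),
                         bool(valid[i] and r[i] <= threshold)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "r",
                                     "valid", "low"])
    df.attrs["bin_size"] = bin_size
    df.attrs["threshold"] = threshold
    return df


def annotate_roi(bins: pd.DataFrame, roi: list[GenomicInterval],
                 majority_bp: int = 500) -> np.ndarray:
    """True for bins whose overlap with the ROI annotation is >= majority_bp."""
    overlap = np.zeros(len(bins), dtype=np.int64)
    by_chrom = {}
    for iv in roi:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for i, (chrom, start, end) in enumerate(
            zip(bins["chrom"], bins["start"], bins["end"])):
        for s, e in by_chrom.get(chrom, ()):
            overlap[i] += max(0, min(end, e) - max(start, s))
    return overlap >= majority_bp


def roi_enrichment(bins: pd.DataFrame, roi: list[GenomicInterval],
                   majority_bp: int = 500) -> TwoByTwoResult:
    """Low-correlation enrichment of an ROI annotation.

    a = low & ROI, b = high & ROI, c = low & background, d = high &
    background, over valid bins only; OR = (a/b)/(c/d) with chi-square
    (df=1, uncorrected) p-value.
    """
    is_roi = annotate_roi(bins, roi, majority_bp)
    valid = bins["valid"].to_numpy()
    low = bins["low"].to_numpy()
    a = int((valid & low & is_roi).sum())
    b = int((valid & ~low & is_roi).sum())
    c = int((valid & low & ~is_roi).sum())
    d = int((valid & ~low & ~is_roi).sum())
    return TwoByTwoResult.from_counts(a, b, c, d)


# ---------------------------------------------------------------------------
# Short-linker Wald tests
# ---------------------------------------------------------------------------

def two_by_two(short_a: int, long_a: int, short_b: int, long_b: int
               ) -> TwoByTwoResult:
    """Odds of short linkers in condition A relative to condition B."""
    return TwoByTwoResult.from_counts(short_a, long_a, short_b, long_b)


def short_linker_wald(linkers_a: LinkerSet, linkers_b: LinkerSet,
                      cutoff: int = 30,
                      groups: list[str] | None = None,
                      pairs: list[tuple[str, str]] | None = None):
    """Per-group short-linker (< cutoff) odds ratios A vs B, plus pairwise
    Wald comparisons of the log odds ratios.

    For groups g1 and g2: z = (logOR1 - logOR2)/sqrt(SE1^2 + SE2^2) with
    one-sided p = 1 - Phi(z) (testing logOR1 > logOR2).  Returns
    (results, comparisons) as dict and DataFrame.
    """
    if groups is None:
        groups = sorted(set(linkers_a.groups) & set(linkers_b.groups)) or ["all"]
    results: dict[str, TwoByTwoResult] = {}
    for g in groups:
        la = linkers_a.in_group(g) if g in linkers_a.groups else linkers_a.lengths
        lb = linkers_b.in_group(g) if g in linkers_b.groups else linkers_b.lengths
        if len(la) == 0 or len(lb) == 0:
            raise ValidationError(f"group {g!r} has no linkers in one condition")
        results[g] = two_by_two(int((la < cutoff).sum()),
                                int((la >= cutoff).sum()),
                                int((lb < cutoff).sum()),
                                int((lb >= cutoff).sum()))
    rows = []
    if pairs is None:
        pairs = [(g1, g2) for i, g1 in enumerate(groups)
                 for g2 in groups[i + 1:]]
    for g1, g2 in pairs:
        r1, r2 = results[g1], results[g2]
        se = np.sqrt(r1.se_log_or ** 2 + r2.se_log_or ** 2)
        z = (r1.log_or - r2.log_or) / se if se > 0 else np.nan
        rows.append((g1, g2, r1.log_or, r2.log_or, float(z),
                     float(stats.norm.sf(z)),
                     float(2 * stats.norm.sf(abs(z)))))
    comparisons = pd.DataFrame(
        rows, columns=["group1", "group2", "log_or1", "log_or2",
                       "z", "p_one_sided", "p_two_sided"])
    return results, comparisons


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (available as an option; not applied by default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues), method="fdr_bh")[1]
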