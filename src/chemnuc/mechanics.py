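"""DNA cyclizability (C-score) aggregation around nucleosome dyads.

A C-score is an externally supplied per-position bendability value (the
prediction for a 50-bp window centered on that position).  This module
averages C-scores within a flank of unique dyads, contrasts the dyad
window (|offset| <= 20 bp) with the shoulder band (42 <= |offset| <= 73
bp, near the DNA entry/exit of the wrap), and stratifies dyads by
Giemsa-band classes or arbitrary labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import DenseTrack, GenomicInterval, ValidationError
from .nucleosome_maps import NucleosomeMap

__all__ = [
    "DyadMechanicsSummary",
    "dyad_cscore_profile",
    "shoulder_dyad_statistic",
    "gband_stratify",
    "gene_density_per_band",
]

DYAD_HALFWIDTH = 20
SHOULDER_BAND = (42, 73)


@dataclass
class DyadMechanicsSummary:
    offsets: np.ndarray                       # -flank..+flank
    profiles: dict[str, np.ndarray]           # stratum -> mean per offset
    counts: dict[str, np.ndarray]             # stratum -> denominators
    n_dyads: dict[str, int] = field(default_factory=dict)

    def stratum_stat(self, stratum: str,
                     dyad_halfwidth: int = DYAD_HALFWIDTH,
                     shoulder_band: tuple[int, int] = SHOULDER_BAND,
                     side: str = "both") -> dict[str, float]:
        prof = self.profiles[stratum]
        offs = self.offsets
        dyad_sel = np.abs(offs) <= dyad_halfwidth
        a, b = shoulder_band
        if side == "both":
            sh_sel = (np.abs(offs) >= a) & (np.abs(offs) <= b)
        elif side == "left":
            sh_sel = (offs <= -a) & (offs >= -b)
        elif side == "right":
            sh_sel = (offs >= a) & (offs <= b)
        else:
            raise ValidationError(f"unknown side {side!r}")
        dyad_mean = float(np.nanmean(prof[dyad_sel]))
        shoulder_mean = float(np.nanmean(prof[sh_sel]))
        return {
            "dyad_mean": dyad_mean,
            "shoulder_mean": shoulder_mean,
            "difference": shoulder_mean - dyad_mean,
            "ratio": shoulder_mean / dyad_mean if dyad_mean != 0 else np.nan,
        }

    def shoulder_peak_offsets(self, stratum: str,
                              shoulder_band=SHOULDER_BAND) -> tuple[int, int]:
        """Argmax offsets of the profile in the left and right shoulders."""
        prof = self.profiles[stratum]
        offs = self.offsets
        a, b = shoulder_band
        left = (offs <= -a) & (offs >= -b)
        right = (offs >= a) & (offs <= b)
        lo = int(offs[left][np.nanargmax(prof[left])])
        ro = int(offs[right][np.nanargmax(prof[right])])
        return lo, ro


def dyad_cscore_profile(cscore: DenseTrack, nmap: NucleosomeMap,
                        flank: int = 1000,
                        strata: dict[str, dict[str, np.ndarray]] | None = None
                        ) -> DyadMechanicsSummary:
    """Mean C-score at each dyad-relative offset, per stratum.

    ``strata`` maps a stratum name to a per-chromosome boolean selector
    over the map's dyads (None = single stratum "all").  Dyads with
    partially masked flanks contribute wherever data exist (per-offset
    denominators); offsets with no data are NaN.  Empty strata are
    omitted with a warning.
    """
    if strata is None:
        strata = {"all": {c: np.ones(len(nmap.positions[c]), dtype=bool)
                          for c in nmap.chroms}}
    offsets = np.arange(-flank, flank + 1)
    profiles, counts, n_dyads = {}, {}, {}
    for name, sel in strata.items():
        num = np.zeros(len(offsets))
        den = np.zeros(len(offsets))
        nd = 0
        for chrom in nmap.chroms:
            if chrom not in cscore.values or chrom not in sel:
                continue
            vals = cscore.values[chrom]
            mvals = cscore.mask[chrom]
            L = len(vals)
            dyads = nmap.positions[chrom][sel[chrom]]
            # keep dyads with any in-range offset; clip the window per dyad
            for d in dyads:
                lo = max(0, d - flank)
                hi = min(L, d + flank + 1)
                if hi <= lo:
                    continue
                nd += 1
                j0 = lo - (d - flank)
                j1 = j0 + (hi - lo)
                seg_m = mvals[lo:hi]
                num[j0:j1] += np.where(seg_m, vals[lo:hi], 0.0)
                den[j0:j1] += seg_m
        if nd == 0:
            warnings.warn(f"stratum {name!r} has no dyads; omitted")
            continue
        prof = np.full(len(offsets), np.nan)
        ok = den > 0
        prof[ok] = num[ok] / den[ok]
        profiles[name], counts[name], n_dyads[name] = prof, den, nd
    if not profiles:
        raise ValidationError("no stratum has any dyad with in-range flank")
    return DyadMechanicsSummary(offsets, profiles, counts, n_dyads)


def shoulder_dyad_statistic(summary: DyadMechanicsSummary,
                            side: str = "both") -> dict[str, dict[str, float]]:
    """Dyad-window vs shoulder-band means per stratum.

    Dyad window |d| <= 20 bp; shoulder band 42 <= |d| <= 73 bp pooled over
    both sides by default (``side`` = "left"/"right" for one side).
    """
    return {name: summary.stratum_stat(name, side=side)
            for name in summary.profiles}


def gband_stratify(nmap: NucleosomeMap, cytobands: list[GenomicInterval],
                   classes=("gneg", "gpos25", "gpos50", "gpos75", "gpos100"),
                   exclude=("acen", "gvar", "stalk")):
    """Assign each dyad the Giemsa stain class of its containing band.

    Cytoband intervals come from :func:`io_formats.load_intervals` with the
    cytoband dialect (name = "stain/band").  Dyads in excluded bands or
    outside all bands are unassigned and counted.  Returns
    (strata, labels, n_excluded, n_unassigned) where strata feeds
    :func:`dyad_cscore_profile`.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for iv in cytobands:
        stain = iv.name.split("/")[0]
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, stain))
    for rows in by_chrom.values():
        rows.sort()
    labels: dict[str, np.ndarray] = {}
    n_excluded = n_unassigned = 0
    for chrom in nmap.chroms:
        pos = nmap.positions[chrom]
        lab = np.full(len(pos), "", dtype="U10")
        rows = by_chrom.get(chrom, [])
        if rows:
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            stains = np.array([r[2] for r in rows], dtype="U10")
            idx = np.searchsorted(starts, pos, side="right") - 1
            inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
            lab[inside] = stains[idx[inside]]
        for i, s in enumerate(lab):
            if s == "":
                n_unassigned += 1
            elif s in exclude:
                n_excluded += 1
                lab[i] = ""
        labels[chrom] = lab
    strata = {cls: {c: labels[c] == cls for c in nmap.chroms}
              for cls in classes}
    return strata, labels, n_excluded, n_unassigned


def gene_density_per_band(tss_anchors, cytobands: list[GenomicInterval],
                          classes=("gneg", "gpos25", "gpos50", "gpos75",
                                   "gpos100")) -> dict[str, float]:
    """Genes per megabase for each stain class (TSS anchors as gene proxies)."""
    bp = {cls: 0 for cls in classes}
    genes = {cls: 0 for cls in classes}
    for iv in cytobands:
        stain = iv.name.split("/")[0]
        if stain in bp:
            bp[stain] += iv.length
    for a in tss_anchors:
        for iv in cytobands:
            if iv.chrom == a.chrom and iv.start <= a.pos < iv.end:
                stain = iv.name.split("/")[0]
                if stain in genes:
                    genes[stain] += 1
                break
    return {cls: (genes[cls] / (bp[cls] / 1e6) if bp[cls] else np.nan)
            for cls in classes}
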