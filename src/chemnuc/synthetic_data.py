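"""Synthetic chromatin landscapes with known ground truth.

Generates toy genomes, planted two-condition nucleosome landscapes
(stable arrays, regulatory repositioning, barrier loss with anti-phasing,
fragile nucleosomes), chemical-cleavage and MNase fragment files under the
strand-local -1/+6 cleavage-offset model, and cyclizability (C-score)
tracks with dyad- or shoulder-enriched bendability.

Every generator is a pure function of its parameters and seed.  Condition
"A" plays the role of the dynamic (interphase-like) state: extra dyads and
shortened linkers in regulatory regions, a nucleosome sitting on each
barrier anchor, and fragile nucleosomes flagged there; condition "B" is the
compact (metaphase-like) state that lacks them, with barrier-flanking
arrays shifted by half a spacing (anti-phased).

Cleavage geometry
-----------------
A nucleosome dyad at reference position D is cut on the Watson strand at
strand-local offsets -1 (primary) and +6 (secondary), i.e. reference
positions D-1 and D+6; on the Crick strand the same strand-local offsets
map to reference positions D+1 and D-6.  A fragment [s, e) records a
Watson cleavage at s and a Crick cleavage at e-1; its two ends are
anchored at adjacent dyads (chemical fragments span roughly one
nucleosome repeat).  Where a dyad has no usable neighbour on one side
(chromosome ends, or a gap too wide for the allowed fragment length) the
partner cut is placed at a fixed auxiliary anchor recorded in the truth
manifest, so that every planted dyad receives cuts on both strands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import (
    DenseTrack,
    FragmentSet,
    GenomeSequence,
    GenomicInterval,
    ValidationError,
)

NUC_SIZE = 147  # bp of DNA in one nucleosome wrap

__all__ = [
    "LinkerMixture",
    "LandscapeParams",
    "CleavageModel",
    "ConditionLandscape",
    "PlantedLandscape",
    "make_genome",
    "default_regions",
    "plant_landscape",
    "simulate_chemical_fragments",
    "simulate_mnase_fragments",
    "make_cscore_track",
    "export_annotations",
]


# ---------------------------------------------------------------------------
# Parameter blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkerMixture:
    """Linker lengths as a 10n+5 periodic component mixed with a smooth one.

    With probability ``weight`` the linker is 10*K + phase with K Poisson
    (periodic, 10n+5 by default); otherwise it is uniform on
    [smooth_lo, smooth_hi] (aperiodic).
    """

    weight: float = 0.7
    period: int = 10
    phase: int = 5
    poisson_mean: float = 3.0     # mean periodic linker = period*mean + phase
    poisson_max: int | None = None
    smooth_lo: int = 5
    smooth_hi: int = 65

    def mean(self) -> float:
        lam, cap = self.poisson_mean, self.poisson_max
        if cap is None:
            mean_k = lam
        else:
            ks = np.arange(cap + 1)
            from scipy.stats import poisson
            pmf = poisson.pmf(ks, lam)
            pmf[-1] += poisson.sf(cap, lam)
            mean_k = float((ks * pmf).sum())
        periodic = self.period * mean_k + self.phase
        smooth = (self.smooth_lo + self.smooth_hi) / 2
        return self.weight * periodic + (1 - self.weight) * smooth

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        periodic = rng.random(size) < self.weight
        k = rng.poisson(self.poisson_mean, size)
        if self.poisson_max is not None:
            k = np.minimum(k, self.poisson_max)
        per = self.period * k + self.phase
        smooth = rng.integers(self.smooth_lo, self.smooth_hi + 1, size)
        return np.where(periodic, per, smooth).astype(np.int64)

    def pmf(self, lengths: np.ndarray) -> np.ndarray:
        """Exact probability of each integer linker length under the mixture."""
        from scipy.stats import poisson

        lengths = np.asarray(lengths)
        p = np.zeros(lengths.shape, dtype=float)
        is_per = (lengths - self.phase) % self.period == 0
        k = (lengths - self.phase) // self.period
        ok = is_per & (k >= 0)
        pk = poisson.pmf(np.where(ok, k, 0), self.poisson_mean)
        if self.poisson_max is not None:
            pk = np.where(k == self.poisson_max,
                          pk + poisson.sf(self.poisson_max, self.poisson_mean), pk)
            pk = np.where(k > self.poisson_max, 0.0, pk)
        p += np.where(ok, self.weight * pk, 0.0)
        n_smooth = self.smooth_hi - self.smooth_lo + 1
        in_smooth = (lengths >= self.smooth_lo) & (lengths <= self.smooth_hi)
        p += np.where(in_smooth, (1 - self.weight) / n_smooth, 0.0)
        return p


# Regulatory (condition A) linkers: mostly short 10n+5 values (<=25 bp) with
# a minority of longer NDR-like gaps; mean ~26 bp versus ~35 bp for the
# stable mixture, which yields a mean unique-nucleosome gain of ~0.5 per
# +/-1 kb regulatory window.
SHORT_LINKER_MIXTURE = LinkerMixture(
    weight=0.8, poisson_mean=1.0, poisson_max=2, smooth_lo=35, smooth_hi=115
)


@dataclass(frozen=True)
class LandscapeParams:
    base_linkers: LinkerMixture = field(default_factory=LinkerMixture)
    regulatory_linkers: LinkerMixture = SHORT_LINKER_MIXTURE
    min_truth_spacing: int = NUC_SIZE
    weight_shape: float = 4.0          # gamma shape of per-dyad abundance
    weight_scale: float = 0.25
    fragile_fraction: float = 0.3      # of regulatory condition-A dyads
    region_margin: int = 80            # no dyads closer than this to a region edge


@dataclass(frozen=True)
class CleavageModel:
    """Strand-local cleavage offsets around the dyad."""

    primary_offset: int = -1
    secondary_offset: int = 6
    w_primary: float = 0.75
    jitter_sd: float = 0.5
    background_rate: float = 0.05

    def __post_init__(self):
        if not (0 < self.w_primary <= 1):
            raise ValidationError("w_primary must be in (0, 1]")
        if self.jitter_sd < 0 or not (0 <= self.background_rate < 1):
            raise ValidationError("invalid cleavage model parameters")

    @property
    def w_secondary(self) -> float:
        return 1.0 - self.w_primary


# ---------------------------------------------------------------------------
# Landscape containers
# ---------------------------------------------------------------------------

@dataclass
class ConditionLandscape:
    name: str
    dyads: dict[str, np.ndarray]          # sorted positions per chromosome
    weights: dict[str, np.ndarray]
    fragile: dict[str, np.ndarray]        # bool per dyad
    region_class: dict[str, np.ndarray]   # {stable, regulatory, barrier}

    def n_dyads(self) -> int:
        return sum(len(d) for d in self.dyads.values())

    def write_truth_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.dyads:
                for i, p in enumerate(self.dyads[c]):
                    flag = "fragile" if self.fragile[c][i] else "stable"
                    fh.write(f"{c}\t{p}\t{p + 1}\t"
                             f"{self.region_class[c][i]};{flag}\t"
                             f"{self.weights[c][i]:.4f}\t+\n")


@dataclass
class PlantedLandscape:
    lengths: dict[str, int]
    conditions: dict[str, ConditionLandscape]
    regions: dict[str, list[GenomicInterval]]
    params: LandscapeParams
    barrier_anchors: list = field(default_factory=list)
    regulatory_anchors: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Genome synthesis
# ---------------------------------------------------------------------------

def make_genome(n_chrom: int = 1, lengths=2_000_000, gc: float = 0.4,
                seed: int = 0, periodic_dinucleotides: bool = False,
                dyad_positions: dict[str, np.ndarray] | None = None,
                plant_spacing: int = 200, plant_flank: int = 70,
                plant_prob: float = 0.8):
    """Random genome with optional 10-bp WW (A/T dinucleotide) periodicity.

    When ``periodic_dinucleotides`` is on, AA/TT/AT/TA dinucleotides are
    planted with probability ``plant_prob`` at offsets that are multiples of
    10 bp within ``plant_flank`` of each planting dyad; dyads come from
    ``dyad_positions`` or, by default, a regular grid with the given
    spacing.  Returns (genome, manifest) where the manifest records the
    planting positions and parameters.
    """
    if np.isscalar(lengths):
        lengths = [int(lengths)] * n_chrom
    if len(lengths) != n_chrom:
        raise ValidationError("lengths must match n_chrom")
    if any(n < 2000 for n in lengths):
        raise ValidationError("chromosome lengths must be >= 2 kb")
    if not (0 < gc < 1):
        raise ValidationError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs: dict[str, str] = {}
    manifest: dict = {"gc": gc, "seed": seed,
                      "periodic_dinucleotides": bool(periodic_dinucleotides),
                      "plant_dyads": {}}
    ww = [b"AA", b"TT", b"AT", b"TA"]
    for ci, length in enumerate(lengths):
        chrom = f"chr{ci + 1}"
        arr = bases[rng.choice(4, size=length, p=p)].copy()
        if periodic_dinucleotides:
            if dyad_positions is not None:
                dyads = np.asarray(dyad_positions[chrom])
            else:
                dyads = np.arange(plant_spacing, length - plant_spacing,
                                  plant_spacing)
            offsets = np.arange(-plant_flank, plant_flank + 1, 10)
            for d in dyads:
                for off in offsets:
                    pos = int(d) + int(off)
                    if 0 <= pos < length - 1 and rng.random() < plant_prob:
                        di = ww[rng.integers(4)]
                        arr[pos] = di[:1]
                        arr[pos + 1] = di[1:]
            manifest["plant_dyads"][chrom] = [int(x) for x in dyads]
        seqs[chrom] = arr.tobytes().decode("ascii")
    return GenomeSequence(seqs), manifest


def default_regions(lengths: dict[str, int],
                    regulatory_every: int = 10, barrier_every: int = 10,
                    block: int = 10_000, feature_width: int = 2000,
                    margin: int = 1000) -> dict[str, list[GenomicInterval]]:
    """Tile each chromosome into blocks and carve out regulatory/barrier
    feature windows on a regular schedule; the rest is stable chromatin.
    """
    regions: dict[str, list[GenomicInterval]] = {
        "stable": [], "regulatory": [], "barrier": []}
    for chrom, length in lengths.items():
        n_blocks = (length - 2 * margin) // block
        counter = 0
        for b in range(n_blocks):
            start = margin + b * block
            end = start + block
            mid = (start + end) // 2
            counter += 1
            if regulatory_every and counter % regulatory_every == regulatory_every - 1:
                half = feature_width // 2
                regions["stable"].append(GenomicInterval(chrom, start, mid - half))
                regions["regulatory"].append(
                    GenomicInterval(chrom, mid - half, mid + half))
                regions["stable"].append(GenomicInterval(chrom, mid + half, end))
            elif barrier_every and counter % barrier_every == 0:
                half = feature_width // 2
                regions["stable"].append(GenomicInterval(chrom, start, mid - half))
                regions["barrier"].append(
                    GenomicInterval(chrom, mid - half, mid + half))
                regions["stable"].append(GenomicInterval(chrom, mid + half, end))
            else:
                regions["stable"].append(GenomicInterval(chrom, start, end))
    return regions


# ---------------------------------------------------------------------------
# Landscape planting
# ---------------------------------------------------------------------------

def _forward_array(rng, lo: int, hi: int, mixture: LinkerMixture,
                   start: int | None = None) -> list[int]:
    """Dyad positions marching left to right through [lo, hi]."""
    if hi < lo:
        return []
    pos = start if start is not None else lo + int(rng.integers(0, 40))
    out = []
    while pos <= hi:
        out.append(pos)
        pos += NUC_SIZE + int(mixture.sample(rng, 1)[0])
    return out


def _backward_array(rng, lo: int, hi: int, mixture: LinkerMixture,
                    start: int) -> list[int]:
    out = []
    pos = start
    while pos >= lo:
        out.append(pos)
        pos -= NUC_SIZE + int(mixture.sample(rng, 1)[0])
    return out[::-1]


def plant_landscape(lengths, regions: dict[str, list[GenomicInterval]],
                    params: LandscapeParams | None = None,
                    seed: int = 0) -> PlantedLandscape:
    """Plant two-condition dyad landscapes over classified regions.

    Stable regions hold identical arrays in both conditions.  Regulatory
    regions get denser, short-linker arrays plus fragile flags in condition
    A only.  Barrier regions put a condition-A dyad on the region midpoint
    (the anchor) with arrays phased off it; condition B lacks the anchor
    dyad and its flanking arrays are shifted by half the mean spacing.
    """
    if isinstance(lengths, GenomeSequence):
        lengths = lengths.lengths
    params = params or LandscapeParams()
    rng = np.random.default_rng(seed)
    for cls in regions:
        if cls not in ("stable", "regulatory", "barrier"):
            raise ValidationError(f"unknown region class {cls!r}")
    # disjointness check and bounds
    per_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for cls, ivs in regions.items():
        for iv in ivs:
            if iv.chrom not in lengths or iv.end > lengths[iv.chrom]:
                raise ValidationError(f"region {iv} outside genome")
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, cls))
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        for (s1, e1, _), (s2, e2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValidationError(f"overlapping regions on {chrom}")

    mean_spacing = NUC_SIZE + params.base_linkers.mean()
    m = params.region_margin
    data = {name: {"dyads": {}, "weights": {}, "fragile": {}, "cls": {}}
            for name in ("A", "B")}
    barrier_anchors, regulatory_anchors = [], []

    def draw_w():
        return max(float(rng.gamma(params.weight_shape, params.weight_scale)),
                   1e-3)

    for chrom in lengths:
        rows = {name: [] for name in ("A", "B")}  # (pos, fragile, cls, weight)
        for start, end, cls in per_chrom.get(chrom, []):
            lo, hi = start + m, end - 1 - m
            if hi < lo:
                raise ValidationError(
                    f"region {chrom}:{start}-{end} too small for margin {m}")
            if cls == "stable":
                arr = _forward_array(rng, lo, hi, params.base_linkers)
                for p in arr:
                    w = draw_w()  # shared: the stable landscape is identical
                    rows["A"].append((p, False, cls, w))
                    rows["B"].append((p, False, cls, w))
            elif cls == "regulatory":
                mid = (start + end) // 2
                regulatory_anchors.append((chrom, mid))
                arr_a = _forward_array(rng, lo, hi, params.regulatory_linkers)
                arr_b = _forward_array(rng, lo, hi, params.base_linkers)
                if not arr_a:
                    raise ValidationError(
                        f"regulatory region {chrom}:{start}-{end} too small")
                for p in arr_a:
                    rows["A"].append(
                        (p, bool(rng.random() < params.fragile_fraction),
                         cls, draw_w()))
                for p in arr_b:
                    rows["B"].append((p, False, cls, draw_w()))
            else:  # barrier
                anchor = (start + end) // 2
                barrier_anchors.append((chrom, anchor))
                half = int(round(mean_spacing / 2))
                a_right = _forward_array(rng, lo, hi, params.base_linkers,
                                         start=anchor)
                a_left = _backward_array(
                    rng, lo, hi=anchor, mixture=params.base_linkers,
                    start=anchor - NUC_SIZE
                    - int(params.base_linkers.sample(rng, 1)[0]))
                b_right = _forward_array(rng, lo, hi, params.base_linkers,
                                         start=anchor + half)
                b_left = _backward_array(rng, lo, anchor, params.base_linkers,
                                         start=anchor - half)
                for p in sorted(set(a_left + a_right)):
                    rows["A"].append((p, False, cls, draw_w()))
                for p in sorted(set(b_left + b_right)):
                    rows["B"].append((p, False, cls, draw_w()))
        for name in ("A", "B"):
            rows[name].sort()
            pos = np.array([r[0] for r in rows[name]], dtype=np.int64)
            frag = np.array([r[1] for r in rows[name]], dtype=bool)
            cls_arr = np.array([r[2] for r in rows[name]], dtype="U10")
            if len(pos) > 1 and (np.diff(pos) < params.min_truth_spacing).any():
                bad = int(np.flatnonzero(
                    np.diff(pos) < params.min_truth_spacing)[0])
                raise ValidationError(
                    f"planted dyads closer than {params.min_truth_spacing} bp "
                    f"on {chrom} near {pos[bad]}")
            data[name]["dyads"][chrom] = pos
            data[name]["weights"][chrom] = np.array(
                [r[3] for r in rows[name]], dtype=float)
            data[name]["fragile"][chrom] = frag
            data[name]["cls"][chrom] = cls_arr

    conditions = {
        name: ConditionLandscape(name, d["dyads"], d["weights"],
                                 d["fragile"], d["cls"])
        for name, d in data.items()
    }
    return PlantedLandscape(dict(lengths), conditions, regions, params,
                            barrier_anchors, regulatory_anchors)


# ---------------------------------------------------------------------------
# Chemical fragment simulation
# ---------------------------------------------------------------------------

def _partner_anchors(dyads: np.ndarray, length: int, mean_spacing: int,
                     max_gap: int):
    """Downstream (Crick-cut) and upstream (Watson-cut) partner anchor per
    dyad, with auxiliary anchors where no neighbour is reachable.
    """
    n = len(dyads)
    down = np.empty(n, dtype=np.int64)
    up = np.empty(n, dtype=np.int64)
    gaps = np.diff(dyads)
    for i in range(n):
        if i + 1 < n and gaps[i] <= max_gap:
            down[i] = dyads[i + 1]
        else:
            v = int(dyads[i]) + (mean_spacing if i + 1 == n else 150)
            down[i] = min(v, length - 8)
        if i > 0 and gaps[i - 1] <= max_gap:
            up[i] = dyads[i - 1]
        else:
            v = int(dyads[i]) - (mean_spacing if i == 0 else 150)
            up[i] = max(v, 8)
    # keep one-strand auxiliary anchors from coinciding (a collision would
    # fabricate both-strand support at a non-dyad position)
    for i in range(n - 1):
        if gaps[i] > max_gap and abs(int(down[i]) - int(up[i + 1])) < 30:
            up[i + 1] = dyads[i + 1] - 210
    dyad_set = set(int(d) for d in dyads)
    aux = sorted({int(x) for x in np.concatenate([down, up])} - dyad_set)
    return down, up, aux


def simulate_chemical_fragments(landscape: PlantedLandscape, condition: str = "A",
                                model: CleavageModel | None = None,
                                n_fragments: int = 100_000, seed: int = 0,
                                min_len: int = 100, max_len: int = 300):
    """Simulate chemical-cleavage fragments for one condition.

    Returns (FragmentSet, truth) where truth maps each fragment to the dyad
    index that sampled it (-1 for background) and lists the auxiliary
    boundary anchors used for partner cuts.
    """
    model = model or CleavageModel()
    if n_fragments < 1:
        raise ValidationError("n_fragments must be >= 1")
    cond = landscape.conditions[condition]
    if cond.n_dyads() == 0:
        raise ValidationError("empty landscape")
    rng = np.random.default_rng(seed)
    mean_spacing = int(round(NUC_SIZE + landscape.params.base_linkers.mean()))
    max_gap = max_len - 20

    chrom_weight = np.array([cond.weights[c].sum() for c in cond.dyads])
    chroms = list(cond.dyads)
    n_bg = rng.binomial(n_fragments, model.background_rate)
    n_sig = n_fragments - n_bg
    per_chrom = rng.multinomial(n_sig, chrom_weight / chrom_weight.sum())

    data, labels, truth_idx = {}, {}, {}
    aux_anchors: dict[str, list[int]] = {}
    wp = model.w_primary
    offs_w = np.array([model.primary_offset, model.secondary_offset])
    offs_c = -offs_w  # strand-local -> reference for Crick
    for chrom, m in zip(chroms, per_chrom):
        dyads = cond.dyads[chrom]
        L = landscape.lengths[chrom]
        down, up, aux = _partner_anchors(dyads, L, mean_spacing, max_gap)
        aux_anchors[chrom] = aux
        p = cond.weights[chrom] / cond.weights[chrom].sum()
        idx = rng.choice(len(dyads), size=m, p=p)
        side = rng.integers(0, 2, size=m)
        watson_anchor = np.where(side == 0, dyads[idx], up[idx])
        crick_anchor = np.where(side == 0, down[idx], dyads[idx])
        w_off = offs_w[(rng.random(m) >= wp).astype(int)]
        c_off = offs_c[(rng.random(m) >= wp).astype(int)]
        jw = np.rint(rng.normal(0, model.jitter_sd, m)).astype(np.int64) \
            if model.jitter_sd > 0 else 0
        jc = np.rint(rng.normal(0, model.jitter_sd, m)).astype(np.int64) \
            if model.jitter_sd > 0 else 0
        s = watson_anchor + w_off + jw
        e = crick_anchor + c_off + jc + 1
        length_ok = (e - s >= min_len) & (e - s <= max_len)
        ok = (s >= 0) & (e <= L) & length_ok
        data[chrom] = [s[ok], e[ok]]
        truth_idx[chrom] = idx[ok]
        labels[chrom] = np.array(
            [f"{condition}:{chrom}:{i}" for i in idx[ok]], dtype=object)

    # uniform background fragments
    bg_chrom = rng.choice(len(chroms), size=n_bg,
                          p=np.array([landscape.lengths[c] for c in chroms],
                                     dtype=float)
                          / sum(landscape.lengths[c] for c in chroms))
    bg_len = rng.integers(min_len, max_len + 1, size=n_bg)
    for ci, chrom in enumerate(chroms):
        sel = bg_chrom == ci
        if not sel.any():
            continue
        lens = bg_len[sel]
        starts = rng.integers(0, np.maximum(
            landscape.lengths[chrom] - lens, 1))
        data.setdefault(chrom, [np.empty(0, np.int64), np.empty(0, np.int64)])
        data[chrom][0] = np.concatenate([data[chrom][0], starts])
        data[chrom][1] = np.concatenate([data[chrom][1], starts + lens])
        truth_idx[chrom] = np.concatenate(
            [truth_idx.get(chrom, np.empty(0, np.int64)),
             np.full(sel.sum(), -1, dtype=np.int64)])
        labels[chrom] = np.concatenate(
            [labels.get(chrom, np.empty(0, dtype=object)),
             np.full(sel.sum(), "background", dtype=object)])

    frags = FragmentSet({c: (v[0], v[1]) for c, v in data.items()}, labels)
    truth = {"condition": condition, "dyad_index": truth_idx,
             "aux_anchors": aux_anchors,
             "background_fragments": int(n_bg)}
    return frags, truth


def simulate_mnase_fragments(landscape: PlantedLandscape, condition: str = "A",
                             protection: float = 0.1, n_fragments: int = 100_000,
                             seed: int = 0, jitter_sd: float = 10.0,
                             min_len: int = 120, max_len: int = 180):
    """MNase-like fragments: midpoints near dyads, fragile dyads depleted.

    ``protection`` scales the sampling weight of fragile-flagged dyads
    (0 = fully digested away, 1 = fully protected).
    """
    if not (0 <= protection <= 1):
        raise ValidationError("protection must be in [0, 1]")
    cond = landscape.conditions[condition]
    rng = np.random.default_rng(seed)
    chroms = list(cond.dyads)
    eff = {c: cond.weights[c] * np.where(cond.fragile[c], protection, 1.0)
           for c in chroms}
    totals = np.array([eff[c].sum() for c in chroms])
    if totals.sum() == 0:
        raise ValidationError("all dyads have zero effective weight")
    per_chrom = rng.multinomial(n_fragments, totals / totals.sum())
    data, labels = {}, {}
    for chrom, m in zip(chroms, per_chrom):
        if m == 0:
            continue
        w = eff[chrom]
        keep = w > 0
        if not keep.any():
            continue
        idx_pool = np.flatnonzero(keep)
        p = w[keep] / w[keep].sum()
        idx = idx_pool[rng.choice(len(idx_pool), size=m, p=p)]
        mid = cond.dyads[chrom][idx] + np.rint(
            rng.normal(0, jitter_sd, m)).astype(np.int64)
        lens = rng.integers(min_len, max_len + 1, size=m)
        s = mid - (lens - 1) // 2
        e = s + lens
        L = landscape.lengths[chrom]
        ok = (s >= 0) & (e <= L)
        data[chrom] = (s[ok], e[ok])
        labels[chrom] = np.array(
            [f"{condition}:{chrom}:{i}" for i in idx[ok]], dtype=object)
    return FragmentSet(data, labels)


# ---------------------------------------------------------------------------
# C-score track synthesis
# ---------------------------------------------------------------------------

def make_cscore_track(landscape: PlantedLandscape, condition: str = "A",
                      modes: dict[str, str] | str = "dyad_enriched",
                      amplitude: float = 0.5, noise_sd: float = 0.05,
                      dyad_sd: float = 10.0, shoulder_center: int = 57,
                      shoulder_sd: float = 8.0, seed: int = 0) -> DenseTrack:
    """Gaussian-bump cyclizability track phased to planted dyads.

    ``modes`` maps region class to ``dyad_enriched`` (one bump on the dyad)
    or ``shoulder_enriched`` (bumps at +/-``shoulder_center`` bp); a bare
    string applies to every class.
    """
    if isinstance(modes, str):
        modes = {cls: modes for cls in ("stable", "regulatory", "barrier")}
    for mode in modes.values():
        if mode not in ("dyad_enriched", "shoulder_enriched"):
            raise ValidationError(f"unknown C-score mode {mode!r}")
    cond = landscape.conditions[condition]
    rng = np.random.default_rng(seed)
    track = DenseTrack(landscape.lengths)
    reach = 120
    d = np.arange(-reach, reach + 1)
    dyad_bump = amplitude * np.exp(-d ** 2 / (2 * dyad_sd ** 2))
    shoulder_bump = amplitude * (
        np.exp(-(d - shoulder_center) ** 2 / (2 * shoulder_sd ** 2))
        + np.exp(-(d + shoulder_center) ** 2 / (2 * shoulder_sd ** 2)))
    for chrom, L in landscape.lengths.items():
        vals = rng.normal(0.0, noise_sd, L) if noise_sd > 0 else np.zeros(L)
        for pos, cls in zip(cond.dyads.get(chrom, ()),
                            cond.region_class.get(chrom, ())):
            mode = modes.get(str(cls))
            if mode is None:
                continue
            bump = dyad_bump if mode == "dyad_enriched" else shoulder_bump
            lo, hi = max(0, pos - reach), min(L, pos + reach + 1)
            vals[lo:hi] += bump[(lo - (pos - reach)):(hi - (pos - reach))]
        track.values[chrom] = vals
        track.mask[chrom][:] = True
    return track


# ---------------------------------------------------------------------------
# Annotation exports
# ---------------------------------------------------------------------------

_STAINS = ["gneg", "gpos25", "gpos50", "gpos75", "gpos100"]


def export_annotations(landscape: PlantedLandscape, outdir, seed: int = 0,
                       band_size: int = 200_000) -> dict[str, str]:
    """Write state BED, anchor BEDs, an FPKM table and a toy cytoband file.

    FPKM values are tied to regulatory anchors (expressed, lognormal) with
    stable-region pseudo-genes mostly silent, so expression stratification
    has signal to find.  Returns a name -> path map.
    """
    import os

    rng = np.random.default_rng(seed)
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    p = os.path.join(outdir, "states.bed")
    with open(p, "w") as fh:
        for cls, ivs in landscape.regions.items():
            for iv in ivs:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cls}\n")
    paths["states"] = p

    for kind, anchors in (("regulatory", landscape.regulatory_anchors),
                          ("barrier", landscape.barrier_anchors)):
        p = os.path.join(outdir, f"anchors_{kind}.bed")
        with open(p, "w") as fh:
            for i, (chrom, pos) in enumerate(anchors):
                strand = "+" if i % 2 == 0 else "-"
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{kind}{i}\t0\t{strand}\n")
        paths[f"anchors_{kind}"] = p

    p = os.path.join(outdir, "expression.tsv")
    with open(p, "w") as fh:
        fh.write("gene_id\tFPKM\n")
        for i, (chrom, pos) in enumerate(landscape.regulatory_anchors):
            fh.write(f"reg{i}\t{rng.lognormal(2.0, 1.0):.3f}\n")
        n_silent = max(1, len(landscape.regulatory_anchors))
        for i in range(n_silent):
            fpkm = 0.0 if rng.random() < 0.7 else rng.lognormal(-1.0, 0.5)
            fh.write(f"stable{i}\t{fpkm:.3f}\n")
    paths["expression"] = p

    p = os.path.join(outdir, "cytoband.txt")
    with open(p, "w") as fh:
        for chrom, L in landscape.lengths.items():
            edges = list(range(0, L, band_size)) + [L]
            for bi, (s, e) in enumerate(zip(edges, edges[1:])):
                if e <= s:
                    continue
                stain = _STAINS[bi % len(_STAINS)]
                arm = "p" if s < L // 2 else "q"
                fh.write(f"{chrom}\t{s}\t{e}\t{arm}{bi}\t{stain}\n")
    paths["cytoband"] = p
    return paths


def write_manifest(path, **entries) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1, default=default)
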