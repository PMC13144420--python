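"""Readers/writers for the external formats the pipeline touches.

All coordinates are 0-based half-open internally.  BED-family files are
native; GTF-lite input (1-based inclusive) is converted on read.  Dense
per-position tracks carry an explicit coverage mask so that "no data" is
distinct from a legal score of zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ValidationError",
    "GenomeSequence",
    "GenomicInterval",
    "PointAnchor",
    "GeneModel",
    "DenseTrack",
    "load_genome",
    "load_intervals",
    "write_intervals",
    "load_gtf_lite",
    "select_representative_transcripts",
    "tss_tts_anchors",
    "exon_boundary_anchors",
    "read_bedgraph",
    "write_bedgraph",
    "read_wiggle",
    "write_wiggle",
    "load_expression_tsv",
    "load_jaspar_pfm",
    "FragmentSet",
    "gc_content",
]

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Inputs are well-formed but violate a semantic precondition."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class GenomeSequence:
    """Uppercase per-chromosome sequences over {A,C,G,T,N}."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise FormatError("genome contains no sequences")
        for name, seq in sequences.items():
            if len(seq) < 1:
                raise FormatError(f"chromosome {name!r} is empty")
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}
        for name, seq in self._seqs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                offset = next(i for i, c in enumerate(seq) if c in bad)
                raise FormatError(
                    f"illegal character {seq[offset]!r} in chromosome "
                    f"{name!r} at offset {offset}"
                )

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start:end]

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + (self.end - self.start - 1) // 2


@dataclass(frozen=True)
class PointAnchor:
    chrom: str
    pos: int
    strand: str = "."
    label: str = "."

    def __post_init__(self):
        if self.pos < 0:
            raise ValidationError(f"negative anchor position {self.pos}")


@dataclass
class GeneModel:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    source: str = ""
    cds_length: int = 0
    fpkm: float | None = None

    def finalize(self) -> "GeneModel":
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        return replace_exons(self, exons)

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand != "-" else self.exons[-1][1] - 1

    @property
    def tts(self) -> int:
        return self.exons[-1][1] - 1 if self.strand != "-" else self.exons[0][0]


def replace_exons(model: GeneModel, exons) -> GeneModel:
    out = GeneModel(
        model.gene_id, model.transcript_id, model.chrom, model.strand,
        list(exons), model.source, model.cds_length, model.fpkm,
    )
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_genome(path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Lowercase input is folded to uppercase; N is preserved.  Duplicate
    chromosome names and characters outside {A,C,G,T,N} raise
    :class:`FormatError` naming the offending record.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise FormatError(f"duplicate chromosome name {record.id!r}")
        seqs[record.id] = str(record.seq)
    if not seqs:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSequence(seqs)


# ---------------------------------------------------------------------------
# BED-family interval files
# ---------------------------------------------------------------------------

_DIALECT_MIN_COLS = {
    "bed3": 3, "bed6": 6, "chromhmm": 4, "cytoband": 5, "narrowpeak": 10,
}


def load_intervals(path, dialect: str = "bed6",
                   genome: GenomeSequence | None = None) -> list[GenomicInterval]:
    """Parse a BED-like file into intervals, in file order.

    Dialects: ``bed3``, ``bed6``, ``chromhmm`` (column 4 = state name),
    ``cytoband`` (UCSC 5-column; name = "gieStain/band"), ``narrowpeak``.
    """
    if dialect not in _DIALECT_MIN_COLS:
        raise FormatError(f"unknown dialect {dialect!r}")
    min_cols = _DIALECT_MIN_COLS[dialect]
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < min_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {min_cols} columns "
                    f"for dialect {dialect!r}, got {len(cols)}"
                )
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative coordinate {start}")
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval ({start} >= {end})"
                )
            name, score, strand = ".", 0.0, "."
            if dialect == "chromhmm":
                name = cols[3]
            elif dialect == "cytoband":
                name = f"{cols[4]}/{cols[3]}"
            elif dialect in ("bed6", "narrowpeak"):
                name = cols[3]
                try:
                    score = float(cols[4]) if cols[4] != "." else 0.0
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad score {cols[4]!r}") from exc
                strand = cols[5]
            if genome is not None:
                if chrom not in genome:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > genome.lengths[chrom]:
                    raise FormatError(
                        f"{path}:{lineno}: interval end {end} beyond chromosome"
                    )
            out.append(GenomicInterval(chrom, start, end, name, score, strand))
    return out


def write_intervals(path, intervals, bed6: bool = True) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if bed6:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}"
                         f"\t{iv.score:g}\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# GTF-lite
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if " " in item:
            key, _, value = item.partition(" ")
            attrs[key] = value.strip().strip('"')
    return attrs


def load_gtf_lite(path) -> list[GeneModel]:
    """Minimal GTF reader: exon and CDS features with gene_id, transcript_id
    and transcript_source attributes only.  GTF coordinates (1-based
    inclusive) are converted to 0-based half-open on read.
    """
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attr_text = cols[:9]
            if feature not in ("exon", "CDS"):
                continue
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from exc
            attrs = _parse_gtf_attributes(attr_text)
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id")
            if tid is None or gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id/transcript_id")
            if tid not in models:
                models[tid] = GeneModel(
                    gid, tid, chrom, strand,
                    source=attrs.get("transcript_source", ""),
                )
            model = models[tid]
            if feature == "exon":
                model.exons.append((s, e))
            else:
                model.cds_length += e - s
    return [m.finalize() for m in models.values()]


# ---------------------------------------------------------------------------
# Representative transcripts and anchors
# ---------------------------------------------------------------------------

def select_representative_transcripts(
    models: list[GeneModel], preferred_source: str = "ensembl_havana"
) -> dict[str, GeneModel]:
    """One representative transcript per gene.

    The transcript whose annotation source equals ``preferred_source`` wins;
    otherwise the transcript with the longest coding region.  Ties (several
    preferred, or equal CDS length) break to the lexicographically smallest
    transcript id, so the choice is independent of input order.
    """
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    out: dict[str, GeneModel] = {}
    for gene, transcripts in by_gene.items():
        if not transcripts:
            raise ValidationError(f"gene {gene!r} has no transcripts")
        preferred = [t for t in transcripts if t.source == preferred_source]
        pool = preferred if preferred else transcripts
        if preferred:
            best = min(pool, key=lambda t: t.transcript_id)
        else:
            best = min(pool, key=lambda t: (-t.cds_length, t.transcript_id))
        out[gene] = best
    return out


def tss_tts_anchors(representative: dict[str, GeneModel]
                    ) -> tuple[list[PointAnchor], list[PointAnchor]]:
    """TSS = transcript 5' end on its strand, TTS = 3' end."""
    tss, tts = [], []
    for gene, m in sorted(representative.items()):
        tss.append(PointAnchor(m.chrom, m.tss, m.strand, gene))
        tts.append(PointAnchor(m.chrom, m.tts, m.strand, gene))
    return tss, tts


def exon_boundary_anchors(representative: dict[str, GeneModel]
                          ) -> dict[str, list[PointAnchor]]:
    """Anchors at internal (non-terminal) exons of representative transcripts.

    ``exon_center``: exon midpoint; for even-length exons the leftmost of the
    two central bases in transcript orientation.  ``intron_exon``: the 5'
    start of the exon (reading direction), ``exon_intron``: its 3' end.
    Transcripts with fewer than three exons contribute nothing.
    """
    centers, ie, ei = [], [], []
    for gene, m in sorted(representative.items()):
        if len(m.exons) < 3:
            continue
        internal = m.exons[1:-1]
        for s, e in internal:
            length = e - s
            if m.strand != "-":
                center = s + (length - 1) // 2
                five, three = s, e - 1
            else:
                # reading 3'->5' in reference coordinates
                center = e - 1 - (length - 1) // 2
                five, three = e - 1, s
            centers.append(PointAnchor(m.chrom, center, m.strand, gene))
            ie.append(PointAnchor(m.chrom, five, m.strand, gene))
            ei.append(PointAnchor(m.chrom, three, m.strand, gene))
    return {"exon_center": centers, "intron_exon": ie, "exon_intron": ei}


# ---------------------------------------------------------------------------
# Dense tracks (bedGraph / wiggle)
# ---------------------------------------------------------------------------

class DenseTrack:
    """Per-chromosome float values with an explicit coverage mask.

    ``values[chrom]`` is a float array over the whole chromosome and
    ``mask[chrom]`` is True where data exist; zero is a legal value and is
    distinct from missing.
    """

    def __init__(self, lengths: dict[str, int]):
        self.lengths = dict(lengths)
        self.values = {c: np.zeros(n, dtype=float) for c, n in lengths.items()}
        self.mask = {c: np.zeros(n, dtype=bool) for c, n in lengths.items()}

    @classmethod
    def from_arrays(cls, values: dict[str, np.ndarray],
                    mask: dict[str, np.ndarray] | None = None) -> "DenseTrack":
        track = cls({c: len(v) for c, v in values.items()})
        for c, v in values.items():
            track.values[c] = np.asarray(v, dtype=float)
            track.mask[c] = (np.ones(len(v), dtype=bool) if mask is None
                             else np.asarray(mask[c], dtype=bool))
        return track

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def set_range(self, chrom: str, start: int, end: int, value: float) -> None:
        self.values[chrom][start:end] = value
        self.mask[chrom][start:end] = True


def read_bedgraph(path, genome: GenomeSequence | None = None,
                  lengths: dict[str, int] | None = None) -> DenseTrack:
    """Read a bedGraph into a dense track.  Overlapping runs are an error
    reported with both line numbers; uncovered positions stay masked out.
    """
    runs: list[tuple[str, int, int, float, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: bad run {start}-{end}")
            runs.append((chrom, start, end, value, lineno))
    if lengths is None:
        lengths = (genome.lengths if genome is not None
                   else {c: max(e for cc, _, e, _, _ in runs if cc == c)
                         for c in {r[0] for r in runs}})
    track = DenseTrack(lengths)
    last_line: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, start, end, value, lineno in runs:
        if chrom not in track.lengths:
            raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if end > track.lengths[chrom]:
            raise FormatError(f"{path}:{lineno}: run extends beyond chromosome")
        for s0, e0, l0 in last_line.get(chrom, []):
            if start < e0 and s0 < end:
                raise FormatError(
                    f"{path}: overlapping runs at lines {l0} and {lineno}"
                )
        last_line.setdefault(chrom, []).append((start, end, lineno))
        track.set_range(chrom, start, end, value)
    return track


def write_bedgraph(path, track: DenseTrack, precision: int = 6) -> None:
    """Write covered positions as maximal constant-value runs."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            vals, mask = track.values[chrom], track.mask[chrom]
            n = len(vals)
            i = 0
            while i < n:
                if not mask[i]:
                    i += 1
                    continue
                j = i + 1
                while j < n and mask[j] and vals[j] == vals[i]:
                    j += 1
                fh.write(f"{chrom}\t{i}\t{j}\t{vals[i]:.{precision}g}\n")
                i = j


def read_wiggle(path, lengths: dict[str, int] | None = None) -> DenseTrack:
    """Fixed-step wiggle reader (step/span 1)."""
    data: dict[str, list[tuple[int, float]]] = {}
    chrom, pos = None, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # wiggle is 1-based
                if int(fields.get("step", 1)) != 1:
                    raise FormatError(f"{path}:{lineno}: only step=1 supported")
                data.setdefault(chrom, [])
                continue
            if chrom is None:
                raise FormatError(f"{path}:{lineno}: value before fixedStep header")
            data[chrom].append((pos, float(line)))
            pos += 1
    if lengths is None:
        lengths = {c: max(p for p, _ in v) + 1 for c, v in data.items()}
    track = DenseTrack(lengths)
    for c, items in data.items():
        for p, v in items:
            track.values[c][p] = v
            track.mask[c][p] = True
    return track


def write_wiggle(path, track: DenseTrack, precision: int = 6) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            vals, mask = track.values[chrom], track.mask[chrom]
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(idx) != 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [idx.size - 1]))
            for a, b in zip(starts, ends):
                fh.write(f"fixedStep chrom={chrom} start={idx[a] + 1} step=1\n")
                for p in idx[a : b + 1]:
                    fh.write(f"{vals[p]:.{precision}g}\n")


# ---------------------------------------------------------------------------
# Expression table and JASPAR PFM
# ---------------------------------------------------------------------------

def load_expression_tsv(path) -> dict[str, float]:
    """TSV with a header containing gene_id and FPKM columns."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols or "fpkm" not in cols:
        raise FormatError(f"{path}: header must contain gene_id and FPKM columns")
    fpkm = df[cols["fpkm"]].astype(float)
    if (fpkm < 0).any():
        raise FormatError(f"{path}: negative FPKM value")
    return dict(zip(df[cols["gene_id"]].astype(str), fpkm))


def load_jaspar_pfm(path) -> tuple[str, np.ndarray]:
    """Read a JASPAR-style position frequency matrix (counts, rows A/C/G/T).

    Accepts both the bracketed JASPAR format ``A [ 1 2 3 ]`` and plain
    4-row numeric matrices.  Returns (motif name, 4xL count matrix).
    """
    name = "motif"
    rows: dict[str, list[float]] = {}
    order = "ACGT"
    plain: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                continue
            if line[0] in order and (len(line) == 1 or not line[1].isdigit()):
                body = line[1:].replace("[", " ").replace("]", " ")
                rows[line[0]] = [float(x) for x in body.split()]
            else:
                plain.append([float(x) for x in line.replace("[", " ")
                              .replace("]", " ").split()])
    if rows:
        if set(rows) != set(order):
            raise FormatError(f"{path}: PFM must have A,C,G,T rows")
        matrix = np.array([rows[b] for b in order], dtype=float)
    elif len(plain) == 4:
        matrix = np.array(plain, dtype=float)
    else:
        raise FormatError(f"{path}: cannot parse PFM")
    if matrix.shape[1] < 1 or not np.isfinite(matrix).all() or (matrix < 0).any():
        raise FormatError(f"{path}: invalid PFM counts")
    return name, matrix


# ---------------------------------------------------------------------------
# Paired-end fragments as BED
# ---------------------------------------------------------------------------

class FragmentSet:
    """Aligned fragment intervals, stored per chromosome as start/end arrays.

    ``labels`` (optional, same length) carry the BED name field, used by the
    simulator to link fragments to truth dyads.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray]],
                 labels: dict[str, np.ndarray] | None = None):
        self.starts = {c: np.asarray(se[0], dtype=np.int64) for c, se in data.items()}
        self.ends = {c: np.asarray(se[1], dtype=np.int64) for c, se in data.items()}
        self.labels = labels or {}
        for c in self.starts:
            if (self.starts[c] >= self.ends[c]).any() or (self.starts[c] < 0).any():
                raise ValidationError(f"invalid fragment on {c}")

    @property
    def chroms(self) -> list[str]:
        return list(self.starts)

    @property
    def n(self) -> int:
        return sum(len(s) for s in self.starts.values())

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.chroms:
                labels = self.labels.get(c)
                for i, (s, e) in enumerate(zip(self.starts[c], self.ends[c])):
                    name = labels[i] if labels is not None else "."
                    fh.write(f"{c}\t{s}\t{e}\t{name}\t0\t+\n")

    @classmethod
    def read_bed(cls, path) -> "FragmentSet":
        data: dict[str, list] = {}
        names: dict[str, list] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                cols = line.split()
                if len(cols) < 3:
                    raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
                c, s, e = cols[0], int(cols[1]), int(cols[2])
                data.setdefault(c, []).append((s, e))
                names.setdefault(c, []).append(cols[3] if len(cols) > 3 else ".")
        arrays = {c: (np.array([x[0] for x in v]), np.array([x[1] for x in v]))
                  for c, v in data.items()}
        labels = {c: np.array(v, dtype=object) for c, v in names.items()}
        return cls(arrays, labels)


def gc_content(genome: GenomeSequence) -> float:
    gc = total = 0
    for chrom in genome.chroms:
        seq = genome[chrom]
        gc += seq.count("G") + seq.count("C")
        total += len(seq) - seq.count("N")
    return gc / total if total else math.nan
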