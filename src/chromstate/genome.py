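"""Core genomic coordinate types, interval arithmetic, and flat-file I/O.

All coordinates are internally 0-based, half-open (BED convention). GFF3
input (1-based, inclusive) is converted on read. Every other module consumes
the types defined here.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised when a BED/bedGraph line cannot be parsed; names the line."""


def _open_text(path, mode: str = "rt"):
    """Open a possibly gzip-compressed text file transparently."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def normalize_chrom(name: str, prefix_map: dict | None = None) -> str:
    """Normalize chromosome-name dialects ("1" vs "chr1") via a prefix map.

    ``prefix_map`` maps exact source names to canonical names; names not in
    the map pass through unchanged.
    """
    if prefix_map:
        return prefix_map.get(name, name)
    return name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open coordinates; ``0 <= start < end`` is enforced.
    strand : str
        One of ``"+"``, ``"-"``, ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval, denominator: str = "b"
) -> float:
    """Fraction of the denominator interval covered by the other interval.

    ``denominator="b"`` returns ``|a ∩ b| / len(b)`` — the convention used
    when asking what fraction of a state bin is covered by a region.
    Disjoint or different-chromosome inputs give 0.
    """
    if denominator not in ("a", "b"):
        raise ValueError("denominator must be 'a' or 'b'")
    inter = a.intersection_length(b)
    denom = a.length if denominator == "a" else b.length
    return inter / denom


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of possibly-overlapping intervals, sorted by (chrom, start).

    Strand is dropped (merged intervals are unstranded). Book-ended
    intervals (end == next start) are merged as well.
    """
    ivs = sorted(intervals, key=lambda v: (v.chrom, v.start, v.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            last = out[-1]
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def coverage_by_set(
    target: GenomicInterval, regions: Sequence[GenomicInterval]
) -> float:
    """Fraction of ``target``'s bases covered by the union of ``regions``."""
    covered = 0
    for iv in merge_intervals(r for r in regions if r.chrom == target.chrom):
        covered += target.intersection_length(iv)
    return covered / target.length


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(
    path,
    merge_overlaps: bool = False,
    chrom_map: dict | None = None,
) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into sorted :class:`GenomicInterval` objects.

    Overlapping intervals on one chromosome are unioned when
    ``merge_overlaps`` is set. Raises :class:`BedParseError` naming the
    offending line on malformed input.
    """
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = cols[5] if len(cols) >= 6 and cols[5] in STRANDS else "."
            try:
                out.append(
                    GenomicInterval(normalize_chrom(cols[0], chrom_map), start, end, strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    out.sort(key=lambda v: (v.chrom, v.start, v.end))
    if merge_overlaps:
        out = merge_intervals(out)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, names=None) -> None:
    """Write intervals as BED (BED6 when a name column is given)."""
    with _open_text(path, "wt") as fh:
        if names is None:
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        else:
            for iv, name in zip(intervals, names):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class GeneModel:
    """A gene with strand-aware TSS/TTS and subfeature structure.

    ``tss`` is ``body.start`` on the + strand and ``body.end - 1`` on the
    − strand; subfeatures (UTRs, coding exons) lie within the body and
    introns are exactly the gaps between consecutive exonic blocks.
    """

    gene_id: str
    body: GenomicInterval
    strand: str
    five_utr: list[GenomicInterval] = field(default_factory=list)
    three_utr: list[GenomicInterval] = field(default_factory=list)
    coding_exons: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for iv in self.five_utr + self.three_utr + self.coding_exons + self.introns:
            if iv.chrom != self.body.chrom or iv.start < self.body.start or iv.end > self.body.end:
                raise ValueError(
                    f"gene {self.gene_id}: subfeature {iv} outside body {self.body}"
                )

    @property
    def chrom(self) -> str:
        return self.body.chrom

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1

    @property
    def tts(self) -> int:
        return self.body.end - 1 if self.strand == "+" else self.body.start

    def exonic_blocks(self) -> list[GenomicInterval]:
        """Union of UTR and coding-exon intervals, merged and sorted."""
        return merge_intervals(self.five_utr + self.three_utr + self.coding_exons)


def _introns_from_blocks(body: GenomicInterval, blocks: list[GenomicInterval]):
    """Gaps between consecutive merged exonic blocks, within the body."""
    introns = []
    for left, right in zip(blocks, blocks[1:]):
        if right.start > left.end:
            introns.append(GenomicInterval(body.chrom, left.end, right.start))
    return introns


def read_genes(path, format: str = "gff3", chrom_map: dict | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 or BED12.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention. Genes without annotated UTRs get empty
    UTR lists; a gene without a strand is an error. Strand ``.`` in BED12
    is treated as ``+`` with a warning.
    """
    if format == "gff3":
        return _read_gff3(path, chrom_map)
    if format == "bed12":
        return _read_bed12(path, chrom_map)
    raise ValueError(f"unknown gene format {format!r}")


def _read_gff3(path, chrom_map):
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.id}: missing strand in GFF3")
        chrom = normalize_chrom(g.seqid, chrom_map)
        body = GenomicInterval(chrom, g.start - 1, g.end, g.strand)
        parts = {"five_prime_UTR": [], "three_prime_UTR": [], "CDS": [], "exon": []}
        for child in db.children(g.id):
            if child.featuretype in parts:
                if child.start - 1 < body.start or child.end > body.end:
                    raise ValueError(
                        f"gene {g.id}: child {child.featuretype} "
                        f"{child.start}-{child.end} outside gene span"
                    )
                parts[child.featuretype].append(
                    GenomicInterval(chrom, child.start - 1, child.end, g.strand)
                )
        five = sorted(parts["five_prime_UTR"], key=lambda v: v.start)
        three = sorted(parts["three_prime_UTR"], key=lambda v: v.start)
        cds = sorted(parts["CDS"], key=lambda v: v.start)
        blocks = merge_intervals(five + three + cds) or merge_intervals(parts["exon"])
        if not blocks:
            blocks = [GenomicInterval(chrom, body.start, body.end)]
        genes.append(
            GeneModel(
                gene_id=g.id,
                body=body,
                strand=g.strand,
                five_utr=five,
                three_utr=three,
                coding_exons=cds if cds else merge_intervals(parts["exon"]),
                introns=_introns_from_blocks(body, blocks),
            )
        )
    genes.sort(key=lambda gm: (gm.chrom, gm.body.start))
    return genes


def _read_bed12(path, chrom_map):
    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise BedParseError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom = normalize_chrom(cols[0], chrom_map)
            start, end = int(cols[1]), int(cols[2])
            strand = cols[5]
            if strand == ".":
                warnings.warn(
                    f"{path}:{lineno}: unstranded gene treated as + strand"
                )
                strand = "+"
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: gene without strand")
            n_blocks = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise BedParseError(f"{path}:{lineno}: blockCount mismatch")
            body = GenomicInterval(chrom, start, end, strand)
            blocks = []
            for off, size in zip(offsets, sizes):
                blk = GenomicInterval(chrom, start + off, start + off + size, strand)
                if blk.end > end:
                    raise ValueError(f"{path}:{lineno}: block outside gene span")
                blocks.append(blk)
            blocks.sort(key=lambda v: v.start)
            genes.append(
                GeneModel(
                    gene_id=cols[3],
                    body=body,
                    strand=strand,
                    coding_exons=blocks,
                    introns=_introns_from_blocks(body, merge_intervals(blocks)),
                )
            )
    genes.sort(key=lambda gm: (gm.chrom, gm.body.start))
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene + UTR/CDS children, 1-based)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tchromstate\tgene\t{g.body.start + 1}\t{g.body.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for ftype, ivs in (
                ("five_prime_UTR", g.five_utr),
                ("CDS", g.coding_exons),
                ("three_prime_UTR", g.three_utr),
            ):
                for i, iv in enumerate(ivs):
                    fh.write(
                        f"{g.chrom}\tchromstate\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}.{ftype}.{i};Parent={g.gene_id}\n"
                    )


# ---------------------------------------------------------------------------
# Peak sets


@dataclass
class PeakSet:
    """Peaks of one histone mark under one condition.

    Overlapping peaks are merged on construction unless ``merged=False`` is
    requested (the enrichment and coverage math assume non-redundant
    regions).
    """

    mark: str
    condition: str
    peaks: list[GenomicInterval]
    merged: bool = True

    def __post_init__(self):
        if self.merged:
            self.peaks = merge_intervals(self.peaks)
        else:
            self.peaks = sorted(self.peaks, key=lambda v: (v.chrom, v.start))

    def __len__(self):
        return len(self.peaks)

    @classmethod
    def from_bed(cls, path, mark: str, condition: str, merge_overlaps: bool = True):
        return cls(mark, condition, read_bed(path), merged=merge_overlaps)


# ---------------------------------------------------------------------------
# State segmentation


class StateSegmentation:
    """The genome tiled by labeled chromatin-state bins.

    Bins are stored per chromosome as sorted, non-overlapping coordinate
    arrays plus an integer state label (1..n_states) per bin. Bins may be
    fixed- or variable-width.
    """

    def __init__(self, bins: Iterable[tuple[GenomicInterval, int]], n_states: int):
        self.n_states = int(n_states)
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for iv, label in bins:
            label = int(label)
            if not 1 <= label <= self.n_states:
                raise ValueError(f"state label {label} outside 1..{self.n_states}")
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, label))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            labels = np.array([r[2] for r in rows], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping state bins on {chrom}")
            self._chroms[chrom] = (starts, ends, labels)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def bins_on(self, chrom: str):
        """(starts, ends, labels) arrays for one chromosome."""
        return self._chroms[chrom]

    def __len__(self):
        return sum(len(v[0]) for v in self._chroms.values())

    def state_totals(self) -> np.ndarray:
        """Number of bins per state; index i-1 holds count(all state_i)."""
        totals = np.zeros(self.n_states, dtype=np.int64)
        for starts, ends, labels in self._chroms.values():
            totals += np.bincount(labels - 1, minlength=self.n_states)
        return totals

    def iter_bins(self):
        for chrom in self.chroms:
            starts, ends, labels = self._chroms[chrom]
            for s, e, lab in zip(starts, ends, labels):
                yield GenomicInterval(chrom, int(s), int(e)), int(lab)

    @classmethod
    def from_bed(cls, path, n_states: int, chrom_map: dict | None = None):
        """Read a segmentation from BED with the state label in column 4."""
        bins = []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                cols = line.split("\t")
                if len(cols) < 4:
                    raise BedParseError(f"{path}:{lineno}: state BED needs 4 columns")
                label = cols[3].lstrip("state_sE")
                bins.append(
                    (
                        GenomicInterval(
                            normalize_chrom(cols[0], chrom_map), int(cols[1]), int(cols[2])
                        ),
                        int(label),
                    )
                )
        return cls(bins, n_states)

    def to_bed(self, path) -> None:
        with _open_text(path, "wt") as fh:
            for iv, label in self.iter_bins():
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


# ---------------------------------------------------------------------------
# Signal tracks


class SignalTrack:
    """Per-chromosome stepwise-constant, non-negative signal density.

    Stored as sorted non-overlapping (start, end, value) arrays per
    chromosome; uncovered bases read as zero. Exact window means are
    computed from a prefix integral, so profile binning is reproducible at
    any bin width, including fractional (percent-scaled) boundaries.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._chroms = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.float64)
            ends = np.asarray(ends, dtype=np.float64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(values < 0):
                raise ValueError(f"negative signal on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping signal intervals on {chrom}")
            # prefix integral at interval starts: cum[i] = ∫ signal over [0, starts[i])
            seg = (ends - starts) * values
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            self._chroms[chrom] = (starts, ends, values, cum)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def intervals_on(self, chrom: str):
        starts, ends, values, _ = self._chroms[chrom]
        return starts.astype(np.int64), ends.astype(np.int64), values

    def _integral_at(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """∫ signal over [0, x) for an array of positions x (float ok)."""
        starts, ends, values, cum = self._chroms[chrom]
        x = np.asarray(x, dtype=np.float64)
        idx = np.searchsorted(starts, x, side="right")
        out = cum[idx]
        # subtract the part of interval idx-1 beyond x (if x is inside it)
        inside = idx > 0
        j = idx[inside] - 1
        overhang = np.clip(ends[j] - x[inside], 0.0, ends[j] - starts[j])
        out[inside] = out[inside] - overhang * values[j]
        return out

    def integral(self, chrom: str, starts, ends) -> np.ndarray:
        """Vectorized ∫ signal over [start, end) windows."""
        if chrom not in self._chroms:
            return np.zeros(len(np.atleast_1d(starts)))
        s = np.atleast_1d(np.asarray(starts, dtype=np.float64))
        e = np.atleast_1d(np.asarray(ends, dtype=np.float64))
        return self._integral_at(chrom, e) - self._integral_at(chrom, s)

    def mean(self, chrom: str, start: float, end: float) -> float:
        """Mean signal density over one window (0 over uncovered bases)."""
        if end <= start:
            raise ValueError("empty window")
        return float(self.integral(chrom, [start], [end])[0] / (end - start))

    def binned_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Mean density in each [edges[i], edges[i+1]) bin."""
        edges = np.asarray(edges, dtype=np.float64)
        ints = self.integral(chrom, edges[:-1], edges[1:])
        widths = np.diff(edges)
        return ints / widths

    @classmethod
    def from_bedgraph(cls, path, chrom_map: dict | None = None) -> "SignalTrack":
        data: dict[str, list[tuple[int, int, float]]] = {}
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                if len(cols) < 4:
                    raise BedParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
                data.setdefault(normalize_chrom(cols[0], chrom_map), []).append(
                    (int(cols[1]), int(cols[2]), float(cols[3]))
                )
        arrays = {}
        for chrom, rows in data.items():
            rows.sort()
            arrays[chrom] = (
                np.array([r[0] for r in rows]),
                np.array([r[1] for r in rows]),
                np.array([r[2] for r in rows]),
            )
        return cls(arrays)

    def to_bedgraph(self, path) -> None:
        with _open_text(path, "wt") as fh:
            for chrom in self.chroms:
                starts, ends, values = self.intervals_on(chrom)
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    @classmethod
    def constant(cls, chrom_sizes: dict[str, int], value: float) -> "SignalTrack":
        """A uniform track — handy for flat-field checks."""
        return cls(
            {
                c: (np.array([0]), np.array([size]), np.array([float(value)]))
                for c, size in chrom_sizes.items()
            }
        )
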