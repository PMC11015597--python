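"""Peak annotation: genomic-subregion distribution and peak→gene assignment.

The genome is partitioned into six subregions — promoter, 5'UTR, coding
exon, intron, 3'UTR, intergenic — and each peak's bases are attributed to
the labels they fall on. Genes carry a mark when a peak overlaps the
window spanning the gene body plus 2 kb upstream of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomicInterval, PeakSet

SUBREGIONS = ("intergenic", "promoter", "intron", "coding_exon", "three_utr", "five_utr")
# paint order above doubles as precedence: later labels overwrite earlier
# ones, so five_utr > three_utr > coding_exon > intron > promoter > intergenic
LABEL_CODE = {name: i for i, name in enumerate(SUBREGIONS)}


@dataclass
class SubregionMap:
    """Per-base subregion labels for every chromosome (int8 arrays)."""

    labels: dict[str, np.ndarray]
    promoter_bp: int

    def label_names(self) -> tuple[str, ...]:
        return SUBREGIONS

    def base_totals(self) -> dict[str, int]:
        totals = np.zeros(len(SUBREGIONS), dtype=np.int64)
        for arr in self.labels.values():
            totals += np.bincount(arr, minlength=len(SUBREGIONS))
        return {name: int(totals[i]) for i, name in enumerate(SUBREGIONS)}


def build_subregion_map(
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    promoter_bp: int = 2000,
) -> SubregionMap:
    """Label every base of the genome with exactly one subregion.

    The promoter is ``promoter_bp`` upstream of the TSS (strand-aware,
    clipped at chromosome bounds). When annotations collide, gene-internal
    labels beat a neighbour's promoter: five_utr > three_utr > coding_exon
    > intron > promoter > intergenic.
    """
    labels = {c: np.zeros(size, dtype=np.int8) for c, size in chrom_sizes.items()}

    def paint(iv: GenomicInterval, code: int):
        arr = labels[iv.chrom]
        s, e = max(0, iv.start), min(len(arr), iv.end)
        if e > s:
            np.maximum(arr[s:e], code, out=arr[s:e])

    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom} not in chrom_sizes")
        if g.body.end > chrom_sizes[g.chrom]:
            raise ValueError(f"gene {g.gene_id} extends beyond chromosome {g.chrom}")
    # paint in increasing precedence so np.maximum resolves collisions
    for g in genes:
        if g.strand == "+":
            ps, pe = g.body.start - promoter_bp, g.body.start
        else:
            ps, pe = g.body.end, g.body.end + promoter_bp
        if pe > ps:
            ps = max(0, ps)
            pe = min(chrom_sizes[g.chrom], pe)
            if pe > ps:
                paint(GenomicInterval(g.chrom, ps, pe), LABEL_CODE["promoter"])
    for g in genes:
        # a gene body with no structure at all counts as coding exon
        blocks = g.introns + g.coding_exons + g.three_utr + g.five_utr
        if not blocks:
            paint(g.body, LABEL_CODE["coding_exon"])
            continue
        for iv in g.introns:
            paint(iv, LABEL_CODE["intron"])
        for iv in g.coding_exons:
            paint(iv, LABEL_CODE["coding_exon"])
        for iv in g.three_utr:
            paint(iv, LABEL_CODE["three_utr"])
        for iv in g.five_utr:
            paint(iv, LABEL_CODE["five_utr"])
    return SubregionMap(labels, promoter_bp)


@dataclass
class SubregionDistribution:
    """Base-pair totals and fractions of peak signal per subregion."""

    totals: dict[str, float]
    fractions: dict[str, float]
    mode: str = "bases"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subregion": list(SUBREGIONS),
                "total": [self.totals[s] for s in SUBREGIONS],
                "fraction": [self.fractions[s] for s in SUBREGIONS],
            }
        )


def peak_subregion_distribution(
    peaks: PeakSet, partition: SubregionMap, mode: str = "bases"
) -> SubregionDistribution:
    """Distribute peaks over the six subregions.

    ``mode="bases"`` (default) attributes each peak base to the label it
    falls on; ``mode="peaks"`` assigns each whole peak to its majority
    label. Fractions sum to 1 when any peak base exists.
    """
    if mode not in ("bases", "peaks"):
        raise ValueError("mode must be 'bases' or 'peaks'")
    counts = np.zeros(len(SUBREGIONS), dtype=np.int64)
    for iv in peaks.peaks:
        if iv.chrom not in partition.labels:
            raise ValueError(f"peak chromosome {iv.chrom} absent from partition")
        arr = partition.labels[iv.chrom]
        s, e = iv.start, min(iv.end, len(arr))
        per_peak = np.bincount(arr[s:e], minlength=len(SUBREGIONS))
        if mode == "bases":
            counts += per_peak
        else:
            counts[int(np.argmax(per_peak))] += 1
    total = counts.sum()
    fractions = counts / total if total > 0 else np.zeros_like(counts, dtype=float)
    return SubregionDistribution(
        totals={n: int(counts[i]) for i, n in enumerate(SUBREGIONS)},
        fractions={n: float(fractions[i]) for i, n in enumerate(SUBREGIONS)},
        mode=mode,
    )


@dataclass
class GeneMarkAssignment:
    """Genes carrying one mark in one condition, with supporting peaks."""

    mark: str
    condition: str
    assignments: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.assignments)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (gid, len(pks), ";".join(f"{p.chrom}:{p.start}-{p.end}" for p in pks))
            for gid, pks in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "n_peaks", "peaks"])


def gene_window(
    gene: GeneModel, upstream_bp: int = 2000, chrom_sizes: dict[str, int] | None = None
) -> GenomicInterval:
    """The peak-assignment window: gene body plus ``upstream_bp`` upstream
    of the TSS, strand-oriented, clipped at chromosome bounds."""
    if gene.strand == "+":
        s, e = gene.body.start - upstream_bp, gene.body.end
    else:
        s, e = gene.body.start, gene.body.end + upstream_bp
    s = max(0, s)
    if chrom_sizes is not None:
        e = min(e, chrom_sizes[gene.chrom])
    return GenomicInterval(gene.chrom, s, e, gene.strand)


def assign_peaks_to_genes(
    peaks: PeakSet,
    genes: list[GeneModel],
    upstream_bp: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> GeneMarkAssignment:
    """A gene carries the mark iff some peak overlaps its assignment
    window (2-kb upstream + gene body by default) by at least 1 bp.

    Peaks overlapping the windows of several genes support all of them.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in peaks.peaks:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts_ends = {
        c: (
            np.array([p.start for p in ivs], dtype=np.int64),
            np.array([p.end for p in ivs], dtype=np.int64),
        )
        for c, ivs in by_chrom.items()
    }
    out: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        if g.chrom not in by_chrom:
            continue
        win = gene_window(g, upstream_bp, chrom_sizes)
        ps, pe = starts_ends[g.chrom]
        hit = np.flatnonzero((ps < win.end) & (pe > win.start))
        if len(hit):
            out[g.gene_id] = [by_chrom[g.chrom][i] for i in hit]
    return GeneMarkAssignment(peaks.mark, peaks.condition, out)


@dataclass
class SetComparison:
    """Overlap summary of two gene sets: counts partition the union."""

    shared: set[str]
    a_only: set[str]
    b_only: set[str]

    @property
    def jaccard(self) -> float:
        union = len(self.shared) + len(self.a_only) + len(self.b_only)
        return len(self.shared) / union if union else float("nan")

    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
        }


def compare_mark_gene_sets(a: GeneMarkAssignment, b: GeneMarkAssignment) -> SetComparison:
    """Shared / exclusive gene counts and Jaccard index of two assignments."""
    ga, gb = a.gene_ids, b.gene_ids
    return SetComparison(shared=ga & gb, a_only=ga - gb, b_only=gb - ga)


def compare_peak_sets(
    a: PeakSet, b: PeakSet, min_fraction: float = 0.0
) -> dict[str, float]:
    """Peak-level overlap of two peak sets (any-bp by default).

    Returns the count and fraction of peaks in each set overlapped by the
    other; ``min_fraction`` requires that fraction of the peak's bases be
    covered.
    """
    from .genome import coverage_by_set

    def frac_overlapped(xs, ys):
        n = 0
        for p in xs:
            cov = coverage_by_set(p, ys)
            if (cov > min_fraction) if min_fraction > 0 else (cov > 0):
                n += 1
        return n

    na = frac_overlapped(a.peaks, b.peaks)
    nb = frac_overlapped(b.peaks, a.peaks)
    return {
        "a_total": len(a.peaks),
        "b_total": len(b.peaks),
        "a_overlapped": na,
        "b_overlapped": nb,
        "a_fraction": na / len(a.peaks) if a.peaks else float("nan"),
        "b_fraction": nb / len(b.peaks) if b.peaks else float("nan"),
    }
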