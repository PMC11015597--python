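"""Ground-truth synthetic data: toy genomes, segmentations, differential
regions, lamina-domain signal tracks, expression and qPCR tables.

Every generator draws from its own substream of one master seed, so adding
draws to one generator never perturbs another, and an identical
configuration plus seed reproduces outputs bit-identically.

Defaults emulate the statistical structure the pipeline is meant to
resolve: a 2 x 1 Mb genome tiled into 10,000 bins over 36 chromatin
states; differential-deposition regions seeded preferentially into chosen
states with a configurable odds multiplier; a body-enriched mark inside
plant lamina-associated domains (PLADs) and a border-enriched mark at
their edges; and expression tables in which genes losing a repressive mark
are upregulated by a known log2 effect.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomicInterval, PeakSet, SignalTrack, StateSegmentation

_SUBSTREAMS = {
    "states": 0,
    "genes": 1,
    "plads": 2,
    "regions": 3,
    "signal": 4,
    "expression": 5,
    "qpcr": 6,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic genome and its downstream data.

    The defaults are the study conditions of the simulation experiments:
    10,000 state bins (2 chromosomes x 1 Mb at 200 bp), 36 states, one
    planted enriched state at odds 8, 2,000 single-bin differential
    regions, PLAD signal levels 5x over background, and a +2 log2
    fold-change on the planted expression shift with 3 replicates.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 1_000_000
    n_genes: int = 400
    gene_length_mean_bp: float = 2_000.0
    gene_length_sd_log: float = 0.5
    n_states: int = 36
    bin_width_bp: int = 200
    state_freqs: tuple | None = None
    dirichlet_alpha: float = 5.0
    enriched_states: tuple = (12,)
    enrichment_odds: float = 8.0
    n_regions: int = 2_000
    region_len_bins: int = 1
    plad_count: int = 30
    plad_length_mean_bp: float = 10_000.0
    plad_length_sd_log: float = 0.4
    plad_flank_bp: int = 2_000
    body_mark_level: float = 5.0
    border_mark_level: float = 5.0
    background_level: float = 1.0
    border_fraction: float = 0.2
    border_outside_bp: int = 500
    signal_step_bp: int = 50
    signal_noise: bool = True
    poisson_events_per_unit: float = 20.0
    de_fraction: float = 0.5
    de_log2fc_mean: float = 2.0
    fpkm_noise_sd: float = 0.2
    n_replicates: int = 3

    def __post_init__(self):
        if self.enrichment_odds < 1:
            raise ValueError("enrichment_odds must be >= 1")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        for name in ("body_mark_level", "border_mark_level", "background_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic substream for one generator."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_SUBSTREAMS[stream],))
        return np.random.default_rng(ss)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chroms)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enriched_states"] = list(self.enriched_states)
        if self.state_freqs is not None:
            d["state_freqs"] = list(self.state_freqs)
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "enriched_states" in raw:
            raw["enriched_states"] = tuple(raw["enriched_states"])
        if raw.get("state_freqs") is not None:
            raw["state_freqs"] = tuple(raw["state_freqs"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Genome, segmentation, PLADs


def _state_probs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.state_freqs is not None:
        p = np.asarray(config.state_freqs, dtype=float)
        if len(p) != config.n_states or p.sum() <= 0:
            raise ValueError("state_freqs must have n_states non-negative entries")
        return p / p.sum()
    return rng.dirichlet(np.full(config.n_states, config.dirichlet_alpha))


def _place_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    lengths: np.ndarray,
    chrom_sizes: dict[str, int],
    margin: int = 0,
) -> list[GenomicInterval]:
    """Place n non-overlapping intervals, keeping a margin from chromosome
    ends.

    Free space is tracked as gaps; each interval picks a gap with
    probability proportional to the number of admissible start positions,
    then a uniform offset within it. Largest intervals are placed first so
    fragmentation cannot strand them; an error is raised only when no gap
    can host an interval.
    """
    gaps: list[tuple[str, int, int]] = []
    for chrom in sorted(chrom_sizes):
        lo, hi = margin, chrom_sizes[chrom] - margin
        if hi > lo:
            gaps.append((chrom, lo, hi))
    out = []
    for L in sorted((int(x) for x in lengths), reverse=True):
        slack = np.array([max(0, e - s - L + 1) for _, s, e in gaps], dtype=float)
        if slack.sum() == 0:
            raise ValueError(
                f"genome too small to place {n} intervals of ~{int(np.mean(lengths))} bp"
            )
        gi = int(rng.choice(len(gaps), p=slack / slack.sum()))
        chrom, gs, ge = gaps.pop(gi)
        s = gs + int(rng.integers(0, ge - gs - L + 1))
        out.append(GenomicInterval(chrom, s, s + L))
        if s > gs:
            gaps.append((chrom, gs, s))
        if s + L < ge:
            gaps.append((chrom, s + L, ge))
    return sorted(out, key=lambda v: (v.chrom, v.start))


def _build_gene(rng: np.random.Generator, span: GenomicInterval, gene_id: str) -> GeneModel:
    """Attach strand and a simple UTR/CDS/intron structure to a placed span."""
    strand = "+" if rng.random() < 0.5 else "-"
    body = GenomicInterval(span.chrom, span.start, span.end, strand)
    L = body.length
    n_ex = int(rng.integers(1, 4)) if L >= 600 else 1
    # split body into n_ex exon blocks separated by introns
    cuts = np.sort(rng.choice(np.arange(1, L), size=2 * (n_ex - 1), replace=False)) if n_ex > 1 else np.array([], dtype=int)
    bounds = np.concatenate([[0], cuts, [L]]) + body.start
    exons = [GenomicInterval(body.chrom, int(bounds[2 * i]), int(bounds[2 * i + 1]), strand)
             for i in range(n_ex)]
    exons = [e for e in exons]
    introns = [GenomicInterval(body.chrom, int(bounds[2 * i + 1]), int(bounds[2 * i + 2]))
               for i in range(n_ex - 1)]
    # carve UTRs off the outer exons (strand-aware), keeping CDS non-empty
    utr = min(150, exons[0].length // 3, exons[-1].length // 3)
    five, three, cds = [], [], []
    first, last = exons[0], exons[-1]
    if utr > 0:
        left = GenomicInterval(body.chrom, first.start, first.start + utr, strand)
        right = GenomicInterval(body.chrom, last.end - utr, last.end, strand)
        (five if strand == "+" else three).append(left)
        (three if strand == "+" else five).append(right)
        if len(exons) == 1:
            cds = [GenomicInterval(body.chrom, first.start + utr, first.end - utr, strand)]
        else:
            cds = [GenomicInterval(body.chrom, first.start + utr, first.end, strand)]
            cds += exons[1:-1]
            cds.append(GenomicInterval(body.chrom, last.start, last.end - utr, strand))
    else:
        cds = exons
    return GeneModel(gene_id, body, strand, five, three, cds, introns)


def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[GeneModel], StateSegmentation, list[GenomicInterval]]:
    """Toy genome: non-overlapping genes, a tiled state segmentation, and
    PLADs placed away from chromosome ends so their flanks exist."""
    # segmentation: tile every chromosome, draw labels from state frequencies
    rng_states = config.rng("states")
    probs = _state_probs(config, rng_states)
    bins = []
    for chrom, size in config.chrom_sizes.items():
        edges = np.arange(0, size + 1, config.bin_width_bp)
        if edges[-1] != size:
            edges = np.append(edges, size)
        labels = rng_states.choice(config.n_states, size=len(edges) - 1, p=probs) + 1
        for s, e, lab in zip(edges[:-1], edges[1:], labels):
            bins.append((GenomicInterval(chrom, int(s), int(e)), int(lab)))
    segmentation = StateSegmentation(bins, config.n_states)

    genes: list[GeneModel] = []
    if config.n_genes > 0:
        rng_genes = config.rng("genes")
        mu = np.log(config.gene_length_mean_bp)
        lengths = np.clip(
            rng_genes.lognormal(mu, config.gene_length_sd_log, config.n_genes), 400, None
        ).astype(int)
        spans = _place_nonoverlapping(
            rng_genes, config.n_genes, lengths, config.chrom_sizes, margin=2_000
        )
        genes = [_build_gene(rng_genes, sp, f"gene{i:05d}") for i, sp in enumerate(spans)]

    plads: list[GenomicInterval] = []
    if config.plad_count > 0:
        rng_plads = config.rng("plads")
        mu = np.log(config.plad_length_mean_bp)
        lengths = np.clip(
            rng_plads.lognormal(mu, config.plad_length_sd_log, config.plad_count),
            3_000,
            None,
        ).astype(int)
        plads = _place_nonoverlapping(
            rng_plads,
            config.plad_count,
            lengths,
            config.chrom_sizes,
            margin=config.plad_flank_bp + config.border_outside_bp,
        )
    return genes, segmentation, plads


# ---------------------------------------------------------------------------
# Differential regions with injected state enrichment


def simulate_differential_regions(
    config: SimulationConfig,
    segmentation: StateSegmentation,
    mark: str = "H3K27me3",
    condition: str = "WT",
) -> tuple[PeakSet, dict]:
    """Differential-deposition regions as runs of consecutive bins, with
    seed bins drawn preferentially from the enriched states.

    A bin in an enriched state is ``enrichment_odds`` times as likely to
    seed a region as any other bin. Returns the (merged) region set and a
    ground-truth record with the realized per-state hit rates.
    """
    rng = config.rng("regions")
    chroms, all_starts, all_ends, all_labels = [], [], [], []
    for chrom in segmentation.chroms:
        s, e, lab = segmentation.bins_on(chrom)
        chroms.extend([chrom] * len(s))
        all_starts.append(s)
        all_ends.append(e)
        all_labels.append(lab)
    starts = np.concatenate(all_starts)
    ends = np.concatenate(all_ends)
    labels = np.concatenate(all_labels)
    n_bins = len(starts)

    if config.n_regions == 0:
        truth = {"enriched_states": list(config.enriched_states), "seed_counts": {}, "realized_rates": {}}
        return PeakSet(mark, condition, []), truth

    weights = np.ones(n_bins)
    enriched_mask = np.isin(labels, list(config.enriched_states))
    weights[enriched_mask] = config.enrichment_odds
    weights /= weights.sum()
    n_seed = min(config.n_regions, n_bins)
    seeds = rng.choice(n_bins, size=n_seed, replace=False, p=weights)

    run = max(1, int(config.region_len_bins))
    regions = []
    for idx in seeds:
        chrom = chroms[idx]
        last = idx
        # extend across consecutive same-chromosome bins
        while last + 1 < n_bins and last - idx + 1 < run and chroms[last + 1] == chrom \
                and starts[last + 1] == ends[last]:
            last += 1
        regions.append(GenomicInterval(chrom, int(starts[idx]), int(ends[last])))

    peaks = PeakSet(mark, condition, regions)
    seed_counts = np.bincount(labels[seeds] - 1, minlength=config.n_states)
    totals = segmentation.state_totals()
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(totals > 0, seed_counts / np.maximum(totals, 1), np.nan)
    truth = {
        "enriched_states": list(config.enriched_states),
        "enrichment_odds": config.enrichment_odds,
        "n_regions": n_seed,
        "seed_counts": {int(i + 1): int(c) for i, c in enumerate(seed_counts)},
        "realized_rates": {int(i + 1): float(r) for i, r in enumerate(rates)},
    }
    return peaks, truth


# ---------------------------------------------------------------------------
# PLAD signal tracks


def _plad_levels(
    config: SimulationConfig, plads_on: list[GenomicInterval], size: int, which: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact piecewise-constant level geometry for one chromosome."""
    bg = config.background_level
    pieces = []  # (start, end, level); later pieces overwrite earlier
    pieces.append((0, size, bg))
    for p in plads_on:
        if which == "body":
            pieces.append((p.start, p.end, config.body_mark_level))
        else:
            border = max(1, int(round(p.length * config.border_fraction)))
            out = config.border_outside_bp
            lvl = config.border_mark_level
            pieces.append((max(0, p.start - out), p.start + border, lvl))
            pieces.append((p.end - border, min(size, p.end + out), lvl))
    # flatten to disjoint intervals: paint onto breakpoints
    bps = sorted({b for s, e, _ in pieces for b in (s, e)})
    bps = [b for b in bps if 0 <= b <= size]
    starts = np.array(bps[:-1], dtype=np.int64)
    ends = np.array(bps[1:], dtype=np.int64)
    levels = np.full(len(starts), bg)
    for s, e, lvl in pieces[1:]:
        sel = (starts >= s) & (ends <= e)
        levels[sel] = lvl
    return starts, ends, levels


def simulate_plad_signal(
    config: SimulationConfig,
    plads: list[GenomicInterval],
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[SignalTrack, SignalTrack]:
    """Signal tracks for a PLAD-body mark and a PLAD-border mark.

    The body mark sits at ``body_mark_level`` across each PLAD; the border
    mark sits at ``border_mark_level`` over the outer ``border_fraction``
    of each PLAD plus ``border_outside_bp`` beyond each edge; everywhere
    else both rest at ``background_level``. With ``signal_noise`` on,
    values are Poisson-perturbed per ``signal_step_bp`` step (mean equal to
    the configured level); with noise off the tracks equal the configured
    levels exactly.
    """
    chrom_sizes = chrom_sizes or config.chrom_sizes
    rng = config.rng("signal")
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_sizes}
    for p in plads:
        by_chrom.setdefault(p.chrom, []).append(p)

    tracks = []
    for which in ("body", "border"):
        data = {}
        for chrom, size in chrom_sizes.items():
            starts, ends, levels = _plad_levels(config, by_chrom.get(chrom, []), size, which)
            if not config.signal_noise:
                data[chrom] = (starts, ends, levels)
                continue
            step = config.signal_step_bp
            edges = np.arange(0, size + step, step)
            edges[-1] = min(edges[-1], size)
            mids = (edges[:-1] + edges[1:]) / 2
            idx = np.clip(np.searchsorted(ends, mids, side="right"), 0, len(levels) - 1)
            mean = levels[idx]
            m = config.poisson_events_per_unit
            vals = rng.poisson(mean * m).astype(float) / m
            data[chrom] = (edges[:-1], edges[1:], vals)
        tracks.append(SignalTrack(data))
    return tracks[0], tracks[1]


# ---------------------------------------------------------------------------
# Expression tables


def simulate_expression(
    config: SimulationConfig,
    genes: list[GeneModel],
    mark_loss_genes: set[str],
) -> tuple[pd.DataFrame, dict]:
    """Replicate FPKM table with a planted upregulation in mark-loss genes.

    Baseline FPKM is log-normal per gene. Each gene is independently
    DE-selected with probability ``de_fraction``; genes that are both
    DE-selected and in ``mark_loss_genes`` get their mutant-condition mean
    shifted by ``de_log2fc_mean`` log2 units. Replicates carry
    multiplicative noise of ``fpkm_noise_sd`` log2 units.

    Returns the wide table (columns ``wt_1..n, mutant_1..n``, index
    gene_id) and a ground-truth record naming the shifted genes.
    """
    gene_ids = [g.gene_id for g in genes]
    unknown = set(mark_loss_genes) - set(gene_ids)
    if unknown:
        raise ValueError(f"mark_loss_genes not in gene set: {sorted(unknown)[:5]}...")
    rng = config.rng("expression")
    n = len(gene_ids)
    baseline = rng.lognormal(np.log(10.0), 1.0, n)
    de_selected = rng.random(n) < config.de_fraction
    in_loss = np.array([gid in mark_loss_genes for gid in gene_ids])
    shifted = de_selected & in_loss
    log2fc = np.where(shifted, config.de_log2fc_mean, 0.0)

    cols = {}
    for cond, mean in (("wt", baseline), ("mutant", baseline * 2.0 ** log2fc)):
        for rep in range(1, config.n_replicates + 1):
            noise = (
                2.0 ** rng.normal(0.0, config.fpkm_noise_sd, n)
                if config.fpkm_noise_sd > 0
                else np.ones(n)
            )
            cols[f"{cond}_{rep}"] = mean * noise
    table = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    truth = {
        "shifted_genes": [gid for gid, s in zip(gene_ids, shifted) if s],
        "de_log2fc_mean": config.de_log2fc_mean,
    }
    return table, truth


# ---------------------------------------------------------------------------
# qPCR CT tables


def simulate_qpcr(
    config: SimulationConfig,
    true_folds: dict[str, float],
    ct_noise_sd: float = 0.0,
    reference_ct: float = 15.0,
    control_delta_ct: float = 5.0,
) -> pd.DataFrame:
    """CT table (long form) whose ΔΔCT analysis recovers ``true_folds``.

    Columns: target, sample (test/control), assay (target/reference),
    replicate, ct. ΔΔCT = ΔCT(test) − ΔCT(control) = −log2(fold).
    """
    rng = config.rng("qpcr")
    rows = []
    for target, fold in true_folds.items():
        if fold <= 0:
            raise ValueError("fold values must be positive")
        ddct = -np.log2(fold)
        for rep in range(1, config.n_replicates + 1):
            noise = lambda: rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
            rows += [
                (target, "control", "reference", rep, reference_ct + noise()),
                (target, "control", "target", rep, reference_ct + control_delta_ct + noise()),
                (target, "test", "reference", rep, reference_ct + noise()),
                (target, "test", "target", rep, reference_ct + control_delta_ct + ddct + noise()),
            ]
    return pd.DataFrame(rows, columns=["target", "sample", "assay", "replicate", "ct"])


# ---------------------------------------------------------------------------
# One-stop fixture writer


def simulate_all(config: SimulationConfig, outdir) -> dict:
    """Generate a full fixture set, write it to ``outdir`` in the standard
    flat-file formats, and return a manifest dict with the ground truth."""
    from pathlib import Path

    from .annotation import assign_peaks_to_genes
    from .genome import write_bed, write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, segmentation, plads = simulate_genome(config)
    regions, region_truth = simulate_differential_regions(config, segmentation)
    body_track, border_track = simulate_plad_signal(config, plads, config.chrom_sizes)
    assignment = assign_peaks_to_genes(regions, genes)
    mark_loss = set(assignment.gene_ids)
    expr, expr_truth = simulate_expression(config, genes, mark_loss)

    write_gff3(genes, outdir / "genes.gff3")
    segmentation.to_bed(outdir / "states.bed")
    write_bed(plads, outdir / "plads.bed")
    write_bed(regions.peaks, outdir / "diff_regions.bed")
    body_track.to_bedgraph(outdir / "plad_body_mark.bedGraph")
    border_track.to_bedgraph(outdir / "plad_border_mark.bedGraph")
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    with open(outdir / "chrom.sizes", "w") as fh:
        for c, s in config.chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")
    config.to_yaml(outdir / "config.yaml")

    manifest = {
        "config": config.to_dict(),
        "n_genes": len(genes),
        "n_bins": len(segmentation),
        "n_plads": len(plads),
        "n_regions": len(regions),
        "region_truth": region_truth,
        "mark_loss_genes": sorted(mark_loss),
        "expression_truth": expr_truth,
        "files": sorted(p.name for p in outdir.iterdir()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
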