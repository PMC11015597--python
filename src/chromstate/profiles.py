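"""Signal profiles: TSS-centred matrices, percent-scaled meta-gene
profiles, standardized region (PLAD) profiles, and profile clustering.

All profile values are mean signal density per positional bin, so results
are comparable across bin widths. Gene profiles are strand-oriented
(upstream on the left); region profiles are unstranded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genome import GeneModel, GenomicInterval, SignalTrack


@dataclass
class ProfileMatrix:
    """Per-entity signal profile: rows are genes/regions, columns are
    positional bins under a recorded coordinate scheme."""

    matrix: pd.DataFrame  # rows: entity ids; columns: ordered bin labels
    scheme: str  # "tss", "metagene", or "region"
    mark: str = ""
    condition: str = ""

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)

    def mean_profile(self) -> pd.Series:
        return self.matrix.mean(axis=0)

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="entity_id")


def _oriented_edges(center_left: float, center_right: float, bin_bp: int, strand: str):
    """Bin edges around a window; column order flips for − strand."""
    edges = np.arange(center_left, center_right + bin_bp, bin_bp, dtype=np.float64)
    edges = edges[edges <= center_right + 1e-9]
    if edges[-1] < center_right:
        edges = np.append(edges, center_right)
    return edges


def _window_means(
    track: SignalTrack, chrom: str, edges: np.ndarray, chrom_size: int | None
) -> np.ndarray:
    """Mean density per bin; clipped bins average only their covered bases
    and bins entirely outside the chromosome read 0."""
    lo, hi = edges[:-1].copy(), edges[1:].copy()
    if chrom_size is not None:
        lo_c = np.clip(lo, 0, chrom_size)
        hi_c = np.clip(hi, 0, chrom_size)
    else:
        lo_c = np.clip(lo, 0, None)
        hi_c = np.clip(hi, 0, None)
    width = hi_c - lo_c
    out = np.zeros(len(lo))
    ok = width > 0
    if chrom in track.chroms and ok.any():
        ints = track.integral(chrom, lo_c[ok], hi_c[ok])
        out[ok] = ints / width[ok]
    return out


def tss_matrix(
    track: SignalTrack,
    genes: list[GeneModel],
    flank_bp: int = 1000,
    bin_bp: int = 50,
    chrom_sizes: dict[str, int] | None = None,
    mark: str = "",
    condition: str = "",
) -> ProfileMatrix:
    """Mean signal in fixed bins across ±``flank_bp`` around each TSS.

    Columns run upstream→downstream regardless of strand and are labelled
    by the bin's downstream-positive start offset (−1000, −950, … 950 for
    the defaults).
    """
    if flank_bp % bin_bp:
        raise ValueError("flank_bp must be divisible by bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    cols = [str(-flank_bp + i * bin_bp) for i in range(n_bins)]
    rows = {}
    for g in genes:
        size = None if chrom_sizes is None else chrom_sizes.get(g.chrom)
        if g.strand == "+":
            edges = g.tss - flank_bp + np.arange(n_bins + 1) * bin_bp
            vals = _window_means(track, g.chrom, edges.astype(float), size)
        else:
            # window mirrored around the − strand TSS (base tss inclusive)
            edges = (g.tss + 1) - flank_bp + np.arange(n_bins + 1) * bin_bp
            vals = _window_means(track, g.chrom, edges.astype(float), size)[::-1]
        rows[g.gene_id] = vals
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return ProfileMatrix(mat, "tss", mark, condition)


def metagene_profile(
    track: SignalTrack,
    genes: list[GeneModel],
    flank_bp: int = 1000,
    body_bins: int = 50,
    flank_bin_bp: int = 50,
    chrom_sizes: dict[str, int] | None = None,
    mark: str = "",
    condition: str = "",
) -> ProfileMatrix:
    """Meta-gene matrix: fixed-bp flanks plus a percent-scaled gene body.

    Each gene body is resampled into ``body_bins`` equal percentile slices
    so genes of different lengths align; 1-kb flanks (default) stay in
    fixed 50-bp bins. Genes shorter than ``body_bins`` bases are skipped
    with a warning. Strand-oriented.
    """
    if not genes:
        raise ValueError("empty gene list")
    if flank_bp % flank_bin_bp:
        raise ValueError("flank_bp must be divisible by flank_bin_bp")
    nf = flank_bp // flank_bin_bp
    cols = (
        [f"u{-flank_bp + i * flank_bin_bp}" for i in range(nf)]
        + [f"b{int(round(100 * (i + 0.5) / body_bins))}%_{i}" for i in range(body_bins)]
        + [f"d{i * flank_bin_bp}" for i in range(nf)]
    )
    rows = {}
    skipped = 0
    for g in genes:
        L = g.body.length
        if L < body_bins:
            skipped += 1
            continue
        size = None if chrom_sizes is None else chrom_sizes.get(g.chrom)
        s, e = g.body.start, g.body.end
        up = s - flank_bp + np.arange(nf + 1, dtype=np.float64) * flank_bin_bp
        body = s + np.arange(body_bins + 1, dtype=np.float64) * (L / body_bins)
        down = e + np.arange(nf + 1, dtype=np.float64) * flank_bin_bp
        vu = _window_means(track, g.chrom, up, size)
        vb = _window_means(track, g.chrom, body, size)
        vd = _window_means(track, g.chrom, down, size)
        vals = np.concatenate([vu, vb, vd])
        if g.strand == "-":
            vals = vals[::-1]
        rows[g.gene_id] = vals
    if skipped:
        warnings.warn(f"metagene_profile: skipped {skipped} genes shorter than {body_bins} bp")
    if not rows:
        raise ValueError("no gene long enough for the requested body bins")
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return ProfileMatrix(mat, "metagene", mark, condition)


def region_scaled_profile(
    track: SignalTrack,
    regions: list[GenomicInterval],
    target_bp: int = 3000,
    flank_bp: int = 2000,
    bin_bp: int = 50,
    chrom_sizes: dict[str, int] | None = None,
    mark: str = "",
    condition: str = "",
) -> ProfileMatrix:
    """Region matrix with bodies standardized to ``target_bp``.

    Each region interior is resampled into ``target_bp / bin_bp`` equal
    slices; flanks stay in fixed ``bin_bp`` bins. Unstranded. Regions with
    fewer bases than interior bins are skipped with a warning.
    """
    if not regions:
        raise ValueError("empty region list")
    if target_bp % bin_bp or flank_bp % bin_bp:
        raise ValueError("target_bp and flank_bp must be divisible by bin_bp")
    nb = target_bp // bin_bp
    nf = flank_bp // bin_bp
    cols = (
        [f"u{-flank_bp + i * bin_bp}" for i in range(nf)]
        + [f"r{i}" for i in range(nb)]
        + [f"d{i * bin_bp}" for i in range(nf)]
    )
    rows = {}
    skipped = 0
    for i, r in enumerate(regions):
        if r.length < nb:
            skipped += 1
            continue
        size = None if chrom_sizes is None else chrom_sizes.get(r.chrom)
        up = r.start - flank_bp + np.arange(nf + 1, dtype=np.float64) * bin_bp
        body = r.start + np.arange(nb + 1, dtype=np.float64) * (r.length / nb)
        down = r.end + np.arange(nf + 1, dtype=np.float64) * bin_bp
        rows[f"{r.chrom}:{r.start}-{r.end}"] = np.concatenate(
            [
                _window_means(track, r.chrom, up, size),
                _window_means(track, r.chrom, body, size),
                _window_means(track, r.chrom, down, size),
            ]
        )
    if skipped:
        warnings.warn(f"region_scaled_profile: skipped {skipped} short regions")
    if not rows:
        raise ValueError("no region long enough for the requested interior bins")
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return ProfileMatrix(mat, "region", mark, condition)


@dataclass
class ClusterAssignment:
    """k-means cluster labels C1..Ck (ordered by descending size) plus
    per-cluster mean profiles for each input matrix."""

    labels: dict[str, str]
    k: int
    cluster_means: dict[str, pd.DataFrame] = field(default_factory=dict)

    def members(self, cluster: str) -> list[str]:
        return [e for e, c in self.labels.items() if c == cluster]

    def sizes(self) -> dict[str, int]:
        out = {f"C{i + 1}": 0 for i in range(self.k)}
        for c in self.labels.values():
            out[c] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["entity_id", "cluster"]
        )


def cluster_profiles(
    matrices: list[ProfileMatrix], k: int = 8, seed: int = 0, n_init: int = 10
) -> ClusterAssignment:
    """Cluster entities on their concatenated, per-matrix standardized
    profiles with seeded k-means.

    All matrices must share an identical row set (e.g., the same genes
    profiled for several marks and conditions). Labels C1..Ck are assigned
    in order of descending cluster size; empty clusters raise a warning.
    """
    if not matrices:
        raise ValueError("no matrices to cluster")
    ids = list(matrices[0].matrix.index)
    for m in matrices[1:]:
        if list(m.matrix.index) != ids:
            raise ValueError("matrices must share an identical row set")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} rows available")

    feats = []
    for m in matrices:
        x = m.matrix.to_numpy(dtype=float)
        mu = x.mean()
        sd = x.std()
        feats.append((x - mu) / sd if sd > 0 else x - mu)
    X = np.hstack(feats)

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    if np.any(sizes == 0):
        warnings.warn("cluster_profiles: some clusters are empty")
    order = np.argsort(-sizes, kind="stable")
    rank = {int(old): f"C{new + 1}" for new, old in enumerate(order)}
    labels = {gid: rank[int(c)] for gid, c in zip(ids, raw)}

    means = {}
    for mi, m in enumerate(matrices):
        key = f"{m.mark or 'mark'}/{m.condition or 'cond'}/{mi}"
        grouped = m.matrix.groupby(pd.Series(labels, index=m.matrix.index)).mean()
        means[key] = grouped
    return ClusterAssignment(labels, k, means)


def profile_contrast(a: ProfileMatrix | pd.Series, b: ProfileMatrix | pd.Series) -> pd.DataFrame:
    """Column-aligned difference and ratio of two averaged profiles.

    Accepts ProfileMatrix (averaged over rows) or precomputed Series.
    Ratios where b is 0 are NaN. Mismatched column schemes are an error.
    """
    pa = a.mean_profile() if isinstance(a, ProfileMatrix) else a
    pb = b.mean_profile() if isinstance(b, ProfileMatrix) else b
    if list(pa.index) != list(pb.index):
        raise ValueError("profiles have mismatched column schemes")
    diff = pa - pb
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pb.to_numpy() != 0, pa.to_numpy() / pb.to_numpy(), np.nan)
    return pd.DataFrame({"column": pa.index, "a": pa.values, "b": pb.values,
                         "difference": diff.values, "ratio": ratio}).set_index("column")
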