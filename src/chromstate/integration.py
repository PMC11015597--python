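"""Epigenome–transcriptome integration and qPCR validation math.

Differentially expressed genes (DEGs) are called from replicate FPKM
tables on the median fold change (|log2FC| >= 0.6 and P <= 0.05,
inclusive); DEG sets are then intersected with differential-mark gene
sets; relative fold enrichment (RFE) from qPCR follows 2^-ΔΔCT with the
SD taken over replicate ΔΔCT values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionTable:
    """Replicate FPKM values for two conditions, one row per gene.

    Wide layout with columns ``<condition>_<replicate>`` (e.g. ``wt_1``,
    ``mutant_3``). The fold change is computed from the per-condition
    median FPKM with a pseudocount:

        log2FC = log2((median_mut + eps) / (median_wt + eps))

    ``eps`` (default 0.01 FPKM) is recorded on the instance.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        condition_test: str = "mutant",
        condition_ref: str = "wt",
        eps: float = 0.01,
    ):
        self.frame = frame
        self.condition_test = condition_test
        self.condition_ref = condition_ref
        self.eps = float(eps)
        self._cols = {
            cond: [c for c in frame.columns if c.startswith(cond + "_")]
            for cond in (condition_ref, condition_test)
        }
        for cond, cols in self._cols.items():
            if not cols:
                raise ValueError(f"no replicate columns for condition {cond!r}")
        if (frame[self.replicate_columns] < 0).any().any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def replicate_columns(self) -> list[str]:
        return self._cols[self.condition_ref] + self._cols[self.condition_test]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    def n_replicates(self, condition: str) -> int:
        return len(self._cols[condition])

    def median(self, condition: str) -> pd.Series:
        return self.frame[self._cols[condition]].median(axis=1)

    def log2fc(self) -> pd.Series:
        """Median-based log2 fold change, test over reference."""
        m_t = self.median(self.condition_test)
        m_r = self.median(self.condition_ref)
        return np.log2((m_t + self.eps) / (m_r + self.eps))

    def welch_pvalues(self) -> pd.Series:
        """Welch's t-test on log2(FPKM + 1) across replicates.

        Zero-variance-in-both-groups rows are undefined under the t
        statistic; they are mapped to p=0 when the group means differ and
        p=1 when they coincide, so noiseless tables behave as exact calls.
        """
        a = np.log2(self.frame[self._cols[self.condition_test]].to_numpy() + 1.0)
        b = np.log2(self.frame[self._cols[self.condition_ref]].to_numpy() + 1.0)
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValueError("Welch's t-test needs >= 2 replicates per condition")
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
        p[degenerate] = np.where(
            a.mean(axis=1)[degenerate] != b.mean(axis=1)[degenerate], 0.0, 1.0
        )
        return pd.Series(p, index=self.frame.index)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0), **kwargs)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def call_degs(
    table: ExpressionTable,
    fc_threshold: float = 0.6,
    p_threshold: float = 0.05,
    test: str = "welch_t_log",
    pvalues: pd.Series | None = None,
) -> pd.DataFrame:
    """Call DEGs at |log2FC| >= ``fc_threshold`` and P <= ``p_threshold``.

    Both threshold comparisons are inclusive. ``test="welch_t_log"``
    computes P-values from the replicates; ``test="none"`` consumes the
    supplied ``pvalues`` series instead. Returns a frame with columns
    gene_id (index), log2fc, pvalue, direction in {up, down, ns}.
    """
    lfc = table.log2fc()
    if test == "welch_t_log":
        p = table.welch_pvalues()
    elif test == "none":
        if pvalues is None:
            raise ValueError("test='none' requires a pvalues series")
        p = pvalues.reindex(table.frame.index)
        if p.isna().any():
            raise ValueError("pvalues missing for some genes")
    else:
        raise ValueError(f"unknown test {test!r}")
    called = (lfc.abs() >= fc_threshold) & (p <= p_threshold)
    direction = np.where(~called, "ns", np.where(lfc > 0, "up", "down"))
    return pd.DataFrame(
        {"log2fc": lfc, "pvalue": p, "direction": direction}, index=table.frame.index
    )


def deg_sets(degs: pd.DataFrame) -> dict[str, set[str]]:
    """Up/down gene-id sets from a call_degs frame."""
    return {
        "up": set(degs.index[degs["direction"] == "up"]),
        "down": set(degs.index[degs["direction"] == "down"]),
    }


@dataclass
class IntersectionResult:
    """Cross-tab of DEG directions against differential-mark gene sets."""

    table: pd.DataFrame  # columns: direction, mark_change, size
    gene_sets: dict[tuple[str, str], set[str]]

    def genes(self, direction: str, mark_change: str) -> set[str]:
        return self.gene_sets[(direction, mark_change)]


def intersect_deg_marks(
    degs: pd.DataFrame, assignments: dict[str, set[str]]
) -> IntersectionResult:
    """Intersect DEG direction sets with differential-mark gene sets.

    ``assignments`` maps a mark-change label (e.g. "H3K27me3_lower_mutant")
    to the gene ids carrying that change. For every (direction,
    mark-change) pair the exact identifier intersection and its size are
    returned — the operation behind statements like "genes with lower
    repressive-mark deposition and upregulated expression".
    """
    dsets = deg_sets(degs)
    rows = []
    gene_sets = {}
    for direction, dgenes in dsets.items():
        for label, mgenes in assignments.items():
            inter = dgenes & set(mgenes)
            gene_sets[(direction, label)] = inter
            rows.append((direction, label, len(inter)))
    return IntersectionResult(
        pd.DataFrame(rows, columns=["direction", "mark_change", "size"]), gene_sets
    )


# ---------------------------------------------------------------------------
# qPCR: ΔΔCT and relative fold enrichment


@dataclass
class QpcrRecord:
    """Replicate CT values for one target across the four assay cells.

    ``ct_*`` arrays are paired by replicate index. ΔCT = CT(target assay)
    − CT(reference assay) within each sample; ΔΔCT = ΔCT(test) −
    ΔCT(control).
    """

    target: str
    ct_target_test: np.ndarray
    ct_ref_test: np.ndarray
    ct_target_control: np.ndarray
    ct_ref_control: np.ndarray

    def __post_init__(self):
        arrs = [
            np.asarray(a, dtype=float)
            for a in (
                self.ct_target_test,
                self.ct_ref_test,
                self.ct_target_control,
                self.ct_ref_control,
            )
        ]
        if len({a.shape for a in arrs}) != 1:
            raise ValueError("replicate arrays must have matching lengths")
        if any(not np.all(np.isfinite(a)) for a in arrs):
            raise ValueError("CT values must be finite")
        (
            self.ct_target_test,
            self.ct_ref_test,
            self.ct_target_control,
            self.ct_ref_control,
        ) = arrs

    def delta_delta_ct(self) -> np.ndarray:
        d_test = self.ct_target_test - self.ct_ref_test
        d_ctrl = self.ct_target_control - self.ct_ref_control
        return d_test - d_ctrl


def relative_fold_enrichment(record: QpcrRecord) -> tuple[float, float]:
    """RFE = 2^-ΔΔCT, reported as mean ± SD over replicate folds.

    Each replicate yields fold_r = 2^-ΔΔCT_r; the returned value is the
    mean fold and the sample SD across replicates (0 when replicates
    agree exactly or only one replicate exists).
    """
    folds = 2.0 ** (-record.delta_delta_ct())
    sd = float(np.std(folds, ddof=1)) if folds.size > 1 else 0.0
    return float(np.mean(folds)), sd


def rfe_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """RFE per target from a long-form CT table.

    Expects columns target, sample ∈ {test, control}, assay ∈ {target,
    reference}, replicate, ct — the layout qPCR instruments export after
    melting. Returns a frame with columns target, fold, sd.
    """
    required = {"target", "sample", "assay", "replicate", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"qPCR table must have columns {sorted(required)}")
    rows = []
    for target, sub in table.groupby("target"):
        pivot = sub.pivot_table(
            index="replicate", columns=["sample", "assay"], values="ct"
        )
        try:
            rec = QpcrRecord(
                target,
                pivot[("test", "target")].to_numpy(),
                pivot[("test", "reference")].to_numpy(),
                pivot[("control", "target")].to_numpy(),
                pivot[("control", "reference")].to_numpy(),
            )
        except KeyError as exc:
            raise ValueError(f"target {target}: missing sample/assay cell {exc}") from exc
        fold, sd = relative_fold_enrichment(rec)
        rows.append((target, fold, sd))
    return pd.DataFrame(rows, columns=["target", "fold", "sd"])


def check_inclusion_exclusion(a: set, b: set, c: set) -> bool:
    """|A∪B∪C| identity over three sets — sanity invariant for set algebra."""
    lhs = len(a | b | c)
    rhs = (
        len(a) + len(b) + len(c)
        - len(a & b) - len(a & c) - len(b & c)
        + len(a & b & c)
    )
    return lhs == rhs
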