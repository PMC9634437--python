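"""Translation-efficiency (TE) analysis from paired transcriptome/translatome
count matrices.

TE for a gene is its abundance in the translatome (heavy-polysomal RNA, CPM)
divided by its abundance in the transcriptome (total RNA, CPM).  TE is
computed for every transcriptome-replicate x translatome-replicate pair
within a condition (the all-pairs scheme: R x P values per gene for R
transcriptome and P translatome replicates), averaged per condition, and the
TE ratio is the resistant-over-sensitive fold change of those means.

Significance: a two-sample Student t-test on log2 TE values per gene,
Benjamini-Hochberg adjusted across tested genes; a gene is called up if its
TE ratio exceeds ``ratio_threshold`` (default 1.25) with adjusted p <= alpha
(default 0.05), down if the ratio is below 1/ratio_threshold with adjusted
p <= alpha.  The t-test is run on log2(TE) rather than raw TE, which
symmetrizes ratios; the equal-variance (Student) variant is used here.

Zero handling: a TE pair with transcriptome CPM = 0 is a missing value, not
infinity.  Genes with fewer than 2 finite TE values in either condition are
``untestable`` and excluded from the BH family.  A configurable pseudo-CPM
(off by default) can be added to both fractions before the ratio instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

__all__ = [
    "TEResult",
    "TESummary",
    "cpm",
    "filter_expressed",
    "pairwise_te",
    "te_ratio_test",
    "summarize_te",
    "concordance_fraction",
    "run_te_pipeline",
]

TE_CLASSES = ("up", "down", "unchanged", "untestable")


@dataclass
class TEResult:
    """Per-gene TE statistics for a resistant-vs-sensitive comparison."""

    gene_id: str
    biotype: str
    te_values_by_condition: dict[str, np.ndarray]
    mean_te_by_condition: dict[str, float]
    te_ratio: float
    log2_te_ratio: float
    p_raw: float
    p_adj: float
    te_class: str

    @property
    def significant(self) -> bool:
        return self.te_class in ("up", "down")


@dataclass(frozen=True)
class TESummary:
    """Median log2 TE ratio over one group of genes."""

    group: str
    n: int
    median_log2_te_ratio: float


def cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million normalization: value / column total * 1e6."""
    if matrix.unit != "raw_counts":
        raise ValueError("cpm() expects a raw_counts matrix")
    totals = matrix.values.sum(axis=0)
    if np.any(totals <= 0):
        bad = [matrix.samples[i].sample_id for i in np.where(totals <= 0)[0]]
        raise ValueError(f"all-zero sample column(s): {bad}")
    return ExpressionMatrix(
        matrix.genes, matrix.samples, matrix.values / totals * 1e6, unit="CPM"
    )


def filter_expressed(
    transcriptome: ExpressionMatrix,
    translatome: ExpressionMatrix,
    min_cpm: float = 5.0,
    min_fraction_of_samples: float = 1.0,
) -> list[str]:
    """Genes detected at >= min_cpm CPM in enough samples of BOTH matrices.

    A gene is kept when its CPM is >= ``min_cpm`` (inclusive) in at least
    ``min_fraction_of_samples`` of the samples of each matrix.  Input order
    is preserved.
    """
    if transcriptome.gene_ids != translatome.gene_ids:
        raise ValueError("gene sets/order differ between matrices")
    for m in (transcriptome, translatome):
        if m.unit != "CPM":
            raise ValueError("filter_expressed expects CPM matrices")
    keep = []
    for i, gid in enumerate(transcriptome.gene_ids):
        ok = True
        for m in (transcriptome, translatome):
            frac = float(np.mean(m.values[i] >= min_cpm))
            if frac < min_fraction_of_samples:
                ok = False
                break
        if ok:
            keep.append(gid)
    return keep


def pairwise_te(
    transcriptome: ExpressionMatrix,
    translatome: ExpressionMatrix,
    condition: str,
    pseudo_cpm: float = 0.0,
) -> dict[str, np.ndarray]:
    """All-pairs TE values for one condition.

    Each transcriptome replicate is compared separately to each translatome
    replicate: for R transcriptome and P translatome replicates every gene
    gets an R x P vector of TE = translatome CPM / transcriptome CPM.  Pairs
    with transcriptome CPM of 0 (after any pseudo-CPM) are NaN.
    """
    for m in (transcriptome, translatome):
        if m.unit != "CPM":
            raise ValueError("pairwise_te expects CPM matrices")
    if transcriptome.gene_ids != translatome.gene_ids:
        raise ValueError("gene sets/order differ between matrices")
    t_idx = transcriptome.sample_indices(condition=condition, fraction="total")
    p_idx = translatome.sample_indices(condition=condition, fraction="polysomal")
    if not t_idx:
        raise ValueError(f"condition {condition!r} absent from transcriptome")
    if not p_idx:
        raise ValueError(f"condition {condition!r} absent from translatome")
    t_vals = transcriptome.values[:, t_idx] + pseudo_cpm  # genes x R
    p_vals = translatome.values[:, p_idx] + pseudo_cpm  # genes x P
    # genes x R x P, flattened to genes x (R*P)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = p_vals[:, None, :] / t_vals[:, :, None]
    te = te.reshape(len(transcriptome.genes), -1)
    te[~np.isfinite(te)] = np.nan
    return {gid: te[i] for i, gid in enumerate(transcriptome.gene_ids)}


def _log2_finite(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    return np.log2(v)


def _batch_student_ttest(
    group_a: Sequence[np.ndarray], group_b: Sequence[np.ndarray]
) -> np.ndarray:
    """Two-sided equal-variance t-test per row; NaN where untestable.

    Rows with fewer than 2 values in either group, or zero variance in both
    groups (degenerate statistic), get NaN.  Rows are NaN-padded to a common
    width and tested in a single vectorized scipy call.
    """
    n = len(group_a)
    width_a = max((len(v) for v in group_a), default=0)
    width_b = max((len(v) for v in group_b), default=0)
    a = np.full((n, max(width_a, 1)), np.nan)
    b = np.full((n, max(width_b, 1)), np.nan)
    for i, v in enumerate(group_a):
        a[i, : len(v)] = v
    for i, v in enumerate(group_b):
        b[i, : len(v)] = v
    n_a = np.isfinite(a).sum(axis=1)
    n_b = np.isfinite(b).sum(axis=1)
    testable = (n_a >= 2) & (n_b >= 2)
    var_sum = np.zeros(n)
    if testable.any():  # variance only where defined, avoiding dof warnings
        var_sum[testable] = np.nanvar(a[testable], axis=1) + np.nanvar(
            b[testable], axis=1
        )
    testable &= var_sum > 0
    p = np.full(n, np.nan)
    if testable.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(
                a[testable], b[testable], axis=1, equal_var=True, nan_policy="omit"
            )
        p[testable] = np.asarray(res.pvalue, dtype=float)
    return p


def te_ratio_test(
    te_sensitive: Mapping[str, np.ndarray],
    te_resistant: Mapping[str, np.ndarray],
    biotypes: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    ratio_threshold: float = 1.25,
    fdr_level: float = 0.10,
    sensitive_label: str = "sensitive",
    resistant_label: str = "resistant",
) -> list[TEResult]:
    """Test per-gene TE differences between conditions.

    A Student (equal-variance) t-test is run on the log2 TE values of each
    gene; Benjamini-Hochberg adjustment is applied across all tested genes.
    Classification: up if te_ratio > ratio_threshold and adjusted p <= alpha;
    down if te_ratio < 1/ratio_threshold and adjusted p <= alpha (symmetric
    on the log scale); otherwise unchanged.  Genes with fewer than 2 finite
    TE values in either condition, or with zero variance in both conditions,
    are untestable and excluded from the BH family.  ``fdr_level`` is carried
    in output metadata for reporting.
    """
    if not te_sensitive:
        raise ValueError("empty input")
    if set(te_sensitive) != set(te_resistant):
        raise ValueError("gene sets differ between conditions")
    gene_ids = list(te_sensitive)
    biotypes = biotypes or {}

    # Stack per-gene log2 TE vectors (NaN-padded) so the t-test runs once
    # across all genes instead of once per gene.
    s_logs = [_log2_finite(np.asarray(te_sensitive[g], dtype=float)) for g in gene_ids]
    r_logs = [_log2_finite(np.asarray(te_resistant[g], dtype=float)) for g in gene_ids]
    p_raw_all = _batch_student_ttest(r_logs, s_logs)

    results: list[TEResult] = []
    tested_idx: list[int] = []
    raw_ps: list[float] = []
    for i, gid in enumerate(gene_ids):
        s_vals = np.asarray(te_sensitive[gid], dtype=float)
        r_vals = np.asarray(te_resistant[gid], dtype=float)
        mean_s = float(np.nanmean(np.where(np.isfinite(s_vals), s_vals, np.nan))) if np.isfinite(s_vals).any() else math.nan
        mean_r = float(np.nanmean(np.where(np.isfinite(r_vals), r_vals, np.nan))) if np.isfinite(r_vals).any() else math.nan
        if mean_s and math.isfinite(mean_s) and math.isfinite(mean_r) and mean_s > 0:
            ratio = mean_r / mean_s
        else:
            ratio = math.nan
        log2_ratio = math.log2(ratio) if (math.isfinite(ratio) and ratio > 0) else math.nan

        p_raw = p_raw_all[i]
        testable = math.isfinite(p_raw)
        if not testable:
            p_raw = math.nan

        res = TEResult(
            gene_id=gid,
            biotype=biotypes.get(gid, "protein_coding"),
            te_values_by_condition={
                sensitive_label: s_vals,
                resistant_label: r_vals,
            },
            mean_te_by_condition={
                sensitive_label: mean_s,
                resistant_label: mean_r,
            },
            te_ratio=ratio,
            log2_te_ratio=log2_ratio,
            p_raw=p_raw,
            p_adj=math.nan,
            te_class="untestable",
        )
        results.append(res)
        if testable:
            tested_idx.append(i)
            raw_ps.append(p_raw)

    if tested_idx:
        _, p_adj, _, _ = multipletests(raw_ps, method="fdr_bh")
        for i, padj in zip(tested_idx, p_adj):
            res = results[i]
            res.p_adj = float(padj)
            ratio = res.te_ratio
            if math.isfinite(ratio) and padj <= alpha:
                if ratio > ratio_threshold:
                    res.te_class = "up"
                elif ratio < 1.0 / ratio_threshold:
                    res.te_class = "down"
                else:
                    res.te_class = "unchanged"
            else:
                res.te_class = "unchanged"
    return results


def summarize_te(
    results: Sequence[TEResult],
    significant_only: bool = False,
    by_biotype: bool = False,
    mrna_biotypes: frozenset[str] = frozenset({"protein_coding"}),
) -> list[TESummary]:
    """Median log2 TE ratios over gene groups.

    With ``significant_only`` the median covers genes with te_class in
    {up, down} exactly; with ``by_biotype`` results split into mRNA
    (protein_coding) and lncRNA (everything else) groups.  Medians are
    computed over finite log2 ratios only.
    """
    if significant_only:
        pool = [r for r in results if r.te_class in ("up", "down")]
        tag = "significant"
    else:
        pool = [r for r in results if r.te_class != "untestable"]
        tag = "all"

    def summarize(group: str, rs: Sequence[TEResult]) -> TESummary:
        vals = np.array(
            [r.log2_te_ratio for r in rs if math.isfinite(r.log2_te_ratio)]
        )
        med = float(np.median(vals)) if len(vals) else math.nan
        return TESummary(group=group, n=len(rs), median_log2_te_ratio=med)

    if not by_biotype:
        return [summarize(tag, pool)]
    mrna = [r for r in pool if r.biotype in mrna_biotypes]
    lnc = [r for r in pool if r.biotype not in mrna_biotypes]
    return [
        summarize(f"{tag}/mRNA", mrna),
        summarize(f"{tag}/lncRNA", lnc),
    ]


def concordance_fraction(
    set_a: Iterable[str], set_b: Iterable[str], rounding: str = "nearest"
) -> float:
    """Percentage of set_a also found in set_b: 100 * |A n B| / |A|.

    ``rounding`` is "nearest" (half away from zero at .5) or "floor".
    Example: an overlap of 119 genes out of 608 differentially transcribed
    genes gives 20 (nearest); 136 of 361 gives 37 (floor).
    """
    a, b = set(set_a), set(set_b)
    if not a:
        raise ValueError("set_a is empty")
    pct = 100.0 * len(a & b) / len(a)
    if rounding == "nearest":
        return float(math.floor(pct + 0.5))
    if rounding == "floor":
        return float(math.floor(pct))
    raise ValueError(f"unknown rounding {rounding!r}")


def run_te_pipeline(
    transcriptome_counts: ExpressionMatrix,
    translatome_counts: ExpressionMatrix,
    sensitive: str,
    resistant: str,
    min_cpm: float = 0.0,
    min_fraction_of_samples: float = 1.0,
    alpha: float = 0.05,
    ratio_threshold: float = 1.25,
    pseudo_cpm: float = 0.0,
) -> pd.DataFrame:
    """Counts in, TE result table out: CPM -> (optional) expression filter ->
    all-pairs TE -> t-test + BH -> classification.

    Returns a DataFrame with one row per gene (columns: gene_id, biotype,
    mean_te_sensitive, mean_te_resistant, te_ratio, log2_te_ratio, p_raw,
    p_adj, te_class).
    """
    trans_cpm = cpm(transcriptome_counts)
    poly_cpm = cpm(translatome_counts)
    biotypes = {g.gene_id: g.biotype for g in transcriptome_counts.genes}
    if min_cpm > 0:
        keep = set(
            filter_expressed(trans_cpm, poly_cpm, min_cpm, min_fraction_of_samples)
        )
    else:
        keep = set(trans_cpm.gene_ids)

    te_sens_t = pairwise_te(trans_cpm, poly_cpm, sensitive, pseudo_cpm)
    te_res_t = pairwise_te(trans_cpm, poly_cpm, resistant, pseudo_cpm)
    te_sens = {g: v for g, v in te_sens_t.items() if g in keep}
    te_res = {g: v for g, v in te_res_t.items() if g in keep}
    results = te_ratio_test(
        te_sens,
        te_res,
        biotypes=biotypes,
        alpha=alpha,
        ratio_threshold=ratio_threshold,
        sensitive_label=sensitive,
        resistant_label=resistant,
    )
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "biotype": [r.biotype for r in results],
            "mean_te_sensitive": [r.mean_te_by_condition[sensitive] for r in results],
            "mean_te_resistant": [r.mean_te_by_condition[resistant] for r in results],
            "te_ratio": [r.te_ratio for r in results],
            "log2_te_ratio": [r.log2_te_ratio for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "te_class": [r.te_class for r in results],
        }
    )
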