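"""Differential protein abundance across the three-line design
(parental VCaP, castration-resistant VCaP-CRPC, enzalutamide-resistant
VCaP-ER) and proteome-to-proteome correlation.

The differential-abundance rule: a protein is called up (down) when either
of the two ER comparisons — ER/VCaP or ER/CRPC fold change of group means —
exceeds the fold threshold (falls below its reciprocal) with p below the p
threshold, so long as the *other* ER comparison does not show a thresholded
variation in the opposite direction.  An opposite trend that fails either
threshold does not veto.  The CRPC/VCaP fold change is computed and reported
but never gates the call.  p-values are two-sided equal-variance t-tests on
log2 abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProteinDECall",
    "DECensus",
    "protein_de",
    "de_census",
    "correlate_proteomes",
]

GROUPS = ("VCaP", "CRPC", "ER")


@dataclass(frozen=True)
class ProteinDECall:
    """Fold changes, p-values and up/down/ns status for one protein."""

    protein_id: str
    group_means: Mapping[str, float]
    fc_er_vcap: float
    fc_er_crpc: float
    fc_crpc_vcap: float
    p_er_vcap: float
    p_er_crpc: float
    status: str  # up / down / ns


@dataclass(frozen=True)
class DECensus:
    n_tested: int
    n_de: int
    n_up: int
    n_down: int


def _passes(fc: float, p: float, fc_threshold: float, p_threshold: float) -> str:
    """'up', 'down', or '' for one comparison under the fold/p thresholds."""
    if not (math.isfinite(fc) and math.isfinite(p)) or p > p_threshold:
        return ""
    if fc > fc_threshold:
        return "up"
    if fc < 1.0 / fc_threshold:
        return "down"
    return ""


def protein_de(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    fc_threshold: float = 1.25,
    p_threshold: float = 0.05,
) -> list[ProteinDECall]:
    """Apply the fold-change/p-value/no-opposite-variation rule per protein.

    ``table`` holds abundances (proteins x sample columns, indexed by protein
    id); ``groups`` maps each sample column to VCaP, CRPC or ER.  The relaxed
    variant of the rule uses ``p_threshold=0.1``.
    """
    cols_by_group: dict[str, list[str]] = {g: [] for g in GROUPS}
    for col, grp in groups.items():
        if grp not in cols_by_group:
            raise ValueError(f"unknown group {grp!r} (expected one of {GROUPS})")
        if col not in table.columns:
            raise ValueError(f"sample column {col!r} not in table")
        cols_by_group[grp].append(col)
    for g, cols in cols_by_group.items():
        if len(cols) < 2:
            raise ValueError(f"group {g} has {len(cols)} replicates; need >=2")

    values = {g: table[cols].to_numpy(dtype=float) for g, cols in cols_by_group.items()}
    for g, v in values.items():
        if np.any(v <= 0) or np.any(~np.isfinite(v)):
            raise ValueError(f"group {g}: abundances must be positive and finite")
    means = {g: v.mean(axis=1) for g, v in values.items()}
    logs = {g: np.log2(v) for g, v in values.items()}

    def ttest(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, axis=1, equal_var=True)
        return np.asarray(res.pvalue, dtype=float)

    p_er_vcap = ttest(logs["ER"], logs["VCaP"])
    p_er_crpc = ttest(logs["ER"], logs["CRPC"])

    calls: list[ProteinDECall] = []
    for i, pid in enumerate(table.index):
        fc_ev = means["ER"][i] / means["VCaP"][i]
        fc_ec = means["ER"][i] / means["CRPC"][i]
        fc_cv = means["CRPC"][i] / means["VCaP"][i]
        call_ev = _passes(fc_ev, p_er_vcap[i], fc_threshold, p_threshold)
        call_ec = _passes(fc_ec, p_er_crpc[i], fc_threshold, p_threshold)
        if {"up", "down"} <= {call_ev, call_ec}:
            status = "ns"  # opposite thresholded variation vetoes the call
        elif call_ev or call_ec:
            status = call_ev or call_ec
        else:
            status = "ns"
        calls.append(
            ProteinDECall(
                protein_id=str(pid),
                group_means={g: float(means[g][i]) for g in GROUPS},
                fc_er_vcap=float(fc_ev),
                fc_er_crpc=float(fc_ec),
                fc_crpc_vcap=float(fc_cv),
                p_er_vcap=float(p_er_vcap[i]),
                p_er_crpc=float(p_er_crpc[i]),
                status=status,
            )
        )
    return calls


def de_census(calls: Sequence[ProteinDECall]) -> DECensus:
    """Counts of differentially abundant proteins by direction."""
    n_up = sum(1 for c in calls if c.status == "up")
    n_down = sum(1 for c in calls if c.status == "down")
    return DECensus(
        n_tested=len(calls), n_de=n_up + n_down, n_up=n_up, n_down=n_down
    )


def correlate_proteomes(
    query_profiles: pd.DataFrame,
    reference_profiles: pd.DataFrame,
    method: str = "pearson",
    query_groups: Mapping[str, str] | None = None,
    reference_groups: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Correlate each query replicate with each reference sample.

    Profiles are proteins x samples over a shared protein-identifier index;
    correlations (Pearson or Spearman) run over the intersection of protein
    ids (>= 3 required), pairwise-dropping missing values.  When
    ``query_groups`` labels query replicates with their cell line, a
    two-sided Student t-test compares the coefficient distributions between
    the two lines within each reference group (one group spanning all
    reference samples when ``reference_groups`` is None).

    Returns (coefficient table: query replicates x reference samples,
    t-test table or None).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    shared = query_profiles.index.intersection(reference_profiles.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared proteins; need >= 3")
    q = query_profiles.loc[shared]
    r = reference_profiles.loc[shared]
    corr = pd.DataFrame(
        index=q.columns, columns=r.columns, dtype=float
    )
    for qc in q.columns:
        for rc in r.columns:
            pair = pd.concat([q[qc], r[rc]], axis=1).dropna()
            if len(pair) < 3:
                corr.loc[qc, rc] = np.nan
                continue
            if method == "pearson":
                coef = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
            else:
                coef = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
            corr.loc[qc, rc] = float(coef)

    tests = None
    if query_groups:
        lines = sorted(set(query_groups.values()))
        if len(lines) != 2:
            raise ValueError("query_groups must label exactly 2 cell lines")
        ref_group_of = reference_groups or {c: "all" for c in r.columns}
        rows = []
        for ref_grp in sorted(set(ref_group_of.values())):
            ref_cols = [c for c in r.columns if ref_group_of[c] == ref_grp]
            by_line = {
                line: corr.loc[
                    [c for c in q.columns if query_groups[c] == line], ref_cols
                ].to_numpy().ravel()
                for line in lines
            }
            a = by_line[lines[0]][~np.isnan(by_line[lines[0]])]
            b = by_line[lines[1]][~np.isnan(by_line[lines[1]])]
            t, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append(
                {
                    "reference_group": ref_grp,
                    f"mean_r_{lines[0]}": float(np.mean(a)),
                    f"mean_r_{lines[1]}": float(np.mean(b)),
                    "t": float(t),
                    "p": float(p),
                }
            )
        tests = pd.DataFrame(rows)
    return corr, tests
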