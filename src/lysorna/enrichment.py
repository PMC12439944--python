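"""Lysosomal enrichment scores, knockout dependence ratios, and stratified summaries.

A gene's lysosomal enrichment E is the mean of its spike/capture-normalized
LysoIP replicate values divided by the mean of its normalized whole-cell
replicate values; E is undefined (NaN) when the whole-cell mean is zero —
no pseudocounts are used, since they would fabricate enrichment for
lyso-only detections. The dependence ratio D = E_ko / E_control quantifies
how much a gene's lysosomal entry relies on the knocked-out factor (D < 1:
dependent). Summaries stratify per-gene statistics by RNA class, protein
localization, or TOPscore bin, the latter with the conventional 3.0 boundary
separating strong 5' TOP motifs.
"""
from __future__ import annotations

import warnings
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import sample_columns

#: default TOPscore bin edges; right-closed bins so scores > 3.0 fall in the
#: top bin, matching the conventional strong-motif threshold
DEFAULT_TOPSCORE_EDGES = (0.0, 1.0, 2.0, 3.0, float("inf"))


def enrichment_from_columns(
    norm: pd.DataFrame, lyso_cols: Sequence[str], wc_cols: Sequence[str]
) -> pd.Series:
    """E = mean(lyso replicates) / mean(whole-cell replicates), per gene.

    NaN where the whole-cell mean is zero.
    """
    if not lyso_cols or not wc_cols:
        raise ValueError("need at least one lyso and one whole-cell replicate column")
    lyso_mean = norm[list(lyso_cols)].to_numpy(dtype=float).mean(axis=1)
    wc_mean = norm[list(wc_cols)].to_numpy(dtype=float).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(wc_mean > 0, lyso_mean / wc_mean, np.nan)
    return pd.Series(e, index=norm["gene_id"].to_numpy(), name="E")


def lysosomal_enrichment(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    genotype: str,
    treatment: str = "none",
) -> pd.Series:
    """Per-gene lysosomal enrichment for one genotype/treatment condition."""
    cond = design[(design["genotype"] == genotype) & (design["treatment"] == treatment)]
    lyso = cond.loc[cond["fraction"] == "lyso", "sample_id"].tolist()
    wc = cond.loc[cond["fraction"] == "whole_cell", "sample_id"].tolist()
    if not lyso or not wc:
        raise ValueError(
            f"condition ({genotype!r}, {treatment!r}) needs >= 1 lyso and "
            ">= 1 whole_cell sample"
        )
    return enrichment_from_columns(norm, lyso, wc)


def enrichment_table(norm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """E for every (genotype, treatment) condition that has both fractions."""
    out = pd.DataFrame({"gene_id": norm["gene_id"].to_numpy()})
    conditions = design[["genotype", "treatment"]].drop_duplicates()
    for _, (genotype, treatment) in conditions.iterrows():
        cond = design[(design["genotype"] == genotype) & (design["treatment"] == treatment)]
        fractions = set(cond["fraction"])
        if {"lyso", "whole_cell"} <= fractions:
            out[f"E_{genotype}_{treatment}"] = lysosomal_enrichment(
                norm, design, genotype, treatment
            ).to_numpy()
    return out


def dependence_ratio(e_ko: pd.Series, e_control: pd.Series) -> pd.Series:
    """D = E_ko / E_control per gene; NaN where either E is undefined or control is 0."""
    sym_diff = set(e_ko.index).symmetric_difference(e_control.index)
    if sym_diff:
        raise ValueError(f"enrichment columns cover different genes: {sorted(sym_diff)[:20]}")
    e_control = e_control.reindex(e_ko.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(
            e_control.to_numpy() > 0,
            e_ko.to_numpy() / e_control.to_numpy(),
            np.nan,
        )
    return pd.Series(d, index=e_ko.index, name="D")


def class_summary(
    values: pd.Series,
    annotation: pd.DataFrame,
    grouping: str = "rna_class",
    topscore_edges: Sequence[float] = DEFAULT_TOPSCORE_EDGES,
) -> pd.DataFrame:
    """n / median / quartiles of a per-gene statistic by annotation group.

    ``grouping`` is an annotation column name or ``"topscore_bin"``, which
    bins by TOPscore with right-closed edges (the default includes the 3.0
    strong-motif boundary). Empty groups are reported with n = 0 and NaN
    statistics.
    """
    ann = annotation.set_index("gene_id")
    vals = values.dropna()
    vals = vals[vals.index.isin(ann.index)]
    if grouping == "topscore_bin":
        groups = pd.cut(
            ann.loc[vals.index, "topscore"], bins=list(topscore_edges),
            right=True, include_lowest=True,
        )
    else:
        if grouping not in ann.columns:
            raise KeyError(f"annotation has no column {grouping!r}")
        groups = ann.loc[vals.index, grouping]
    rows = []
    grouped = vals.groupby(groups, observed=False)
    for name, sub in grouped:
        rows.append(
            {
                "group": str(name),
                "n": int(len(sub)),
                "median": float(sub.median()) if len(sub) else np.nan,
                "q1": float(sub.quantile(0.25)) if len(sub) else np.nan,
                "q3": float(sub.quantile(0.75)) if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def collapse_identical_trnas(
    counts: pd.DataFrame, sequences: Mapping[str, str]
) -> pd.DataFrame:
    """Sum count rows of tRNA genes whose sequences are identical.

    Each collapsed row is represented by the lexicographically first member
    id, with the full member list retained in a ``members`` column. Genes
    without a supplied sequence pass through uncollapsed with a warning.
    """
    out = counts.copy()
    has_seq = out["gene_id"].map(lambda g: g in sequences)
    if not has_seq.all():
        missing = out.loc[~has_seq, "gene_id"].tolist()
        warnings.warn(
            f"no sequence for {missing[:10]}; passed through uncollapsed",
            stacklevel=2,
        )
    scols = sample_columns(out)
    with_seq = out[has_seq].copy()
    with_seq["_seq"] = with_seq["gene_id"].map(sequences)
    collapsed_rows = []
    for _, grp in with_seq.groupby("_seq", sort=False):
        members = sorted(grp["gene_id"])
        row = grp.sort_values("gene_id").iloc[0].drop("_seq").copy()
        for c in scols:
            row[c] = grp[c].sum()
        row["members"] = ",".join(members)
        row["gene_id"] = members[0]
        collapsed_rows.append(row)
    passthrough = out[~has_seq].copy()
    if len(passthrough):
        passthrough["members"] = passthrough["gene_id"]
    pieces = [pd.DataFrame(collapsed_rows)] if collapsed_rows else []
    if len(passthrough):
        pieces.append(passthrough)
    result = pd.concat(pieces, ignore_index=True) if pieces else out.iloc[0:0].copy()
    return result.reset_index(drop=True)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Ties receive their mean rank. Returns NaN (undefined) when either
    vector is constant; requires >= 3 paired finite values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 paired finite values")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def delta_delta_ct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative RT-qPCR fold change, 2^-ddCT, with an internal reference gene."""
    values = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(np.isfinite(v) for v in values):
        raise ValueError("CT values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))
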