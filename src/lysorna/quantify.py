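"""Read-to-feature assignment counting: fractional multimapping, sequential-reference merging, RPK.

Alignment itself is out of scope; input is a tidy assignment table (one row
per read x candidate feature) as produced upstream of counting. A read
mapping to ``n`` loci contributes ``1/n`` to each, so total reads are
conserved exactly. References are searched sequentially (rRNA, tRNA, mito,
ncRNA, whole transcriptome); when a gene id occurs in several per-tier count
matrices the earliest tier wins.
"""
from __future__ import annotations

import warnings
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

#: columns that carry gene metadata rather than per-sample values
META_COLUMNS = ("gene_id", "biotype", "length_nt", "reference_tier")

ASSIGNMENT_COLUMNS = ("read_id", "sample_id", "feature_id", "n_locations", "reference_tier")


def sample_columns(counts: pd.DataFrame) -> List[str]:
    """Names of the per-sample numeric columns of a count matrix."""
    return [c for c in counts.columns if c not in META_COLUMNS]


def validate_assignments(assignments: pd.DataFrame) -> None:
    """Check the assignment-table invariants, raising on violation.

    Every (read_id, sample_id) must sit in exactly one reference tier and
    have exactly ``n_locations`` rows, all agreeing on ``n_locations``.
    """
    missing = set(ASSIGNMENT_COLUMNS) - set(assignments.columns)
    if missing:
        raise ValueError(f"assignment table missing columns: {sorted(missing)}")
    if (assignments["n_locations"] < 1).any():
        bad = assignments.loc[assignments["n_locations"] < 1, "read_id"].unique()
        raise ValueError(f"n_locations must be >= 1; offending reads: {list(bad[:10])}")
    grouped = assignments.groupby(["read_id", "sample_id"], sort=False)
    sizes = grouped.size()
    n_loc = grouped["n_locations"].agg(["min", "max"])
    tiers = grouped["reference_tier"].nunique()
    inconsistent = (
        (n_loc["min"] != n_loc["max"])
        | (sizes != n_loc["min"])
        | (tiers != 1)
    )
    if inconsistent.any():
        bad = [f"{r}/{s}" for r, s in inconsistent[inconsistent].index[:10]]
        raise ValueError(
            "assignment table invariant violated (row multiplicity, n_locations "
            f"or tier inconsistent) for reads: {bad}"
        )


def fractional_count(assignments: pd.DataFrame) -> pd.DataFrame:
    """Count reads into features, multimappers contributing 1/n_locations each.

    Returns a wide matrix (gene_id x sample columns). Per-sample column sums
    equal the number of distinct reads in that sample exactly (up to float
    accumulation), since each read distributes a total weight of 1.
    """
    validate_assignments(assignments)
    weighted = assignments.assign(_w=1.0 / assignments["n_locations"].to_numpy())
    wide = (
        weighted.pivot_table(
            index="feature_id", columns="sample_id", values="_w",
            aggfunc="sum", fill_value=0.0,
        )
        .rename_axis(index=None, columns=None)
    )
    out = wide.reset_index().rename(columns={"index": "gene_id"})
    return out


def merge_sequential_references(per_tier_counts: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-tier count matrices, keeping the first instance of each gene id.

    The input list must be ordered by reference tier (earliest first). If a
    retained id reappears later with a conflicting length, a warning is
    emitted and the earliest row kept.
    """
    if not per_tier_counts:
        raise ValueError("no count matrices to merge")
    frames = [df for df in per_tier_counts]
    merged = pd.concat(frames, ignore_index=True, sort=False)
    if "length_nt" in merged.columns:
        lengths = merged.dropna(subset=["length_nt"]).groupby("gene_id")["length_nt"].nunique()
        conflicts = lengths[lengths > 1]
        if len(conflicts):
            warnings.warn(
                f"conflicting lengths across tiers for {list(conflicts.index[:10])}; "
                "keeping earliest tier",
                stacklevel=2,
            )
    merged = merged.drop_duplicates(subset="gene_id", keep="first", ignore_index=True)
    return merged.fillna({c: 0.0 for c in sample_columns(merged)})


def rpk_normalize(
    counts: pd.DataFrame,
    lengths: Optional[pd.DataFrame] = None,
    enabled: bool = True,
) -> pd.DataFrame:
    """Divide counts by gene length in kilobases (count / (length_nt / 1000)).

    ``lengths`` may supply a (gene_id, length_nt) table when the matrix does
    not carry lengths. With ``enabled=False`` the matrix is returned
    unchanged (the pulse-chase pipeline skips length normalization).
    """
    if not enabled:
        return counts.copy()
    out = counts.copy()
    if "length_nt" not in out.columns:
        if lengths is None:
            raise ValueError("length_nt column absent and no lengths table supplied")
        out = out.merge(lengths[["gene_id", "length_nt"]], on="gene_id", how="left")
    length = out["length_nt"].to_numpy(dtype=float)
    bad = ~np.isfinite(length) | (length <= 0)
    if bad.any():
        ids = out.loc[bad, "gene_id"].tolist()
        raise ValueError(f"nonpositive or missing length for genes: {ids[:20]}")
    kb = length / 1000.0
    for col in sample_columns(out):
        out[col] = out[col].to_numpy(dtype=float) / kb
    return out
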