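"""Spike-in filtering, standard-curve slopes, and absolute-scale normalization.

Expression values of sample ``s`` are placed on a common absolute scale by
dividing by the slope of the per-sample ordinary-least-squares regression of
spike-in signal on known spike concentration, then multiplying by the
sample's capture-efficiency factor ``f_s`` (lysosome recovery, estimated
experimentally and supplied as design metadata). Spike-ins are first
filtered for adequate coverage — by default a spike must have >= 10 reads in
at least 75% of samples, generalizing the study design's 18-of-24 rule.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import rpk_normalize, sample_columns

SPIKE_META = ("spike_id", "known_concentration")


def spike_sample_columns(spikes: pd.DataFrame) -> List[str]:
    return [c for c in spikes.columns if c not in SPIKE_META]


def filter_spikeins(
    spikes: pd.DataFrame,
    min_reads: float = 10,
    min_sample_fraction: float = 0.75,
) -> pd.DataFrame:
    """Keep spikes with >= min_reads in at least ceil(fraction x n_samples) samples."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if not (0 < min_sample_fraction <= 1):
        raise ValueError("min_sample_fraction must lie in (0, 1]")
    cols = spike_sample_columns(spikes)
    if not cols:
        raise ValueError("spike table has no sample columns")
    needed = math.ceil(min_sample_fraction * len(cols))
    ok = (spikes[cols].to_numpy(dtype=float) >= min_reads).sum(axis=1) >= needed
    kept = spikes.loc[ok].reset_index(drop=True)
    if kept.empty:
        raise ValueError(
            "no spike-ins pass the coverage filter; relax min_reads or "
            "min_sample_fraction (regression is impossible without spikes)"
        )
    return kept


def fit_spike_slope(spikes: pd.DataFrame, sample_id: str) -> float:
    """OLS slope of spike signal on known concentration for one sample.

    The regression includes an intercept (which absorbs additive
    background) but only the slope is used downstream.
    """
    if sample_id not in spikes.columns:
        raise KeyError(f"sample {sample_id!r} not in spike table")
    x = spikes["known_concentration"].to_numpy(dtype=float)
    y = spikes[sample_id].to_numpy(dtype=float)
    if len(x) < 2 or np.unique(x).size < 2:
        raise ValueError(
            f"need >= 2 spikes with distinct concentrations to fit a slope "
            f"for sample {sample_id!r}"
        )
    slope = stats.linregress(x, y).slope
    if not np.isfinite(slope) or slope <= 0:
        raise ValueError(
            f"degenerate or inverted spike standard curve for sample "
            f"{sample_id!r}: slope {slope!r}"
        )
    return float(slope)


def normalize_sample(values: np.ndarray, beta: float, f: float) -> np.ndarray:
    """Divide by the spike slope, multiply by the capture factor: (v / beta) * f."""
    if beta <= 0:
        raise ValueError("spike slope must be positive")
    if f <= 0:
        raise ValueError("capture factor must be positive")
    return np.asarray(values, dtype=float) / beta * f


def normalize_counts(
    counts: pd.DataFrame,
    spikes: pd.DataFrame,
    design: pd.DataFrame,
    rpk: bool = False,
    min_reads: float = 10,
    min_sample_fraction: float = 0.75,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, float]]:
    """Spike/capture-normalize every sample of a count matrix.

    Returns (normalized gene matrix, normalized spike matrix, per-sample
    slopes). Samples are taken from the design table; each must appear as a
    column in both the count and spike tables, with a positive
    capture_factor. When ``rpk`` is true, gene counts are first divided by
    length in kb (spike signals are used as supplied).
    """
    missing = {"sample_id", "capture_factor"} - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    kept = filter_spikeins(spikes, min_reads=min_reads, min_sample_fraction=min_sample_fraction)
    genes = rpk_normalize(counts, enabled=rpk)
    norm_spikes = kept.copy()
    slopes: Dict[str, float] = {}
    for _, row in design.iterrows():
        s = row["sample_id"]
        f_s = float(row["capture_factor"])
        if not np.isfinite(f_s) or f_s <= 0:
            raise ValueError(f"capture factor for sample {s!r} must be positive")
        if s not in genes.columns:
            raise KeyError(f"sample {s!r} not in count matrix")
        beta = fit_spike_slope(kept, s)
        slopes[s] = beta
        genes[s] = normalize_sample(genes[s].to_numpy(), beta, f_s)
        norm_spikes[s] = normalize_sample(kept[s].to_numpy(), beta, f_s)
    return genes, norm_spikes, slopes
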