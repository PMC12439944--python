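"""5EU pulse-chase half-life estimation with a background-corrected exponential model.

Per gene, genotype and replicate, the log2 of the t0-normalized,
nLuc-normalized signal y at chase time x (hours) is fit by bounded
nonlinear least squares to

    y = log2(C * exp(-k * x)) + z            (background_mode="log_offset")

or, with the background entering as a linear-scale plateau,

    y = log2(C * exp(-k * x) + z)            (background_mode="linear_plateau")

where C (initial level) and k (decay rate, per hour) are constrained to
[0, inf) with starting values 2^max(y) and 1, and z is a fixed per-gene
background term derived from mock-IP samples. For Torin1-treated series C is
fixed to the fitted C of the untreated series of the same replicate, since
the initial level should not depend on a treatment applied after labeling.
Wald standard errors and two-sided p-values come from the Jacobian-based
covariance; only fits with p < 0.05 for k (and for C when it was free) are
retained. Half-life is ln(2)/k capped at 50 h; synthesis rate S = C * k.

The autophagy-dependent Torin1-induced stability value
A = (t_WT,Torin1 / t_WT) / (t_KO,Torin1 / t_KO) compares how Torin1 changes
half-lives in autophagy-competent versus autophagy-deficient cells; A < 1
means autophagy destabilizes the RNA upon mTORC1 inhibition.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

LN2 = math.log(2.0)

#: default half-life ceiling (hours)
HALFLIFE_CAP_H = 50.0

#: default floor inside the background term
BACKGROUND_FLOOR = 0.000005

_C_MIN = 1e-12  # positive lower bound so log2(C) stays finite


def nluc_normalize(
    timecourse: pd.DataFrame, nluc_id: str = "nLuc"
) -> pd.DataFrame:
    """Divide every gene's counts by the nLuc spike count of the same sample.

    A sample is one (genotype, treatment, replicate, time_h) combination;
    the nLuc row is removed from the output. Raises if nLuc is missing or
    nonpositive in any sample.
    """
    keys = ["genotype", "treatment", "replicate", "time_h"]
    nluc = timecourse[timecourse["gene_id"] == nluc_id]
    samples = timecourse[keys].drop_duplicates()
    merged_check = samples.merge(nluc, on=keys, how="left")
    bad = merged_check["count"].isna() | (merged_check["count"] <= 0)
    if bad.any():
        row = merged_check[bad].iloc[0]
        raise ValueError(
            f"nLuc spike missing or nonpositive in sample "
            f"({row['genotype']}, {row['treatment']}, rep {row['replicate']}, "
            f"t={row['time_h']} h)"
        )
    genes = timecourse[timecourse["gene_id"] != nluc_id].copy()
    genes = genes.merge(
        nluc[keys + ["count"]].rename(columns={"count": "_nluc"}), on=keys, how="left"
    )
    genes["count"] = genes["count"] / genes["_nluc"]
    return genes.drop(columns="_nluc")


def t0_normalize(values: np.ndarray, timepoints: np.ndarray) -> np.ndarray:
    """Divide a series by its t = 0 value so it starts at 1.

    Raises ValueError when there is no t = 0 point or its value is zero;
    callers exclude such genes and record them.
    """
    values = np.asarray(values, dtype=float)
    timepoints = np.asarray(timepoints, dtype=float)
    at0 = np.flatnonzero(timepoints == 0)
    if at0.size == 0:
        raise ValueError("series has no t = 0 point")
    v0 = values[at0[0]]
    if not np.isfinite(v0) or v0 <= 0:
        raise ValueError("t = 0 value is zero or undefined")
    return values / v0


def background_z(
    mock_values: Sequence[float],
    t0_spike_normalized_reads: float,
    floor: float = BACKGROUND_FLOOR,
    z_mode: str = "max_then_divide",
) -> float:
    """Per-gene background term from the mock-IP samples.

    ``max_then_divide`` (default): z = max(max(mocks), floor) / t0 reads —
    the floor competes with the mock values before the division.
    ``floor_quotient``: z = max(max(mocks), floor / t0 reads) — the floor is
    already a quotient. Both readings of the protocol are supported because
    its wording is ambiguous.
    """
    if t0_spike_normalized_reads <= 0:
        raise ValueError("t0 spike-normalized reads must be positive")
    mock_max = float(np.max(np.asarray(mock_values, dtype=float)))
    if z_mode == "max_then_divide":
        return max(mock_max, floor) / t0_spike_normalized_reads
    if z_mode == "floor_quotient":
        return max(mock_max, floor / t0_spike_normalized_reads)
    raise ValueError(f"unknown z_mode {z_mode!r}")


@dataclass
class DecayFit:
    """Result of one per-replicate exponential fit."""

    C: float
    k: float
    z: float
    se_C: float
    se_k: float
    p_C: float
    p_k: float
    halflife_h: float
    synthesis: float
    c_was_fixed: bool
    converged: bool
    sse: float
    n_points: int

    def to_dict(self) -> dict:
        return asdict(self)


def half_life(k: float, cap_h: float = HALFLIFE_CAP_H) -> float:
    """t1/2 = ln(2)/k, capped at ``cap_h``; k = 0 maps to the cap."""
    if k < 0:
        raise ValueError("decay rate k must be >= 0")
    if k == 0:
        return cap_h
    return min(LN2 / k, cap_h)


def _model_and_jac(background_mode: str):
    if background_mode == "log_offset":
        def predict(C, k, x, z):
            return np.log2(np.maximum(C, _C_MIN)) - k * x / LN2 + z

        def jac(C, k, x, z):
            dC = np.full_like(x, 1.0 / (max(C, _C_MIN) * LN2))
            dk = -x / LN2
            return dC, dk
    elif background_mode == "linear_plateau":
        def predict(C, k, x, z):
            u = np.maximum(C * np.exp(-k * x) + z, 1e-300)
            return np.log2(u)

        def jac(C, k, x, z):
            e = np.exp(-k * x)
            u = np.maximum(C * e + z, 1e-300)
            dC = e / (u * LN2)
            dk = -C * x * e / (u * LN2)
            return dC, dk
    else:
        raise ValueError(f"unknown background_mode {background_mode!r}")
    return predict, jac


def fit_decay(
    time_h: np.ndarray,
    y: np.ndarray,
    z: float,
    c_fixed: Optional[float] = None,
    cap_h: float = HALFLIFE_CAP_H,
    background_mode: str = "log_offset",
) -> DecayFit:
    """Bounded least-squares fit of the decay model to one log2 series.

    ``y`` is log2 of the t0-normalized signal. C and k are bounded to
    [0, inf) with starting values 2^max(y) and 1. When ``c_fixed`` is given
    only k is optimized and the returned C equals ``c_fixed`` exactly.
    Standard errors use the asymptotic covariance s^2 (J^T J)^-1 with
    residual degrees of freedom n - n_free; a k estimate at the zero
    boundary gets p_k = 1 (a boundary estimate is not evidence of decay).
    """
    x = np.asarray(time_h, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("time and value arrays must have the same length")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("time course contains non-finite values")
    n_free = 1 if c_fixed is not None else 2
    if x.size < n_free + 1:
        raise ValueError(
            f"need >= {n_free + 1} timepoints for {n_free} free parameter(s)"
        )
    predict, jacfun = _model_and_jac(background_mode)

    if c_fixed is not None:
        if c_fixed <= 0:
            raise ValueError("c_fixed must be positive")

        def residuals(theta):
            return predict(c_fixed, theta[0], x, z) - y

        def jacobian(theta):
            _, dk = jacfun(c_fixed, theta[0], x, z)
            return dk.reshape(-1, 1)

        theta0 = np.array([1.0])
        lower, upper = [0.0], [np.inf]
    else:

        def residuals(theta):
            return predict(theta[0], theta[1], x, z) - y

        def jacobian(theta):
            dC, dk = jacfun(theta[0], theta[1], x, z)
            return np.column_stack([dC, dk])

        c0 = max(float(2.0 ** np.max(y)), _C_MIN)
        theta0 = np.array([c0, 1.0])
        lower, upper = [_C_MIN, 0.0], [np.inf, np.inf]

    res = optimize.least_squares(
        residuals,
        theta0,
        jac=jacobian,
        bounds=(lower, upper),
        method="trf",
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
    )
    converged = bool(res.status > 0)
    if c_fixed is not None:
        C, k = float(c_fixed), float(res.x[0])
    else:
        C, k = float(res.x[0]), float(res.x[1])
    sse = float(2.0 * res.cost)
    dof = x.size - n_free
    se = np.full(n_free, np.nan)
    if dof > 0:
        J = jacobian(res.x)
        s2 = sse / dof
        JtJ = J.T @ J
        try:
            cov = s2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(JtJ)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    def wald_p(estimate: float, stderr: float) -> float:
        if dof <= 0 or not np.isfinite(stderr) or stderr == 0:
            return float("nan")
        t = abs(estimate) / stderr
        return float(2.0 * stats.t.sf(t, dof))

    if c_fixed is not None:
        se_C, p_C = float("nan"), float("nan")
        se_k = float(se[0])
        p_k = 1.0 if k == 0 else wald_p(k, se_k)
    else:
        se_C, se_k = float(se[0]), float(se[1])
        p_C = wald_p(C, se_C)
        p_k = 1.0 if k == 0 else wald_p(k, se_k)

    return DecayFit(
        C=C,
        k=k,
        z=float(z),
        se_C=se_C,
        se_k=se_k,
        p_C=p_C,
        p_k=p_k,
        halflife_h=half_life(k, cap_h),
        synthesis=C * k,
        c_was_fixed=c_fixed is not None,
        converged=converged,
        sse=sse,
        n_points=int(x.size),
    )


def fit_timecourse(
    timecourse: pd.DataFrame,
    mock: pd.DataFrame,
    nluc_id: str = "nLuc",
    floor: float = BACKGROUND_FLOOR,
    cap_h: float = HALFLIFE_CAP_H,
    background_mode: str = "log_offset",
    z_mode: str = "max_then_divide",
) -> pd.DataFrame:
    """Run the full per-replicate fitting pipeline on a long time-course table.

    Steps: nLuc normalization, t0 normalization, per-gene background term
    from the mock table, untreated fits (C and k free), then Torin1 fits
    with C fixed to the untreated C of the same replicate (free if no
    untreated fit exists). Returns one row per
    (gene, genotype, treatment, replicate) fit; genes with a zero t0 value
    are excluded and flagged in the ``excluded`` column of the attrs.
    """
    counts = nluc_normalize(timecourse, nluc_id=nluc_id)
    mock_cols = [c for c in mock.columns if c.startswith("mock_")]
    mock_idx = mock.set_index("gene_id")
    z_by_gene = {
        g: background_z(
            row[mock_cols].to_numpy(dtype=float), float(row["t0_reads"]),
            floor=floor, z_mode=z_mode,
        )
        for g, row in mock_idx.iterrows()
    }

    rows: List[dict] = []
    excluded: List[str] = []
    series_keys = ["gene_id", "genotype", "replicate"]
    for (gene, genotype, rep), grp in counts.groupby(series_keys, sort=True):
        if gene not in z_by_gene:
            raise KeyError(f"gene {gene!r} absent from mock table")
        z = z_by_gene[gene]
        fits_by_treatment: Dict[str, Optional[DecayFit]] = {}
        for treatment in ("none", "torin1"):
            sub = grp[grp["treatment"] == treatment].sort_values("time_h")
            if sub.empty:
                fits_by_treatment[treatment] = None
                continue
            x = sub["time_h"].to_numpy(dtype=float)
            v = sub["count"].to_numpy(dtype=float)
            try:
                normed = t0_normalize(v, x)
            except ValueError:
                excluded.append(f"{gene}/{genotype}/{treatment}/r{rep}")
                fits_by_treatment[treatment] = None
                continue
            with np.errstate(divide="ignore"):
                yvals = np.log2(normed)
            c_fixed = None
            if treatment == "torin1":
                untreated = fits_by_treatment.get("none")
                if untreated is not None:
                    c_fixed = untreated.C
            fit = fit_decay(
                x, yvals, z, c_fixed=c_fixed, cap_h=cap_h,
                background_mode=background_mode,
            )
            fits_by_treatment[treatment] = fit
            rows.append(
                {
                    "gene_id": gene,
                    "genotype": genotype,
                    "treatment": treatment,
                    "replicate": rep,
                    **fit.to_dict(),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out


def filter_fits(fits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep converged fits with p_k < alpha and (C fixed or p_C < alpha)."""
    keep = (
        fits["converged"].astype(bool)
        & (fits["p_k"] < alpha)
        & (fits["c_was_fixed"].astype(bool) | (fits["p_C"] < alpha))
    )
    return fits[keep.fillna(False)].reset_index(drop=True)


def average_replicates(fits: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of surviving per-replicate half-lives per condition."""
    grouped = fits.groupby(["gene_id", "genotype", "treatment"], sort=True)
    out = grouped.agg(
        halflife_h=("halflife_h", "mean"),
        n_replicates=("halflife_h", "size"),
    ).reset_index()
    return out


def stability_metric(
    hl_wt: float, hl_wt_torin: float, hl_ko: float, hl_ko_torin: float
) -> float:
    """A = (t_WT,Torin1 / t_WT) / (t_KO,Torin1 / t_KO)."""
    values = (hl_wt, hl_wt_torin, hl_ko, hl_ko_torin)
    if any(v is None or not np.isfinite(v) or v <= 0 for v in values):
        return float("nan")
    return (hl_wt_torin / hl_wt) / (hl_ko_torin / hl_ko)


def stability_table(
    halflives: pd.DataFrame,
    wt_genotype: str = "WT",
    ko_genotype: str = "ATG7_KO",
) -> pd.DataFrame:
    """Per-gene autophagy-dependent Torin1-induced stability values.

    ``halflives`` is the output of :func:`average_replicates`. A is defined
    only for genes with half-lives in all four (genotype, treatment)
    conditions.
    """
    wide = halflives.pivot_table(
        index="gene_id", columns=["genotype", "treatment"],
        values="halflife_h", aggfunc="first",
    )
    needed = [
        (wt_genotype, "none"), (wt_genotype, "torin1"),
        (ko_genotype, "none"), (ko_genotype, "torin1"),
    ]
    for col in needed:
        if col not in wide.columns:
            wide[col] = np.nan
    out = pd.DataFrame(
        {
            "gene_id": wide.index,
            "halflife_wt": wide[(wt_genotype, "none")].to_numpy(),
            "halflife_wt_torin": wide[(wt_genotype, "torin1")].to_numpy(),
            "halflife_ko": wide[(ko_genotype, "none")].to_numpy(),
            "halflife_ko_torin": wide[(ko_genotype, "torin1")].to_numpy(),
        }
    )
    out["stability"] = [
        stability_metric(w, wt, k, kt)
        for w, wt, k, kt in zip(
            out["halflife_wt"], out["halflife_wt_torin"],
            out["halflife_ko"], out["halflife_ko_torin"],
        )
    ]
    return out.reset_index(drop=True)
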