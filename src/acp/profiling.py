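"""Pearson correlation of protein abundance profiles with the activity profile.

Each protein's per-fraction profile is compared with the per-fraction
activity readout over the fractions common to both (by default the six
TMT-quantified fractions); duplicate activity measurements are averaged
per fraction first. Correlations are computed per technical replicate and
aggregated as mean +/- sample SD. Zero-variance (flat) profiles yield a
missing correlation (NaN), never 0 — missingness propagates to curation
as "fails threshold".
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import ActivityProfile
from .gradient import ProfileMatrix

__all__ = [
    "InsufficientOverlap",
    "pearson_r",
    "correlate_profiles",
    "aggregate_replicates",
    "peak_fraction",
    "peak_fractions",
    "mean_mass_by_peak",
]


class InsufficientOverlap(ValueError):
    """Fewer than the required number of common fractions."""


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors.

    Returns NaN (undefined) when either vector has zero variance, rather
    than raising or returning 0; invariant under positive affine maps of
    either argument.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0 or not np.isfinite(denom):
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def correlate_profiles(
    matrix: ProfileMatrix,
    activity: ActivityProfile,
    min_overlap: int = 3,
) -> pd.Series:
    """Per-protein correlation with the activity profile for one replicate.

    Returns a Series indexed by protein id, named after the replicate;
    NaN flags proteins with zero-variance (or partly missing) profiles.

    Raises
    ------
    InsufficientOverlap
        If matrix and activity share fewer than ``min_overlap`` fractions.
    """
    act = activity.mean_by_fraction()
    common = [f for f in matrix.fractions if f in act.index]
    if len(common) < min_overlap:
        raise InsufficientOverlap(
            f"only {len(common)} common fractions between profiles "
            f"({matrix.fractions}) and activity ({list(act.index)}); "
            f"need >= {min_overlap}"
        )
    X = matrix.data[common].to_numpy(dtype=float)
    y = act[common].to_numpy(dtype=float)
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    Xc = X - X.mean(axis=1, keepdims=True)
    x_ss = (Xc * Xc).sum(axis=1)
    denom = np.sqrt(x_ss * y_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xc @ yc) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    r[~np.isfinite(X).all(axis=1)] = np.nan
    if y_ss == 0.0:
        r[:] = np.nan
    return pd.Series(r, index=matrix.data.index.copy(), name=matrix.replicate_id)


def aggregate_replicates(per_replicate: Sequence[pd.Series]) -> pd.DataFrame:
    """Mean +/- SD of per-replicate correlations, per protein.

    Returns a DataFrame indexed by protein id with one column per
    replicate plus ``r_mean``, ``r_sd`` (sample SD over the replicates in
    which R is defined; 0 by convention when only one is defined) and
    ``n_defined``. Proteins defined in no replicate keep NaN mean/SD.
    """
    if len(per_replicate) == 0:
        raise ValueError("need at least one replicate")
    names = []
    for i, s in enumerate(per_replicate, start=1):
        names.append(s.name if s.name else f"rep{i}")
    df = pd.concat(per_replicate, axis=1)
    df.columns = [f"r_{n}" for n in names]
    rep_cols = list(df.columns)
    df["n_defined"] = df[rep_cols].notna().sum(axis=1)
    df["r_mean"] = df[rep_cols].mean(axis=1)
    sd = df[rep_cols].std(axis=1, ddof=1)
    sd[df["n_defined"] == 1] = 0.0
    sd[df["n_defined"] == 0] = np.nan
    df["r_sd"] = sd
    df.index.name = "protein_id"
    return df[rep_cols + ["r_mean", "r_sd", "n_defined"]]


def peak_fraction(profile: pd.Series) -> int:
    """Fraction of maximum abundance; ties break toward the lowest index."""
    if len(profile) == 0:
        raise ValueError("empty profile")
    vals = profile.to_numpy(dtype=float)
    fracs = np.array([int(f) for f in profile.index])
    order = np.argsort(fracs, kind="stable")
    vals, fracs = vals[order], fracs[order]
    return int(fracs[int(np.argmax(vals))])


def peak_fractions(matrix: ProfileMatrix) -> pd.Series:
    """Per-protein peak fraction (vectorized :func:`peak_fraction`)."""
    cols = sorted(matrix.fractions)
    X = matrix.data[cols].to_numpy(dtype=float)
    idx = np.argmax(X, axis=1)
    return pd.Series(
        [cols[i] for i in idx], index=matrix.data.index.copy(), name="peak_fraction"
    )


def mean_mass_by_peak(
    matrix: ProfileMatrix, masses: Mapping[str, float] | pd.Series
) -> pd.Series:
    """Average molecular mass of proteins peaking in each fraction.

    Groups proteins by their peak fraction and averages their masses (kDa).
    Proteins without a mass are excluded with a warning; fractions in
    which no protein peaks are reported as NaN.
    """
    import warnings

    masses = pd.Series(dict(masses)) if not isinstance(masses, pd.Series) else masses
    peaks = peak_fractions(matrix)
    missing = [pid for pid in peaks.index if pid not in masses.index]
    if missing:
        warnings.warn(
            f"{len(missing)} protein(s) without mass excluded: {missing[:5]}...",
            stacklevel=2,
        )
        peaks = peaks.drop(index=missing)
    grouped = masses.loc[peaks.index].groupby(peaks).mean()
    out = pd.Series(np.nan, index=sorted(matrix.fractions), name="mean_mass_kda")
    out.loc[grouped.index] = grouped
    out.index.name = "fraction"
    return out
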