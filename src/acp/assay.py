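"""End-point lectin-capture model of the proteoliposome reconstitution assay.

The reporter glycolipid is distributed between the two leaflets of large
unilamellar vesicles (outer-leaflet fraction ``f_out``, 0.5 for symmetric
reconstitution). The lectin captures every reporter molecule on the outer
leaflet; in vesicles that received at least one functional scramblase the
inner-leaflet pool is scrambled outward faster than it is captured, so the
assay is a pure end point. With scramblase copies distributed over the
vesicle ensemble by Poisson statistics (mean occupancy ``lambda``), the
expected captured share is::

    capture% = 100 * (f_out + (1 - f_out) * (1 - exp(-lambda)))

ranging from 50% (protein-free liposomes, f_out = 0.5) to 100% (every
vesicle occupied). Raw scintillation counts enter through the pellet share
``R = 100*P/(P+S)`` and the normalized flipping statistic
``100*(R_ConA - R_buffer)/(R_ConA-TX - R_buffer)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "AssayCounts",
    "ReconstitutionParams",
    "ActivityProfile",
    "AssayWindowCollapse",
    "capture_ratio",
    "flipping_percent",
    "expected_capture",
    "expected_flipping",
    "occupancy_for_occupied_fraction",
    "scale_for_peak_capture",
    "ideal_triplet",
    "activity_profile",
    "depletion_readout",
]

CONDITIONS = ("buffer", "conA", "conA_TX")


class AssayWindowCollapse(ValueError):
    """The assay window R_ConA-TX - R_buffer is degenerate."""


@dataclass(frozen=True)
class AssayCounts:
    """Scintillation counts for one assay condition.

    P and S are pellet and supernatant counts (cpm); a usable measurement
    needs P + S > 0.
    """

    condition: str
    P: float
    S: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.P < 0 or self.S < 0:
            raise ValueError("counts must be >= 0")
        if self.P + self.S <= 0:
            raise ValueError("P + S must be > 0 for a usable measurement")

    @property
    def capture(self) -> float:
        return capture_ratio(self.P, self.S)


def capture_ratio(P: float, S: float) -> float:
    """Percentage of reporter recovered in the pellet: 100*P/(P+S)."""
    if P < 0 or S < 0:
        raise ValueError("counts must be >= 0")
    total = P + S
    if total <= 0:
        raise ValueError("undefined measurement: P + S must be > 0")
    return 100.0 * P / total


def flipping_percent(
    buffer: AssayCounts,
    conA: AssayCounts,
    conA_TX: AssayCounts,
    window_tol: float = 1e-9,
) -> float:
    """Normalized flipping statistic from an assay triplet.

    ``100*(R_ConA - R_buffer)/(R_ConA-TX - R_buffer)``: 0 when the ConA
    sample matches the buffer blank, 100 when it matches the fully
    solubilized (detergent) control. Invariant under uniform rescaling of
    all counts.
    """
    r_buf = buffer.capture
    r_cona = conA.capture
    r_tx = conA_TX.capture
    window = r_tx - r_buf
    if abs(window) <= window_tol:
        raise AssayWindowCollapse(
            f"assay window collapsed: R_ConA-TX ({r_tx:.3f}) ~= R_buffer ({r_buf:.3f})"
        )
    return 100.0 * (r_cona - r_buf) / window


@dataclass(frozen=True)
class ReconstitutionParams:
    """Parameters linking reconstituted scramblase amount to the readout.

    f_out : outer-leaflet fraction of reporter lipid (0.5 = symmetric).
    occupancy_scale : mean scramblase copies per vesicle contributed by
        one unit of reconstituted scramblase amount; the free calibration
        constant of the model (vesicle number/size are not modeled).
    """

    f_out: float = 0.5
    occupancy_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_out <= 1.0:
            raise ValueError("f_out must be in [0, 1]")
        if self.occupancy_scale < 0:
            raise ValueError("occupancy_scale must be >= 0")


def expected_capture(lam, f_out: float = 0.5):
    """Expected end-point capture %% at Poisson occupancy ``lam``.

    ``100*(f_out + (1 - f_out)*(1 - exp(-lam)))``; monotone nondecreasing
    in ``lam`` and bounded in ``[100*f_out, 100]``.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0):
        raise ValueError("occupancy lambda must be >= 0")
    if not 0.0 <= f_out <= 1.0:
        raise ValueError("f_out must be in [0, 1]")
    out = 100.0 * (f_out + (1.0 - f_out) * (-np.expm1(-lam_arr)))
    return float(out) if np.isscalar(lam) else out


def expected_flipping(lam):
    """Expected flipping %% at Poisson occupancy ``lam``: 100*(1 - exp(-lam))."""
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0):
        raise ValueError("occupancy lambda must be >= 0")
    out = 100.0 * (-np.expm1(-lam_arr))
    return float(out) if np.isscalar(lam) else out


def occupancy_for_occupied_fraction(occupied: float) -> float:
    """Poisson mean ``lam`` giving an occupied-vesicle fraction 1 - exp(-lam)."""
    if not 0.0 <= occupied < 1.0:
        raise ValueError("occupied fraction must be in [0, 1)")
    return float(-np.log1p(-occupied))


def ideal_triplet(
    lam: float, f_out: float = 0.5, total_cpm: float = 20_000.0
) -> dict[str, AssayCounts]:
    """Noise-free assay triplet implied by occupancy ``lam``.

    buffer: only the outer-leaflet pool is captured; conA: the end-point
    model; conA_TX: detergent exposes everything (100%). Useful as the
    analytic bridge between the count-space and occupancy-space
    parameterizations.
    """
    r = {
        "buffer": 100.0 * f_out,
        "conA": expected_capture(lam, f_out),
        "conA_TX": 100.0,
    }
    return {
        cond: AssayCounts(cond, total_cpm * r[cond] / 100.0,
                          total_cpm * (1.0 - r[cond] / 100.0))
        for cond in CONDITIONS
    }


def scale_for_peak_capture(
    amounts: pd.Series,
    target_capture: float = 70.0,
    f_out: float = 0.5,
    reconstituted_share: float = 0.5,
) -> float:
    """Occupancy scale making the peak fraction report ``target_capture`` %.

    Mirrors the experimental design rule of reconstituting just enough
    protein (half of each fraction) that the fraction richest in
    scramblase reports ~70% capture. Returns 0 for an all-zero profile.
    """
    peak = float(np.max(np.asarray(amounts, dtype=float), initial=0.0))
    if peak <= 0:
        return 0.0
    occupied = (target_capture / 100.0 - f_out) / (1.0 - f_out)
    if not 0.0 <= occupied < 1.0:
        raise ValueError(
            f"target capture {target_capture}% not reachable with f_out={f_out}"
        )
    lam_peak = occupancy_for_occupied_fraction(occupied)
    return lam_peak / (reconstituted_share * peak)


@dataclass
class ActivityProfile:
    """Per-fraction activity readout, possibly with duplicate measurements.

    ``data`` columns: fraction (int), replicate (int, 1-based), value.
    ``readout`` flags whether values are capture %% or flipping %%.
    """

    data: pd.DataFrame
    readout: str = "capture"

    def __post_init__(self) -> None:
        required = {"fraction", "replicate", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"activity data needs columns {sorted(required)}")
        if self.readout not in ("capture", "flipping"):
            raise ValueError("readout must be 'capture' or 'flipping'")

    @property
    def fractions(self) -> list[int]:
        return sorted(int(f) for f in self.data["fraction"].unique())

    def mean_by_fraction(self) -> pd.Series:
        """Duplicate measurements averaged per fraction."""
        s = self.data.groupby("fraction")["value"].mean()
        s.index = s.index.astype(int)
        return s.sort_index()


def activity_profile(
    amounts: pd.Series,
    params: ReconstitutionParams,
    reconstituted_share: float = 0.5,
    readout: str = "capture",
    n_duplicates: int = 1,
    cv: float = 0.0,
    seed: int | None = None,
) -> ActivityProfile:
    """Simulated activity readout across the assayed fractions.

    Per fraction j, ``lam_j = occupancy_scale * reconstituted_share *
    amount_j`` and the value is the expected capture (or flipping) percent.
    Duplicate measurements perturb ``lam_j`` with log-normal noise of the
    given cv before the end-point transform, keeping values in the
    physical range; cv = 0 gives ideal duplicates.
    """
    if n_duplicates <= 0:
        raise ValueError("n_duplicates must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    vals = np.asarray(amounts, dtype=float)
    if np.any(vals < 0):
        raise ValueError("amounts must be >= 0")
    fractions = [int(f) for f in amounts.index]
    lam = params.occupancy_scale * reconstituted_share * vals
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv ** 2))
    rows = []
    for rep in range(1, n_duplicates + 1):
        lam_rep = lam
        if cv > 0:
            lam_rep = lam * np.exp(rng.normal(0.0, sigma, size=lam.shape))
        if readout == "capture":
            values = expected_capture(lam_rep, params.f_out)
        elif readout == "flipping":
            values = expected_flipping(lam_rep)
        else:
            raise ValueError("readout must be 'capture' or 'flipping'")
        rows.append(pd.DataFrame(
            {"fraction": fractions, "replicate": rep, "value": values}
        ))
    return ActivityProfile(pd.concat(rows, ignore_index=True), readout)


def depletion_readout(
    pool,
    removed_ids: set[str],
    ppr_grid,
    params: ReconstitutionParams,
) -> pd.DataFrame:
    """In-silico immunodepletion over a protein-to-phospholipid ratio grid.

    The occupancy at ratio ``ppr`` is ``occupancy_scale * ppr`` for the
    mock-treated extract; depletion scales it by the share of active
    abundance surviving removal. Returns a DataFrame with columns
    ppr, flipping_mock, flipping_depleted. A sole active species removed
    gives 0% flipping at every ratio; in the small-occupancy regime the
    depleted/mock ratio approaches the surviving active share.
    """
    ppr = np.asarray(list(ppr_grid), dtype=float)
    if ppr.size == 0:
        raise ValueError("ppr_grid must not be empty")
    ids = {sp.id for sp in pool}
    unknown = set(removed_ids) - ids
    if unknown:
        raise KeyError(f"removed ids not in pool: {sorted(unknown)}")
    a_full = sum(sp.abundance for sp in pool if sp.is_active)
    a_left = sum(
        sp.abundance for sp in pool if sp.is_active and sp.id not in removed_ids
    )
    surviving = a_left / a_full if a_full > 0 else 0.0
    lam_mock = params.occupancy_scale * ppr
    return pd.DataFrame(
        {
            "ppr": ppr,
            "flipping_mock": expected_flipping(lam_mock),
            "flipping_depleted": expected_flipping(lam_mock * surviving),
        }
    )
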