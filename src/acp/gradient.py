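"""Synthetic velocity-gradient fractionation of a crude membrane-protein mixture.

This module generates the ground truth and the observed data for an
activity-correlation-profiling experiment: a pool of protein species
(monomers and complexes) is sedimented through a glycerol gradient, the
gradient is cut into fractions, and the per-fraction abundance of each
species is quantified TMT-style in one or more technical replicates with
multiplicative measurement noise.

The physical model is deliberately simple:

* a species of sedimentation coefficient ``s`` (Svedberg) comes to rest at
  gradient position ``slope * s + intercept`` (fractions, 1-based from the
  top) — a linear map fitted from sedimentation standards;
* the band it forms is a Gaussian of width ``band_sigma`` fractions,
  discretized over the fraction grid and renormalized so the per-fraction
  amounts sum to the species' abundance (mass conservation; tails clipped
  at the gradient ends are folded back by the renormalization);
* species sharing a parent id (``pool_of``) are indistinguishable to the
  mass spectrometer and their per-fraction signals are summed under one id.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DEFAULT_K",
    "DEFAULT_STANDARDS",
    "Species",
    "GradientSpec",
    "Calibration",
    "ProfileMatrix",
    "MixtureConfig",
    "s_from_mass",
    "mass_from_s",
    "calibrate_gradient",
    "default_calibration",
    "band_profile",
    "species_profiles",
    "active_amounts",
    "simulate_tmt",
    "generate_mixture",
    "generate_annotations",
]

#: Svedberg per Da^(2/3); anchored so a 29 kDa globular standard
#: (carbonic anhydrase) sediments at 2.8 S.
DEFAULT_K = 2.8 / 29_000 ** (2.0 / 3.0)

#: Nominal (s_value, peak_position) pairs for the four sedimentation
#: standards resolved in a parallel gradient (2.8, 3.6, 4.2 and 8.9 S).
#: Positions follow the package's nominal linear map position = S + 1,
#: which places a 6.5 S species at position 7.5 (activity peak in
#: fractions 7-8).
DEFAULT_STANDARDS: tuple[tuple[float, float], ...] = (
    (2.8, 3.8),
    (3.6, 4.6),
    (4.2, 5.2),
    (8.9, 9.9),
)


class CalibrationError(ValueError):
    """Raised when a gradient calibration cannot be fitted."""


def s_from_mass(mass_kda: float, k: float = DEFAULT_K) -> float:
    """Sedimentation coefficient (Svedberg) of a globular species.

    Uses the globular-protein scaling ``s = k * M^(2/3)`` with ``M`` in Da,
    which is strictly increasing in mass.

    Parameters
    ----------
    mass_kda : float
        Molecular mass in kDa, > 0.
    k : float
        Scaling constant in Svedberg per Da^(2/3). The default is anchored
        to a 29 kDa / 2.8 S standard.
    """
    if not mass_kda > 0:
        raise ValueError(f"mass must be > 0 kDa, got {mass_kda}")
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    return float(k * (mass_kda * 1000.0) ** (2.0 / 3.0))


def mass_from_s(s_value: float, k: float = DEFAULT_K) -> float:
    """Inverse of :func:`s_from_mass`; returns mass in kDa."""
    if not s_value > 0:
        raise ValueError(f"s_value must be > 0, got {s_value}")
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    return float((s_value / k) ** 1.5 / 1000.0)


@dataclass(frozen=True)
class Species:
    """One sedimenting species of the simulated mixture.

    A physical protein occupying several oligomeric states (the 'X + XY'
    situation) is represented as several Species sharing a ``pool_of``
    parent id; their per-fraction MS signals are summed under that id.

    Attributes
    ----------
    id : str
        Unique identifier of this sedimenting pool.
    mass : float
        Molecular mass in kDa, > 0.
    s_value : float or None
        Sedimentation coefficient in Svedberg; derived from ``mass`` via
        :func:`s_from_mass` when not given.
    abundance : float
        Total amount across the gradient, arbitrary units >= 0.
    is_active : bool
        Whether this pool carries the assayed activity.
    pool_of : str or None
        Parent protein id for pooled oligomeric states.
    """

    id: str
    mass: float
    s_value: float | None = None
    abundance: float = 1.0
    is_active: bool = False
    pool_of: str | None = None

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"species {self.id!r}: mass must be > 0")
        if self.s_value is not None and not self.s_value > 0:
            raise ValueError(f"species {self.id!r}: s_value must be > 0")
        if self.abundance < 0:
            raise ValueError(f"species {self.id!r}: abundance must be >= 0")

    @property
    def svedberg(self) -> float:
        """Sedimentation coefficient, deriving it from mass if unset."""
        return self.s_value if self.s_value is not None else s_from_mass(self.mass)

    @property
    def ms_id(self) -> str:
        """Identifier under which the mass spectrometer reports this pool."""
        return self.pool_of if self.pool_of is not None else self.id


@dataclass(frozen=True)
class GradientSpec:
    """Fraction layout of the velocity gradient.

    Fractions are indexed 1-based from the top. By default the gradient is
    cut into 12 fractions; fractions 5-11 are assayed for activity and the
    six fractions 5-10 are TMT-quantified.
    """

    n_fractions: int = 12
    assayed_fractions: tuple[int, int] = (5, 11)
    ms_fractions: tuple[int, int] = (5, 10)
    band_sigma: float = 0.8

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ValueError("n_fractions must be >= 2")
        if not self.band_sigma > 0:
            raise ValueError("band_sigma must be > 0")
        for name, (lo, hi) in (
            ("assayed_fractions", self.assayed_fractions),
            ("ms_fractions", self.ms_fractions),
        ):
            if not (1 <= lo <= hi <= self.n_fractions):
                raise ValueError(
                    f"{name} {lo}..{hi} not within 1..{self.n_fractions}"
                )

    @property
    def fractions(self) -> np.ndarray:
        return np.arange(1, self.n_fractions + 1)

    @property
    def assayed(self) -> list[int]:
        lo, hi = self.assayed_fractions
        return list(range(lo, hi + 1))

    @property
    def ms(self) -> list[int]:
        lo, hi = self.ms_fractions
        return list(range(lo, hi + 1))


@dataclass(frozen=True)
class Calibration:
    """Linear map from sedimentation coefficient to gradient position.

    ``position = slope * s + intercept`` with slope > 0 (larger S
    sediments deeper, i.e. toward higher fraction indices).
    """

    slope: float
    intercept: float
    fitted_from: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise CalibrationError(f"slope must be > 0, got {self.slope}")

    def position(self, s_value):
        return self.slope * np.asarray(s_value, dtype=float) + self.intercept

    def s_at(self, position):
        return (np.asarray(position, dtype=float) - self.intercept) / self.slope


def calibrate_gradient(standards: Sequence[tuple[float, float]]) -> Calibration:
    """Least-squares linear fit of peak position against S for standards.

    With exactly two distinct standards the fit is exact.

    Raises
    ------
    CalibrationError
        If fewer than two standards are given or all S values coincide.
    """
    standards = [(float(s), float(p)) for s, p in standards]
    if len(standards) < 2:
        raise CalibrationError("need at least 2 standards to calibrate")
    s = np.array([sv for sv, _ in standards])
    p = np.array([pos for _, pos in standards])
    if np.allclose(s, s[0]):
        raise CalibrationError("standards have no spread in S")
    slope, intercept = np.polyfit(s, p, 1)
    return Calibration(float(slope), float(intercept), tuple(standards))


def default_calibration() -> Calibration:
    """Calibration fitted from the four nominal standards."""
    return calibrate_gradient(DEFAULT_STANDARDS)


def _band_matrix(
    positions: np.ndarray, gradient: GradientSpec
) -> np.ndarray:
    """Discretized Gaussian band for each position; rows sum to 1.

    The band mass in fraction ``j`` is the integral of a normal density
    (mean = position, sd = band_sigma) over ``[j - 0.5, j + 0.5]``;
    clipped tails are folded back by renormalization.
    """
    pos = np.atleast_1d(np.asarray(positions, dtype=float))[:, None]
    edges = np.arange(0.5, gradient.n_fractions + 0.6)
    cdf = norm.cdf((edges[None, :] - pos) / gradient.band_sigma)
    w = np.diff(cdf, axis=1)
    total = w.sum(axis=1, keepdims=True)
    # a band centred far outside the gradient collapses onto the nearest end
    degenerate = total[:, 0] <= 1e-300
    if degenerate.any():
        w[degenerate] = 0.0
        idx = np.where(pos[degenerate, 0] < 1, 0, gradient.n_fractions - 1)
        w[np.where(degenerate)[0], idx] = 1.0
        total = w.sum(axis=1, keepdims=True)
    return w / total


def band_profile(
    species: Species, gradient: GradientSpec, cal: Calibration
) -> np.ndarray:
    """Per-fraction amounts of one species over fractions 1..n_fractions.

    The amounts sum to ``species.abundance`` (mass conservation).
    """
    pos = cal.position(species.svedberg)
    return _band_matrix(np.array([pos]), gradient)[0] * species.abundance


@dataclass
class ProfileMatrix:
    """Fraction-by-protein abundance values for one (true or noisy) run.

    ``data`` has one row per MS-level protein id (oligomeric pools merged)
    and one integer-labelled column per fraction; all values are >= 0
    (NaN marks a missing measurement).
    """

    data: pd.DataFrame
    replicate_id: str = "truth"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate protein id {dup!r} in profile matrix")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("profile matrix contains negative values")
        self.data.index.name = "protein_id"

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def fractions(self) -> list[int]:
        return [int(c) for c in self.data.columns]

    def restrict(self, fractions: Sequence[int]) -> "ProfileMatrix":
        """Sub-matrix over the given fractions (e.g. the TMT channels)."""
        missing = [f for f in fractions if f not in self.data.columns]
        if missing:
            raise KeyError(f"fractions {missing} absent from matrix")
        return ProfileMatrix(self.data[list(fractions)].copy(), self.replicate_id)


def species_profiles(
    pool: Sequence[Species], gradient: GradientSpec, cal: Calibration
) -> ProfileMatrix:
    """True (noise-free) profile matrix of a species pool.

    Species sharing a ``pool_of`` parent are merged: their per-fraction
    amounts are summed under the parent id, as a mass spectrometer that
    cannot distinguish oligomeric states would report them.
    """
    if len(pool) == 0:
        raise ValueError("empty species pool")
    positions = cal.position(np.array([sp.svedberg for sp in pool]))
    bands = _band_matrix(positions, gradient)
    bands *= np.array([sp.abundance for sp in pool])[:, None]
    df = pd.DataFrame(bands, index=[sp.ms_id for sp in pool],
                      columns=gradient.fractions)
    merged = df.groupby(level=0, sort=False).sum()
    return ProfileMatrix(merged, "truth")


def active_amounts(
    pool: Sequence[Species],
    gradient: GradientSpec,
    cal: Calibration,
    fractions: Sequence[int] | None = None,
) -> pd.Series:
    """Per-fraction amount of activity-carrying protein.

    Sums the bands of all ``is_active`` species over the requested
    fractions (default: the assayed fractions). Inactive pools contribute
    nothing, whatever protein id they report under.
    """
    fractions = list(fractions) if fractions is not None else gradient.assayed
    total = np.zeros(gradient.n_fractions)
    for sp in pool:
        if sp.is_active:
            total += band_profile(sp, gradient, cal)
    full = pd.Series(total, index=gradient.fractions)
    return full[fractions]


def simulate_tmt(
    truth: ProfileMatrix, cv: float, n_replicates: int, seed: int
) -> list[ProfileMatrix]:
    """Noisy TMT-style technical replicates of a true profile matrix.

    Each cell is multiplied by ``exp(eps)`` with ``eps ~ Normal(0, sigma)``
    and ``sigma = sqrt(log(1 + cv**2))``, so the requested coefficient of
    variation is attained and the noise is unbiased in the median.
    ``cv = 0`` returns exact copies of the truth. Replicates differ only
    through the seeded RNG.
    """
    if n_replicates <= 0:
        raise ValueError("n_replicates must be a positive integer")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv ** 2))
    out = []
    for i in range(1, n_replicates + 1):
        vals = truth.data.to_numpy(dtype=float)
        if cv > 0:
            vals = vals * np.exp(rng.normal(0.0, sigma, size=vals.shape))
        df = pd.DataFrame(vals, index=truth.data.index.copy(),
                          columns=truth.data.columns.copy())
        out.append(ProfileMatrix(df, f"rep{i}"))
    return out


@dataclass(frozen=True)
class MixtureConfig:
    """Scenario builder configuration for :func:`generate_mixture`.

    Emulates a crude ER-membrane-protein extract: one active species and
    ``n_decoys`` inactive decoys with log-uniform masses and log-normal
    abundances. Setting ``complex_fraction`` > 0 splits the active protein
    into an active monomer and an oligomeric pool of mass
    ``active_mass + mass_y`` reported under the same id ('X + XY').
    """

    n_decoys: int = 2999
    mass_range_kda: tuple[float, float] = (20.0, 300.0)
    abundance_sdlog: float = 1.0
    active_id: str = "scramblase"
    active_s: float = 6.5
    active_mass: float | None = None
    active_abundance: float = 1.0
    complex_fraction: float = 0.0
    mass_y: float = 0.0
    complex_active: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")
        lo, hi = self.mass_range_kda
        if not (0 < lo <= hi):
            raise ValueError("mass_range_kda must satisfy 0 < lo <= hi")
        if not 0.0 <= self.complex_fraction <= 1.0:
            raise ValueError("complex_fraction must be in [0, 1]")

    @property
    def resolved_active_mass(self) -> float:
        if self.active_mass is not None:
            return self.active_mass
        return mass_from_s(self.active_s)


def generate_mixture(cfg: MixtureConfig) -> list[Species]:
    """Reproducible species pool; exactly the configured species are active.

    Decoy masses are drawn log-uniformly over ``mass_range_kda`` and their
    abundances log-normally (median 1, sdlog ``abundance_sdlog``); decoy S
    values follow from mass via the globular scaling. The active species
    keeps its configured S value (it need not be globular-monomer sized).
    """
    mass_x = cfg.resolved_active_mass
    monomer_share = 1.0 - cfg.complex_fraction
    pool: list[Species] = [
        Species(
            id=cfg.active_id,
            mass=mass_x,
            s_value=cfg.active_s,
            abundance=cfg.active_abundance * monomer_share,
            is_active=True,
        )
    ]
    if cfg.complex_fraction > 0:
        if not cfg.mass_y > 0:
            raise ValueError("mass_y must be > 0 when complex_fraction > 0")
        pool.append(
            Species(
                id=f"{cfg.active_id}::XY",
                mass=mass_x + cfg.mass_y,
                abundance=cfg.active_abundance * cfg.complex_fraction,
                is_active=cfg.complex_active,
                pool_of=cfg.active_id,
            )
        )
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mass_range_kda
    masses = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_decoys))
    abundances = np.exp(rng.normal(0.0, cfg.abundance_sdlog, cfg.n_decoys))
    width = len(str(max(cfg.n_decoys, 1)))
    for i in range(cfg.n_decoys):
        pool.append(
            Species(
                id=f"D{i + 1:0{width}d}",
                mass=float(masses[i]),
                abundance=float(abundances[i]),
            )
        )
    if not pool:
        raise ValueError("empty species pool")
    return pool


def generate_annotations(
    pool: Sequence[Species],
    seed: int,
    p_essential: float = 0.18,
    p_membrane: float = 0.25,
    localizations: Sequence[tuple[str, float]] = (
        ("ER", 0.15),
        ("Golgi", 0.10),
        ("mitochondria", 0.15),
        ("plasma membrane", 0.10),
        ("cytosol", 0.30),
        ("unknown", 0.20),
    ),
) -> pd.DataFrame:
    """Synthetic annotation table for a simulated pool.

    Active species are annotated as essential, polytopic (10 TM spans) ER
    residents — the profile the candidate curation hypothesizes for the
    activity carrier. Decoys draw essentiality, TM-span counts (0 for
    soluble proteins, 1-14 for membrane proteins) and a localization label
    independently. Columns: protein_id, essential, tm_spans, localization.
    """
    rng = np.random.default_rng(seed)
    ids = sorted({sp.ms_id for sp in pool})
    active_ids = {sp.ms_id for sp in pool if sp.is_active}
    labels = [lab for lab, _ in localizations]
    probs = np.array([p for _, p in localizations], dtype=float)
    probs = probs / probs.sum()
    rows = []
    for pid in ids:
        if pid in active_ids:
            rows.append((pid, True, 10, "ER"))
            continue
        essential = bool(rng.random() < p_essential)
        if rng.random() < p_membrane:
            tm = int(rng.integers(1, 15))
        else:
            tm = 0
        loc = str(rng.choice(labels, p=probs))
        rows.append((pid, essential, tm, loc))
    return pd.DataFrame(
        rows, columns=["protein_id", "essential", "tm_spans", "localization"]
    )
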