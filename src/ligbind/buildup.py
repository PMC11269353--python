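"""STD amplification factors, build-up curve fitting, and epitope maps.

In a saturation transfer difference (STD) experiment the protein is selectively
saturated and magnetization spreads to bound-ligand protons by NOE. For each
proton the amplification factor

    eta = (I0 - I_STD) / I0 * epsilon

(with ``epsilon`` the ligand:protein concentration ratio) grows with the
saturation time ``t`` following a saturating mono-exponential,

    eta(t) = STD_max * (1 - exp(-k_sat * t)).

The initial slope ``STD0 = STD_max * k_sat`` is the per-proton transfer measure
used for epitope mapping, because it is insensitive to differences in
spin-lattice relaxation and intramolecular spin diffusion between protons.
Normalizing STD0 to the largest value per ligand (100%) yields the
epitope-binding map: the higher the normalized value, the closer that proton's
contact with the protein surface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    EmptyEpitopeMapError,
    FitConvergenceError,
    InvalidInputError,
    NoBindingDetectedError,
    SignalOverlapError,
)

#: Saturation-time schedule (s) used for the build-up experiments.
DEFAULT_SCHEDULE = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0)

#: Default ligand:protein concentration ratio (800 µM ligand / 20 µM protein).
DEFAULT_EPSILON = 40.0

#: Default floor below which a series counts as "no binding detected".
DEFAULT_ETA_FLOOR = 1e-3

_KSAT_BOUNDS = (1e-6, 100.0)
_MAX_NFEV = 10_000


@dataclass(frozen=True)
class SaturationSeries:
    """On/off-resonance intensities of one proton over the saturation schedule."""

    ligand_id: str
    proton_id: str
    chemical_shift: float
    times: tuple[float, ...]
    I0: tuple[float, ...]
    ISTD: tuple[float, ...]
    epsilon: float = DEFAULT_EPSILON
    overlap_flag: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i0 = np.asarray(self.I0, dtype=float)
        istd = np.asarray(self.ISTD, dtype=float)
        if t.size == 0:
            raise InvalidInputError("empty saturation-time schedule")
        if not (t.size == i0.size == istd.size):
            raise InvalidInputError("times, I0 and ISTD must have equal length")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing and > 0")
        if np.any(i0 <= 0):
            raise InvalidInputError("off-resonance intensities I0 must be > 0")
        if not self.epsilon > 0:
            raise InvalidInputError("epsilon must be > 0")

    @property
    def eta(self) -> np.ndarray:
        """Amplification factors at each saturation time."""
        return amplification_factor(np.asarray(self.I0), np.asarray(self.ISTD), self.epsilon)


@dataclass(frozen=True)
class BuildUpFit:
    """Fitted build-up parameters for one proton.

    ``STD0 = STD_max * k_sat`` holds exactly by construction; ``se_STD0`` is
    propagated to first order from the fit covariance (including the
    STD_max/k_sat covariance term).
    """

    proton_id: str
    STD_max: float
    k_sat: float
    STD0: float
    se_STD_max: float
    se_k_sat: float
    se_STD0: float
    rss: float
    converged: bool
    n_points: int
    chemical_shift: float = math.nan
    warnings: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class EpitopeMap:
    """Normalized STD0 map for one ligand (maximum entry = 100%)."""

    ligand_id: str
    entries: tuple[tuple[str, float, float], ...]  # (proton_id, shift, normalized %)
    reference_proton: str
    undetermined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {pid: pct for pid, _, pct in self.entries}


def amplification_factor(I0, ISTD, epsilon: float):
    """STD amplification factor ``eta = (I0 - ISTD) / I0 * epsilon``.

    Accepts scalars or arrays. Negative values (possible under noise when
    ISTD > I0) are returned as-is; callers decide whether to flag them.
    """
    I0 = np.asarray(I0, dtype=float)
    ISTD = np.asarray(ISTD, dtype=float)
    if np.any(I0 <= 0):
        raise InvalidInputError("I0 must be > 0")
    if not epsilon > 0:
        raise InvalidInputError("epsilon must be > 0")
    eta = (I0 - ISTD) / I0 * epsilon
    if eta.ndim == 0:
        return float(eta)
    return eta


def buildup_model(t, STD_max: float, k_sat: float):
    """Mono-exponential build-up ``STD_max * (1 - exp(-k_sat t))``."""
    return STD_max * (1.0 - np.exp(-k_sat * np.asarray(t, dtype=float)))


def fit_buildup(series: SaturationSeries, eta_floor: float = DEFAULT_ETA_FLOOR) -> BuildUpFit:
    """Nonlinear least-squares fit of the build-up curve for one proton.

    Fits ``eta(t) = STD_max (1 - exp(-k_sat t))`` by unweighted least squares
    (trust-region-reflective, bounded: STD_max in (0, epsilon], k_sat in
    (0, 100] s^-1). Initial values: STD_max from the largest observed eta;
    k_sat from the first-point slope, clipped to [1e-3, 10] s^-1.

    Negative eta values are retained in the fit (clipping would bias the
    plateau downward); a warning is attached to the result instead.

    Raises
    ------
    SignalOverlapError
        If the series is overlap-flagged (entry is undetermined).
    NoBindingDetectedError
        If every eta sits below ``eta_floor``.
    InvalidInputError
        If fewer than 3 time points are available.
    """
    if series.overlap_flag:
        raise SignalOverlapError(
            f"proton {series.proton_id}: signal overlap, STD0 cannot be determined"
        )
    t = np.asarray(series.times, dtype=float)
    if t.size < 3:
        raise InvalidInputError("need >= 3 time points to fit a two-parameter build-up")
    eta = series.eta
    if np.all(eta < eta_floor):
        raise NoBindingDetectedError(
            f"proton {series.proton_id}: all amplification factors below {eta_floor}"
        )

    notes: list[str] = []
    if np.any(eta < 0):
        notes.append("negative amplification factors retained in fit")

    std_max0 = float(np.max(eta))
    k0 = float(np.clip(eta[0] / (std_max0 * t[0]), 1e-3, 10.0))
    lower = (1e-12, _KSAT_BOUNDS[0])
    upper = (series.epsilon, _KSAT_BOUNDS[1])

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # OptimizeWarning on singular covariance
            popt, pcov = curve_fit(
                buildup_model, t, eta,
                p0=(min(std_max0, series.epsilon), k0),
                bounds=(lower, upper),
                xtol=1e-10, ftol=1e-10, gtol=1e-10,
                max_nfev=_MAX_NFEV,
            )
    except RuntimeError:
        raise FitConvergenceError(
            f"proton {series.proton_id}: build-up fit did not converge"
        ) from None

    std_max, k_sat = float(popt[0]), float(popt[1])
    resid = eta - buildup_model(t, std_max, k_sat)
    rss = float(np.dot(resid, resid))
    if not np.all(np.isfinite(pcov)):
        converged = False
        notes.append("singular covariance; standard errors unreliable")
        pcov = np.full((2, 2), np.nan)

    var_m, var_k = float(pcov[0, 0]), float(pcov[1, 1])
    cov_mk = float(pcov[0, 1])
    se_m = math.sqrt(var_m) if var_m >= 0 else math.nan
    se_k = math.sqrt(var_k) if var_k >= 0 else math.nan
    # First-order propagation for STD0 = STD_max * k_sat.
    var_std0 = k_sat**2 * var_m + std_max**2 * var_k + 2.0 * std_max * k_sat * cov_mk
    se_std0 = math.sqrt(var_std0) if var_std0 >= 0 else math.nan

    # Boundary solutions mean the optimizer gave up inside the feasible box.
    if k_sat >= _KSAT_BOUNDS[1] * (1 - 1e-9) or std_max >= series.epsilon * (1 - 1e-12):
        converged = False
        notes.append("parameter at bound")

    return BuildUpFit(
        proton_id=series.proton_id,
        STD_max=std_max,
        k_sat=k_sat,
        STD0=std_max * k_sat,
        se_STD_max=se_m,
        se_k_sat=se_k,
        se_STD0=se_std0,
        rss=rss,
        converged=converged,
        n_points=int(t.size),
        chemical_shift=series.chemical_shift,
        warnings=tuple(notes),
    )


def epitope_map(ligand_id: str, fits: list[BuildUpFit],
                undetermined: list[str] | None = None) -> EpitopeMap:
    """Normalize STD0 values of converged fits to the per-ligand maximum.

    Each entry is ``100 * STD0 / max(STD0)``; the proton attaining the maximum
    is the reference (ties broken by lowest chemical shift so output is
    deterministic). Entries are sorted by descending normalized value.
    Undetermined protons (overlap, non-convergence) are listed separately and
    never enter the normalization.
    """
    usable = [f for f in fits if f.converged and f.STD0 > 0]
    if not usable:
        raise EmptyEpitopeMapError(f"ligand {ligand_id}: no converged fit with STD0 > 0")
    max_std0 = max(f.STD0 for f in usable)
    at_max = [f for f in usable if f.STD0 == max_std0]
    reference = min(at_max, key=lambda f: (f.chemical_shift, f.proton_id))
    entries = sorted(
        ((f.proton_id, f.chemical_shift, 100.0 * f.STD0 / max_std0) for f in usable),
        key=lambda e: (-e[2], e[1], e[0]),
    )
    return EpitopeMap(
        ligand_id=ligand_id,
        entries=tuple(entries),
        reference_proton=reference.proton_id,
        undetermined=tuple(undetermined or ()),
    )


def fit_all(series_list: list[SaturationSeries],
            eta_floor: float = DEFAULT_ETA_FLOOR) -> tuple[list[BuildUpFit], dict[str, str]]:
    """Fit every series, collecting per-proton failures instead of aborting.

    Returns the successful fits and a mapping proton_id -> failure reason for
    series that raised overlap / no-binding / convergence errors.
    """
    fits: list[BuildUpFit] = []
    failures: dict[str, str] = {}
    for s in series_list:
        try:
            fits.append(fit_buildup(s, eta_floor=eta_floor))
        except (SignalOverlapError, NoBindingDetectedError, FitConvergenceError) as exc:
            failures[s.proton_id] = exc.category
    return fits, failures
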