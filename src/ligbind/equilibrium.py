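"""Binding equilibria, dialysis binding degree, and thermodynamic conversions.

The module covers three related computations used when reconciling separative
(equilibrium dialysis / ultrafiltration) measurements with ligand-observed NMR
and docking energetics:

* binding degree from total and free drug concentrations,
  ``100 * (D_t - D_f) / D_t``;
* mass-action equilibria for a ligand binding one or two independent protein
  sites, optionally competing with a single-site probe (warfarin for Sudlow
  site I, diazepam for Sudlow site II on serum albumin);
* interconversion of a binding free energy (kcal/mol, 1 M standard state) and
  a dissociation constant via ``Kd = exp(dG / (R T))``.

Concentrations are micromolar throughout unless stated otherwise; dissociation
constants returned by the thermodynamic helpers are molar, matching the
convention in which docking energies are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidInputError, SolverError

#: Gas constant in kcal mol^-1 K^-1 (the convention used for docking energies).
GAS_CONSTANT_KCAL = 1.9872e-3

#: Default experimental temperature in kelvin.
DEFAULT_TEMPERATURE_K = 298.0

#: Canonical site identifiers for the two principal drug pockets of albumin.
SITE_I = "site_I"
SITE_II = "site_II"

_MASS_BALANCE_RTOL = 1e-9


@dataclass(frozen=True)
class DialysisMeasurement:
    """One equilibrium-dialysis or ultrafiltration measurement.

    Parameters
    ----------
    D_t
        Total drug concentration in the protein compartment.
    D_f
        Free drug concentration (permeate/filtrate). Same units as ``D_t``.
    method_tag
        ``"ED"`` (equilibrium dialysis) or ``"UF"`` (ultrafiltration).
    """

    D_t: float
    D_f: float
    method_tag: str = "ED"

    def __post_init__(self) -> None:
        if not self.D_t > 0:
            raise InvalidInputError(f"D_t must be > 0, got {self.D_t}")
        if self.D_f < 0:
            raise InvalidInputError(f"D_f must be >= 0, got {self.D_f}")
        if self.D_f > self.D_t:
            raise InvalidInputError(
                f"D_f ({self.D_f}) exceeds D_t ({self.D_t}); "
                "this flags an analytical error and is not clipped"
            )
        if self.method_tag not in ("ED", "UF"):
            raise InvalidInputError(f"method_tag must be 'ED' or 'UF', got {self.method_tag!r}")


@dataclass(frozen=True)
class BindingSystem:
    """Concentrations and dissociation constants for an equilibrium computation.

    Sites are treated as independent (no cooperativity): each protein molecule
    carries one copy of every site in ``Kd_site``. A competition probe, when
    present, binds exactly one site (``probe_site``) with constant ``Kd_probe``.

    All concentrations in µM, all Kd in µM, temperature in K.
    """

    P_t: float
    L_t: float
    Kd_site: Mapping[str, float] = field(default_factory=dict)
    Q_t: float = 0.0
    Kd_probe: float | None = None
    probe_site: str | None = None
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.P_t < 0 or self.L_t < 0 or self.Q_t < 0:
            raise InvalidInputError("concentrations must be nonnegative")
        if not self.temperature > 0:
            raise InvalidInputError("temperature must be > 0 K")
        if not self.Kd_site:
            raise InvalidInputError("Kd_site must name at least one site")
        for site, kd in self.Kd_site.items():
            if not (math.isfinite(kd) and kd > 0):
                raise InvalidInputError(f"Kd for {site} must be finite and > 0, got {kd}")
        if self.Q_t > 0:
            if self.probe_site is None or self.probe_site not in self.Kd_site:
                raise InvalidInputError(
                    "probe_site must name one of the ligand's sites when Q_t > 0"
                )
            if self.Kd_probe is None or not self.Kd_probe > 0:
                raise InvalidInputError("Kd_probe must be > 0 when Q_t > 0")

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(self.Kd_site)


@dataclass(frozen=True)
class ThermoParams:
    """A (deltaG, Kd, T) triple satisfying Kd = exp(deltaG / (R T)).

    ``deltaG`` in kcal/mol (negative = favorable), ``Kd`` in M at the 1 M
    standard state, ``temperature`` in K.
    """

    deltaG: float
    Kd: float
    temperature: float = DEFAULT_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        expected = math.exp(self.deltaG / (self.gas_constant * self.temperature))
        if abs(self.Kd - expected) > 1e-12 * max(abs(expected), 1e-300):
            raise InvalidInputError(
                f"Kd={self.Kd} inconsistent with deltaG={self.deltaG} at T={self.temperature}"
            )


@dataclass(frozen=True)
class EquilibriumState:
    """Solved species concentrations (µM) for a :class:`BindingSystem`."""

    L_free: float
    Q_free: float
    L_bound_per_site: Mapping[str, float]
    Q_bound: float

    @property
    def L_bound(self) -> float:
        return float(sum(self.L_bound_per_site.values()))


def binding_degree(m: DialysisMeasurement) -> float:
    """Percentage of drug bound to protein, ``100 * (D_t - D_f) / D_t``.

    Scale-invariant in the concentration unit. ``D_f > D_t`` is rejected at
    construction of the measurement rather than clipped to 0%, so analytical
    failures surface as errors. Computed as ``100 (1 - D_f/D_t)`` so the
    boundary cases (fully bound, fully free) are exact in floating point.
    """
    return 100.0 * (1.0 - m.D_f / m.D_t)


def solve_free_ligand_1to1(P_t: float, L_t: float, Kd: float) -> float:
    """Free ligand concentration for 1:1 binding, from the mass-action quadratic.

    Solves ``L_f^2 + (P_t - L_t + Kd) L_f - Kd L_t = 0`` for its positive root
    using the numerically stable form (avoids cancellation when the linear
    coefficient is large and positive).
    """
    if P_t < 0 or L_t < 0:
        raise InvalidInputError("concentrations must be nonnegative")
    if not Kd > 0:
        raise InvalidInputError("Kd must be > 0")
    if L_t == 0:
        return 0.0
    b = P_t - L_t + Kd
    c = -Kd * L_t
    disc = math.sqrt(b * b - 4.0 * c)
    # c < 0 guarantees one positive root; pick the cancellation-free branch.
    if b >= 0:
        L_f = -2.0 * c / (b + disc)
    else:
        L_f = (-b + disc) / 2.0
    return min(L_f, L_t)


def solve_competitive_two_site(system: BindingSystem) -> EquilibriumState:
    """Solve independent-site competitive mass action for ligand and probe.

    Each site ``s`` (total concentration ``P_t``) binds the ligand with
    ``Kd_site[s]``; the probe competes at ``probe_site`` only. For a trial
    free-ligand value the free probe follows from a closed-form quadratic, so
    the ligand mass balance reduces to a one-dimensional root bracketed on
    ``[0, L_t]`` and solved with Brent's method.

    Returns the full species breakdown; raises :class:`SolverError` rather
    than returning partial output if the root finder fails.
    """
    P, L_t, Q_t = system.P_t, system.L_t, system.Q_t
    kd = dict(system.Kd_site)
    ps, kq = system.probe_site, system.Kd_probe

    def free_probe(L_f: float) -> float:
        if Q_t == 0 or ps is None:
            return 0.0
        # Q_t = Q_f + P * (Q_f/kq) / (1 + L_f/kd[ps] + Q_f/kq)
        # => quadratic a Q_f^2 + b Q_f + c = 0 with a > 0, c < 0.
        alpha = 1.0 + L_f / kd[ps]
        a = 1.0 / kq
        b = alpha + P / kq - Q_t / kq
        c = -alpha * Q_t
        disc = math.sqrt(b * b - 4.0 * a * c)
        if b >= 0:
            return -2.0 * c / (b + disc)
        return (-b + disc) / (2.0 * a)

    def bound_ligand(L_f: float, Q_f: float) -> dict[str, float]:
        out = {}
        for s, k in kd.items():
            denom = 1.0 + L_f / k + (Q_f / kq if (ps == s and Q_t > 0) else 0.0)
            out[s] = P * (L_f / k) / denom
        return out

    def residual(L_f: float) -> float:
        Q_f = free_probe(L_f)
        return L_f + sum(bound_ligand(L_f, Q_f).values()) - L_t

    if L_t == 0:
        Q_f = free_probe(0.0)
        return EquilibriumState(0.0, Q_f, {s: 0.0 for s in kd}, Q_t - Q_f)

    try:
        L_f = brentq(residual, 0.0, L_t, xtol=1e-15, rtol=8.9e-16, maxiter=300)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
        raise SolverError(f"competitive equilibrium did not converge: {exc}") from exc

    Q_f = free_probe(L_f)
    bound = bound_ligand(L_f, Q_f)
    state = EquilibriumState(L_f, Q_f, bound, Q_t - Q_f)
    if abs(state.L_free + state.L_bound - L_t) > _MASS_BALANCE_RTOL * max(L_t, 1.0):
        raise SolverError("ligand mass balance violated beyond tolerance")
    if Q_t > 0 and abs(state.Q_free + state.Q_bound - Q_t) > _MASS_BALANCE_RTOL * max(Q_t, 1.0):
        raise SolverError("probe mass balance violated beyond tolerance")
    return state


def predicted_bound_fraction(system: BindingSystem) -> float:
    """Model-predicted binding degree, ``100 * (L_t - L_f) / L_t`` (percent).

    Uses the two-site competitive solver, which reduces to the 1:1 quadratic
    for a single site without probe.
    """
    if system.L_t == 0:
        raise InvalidInputError("L_t must be > 0 to define a bound fraction")
    state = solve_competitive_two_site(system)
    return 100.0 * (system.L_t - state.L_free) / system.L_t


def kd_from_deltaG(deltaG: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Dissociation constant (M, 1 M standard state) from a binding free energy.

    ``Kd = exp(deltaG / (R T))`` with R = 1.9872e-3 kcal/(mol K); a negative
    (favorable) deltaG gives Kd < 1 M.
    """
    if not temperature > 0:
        raise InvalidInputError("temperature must be > 0 K")
    return math.exp(deltaG / (GAS_CONSTANT_KCAL * temperature))


def deltaG_from_kd(Kd: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Binding free energy (kcal/mol) from a dissociation constant in M."""
    if not temperature > 0:
        raise InvalidInputError("temperature must be > 0 K")
    if not Kd > 0:
        raise InvalidInputError("Kd must be > 0")
    return GAS_CONSTANT_KCAL * temperature * math.log(Kd)


def thermo_params(deltaG: float, temperature: float = DEFAULT_TEMPERATURE_K) -> ThermoParams:
    """Build a consistent :class:`ThermoParams` from a free energy."""
    return ThermoParams(deltaG=deltaG, Kd=kd_from_deltaG(deltaG, temperature),
                        temperature=temperature)


def binding_degree_summary(measurements: list[DialysisMeasurement]) -> dict[str, dict[str, float]]:
    """Mean ± sd of binding degree per method tag (ED/UF), for reporting."""
    if not measurements:
        raise InvalidInputError("no dialysis measurements provided")
    out: dict[str, dict[str, float]] = {}
    for tag in sorted({m.method_tag for m in measurements}):
        vals = np.array([binding_degree(m) for m in measurements if m.method_tag == tag])
        out[tag] = {
            "mean_percent": float(vals.mean()),
            "sd_percent": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n": int(vals.size),
        }
    return out
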