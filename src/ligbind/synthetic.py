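"""Synthetic STD-NMR and dialysis datasets with embedded ground truth.

The generator emulates the statistical structure of ligand-observed binding
measurements on a serum-albumin-like system, at the default conditions of the
experiments it stands in for: 20 µM protein with 800 µM ligand (ratio
``epsilon = 40``), saturation schedule {0.5, 1, 1.5, 2, 3, 4, 5, 6} s, and
800 µM of a site-selective competition probe when competing.

For each proton the noiseless amplification factor follows the
mono-exponential build-up ``STD_max (1 - exp(-k_sat t))``. Measurement noise
is multiplicative Gaussian (coefficient of variation ``intensity_cv``,
default 0.02) applied independently to the two peaks an STD experiment
records: the off-resonance intensity and the difference-spectrum intensity
``I0 - ISTD`` (STD spectra are acquired by internal subtraction, so the
difference peak — not the on-resonance peak — carries its own proportional
error). The tabulated on-resonance intensity is reconstructed as their
difference. Competition scales
each proton's plateau ``STD_max`` by the probe-induced change in
site-weight-averaged bound-ligand concentration, computed from the competitive
two-site mass-action equilibrium; the saturation rate ``k_sat`` is left
unchanged. Dialysis replicates are drawn around the model's equilibrium free
and total ligand concentrations.

Every generator returns the ground truth alongside the data, so parameter
recovery and site-assignment accuracy can be scored exactly. One top-level
seed feeds a single ``numpy.random.default_rng`` stream; identical seed and
configuration give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .buildup import DEFAULT_EPSILON, DEFAULT_SCHEDULE, SaturationSeries
from .equilibrium import (
    SITE_I,
    SITE_II,
    BindingSystem,
    DialysisMeasurement,
    EquilibriumState,
    solve_competitive_two_site,
)
from .errors import InvalidInputError

#: Base off-resonance intensity (arbitrary spectrometer units).
BASE_INTENSITY = 1000.0


@dataclass(frozen=True)
class ProtonSpec:
    """Ground-truth build-up parameters for one ligand proton.

    ``site_weights`` gives the fractional contribution of (site I, site II)
    occupancy to this proton's saturation transfer; the two entries are
    nonnegative and sum to 1.
    """

    proton_id: str
    chemical_shift: float
    std_max: float
    k_sat: float
    site_weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if not (self.std_max > 0 and self.k_sat > 0):
            raise InvalidInputError("std_max and k_sat must be > 0")
        w = self.site_weights
        if len(w) != 2 or any(x < 0 or x > 1 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise InvalidInputError("site_weights must be two fractions in [0,1] summing to 1")


@dataclass(frozen=True)
class LigandTemplate:
    """A ligand's proton set with true build-up parameters."""

    ligand_id: str
    protons: tuple[ProtonSpec, ...]

    def __post_init__(self) -> None:
        if not self.protons:
            raise InvalidInputError("template must define at least one proton")
        ids = [p.proton_id for p in self.protons]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("proton_ids must be unique within a ligand")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise.

    ``intensity_cv`` applies independently to every measured intensity
    (on- and off-resonance, every time point); ``concentration_cv`` to every
    dialysis concentration. Zero means noiseless.
    """

    intensity_cv: float = 0.02
    concentration_cv: float = 0.01

    def __post_init__(self) -> None:
        if self.intensity_cv < 0 or self.concentration_cv < 0:
            raise InvalidInputError("noise coefficients of variation must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True parameters embedded in a synthetic dataset."""

    #: proton_id -> {"std_max", "k_sat", "std0"} (std0 = std_max * k_sat exactly)
    protons: dict[str, dict[str, float]] = field(default_factory=dict)
    #: site receiving the larger occupancy-weighted saturation contribution
    main_site: str | None = None
    #: proton_id -> noiseless expected attenuation ratio (percent) under the probe
    attenuation_percent: dict[str, float] | None = None
    bound_fraction_percent: float | None = None


# --- default ligand templates -------------------------------------------------
# Chemical shifts mirror the observed proton sets of the two
# chloromethcathinone positional isomers (aromatic protons, the methine CH,
# N-CH3 and the C-CH3); shifts are labels only and never used numerically.
# Plateau/rate values are chosen so the aromatic ring dominates the epitope
# map and the methyl groups trail it, the pattern typical of these ligands;
# site weights lean toward Sudlow site II, the main site of both isomers.

CMC3_TEMPLATE = LigandTemplate(
    ligand_id="3-CMC",
    protons=(
        ProtonSpec("H2", 7.99, 2.40, 0.50, (0.30, 0.70)),
        ProtonSpec("H4", 7.87, 2.20, 0.46, (0.30, 0.70)),
        ProtonSpec("H5", 7.71, 2.00, 0.44, (0.32, 0.68)),
        ProtonSpec("H6", 7.53, 1.90, 0.40, (0.32, 0.68)),
        ProtonSpec("CH", 4.90, 1.50, 0.42, (0.35, 0.65)),
        ProtonSpec("NCH3", 2.69, 1.30, 0.35, (0.35, 0.65)),
        ProtonSpec("CCH3", 1.50, 1.20, 0.33, (0.40, 0.60)),
    ),
)

CMC4_TEMPLATE = LigandTemplate(
    ligand_id="4-CMC",
    protons=(
        ProtonSpec("H26", 7.93, 2.30, 0.52, (0.30, 0.70)),
        ProtonSpec("H35", 7.57, 2.10, 0.46, (0.30, 0.70)),
        ProtonSpec("CH", 4.96, 1.60, 0.42, (0.35, 0.65)),
        ProtonSpec("NCH3", 2.69, 1.50, 0.37, (0.35, 0.65)),
        ProtonSpec("CCH3", 1.51, 1.35, 0.365, (0.40, 0.60)),
    ),
)

DEFAULT_TEMPLATES = {"3-CMC": CMC3_TEMPLATE, "4-CMC": CMC4_TEMPLATE}

#: Default competitive system: 20 µM protein, 800 µM ligand, micromolar site
#: dissociation constants favoring site II, 800 µM single-site probe.
DEFAULT_COMPETITION_SYSTEM = BindingSystem(
    P_t=20.0,
    L_t=800.0,
    Kd_site={SITE_I: 100.0, SITE_II: 13.0},
    Q_t=800.0,
    Kd_probe=5.0,
    probe_site=SITE_II,
)

#: Default dialysis system: physiological albumin (~600 µM) with a trace drug
#: dose and a dissociation constant giving ~80% bound, the regime typical of
#: plasma protein binding of these cathinones.
DEFAULT_DIALYSIS_SYSTEM = BindingSystem(
    P_t=600.0,
    L_t=10.0,
    Kd_site={SITE_II: 150.0},
)


def _simulate_series(rng: np.random.Generator, template: LigandTemplate,
                     schedule, epsilon: float, noise: NoiseModel,
                     std_max_scale: dict[str, float] | None = None,
                     ) -> list[SaturationSeries]:
    t = np.asarray(schedule, dtype=float)
    cv = noise.intensity_cv
    out = []
    for p in template.protons:
        scale = 1.0 if std_max_scale is None else std_max_scale[p.proton_id]
        eta = scale * p.std_max * (1.0 - np.exp(-p.k_sat * t))
        if np.any(eta >= epsilon):
            raise InvalidInputError(
                f"proton {p.proton_id}: std_max * scale must stay below epsilon"
            )
        i0_true = np.full_like(t, BASE_INTENSITY)
        diff_true = i0_true * eta / epsilon  # difference-spectrum peak
        # Multiplicative noise on each measured peak: the off-resonance
        # intensity and the STD difference-spectrum intensity (the quantity a
        # spectrometer actually records via internal subtraction). The
        # on-resonance intensity is their difference, so eta noise reflects
        # both channels and scales with eta itself.
        i0 = i0_true * (1.0 + cv * rng.standard_normal(t.size))
        diff = diff_true * (1.0 + cv * rng.standard_normal(t.size))
        istd = i0 - diff
        out.append(SaturationSeries(
            ligand_id=template.ligand_id,
            proton_id=p.proton_id,
            chemical_shift=p.chemical_shift,
            times=tuple(t),
            I0=tuple(i0),
            ISTD=tuple(istd),
            epsilon=epsilon,
        ))
    return out


def _ground_truth_protons(template: LigandTemplate) -> dict[str, dict[str, float]]:
    return {
        p.proton_id: {"std_max": p.std_max, "k_sat": p.k_sat, "std0": p.std_max * p.k_sat}
        for p in template.protons
    }


def generate_buildup_dataset(template: LigandTemplate,
                             schedule=DEFAULT_SCHEDULE,
                             epsilon: float = DEFAULT_EPSILON,
                             noise: NoiseModel = NoiseModel(),
                             seed: int = 0,
                             ) -> tuple[list[SaturationSeries], GroundTruth]:
    """Simulate one build-up experiment (no probe) for a ligand template.

    The noiseless amplification factor of each proton equals
    ``std_max (1 - exp(-k_sat t))`` exactly; multiplicative noise is applied
    to both intensity channels at every time point.
    """
    sched = np.asarray(schedule, dtype=float)
    if sched.size == 0:
        raise InvalidInputError("empty saturation schedule")
    if np.any(sched <= 0) or np.any(np.diff(sched) <= 0):
        raise InvalidInputError("schedule must be strictly increasing and > 0")
    if not epsilon > 0:
        raise InvalidInputError("epsilon must be > 0")
    rng = np.random.default_rng(seed)
    series = _simulate_series(rng, template, sched, epsilon, noise)
    return series, GroundTruth(protons=_ground_truth_protons(template))


def _site_index(site: str) -> int:
    if site == SITE_I:
        return 0
    if site == SITE_II:
        return 1
    raise InvalidInputError(f"unknown site {site!r}; expected {SITE_I!r} or {SITE_II!r}")


def _weighted_transfer(template: LigandTemplate, state: EquilibriumState) -> dict[str, float]:
    """Per-proton site-weight-averaged bound-ligand concentration."""
    bound = [state.L_bound_per_site.get(SITE_I, 0.0),
             state.L_bound_per_site.get(SITE_II, 0.0)]
    return {
        p.proton_id: p.site_weights[0] * bound[0] + p.site_weights[1] * bound[1]
        for p in template.protons
    }


def true_main_site(template: LigandTemplate, state: EquilibriumState) -> str:
    """Site with the larger occupancy-weighted saturation contribution."""
    mean_w = np.mean([p.site_weights for p in template.protons], axis=0)
    contrib = {
        SITE_I: mean_w[0] * state.L_bound_per_site.get(SITE_I, 0.0),
        SITE_II: mean_w[1] * state.L_bound_per_site.get(SITE_II, 0.0),
    }
    return max(sorted(contrib), key=lambda s: contrib[s])


def generate_competition_dataset(template: LigandTemplate,
                                 system: BindingSystem = DEFAULT_COMPETITION_SYSTEM,
                                 probe_site: str | None = None,
                                 schedule=DEFAULT_SCHEDULE,
                                 epsilon: float = DEFAULT_EPSILON,
                                 noise: NoiseModel = NoiseModel(),
                                 seed: int = 0,
                                 ) -> tuple[list[SaturationSeries], list[SaturationSeries], GroundTruth]:
    """Simulate paired reference / with-probe build-up experiments.

    The probe occupies ``probe_site`` (defaults to ``system.probe_site``) and
    displaces ligand there; each proton's plateau is scaled by the ratio of
    its site-weight-averaged bound-ligand concentration with vs without
    probe. Both sites of the system must be present for the competition to be
    meaningful. Returns (reference series, with-probe series, ground truth);
    the ground truth records the true main site and the noiseless expected
    attenuation percentages.
    """
    probe_site = probe_site or system.probe_site
    if probe_site is None:
        raise InvalidInputError("probe_site must be given here or on the system")
    _site_index(probe_site)
    if system.Q_t < 0:
        raise InvalidInputError("probe concentration must be nonnegative")
    system = dataclasses.replace(system, probe_site=probe_site)

    no_probe = dataclasses.replace(system, Q_t=0.0, Kd_probe=None, probe_site=None)
    state_ref = solve_competitive_two_site(no_probe)
    state_probe = solve_competitive_two_site(system)

    transfer_ref = _weighted_transfer(template, state_ref)
    transfer_probe = _weighted_transfer(template, state_probe)
    scale = {pid: (transfer_probe[pid] / transfer_ref[pid]) if transfer_ref[pid] > 0 else 0.0
             for pid in transfer_ref}

    rng = np.random.default_rng(seed)
    sched = np.asarray(schedule, dtype=float)
    reference = _simulate_series(rng, template, sched, epsilon, noise)
    with_probe = _simulate_series(rng, template, sched, epsilon, noise, std_max_scale=scale)

    truth = GroundTruth(
        protons=_ground_truth_protons(template),
        main_site=true_main_site(template, state_ref),
        attenuation_percent={pid: 100.0 * s for pid, s in scale.items()},
    )
    return reference, with_probe, truth


def generate_dialysis_dataset(system: BindingSystem = DEFAULT_DIALYSIS_SYSTEM,
                              n_replicates: int = 5,
                              noise: NoiseModel = NoiseModel(),
                              seed: int = 0,
                              method_tag: str = "ED",
                              ) -> tuple[list[DialysisMeasurement], GroundTruth]:
    """Simulate replicate dialysis / ultrafiltration measurements.

    Total concentration replicates are drawn around ``L_t`` and free-drug
    replicates around the equilibrium free-ligand concentration, both with
    multiplicative noise ``concentration_cv``. The noiseless case reproduces
    the model bound fraction exactly; zero protein gives 0% binding.

    Free-drug draws are truncated at the total-drug draw (a free concentration
    cannot exceed the total), which matters only when binding is near zero and
    noise is large.
    """
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    if system.L_t <= 0:
        raise InvalidInputError("L_t must be > 0")
    state = solve_competitive_two_site(system)
    rng = np.random.default_rng(seed)
    cv = noise.concentration_cv
    measurements = []
    for _ in range(n_replicates):
        d_t = system.L_t * (1.0 + cv * rng.standard_normal())
        d_f = state.L_free * (1.0 + cv * rng.standard_normal())
        measurements.append(DialysisMeasurement(D_t=d_t, D_f=min(d_f, d_t),
                                                method_tag=method_tag))
    truth = GroundTruth(
        bound_fraction_percent=100.0 * (system.L_t - state.L_free) / system.L_t,
    )
    return measurements, truth
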