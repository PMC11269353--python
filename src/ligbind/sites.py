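"""Competition-probe attenuation, binding-site assignment, and WaterLOGSY calls.

Serum albumin carries two principal drug pockets, Sudlow site I (subdomain
IIA, classically probed by warfarin) and Sudlow site II (subdomain IIIA,
probed by diazepam). Adding a site-selective probe displaces ligand from that
site and attenuates the ligand's STD response; the probe whose presence
attenuates STD0 the most marks the ligand's main binding site. Attenuation is
quantified per proton as the percentage ratio

    ratio = 100 * STD0_with_probe / STD0_without_probe

and aggregated per probe by the median over determined protons (robust to
single-proton outliers). A second probe whose median also falls clearly below
100% indicates a secondary site.

WaterLOGSY complements this with a sign criterion: ligand signals that invert
between the free and protein-containing samples indicate binding; signals
merely attenuated without inversion are weak or ambiguous evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .buildup import BuildUpFit
from .equilibrium import SITE_I, SITE_II
from .errors import InsufficientDataError, InvalidInputError

#: Default probe -> site mapping (configuration, not hard-coded chemistry:
#: override when other probes are used).
DEFAULT_PROBE_SITES: Mapping[str, str] = {"warfarin": SITE_I, "diazepam": SITE_II}

#: Median separation (percentage points) below which the verdict is ambiguous.
DEFAULT_AMBIGUITY_THRESHOLD = 10.0

#: A probe competes at its site when its median ratio < 100 - this tolerance.
DEFAULT_COMPETITION_TOLERANCE = 10.0

UNDETERMINED_REASONS = ("overlap", "non-convergence", "missing")


@dataclass(frozen=True)
class CompetitionEntry:
    """Attenuation of one proton's STD0 by one probe (percent), or undetermined."""

    proton_id: str
    chemical_shift: float
    probe_id: str
    ratio: float | None
    undetermined_reason: str | None = None

    def __post_init__(self) -> None:
        if self.ratio is None and self.undetermined_reason is None:
            raise InvalidInputError("undetermined entry must carry a reason")
        if self.ratio is not None:
            if not self.ratio > 0:
                raise InvalidInputError("determined ratio must be > 0")
            if self.undetermined_reason is not None:
                raise InvalidInputError("entry cannot be both determined and undetermined")

    @property
    def determined(self) -> bool:
        return self.ratio is not None


@dataclass(frozen=True)
class SiteAssignment:
    """Main/secondary site verdict for one ligand."""

    ligand_id: str
    main_site: str
    secondary_site: str | None
    median_ratio_per_probe: Mapping[str, float]
    margin: float
    ambiguous: bool
    statistic: str = "median"


@dataclass(frozen=True)
class WaterLogsyObservation:
    """Sign of one proton's WaterLOGSY signal without and with protein."""

    proton_id: str
    sign_free: Literal["positive", "negative"]
    sign_with_protein: Literal["positive", "negative"]
    attenuated: bool = False

    def __post_init__(self) -> None:
        for s in (self.sign_free, self.sign_with_protein):
            if s not in ("positive", "negative"):
                raise InvalidInputError(f"sign must be 'positive' or 'negative', got {s!r}")


def attenuation_ratios(fits_reference: list[BuildUpFit],
                       fits_with_probe: list[BuildUpFit],
                       probe_id: str,
                       undetermined_with_probe: Mapping[str, str] | None = None,
                       ) -> list[CompetitionEntry]:
    """Per-proton ``100 * STD0_with / STD0_ref`` for one competition probe.

    Protons of the reference condition that are missing, overlap-flagged or
    non-converged in the with-probe condition are emitted as undetermined
    entries (with the reason) rather than dropped, mirroring how competition
    tables mark cells that cannot be determined.

    ``undetermined_with_probe`` maps proton_id -> reason for protons whose
    with-probe fit failed upstream.
    """
    ref = {f.proton_id: f for f in fits_reference if f.converged and f.STD0 > 0}
    if not ref:
        raise InvalidInputError("no converged reference fits")
    probe_fits = {f.proton_id: f for f in fits_with_probe}
    failed = dict(undetermined_with_probe or {})

    entries: list[CompetitionEntry] = []
    matched = 0
    for pid, rf in sorted(ref.items(), key=lambda kv: (-kv[1].chemical_shift, kv[0])):
        wf = probe_fits.get(pid)
        if wf is None:
            reason = failed.get(pid, "missing")
            reason = "overlap" if reason == "signal-overlap" else reason
            entries.append(CompetitionEntry(pid, rf.chemical_shift, probe_id, None,
                                            undetermined_reason=reason))
            continue
        if not wf.converged:
            entries.append(CompetitionEntry(pid, rf.chemical_shift, probe_id, None,
                                            undetermined_reason="non-convergence"))
            continue
        matched += 1
        ratio = 100.0 * wf.STD0 / rf.STD0
        if ratio > 100.0:
            warnings.warn(
                f"proton {pid}: attenuation ratio {ratio:.1f}% exceeds 100% (noise); "
                "retained but it cannot indicate competition",
                stacklevel=2,
            )
        entries.append(CompetitionEntry(pid, rf.chemical_shift, probe_id, ratio))
    if matched == 0 and not entries:
        raise InvalidInputError(f"no matching protons between conditions for probe {probe_id}")
    return entries


def assign_sites(ligand_id: str,
                 entries: list[CompetitionEntry],
                 probe_sites: Mapping[str, str] = DEFAULT_PROBE_SITES,
                 ambiguity_threshold: float = DEFAULT_AMBIGUITY_THRESHOLD,
                 competition_tolerance: float = DEFAULT_COMPETITION_TOLERANCE,
                 statistic: str = "median") -> SiteAssignment:
    """Assign main and secondary binding sites from competition entries.

    The probe with the smallest aggregated ratio (strongest attenuation) marks
    the main site. Any other probe whose aggregate falls below
    ``100 - competition_tolerance`` marks a secondary site; otherwise its site
    is reported as not competed (``secondary_site = None``). The verdict is
    ambiguous when the two smallest aggregates differ by less than
    ``ambiguity_threshold`` percentage points.

    The aggregation statistic is the median by default (robust to the
    occasional outlier proton); ``statistic="mean"`` is available.

    Raises :class:`InsufficientDataError`, naming the probe, when a probe has
    no determined entry, and :class:`InvalidInputError` when fewer than two
    probes are covered.
    """
    if statistic not in ("median", "mean"):
        raise InvalidInputError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    probes = sorted({e.probe_id for e in entries})
    if len(probes) < 2:
        raise InvalidInputError("site assignment requires entries from >= 2 probes")
    unknown = [p for p in probes if p not in probe_sites]
    if unknown:
        raise InvalidInputError(f"no site mapping for probe(s): {', '.join(unknown)}")

    agg = np.median if statistic == "median" else np.mean
    medians: dict[str, float] = {}
    for probe in probes:
        vals = [e.ratio for e in entries if e.probe_id == probe and e.determined]
        if not vals:
            raise InsufficientDataError(f"probe {probe!r} has no determined entries")
        medians[probe] = float(agg(vals))

    # Deterministic order: by aggregated ratio, probe id breaking exact ties.
    ranked = sorted(probes, key=lambda p: (medians[p], p))
    main_probe, runner_up = ranked[0], ranked[1]
    margin = medians[runner_up] - medians[main_probe]
    secondary = None
    if medians[runner_up] < 100.0 - competition_tolerance:
        secondary = probe_sites[runner_up]
    return SiteAssignment(
        ligand_id=ligand_id,
        main_site=probe_sites[main_probe],
        secondary_site=secondary,
        median_ratio_per_probe=dict(sorted(medians.items())),
        margin=margin,
        ambiguous=margin < ambiguity_threshold,
        statistic=statistic,
    )


def classify_waterlogsy(obs: WaterLogsyObservation) -> str:
    """Classify a WaterLOGSY response as binder / weak_or_ambiguous / non_binder.

    Sign inversion between the free-ligand and with-protein spectra is the
    binder hallmark; attenuation without inversion is weak or ambiguous
    evidence; an unchanged, unattenuated signal indicates no binding.
    """
    if obs.sign_free != obs.sign_with_protein:
        return "binder"
    return "weak_or_ambiguous" if obs.attenuated else "non_binder"
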