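"""Reported reference data for the chloromethcathinone / albumin system.

``CMC_COMPETITION_RATIOS`` holds the literature-reported attenuation of STD0
(percent, ``100 * STD0_with_probe / STD0_without``) for 3- and 4-chloro-
methcathinone bound to human serum albumin in the presence of 800 µM of a
Sudlow-site probe (warfarin for site I, diazepam for site II). ``None`` marks
cells that could not be determined because the ligand resonance overlaps a
probe resonance. Keys are the observed proton chemical shifts in ppm.

These numbers are inputs for the site-assignment worked example; feeding them
through :func:`ligbind.sites.assign_sites` reproduces the published verdict
that Sudlow site II is the main binding site of both isomers, with site I
secondary.
"""

from __future__ import annotations

from .sites import CompetitionEntry

#: ligand -> probe -> {chemical shift (ppm): ratio % or None (overlap)}
CMC_COMPETITION_RATIOS: dict[str, dict[str, dict[float, float | None]]] = {
    "3-CMC": {
        "diazepam": {7.99: 37.0, 7.87: 30.0, 7.71: 38.0, 7.53: None,
                     4.90: 39.0, 2.69: 37.0, 1.50: 40.0},
        "warfarin": {7.99: 82.0, 7.87: None, 7.71: 77.0, 7.53: None,
                     4.90: 73.0, 2.69: 69.0, 1.50: 76.0},
    },
    "4-CMC": {
        "diazepam": {7.93: 43.0, 7.57: 38.0, 4.96: 45.0, 2.69: 49.0, 1.51: 42.0},
        "warfarin": {7.93: 60.0, 7.57: 58.0, 4.96: 62.0, 2.69: 61.0, 1.51: 58.0},
    },
}

#: Reported range of docking binding free energies (kcal/mol) for the
#: CMC/albumin poses; used for the thermodynamic consistency check.
CMC_DOCKING_DELTAG_RANGE_KCAL = (-6.67, -5.07)

#: Reported plasma protein-binding degrees (percent, mean over n = 5) by
#: method (ultrafiltration UF, equilibrium dialysis ED).
CMC_BINDING_DEGREES_PERCENT = {
    "3-CMC": {"UF": 80.2, "ED": 79.1},
    "4-CMC": {"UF": 80.5, "ED": 79.3},
}


def competition_entries(ligand_id: str) -> list[CompetitionEntry]:
    """Reported attenuation ratios as :class:`CompetitionEntry` objects."""
    try:
        per_probe = CMC_COMPETITION_RATIOS[ligand_id]
    except KeyError:
        raise KeyError(
            f"no reference data for {ligand_id!r}; available: "
            f"{sorted(CMC_COMPETITION_RATIOS)}"
        ) from None
    entries = []
    for probe, ratios in sorted(per_probe.items()):
        for shift, ratio in sorted(ratios.items(), reverse=True):
            pid = f"H{shift:.2f}"
            if ratio is None:
                entries.append(CompetitionEntry(pid, shift, probe, None,
                                                undetermined_reason="overlap"))
            else:
                entries.append(CompetitionEntry(pid, shift, probe, ratio))
    return entries
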