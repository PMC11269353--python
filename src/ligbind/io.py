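"""Delimited-text table schemas, configuration, the pipeline, and reports.

All tables are comma-separated UTF-8 text with a mandatory header row and "."
as the decimal mark. Undetermined cells are serialized as the explicit marker
``"ND"``, never left empty. Three schemas are defined:

intensity table (one row per proton, condition, saturation time)
    ``ligand_id, proton_id, chemical_shift_ppm, condition, saturation_time_s,
    intensity_off, intensity_on, overlap_flag`` where ``condition`` is
    ``reference`` or ``probe:<probe_id>``.

dialysis table
    ``sample_id, method, D_t, D_f, unit`` with ``method`` in {ED, UF}; ``unit``
    is ``uM`` or ``ug/mL`` (the latter converted with a caller-supplied molar
    mass).

fit table (export)
    one row per proton with the fitted plateau, rate, initial slope and their
    standard errors.

:func:`run_pipeline` composes the full analysis — simulate or read, build-up
fits, epitope map, competition ratios, site assignment, binding degree — and
returns a deterministic, JSON-serializable report; per-stage failures are
recorded in the report without aborting unrelated stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .buildup import (
    DEFAULT_EPSILON,
    DEFAULT_SCHEDULE,
    BuildUpFit,
    EpitopeMap,
    SaturationSeries,
    epitope_map,
    fit_all,
)
from .equilibrium import (
    SITE_I,
    SITE_II,
    BindingSystem,
    DialysisMeasurement,
    binding_degree_summary,
)
from .errors import LigbindError, SchemaError
from .sites import (
    DEFAULT_AMBIGUITY_THRESHOLD,
    DEFAULT_COMPETITION_TOLERANCE,
    DEFAULT_PROBE_SITES,
    CompetitionEntry,
    attenuation_ratios,
    assign_sites,
)
from .synthetic import (
    DEFAULT_COMPETITION_SYSTEM,
    DEFAULT_DIALYSIS_SYSTEM,
    DEFAULT_TEMPLATES,
    GroundTruth,
    NoiseModel,
    generate_buildup_dataset,
    generate_competition_dataset,
    generate_dialysis_dataset,
)

#: Marker for undetermined cells in delimited-text output.
ND_MARKER = "ND"

INTENSITY_COLUMNS = (
    "ligand_id", "proton_id", "chemical_shift_ppm", "condition",
    "saturation_time_s", "intensity_off", "intensity_on", "overlap_flag",
)
DIALYSIS_COLUMNS = ("sample_id", "method", "D_t", "D_f", "unit")

REFERENCE_CONDITION = "reference"


def probe_condition(probe_id: str) -> str:
    return f"probe:{probe_id}"


# --- intensity tables ---------------------------------------------------------

def write_intensity_table(conditions: Mapping[str, list[SaturationSeries]],
                          path: str | Path) -> None:
    """Write series grouped by condition to the intensity-table schema."""
    rows = []
    for condition in conditions:
        for s in conditions[condition]:
            for t, i0, istd in zip(s.times, s.I0, s.ISTD):
                rows.append({
                    "ligand_id": s.ligand_id,
                    "proton_id": s.proton_id,
                    "chemical_shift_ppm": s.chemical_shift,
                    "condition": condition,
                    "saturation_time_s": t,
                    "intensity_off": i0,
                    "intensity_on": istd,
                    "overlap_flag": int(s.overlap_flag),
                })
    pd.DataFrame(rows, columns=list(INTENSITY_COLUMNS)).to_csv(path, index=False)


def read_intensity_table(path: str | Path,
                         epsilon: float = DEFAULT_EPSILON,
                         ) -> dict[str, list[SaturationSeries]]:
    """Read an intensity table, grouped by condition, sorted by saturation time.

    The header is checked against the schema; duplicate
    (proton, condition, time) keys and non-numeric cells are reported with
    their 1-based file line numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse as CSV: {exc}") from exc
    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns: {', '.join(missing)}")

    bad_lines = []
    numeric = {}
    for col in ("chemical_shift_ppm", "saturation_time_s", "intensity_off",
                "intensity_on", "overlap_flag"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        bad_lines.extend((int(i) + 2, col) for i in bad)  # +2: header + 1-based
        numeric[col] = vals
    if bad_lines:
        listing = "; ".join(f"line {ln} ({col})" for ln, col in sorted(bad_lines))
        raise SchemaError(f"{path}: non-numeric cells: {listing}")

    keys = df[["ligand_id", "proton_id", "condition"]].copy()
    keys["t"] = numeric["saturation_time_s"]
    dup = keys.duplicated(keep=False)
    if dup.any():
        first_dupes = keys[keys.duplicated()].index
        listing = ", ".join(str(int(i) + 2) for i in first_dupes)
        raise SchemaError(f"{path}: duplicate (proton, condition, time) rows at lines {listing}")

    out: dict[str, list[SaturationSeries]] = {}
    group_cols = ["condition", "ligand_id", "proton_id"]
    for (condition, ligand, proton), g in df.groupby(group_cols, sort=True):
        order = numeric["saturation_time_s"][g.index].sort_values().index
        out.setdefault(condition, []).append(SaturationSeries(
            ligand_id=ligand,
            proton_id=proton,
            chemical_shift=float(numeric["chemical_shift_ppm"][order[0]]),
            times=tuple(numeric["saturation_time_s"][order]),
            I0=tuple(numeric["intensity_off"][order]),
            ISTD=tuple(numeric["intensity_on"][order]),
            epsilon=epsilon,
            overlap_flag=bool(numeric["overlap_flag"][order].any()),
        ))
    return out


# --- dialysis tables ----------------------------------------------------------

def write_dialysis_table(measurements: list[DialysisMeasurement],
                         path: str | Path, unit: str = "uM") -> None:
    rows = [{
        "sample_id": f"s{i + 1}",
        "method": m.method_tag,
        "D_t": m.D_t,
        "D_f": m.D_f,
        "unit": unit,
    } for i, m in enumerate(measurements)]
    pd.DataFrame(rows, columns=list(DIALYSIS_COLUMNS)).to_csv(path, index=False)


def read_dialysis_table(path: str | Path,
                        molar_mass_g_per_mol: float | None = None,
                        ) -> list[DialysisMeasurement]:
    """Read dialysis measurements; ``ug/mL`` rows require a molar mass (µM =
    1000 × (µg/mL) / M)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in DIALYSIS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns: {', '.join(missing)}")
    out = []
    for i, row in df.iterrows():
        d_t, d_f, unit = float(row["D_t"]), float(row["D_f"]), str(row["unit"])
        if unit == "ug/mL":
            if molar_mass_g_per_mol is None:
                raise SchemaError(
                    f"{path}: line {int(i) + 2} uses ug/mL but no molar mass was supplied"
                )
            d_t = 1000.0 * d_t / molar_mass_g_per_mol
            d_f = 1000.0 * d_f / molar_mass_g_per_mol
        elif unit != "uM":
            raise SchemaError(f"{path}: line {int(i) + 2}: unknown unit {unit!r}")
        out.append(DialysisMeasurement(D_t=d_t, D_f=d_f, method_tag=str(row["method"])))
    return out


# --- fit / competition exports ------------------------------------------------

def fits_to_frame(fits: list[BuildUpFit]) -> pd.DataFrame:
    """Flat fit table, one row per proton."""
    return pd.DataFrame([{
        "proton_id": f.proton_id,
        "chemical_shift_ppm": f.chemical_shift,
        "STD_max": f.STD_max,
        "se_STD_max": f.se_STD_max,
        "k_sat_per_s": f.k_sat,
        "se_k_sat": f.se_k_sat,
        "STD0_per_s": f.STD0,
        "se_STD0": f.se_STD0,
        "rss": f.rss,
        "n_points": f.n_points,
        "converged": f.converged,
    } for f in fits])


def competition_to_frame(entries: list[CompetitionEntry]) -> pd.DataFrame:
    """Competition table: one row per chemical shift, one column per probe."""
    probes = sorted({e.probe_id for e in entries})
    shifts = sorted({(e.chemical_shift, e.proton_id) for e in entries}, reverse=True)
    rows = []
    by_key = {(e.chemical_shift, e.proton_id, e.probe_id): e for e in entries}
    for shift, pid in shifts:
        row: dict[str, Any] = {"chemical_shift_ppm": shift, "proton_id": pid}
        for probe in probes:
            e = by_key.get((shift, pid, probe))
            row[f"ratio_{probe}_percent"] = (
                ND_MARKER if e is None or not e.determined else e.ratio)
        rows.append(row)
    return pd.DataFrame(rows)


# --- ground truth sidecar / config --------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(truth), fh, sort_keys=True)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        return GroundTruth(**yaml.safe_load(fh))


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


# --- analysis report ----------------------------------------------------------

@dataclass
class AnalysisReport:
    """Consolidated pipeline output; serialization is deterministic."""

    provenance: dict[str, Any]
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    ligands: dict[str, dict[str, Any]] = field(default_factory=dict)
    binding_degree: dict[str, Any] | None = None

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "provenance": self.provenance,
            "stages": self.stages,
            "ligands": self.ligands,
        }
        if self.binding_degree is not None:
            out["binding_degree"] = self.binding_degree
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")


def _epitope_to_dict(emap: EpitopeMap) -> dict[str, Any]:
    return {
        "reference_proton": emap.reference_proton,
        "entries": [
            {"proton_id": pid, "chemical_shift_ppm": shift, "normalized_STD0_percent": pct}
            for pid, shift, pct in emap.entries
        ],
        "undetermined": list(emap.undetermined),
    }


def _entries_to_records(entries: list[CompetitionEntry]) -> list[dict[str, Any]]:
    return [{
        "proton_id": e.proton_id,
        "chemical_shift_ppm": e.chemical_shift,
        "probe_id": e.probe_id,
        "ratio_percent": e.ratio if e.determined else ND_MARKER,
        "undetermined_reason": e.undetermined_reason,
    } for e in entries]


def _simulate_inputs(cfg: dict[str, Any]) -> tuple[
        dict[str, dict[str, list[SaturationSeries]]],
        list[DialysisMeasurement], dict[str, GroundTruth]]:
    """Generate pipeline inputs per the ``simulate`` config block."""
    sim = cfg.get("simulate") or {}
    seed = int(cfg.get("seed", 0))
    noise_cfg = cfg.get("noise") or {}
    noise = NoiseModel(
        intensity_cv=float(noise_cfg.get("intensity_cv", 0.02)),
        concentration_cv=float(noise_cfg.get("concentration_cv", 0.01)),
    )
    schedule = tuple(cfg.get("schedule", DEFAULT_SCHEDULE))
    epsilon = float(cfg.get("epsilon", DEFAULT_EPSILON))
    probes: Mapping[str, str] = sim.get("probes", dict(DEFAULT_PROBE_SITES))

    nmr: dict[str, dict[str, list[SaturationSeries]]] = {}
    truths: dict[str, GroundTruth] = {}
    for offset, ligand in enumerate(sim.get("ligands", ["3-CMC"])):
        template = DEFAULT_TEMPLATES[ligand]
        conditions: dict[str, list[SaturationSeries]] = {}
        ref, _ = generate_buildup_dataset(template, schedule, epsilon, noise,
                                          seed=seed + 1000 * offset)
        conditions[REFERENCE_CONDITION] = ref
        for j, (probe, site) in enumerate(sorted(probes.items())):
            system = dataclasses.replace(DEFAULT_COMPETITION_SYSTEM, probe_site=site)
            _, with_probe, truth = generate_competition_dataset(
                template, system, site, schedule, epsilon, noise,
                seed=seed + 1000 * offset + 10 * (j + 1))
            conditions[probe_condition(probe)] = with_probe
            truths[ligand] = truth
        nmr[ligand] = conditions

    dialysis: list[DialysisMeasurement] = []
    dia_cfg = sim.get("dialysis")
    if dia_cfg:
        n = int(dia_cfg.get("n_replicates", 5))
        for k, method in enumerate(dia_cfg.get("methods", ["ED", "UF"])):
            ms, _ = generate_dialysis_dataset(
                DEFAULT_DIALYSIS_SYSTEM, n, noise, seed=seed + 77 + k,
                method_tag=method)
            dialysis.extend(ms)
    return nmr, dialysis, truths


def run_pipeline(config: dict[str, Any]) -> AnalysisReport:
    """Run fit → epitope → competition → assignment → binding degree.

    ``config`` either names input tables (``inputs.intensity_table``,
    ``inputs.dialysis_table``) or requests simulation (``simulate`` block).
    Stages that receive no input are skipped; a stage failure is recorded
    under ``stages`` and unrelated stages still run. Fixed config and seed
    give byte-identical reports.
    """
    report = AnalysisReport(provenance={
        "package": "ligbind",
        "version": __version__,
        "seed": config.get("seed"),
        "config": config,
    })
    assign_cfg = config.get("assignment") or {}
    probe_sites: Mapping[str, str] = (
        (config.get("simulate") or {}).get("probes") or dict(DEFAULT_PROBE_SITES))
    epsilon = float(config.get("epsilon", DEFAULT_EPSILON))

    nmr: dict[str, dict[str, list[SaturationSeries]]] = {}
    dialysis: list[DialysisMeasurement] = []
    inputs = config.get("inputs") or {}
    try:
        if config.get("simulate"):
            nmr, dialysis, _ = _simulate_inputs(config)
        if inputs.get("intensity_table"):
            by_condition = read_intensity_table(inputs["intensity_table"], epsilon=epsilon)
            for cond, series_list in by_condition.items():
                for s in series_list:
                    nmr.setdefault(s.ligand_id, {}).setdefault(cond, []).append(s)
        if inputs.get("dialysis_table"):
            dialysis.extend(read_dialysis_table(
                inputs["dialysis_table"],
                molar_mass_g_per_mol=inputs.get("molar_mass_g_per_mol")))
        report.stages["load"] = {"status": "ok",
                                 "ligands": sorted(nmr), "n_dialysis": len(dialysis)}
    except LigbindError as exc:
        report.stages["load"] = {"status": "error", "category": exc.category,
                                 "message": str(exc)}
        return report

    for ligand in sorted(nmr):
        conditions = nmr[ligand]
        block: dict[str, Any] = {}
        report.ligands[ligand] = block
        ref_series = conditions.get(REFERENCE_CONDITION, [])
        if not ref_series:
            report.stages[f"fit:{ligand}"] = {
                "status": "error", "category": "invalid-input",
                "message": "no reference condition"}
            continue
        ref_fits, ref_failures = fit_all(ref_series)
        block["fits"] = json.loads(
            fits_to_frame(ref_fits).to_json(orient="records"))
        report.stages[f"fit:{ligand}"] = {"status": "ok", "n_fits": len(ref_fits),
                                          "failures": ref_failures}
        try:
            emap = epitope_map(ligand, ref_fits, undetermined=sorted(ref_failures))
            block["epitope_map"] = _epitope_to_dict(emap)
            report.stages[f"epitope:{ligand}"] = {"status": "ok"}
        except LigbindError as exc:
            report.stages[f"epitope:{ligand}"] = {
                "status": "error", "category": exc.category, "message": str(exc)}

        entries: list[CompetitionEntry] = []
        for cond in sorted(conditions):
            if not cond.startswith("probe:"):
                continue
            probe = cond.split(":", 1)[1]
            probe_fits, probe_failures = fit_all(conditions[cond])
            try:
                entries.extend(attenuation_ratios(
                    ref_fits, probe_fits, probe,
                    undetermined_with_probe=probe_failures))
                report.stages[f"compete:{ligand}:{probe}"] = {"status": "ok"}
            except LigbindError as exc:
                report.stages[f"compete:{ligand}:{probe}"] = {
                    "status": "error", "category": exc.category, "message": str(exc)}
        if entries:
            block["competition"] = _entries_to_records(entries)
            try:
                verdict = assign_sites(
                    ligand, entries, probe_sites=probe_sites,
                    ambiguity_threshold=float(assign_cfg.get(
                        "ambiguity_threshold", DEFAULT_AMBIGUITY_THRESHOLD)),
                    competition_tolerance=float(assign_cfg.get(
                        "competition_tolerance", DEFAULT_COMPETITION_TOLERANCE)),
                    statistic=assign_cfg.get("statistic", "median"))
                block["site_assignment"] = {
                    "main_site": verdict.main_site,
                    "secondary_site": verdict.secondary_site,
                    "median_ratio_per_probe": dict(verdict.median_ratio_per_probe),
                    "margin_percent": verdict.margin,
                    "ambiguous": verdict.ambiguous,
                    "statistic": verdict.statistic,
                }
                report.stages[f"assign:{ligand}"] = {"status": "ok"}
            except LigbindError as exc:
                report.stages[f"assign:{ligand}"] = {
                    "status": "error", "category": exc.category, "message": str(exc)}

    if dialysis:
        try:
            report.binding_degree = binding_degree_summary(dialysis)
            report.stages["binding-degree"] = {"status": "ok", "n": len(dialysis)}
        except LigbindError as exc:
            report.stages["binding-degree"] = {
                "status": "error", "category": exc.category, "message": str(exc)}
    return report
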