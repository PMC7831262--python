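"""End-to-end screen pipeline: simulate -> validate -> QC -> hits -> enrichment.

One :class:`RunConfig` carries every tunable with its default (hit-call
k_sd = 3, hypertrophy ratio threshold 1.5, sphere thresholds 80/30/50 um,
sphere frequency 1/500, bolus 2 uL into 7 uL). A run writes its tables,
QC report, hit list, enrichment result, resolved config, log and a
checksum manifest into one output directory; identical seeds give
identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import platescreen, synthdata
from .errors import ConfigError

logger = logging.getLogger(__name__)

VALID_ROLES = {"control_1x", "control_2x", "compound", "empty"}


@dataclass
class RunConfig:
    """Every pipeline tunable, with defaults mirroring the screen design."""

    out_dir: str = "phenoscreen_run"
    seed: int = 0
    # analysis
    k_sd: float = 3.0
    hypertrophy_threshold: float = 1.5
    pooling: str = "screen"
    enrichment_class: str | None = None
    min_ssmd: float = 3.0  # QC gate on the weaker channel
    # simulation (used when no input tables are supplied)
    n_screens: int = 2
    n_compounds: int = 400
    effect_table: dict = field(default_factory=dict)  # compound -> [fold_n, fold_a]
    control_cv: float = 0.1
    channel_correlation: float = 0.5
    library_classes: dict = field(default_factory=dict)  # compound -> class
    # fixed assay constants
    rsc_threshold_um: float = 80.0
    pmp_min_um: float = 30.0
    pmp_large_um: float = 50.0
    sphere_frequency: float = 1.0 / 500.0
    bolus_volume_ul: float = 2.0
    final_volume_ul: float = 7.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class ValidationReport:
    errors: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    plate_map: pd.DataFrame,
    measurements: pd.DataFrame,
    library: pd.DataFrame | None = None,
) -> ValidationReport:
    """Schema, role-coverage and referential-integrity checks.

    Errors: missing columns, unknown role labels, measurement wells absent
    from the plate map, fewer than two 1x control wells, compound wells
    without a compound id. Warnings: plate-map wells with no measurement,
    compounds missing from the library annotation.
    """
    errors: list[str] = []
    warnings: list[str] = []

    need_map = {"plate_id", "well", "role", "compound_id", "conc_um"}
    need_meas = {"plate_id", "well", "nuclei_count", "gfp_area"}
    missing = need_map - set(plate_map.columns)
    if missing:
        errors.append(f"plate map missing columns: {sorted(missing)}")
    missing = need_meas - set(measurements.columns)
    if missing:
        errors.append(f"measurements missing columns: {sorted(missing)}")
    if errors:
        return ValidationReport(errors=errors, warnings=warnings)

    bad_roles = set(plate_map["role"]) - VALID_ROLES
    if bad_roles:
        errors.append(f"unknown role labels: {sorted(bad_roles)}")

    map_keys = set(zip(plate_map["plate_id"], plate_map["well"]))
    meas_keys = set(zip(measurements["plate_id"], measurements["well"]))
    orphans = meas_keys - map_keys
    if orphans:
        errors.append(f"{len(orphans)} measured well(s) absent from plate map")
    unmeasured = map_keys - meas_keys
    if unmeasured:
        warnings.append(f"{len(unmeasured)} plate-map well(s) have no measurement")

    n_ctrl = int((plate_map["role"] == "control_1x").sum())
    if n_ctrl < 2:
        errors.append(f"insufficient controls: {n_ctrl} control_1x well(s), need >= 2")

    comp = plate_map[plate_map["role"] == "compound"]
    if comp["compound_id"].isna().any():
        errors.append("compound wells without compound_id")
    if library is not None:
        unknown = set(comp["compound_id"].dropna()) - set(library["compound_id"])
        if unknown:
            warnings.append(f"{len(unknown)} compound(s) missing from library annotation")

    if (measurements[["nuclei_count", "gfp_area"]] < 0).any().any():
        errors.append("negative measurements")
    return ValidationReport(errors=errors, warnings=warnings)


def _write_checksums(out: Path) -> None:
    manifest = {}
    for p in sorted(out.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_screen_pipeline(
    config: RunConfig,
    plate_tables: list[pd.DataFrame] | None = None,
    library: pd.DataFrame | None = None,
) -> dict:
    """Run the full screen analysis; returns the in-memory results.

    When ``plate_tables`` is None, ``config.n_screens`` screens are
    simulated from ``config.effect_table`` (compounds absent from the
    table are padded at fold 1 up to ``config.n_compounds``). Artifacts
    (wells.csv per screen, hits.csv, qc.json, enrichment.json, the
    resolved config, a log and a sha256 manifest) land in
    ``config.out_dir``. ``result["qc_pass"]`` reflects the SSMD gate.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    if plate_tables is None:
        effects = {c: tuple(f) for c, f in config.effect_table.items()}
        for i in range(len(effects), config.n_compounds):
            effects.setdefault(f"cmpd_{i + 1:04d}", (1.0, 1.0))
        plate_tables = []
        for s in range(config.n_screens):
            sim = synthdata.ScreenSimConfig(
                effect_table=effects,
                control_cv=config.control_cv,
                channel_correlation=config.channel_correlation,
                seed=config.seed * 1000 + s,
            )
            df, _ = synthdata.gen_screen_plate(sim)
            plate_tables.append(df)
            log(f"simulated screen {s + 1}: {len(df)} wells (seed {sim.seed})")
    if library is None and config.library_classes:
        library = pd.DataFrame(
            {"compound_id": list(config.library_classes),
             "class": list(config.library_classes.values())}
        )

    qc_report, hit_frames, hit_lists, qc_pass = {}, [], [], True
    for i, wells in enumerate(plate_tables, start=1):
        rep = validate_inputs(
            wells[["plate_id", "well", "role", "compound_id", "conc_um"]],
            wells[["plate_id", "well", "nuclei_count", "gfp_area"]],
            library,
        )
        if not rep.ok:
            raise ConfigError(f"screen {i} failed validation: {rep.errors}")
        for w in rep.warnings:
            log(f"screen {i} warning: {w}")
        s1 = platescreen.control_stats(wells, "control_1x")
        s2 = platescreen.control_stats(wells, "control_2x")
        qc = platescreen.screen_qc(s1, s2)
        qc_report[f"screen_{i}"] = {
            "ssmd": dict(qc.ssmd),
            "signal_to_noise": dict(qc.signal_to_noise),
            "cv_1x": dict(qc.cv_1x),
            "cv_2x": dict(qc.cv_2x),
        }
        if min(qc.ssmd.values()) < config.min_ssmd:
            qc_pass = False
            log(f"screen {i} FAILED QC gate: min SSMD {min(qc.ssmd.values()):.2f} "
                f"< {config.min_ssmd}")
        calls = platescreen.call_hits(
            wells, k_sd=config.k_sd,
            hypertrophy_threshold=config.hypertrophy_threshold,
            pooling=config.pooling,
        ).assign(screen=i)
        log(f"screen {i}: k_sd={config.k_sd}, pooling={config.pooling}, "
            f"{int(calls['is_hit'].sum())} dual-channel hit(s)")
        hit_frames.append(calls)
        hit_lists.append(sorted(calls.loc[calls["is_hit"], "compound_id"]))
        wells.to_csv(out / f"wells_screen{i}.csv", index=False)

    hits = pd.concat(hit_frames, ignore_index=True)
    recon = platescreen.reconcile_screens(hit_lists)
    log(f"reconciled {recon['per_screen_counts']} -> {recon['n_unique']} unique hit(s)")

    enrichment = None
    if config.enrichment_class is not None and library is not None:
        res = platescreen.class_enrichment(
            library, recon["union"], config.enrichment_class
        )
        enrichment = dataclasses.asdict(res)
        log(f"enrichment of {res.class_name!r}: k={res.class_hits}/K={res.class_size}, "
            f"p_tail={res.p_tail:.3g}")
        (out / "enrichment.json").write_text(json.dumps(enrichment, indent=2))

    hits.to_csv(out / "hits.csv", index=False)
    (out / "qc.json").write_text(json.dumps(qc_report, indent=2, sort_keys=True))
    (out / "reconciled.json").write_text(json.dumps(recon, indent=2))
    config.to_yaml(out / "config.yaml")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    _write_checksums(out)
    return {
        "qc": qc_report,
        "qc_pass": qc_pass,
        "hits": hits,
        "hit_lists": hit_lists,
        "reconciled": recon,
        "enrichment": enrichment,
        "out_dir": str(out),
    }
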