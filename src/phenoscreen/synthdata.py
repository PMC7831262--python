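"""Synthetic screening and assay data with known ground truth.

Generates well-level screening plates, clonal sphere assays, dose-response
series, and viability/proliferation time courses with the statistical
structure the analysis modules assume: percent-of-control normalisable
plates with 1x vehicle controls and 2x-density pseudo-positive controls,
lognormal sphere diameters around a size threshold, and binomial
EthD-1/EdU labelling counts. Every generator returns both a tidy table and
a :class:`SimTruth` record so estimator-recovery tests can compare against
the configured truth.

Noise model
-----------
Channel noise is multiplicative and CV-parameterised. The default is
lognormal (strictly positive, CV-stable, the usual behaviour of cell-count
data); a Gaussian option (``1 + cv*z``) is provided for analytic-tail
calibration studies. Nuclei-count and GFP-area noise share a latent
bivariate-normal factor with configurable correlation, since both channels
read out the same cell population. Counts are rounded; pathological
negative draws are truncated at zero and logged, never silent.

Seeding
-------
Each config carries one master seed; every table derives its own
``numpy.random.Generator`` from a named child of that seed, so adding a
generator never shifts the streams of existing ones and identical
seed + config is bit-identical after serialization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

logger = logging.getLogger(__name__)

PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = 12
WELLS_PER_PLATE = len(PLATE_ROWS) * PLATE_COLS  # 96

_STREAMS = {"screen": 0, "sphere": 1, "timecourse": 2, "dose": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the master seed (stable across generator additions)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def _noise_factors(
    rng: np.random.Generator, n: int, cv: float, model: str, z: np.ndarray | None = None
) -> np.ndarray:
    """Multiplicative noise factors with unit mean and the given CV."""
    if cv < 0:
        raise ConfigError(f"CV must be >= 0, got {cv}")
    if cv == 0:
        return np.ones(n)
    if z is None:
        z = rng.standard_normal(n)
    if model == "gaussian":
        return 1.0 + cv * z
    if model == "lognormal":
        sigma = np.sqrt(np.log1p(cv**2))
        return np.exp(sigma * z - 0.5 * sigma**2)
    raise ConfigError(f"unknown noise model {model!r}")


def _finalize_counts(values: np.ndarray, what: str) -> np.ndarray:
    """Round to integer counts, truncating negatives at zero (logged)."""
    n_neg = int(np.sum(values < 0))
    if n_neg:
        logger.warning("%d negative %s draw(s) truncated at 0", n_neg, what)
    return np.rint(np.clip(values, 0, None)).astype(np.int64)


@dataclass
class SimTruth:
    """Ground-truth record emitted alongside every synthetic table.

    ``kind`` names the generator; ``params`` holds the true parameter
    values (folds, frequencies, per-day fractions, ...) on their natural
    scale. Round-trips losslessly through JSON.
    """

    kind: str
    seed: int
    params: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(kind=d["kind"], seed=d["seed"], params=d["params"])


# ---------------------------------------------------------------------------
# Screening plates
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """One screen: vehicle controls, 2x-density pseudo-positives, compounds.

    Well counts are totals across the screen's ``n_plates`` plates;
    control wells are spread round-robin across plates, compound wells
    fill the remainder in library order (single replicate per compound,
    matching the one-well-per-compound screen design). Compound wells are
    dosed at ``conc_um``; every compound in ``effect_table`` gets one well.
    """

    effect_table: Mapping[str, tuple[float, float]]  # compound -> (fold_nuclei, fold_area)
    n_plates: int | None = None  # None: fewest plates that hold all wells
    wells_control_1x: int = 80
    wells_control_2x: int = 12
    control_nuclei_mean: float = 1000.0
    control_cv: float = 0.1
    channel_correlation: float = 0.5
    area_per_cell_mean: float = 400.0  # um^2 of GFP footprint per cell
    conc_um: float = 1.0
    noise_model: str = "lognormal"
    seed: int = 0

    @property
    def n_wells_total(self) -> int:
        return self.wells_control_1x + self.wells_control_2x + len(self.effect_table)

    def validate(self) -> None:
        n_total = self.n_wells_total
        if self.n_plates is not None and n_total > self.n_plates * WELLS_PER_PLATE:
            raise ConfigError(
                f"{n_total} wells exceed capacity of {self.n_plates} x 96-well plates"
            )
        if self.wells_control_1x < 2:
            raise ConfigError("need >= 2 control_1x wells")
        if self.control_cv < 0:
            raise ConfigError("control_cv must be >= 0")
        if not -1.0 <= self.channel_correlation <= 1.0:
            raise ConfigError("channel_correlation must lie in [-1, 1]")
        for comp, (fn, fa) in self.effect_table.items():
            if fn < 0 or fa < 0:
                raise ConfigError(f"negative effect fold for {comp!r}")


def _well_positions(n: int) -> tuple[list[int], list[str], list[str], list[int]]:
    """Sequential A1..H12 positions across as many plates as needed."""
    plates, wells, rows, cols = [], [], [], []
    for i in range(n):
        plate, idx = divmod(i, WELLS_PER_PLATE)
        r, c = divmod(idx, PLATE_COLS)
        plates.append(plate + 1)
        rows.append(PLATE_ROWS[r])
        cols.append(c + 1)
        wells.append(f"{PLATE_ROWS[r]}{c + 1}")
    return plates, wells, rows, cols


def gen_screen_plate(config: ScreenSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate one full screen as a tidy well table plus its ground truth.

    Returns a DataFrame with one row per well: ``plate_id, well, row, col,
    role, compound_id, conc_um, nuclei_count, gfp_area``. 1x controls are
    drawn around the control mean, 2x controls around twice it, and each
    compound well around control mean x its configured per-channel fold.
    """
    config.validate()
    rng = _rng(config.seed, "screen")

    compounds = list(config.effect_table)
    roles = (
        ["control_1x"] * config.wells_control_1x
        + ["control_2x"] * config.wells_control_2x
        + ["compound"] * len(compounds)
    )
    n = len(roles)
    # interleave controls among compounds deterministically so each plate
    # carries its share of controls
    order = rng.permutation(n)
    roles = [roles[i] for i in order]
    comp_iter = iter(compounds)
    compound_ids = [next(comp_iter) if r == "compound" else None for r in roles]

    fold_n = np.ones(n)
    fold_a = np.ones(n)
    for i, (role, comp) in enumerate(zip(roles, compound_ids)):
        if role == "control_2x":
            fold_n[i] = fold_a[i] = 2.0
        elif role == "compound":
            fn, fa = config.effect_table[comp]
            fold_n[i], fold_a[i] = fn, fa

    rho = config.channel_correlation
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    m = config.control_nuclei_mean
    nuclei = m * fold_n * _noise_factors(rng, n, config.control_cv, config.noise_model, z1)
    area = (
        m
        * config.area_per_cell_mean
        * fold_a
        * _noise_factors(rng, n, config.control_cv, config.noise_model, z2)
    )

    plates, wells, rows, cols = _well_positions(n)
    df = pd.DataFrame(
        {
            "plate_id": plates,
            "well": wells,
            "row": rows,
            "col": cols,
            "role": roles,
            "compound_id": compound_ids,
            "conc_um": [config.conc_um if r == "compound" else 0.0 for r in roles],
            "nuclei_count": _finalize_counts(nuclei, "nuclei"),
            "gfp_area": np.clip(area, 0, None),
        }
    )
    truth = SimTruth(
        kind="screen",
        seed=config.seed,
        params={
            "control_nuclei_mean": config.control_nuclei_mean,
            "control_gfp_area_mean": config.control_nuclei_mean * config.area_per_cell_mean,
            "control_cv": config.control_cv,
            "channel_correlation": config.channel_correlation,
            "effects": {c: list(f) for c, f in config.effect_table.items()},
        },
    )
    return df, truth


# ---------------------------------------------------------------------------
# Clonal sphere assays
# ---------------------------------------------------------------------------

@dataclass
class SphereSimConfig:
    """Clonal sphere assay: rare founders, lognormal diameters.

    Defaults reflect the retinal stem cell assay: ~1/500 plated cells
    found a free-floating clonal sphere after 7 days, with diameters
    spread around the 80-um stem/progenitor threshold. ``assay_kind``
    "PMP" marks the pancreatic assay (30/50-um bins downstream).
    Treatment enters as multiplicative shifts of the founding frequency
    and of the median diameter.
    """

    n_cells_plated: int = 10_000
    sphere_frequency: float = 1.0 / 500.0
    diameter_log_mean: float = float(np.log(70.0))  # median 70 um
    diameter_log_sd: float = 0.35
    treatment_diameter_shift: float = 1.0
    treatment_frequency_shift: float = 1.0
    assay_kind: str = "RSC"
    condition: str = "control"
    intensity_mean: float | None = None  # per-sphere mean gray value, if simulated
    intensity_cv: float = 0.2
    treatment_intensity_shift: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.sphere_frequency <= 1.0:
            raise ConfigError("sphere_frequency must lie in [0, 1]")
        eff = self.sphere_frequency * self.treatment_frequency_shift
        if not 0.0 <= eff <= 1.0:
            raise ConfigError(f"effective sphere frequency {eff} outside [0, 1]")
        if self.n_cells_plated < 0:
            raise ConfigError("n_cells_plated must be >= 0")
        if self.diameter_log_sd < 0:
            raise ConfigError("diameter_log_sd must be >= 0")
        if self.assay_kind not in ("RSC", "PMP"):
            raise ConfigError(f"unknown assay_kind {self.assay_kind!r}")


def gen_sphere_assay(config: SphereSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate one sphere-assay condition.

    Sphere count ~ Binomial(n_cells_plated, frequency x frequency_shift);
    diameters lognormal with the configured median shift. Columns:
    ``sample_id, condition, assay_kind, sphere_id, diameter_um,
    mean_intensity`` (intensity NaN unless configured).
    """
    config.validate()
    rng = _rng(config.seed, "sphere")
    p = config.sphere_frequency * config.treatment_frequency_shift
    k = int(rng.binomial(config.n_cells_plated, p)) if config.n_cells_plated else 0
    log_mean = config.diameter_log_mean + np.log(config.treatment_diameter_shift)
    diam = np.exp(log_mean + config.diameter_log_sd * rng.standard_normal(k))
    if config.intensity_mean is not None:
        inten = (
            config.intensity_mean
            * config.treatment_intensity_shift
            * _noise_factors(rng, k, config.intensity_cv, "lognormal")
        )
    else:
        inten = np.full(k, np.nan)
    df = pd.DataFrame(
        {
            "sample_id": [f"{config.condition}_s{config.seed}"] * k,
            "condition": [config.condition] * k,
            "assay_kind": [config.assay_kind] * k,
            "sphere_id": np.arange(1, k + 1),
            "diameter_um": diam,
            "mean_intensity": inten,
        }
    )
    truth = SimTruth(
        kind="sphere",
        seed=config.seed,
        params={
            "condition": config.condition,
            "assay_kind": config.assay_kind,
            "n_cells_plated": config.n_cells_plated,
            "true_frequency": p,
            "diameter_log_mean": log_mean,
            "diameter_log_sd": config.diameter_log_sd,
        },
    )
    return df, truth


# ---------------------------------------------------------------------------
# Viability / proliferation time courses
# ---------------------------------------------------------------------------

@dataclass
class TimecourseSimConfig:
    """Monolayer time course with EthD-1 (death) and EdU (S-phase) labelling.

    Defaults mirror the retinal progenitor monolayer assay: heavy early
    death (live fraction ~0.42 at day 2) resolving by day 6 (~0.90), and
    an S-phase pulse peaking at day 4. Per-compound EdU folds multiply the
    control EdU fraction day-wise; products above 1 are clipped with a
    logged warning. ``sampling="expected"`` replaces binomial draws with
    rounded expected counts — the zero-noise mode for exact-recovery use.
    """

    days: Sequence[int] = (2, 4, 6)
    live_fraction_means: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.42, 4: 0.80, 6: 0.90}
    )
    edu_fraction_control: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.02, 4: 0.05, 6: 0.005}
    )
    edu_fold_by_compound: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    n_wells: int = 6
    cells_per_well: int = 2000
    sampling: str = "binomial"  # or "expected"
    seed: int = 0

    def validate(self) -> None:
        for day in self.days:
            if day not in self.live_fraction_means:
                raise ConfigError(f"day {day} missing from live_fraction_means")
            if day not in self.edu_fraction_control:
                raise ConfigError(f"day {day} missing from edu_fraction_control")
        for m in (self.live_fraction_means, self.edu_fraction_control):
            for day, p in m.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"fraction {p} for day {day} outside [0, 1]")
        for comp, folds in self.edu_fold_by_compound.items():
            for day in self.days:
                if day not in folds:
                    raise ConfigError(f"day {day} missing from EdU folds of {comp!r}")
        if self.sampling not in ("binomial", "expected"):
            raise ConfigError(f"unknown sampling mode {self.sampling!r}")


def gen_timecourse(config: TimecourseSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate the time course for control plus every configured compound.

    Per well per day: ``total`` nuclei (= cells_per_well), EthD-1-positive
    ~ Binomial(total, 1 - live fraction), EdU-positive ~ Binomial(total,
    control EdU fraction x fold). Columns: ``well_id, condition, day,
    total, ethd1_pos, edu_pos``.
    """
    config.validate()
    rng = _rng(config.seed, "timecourse")
    conditions = ["control"] + list(config.edu_fold_by_compound)
    rows = []
    clipped = 0
    for cond in conditions:
        for day in config.days:
            p_dead = 1.0 - config.live_fraction_means[day]
            p_edu = config.edu_fraction_control[day]
            if cond != "control":
                p_edu *= config.edu_fold_by_compound[cond][day]
                if p_edu > 1.0:
                    clipped += 1
                    p_edu = 1.0
            for w in range(config.n_wells):
                total = config.cells_per_well
                if config.sampling == "binomial":
                    dead = int(rng.binomial(total, p_dead))
                    edu = int(rng.binomial(total, p_edu))
                else:
                    dead = int(round(total * p_dead))
                    edu = int(round(total * p_edu))
                rows.append((f"{cond}_d{day}_w{w + 1}", cond, day, total, dead, edu))
    if clipped:
        logger.warning("%d EdU fold x fraction product(s) clipped to 1.0", clipped)
    df = pd.DataFrame(
        rows, columns=["well_id", "condition", "day", "total", "ethd1_pos", "edu_pos"]
    )
    truth = SimTruth(
        kind="timecourse",
        seed=config.seed,
        params={
            "days": list(config.days),
            "live_fraction_means": {str(d): config.live_fraction_means[d] for d in config.days},
            "edu_fraction_control": {str(d): config.edu_fraction_control[d] for d in config.days},
            "edu_fold_by_compound": {
                c: {str(d): f[d] for d in config.days}
                for c, f in config.edu_fold_by_compound.items()
            },
        },
    )
    return df, truth


# ---------------------------------------------------------------------------
# Dose-response series
# ---------------------------------------------------------------------------

def gen_dose_response(
    compounds: Sequence[str],
    doses: Sequence[float],
    folds: Mapping[tuple[str, float], float],
    replicates: int = 3,
    noise_cv: float = 0.1,
    control_mean: float = 1000.0,
    noise_model: str = "lognormal",
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a multi-point dose-response table with vehicle rows.

    Each (compound, dose) cell gets ``replicates`` cell counts drawn
    around ``control_mean x fold``; vehicle rows sit at fold 1 with the
    same replicate count and noise. Columns: ``compound_id, dose_um,
    replicate, cell_count, condition``.
    """
    doses = [float(d) for d in doses]
    if len(set(doses)) != len(doses) or any(d <= 0 for d in doses):
        raise ConfigError("doses must be positive and distinct")
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    for comp in compounds:
        for d in doses:
            if (comp, d) not in folds:
                raise ConfigError(f"missing fold for ({comp!r}, {d} uM)")

    rng = _rng(seed, "dose")
    rows = []
    noise = lambda n: _noise_factors(rng, n, noise_cv, noise_model)  # noqa: E731
    for r, f in enumerate(noise(replicates), start=1):
        rows.append(("vehicle", 0.0, r, control_mean * f, "vehicle"))
    for comp in compounds:
        for d in doses:
            mu = control_mean * folds[(comp, d)]
            for r, f in enumerate(noise(replicates), start=1):
                rows.append((comp, d, r, mu * f, "drug"))
    df = pd.DataFrame(
        rows, columns=["compound_id", "dose_um", "replicate", "cell_count", "condition"]
    )
    df["cell_count"] = _finalize_counts(df["cell_count"].to_numpy(), "cell count")
    truth = SimTruth(
        kind="dose_response",
        seed=seed,
        params={
            "control_mean": control_mean,
            "noise_cv": noise_cv,
            "folds": {f"{c}@{d}": folds[(c, d)] for c in compounds for d in doses},
        },
    )
    return df, truth
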