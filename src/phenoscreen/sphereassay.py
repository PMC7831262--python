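"""Clonal sphere assay quantification.

Free-floating clonal sphere assays read out stem/progenitor activity: a
rare founding cell (~1 in 500 for retinal stem cells) proliferates into a
sphere whose diameter separates stem-derived from progenitor-derived
colonies. Two binning conventions are supported:

* ``RSC`` — retinal stem cell assay: spheres >= 80 um are stem-derived,
  < 80 um progenitor-derived. The 80-um boundary is inclusive (a sphere at
  exactly 80.0 um counts as stem-derived); the constant is configurable.
* ``PMP`` — pancreatic multipotent progenitor assay: objects < 30 um are
  aggregation artifacts and excluded entirely; quantified bins are
  total >= 30 um, 30-49 um, and >= 50 um.

Also provided: sphere-forming frequency with an exact (Clopper-Pearson)
binomial CI, fold-changes with Welch's t test, the drug-free tertiary
passaging self-renewal index, and per-sphere mean gray value from a
label-mask/image pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InputConsistencyError, InsufficientReplicatesError

logger = logging.getLogger(__name__)

RSC_THRESHOLD_UM = 80.0
PMP_MIN_UM = 30.0
PMP_LARGE_UM = 50.0


@dataclass
class SphereBins:
    """Size-bin counts for one sphere-assay condition."""

    assay_kind: str
    counts: Mapping[str, int]
    n_rejected: int = 0  # nonpositive diameters dropped
    n_cells_plated: int | None = None


@dataclass
class SphereFrequency:
    """Sphere-forming frequency with an exact 95% binomial CI."""

    n_spheres: int
    n_cells_plated: int
    frequency: float
    ci_low: float
    ci_high: float


@dataclass
class SelfRenewalResult:
    condition: str
    tertiary_sphere_count: float
    fold_vs_control: float


def classify_spheres(
    records: pd.DataFrame,
    assay_kind: str,
    rsc_threshold_um: float = RSC_THRESHOLD_UM,
    pmp_min_um: float = PMP_MIN_UM,
    pmp_large_um: float = PMP_LARGE_UM,
    n_cells_plated: int | None = None,
) -> SphereBins:
    """Bin sphere diameters by the assay's size convention.

    All size boundaries are inclusive on the upper bin (>= threshold).
    Records with nonpositive diameter are rejected with a logged reason;
    an empty table yields all-zero bins.
    """
    if assay_kind not in ("RSC", "PMP"):
        raise ValueError(f"unknown assay_kind {assay_kind!r}")
    d = records["diameter_um"].to_numpy(dtype=float) if len(records) else np.array([])
    bad = ~(d > 0)
    if bad.any():
        logger.warning("rejecting %d sphere(s) with nonpositive diameter", int(bad.sum()))
    d = d[~bad]
    if assay_kind == "RSC":
        counts = {
            "lt_80": int((d < rsc_threshold_um).sum()),
            "ge_80": int((d >= rsc_threshold_um).sum()),
        }
    else:
        mid = (d >= pmp_min_um) & (d < pmp_large_um)
        counts = {
            "ge_30_total": int((d >= pmp_min_um).sum()),
            "30_49": int(mid.sum()),
            "ge_50": int((d >= pmp_large_um).sum()),
        }
    return SphereBins(
        assay_kind=assay_kind,
        counts=counts,
        n_rejected=int(bad.sum()),
        n_cells_plated=n_cells_plated,
    )


def sphere_forming_frequency(n_spheres: int, n_cells_plated: int) -> SphereFrequency:
    """Frequency = spheres/cells plated, with a Clopper-Pearson 95% CI."""
    if n_cells_plated <= 0:
        raise ValueError("n_cells_plated must be positive")
    if not 0 <= n_spheres <= n_cells_plated:
        raise InputConsistencyError(
            f"{n_spheres} spheres from {n_cells_plated} cells is impossible"
        )
    lo, hi = proportion_confint(n_spheres, n_cells_plated, alpha=0.05, method="beta")
    return SphereFrequency(
        n_spheres=int(n_spheres),
        n_cells_plated=int(n_cells_plated),
        frequency=n_spheres / n_cells_plated,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def sphere_fold_change(
    treated_counts: Iterable[float], control_counts: Iterable[float]
) -> dict:
    """Fold-change of per-replicate sphere counts with a Welch two-sided t.

    fold = mean(treated)/mean(control). Requires >= 2 replicates per group
    and a positive control mean.
    """
    t_arr = np.asarray(list(treated_counts), dtype=float)
    c_arr = np.asarray(list(control_counts), dtype=float)
    if t_arr.size < 2 or c_arr.size < 2:
        raise InsufficientReplicatesError("need >= 2 replicates per condition")
    c_mean = c_arr.mean()
    if c_mean <= 0:
        raise ValueError("control mean must be positive for a fold-change")
    res = stats.ttest_ind(t_arr, c_arr, equal_var=False)
    return {
        "fold": float(t_arr.mean() / c_mean),
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "n_treated": int(t_arr.size),
        "n_control": int(c_arr.size),
    }


def self_renewal_index(
    tertiary_counts: Mapping[str, Sequence[float] | float], control_label: str
) -> list[SelfRenewalResult]:
    """Fold-change in drug-free tertiary sphere count vs control.

    The assay passages spheres grown under each condition into compound-free
    tertiary culture; the tertiary sphere count relative to control proxies
    symmetric stem-cell self-renewal during the prior exposure. Values may
    be scalars or per-replicate sequences (means are used).
    """
    if control_label not in tertiary_counts:
        raise InputConsistencyError(f"control label {control_label!r} missing")
    means = {
        cond: float(np.mean(np.atleast_1d(np.asarray(v, dtype=float))))
        for cond, v in tertiary_counts.items()
    }
    c_mean = means[control_label]
    if c_mean <= 0:
        raise ValueError("control tertiary count must be positive")
    return [
        SelfRenewalResult(
            condition=cond,
            tertiary_sphere_count=m,
            fold_vs_control=m / c_mean,
        )
        for cond, m in means.items()
    ]


def sphere_mean_intensity(mask: np.ndarray, image: np.ndarray) -> dict[int, float]:
    """Mean gray value of each labelled sphere in an intensity image.

    ``mask`` holds positive integer labels (0 = background); the mean is
    the arithmetic mean of ``image`` pixels under each label, background
    excluded. Labels absent from the mask are skipped with a warning.
    """
    mask = np.asarray(mask)
    image = np.asarray(image, dtype=float)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    if mask.size and mask.min() < 0:
        raise ValueError("labels must be nonnegative integers")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        logger.warning("mask contains no labelled spheres")
        return {}
    means = ndimage.mean(image, labels=mask, index=labels)
    return {int(lbl): float(m) for lbl, m in zip(labels, means)}
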