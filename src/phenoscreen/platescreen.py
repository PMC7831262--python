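"""Plate-level screen analysis: POC normalisation, QC, 3-SD hit calling.

The screen design this module analyses: 96-well plates of single-replicate
compound wells surrounded by 1x-density vehicle controls and 2x-density
pseudo-positive controls. Measurements are two channels per well — nuclei
count and GFP area. A hit is a compound whose value on *both* channels
strictly exceeds the vehicle-control mean + k SD (k = 3 by default); the
GFP-area-to-nuclei POC ratio screens hits for hypertrophy (bigger cells
rather than more cells).

Thresholds are computed by default from the screen's pooled 1x controls
(one control set per screen); a per-plate mode is available. The hit
criterion is affine-equivariant, so calling on raw values or on
percent-of-control values gives identical flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateControlError,
    InputConsistencyError,
    InsufficientReplicatesError,
)

CHANNELS = ("nuclei_count", "gfp_area")


@dataclass
class ChannelSummary:
    """Mean/SD/CV of one channel over one control group (sample SD, n-1)."""

    n: int
    mean: float
    sd: float
    cv: float
    degenerate: bool  # sd == 0

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "ChannelSummary":
        x = np.asarray(list(values), dtype=float)
        if x.size < 2:
            raise InsufficientReplicatesError(
                f"need >= 2 values for an SD, got {x.size}"
            )
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        cv = sd / mean if mean != 0 else float("nan")
        return cls(n=int(x.size), mean=mean, sd=sd, cv=cv, degenerate=(sd == 0.0))


@dataclass
class ControlSummary:
    """Per-channel control statistics for one role (control_1x or control_2x)."""

    role: str
    channels: Mapping[str, ChannelSummary]


@dataclass
class ScreenQC:
    """Screen quality metrics from the 1x vs 2x control separation.

    SSMD uses the two-group unequal-variance form
    (mean_2x - mean_1x) / sqrt(sd_1x^2 + sd_2x^2); signal-to-noise is
    (mean_2x - mean_1x) / sd_1x.
    """

    ssmd: Mapping[str, float]
    signal_to_noise: Mapping[str, float]
    cv_1x: Mapping[str, float]
    cv_2x: Mapping[str, float]


@dataclass
class HitCall:
    """Per-compound call: POC per channel, per-channel and combined flags."""

    compound_id: str
    poc_nuclei: float
    poc_area: float
    hit_nuclei: bool
    hit_area: bool
    is_hit: bool
    hypertrophy_ratio: float
    hypertrophy_flag: bool
    boundary_tie: bool = False  # sat exactly on a threshold on some channel


@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric enrichment of one compound class in the hits."""

    class_name: str
    library_size: int  # N
    class_size: int  # K
    hits_drawn: int  # n
    class_hits: int  # k
    p_tail: float  # P(X >= k)


def poc_normalize(values, control_values) -> np.ndarray:
    """Percent-of-control: 100 x value / mean(vehicle controls).

    The control wells' own POC values average exactly 100 by construction.
    Raises :class:`DegenerateControlError` when the control mean is <= 0.
    """
    controls = np.asarray(list(control_values), dtype=float)
    if controls.size < 2:
        raise InsufficientReplicatesError("need >= 2 control values")
    m = controls.mean()
    if m <= 0:
        raise DegenerateControlError(f"control mean {m} is not positive")
    return 100.0 * np.asarray(values, dtype=float) / m


def control_stats(wells: pd.DataFrame, role: str = "control_1x") -> ControlSummary:
    """Per-channel mean, sample SD and CV of the wells with the given role."""
    sub = wells[wells["role"] == role]
    if len(sub) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 wells with role {role!r}, got {len(sub)}"
        )
    return ControlSummary(
        role=role,
        channels={ch: ChannelSummary.from_values(sub[ch]) for ch in CHANNELS},
    )


def screen_qc(summary_1x: ControlSummary, summary_2x: ControlSummary) -> ScreenQC:
    """QC metrics from the separation between 1x and 2x control groups."""
    ssmd, s2n, cv1, cv2 = {}, {}, {}, {}
    for ch in CHANNELS:
        a, b = summary_1x.channels[ch], summary_2x.channels[ch]
        denom = np.sqrt(a.sd**2 + b.sd**2)
        if denom == 0:
            raise DegenerateControlError(
                f"both control SDs are zero on {ch}; SSMD undefined"
            )
        ssmd[ch] = (b.mean - a.mean) / denom
        s2n[ch] = (b.mean - a.mean) / a.sd if a.sd > 0 else float("inf")
        cv1[ch] = a.cv
        cv2[ch] = b.cv
    return ScreenQC(ssmd=ssmd, signal_to_noise=s2n, cv_1x=cv1, cv_2x=cv2)


def call_hits(
    wells: pd.DataFrame,
    k_sd: float = 3.0,
    hypertrophy_threshold: float = 1.5,
    pooling: str = "screen",
) -> pd.DataFrame:
    """Call dual-channel hits against control mean + k_sd x control SD.

    ``pooling="screen"`` (default) derives one threshold per channel from
    all 1x control wells pooled across plates; ``"plate"`` thresholds each
    plate against its own controls. The inequality is strict; compounds
    sitting exactly on a threshold are reported with ``boundary_tie``.

    Returns one row per compound well with POC values, per-channel flags,
    the combined flag, and the hypertrophy ratio POC(area)/POC(nuclei).
    """
    if pooling not in ("screen", "plate"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    groups = [wells] if pooling == "screen" else [
        g for _, g in wells.groupby("plate_id", sort=True)
    ]
    frames = []
    for g in groups:
        summary = control_stats(g, "control_1x")
        for ch in CHANNELS:
            if summary.channels[ch].degenerate:
                raise DegenerateControlError(
                    f"control SD is zero on {ch}; inspect screen_qc before hit calling"
                )
        comp = g[g["role"] == "compound"]
        calls = {"compound_id": comp["compound_id"].to_numpy()}
        ties = np.zeros(len(comp), dtype=bool)
        for ch, name in zip(CHANNELS, ("nuclei", "area")):
            s = summary.channels[ch]
            raw = comp[ch].to_numpy(dtype=float)
            thr = s.mean + k_sd * s.sd
            calls[f"poc_{name}"] = 100.0 * raw / s.mean
            calls[f"hit_{name}"] = raw > thr
            ties |= raw == thr
        frames.append(pd.DataFrame(calls).assign(boundary_tie=ties))
    out = pd.concat(frames, ignore_index=True)
    out["is_hit"] = out["hit_nuclei"] & out["hit_area"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["poc_area"] / out["poc_nuclei"]
    out["hypertrophy_ratio"] = np.where(out["poc_nuclei"] > 0, ratio, np.nan)
    out["hypertrophy_flag"] = out["hypertrophy_ratio"] > hypertrophy_threshold
    cols = [
        "compound_id", "poc_nuclei", "poc_area", "hit_nuclei", "hit_area",
        "is_hit", "hypertrophy_ratio", "hypertrophy_flag", "boundary_tie",
    ]
    return out[cols]


def reconcile_screens(hit_lists: Sequence[Iterable[str]]) -> dict:
    """Combine per-screen hit lists into union/intersection and counts.

    Each list must contain unique compound ids. Returns a dict with
    ``union`` (sorted), ``intersection`` (sorted, hits in *every* screen),
    ``per_screen_counts``, ``n_unique``.
    """
    sets = []
    for i, lst in enumerate(hit_lists, start=1):
        lst = list(lst)
        if len(set(lst)) != len(lst):
            raise InputConsistencyError(f"hit list {i} contains duplicates")
        sets.append(set(lst))
    union = sorted(set().union(*sets)) if sets else []
    inter = sorted(set.intersection(*sets)) if sets else []
    return {
        "union": union,
        "intersection": inter,
        "per_screen_counts": [len(s) for s in sets],
        "n_unique": len(union),
    }


def class_enrichment(
    library: pd.DataFrame,
    hits: Iterable[str],
    class_name: str,
    class_column: str = "class",
    id_column: str = "compound_id",
) -> EnrichmentResult:
    """Exact upper-tail hypergeometric test for one pharmacological class.

    With N library compounds of which K belong to the class, and n hits
    drawn, the p-value is P(X >= k) for the k class members among the
    hits. The draw count n defaults to whatever hit list is passed (e.g.
    the union across screens); pass a per-screen list for per-screen mode.
    """
    hits = list(hits)
    lib_ids = set(library[id_column])
    missing = [h for h in hits if h not in lib_ids]
    if missing:
        raise InputConsistencyError(f"hits not in library: {missing}")
    classes = set(library[class_column])
    if class_name not in classes:
        raise InputConsistencyError(f"class {class_name!r} not in annotation")
    N = len(lib_ids)
    class_ids = set(library.loc[library[class_column] == class_name, id_column])
    K = len(class_ids)
    n = len(hits)
    k = len(class_ids.intersection(hits))
    if k > min(K, n):
        raise InputConsistencyError("more class hits than possible")
    p_tail = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        class_name=class_name, library_size=N, class_size=K,
        hits_drawn=n, class_hits=k, p_tail=p_tail,
    )


def hypertrophy_assess(
    hit_calls: pd.DataFrame, ratio_threshold: float = 1.5
) -> pd.DataFrame:
    """Flag calls whose area:nuclei POC ratio exceeds the threshold.

    Rows with poc_nuclei = 0 have an undefined ratio and are returned in a
    separate ``undefined_ratio`` column rather than flagged.
    """
    out = hit_calls.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["poc_area"] / out["poc_nuclei"]
    out["hypertrophy_ratio"] = np.where(out["poc_nuclei"] > 0, ratio, np.nan)
    out["undefined_ratio"] = ~(out["poc_nuclei"] > 0)
    out["hypertrophy_flag"] = out["hypertrophy_ratio"] > ratio_threshold
    return out
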