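"""Dose-response summaries, receptor effect partitioning, dilution arithmetic.

Dose-response tables are summarised as fold-of-control (ratio of group
means by default; mean of per-replicate ratios optional). A drug's
fold-increase can be partitioned between receptor pathways using
antagonist co-treatment: if the drug alone gives FC_d-fold of control and
drug + antagonist gives FC_c, then the antagonised receptor mediated

    pct = 100 * (FC_d - FC_c) / (FC_d - 1)

percent of the drug-induced increase. Intravitreal bolus dosing follows
final = injected * bolus_volume / final_volume (mouse vitreous 7 uL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateControlError, InputConsistencyError


@dataclass
class EffectPartition:
    """Share of a drug's fold-increase abolished by a receptor antagonist.

    ``pct_mediated`` < 0 (combo above drug) or > 100 (combo below control)
    is reported with ``out_of_range`` set, never clamped — such values are
    diagnostically meaningful.
    """

    fc_drug: float
    fc_combo: float
    pct_mediated: float
    out_of_range: bool


@dataclass
class DilutionSpec:
    injected_conc: float  # uM
    bolus_volume: float  # uL
    final_volume: float  # uL
    final_conc: float  # uM


def summarize_dose_response(
    table: pd.DataFrame, method: str = "ratio_of_means"
) -> dict:
    """Per (compound, dose): mean fold-of-control, SE, N; plus the argmax.

    ``method="ratio_of_means"`` (default): fold = mean(drug)/mean(vehicle),
    SE from the drug-group replicate SD over the vehicle mean (delta
    method with the vehicle treated as a fixed denominator).
    ``method="mean_of_ratios"``: replicate i of the drug group is paired
    with vehicle replicate i and the per-replicate ratios averaged
    (requires matching replicate counts).

    Returns ``{"summary": DataFrame, "max_fold": float, "argmax": [(compound,
    dose), ...]}`` with ties listed.
    """
    if method not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError(f"unknown method {method!r}")
    veh_df = table[table["condition"] == "vehicle"]
    if "replicate" in veh_df.columns:
        veh_df = veh_df.sort_values("replicate")
    veh = veh_df["cell_count"].to_numpy(dtype=float)
    if veh.size == 0:
        raise InputConsistencyError("no vehicle rows in dose-response table")
    v_mean = veh.mean()
    if v_mean <= 0:
        raise DegenerateControlError(f"vehicle mean {v_mean} is not positive")

    drug = table[table["condition"] == "drug"]
    rows = []
    for (comp, dose), g in drug.groupby(["compound_id", "dose_um"], sort=True):
        x = g.sort_values("replicate")["cell_count"].to_numpy(dtype=float)
        if method == "mean_of_ratios":
            if x.size != veh.size:
                raise InputConsistencyError(
                    "mean_of_ratios pairing needs equal drug/vehicle replicate counts"
                )
            ratios = x / veh
        else:
            ratios = x / v_mean
        fold = float(ratios.mean())
        se = float(ratios.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
        rows.append((comp, dose, fold, se, int(x.size)))
    summary = pd.DataFrame(rows, columns=["compound_id", "dose_um", "fold", "se", "n"])
    if summary.empty:
        return {"summary": summary, "max_fold": float("nan"), "argmax": []}
    max_fold = summary["fold"].max()
    argmax = [
        (r.compound_id, r.dose_um)
        for r in summary.itertuples()
        if r.fold == max_fold
    ]
    return {"summary": summary, "max_fold": float(max_fold), "argmax": argmax}


def partition_effect(fc_drug: float, fc_combo: float) -> EffectPartition:
    """Partition a drug's fold-increase using an antagonist co-treatment.

    Defined only when the drug has an effect (fc_drug > 1). Examples from
    a dexamethasone/receptor-blockade experiment: (2.45, 1.78) -> 46.2%
    mediated by the blocked receptor; (2.45, 1.55) -> 62.1%.
    """
    if fc_drug <= 1.0:
        raise InputConsistencyError(
            f"partition undefined: drug fold {fc_drug} shows no increase over control"
        )
    if fc_combo < 0:
        raise InputConsistencyError(f"negative combo fold {fc_combo}")
    pct = 100.0 * (fc_drug - fc_combo) / (fc_drug - 1.0)
    return EffectPartition(
        fc_drug=fc_drug,
        fc_combo=fc_combo,
        pct_mediated=pct,
        out_of_range=not (0.0 <= pct <= 100.0),
    )


def intravitreal_concentration(
    injected_conc: float, bolus_volume: float = 2.0, final_volume: float = 7.0
) -> DilutionSpec:
    """Final in-vivo concentration after an intravitreal bolus.

    A 2-uL bolus into the mouse eye equilibrates to the standard 7-uL
    vitreous volume, so final = injected * 2/7 (35 uM -> 10 uM).
    """
    if bolus_volume <= 0 or final_volume <= 0:
        raise ValueError("volumes must be positive")
    if injected_conc < 0:
        raise ValueError("concentration must be >= 0")
    return DilutionSpec(
        injected_conc=injected_conc,
        bolus_volume=bolus_volume,
        final_volume=final_volume,
        final_conc=injected_conc * bolus_volume / final_volume,
    )


def injected_for_target(
    final_conc: float, bolus_volume: float = 2.0, final_volume: float = 7.0
) -> DilutionSpec:
    """Inverse mode: required injected concentration for a target final one."""
    if bolus_volume <= 0 or final_volume <= 0:
        raise ValueError("volumes must be positive")
    if final_conc < 0:
        raise ValueError("concentration must be >= 0")
    return DilutionSpec(
        injected_conc=final_conc * final_volume / bolus_volume,
        bolus_volume=bolus_volume,
        final_volume=final_volume,
        final_conc=final_conc,
    )
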