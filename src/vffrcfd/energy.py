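"""Energy and monetary cost of simulation campaigns.

Each compute arm is assigned a constant average electrical power draw
(a conservative device-level estimate, e.g. 50 W for a four-core CPU slice,
295 W for a GPU at its maximum rating); the energy per case is then simply
``P x t / 3600`` watt-hours, and campaign cost converts watt-hours to
kilowatt-hours at a tariff.  All conversions are explicit: energy in Wh,
tariff per kWh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StatsError, ValidationError
from .benchmark import WilcoxonResult, wilcoxon_signed_rank

__all__ = ["PowerModel", "energy_wh", "campaign_cost", "EnergySummary",
           "summarize_energy", "CPU_POWER_W", "GPU_POWER_W"]

#: Conservative average power of a four-core CPU slice, W.
CPU_POWER_W = 50.0
#: Maximum (used as average) power of a workstation GPU, W.
GPU_POWER_W = 295.0


@dataclass(frozen=True)
class PowerModel:
    """Constant average power draw of a compute device."""

    device: str
    average_power: float     # W
    note: str = ""

    def __post_init__(self):
        if self.average_power <= 0:
            raise ValidationError(
                f"average_power must be > 0 W, got {self.average_power}")


def energy_wh(power_w: float, duration_s: float) -> float:
    """Energy in watt-hours of a run: ``power_w * duration_s / 3600``."""
    if power_w <= 0:
        raise ValidationError(f"power must be > 0 W, got {power_w}")
    if duration_s < 0:
        raise ValidationError(f"duration must be >= 0 s, got {duration_s}")
    return power_w * duration_s / 3600.0


def campaign_cost(energy_per_case_wh: float, n_cases: int,
                  tariff_per_kwh: float) -> float:
    """Cost of a simulation campaign: Wh/case x cases -> kWh x tariff.

    The Wh -> kWh conversion is explicit (divide by 1000); e.g. 1000 cases
    at 8.44 Wh each and 0.25 currency/kWh cost 8.44 kWh x 0.25 = 2.11.
    """
    if energy_per_case_wh < 0 or n_cases < 0 or tariff_per_kwh < 0:
        raise ValidationError("campaign inputs must be non-negative")
    return energy_per_case_wh * n_cases / 1000.0 * tariff_per_kwh


@dataclass
class EnergySummary:
    records: pd.DataFrame        # case_id, arm, device, duration_s, energy_wh
    summary: pd.DataFrame        # per arm median/IQR Wh
    comparisons: dict            # arm -> WilcoxonResult vs the reference arm


def summarize_energy(records: pd.DataFrame, power_models: dict,
                     reference_arm: str = "reference",
                     confidence: float = 0.95) -> EnergySummary:
    """Per-arm energy medians/IQRs and paired contrasts vs a reference arm.

    ``records`` needs columns ``case_id``, ``method``, ``fidelity_percent``,
    ``duration_s`` and ``converged`` (the benchmark sweep's record table).
    ``power_models`` maps arm labels ("reference", "fidelity") to
    :class:`PowerModel` instances or plain wattages; an arm without a model
    is a configuration error.  A ``power_w`` column in ``records`` (a
    measured per-run draw, where instrumentation exists) overrides the
    constant arm power for those rows.  Because each arm's power is constant, the
    energy median is the power times the duration median — the map is
    monotone, so ranks (and Wilcoxon p-values) match the duration tests.
    """
    recs = records[records["converged"]].copy()
    models = {}
    for label, pm in power_models.items():
        models[label] = pm if isinstance(pm, PowerModel) else PowerModel(
            device=str(label), average_power=float(pm))
    missing = set(recs["method"].unique()) - set(models)
    if missing:
        raise ValidationError(f"no power model for arm(s): {sorted(missing)}")

    def arm_label(row):
        if row["method"] == "reference":
            return "reference"
        return f"fidelity_{int(row['fidelity_percent'])}"

    recs["arm"] = recs.apply(arm_label, axis=1)
    recs["device"] = recs["method"].map(lambda mth: models[mth].device)
    arm_power = recs["method"].map(
        lambda mth: models[mth].average_power).to_numpy(dtype=float)
    if "power_w" in recs.columns:
        measured = pd.to_numeric(recs["power_w"], errors="coerce").to_numpy()
        arm_power = np.where(np.isfinite(measured), measured, arm_power)
    recs["energy_wh"] = [energy_wh(p_, t)
                         for p_, t in zip(arm_power, recs["duration_s"])]

    rows = []
    for arm, sub in recs.groupby("arm"):
        e = sub["energy_wh"].to_numpy()
        rows.append({"arm": arm, "n": len(e),
                     "median_wh": float(np.median(e)),
                     "iqr_low_wh": float(np.percentile(e, 25)),
                     "iqr_high_wh": float(np.percentile(e, 75))})
    summary = pd.DataFrame(rows).set_index("arm")

    comparisons = {}
    ref = recs[recs["arm"] == reference_arm].set_index("case_id")["energy_wh"]
    for arm, sub in recs.groupby("arm"):
        if arm == reference_arm:
            continue
        sub = sub.set_index("case_id")
        common = ref.index.intersection(sub.index)
        if len(common) >= 5:
            try:
                comparisons[arm] = wilcoxon_signed_rank(
                    (ref.loc[common] - sub.loc[common, "energy_wh"]).to_numpy(),
                    confidence)
            except StatsError:
                pass
    return EnergySummary(records=recs, summary=summary, comparisons=comparisons)
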