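"""Timber-value projection of range change.

Lost or gained range is converted to money with a fixed stand volume and a
static export price: area (km^2) x 100 ha/km^2 x volume (m^3/ha) x price
(USD/m^3). Defaults are 1.74 m^3/ha (inventory estimate for large-diameter
cumaru stems) and 1000 USD per m^3 (approximate export price). Sign
convention: range loss is reported as positive monetary impact, gain as
negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .change import ChangeSummary

HA_PER_KM2 = 100.0


@dataclass(frozen=True)
class TimberParams:
    volume_density: float = 1.74  # m^3 per ha
    price: float = 1000.0  # USD per m^3

    def __post_init__(self) -> None:
        if self.volume_density <= 0 or self.price <= 0:
            raise ValueError("volume_density and price must be > 0")


def timber_value_usd(area_km2: float, params: TimberParams = TimberParams()) -> float:
    """USD value of timber standing on ``area_km2`` of range."""
    if area_km2 < 0:
        raise ValueError("area must be nonnegative")
    return area_km2 * HA_PER_KM2 * params.volume_density * params.price


def economic_change_table(summaries: list[ChangeSummary],
                          params: TimberParams = TimberParams()) -> tuple[pd.DataFrame, dict]:
    """Per-species and total monetary impact of projected range change.

    net_usd = value(lost) - value(gained): a species that gains range has a
    negative net. Totals report both the net sum and the gross loss
    (lost-area value only).
    """
    rows = []
    for s in summaries:
        lost_v = timber_value_usd(s.lost_km2, params)
        gained_v = timber_value_usd(s.gained_km2, params)
        rows.append({
            "species": s.species,
            "period_label": s.period_label,
            "lost_km2": s.lost_km2,
            "gained_km2": s.gained_km2,
            "net_usd": lost_v - gained_v,
            "gross_loss_usd": lost_v,
        })
    table = pd.DataFrame(rows)
    totals = {
        "net_usd": float(table["net_usd"].sum()) if len(table) else 0.0,
        "gross_loss_usd": float(table["gross_loss_usd"].sum()) if len(table) else 0.0,
    }
    return table, totals
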