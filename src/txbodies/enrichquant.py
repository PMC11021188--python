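"""Per-nucleus enrichment statistics for the two large transcription bodies.

Three statistics per nucleus and channel, computed from manual (or
simulated) area/mean-intensity measurements with background correction
taken from no-primary control nuclei:

* PercentageArea   = 100 · (A_B1 + A_B2) / A_Nuc
* PercentageIntensity = 100 · (A_B1·M_B1 + A_B2·M_B2) / (A_Nuc · [M_Nuc − bg])
* IntensityEnrichment = [(A_B1·M_B1 + A_B2·M_B2)/(A_B1 + A_B2)] / [M_Nuc − bg]

Body means are deliberately left uncorrected in the numerators while the
nucleus mean in the denominator is background-corrected; an explicitly
non-canonical fully-corrected variant is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentMeasurement",
    "SensorMeasurement",
    "UndefinedEnrichmentError",
    "background_mean",
    "percentage_area",
    "percentage_intensity",
    "intensity_enrichment",
    "sensor_ratio",
    "quantify_table",
]


class UndefinedEnrichmentError(ValueError):
    """Corrected nucleus mean is non-positive; the ratio is undefined."""


@dataclass(frozen=True)
class EnrichmentMeasurement:
    area_body1: float
    area_body2: float
    mean_body1: float
    mean_body2: float
    area_nucleus: float
    mean_nucleus: float
    mean_nucleus_noprimary: float = 0.0
    channel: str | None = None
    nucleus: int | str | None = None

    def __post_init__(self) -> None:
        if self.area_body1 <= 0 or self.area_body2 <= 0 or self.area_nucleus <= 0:
            raise ValueError("areas must be > 0")
        if self.area_body1 + self.area_body2 > self.area_nucleus:
            raise ValueError("bodies cannot occupy more than the whole nucleus")

    @property
    def corrected_nucleus_mean(self) -> float:
        return self.mean_nucleus - self.mean_nucleus_noprimary

    def _require_defined(self) -> None:
        if self.corrected_nucleus_mean <= 0:
            raise UndefinedEnrichmentError(
                f"nucleus {self.nucleus!r}: corrected nucleus mean "
                f"{self.corrected_nucleus_mean} <= 0"
            )


@dataclass(frozen=True)
class SensorMeasurement:
    egfp_head: float
    egfp_background: float
    rfp_head: float
    rfp_background: float


def background_mean(control_nucleus_means: list[float]) -> float:
    """Arithmetic mean intensity over no-primary control nuclei."""
    if len(control_nucleus_means) < 1:
        raise ValueError("at least one control nucleus required")
    return float(np.mean(control_nucleus_means))


def percentage_area(m: EnrichmentMeasurement) -> float:
    """Percent of nuclear area occupied by the two bodies."""
    return 100.0 * (m.area_body1 + m.area_body2) / m.area_nucleus


def percentage_intensity(m: EnrichmentMeasurement) -> float:
    """Percent of (background-corrected) nuclear signal inside the two bodies.

    May exceed 100 because body means are uncorrected, as in the source
    formulation.
    """
    m._require_defined()
    num = m.area_body1 * m.mean_body1 + m.area_body2 * m.mean_body2
    return 100.0 * num / (m.area_nucleus * m.corrected_nucleus_mean)


def intensity_enrichment(m: EnrichmentMeasurement, fully_corrected: bool = False) -> float:
    """Observed-over-expected mean intensity in the two bodies.

    Algebraically identical to percentage_intensity / percentage_area.
    ``fully_corrected=True`` subtracts the background from the body means as
    well — a non-canonical variant, clearly not the published formula.
    """
    m._require_defined()
    correction = m.mean_nucleus_noprimary if fully_corrected else 0.0
    num = m.area_body1 * (m.mean_body1 - correction) + m.area_body2 * (
        m.mean_body2 - correction
    )
    body_mean = num / (m.area_body1 + m.area_body2)
    return body_mean / m.corrected_nucleus_mean


def sensor_ratio(s: SensorMeasurement) -> float:
    """Background-subtracted eGFP over background-subtracted RFP."""
    denom = s.rfp_head - s.rfp_background
    if denom <= 0:
        raise ValueError(
            f"RFP head minus background must be > 0, got {denom}"
        )
    return (s.egfp_head - s.egfp_background) / denom


def quantify_table(
    df: pd.DataFrame, background: float | None = None
) -> pd.DataFrame:
    """Apply the three statistics to a per-nucleus measurement table.

    Expects columns matching EnrichmentMeasurement field names (a
    ``mean_nucleus_noprimary`` column overrides ``background``). Nuclei with
    a non-positive corrected mean are kept in the output with NaN statistics
    and an exclusion reason — never silently clamped.
    """
    rows = []
    for _, r in df.iterrows():
        bg = r.get("mean_nucleus_noprimary", background)
        if bg is None or (isinstance(bg, float) and math.isnan(bg)):
            bg = background if background is not None else 0.0
        out = dict(r)
        try:
            m = EnrichmentMeasurement(
                area_body1=r["area_body1"],
                area_body2=r["area_body2"],
                mean_body1=r["mean_body1"],
                mean_body2=r["mean_body2"],
                area_nucleus=r["area_nucleus"],
                mean_nucleus=r["mean_nucleus"],
                mean_nucleus_noprimary=float(bg),
                nucleus=r.get("nucleus"),
                channel=r.get("channel"),
            )
            out["percentage_area"] = percentage_area(m)
            out["percentage_intensity"] = percentage_intensity(m)
            out["intensity_enrichment"] = intensity_enrichment(m)
            out["log2_intensity_enrichment"] = (
                math.log2(out["intensity_enrichment"])
                if out["intensity_enrichment"] > 0
                else np.nan
            )
            out["excluded_reason"] = ""
        except (ValueError, UndefinedEnrichmentError) as exc:
            out["percentage_area"] = np.nan
            out["percentage_intensity"] = np.nan
            out["intensity_enrichment"] = np.nan
            out["log2_intensity_enrichment"] = np.nan
            out["excluded_reason"] = str(exc)
        rows.append(out)
    return pd.DataFrame(rows)
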