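"""Size-based ingestion-fate classes for microplastic particles.

Gastrointestinal fate depends strongly on particle size: sub-micron
particles can passively cross cell membranes; small particles up to a few
micrometres transit the digestive tract passively; particles of 5-20 um
may cross the gut epithelium only via endocytosis or paracellular
diffusion; anything larger than 20 um is likely simply excreted. The
classifier is a total, monotone step function of the chosen dimension.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = ["RiskClass", "RiskAssessment", "classify_risk", "classify_size", "summarize_risk"]


class RiskClass(Enum):
    PASSIVE_MEMBRANE = "passive_membrane"            # < 1 um
    PASSIVE_TRANSIT = "passive_transit"              # 1 to < 5 um
    ENDOCYTOSIS_PARACELLULAR = "endocytosis_paracellular"  # 5 to 20 um inclusive
    EXCRETED = "excreted"                            # > 20 um


_RULE_NOTES = {
    RiskClass.PASSIVE_MEMBRANE: "particles smaller than 1 um can passively pass through cell membranes",
    RiskClass.PASSIVE_TRANSIT: "smaller particles pass through the digestive tract passively",
    RiskClass.ENDOCYTOSIS_PARACELLULAR: (
        "particles between 5 um and 20 um may cross the epithelium only by "
        "endocytosis or paracellular diffusion"
    ),
    RiskClass.EXCRETED: "particles larger than 20 um are likely excreted from the gastrointestinal tract",
}

_DIMENSION_COLUMNS = {"major": "major_um", "minor": "minor_um", "area": "area_um2"}


@dataclass(frozen=True)
class RiskAssessment:
    risk_class: RiskClass
    size_um: float
    rule_note: str


def classify_size(size_um: float) -> RiskClass:
    """Map a dimension in micrometres to its ingestion-fate class."""
    if not size_um > 0:
        raise ValueError(f"size must be positive, got {size_um}")
    if size_um < 1.0:
        return RiskClass.PASSIVE_MEMBRANE
    if size_um < 5.0:
        return RiskClass.PASSIVE_TRANSIT
    if size_um <= 20.0:
        return RiskClass.ENDOCYTOSIS_PARACELLULAR
    return RiskClass.EXCRETED


def classify_risk(particle, dimension: str = "major") -> RiskAssessment:
    """Classify one particle record (mapping-like or ParticleMeasurement).

    ``dimension`` selects which measured quantity is classified: "major"
    (default, the particle's largest extent), "minor", or "area" (then the
    square root of the area, an equivalent edge length, is used).
    """
    if dimension not in _DIMENSION_COLUMNS:
        raise ValueError(f"dimension must be one of {sorted(_DIMENSION_COLUMNS)}")
    col = _DIMENSION_COLUMNS[dimension]
    value = particle[col] if isinstance(particle, (dict, pd.Series)) else getattr(particle, col)
    if value is None or pd.isna(value):
        ident = ""
        try:
            ident = f" (particle {particle['particle_id']})" if isinstance(particle, (dict, pd.Series)) else ""
        except KeyError:
            pass
        raise ValueError(f"dimension {col!r} is missing{ident}; cannot classify")
    value = float(value)
    if dimension == "area":
        value = value ** 0.5
    cls = classify_size(value)
    return RiskAssessment(cls, value, _RULE_NOTES[cls])


def summarize_risk(table: pd.DataFrame, dimension: str = "major", missing: str = "fail") -> pd.DataFrame:
    """Per-class particle counts and fractions for a measurement table.

    Parameters
    ----------
    table : DataFrame
        Measurement table with at least the column for ``dimension``.
    dimension : str
        Which dimension to classify ("major", "minor", "area").
    missing : {"fail", "drop"}
        Whether rows with a missing dimension abort ("fail") or are
        silently excluded ("drop").

    Returns
    -------
    DataFrame indexed by class name with ``count`` and ``fraction``
    columns; fractions sum to 1 for a non-empty table. An empty input
    yields an empty summary.
    """
    if missing not in ("fail", "drop"):
        raise ValueError("missing must be 'fail' or 'drop'")
    if len(table) == 0:
        return pd.DataFrame(columns=["count", "fraction"])
    col = _DIMENSION_COLUMNS[dimension] if dimension in _DIMENSION_COLUMNS else None
    if col is None:
        raise ValueError(f"dimension must be one of {sorted(_DIMENSION_COLUMNS)}")
    work = table
    if missing == "drop":
        work = table[table[col].notna()]
        if len(work) == 0:
            return pd.DataFrame(columns=["count", "fraction"])
    counts: dict[str, int] = {}
    for _, row in work.iterrows():
        cls = classify_risk(row, dimension=dimension).risk_class
        counts[cls.name] = counts.get(cls.name, 0) + 1
    out = pd.DataFrame({"count": pd.Series(counts, dtype=int)})
    out["fraction"] = out["count"] / out["count"].sum()
    return out.sort_values("count", ascending=False)
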