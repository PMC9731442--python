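"""Per-pool sample metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

#: Arctic Ocean region labels used for regional FST aggregation
ARCTIC_REGIONS = (
    "Pacific-Arctic",
    "Kara-Laptev",
    "Atlantic-Arctic",
    "Arctic Archipelago",
    "Davis-Baffin",
)

#: environmental variables expected in a raw metadata table
ENV_VARIABLES = (
    "temperature",
    "salinity",
    "oxygen",
    "ammonium",
    "iron",
    "nitrate",
    "nitrite",
    "phosphate",
    "silicate",
)


@dataclass
class PopulationSample:
    """One population pool: station/depth identity, location, environment."""

    sample_id: str
    station: str
    depth: str  # e.g. SUR or DCM
    region: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    environment: dict = field(default_factory=dict)
    mapped_read_count: int = 0
    total_read_count: int = 0
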