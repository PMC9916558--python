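"""Explant-level record container.

One :class:`ExplantRecord` describes a single cultured spiral ganglion
explant: its position in the experimental design (plate, well, cochlear
turn, treatment) plus the animal covariates, and — once measured — its
morphometry or immunoreactivity metrics. The record is the unit of all
downstream statistics; tabular workflows use a pandas DataFrame with one
row per record (see :func:`ExplantRecord.to_dict`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Optional

TURNS = ("apical", "middle", "basal")
SIDES = ("left", "right")
AGES = ("P6", "P7")


@dataclass
class ExplantRecord:
    id: str
    turn: str
    treatment: str = "NT CTRL"
    is_control: bool = True
    plate: Optional[str] = None
    well: Optional[str] = None
    sex: Optional[str] = None
    side: Optional[str] = None
    age: Optional[str] = None
    weight_g: Optional[float] = None
    litter: Optional[str] = None
    metrics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.turn not in TURNS:
            raise ValueError(f"turn must be one of {TURNS}, got {self.turn!r}")
        if self.side is not None and self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.age is not None and self.age not in AGES:
            raise ValueError(f"age must be one of {AGES}, got {self.age!r}")

    def to_dict(self) -> dict[str, Any]:
        """Flatten into one table row (metrics inlined as columns)."""
        d = asdict(self)
        metrics = d.pop("metrics")
        d.update(metrics)
        return d
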