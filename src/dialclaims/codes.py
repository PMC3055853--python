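"""Procedure code sets for outpatient dialysis claims.

The default set holds the six CCP (Canadian Classification of Diagnostic,
Therapeutic and Surgical Procedures) physician-billing codes that identify
outpatient dialysis care in Alberta claims data: per-encounter hemodialysis
and peritoneal-dialysis codes plus the two per-week management codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping


@dataclass(frozen=True)
class CodeSet:
    """A named set of procedure codes with per-code descriptions."""

    codes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError("a CodeSet must contain at least one code")
        for code in self.codes:
            if not code or not code.strip():
                raise ValueError("procedure codes must be non-empty")

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __iter__(self) -> Iterator[str]:
        return iter(self.codes)

    def __len__(self) -> int:
        return len(self.codes)

    def description(self, code: str) -> str:
        return self.codes[code]


#: CCP outpatient dialysis billing codes.
CCP_DIALYSIS = CodeSet(
    {
        "13.99A": "Hemodialysis treatment, unstable patient",
        "13.99B": "Hemodialysis treatment, stable patient",
        "13.99C": (
            "Assessment and management of an unstable patient with "
            "acute/chronic renal failure treated by peritoneal dialysis"
        ),
        "13.99D": (
            "Assessment and management of a stable patient with chronic "
            "renal failure treated by peritoneal dialysis"
        ),
        "13.99O": (
            "Management of dialysis patients on home dialysis or receiving "
            "treatment in a remote hemodialysis unit (per week)"
        ),
        "13.99OA": (
            "Management of patient on hemodialysis or peritoneal dialysis "
            "(per week)"
        ),
    }
)
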