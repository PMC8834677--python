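"""Chamber labels and conventions shared across the pipeline.

The four-chamber (4CH) view shows both ventricles and both atria in one
plane.  Label codes follow the mask convention used throughout:
0 = background, 1 = LV, 2 = LA, 3 = RV, 4 = RA.
"""

from __future__ import annotations

CHAMBERS: tuple[str, ...] = ("LV", "LA", "RV", "RA")

CHAMBER_CODES: dict[str, int] = {"LV": 1, "LA": 2, "RV": 3, "RA": 4}
CODE_TO_CHAMBER: dict[int, str] = {v: k for k, v in CHAMBER_CODES.items()}

LABEL_NAMES: dict[int, str] = {
    0: "background",
    1: "LV",
    2: "LA",
    3: "RV",
    4: "RA",
}

VENTRICLES: frozenset[str] = frozenset({"LV", "RV"})
ATRIA: frozenset[str] = frozenset({"LA", "RA"})


def chamber_type(chamber: str) -> str:
    """Return ``"ventricle"`` or ``"atrium"`` for a chamber id."""
    if chamber in VENTRICLES:
        return "ventricle"
    if chamber in ATRIA:
        return "atrium"
    raise ValueError(f"unknown chamber {chamber!r}")
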