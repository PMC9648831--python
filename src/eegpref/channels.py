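"""Canonical 19-channel montage and the 5x5 scalp-layout grid.

The montage is the classic 10-20 set recorded referentially (A1). T3/T4 and
T5/T6 are the older names for T7/T8 and P7/P8; both spellings are accepted
when looking channels up.
"""

from __future__ import annotations

import numpy as np

#: Canonical channel order used everywhere in the package (rows of every
#: signal array, entries of every 19-vector of band power).
CHANNELS_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Modern aliases mapped onto the canonical names.
ALIASES: dict[str, str] = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

_INDEX = {name: i for i, name in enumerate(CHANNELS_19)}


def channel_index(name: str) -> int:
    """Index of a channel in the canonical order (aliases accepted)."""
    key = ALIASES.get(name, name)
    try:
        return _INDEX[key]
    except KeyError:
        raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS_19}") from None


# The 5x5 scalp grid.  Real electrodes occupy 19 cells; the six corner-ish
# gaps (marked *1..*6) are filled with the arithmetic mean of the adjacent
# electrodes listed in LAYOUT_FILLS.
LAYOUT_GRID: tuple[tuple[str, ...], ...] = (
    ("*1", "Fp1", "*2", "Fp2", "*3"),
    ("F7", "F3", "Fz", "F4", "F8"),
    ("T3", "C3", "Cz", "C4", "T4"),
    ("T5", "P3", "Pz", "P4", "T6"),
    ("*4", "O1", "*5", "O2", "*6"),
)

LAYOUT_FILLS: dict[str, tuple[str, ...]] = {
    "*1": ("Fp1", "F7", "F3"),
    "*2": ("Fp1", "Fz", "Fp2"),
    "*3": ("Fp2", "F4", "F8"),
    "*4": ("T5", "P3", "O1"),   # P7 == T5
    "*5": ("Pz", "O1", "O2"),
    "*6": ("T6", "P4", "O2"),   # P8 == T6
}


def _build_layout_matrix() -> np.ndarray:
    """25x19 matrix M with grid.ravel() == M @ channel_values."""
    m = np.zeros((25, 19))
    for r, row in enumerate(LAYOUT_GRID):
        for c, cell in enumerate(row):
            k = 5 * r + c
            if cell.startswith("*"):
                srcs = LAYOUT_FILLS[cell]
                for s in srcs:
                    m[k, channel_index(s)] = 1.0 / len(srcs)
            else:
                m[k, channel_index(cell)] = 1.0
    return m


#: Linear map from a 19-vector of channel values to the flattened 5x5 grid.
LAYOUT_MATRIX: np.ndarray = _build_layout_matrix()
LAYOUT_MATRIX.setflags(write=False)
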