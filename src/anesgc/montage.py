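"""Standard 10/20 montage labels and the five scalp region groupings.

Regions follow the usual fronto-posterior partition used for region-averaged
effective-connectivity analysis: left/right frontal (LF, RF), left/right
posterior (LP, RP) and the midline (Z).
"""

from __future__ import annotations

CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Region -> member electrodes (order fixed; averaging is over the members
#: that are present and not excluded).
REGIONS: dict[str, tuple[str, ...]] = {
    "LF": ("Fp1", "F7", "F3", "T3", "C3"),
    "RF": ("Fp2", "F8", "F4", "C4", "T4"),
    "LP": ("T5", "P3", "O1"),
    "RP": ("T6", "P4", "O2"),
    "Z": ("Fz", "Cz", "Pz"),
}

REGION_NAMES: tuple[str, ...] = ("LF", "RF", "LP", "RP", "Z")

FRONTAL_REGIONS: tuple[str, ...] = ("LF", "RF")
POSTERIOR_REGIONS: tuple[str, ...] = ("LP", "RP")

#: Ordered frontal->posterior pairs used as classification features.
FEATURE_PAIRS: tuple[tuple[str, str], ...] = (
    ("LF", "LP"), ("RF", "LP"), ("LF", "RP"), ("RF", "RP"),
)

_CANONICAL = {name.lower(): name for name in CHANNELS_1020}


def normalize_label(label: str) -> str:
    """Map a case-insensitive channel name onto its canonical 10/20 spelling.

    Raises ``ValueError`` for labels outside the 19-channel montage.
    """
    key = label.strip().lower()
    if key not in _CANONICAL:
        raise ValueError(f"unknown 10/20 channel label: {label!r}")
    return _CANONICAL[key]


def all_region_pairs(present: tuple[str, ...] = REGION_NAMES) -> list[tuple[str, str]]:
    """Unordered region pairs among the present regions (10 when all 5 exist)."""
    present = tuple(r for r in REGION_NAMES if r in present)
    return [
        (a, b)
        for i, a in enumerate(present)
        for b in present[i + 1:]
    ]
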