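"""Shared vocabulary for the MNALCI pipeline.

Class labels, matrix tags, the analysed mass window and the reference
calibrant/biomarker panels used throughout the package.
"""

from __future__ import annotations

MZ_MIN: float = 100.0
MZ_MAX: float = 1000.0

#: Fixed cancer-class order; also the tie-break order for fused argmax calls.
CANCER_CLASSES: tuple[str, ...] = ("HCC", "NSCLC", "PAAD", "CRC", "GC", "PTC")

#: All cohort labels, healthy controls first.
CLASSES: tuple[str, ...] = ("HC",) + CANCER_CLASSES

STAGES: tuple[str, ...] = ("I", "II", "III", "IV", "none")

SPLITS: tuple[str, ...] = ("train", "internal_validation", "external_validation")

MATRICES: tuple[str, ...] = ("GNS", "SiNW")

#: The six-component "home-made" calibration standard: (name, reference m/z in Da).
DEFAULT_CALIBRANTS: tuple[tuple[str, float], ...] = (
    ("serine", 105.09),
    ("glucose", 180.16),
    ("tryptophan", 204.23),
    ("sucrose", 342.29),
    ("maltotriose", 504.44),
    ("amylopentaose", 828.72),
)

#: The eight serum metabolite biomarkers. 5-hydroxymethyluracil (164.98) and
#: 4-methylcatechol (147.02) carry fixed m/z values; the remaining six default
#: to nominal singly protonated masses and are configurable.
BIOMARKERS: tuple[tuple[str, float], ...] = (
    ("2-oxovaleric acid", 117.05),
    ("histamine", 112.09),
    ("glucose", 180.16),
    ("5-hydroxymethyluracil", 164.98),
    ("2-furoic acid", 113.02),
    ("methylmalonic acid", 119.03),
    ("4-methylcatechol", 147.02),
    ("L-carnitine", 162.11),
)

#: Biomarkers whose m/z assignment is fixed (confirmed ion species).
FIXED_BIOMARKER_MZ: dict[str, float] = {
    "5-hydroxymethyluracil": 164.98,
    "4-methylcatechol": 147.02,
}
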