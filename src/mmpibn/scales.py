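"""Canonical MMPI-2 scale ordering and published group-level moments.

The package analyses the three validity scales (L, F, K) and the ten
clinical scales of the MMPI-2, always in the fixed canonical order below.
T-scores are standardized to population mean 50, SD 10; group-specific
moments used by the synthetic generators come from the study cohort's
demographic table (714 healthy vs 714 schizophrenia participants).
"""

from __future__ import annotations

# Canonical node order used everywhere: validity scales first, then the ten
# clinical scales in their numbered order (1=Hs ... 0=Si).
CANONICAL_SCALES: tuple[str, ...] = (
    "L", "F", "K", "Hs", "D", "Hy", "Pd", "Mf", "Pa", "Pt", "Sc", "Ma", "Si",
)

SCALE_INDEX: dict[str, int] = {s: i for i, s in enumerate(CANONICAL_SCALES)}

#: Clinical-scale number -> canonical name (Scale 2 = D, Scale 7 = Pt, Scale 8 = Sc).
SCALE_NUMBERS: dict[int, str] = {
    1: "Hs", 2: "D", 3: "Hy", 4: "Pd", 5: "Mf",
    6: "Pa", 7: "Pt", 8: "Sc", 9: "Ma", 0: "Si",
}

#: Group-wise marginal T-score mean/SD per scale: (healthy, schizophrenia).
TSCORE_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "healthy": {
        "L": (50.19, 13.43), "F": (55.65, 14.38), "K": (50.96, 13.01),
        "Hs": (58.17, 14.10), "D": (56.11, 15.62), "Hy": (60.38, 14.42),
        "Pd": (57.11, 14.53), "Mf": (51.19, 13.51), "Pa": (52.54, 10.55),
        "Pt": (57.81, 13.58), "Sc": (56.19, 13.31), "Ma": (54.66, 11.01),
        "Si": (47.06, 12.54),
    },
    "schizophrenia": {
        "L": (57.74, 15.37), "F": (62.70, 14.55), "K": (56.89, 14.41),
        "Hs": (59.26, 11.13), "D": (53.95, 10.61), "Hy": (62.99, 14.25),
        "Pd": (56.87, 11.24), "Mf": (52.78, 10.34), "Pa": (56.23, 9.85),
        "Pt": (54.00, 10.16), "Sc": (57.79, 11.88), "Ma": (56.44, 9.98),
        "Si": (43.10, 8.93),
    },
}

DEMOGRAPHIC_COLUMNS: tuple[str, ...] = ("age", "gender", "education", "marital")
LABEL_COLUMN: str = "diagnosis"
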