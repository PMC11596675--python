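"""Published method-validation reference values for the default panel.

These are the reported sensitivity figures of the validated method (ICH
slope method, low-range regression in solvent + 10% ISTD): limit of
detection and limit of quantification in nM per analyte. They serve as
reference inputs for consistency checks — e.g. every (LOD, LOQ) pair must
satisfy the slope-method construction LOQ = LOD x 10/3.3 — not as values the
pipeline produces from data.
"""

from __future__ import annotations

__all__ = ["PUBLISHED_SENSITIVITY_NM"]

#: analyte -> (LOD nM, LOQ nM), as reported for the validated method.
PUBLISHED_SENSITIVITY_NM: dict[str, tuple[float, float]] = {
    "NAM": (26.73, 80.98),
    "NCA": (11.77, 35.68),
    "1-mNAM": (4.02, 12.19),
    "NR": (5.64, 17.11),
    "FAD": (6.74, 20.43),
    "NADH": (57.14, 173.15),
    "ADPR": (1.52, 4.61),
    "NAD+": (3.96, 11.99),
    "NMN": (3.79, 11.48),
    "NAMN": (5.38, 16.32),
    "NADPH": (29.47, 89.29),
    "NADP+": (16.67, 50.51),
}
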