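"""Natural-abundance isotopologue distributions and MRM crosstalk flagging.

A molecule containing n carbons has, at natural abundance, a sizeable M+1
isotopologue (one 13C): for NAD+ (21 carbons) the M+1 species is roughly a
quarter of the all-12C signal. On a unit-resolution triple quadrupole, that
M+1 signal falls in the MRM channel of any co-eluting analyte whose parent
ion is one nominal mass unit heavier — e.g. NAD+ (664.1) bleeding into NAAD
(665.2). This module computes the per-analyte isotopologue distribution by
exact elemental convolution and scans a panel for such channel collisions.

The scan flags; it does not unmix. Crosstalk-compromised channels are
excluded from quantification rather than deconvolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_io import AnalytePanel, MolecularFormula

__all__ = [
    "ISOTOPE_ABUNDANCES",
    "IsotopologueDistribution",
    "CrosstalkFlag",
    "isotopologue_distribution",
    "crosstalk_scan",
]

#: Natural isotope abundances by nominal mass shift from the monoisotopic
#: species (IUPAC representative values). Phosphorus is monoisotopic.
ISOTOPE_ABUNDANCES: dict[str, dict[int, float]] = {
    "C": {0: 0.9893, 1: 0.0107},
    "H": {0: 0.999885, 1: 0.000115},
    "N": {0: 0.99636, 1: 0.00364},
    "O": {0: 0.99757, 1: 0.00038, 2: 0.00205},
    "P": {0: 1.0},
}


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Relative abundances of the M+0 ... M+K nominal-mass isotopologues."""

    analyte: str
    fractions: tuple[float, ...]  # index k -> abundance of M+k, sum <= 1

    @property
    def m0(self) -> float:
        return self.fractions[0]

    def ratio_to_m0(self, k: int) -> float:
        """Abundance of M+k relative to M+0."""
        return self.fractions[k] / self.fractions[0]


@dataclass(frozen=True)
class CrosstalkFlag:
    """Predicted bleed-through of one analyte's M+k signal into another's channel."""

    source: str
    target: str
    mass_shift: int
    mz_gap: float  # |source parent + k - target parent|, Da
    rt_gap: float  # |RT(source) - RT(target)|, min
    interference: float  # source M+k signal as a fraction of its M+0 signal


def _element_profile(element: str, count: int, max_shift: int,
                     abundances: dict[str, dict[int, float]]) -> np.ndarray:
    """Isotopologue profile of `count` atoms of one element, truncated at max_shift."""
    try:
        iso = abundances[element]
    except KeyError:
        raise ValueError(f"unknown element symbol {element!r}") from None
    single = np.zeros(max_shift + 1)
    for shift, frac in iso.items():
        if shift <= max_shift:
            single[shift] = frac
    profile = np.zeros(max_shift + 1)
    profile[0] = 1.0
    for _ in range(count):
        profile = np.convolve(profile, single)[: max_shift + 1]
    return profile


def isotopologue_distribution(
    formula: MolecularFormula,
    max_shift: int = 3,
    abundances: dict[str, dict[int, float]] | None = None,
    analyte: str = "",
) -> IsotopologueDistribution:
    """Exact natural-abundance isotopologue distribution of a formula.

    Convolves per-element multinomial isotope profiles and collapses them to
    nominal mass shifts M+0 ... M+max_shift. Fractions are absolute molecular
    probabilities (the truncated tail beyond M+max_shift is simply absent),
    so they sum to <= 1.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    abundances = abundances or ISOTOPE_ABUNDANCES
    total = np.zeros(max_shift + 1)
    total[0] = 1.0
    for element, count in formula.element_counts.items():
        if count == 0:
            continue
        total = np.convolve(
            total, _element_profile(element, count, max_shift, abundances)
        )[: max_shift + 1]
    return IsotopologueDistribution(analyte=analyte, fractions=tuple(total))


def crosstalk_scan(
    panel: AnalytePanel,
    mz_tol: float = 0.5,
    rt_window: float = 0.5,
    max_shift: int = 3,
) -> list[CrosstalkFlag]:
    """Flag ordered analyte pairs whose isotopologues collide in MRM channels.

    A pair (source -> target) is flagged when, for some shift k in 1..max_shift,
    the source quantifier parent m/z plus k nominal mass units falls within
    ``mz_tol`` of the target quantifier parent m/z, and the retention times lie
    within ``rt_window`` of each other. The predicted interference is the
    source's M+k abundance relative to its M+0 signal.
    """
    if mz_tol <= 0 or rt_window <= 0:
        raise ValueError("mz_tol and rt_window must be positive")
    flags: list[CrosstalkFlag] = []
    analytes = panel.monitored
    dists = {
        a.name: isotopologue_distribution(a.formula, max_shift, analyte=a.name)
        for a in analytes
    }
    for src in analytes:
        for tgt in analytes:
            if src.name == tgt.name:
                continue
            rt_gap = abs(src.retention_time - tgt.retention_time)
            if rt_gap > rt_window:
                continue
            for k in range(1, max_shift + 1):
                mz_gap = abs(src.quantifier.parent_mz + k - tgt.quantifier.parent_mz)
                if mz_gap <= mz_tol:
                    interference = min(dists[src.name].ratio_to_m0(k), 1.0)
                    flags.append(
                        CrosstalkFlag(
                            source=src.name,
                            target=tgt.name,
                            mass_shift=k,
                            mz_gap=mz_gap,
                            rt_gap=rt_gap,
                            interference=interference,
                        )
                    )
    return flags
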