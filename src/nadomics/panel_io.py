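"""Analyte panel definitions and file interfaces.

The panel registry carries, per analyte: molecular formula, retention time
(with inter-run tolerance), MRM transitions (quantifier + qualifier, with
cone voltage and collision energy), and the internal-standard (ISTD) mapping.
Quantification is by isotope dilution: each analyte is ratioed against a
uniformly 13C-labeled channel — its own 13C isotopologue when that channel is
detectable in labeled cell extract, otherwise the 13C channel of a
structurally similar, closely eluting surrogate analyte.

Peak tables are long-format CSV (one row per sample x MRM channel), the shape
of a TargetLynx-style export after peak integration. Channels are named
``"<analyte>|12C"`` and ``"<analyte>|13C"``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "MolecularFormula",
    "MRMTransition",
    "AnalyteDef",
    "AnalytePanel",
    "PeakTable",
    "PanelConfigError",
    "PeakTableError",
    "default_panel",
    "load_panel",
    "read_peak_table",
    "read_sample_meta",
    "write_results",
    "channel_id",
    "SAMPLE_ROLES",
]

ISOTOPE_LABELS = ("12C", "13C")
SAMPLE_ROLES = ("blank", "standard", "lod_standard", "qc", "unknown")

#: Default retention-time match tolerance (min). Table-level inter-run SDs run
#: up to +-0.5 min and drift occurs on column/mobile-phase change, so observed
#: RT deviations are flagged, never dropped.
DEFAULT_RT_TOLERANCE = 0.5


class PanelConfigError(ValueError):
    """Raised for an invalid or internally inconsistent panel configuration."""


class PeakTableError(ValueError):
    """Raised for a malformed peak-area table."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Elemental composition, e.g. ``MolecularFormula.from_string("C21H27N7O14P2")``."""

    element_counts: Mapping[str, int]

    def __post_init__(self):
        if not self.element_counts:
            raise PanelConfigError("empty molecular formula")
        for elem, n in self.element_counts.items():
            if n < 0:
                raise PanelConfigError(f"negative count for element {elem}")
        object.__setattr__(
            self, "element_counts", dict(self.element_counts)
        )

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos or not m.group(1):
                break
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text) or not counts:
            raise PanelConfigError(f"cannot parse molecular formula {text!r}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    @property
    def n_atoms(self) -> int:
        return sum(self.element_counts.values())

    def __str__(self) -> str:
        return "".join(
            f"{e}{n if n != 1 else ''}"
            for e, n in self.element_counts.items()
            if n
        )


@dataclass(frozen=True)
class MRMTransition:
    """A parent -> product ion transition with its source settings."""

    parent_mz: float
    product_mz: float
    role: str = "quantifier"  # or "qualifier"
    cone_voltage: float | None = None
    collision_energy: float | None = None

    def __post_init__(self):
        if self.product_mz >= self.parent_mz:
            raise PanelConfigError(
                f"product m/z {self.product_mz} not below parent m/z {self.parent_mz}"
            )
        if self.role not in ("quantifier", "qualifier"):
            raise PanelConfigError(f"unknown transition role {self.role!r}")


@dataclass(frozen=True)
class AnalyteDef:
    name: str
    formula: MolecularFormula
    retention_time: float
    rt_sd: float = 0.0
    transitions: tuple[MRMTransition, ...] = ()
    istd_mode: str = "own_13C"  # or "surrogate"
    istd_ref: str | None = None  # surrogate analyte name when istd_mode == "surrogate"
    istd_transition: MRMTransition | None = None
    quantified: bool = True

    def __post_init__(self):
        if self.retention_time <= 0:
            raise PanelConfigError(f"{self.name}: retention time must be > 0")
        if not self.transitions:
            raise PanelConfigError(f"{self.name}: at least one MRM transition required")
        n_quant = sum(t.role == "quantifier" for t in self.transitions)
        if n_quant != 1:
            raise PanelConfigError(
                f"{self.name}: exactly one quantifier transition required, got {n_quant}"
            )
        if self.istd_mode not in ("own_13C", "surrogate"):
            raise PanelConfigError(f"{self.name}: unknown istd_mode {self.istd_mode!r}")
        if self.istd_mode == "surrogate" and not self.istd_ref:
            raise PanelConfigError(f"{self.name}: surrogate ISTD requires a reference analyte")

    @property
    def quantifier(self) -> MRMTransition:
        return next(t for t in self.transitions if t.role == "quantifier")


def channel_id(analyte: str, label: str = "12C") -> str:
    if label not in ISOTOPE_LABELS:
        raise ValueError(f"isotope label must be one of {ISOTOPE_LABELS}")
    return f"{analyte}|{label}"


class AnalytePanel:
    """Ordered registry of monitored analytes.

    ``panel.analytes`` is the quantified panel (twelve by default);
    ``panel.monitored`` additionally includes monitor-only channels (NAAD,
    which is acquired but excluded from quantification because of isotopologue
    crosstalk from co-eluting NAD+).
    """

    def __init__(self, analytes: Iterable[AnalyteDef]):
        self._all = list(analytes)
        names = [a.name for a in self._all]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelConfigError(f"duplicate analyte names: {dupes}")
        by_name = {a.name: a for a in self._all}
        for a in self._all:
            if a.istd_mode == "surrogate":
                ref = by_name.get(a.istd_ref)
                if ref is None:
                    raise PanelConfigError(
                        f"{a.name}: surrogate ISTD references unknown analyte {a.istd_ref!r}"
                    )
                if ref.istd_mode != "own_13C" or ref.istd_transition is None:
                    raise PanelConfigError(
                        f"{a.name}: surrogate {a.istd_ref!r} has no own 13C channel"
                    )
        self._by_name = by_name

    @property
    def monitored(self) -> list[AnalyteDef]:
        return list(self._all)

    @property
    def analytes(self) -> list[AnalyteDef]:
        return [a for a in self._all if a.quantified]

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.analytes]

    def __len__(self) -> int:
        return len(self.analytes)

    def __iter__(self):
        return iter(self.analytes)

    def __getitem__(self, name: str) -> AnalyteDef:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"analyte {name!r} not in panel") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def istd_channel(self, analyte: str) -> str:
        """Channel id of the 13C ISTD used to ratio *analyte* (own or surrogate)."""
        a = self[analyte]
        source = a.name if a.istd_mode == "own_13C" else a.istd_ref
        return channel_id(source, "13C")

    def surrogate_map(self) -> dict[str, str]:
        """analyte -> surrogate name, for analytes without their own 13C channel."""
        return {
            a.name: a.istd_ref for a in self._all if a.istd_mode == "surrogate"
        }

    def valid_channels(self) -> set[str]:
        chans = set()
        for a in self._all:
            chans.add(channel_id(a.name, "12C"))
            if a.istd_mode == "own_13C":
                chans.add(channel_id(a.name, "13C"))
        return chans

    def to_dict(self) -> dict:
        out = {"analytes": []}
        for a in self._all:
            d = {
                "name": a.name,
                "formula": str(a.formula),
                "retention_time": a.retention_time,
                "rt_sd": a.rt_sd,
                "quantified": a.quantified,
                "istd_mode": a.istd_mode,
                "transitions": [
                    dataclasses.asdict(t) for t in a.transitions
                ],
            }
            if a.istd_ref:
                d["istd_ref"] = a.istd_ref
            if a.istd_transition is not None:
                d["istd_transition"] = dataclasses.asdict(a.istd_transition)
            out["analytes"].append(d)
        return out


# ---------------------------------------------------------------------------
# Built-in panel: twelve quantified pyridine/flavin nucleotides plus the
# monitor-only NAAD channel. RTs are inter-run averages (min +- SD); MRM
# settings are the tuned ESI-positive source parameters.
# ---------------------------------------------------------------------------

def _t(parent, product, role, cv, ce):
    return MRMTransition(parent, product, role, cv, ce)


_DEFAULT_ROWS = [
    # name, formula, RT, RT SD, quantifier, qualifier, istd
    ("NAM", "C6H6N2O", 1.0, 0.0,
     _t(123.0, 79.7, "quantifier", 38.0, 18.0), _t(123.0, 96.0, "qualifier", 38.0, 14.0),
     ("own", _t(129.1, 84.8, "quantifier", 38.0, 18.0))),
    ("NCA", "C6H5NO2", 1.6, 0.2,
     _t(124.0, 80.2, "quantifier", 38.0, 18.0), _t(124.0, 53.0, "qualifier", 38.0, 22.0),
     ("surrogate", "NAM")),
    ("1-mNAM", "C7H9N2O", 2.5, 0.2,
     _t(137.0, 78.0, "quantifier", 24.0, 22.0), _t(137.0, 108.1, "qualifier", 24.0, 16.0),
     ("surrogate", "NR")),
    ("NR", "C11H15N2O5", 2.9, 0.1,
     _t(255.9, 123.7, "quantifier", 14.0, 8.0), _t(255.9, 80.2, "qualifier", 14.0, 36.0),
     ("own", _t(266.9, 129.7, "quantifier", 14.0, 8.0))),
    ("FAD", "C27H33N9O15P2", 3.2, 0.5,
     _t(786.1, 348.0, "quantifier", 20.0, 22.0), _t(786.1, 439.1, "qualifier", 20.0, 28.0),
     ("own", _t(813.2, 358.0, "quantifier", 20.0, 22.0))),
    ("NADH", "C21H29N7O14P2", 3.7, 0.4,
     _t(666.1, 649.0, "quantifier", 20.0, 17.0), _t(666.1, 514.1, "qualifier", 20.0, 26.0),
     ("own", _t(687.1, 670.0, "quantifier", 20.0, 17.0))),
    ("ADPR", "C15H23N5O14P2", 3.8, 0.3,
     _t(560.1, 136.1, "quantifier", 26.0, 32.0), _t(560.1, 348.1, "qualifier", 26.0, 16.0),
     ("surrogate", "NADH")),
    ("NAD+", "C21H27N7O14P2", 4.2, 0.3,
     _t(664.1, 428.0, "quantifier", 20.0, 26.0), _t(664.1, 524.0, "qualifier", 20.0, 18.0),
     ("own", _t(685.1, 438.0, "quantifier", 20.0, 26.0))),
    ("NAAD", "C21H26N6O15P2", 4.5, 0.1,
     _t(665.2, 136.1, "quantifier", 42.0, 36.0), _t(665.2, 428.1, "qualifier", 42.0, 24.0),
     ("surrogate", "NAD+")),
    ("NMN", "C11H15N2O8P", 4.9, 0.2,
     _t(335.0, 123.1, "quantifier", 22.0, 14.0), _t(335.0, 97.0, "qualifier", 22.0, 26.0),
     ("surrogate", "NAMN")),
    ("NAMN", "C11H14NO9P", 5.1, 0.2,
     _t(336.0, 124.1, "quantifier", 22.0, 12.0), _t(336.0, 97.0, "qualifier", 22.0, 22.0),
     ("own", _t(347.0, 130.1, "quantifier", 22.0, 12.0))),
    ("NADPH", "C21H30N7O17P3", 5.1, 0.2,
     _t(746.1, 729.0, "quantifier", 20.0, 17.0), _t(746.1, 302.0, "qualifier", 20.0, 32.0),
     ("own", _t(767.1, 750.0, "quantifier", 20.0, 17.0))),
    ("NADP+", "C21H28N7O17P3", 5.5, 0.2,
     _t(744.1, 604.0, "quantifier", 20.0, 20.0), _t(744.1, 508.0, "qualifier", 20.0, 30.0),
     ("own", _t(765.1, 619.0, "quantifier", 20.0, 20.0))),
]

#: Channels acquired but excluded from quantification (crosstalk-compromised).
MONITOR_ONLY = frozenset({"NAAD"})


def default_panel() -> AnalytePanel:
    """The built-in twelve-analyte NADome panel (plus the monitor-only NAAD channel)."""
    defs = []
    for name, formula, rt, rt_sd, quant, qual, istd in _DEFAULT_ROWS:
        if istd[0] == "own":
            mode, ref, istd_tr = "own_13C", None, istd[1]
        else:
            mode, ref, istd_tr = "surrogate", istd[1], None
        defs.append(
            AnalyteDef(
                name=name,
                formula=MolecularFormula.from_string(formula),
                retention_time=rt,
                rt_sd=rt_sd,
                transitions=(quant, qual),
                istd_mode=mode,
                istd_ref=ref,
                istd_transition=istd_tr,
                quantified=name not in MONITOR_ONLY,
            )
        )
    return AnalytePanel(defs)


def _transition_from_dict(d: dict, analyte: str) -> MRMTransition:
    try:
        return MRMTransition(
            parent_mz=float(d["parent_mz"]),
            product_mz=float(d["product_mz"]),
            role=d.get("role", "quantifier"),
            cone_voltage=d.get("cone_voltage"),
            collision_energy=d.get("collision_energy"),
        )
    except KeyError as exc:
        raise PanelConfigError(f"{analyte}: transition missing field {exc}") from None


def load_panel(config_path: str | Path | None = None) -> AnalytePanel:
    """Load an analyte panel from a YAML config; built-in panel when no file given."""
    if config_path is None:
        return default_panel()
    path = Path(config_path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "analytes" not in cfg:
        raise PanelConfigError(f"{path}: expected a mapping with an 'analytes' list")
    defs = []
    for block in cfg["analytes"]:
        name = block.get("name")
        if not name:
            raise PanelConfigError(f"{path}: analyte block without a name")
        for req in ("formula", "retention_time", "transitions"):
            if req not in block:
                raise PanelConfigError(f"{name}: missing required field {req!r}")
        transitions = tuple(
            _transition_from_dict(t, name) for t in block["transitions"]
        )
        istd_tr = block.get("istd_transition")
        defs.append(
            AnalyteDef(
                name=name,
                formula=MolecularFormula.from_string(str(block["formula"])),
                retention_time=float(block["retention_time"]),
                rt_sd=float(block.get("rt_sd", 0.0)),
                transitions=transitions,
                istd_mode=block.get("istd_mode", "own_13C"),
                istd_ref=block.get("istd_ref"),
                istd_transition=_transition_from_dict(istd_tr, name) if istd_tr else None,
                quantified=bool(block.get("quantified", True)),
            )
        )
    return AnalytePanel(defs)


# ---------------------------------------------------------------------------
# Peak tables
# ---------------------------------------------------------------------------

PEAK_COLUMNS = ["sample_id", "channel_id", "area", "rt", "role"]
OPTIONAL_PEAK_COLUMNS = ["level_nM", "tech_rep", "bio_rep", "timepoint"]


@dataclass
class PeakTable:
    """Long-format integrated peak areas with per-record sample roles.

    ``data`` holds records whose channel resolved against the panel;
    ``unmapped`` collects rows with unknown channel ids (reported, excluded
    from quantification); ``rt_flagged`` indexes records whose observed RT
    deviates from the panel value by more than the tolerance.
    """

    data: pd.DataFrame
    unmapped: pd.DataFrame = field(default_factory=pd.DataFrame)
    rt_flagged: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.data)

    def by_role(self, role: str) -> pd.DataFrame:
        if role not in SAMPLE_ROLES:
            raise ValueError(f"unknown sample role {role!r}")
        return self.data[self.data["role"] == role]


def _as_peak_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableError(f"{source}: missing required columns {missing}")
    df = df.copy()
    for col in OPTIONAL_PEAK_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df["area"] = pd.to_numeric(df["area"])
    df["rt"] = pd.to_numeric(df["rt"])
    df["level_nM"] = pd.to_numeric(df["level_nM"], errors="coerce")
    return df


def build_peak_table(
    df: pd.DataFrame,
    panel: AnalytePanel,
    rt_tolerance: float = DEFAULT_RT_TOLERANCE,
    source: str = "<frame>",
) -> PeakTable:
    """Validate a long-format peak frame against a panel."""
    df = _as_peak_frame(df, source)
    if (df["area"] < 0).any():
        bad = df.loc[df["area"] < 0, ["sample_id", "channel_id", "area"]]
        raise PeakTableError(f"{source}: negative peak areas:\n{bad.to_string(index=False)}")
    bad_roles = set(df["role"]) - set(SAMPLE_ROLES)
    if bad_roles:
        raise PeakTableError(f"{source}: unknown sample roles {sorted(bad_roles)}")
    needs_level = df["role"].isin(["standard", "lod_standard", "qc"])
    if needs_level.any():
        levels = df.loc[needs_level, "level_nM"]
        if levels.isna().any() or (levels <= 0).any():
            raise PeakTableError(f"{source}: standard/QC records require level_nM > 0")
    dup = df.duplicated(subset=["sample_id", "channel_id"], keep=False)
    if dup.any():
        pairs = (
            df.loc[dup, ["sample_id", "channel_id"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise PeakTableError(f"{source}: duplicate (sample_id, channel_id) pairs: {pairs}")

    valid = panel.valid_channels()
    mapped = df["channel_id"].isin(valid)
    unmapped = df[~mapped]
    data = df[mapped].copy()

    # RT deviation check against the panel reference for 12C channels.
    ref_rt = {channel_id(a.name, "12C"): a.retention_time for a in panel.monitored}
    ref_rt.update(
        {channel_id(a.name, "13C"): a.retention_time for a in panel.monitored}
    )
    dev = (data["rt"] - data["channel_id"].map(ref_rt)).abs()
    flagged = data[dev.notna() & (dev > rt_tolerance)]
    data["rt_flag"] = dev.notna() & (dev > rt_tolerance)
    if len(unmapped):
        warnings.warn(
            f"{source}: {len(unmapped)} records with unmapped channels "
            f"{sorted(unmapped['channel_id'].unique())} excluded from quantification",
            stacklevel=2,
        )
    return PeakTable(data=data.reset_index(drop=True),
                     unmapped=unmapped.reset_index(drop=True),
                     rt_flagged=flagged.reset_index(drop=True))


def read_peak_table(
    csv_path: str | Path,
    panel: AnalytePanel,
    rt_tolerance: float = DEFAULT_RT_TOLERANCE,
) -> PeakTable:
    """Read a long-format peak-area CSV and validate it against the panel."""
    path = Path(csv_path)
    df = pd.read_csv(path)
    return build_peak_table(df, panel, rt_tolerance=rt_tolerance, source=str(path))


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

META_COLUMNS = [
    "sample_id", "dilution_factor", "extract_volume_l", "broth_volume_l", "cdw_g_per_l",
]


def read_sample_meta(csv_path: str | Path) -> pd.DataFrame:
    """Read per-sample dilution factors, volumes and CDW from CSV."""
    df = pd.read_csv(csv_path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableError(f"{csv_path}: missing metadata columns {missing}")
    for col in ("dilution_factor", "extract_volume_l", "broth_volume_l"):
        if (pd.to_numeric(df[col]) <= 0).any():
            raise PeakTableError(f"{csv_path}: column {col} must be positive")
    if (pd.to_numeric(df["dilution_factor"]) < 1).any():
        raise PeakTableError(f"{csv_path}: dilution_factor must be >= 1")
    return df


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def write_results(quant, curves, out_dir: str | Path, *, seed=None, config=None) -> dict:
    """Write concentrations, curve parameters and a JSON run manifest.

    Parameters
    ----------
    quant : pandas.DataFrame
        Long-format quantification matrix (``analyte``, ``sample_id``,
        ``conc_nmol_per_gcdw``, ``censored``, ``outlier``, ...).
    curves : iterable of CalibrationCurve
    out_dir : path
        Created if absent.

    Returns the mapping of logical name -> written path.
    """
    if quant is None or len(quant) == 0:
        raise ValueError("empty quantification matrix; nothing to write")
    curves = list(curves)
    if not curves:
        raise ValueError("no calibration curves; nothing to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    quant = quant.copy()
    if "censored" in quant.columns:
        quant["reported"] = quant.apply(
            lambda r: "<LOQ" if bool(r.get("censored"))
            else format(r["conc_nmol_per_gcdw"], ".6g"),
            axis=1,
        )
    conc_path = out / "concentrations.csv"
    quant.to_csv(conc_path, index=False)

    curve_rows = []
    for c in curves:
        curve_rows.append({
            "analyte": c.analyte,
            "slope": c.slope,
            "intercept": c.intercept,
            "r_squared": c.r_squared,
            "residual_sd": c.residual_sd,
            "lod_nM": c.lod,
            "loq_nM": c.loq,
            "n_points": c.n_points,
            "matrix_matched": c.matrix_matched,
            "rejected": c.rejected,
        })
    curves_path = out / "curves.csv"
    pd.DataFrame(curve_rows).to_csv(curves_path, index=False)

    cfg_text = json.dumps(config, sort_keys=True, default=str) if config else ""
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest() if cfg_text else None,
        "n_quant_records": int(len(quant)),
        "n_curves": len(curves),
        "versions": {
            "pandas": pd.__version__,
        },
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"concentrations": conc_path, "curves": curves_path, "manifest": manifest_path}
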