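"""Seeded synthetic MRM peak tables and culture physiology.

The generator emulates the data the quantification pipeline consumes, with
known ground truth, so every stage is verifiable without instrument data:

* a calibration batch: matrix blanks (endogenous background only), a
  twelve-point matrix-matched standard series (50-10,000 nM, duplicate
  injections), QC standards at 250/2500/7500 nM in matrix, and a
  low-concentration sensitivity series (0.78-100 nM, in solvent) for the
  ICH LOD/LOQ regression;
* a biological experiment: five sampling timepoints (aerobic reference T1,
  oxygen-limited T2, anaerobic T3-T5) x 2 biological x 5 technical
  replicates, with planted effect multipliers on the true intracellular
  pools (NADP+/NADPH halved from T2, NCA/NR tripled, ADPR doubled from T3,
  NAD+/NADH unchanged; NMN baseline sits below the LOQ to exercise
  censoring);
* a dense bioreactor time series: exponential aerobic growth, then linear
  growth under oxygen limitation/anaerobiosis, with glucose, mixed-acid
  products and off-gas consistent with the configured rates.

Noise model: peak areas are positive and heteroscedastic, so noise is
multiplicative lognormal (unit mean). A per-sample common-mode injection
factor multiplies every channel of a sample and cancels in the
isotope-dilution ratio; the analyte (12C) channel additionally carries the
configured technical CV, so the response CV equals the configured technical
CV. Biological CV perturbs the true pools per biological replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import isotopes
from .panel_io import AnalytePanel, PeakTable, build_peak_table, channel_id, default_panel

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_peak_tables",
    "simulate_experiment",
    "simulate_physiology",
]

TIMEPOINTS = ("T1", "T2", "T3", "T4", "T5")


def _default_effects() -> dict[str, dict[str, float]]:
    eff: dict[str, dict[str, float]] = {}
    later = ("T2", "T3", "T4", "T5")
    for a in ("NADP+", "NADPH"):
        eff[a] = {tp: 0.5 for tp in later}
    for a in ("NCA", "NR"):
        eff[a] = {tp: 3.0 for tp in later}
    eff["ADPR"] = {tp: 2.0 for tp in ("T3", "T4", "T5")}
    eff["NAM"] = {"T5": 1.5}
    return eff


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator (defaults = the design
    the pipeline is meant for)."""

    panel: AnalytePanel = field(default_factory=default_panel)

    # instrument response (area counts per nM), per 12C channel
    response_factor: float = 100.0
    #: concentration-equivalent of each 13C ISTD channel after the 10% spike
    istd_conc_nM: float = 500.0
    istd_spike_fraction: float = 0.10

    # calibration design
    calibration_levels: tuple[float, ...] = tuple(
        np.geomspace(50.0, 10000.0, 12).round(1)
    )
    calibration_replicates: int = 2
    qc_levels: tuple[float, ...] = (250.0, 2500.0, 7500.0)
    qc_replicates: int = 2
    low_series_levels: tuple[float, ...] = (
        0.78, 1.56, 3.13, 6.25, 12.5, 25.0, 50.0, 100.0
    )
    low_series_replicates: int = 2
    n_blanks: int = 3

    #: endogenous extract concentrations (nM) of the pooled calibration
    #: matrix; the redox cofactors dominate (NAD+/NADH well above the LQC)
    matrix_endogenous_nM: dict[str, float] = field(default_factory=lambda: {
        "NAD+": 1200.0, "NADH": 400.0, "NADP+": 150.0, "NADPH": 100.0,
        "FAD": 200.0, "NAM": 40.0, "NCA": 15.0, "NR": 10.0, "NMN": 5.0,
        "NAMN": 25.0, "ADPR": 50.0, "1-mNAM": 0.0, "NAAD": 0.0,
    })

    # noise (CVs of unit-mean lognormals)
    technical_cv: float = 0.05
    biological_cv: float = 0.10
    injection_cv: float = 0.03  # common-mode, cancels in the ID ratio
    crosstalk: bool = True
    #: (source, target, mass shift) pairs physically injected when crosstalk
    #: is on. Bleed-through needs a shared product ion as well as the parent
    #: collision, so only the NAD+ M+1 -> NAAD pair (common fragment 136.1)
    #: is injected by default; the crosstalk_scan parent-m/z screen is wider
    #: by design (it flags potential interferences for review).
    crosstalk_pairs: tuple[tuple[str, str, int], ...] = (("NAD+", "NAAD", 1),)

    # biological experiment
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_biological: int = 2
    n_technical: int = 5
    #: baseline intracellular pools (nmol / g CDW), aerobic reference;
    #: precursors <= 100, cofactors in the hundreds; NMN below the LOQ
    baseline_pools: dict[str, float] = field(default_factory=lambda: {
        "NAD+": 800.0, "NADH": 300.0, "NADP+": 150.0, "NADPH": 120.0,
        "FAD": 200.0, "NAM": 30.0, "NCA": 12.0, "NR": 10.0, "NMN": 1.0,
        "NAMN": 20.0, "ADPR": 40.0, "1-mNAM": 0.0,
    })
    effect_multipliers: dict[str, dict[str, float]] = field(
        default_factory=_default_effects
    )
    #: CDW (g/L) at the samplings: aerobic reference ~OD 2, oxygen-limited
    #: ~OD 4, then slow linear anaerobic growth (matches the physiology
    #: trajectory defaults below)
    cdw_by_timepoint: dict[str, float] = field(default_factory=lambda: {
        "T1": 0.80, "T2": 1.50, "T3": 1.62, "T4": 1.72, "T5": 1.78,
    })
    broth_volume_l: float = 1e-3
    extract_volume_l: float = 3e-4
    dilution_factor: float = 1.0

    # physiology (rates in the units the kinetics module reports)
    mu_aerobic: float = 0.61
    x0_g_per_l: float = 0.05
    glucose0_g_per_l: float = 20.0
    linear_growth_g_per_l_h: tuple[float, ...] = (0.35, 0.10, 0.08, 0.05)
    q_s: float = 1.9
    sampling_times_h: tuple[float, ...] = (0.0, 4.54, 6.54, 7.74, 8.94, 10.14)
    q_p_by_interval: dict[str, tuple[float, ...]] = field(default_factory=lambda: {
        "acetate": (0.01, 0.30, 0.19, 0.24, 0.25),
        "formate": (0.01, 0.29, 0.32, 0.63, 0.35),
        "lactate": (0.01, 0.15, 0.55, 0.55, 0.31),
        "succinate": (0.01, 0.00, 0.05, 0.08, 0.06),
        "ethanol": (0.00, 0.11, 0.19, 0.25, 0.18),
    })
    rq_by_interval: tuple[float | None, ...] = (1.0, 0.9, None, None, None)
    o2_in: float = 0.2095
    co2_in: float = 0.0004
    physiology_noise_cv: float = 0.0

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def pool_at(self, analyte: str, timepoint: str) -> float:
        mult = self.effect_multipliers.get(analyte, {}).get(timepoint, 1.0)
        return self.baseline_pools.get(analyte, 0.0) * mult

    def pool_to_extract_nM(self, pool: float, cdw: float) -> float:
        """nmol/gCDW -> extract concentration (nM) through the sampling chain."""
        biomass_g = cdw * self.broth_volume_l
        return pool * biomass_g / (self.extract_volume_l * self.dilution_factor)

    def true_slope(self, analyte: str) -> float:
        """True calibration slope (response per nM) implied by the generator."""
        return 1.0 / self.istd_conc_nM


@dataclass
class GroundTruth:
    """What the generator actually put in, for parameter-recovery tests."""

    extract_conc_nM: pd.DataFrame  # sample_id, analyte, true extract conc
    pools: pd.DataFrame | None = None  # sample_id, analyte, true nmol/gCDW
    slopes: dict[str, float] = field(default_factory=dict)
    effect_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(() if size is None else size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def _crosstalk_pairs(config: SimulationConfig):
    if not config.crosstalk:
        return []
    out = []
    for src, tgt, k in config.crosstalk_pairs:
        if src not in config.panel or tgt not in config.panel:
            raise ValueError(f"crosstalk pair references unknown analyte: {src}->{tgt}")
        dist = isotopes.isotopologue_distribution(config.panel[src].formula, max_shift=k)
        out.append((src, tgt, dist.ratio_to_m0(k)))
    return out


def _emit_sample(
    rows: list[dict],
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str,
    role: str,
    conc_by_analyte: dict[str, float],
    level: float | None = None,
    with_istd: bool = True,
    tech_rep=None,
    bio_rep=None,
    timepoint=None,
) -> None:
    """Generate 12C (+13C) areas for one injected sample, in place."""
    panel = config.panel
    inj = _lognormal_factor(rng, config.injection_cv, None)
    areas12: dict[str, float] = {}
    for a in panel.monitored:
        conc = conc_by_analyte.get(a.name, 0.0)
        eps = _lognormal_factor(rng, config.technical_cv, None)
        areas12[a.name] = config.response_factor * conc * inj * eps
    for src, tgt, frac in _crosstalk_pairs(config):
        areas12[tgt] += areas12[src] * frac
    for a in panel.monitored:
        rows.append({
            "sample_id": sample_id,
            "channel_id": channel_id(a.name, "12C"),
            "area": areas12[a.name],
            "rt": a.retention_time,
            "role": role,
            "level_nM": level,
            "tech_rep": tech_rep, "bio_rep": bio_rep, "timepoint": timepoint,
        })
        if with_istd and a.istd_mode == "own_13C":
            rows.append({
                "sample_id": sample_id,
                "channel_id": channel_id(a.name, "13C"),
                "area": config.response_factor * config.istd_conc_nM * inj,
                "rt": a.retention_time,
                "role": role,
                "level_nM": level,
                "tech_rep": tech_rep, "bio_rep": bio_rep, "timepoint": timepoint,
            })


def simulate_peak_tables(
    config: SimulationConfig, seed: int = 0
) -> tuple[PeakTable, pd.DataFrame, GroundTruth]:
    """Calibration batch: blanks, matrix standards, QCs and the low series.

    Deterministic for a given (config, seed). Returns the peak table, a
    per-sample metadata frame (trivial for instrument-side samples), and the
    ground truth (true extract concentrations and true slopes).
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    truth_rows: list[dict] = []
    quant_names = config.panel.names
    endo = config.matrix_endogenous_nM

    def record_truth(sample_id, conc_by_analyte):
        for a in quant_names:
            truth_rows.append({
                "sample_id": sample_id, "analyte": a,
                "true_extract_nM": conc_by_analyte.get(a, 0.0),
            })

    for i in range(config.n_blanks):
        sid = f"blank_{i + 1}"
        conc = dict(endo)
        _emit_sample(rows, config, rng, sid, "blank", conc)
        record_truth(sid, conc)

    for level in config.calibration_levels:
        for rep in range(config.calibration_replicates):
            sid = f"std_{level:g}_{rep + 1}"
            conc = {a: endo.get(a, 0.0) + level for a in quant_names}
            conc["NAAD"] = endo.get("NAAD", 0.0)  # monitor-only, never spiked
            _emit_sample(rows, config, rng, sid, "standard", conc,
                         level=level, tech_rep=rep + 1)
            record_truth(sid, conc)

    for level in config.qc_levels:
        for rep in range(config.qc_replicates):
            sid = f"qc_{level:g}_{rep + 1}"
            conc = {a: endo.get(a, 0.0) + level for a in quant_names}
            conc["NAAD"] = endo.get("NAAD", 0.0)
            _emit_sample(rows, config, rng, sid, "qc", conc,
                         level=level, tech_rep=rep + 1)
            record_truth(sid, conc)

    for level in config.low_series_levels:
        for rep in range(config.low_series_replicates):
            sid = f"lod_{level:g}_{rep + 1}"
            conc = {a: level for a in quant_names}  # solvent: no matrix background
            _emit_sample(rows, config, rng, sid, "lod_standard", conc,
                         level=level, tech_rep=rep + 1)
            record_truth(sid, conc)

    peaks = build_peak_table(pd.DataFrame(rows), config.panel, source="simulated")
    meta = pd.DataFrame({
        "sample_id": sorted({r["sample_id"] for r in rows}),
        "dilution_factor": 1.0,
        "extract_volume_l": config.extract_volume_l,
        "broth_volume_l": config.broth_volume_l,
        "cdw_g_per_l": np.nan,
    })
    truth = GroundTruth(
        extract_conc_nM=pd.DataFrame(truth_rows),
        slopes={a: config.true_slope(a) for a in quant_names},
    )
    return peaks, meta, truth


def simulate_experiment(
    config: SimulationConfig, seed: int = 0
) -> tuple[PeakTable, pd.DataFrame, GroundTruth]:
    """Biological samples with planted timepoint effects.

    True pools = baseline x effect multiplier x biological lognormal noise
    (shared across technical replicates of a biological replicate); extract
    concentrations follow through CDW and sampling volumes; areas as in the
    calibration batch.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    truth_rows: list[dict] = []
    meta_rows: list[dict] = []
    quant_names = [a for a in config.panel.names]

    for tp in config.timepoints:
        cdw = config.cdw_by_timepoint[tp]
        for b in range(1, config.n_biological + 1):
            bio_noise = {
                a: _lognormal_factor(rng, config.biological_cv, None)
                for a in quant_names
            }
            for t in range(1, config.n_technical + 1):
                sid = f"{tp}_b{b}_t{t}"
                pools = {
                    a: config.pool_at(a, tp) * bio_noise[a] for a in quant_names
                }
                conc = {
                    a: config.pool_to_extract_nM(pools[a], cdw)
                    for a in quant_names
                }
                _emit_sample(rows, config, rng, sid, "unknown", conc,
                             tech_rep=t, bio_rep=b, timepoint=tp)
                meta_rows.append({
                    "sample_id": sid,
                    "dilution_factor": config.dilution_factor,
                    "extract_volume_l": config.extract_volume_l,
                    "broth_volume_l": config.broth_volume_l,
                    "cdw_g_per_l": cdw,
                    "timepoint": tp, "bio_rep": b, "tech_rep": t,
                })
                for a in quant_names:
                    truth_rows.append({
                        "sample_id": sid, "analyte": a, "timepoint": tp,
                        "bio_rep": b, "tech_rep": t,
                        "true_pool_nmol_per_gcdw": pools[a],
                        "true_extract_nM": conc[a],
                    })

    peaks = build_peak_table(pd.DataFrame(rows), config.panel, source="simulated")
    truth_df = pd.DataFrame(truth_rows)
    truth = GroundTruth(
        extract_conc_nM=truth_df[["sample_id", "analyte", "true_extract_nM"]],
        pools=truth_df,
        slopes={a: config.true_slope(a) for a in quant_names},
        effect_multipliers=config.effect_multipliers,
    )
    return peaks, pd.DataFrame(meta_rows), truth


def simulate_physiology(
    config: SimulationConfig, seed: int = 0, dt: float = 0.05
) -> tuple[pd.DataFrame, GroundTruth]:
    """Dense culture time series consistent with the configured kinetics.

    Biomass grows exponentially (rate ``mu_aerobic``) over the first
    sampling interval, then linearly with the configured slopes. Glucose and
    products integrate the configured specific rates against the biomass
    trajectory analytically, so the kinetics module recovers the configured
    q_s / q_p / yields exactly on noiseless data. Off-gas fractions encode
    the configured per-interval RQ (undefined intervals have zero O2 uptake).
    """
    times = config.sampling_times_h
    n_int = len(times) - 1
    rng = np.random.default_rng(seed)

    # biomass at the sampling boundaries
    xb = [config.x0_g_per_l]
    xb.append(xb[0] * np.exp(config.mu_aerobic * (times[1] - times[0])))
    for i in range(1, n_int):
        xb.append(xb[i] + config.linear_growth_g_per_l_h[i - 1] * (times[i + 1] - times[i]))

    # include the sampling boundaries exactly so interval rates are not
    # blurred by interpolation across a phase change
    grid = np.unique(np.concatenate([
        np.arange(times[0], times[-1] + dt / 2, dt), np.asarray(times)
    ]))
    recs = []
    prod_names = list(config.q_p_by_interval)
    S_at = {times[0]: config.glucose0_g_per_l}
    P_at = {p: {times[0]: 0.0} for p in prod_names}

    def integral_x(i, t):
        """Integral of X over [times[i], t] within interval i."""
        t0, x0 = times[i], xb[i]
        if i == 0:
            mu = config.mu_aerobic
            return (x0 * np.exp(mu * (t - t0)) - x0) / mu
        r = config.linear_growth_g_per_l_h[i - 1]
        return x0 * (t - t0) + 0.5 * r * (t - t0) ** 2

    # propagate boundary values of glucose/products
    for i in range(n_int):
        area = integral_x(i, times[i + 1])
        S_at[times[i + 1]] = S_at[times[i]] - config.q_s * area
        for p in prod_names:
            P_at[p][times[i + 1]] = (
                P_at[p][times[i]] + config.q_p_by_interval[p][i] * area
            )

    for t in grid:
        i = min(np.searchsorted(times, t, side="right") - 1, n_int - 1)
        t0, x0 = times[i], xb[i]
        if i == 0:
            x = x0 * np.exp(config.mu_aerobic * (t - t0))
        else:
            x = x0 + config.linear_growth_g_per_l_h[i - 1] * (t - t0)
        area = integral_x(i, t)
        s = S_at[times[i]] - config.q_s * area
        rec = {"time_h": round(float(t), 6), "cdw_g_per_l": x,
               "glucose_g_per_l": max(s, 0.0)}
        for p in prod_names:
            rec[p] = P_at[p][times[i]] + config.q_p_by_interval[p][i] * area
        rq = config.rq_by_interval[i]
        rec["o2_in"], rec["co2_in"] = config.o2_in, config.co2_in
        if rq is None:
            rec["o2_out"] = config.o2_in  # no uptake: N2-sparged phase
            rec["co2_out"] = config.co2_in + 0.005 * x
        else:
            uptake = min(0.01 * x, 0.5 * config.o2_in)
            rec["o2_out"] = config.o2_in - uptake
            rec["co2_out"] = config.co2_in + rq * uptake
        recs.append(rec)

    ts = pd.DataFrame(recs)
    if config.physiology_noise_cv > 0:
        for col in ["cdw_g_per_l", "glucose_g_per_l"] + prod_names:
            ts[col] *= _lognormal_factor(rng, config.physiology_noise_cv, len(ts))

    truth = GroundTruth(
        extract_conc_nM=pd.DataFrame(),
        kinetics={
            "mu_aerobic": config.mu_aerobic,
            "q_s": config.q_s,
            "q_p_by_interval": config.q_p_by_interval,
            "rq_by_interval": config.rq_by_interval,
            "sampling_times_h": times,
            "biomass_at_boundaries": xb,
        },
    )
    return ts, truth
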