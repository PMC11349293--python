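"""End-to-end orchestration: simulate -> QC -> features -> stats -> plasticity.

A single :class:`PipelineConfig` carries every tunable constant; its
defaults are the analysis defaults (bands, SNR > 4, < 1% ISI violations,
5000 permutations, alpha = 0.05).  One master seed fans out to per-stage
child seeds through ``numpy.random.SeedSequence(seed).spawn``, so stages
are isolated and the whole run is bit-reproducible; a manifest (config
hash, seeds, versions) is written alongside the output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import pallidyn
from pallidyn import features as ft
from pallidyn import io as pio
from pallidyn import plasticity as pl
from pallidyn import simulate as sim
from pallidyn import stats as st

logger = logging.getLogger(__name__)

STAGES = ("cohort", "features", "stats", "plasticity", "report")

DEFAULT_FEATURES = ["fr_median", "bi_p90", "cv_p90",
                    "theta_p90", "alpha_p90", "low_beta_p90", "high_beta_p90"]


@dataclass
class PipelineConfig:
    """All pipeline constants; defaults are the analysis defaults."""

    seed: int = 0
    out_dir: str = "pallidyn_out"
    # QC
    snr_threshold: float = 4.0
    isi_violation_threshold: float = 0.01
    refractory_ms: float = 1.0
    # bands / oscillation analysis
    bands: list[list] = field(default_factory=lambda: [
        ["theta", 4.0, 8.0], ["alpha", 8.0, 12.0],
        ["low_beta", 12.0, 21.0], ["high_beta", 21.0, 30.0]])
    freq_lo: float = 1.0
    freq_hi: float = 100.0
    freq_step: float = 0.25
    acf_bin_ms: float = 2.0
    acf_max_lag_s: float = 1.0
    band_statistic: str = "max"
    # statistics
    n_perm: int = 5000
    alpha: float = 0.05
    correlation_family: str = "combined"
    # plasticity measurement windows (ms)
    fep_window_ms: list[float] = field(default_factory=lambda: [1.0, 10.0])
    fep_blank_ms: float = 1.0
    # simulation scenario
    simulate: bool = True
    n_pd: int = 44
    n_dystonia: int = 19
    segments_per_patient: list[int] = field(default_factory=lambda: [4, 8])
    segment_duration_s: float = 20.0
    n_pd_fep_patients: int = 10
    n_pd_fep_sites: int = 13
    n_dys_fep_patients: int = 8
    n_dys_fep_sites: int = 12
    run_spiketrain_arm: bool = True
    run_plasticity_arm: bool = True

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def band_definitions(self) -> list[ft.BandDefinition]:
        return [ft.BandDefinition(str(n), float(lo), float(hi))
                for n, lo, hi in self.bands]

    def freq_grid(self) -> np.ndarray:
        return np.arange(self.freq_lo, self.freq_hi + 1e-9, self.freq_step)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Return all config violations at once (empty list means valid)."""
    errors: list[str] = []
    for name, lo, hi in config.bands:
        if not (0 < float(lo) < float(hi)):
            errors.append(f"band {name}: must satisfy 0 < lo < hi "
                          f"(got lo={lo}, hi={hi})")
        if float(lo) < config.freq_lo or float(hi) > config.freq_hi:
            errors.append(f"band {name}: outside frequency grid")
    if config.n_perm < 1:
        errors.append("n_perm must be >= 1")
    if not (0.0 < config.alpha < 1.0):
        errors.append("alpha must lie in (0, 1)")
    if config.snr_threshold <= 0:
        errors.append("snr_threshold must be positive")
    if not (0.0 < config.isi_violation_threshold <= 1.0):
        errors.append("isi_violation_threshold must lie in (0, 1]")
    if config.freq_step <= 0 or config.freq_lo <= 0 \
            or config.freq_hi <= config.freq_lo:
        errors.append("frequency grid must satisfy 0 < lo < hi, step > 0")
    if config.acf_bin_ms <= 0 or config.acf_max_lag_s <= 0:
        errors.append("ACF bin and max lag must be positive")
    if len(config.fep_window_ms) != 2 \
            or config.fep_window_ms[0] >= config.fep_window_ms[1]:
        errors.append("fep_window_ms must be [lo, hi] with lo < hi")
    if config.correlation_family not in ("combined", "per_disease"):
        errors.append("correlation_family must be 'combined' or 'per_disease'")
    if list(config.segments_per_patient)[0] > list(config.segments_per_patient)[1]:
        errors.append("segments_per_patient must be a [min, max] range")
    return errors


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {stage: int(child.generate_state(1)[0] % (2**31 - 1))
            for stage, child in zip(STAGES, children)}


def _feature_table(segments, config: PipelineConfig) -> pd.DataFrame:
    bands = config.band_definitions()
    grid = config.freq_grid()
    rows = []
    for seg in segments:
        f = ft.segment_features(seg, bands=bands, f_grid=grid,
                                acf_bin_ms=config.acf_bin_ms,
                                acf_max_lag_s=config.acf_max_lag_s,
                                band_statistic=config.band_statistic)
        row = {"segment_id": f.segment_id, "patient_id": f.patient_id,
               "disease": f.disease, "fr_hz": f.fr_hz, "cv": f.cv,
               "bi": f.bi, "bi_degenerate": f.bi_degenerate}
        for b in bands:
            row[f"{b.name}_power"] = f.band_power[b.name]
        rows.append(row)
    return pd.DataFrame(rows)


def patient_summary_table(feature_df: pd.DataFrame, scores: pd.DataFrame,
                          band_names: list[str]) -> pd.DataFrame:
    """Patient-level aggregation of the per-segment feature table."""
    score_map = scores.set_index("patient_id")["clinical_score_pct"].to_dict() \
        if scores is not None and len(scores) else {}
    rows = []
    for pid, g in feature_df.groupby("patient_id", sort=True):
        p90 = lambda col: float(np.percentile(g[col], 90, method="linear"))
        row = {"patient_id": pid, "disease": g["disease"].iloc[0],
               "n_segments": len(g),
               "fr_median": float(g["fr_hz"].median()),
               "bi_p90": p90("bi"), "cv_p90": p90("cv"),
               "clinical_score_pct": score_map.get(pid, np.nan)}
        for b in band_names:
            row[f"{b}_p90"] = p90(f"{b}_power")
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir: Path | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Execute the configured stages and write all report tables.

    Returns the tables as DataFrames keyed by name; each is also written
    to ``out_dir`` as CSV together with a JSON run manifest.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    tables: dict[str, pd.DataFrame] = {}
    band_names = [b[0] for b in config.bands]

    if config.run_spiketrain_arm:
        cohort_cfg = sim.CohortConfig(
            n_pd=config.n_pd, n_dystonia=config.n_dystonia,
            segments_per_patient=tuple(config.segments_per_patient),
            segment_duration_s=config.segment_duration_s)
        segments, scores, _truth = sim.gen_cohort(cohort_cfg,
                                                  seed=seeds["cohort"])
        pio.write_spike_tables(segments, out)
        scores.to_csv(out / "clinical_scores.csv", index=False)

        feature_df = _feature_table(segments, config)
        tables["segment_features"] = feature_df
        summaries = patient_summary_table(feature_df, scores, band_names)
        tables["patient_summaries"] = summaries

        feat_cols = (["fr_median", "bi_p90", "cv_p90"]
                     + [f"{b}_p90" for b in band_names])
        tables["group_comparison"] = st.run_group_comparison(
            summaries[summaries["disease"] == "PD"],
            summaries[summaries["disease"] == "dystonia"],
            feat_cols, alpha=config.alpha)
        tables["clinical_correlations"] = st.run_clinical_correlations(
            summaries, feat_cols, n_perm=config.n_perm,
            seed=seeds["stats"], alpha=config.alpha,
            family=config.correlation_family)

    if config.run_plasticity_arm:
        sessions, _fep_truth = sim.gen_fep_cohort(
            n_pd_patients=config.n_pd_fep_patients,
            n_pd_sites=config.n_pd_fep_sites,
            n_dys_patients=config.n_dys_fep_patients,
            n_dys_sites=config.n_dys_fep_sites,
            seed=seeds["plasticity"])
        pio.write_fep_sessions(sessions, out / "fep_sessions.csv")
        per_disease, cross = pl.longterm_plasticity(sessions)
        lt_rows = []
        for disease, res in per_disease.items():
            lt_rows.append({
                "disease": disease,
                "epoch_effect": res.fit.fixed_effect, "se": res.fit.se,
                "p": res.fit.p,
                "random_intercept_sd": res.fit.random_intercept_sd,
                "n_sites": res.fit.n_obs // 2,
                "n_patients": res.fit.n_groups, "method": res.fit.method})
        tables["longterm_fits"] = pd.DataFrame(lt_rows)
        tables["longterm_sites"] = pd.concat(
            [r.site_table for r in per_disease.values()], ignore_index=True)
        tables["longterm_cross_disease"] = pd.DataFrame([{
            "effect_pct_pd_minus_dystonia": cross.fixed_effect,
            "se": cross.se, "p": cross.p, "method": cross.method}])
        st_table = pl.shortterm_from_sessions(sessions)
        tables["shortterm_sites"] = st_table
        hl = pl.compare_halflife(st_table)
        tables["shortterm_cross_disease"] = pd.DataFrame([{
            "effect_pulses_dystonia_minus_pd": hl.fixed_effect,
            "se": hl.se, "p": hl.p, "method": hl.method}])

    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "versions": {"pallidyn": pallidyn.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "tables": sorted(tables),
    }
    pio.write_json(manifest, out / "manifest.json")
    return tables
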