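"""End-to-end study orchestration: simulate → measure → model → report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cardiac, connectivity, spectral, stats, synthetic
from .connectivity import ROICatalog, PRECUNEUS_REGIONS
from .synthetic import BAND_EDGES, SimulationConfig

__all__ = ["RunConfig", "run_study", "report", "default_run_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full study run (YAML-serializable)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    roi_catalog_path: str | None = None      # None → built-in catalog
    min_epochs: int = 15
    fdr_q: float = 0.05
    fc_anchor: tuple[str, ...] = PRECUNEUS_REGIONS
    fc_bands: tuple[str, ...] = ("alpha", "beta")
    power_bands: tuple[str, ...] = ("theta", "alpha", "beta")
    sensor_channels: tuple[str, ...] | None = None   # None → all channels
    n_ibi_events: int = 30
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.roi_catalog_path is not None and not Path(self.roi_catalog_path).exists():
            raise FileNotFoundError(f"ROI catalog not found: {self.roi_catalog_path}")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        if seed is not None:
            sim_raw["random_seed"] = seed
        for key in ("band_effects", "coupling_effects", "baseline_coupling"):
            if key in sim_raw:
                sim_raw[key] = {
                    _parse_effect_key(k): v for k, v in sim_raw[key].items()
                }
        if "regions" in sim_raw:
            sim_raw["regions"] = tuple(sim_raw["regions"])
        sim = SimulationConfig(**sim_raw)
        for key in ("fc_anchor", "fc_bands", "power_bands", "sensor_channels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


def _parse_effect_key(key: str):
    """YAML effect keys: ``region|band`` or ``regionA,regionB|band``."""
    head, band = key.rsplit("|", 1)
    if "," in head:
        a, b = (s.strip() for s in head.split(",", 1))
        return ((a, b), band.strip())
    return (head.strip(), band.strip())


def default_run_config(seed: int = 0, demo_scale: bool = True) -> RunConfig:
    """A runnable default configuration.

    ``demo_scale`` shrinks the cohort and sampling rate so a full run
    finishes in minutes on one CPU; study scale is 73 participants at
    512 Hz.
    """
    sim = SimulationConfig(random_seed=seed)
    if demo_scale:
        sim = SimulationConfig(
            n_participants=10,
            n_epochs_per_condition=16,
            fs=256.0,
            random_seed=seed,
        )
    return RunConfig(simulation=sim)


def run_study(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full synthetic study and return the result tables.

    Stages: generate epochs per participant/condition, apply the
    epoch-count inclusion rule, compute relative band power (sensor-level
    average and per region), orthogonalized AEC over the anchored
    connection set, event-related IBI differences, questionnaire scores,
    then the mixed-model / BF / FDR statistical layer over the enumerated
    test family.  Outputs are written as CSV when ``out_dir`` is set;
    reruns with the same configuration are reproducible.
    """
    sim = config.simulation
    catalog = (
        ROICatalog.from_yaml(config.roi_catalog_path)
        if config.roi_catalog_path
        else ROICatalog()
    )
    bands = spectral.BandScheme()
    connections = connectivity.enumerate_connections(
        list(sim.regions), config.fc_bands, anchor=config.fc_anchor
    )

    power_rows, fc_frames, count_rows = [], [], []
    try:
        for p, by_cond in synthetic.generate_study(sim):
            for cond, es in by_cond.items():
                count_rows.append(
                    {"participant": es.participant, "condition": cond, "n_epochs": es.n_epochs}
                )
                pt = spectral.power_table_from_epochs([es], bands=bands)
                power_rows.append(pt)
                fc_frames.append(
                    connectivity.connectivity_table_from_epochs(
                        [es], connections, BAND_EDGES
                    )
                )
    except Exception as exc:
        raise RuntimeError(f"stage 'measurement' failed: {exc}") from exc

    epoch_counts = pd.DataFrame(count_rows)
    retained = stats.inclusion_filter(epoch_counts, min_epochs=config.min_epochs)
    logger.info("%d of %d participants pass the inclusion rule", len(retained), sim.n_participants)

    power = pd.concat(power_rows, ignore_index=True)
    power = power[power["participant"].isin(retained)]
    fc = pd.concat(fc_frames, ignore_index=True)
    fc = fc[fc["participant"].isin(retained)]

    sensor_channels = config.sensor_channels or tuple(sim.channel_labels)
    sensor = spectral.frontal_average(power, channels=sensor_channels)

    # cardiac stage
    events = synthetic.default_event_times(config.n_ibi_events)
    ibi_frames = []
    for p in range(sim.n_participants):
        pid = synthetic.participant_id(p)
        if pid not in retained:
            continue
        for cond in ("control", "negative"):
            peaks = synthetic.generate_rpeaks(sim, events, condition=cond, participant=p)
            ibi_frames.append(cardiac.ibi_table(peaks, events, cond, participant=pid))
    ibi = pd.concat(ibi_frames, ignore_index=True)
    ibi_means, ibi_model_input = cardiac.condition_contrast_ibi(ibi)

    scores = pd.concat(
        [synthetic.generate_scores(sim, scale=s) for s in ("valence", "arousal")],
        ignore_index=True,
    )
    scores = scores[scores["participant"].isin(retained)]

    # statistical layer over the enumerated family
    test_ids = stats.enumerate_tests(
        sensor_bands=config.power_bands,
        source_regions=sim.regions,
        source_bands=config.power_bands,
        fc_connections=connections,
    )
    measures: dict[str, pd.DataFrame] = {}
    for band in config.power_bands:
        sub = sensor[sensor["band"] == band]
        measures[f"power:frontal:{band}"] = sub.rename(columns={"relative_power": "value"})
    for region in sim.regions:
        for band in config.power_bands:
            sub = power[(power["region"] == region) & (power["band"] == band)]
            measures[f"power:{region}:{band}"] = sub.rename(columns={"relative_power": "value"})
    for (a, b), band in connections:
        sub = fc[(fc["region_a"] == a) & (fc["region_b"] == b) & (fc["band"] == band)]
        measures[f"fc:{a}--{b}:{band}"] = sub.rename(columns={"aec": "value"})

    try:
        results = stats.fit_measure_table(measures, test_ids, q=config.fdr_q)
    except Exception as exc:
        raise RuntimeError(f"stage 'stats' failed: {exc}") from exc

    # Bayes factors for the sensor-level measures (null-favouring evidence)
    bf = {}
    for band in config.power_bands:
        tid = f"power:frontal:{band}"
        try:
            fam = results.loc[results["measure"] == tid, "family"].iloc[0]
            bf[tid] = stats.bayes_factor_bic(measures[tid], family=fam)
        except Exception as exc:  # noqa: BLE001 - BF is best-effort per measure
            logger.warning("BF01 unavailable for %s: %s", tid, exc)
            bf[tid] = np.nan
    results["bf01"] = results["measure"].map(bf)

    # per-index IBI contrasts (separate family, linear only)
    ibi_rows = []
    for k in cardiac.IBI_INDICES:
        if k == cardiac.REFERENCE_INDEX:
            continue
        sub = ibi_model_input[ibi_model_input["index"] == k]
        try:
            res = stats.fit_condition_model(sub, measure=f"ibi_diff[{k}]")
        except stats.ConvergenceError as exc:
            logger.warning("IBI index %d: %s", k, exc)
            continue
        ibi_rows.append(
            {"index": k, "beta": res.beta, "se": res.se, "t": res.t, "p_raw": res.p_raw}
        )
    ibi_stats = pd.DataFrame(ibi_rows)
    if not ibi_stats.empty:
        ibi_stats["p_fdr"] = stats.fdr_correct(ibi_stats["p_raw"].to_numpy(), q=config.fdr_q)

    score_rows = []
    for scale in ("valence", "arousal"):
        sub = scores[scores["scale"] == scale]
        try:
            res = stats.fit_condition_model(sub, measure=f"sam:{scale}")
            score_rows.append(
                {
                    "scale": scale,
                    "family": res.family,
                    "beta": res.beta,
                    "se": res.se,
                    "t": res.t,
                    "p_raw": res.p_raw,
                    "ses": res.ses,
                }
            )
        except stats.ConvergenceError as exc:
            logger.warning("score scale %s: %s", scale, exc)

    out = {
        "epoch_counts": epoch_counts,
        "power_table": pd.concat([sensor, power], ignore_index=True),
        "connectivity_table": fc,
        "ibi_table": ibi,
        "ibi_means": ibi_means,
        "ibi_stats": ibi_stats,
        "scores": scores,
        "score_stats": pd.DataFrame(score_rows),
        "stat_results": results,
    }
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
        (out_dir / "report.md").write_text(report(results))
        logger.info("results written to %s", out_dir)
    return out


def _fmt(x, digits=4) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "n/a"
    return f"{x:.{digits}g}"


def report(results: pd.DataFrame, q: float = 0.05) -> str:
    """Human-readable per-measure report in the (ß; SE; t; p; SES; CI) style."""
    lines = ["# Condition contrasts", ""]
    if results.empty:
        return "\n".join(lines) + "\n"
    for _, row in results.iterrows():
        if pd.isna(row.get("p_raw")):
            lines.append(f"- {row['measure']}: model did not converge")
            continue
        flag = " **significant (FDR)**" if pd.notna(row.get("p_fdr")) and row["p_fdr"] <= q else ""
        line = (
            f"- {row['measure']} [{row.get('family', '?')}]: "
            f"(ß = {_fmt(row['beta'])}; SE = {_fmt(row['se'])}; t = {_fmt(row['t'])}; "
            f"p = {_fmt(row['p_raw'])}; p_FDR = {_fmt(row.get('p_fdr'))}; "
            f"SES = {_fmt(row.get('ses'))}; "
            f"CI = {_fmt(row.get('ses_lo'))}; {_fmt(row.get('ses_hi'))})"
            f"{flag}"
        )
        bf01 = row.get("bf01")
        if bf01 is not None and pd.notna(bf01):
            line += f" — BF01 = {_fmt(bf01)} ({stats.jeffreys_label(bf01)})"
        lines.append(line)
    return "\n".join(lines) + "\n"
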