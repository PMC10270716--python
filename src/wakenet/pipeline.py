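"""End-to-end study analysis.

``run_study`` drives the full chain for every recording of a study —
broadband filtering, reference-based subspace cleaning, standardized Welch
band power, per-band wPLI connectivity, weighted graph metrics — and then
the inferential layer: baseline-vs-bout and condition contrasts per band
and metric, electrode-level clustering contrasts with within-band FDR, and
brain-behavior correlations at the first post-awakening bout of the
control condition.  All outputs are tidy delimited tables; a run is fully
reproducible from its config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BandDefinition, DEFAULT_BANDS
from .io import read_brainvision, read_matrix
from .preprocess import (
    NoReferenceError,
    asr_clean,
    band_decompose,
    bandpass_filter,
    build_reference_signal,
)
from .spectral import welch_psd, standardize_psd, band_power
from .connectivity import wpli_matrix
from .graph import GraphMetrics
from .stats import bh_fdr, paired_compare, pearson_corr, summarize_behavior
from .simulate import SyntheticStudyConfig, StudyData, generate_study


class ManifestError(ValueError):
    """A requested comparison cannot be formed from the available recordings."""


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    synthetic: SyntheticStudyConfig | None = None
    manifest: list[dict] | None = None  # entries: path, subject, condition, bout
    input_format: str = "matrix"  # or "brainvision"
    matrix_sampling_rate: float | None = None
    matrix_labels: list[str] | None = None
    behavior_path: str | None = None

    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    prefilter: tuple[float, float] = (0.5, 50.0)
    filter_order: int = 3
    asr_enabled: bool = True
    amp_threshold_uv: float = 100.0
    min_segment_ms: float = 1000.0
    asr_window_ms: float = 500.0
    asr_k_sd: float = 5.0
    welch_window_s: float = 4.0
    welch_overlap: float = 0.5
    psd_source: str = "broadband"  # or "bandpassed": PSD from band-filtered copies
    edge_trim_s: float = 2.0
    wpli_segment_s: float | None = None  # None = whole-epoch accumulation
    convention: str = "bct"

    baseline_bout: str = "BL"
    correlation_key: tuple[str, str] = ("control", "T1")
    electrode_metric_bands: tuple[str, ...] = ("delta",)
    fdr_q: float = 0.05
    write_connectivity: bool = True
    outdir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            kwargs["synthetic"] = _synthetic_from_dict(kwargs["synthetic"])
        if "bands" in kwargs:
            kwargs["bands"] = tuple(BandDefinition(**b) for b in kwargs["bands"])
        for key in ("prefilter", "correlation_key", "electrode_metric_bands"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _synthetic_from_dict(d: dict) -> SyntheticStudyConfig:
    from .simulate import ArtifactSpec, BandSpec, EffectSpec, NoiseSpec

    d = dict(d)
    if "band_specs" in d:
        d["band_specs"] = tuple(BandSpec(**b) for b in d["band_specs"])
    for key, cls in (("artifact_spec", ArtifactSpec), ("noise_spec", NoiseSpec)):
        if key in d and isinstance(d[key], dict):
            d[key] = cls(**d[key])
    if "effect_specs" in d and isinstance(d["effect_specs"], dict):
        e = dict(d["effect_specs"])
        for mapkey in ("clustering", "power"):
            if mapkey in e:
                e[mapkey] = {tuple(k.split("|")): v for k, v in e[mapkey].items()}
        d["effect_specs"] = EffectSpec(**e)
    for key in ("bouts", "conditions"):
        if key in d:
            d[key] = tuple(d[key])
    return SyntheticStudyConfig(**d)


@dataclass
class ResultBundle:
    """All tables produced by one analysis run."""

    channel_power: pd.DataFrame
    global_power: pd.DataFrame
    network: pd.DataFrame
    node_metrics: pd.DataFrame
    connectivity: dict  # (subject, condition, bout, band) -> ConnectivityMatrix
    stats: pd.DataFrame
    electrode_stats: pd.DataFrame
    correlations: pd.DataFrame
    behavior: pd.DataFrame
    log: list[str] = field(default_factory=list)


def _load_recordings(config: AnalysisConfig) -> tuple[dict, pd.DataFrame]:
    """Resolve recordings and the behavioral table from config."""
    if config.synthetic is not None:
        synth = config.synthetic
        study: StudyData = generate_study(synth)
        behavior = pd.DataFrame(
            [
                {
                    "subject": r.subject, "condition": r.condition, "bout": r.bout,
                    "kss": r.kss,
                    **_behavior_summary_fields(r),
                }
                for r in study.behavior
            ]
        )
        return study.recordings, behavior
    if not config.manifest:
        raise ManifestError("config provides neither a synthetic study nor a manifest")
    recordings: dict = {}
    for entry in config.manifest:
        key = (entry["subject"], entry["condition"], entry["bout"])
        if key in recordings:
            raise ManifestError(f"duplicate manifest key {key}")
        path = Path(entry["path"])
        if config.input_format == "brainvision" or path.suffix == ".vhdr":
            rec = read_brainvision(path)
            rec.metadata.update(subject=key[0], condition=key[1], bout=key[2])
        else:
            if config.matrix_sampling_rate is None:
                raise ManifestError("matrix input requires matrix_sampling_rate")
            rec = read_matrix(
                path, config.matrix_sampling_rate, config.matrix_labels,
                metadata={"subject": key[0], "condition": key[1], "bout": key[2]},
            )
        recordings[key] = rec
    behavior = pd.DataFrame()
    if config.behavior_path:
        raw = pd.read_csv(config.behavior_path, sep="\t")
        rows = []
        for _, r in raw.iterrows():
            rts = np.asarray([float(x) for x in str(r["rt_series_ms"]).split(";")])
            s = summarize_behavior(r["subject"], r["condition"], r["bout"], int(r["kss"]), rts)
            rows.append(
                {"subject": s.subject, "condition": s.condition, "bout": s.bout,
                 "kss": s.kss, "mean_speed": s.mean_speed, "lapses": s.lapses}
            )
        behavior = pd.DataFrame(rows)
    return recordings, behavior


def _behavior_summary_fields(record) -> dict:
    s = summarize_behavior(record.subject, record.condition, record.bout,
                           record.kss, record.rt_series_ms)
    return {"mean_speed": s.mean_speed, "lapses": s.lapses}


def run_study(config: AnalysisConfig) -> ResultBundle:
    """Run the complete analysis described by ``config``."""
    log: list[str] = []
    log.append(f"seed={config.seed} config_hash={_config_hash(config)}")
    recordings, behavior = _load_recordings(config)
    log.append(f"loaded {len(recordings)} recordings")

    subjects = sorted({k[0] for k in recordings})
    conditions = sorted({k[1] for k in recordings})
    bouts = list(dict.fromkeys(k[2] for k in sorted(recordings)))
    if config.baseline_bout not in bouts:
        raise ManifestError(f"baseline bout {config.baseline_bout!r} absent from recordings")

    power_tables = []
    network_rows = []
    node_rows = []
    connectivity: dict = {}

    for key in sorted(recordings):
        rec = recordings[key]
        rec = bandpass_filter(rec, *config.prefilter, order=config.filter_order)
        if config.asr_enabled:
            try:
                ref = build_reference_signal(rec, config.min_segment_ms, config.amp_threshold_uv)
                rec = asr_clean(rec, ref, config.asr_window_ms, config.asr_k_sd)
            except NoReferenceError:
                log.append(f"{key}: no clean reference segment; subspace cleaning skipped")
        band_recs = band_decompose(rec, config.bands, config.filter_order)
        if config.psd_source == "broadband":
            psd = standardize_psd(welch_psd(rec, config.welch_window_s, config.welch_overlap))
            power_tables.append(band_power(psd, config.bands).channel_table)
        elif config.psd_source == "bandpassed":
            for band in config.bands:
                psd = standardize_psd(
                    welch_psd(band_recs[band.name], config.welch_window_s, config.welch_overlap))
                power_tables.append(band_power(psd, [band]).channel_table)
        else:
            raise ValueError(f"unknown psd_source {config.psd_source!r}")

        for band_name, band_rec in band_recs.items():
            conn = wpli_matrix(band_rec, config.edge_trim_s, band=band_name,
                               segment_s=config.wpli_segment_s)
            connectivity[(*key, band_name)] = conn
            gm = GraphMetrics.from_connectivity(conn, config.convention)
            subject, condition, bout = key
            network_rows.append(
                {"subject": subject, "condition": condition, "bout": bout, "band": band_name,
                 "clustering": gm.mean_clustering, "path_length": gm.path_length,
                 "disconnected_pairs": gm.disconnected_pairs}
            )
            for ch, c_i, k_i in zip(conn.channel_labels, gm.clustering, gm.degree):
                node_rows.append(
                    {"subject": subject, "condition": condition, "bout": bout,
                     "band": band_name, "channel": ch, "clustering": c_i, "degree": k_i}
                )

    channel_power = pd.concat(power_tables, ignore_index=True)
    global_power = (
        channel_power.groupby(["subject", "condition", "bout", "band"], sort=True)["power"]
        .mean().reset_index().rename(columns={"power": "global_power"})
    )
    network = pd.DataFrame(network_rows)
    node_metrics = pd.DataFrame(node_rows)
    log.append(f"computed {len(connectivity)} connectivity matrices")

    stats_df = _global_contrasts(config, global_power, network, subjects, conditions, bouts)
    electrode_df = _electrode_contrasts(config, node_metrics, subjects, conditions, bouts)
    corr_df = _correlations(config, global_power, network, behavior)
    log.append(
        f"stats: {len(stats_df)} global contrasts, {len(electrode_df)} electrode rows, "
        f"{len(corr_df)} correlations"
    )

    bundle = ResultBundle(channel_power, global_power, network, node_metrics, connectivity,
                          stats_df, electrode_df, corr_df, behavior, log)
    if config.outdir:
        _write_bundle(bundle, config)
    return bundle


def _metric_series(global_power, network, metric, band, condition, bout, subjects):
    """Per-subject values of one metric at one (condition, bout, band)."""
    if metric == "global_power":
        tab = global_power
        col = "global_power"
    else:
        tab = network
        col = metric
    sel = tab[(tab.condition == condition) & (tab.bout == bout) & (tab.band == band)]
    sel = sel.set_index("subject")[col]
    missing = [s for s in subjects if s not in sel.index]
    if missing:
        raise ManifestError(
            f"metric {metric!r} band {band!r}: missing ({condition}, {bout}) for subjects {missing}"
        )
    return sel.loc[list(subjects)].to_numpy()


def _global_contrasts(config, global_power, network, subjects, conditions, bouts) -> pd.DataFrame:
    rows = []
    bl = config.baseline_bout
    test_bouts = [b for b in bouts if b != bl]
    metrics = ["global_power", "clustering", "path_length"]
    bands = [b.name for b in config.bands]
    for band in bands:
        for metric in metrics:
            for condition in conditions:
                x_bl = _metric_series(global_power, network, metric, band, condition, bl, subjects)
                for bout in test_bouts:
                    y = _metric_series(global_power, network, metric, band, condition, bout, subjects)
                    res = paired_compare(x_bl, y, f"{bl}_vs_{bout}_{condition}", metric, band)
                    rows.append(res)
            if len(conditions) == 2:
                c0, c1 = conditions
                for bout in test_bouts:
                    x = _metric_series(global_power, network, metric, band, c0, bout, subjects)
                    y = _metric_series(global_power, network, metric, band, c1, bout, subjects)
                    rows.append(paired_compare(x, y, f"{bout}_{c0}_vs_{c1}", metric, band))
    return pd.DataFrame([r.__dict__ for r in rows])


def _electrode_contrasts(config, node_metrics, subjects, conditions, bouts) -> pd.DataFrame:
    """Per-electrode clustering contrasts; BH-FDR applied within band."""
    bl = config.baseline_bout
    rows = []
    channels = list(dict.fromkeys(node_metrics["channel"]))

    def series(condition, bout, band, channel):
        sel = node_metrics[
            (node_metrics.condition == condition) & (node_metrics.bout == bout)
            & (node_metrics.band == band) & (node_metrics.channel == channel)
        ].set_index("subject")["clustering"]
        missing = [s for s in subjects if s not in sel.index]
        if missing:
            raise ManifestError(
                f"electrode map: missing ({condition}, {bout}, {band}) for subjects {missing}"
            )
        return sel.loc[list(subjects)].to_numpy()

    comparisons = []
    first_test = next((b for b in bouts if b != bl), None)
    if first_test is not None:
        for condition in conditions:
            comparisons.append((f"{bl}_vs_{first_test}_{condition}",
                                (condition, bl), (condition, first_test)))
        if len(conditions) == 2:
            c0, c1 = conditions
            comparisons.append((f"{first_test}_{c0}_vs_{c1}", (c0, first_test), (c1, first_test)))

    for band in config.electrode_metric_bands:
        for label, (cond_x, bout_x), (cond_y, bout_y) in comparisons:
            family = []
            for ch in channels:
                x = series(cond_x, bout_x, band, ch)
                y = series(cond_y, bout_y, band, ch)
                res = paired_compare(x, y, label, "clustering", band)
                family.append((ch, res))
            flags = bh_fdr([r.p for _, r in family], q=config.fdr_q)
            for (ch, res), flag in zip(family, flags):
                rows.append(
                    {"comparison": label, "band": band, "channel": ch, "t": res.t,
                     "df": res.df, "p": res.p, "g": res.g, "q_significant": bool(flag)}
                )
    return pd.DataFrame(rows)


def _correlations(config, global_power, network, behavior) -> pd.DataFrame:
    """Brain-behavior Pearson correlations at the configured (condition, bout)."""
    if behavior.empty:
        return pd.DataFrame(columns=["condition", "bout", "band", "metric", "behavior", "n", "R", "p"])
    condition, bout = config.correlation_key
    beh = behavior[(behavior.condition == condition) & (behavior.bout == bout)]
    if beh.empty:
        return pd.DataFrame(columns=["condition", "bout", "band", "metric", "behavior", "n", "R", "p"])
    beh = beh.set_index("subject")
    rows = []
    for band in [b.name for b in config.bands]:
        for metric, table, col in (
            ("global_power", global_power, "global_power"),
            ("clustering", network, "clustering"),
            ("path_length", network, "path_length"),
        ):
            sel = table[(table.condition == condition) & (table.bout == bout) & (table.band == band)]
            sel = sel.set_index("subject")[col]
            common = [s for s in sel.index if s in beh.index]
            if len(common) < 3:
                continue
            brain = sel.loc[common].to_numpy()
            for beh_name in ("kss", "mean_speed", "lapses"):
                vals = beh.loc[common, beh_name].to_numpy(dtype=float)
                try:
                    R, p = pearson_corr(brain, vals)
                except ValueError:
                    continue
                rows.append(
                    {"condition": condition, "bout": bout, "band": band, "metric": metric,
                     "behavior": beh_name, "n": len(common), "R": R, "p": p}
                )
    return pd.DataFrame(rows)


def _config_hash(config: AnalysisConfig) -> str:
    from dataclasses import replace

    # hash the scientific configuration only, not where the tables land
    text = json.dumps(repr(replace(config, outdir=None)), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _write_bundle(bundle: ResultBundle, config: AnalysisConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    tables = {
        "channel_power.tsv": bundle.channel_power,
        "global_power.tsv": bundle.global_power,
        "network_metrics.tsv": bundle.network,
        "node_metrics.tsv": bundle.node_metrics,
        "stats.tsv": bundle.stats,
        "electrode_stats.tsv": bundle.electrode_stats,
        "correlations.tsv": bundle.correlations,
        "behavior.tsv": bundle.behavior,
    }
    for name, df in tables.items():
        df.to_csv(outdir / name, sep="\t", index=False, float_format=fmt)
    if config.write_connectivity:
        conn_dir = outdir / "connectivity"
        conn_dir.mkdir(exist_ok=True)
        for (subject, condition, bout, band), conn in sorted(bundle.connectivity.items()):
            header = "\t".join(conn.channel_labels)
            np.savetxt(
                conn_dir / f"wpli_{subject}_{condition}_{bout}_{band}.tsv",
                conn.weights, fmt=fmt, delimiter="\t", header=header, comments="",
            )
    (outdir / "run.log").write_text("\n".join(bundle.log) + "\n")
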