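"""End-to-end orchestration: align -> envelope -> correlations ->
surrogate nulls -> significance maps -> SNR contrasts -> report tables.

Each stage is a plain function over in-memory objects so that the CLI,
the tests, and interactive use share one code path.  A full run is
deterministic under a fixed root seed; the configuration hash and seed
are embedded in the report provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import estimate_stimulus_lag, map_volume_to_grid, trim_to_window
from .clusters import (
    AdjacencyGraph,
    ClusterResult,
    adjacency_from_coords,
    bh_reject,
    cluster_permutation_test,
    form_clusters,
    snr_difference_map,
)
from .containers import EnvelopeSet, band_table
from .filters import bandpass_filter, log_analytic_amplitude, notch_filter, resample
from .io import AnalysisConfig
from .reliability import ComparisonSpec, compute_comparison, grand_average
from .surrogates import (
    NullDistribution,
    ReliabilityMap,
    bootstrap_null,
    null_from_surrogates,
    standardize_and_test,
    surrogate_correlations,
)
from .synthetic import CohortDataset

logger = logging.getLogger("stimrel")

__all__ = ["ReportBundle", "run_pipeline", "stage_envelopes", "stage_maps", "stage_contrasts"]


def _ephys_envelopes(ds: CohortDataset, config: AnalysisConfig) -> EnvelopeSet:
    """Raw-mode filter chain: notch -> bandpass -> log amplitude ->
    resample to the analysis rate (envelope-mode data pass through)."""
    if all(r.meta.get("band") is not None for r in ds.recordings):
        return ds.to_envelope_set()
    bands = band_table(config.bands)
    envelopes = {}
    for rec in ds.recordings:
        clean = notch_filter(rec, config.notch_freqs)
        if clean.duration_s > config.window_duration_s + 1e-6:
            clean = trim_to_window(clean, config.window_start_s, config.window_duration_s)
        for band in bands:
            env = log_analytic_amplitude(bandpass_filter(clean, band))
            env = resample(env, config.analysis_rate_hz, method="decimate")
            envelopes[(band.name, rec.subject_id, rec.viewing_id)] = env.data
        logger.info("envelope: %s subject=%s viewing=%s", ds.modality, rec.subject_id, rec.viewing_id)
    method = "spearman" if ds.modality == "montage" else "pearson"
    return EnvelopeSet(
        envelopes=envelopes,
        geometry=ds.geometry[ds.modality],
        fs=config.analysis_rate_hz,
        correlation_method=method,
        modality=ds.modality,
    )


def _hemo_envelopes(
    ds: CohortDataset, config: AnalysisConfig, grid_geometry
) -> EnvelopeSet:
    """Hemodynamic chain: interpolate to the analysis rate, remove the
    stimulus lag estimated from the audio envelope over auditory channels,
    and pool voxels onto the source grid."""
    audio = ds.latent.audio_envelope
    geom = ds.geometry[ds.modality]
    envelopes = {}
    mask = None
    lags = []
    for rec in ds.recordings:
        up = resample(rec, config.analysis_rate_hz, method="linear")
        if up.n_samples < len(audio):  # pad the tail sample lost to TR gridding
            pad = len(audio) - up.n_samples
            up = up.copy_with(data=np.pad(up.data, ((0, 0), (0, pad)), mode="edge"))
        elif up.n_samples > len(audio):
            up = up.copy_with(data=up.data[:, : len(audio)])
        lag = estimate_stimulus_lag(
            audio, up, geom, mask_tag="auditory",
            n_nearest=config.n_nearest, max_lag_s=config.max_lag_s,
        )
        lags.append(lag)
        n = int(round(lag * config.analysis_rate_hz))
        data = up.data
        if n > 0:  # signal lags the stimulus: advance it
            data = np.concatenate([data[:, n:], np.repeat(data[:, -1:], n, axis=1)], axis=1)
        elif n < 0:
            data = np.concatenate([np.repeat(data[:, :1], -n, axis=1), data[:, :n]], axis=1)
        shifted = up.copy_with(data=data)
        if grid_geometry is not None and geom.kind == "voxel":
            mapped = map_volume_to_grid(shifted, geom, grid_geometry)
            mask = ~mapped.meta["missing_mask"] if mask is None else mask & ~mapped.meta["missing_mask"]
            out_geom = grid_geometry
            data = mapped.data
        else:
            out_geom = geom
            data = shifted.data
        envelopes[("bold", rec.subject_id, rec.viewing_id)] = data
        logger.info("hemo align: subject=%s viewing=%s lag=%.2fs", rec.subject_id, rec.viewing_id, lag)
    env = EnvelopeSet(
        envelopes=envelopes,
        geometry=out_geom,
        fs=config.analysis_rate_hz,
        correlation_method="pearson",
        modality="hemo",
        channel_mask=mask,
    )
    return env


def stage_envelopes(
    cohorts: dict[str, CohortDataset], config: AnalysisConfig
) -> dict[str, EnvelopeSet]:
    out: dict[str, EnvelopeSet] = {}
    grid_geom = None
    if "ephys" in cohorts:
        grid_geom = cohorts["ephys"].geometry["ephys"]
    for modality, ds in cohorts.items():
        if modality == "hemo":
            out[modality] = _hemo_envelopes(ds, config, grid_geom)
        else:
            out[modality] = _ephys_envelopes(ds, config)
    return out


@dataclass
class ComparisonResult:
    name: str
    band: str
    map: ReliabilityMap
    null: NullDistribution
    geometry: object = None


def stage_maps(
    envsets: dict[str, EnvelopeSet], config: AnalysisConfig
) -> dict[tuple[str, str], ComparisonResult]:
    """Empirical GA + surrogate null + standardized significance map for
    every configured comparison and band."""
    results: dict[tuple[str, str], ComparisonResult] = {}
    for comp in config.comparisons:
        cohort_a = envsets[comp["cohort_a"]]
        cohort_b = envsets.get(comp.get("cohort_b", ""), None)
        bands = config.bands if "bold" not in cohort_a.bands else ["bold"]
        for band in bands:
            if band not in cohort_a.bands:
                continue
            spec = ComparisonSpec(
                level=comp["level"],
                cohort_a=cohort_a,
                cohort_b=cohort_b,
                band=band,
                pairing=comp.get("pairing", config.pairing),
            )
            cs = compute_comparison(spec)
            ga = grand_average(cs)
            single = cs.n_entries == 1
            n_surr = config.n_surr_single_subject if single else config.n_surr
            store = surrogate_correlations(
                spec, n_surr=n_surr, seed=config.seed, max_iter=config.surrogate_max_iter
            )
            null = null_from_surrogates(store) if single else bootstrap_null(
                store, n_boot=config.n_boot, seed=config.seed
            )
            rmap = standardize_and_test(
                ga, null, q=config.q_map,
                sided=comp.get("sided", "one_sided_positive"),
            )
            rmap.meta.update({"comparison": comp["name"], "band": band, "level": comp["level"]})
            results[(comp["name"], band)] = ComparisonResult(
                comp["name"], band, rmap, null, cohort_a.geometry
            )
            logger.info("map: %s band=%s %%MC=%.1f", comp["name"], band, rmap.pct_mc)
    return results


@dataclass
class ContrastResult:
    name: str
    band: str
    result: ClusterResult
    fdr_pass: dict  # tail -> bool


def stage_contrasts(
    maps: dict[tuple[str, str], ComparisonResult],
    config: AnalysisConfig,
    graph: AdjacencyGraph,
) -> list[ContrastResult]:
    out: list[ContrastResult] = []
    for con in config.contrasts:
        bands = sorted({b for (n, b) in maps if n == con["map_a"]})
        for band in bands:
            band_b = band if (con["map_b"], band) in maps else "bold"
            if (con["map_b"], band_b) not in maps:
                continue
            ra = maps[(con["map_a"], band)]
            rb = maps[(con["map_b"], band_b)]
            rb.map.meta = dict(rb.map.meta, band=band)  # contrast on the A-side band
            dz, mask = snr_difference_map(ra.map, rb.map, abs_b=con.get("abs_b", False))
            emp = form_clusters(dz, graph, mask=mask)
            tested = cluster_permutation_test(
                ra.null, rb.null, emp, graph,
                n_maps=config.n_maps, abs_b=con.get("abs_b", False), seed=config.seed,
            )
            ps = [tested.p_values[t] for t in ("positive", "negative") if t in tested.p_values]
            rejected = bh_reject(np.asarray(ps), config.q_cluster)
            fdr = {}
            k = 0
            for t in ("positive", "negative"):
                if t in tested.p_values:
                    fdr[t] = bool(rejected[k])
                    k += 1
            out.append(ContrastResult(con["name"], band, tested, fdr))
            logger.info("contrast: %s band=%s p=%s", con["name"], band, tested.p_values)
    return out


@dataclass
class ReportBundle:
    """Summary tables plus provenance for one full pipeline run."""

    reliability: pd.DataFrame
    clusters: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _reliability_table(maps: dict[tuple[str, str], ComparisonResult]) -> pd.DataFrame:
    rows = []
    for (name, band), res in sorted(maps.items()):
        m = res.map
        geometry = res.geometry
        surv = m.fdr_pass & m.channel_mask
        if surv.any():
            zs = m.z[surv]
            peak_local = int(np.argmax(np.abs(zs)))
            peak = np.nonzero(surv)[0][peak_local]
            coords = geometry.coords[peak]
            rows.append(
                {
                    "comparison": name,
                    "band": band,
                    "Mz": float(np.mean(zs)),
                    "SDz": float(np.std(zs, ddof=0)),
                    "pct_mc": m.pct_mc,
                    "r_max": float(np.max(np.abs(m.r[surv]))),
                    "peak_z": float(m.z[peak]),
                    "peak_x": coords[0], "peak_y": coords[1], "peak_z_mm": coords[2],
                    "peak_region": geometry.region_tags[peak],
                }
            )
        else:
            rows.append(
                {"comparison": name, "band": band, "Mz": np.nan, "SDz": np.nan,
                 "pct_mc": m.pct_mc, "r_max": np.nan, "peak_z": np.nan,
                 "peak_x": np.nan, "peak_y": np.nan, "peak_z_mm": np.nan,
                 "peak_region": ""}
            )
    return pd.DataFrame.from_records(rows)


def _cluster_table(contrasts: list[ContrastResult], geometry) -> pd.DataFrame:
    rows = []
    for cr in contrasts:
        for tail in ("positive", "negative"):
            mc = cr.result.max_cluster(tail)
            if mc is None:
                continue
            dz = cr.result.dz[mc.channels]
            peak = mc.channels[int(np.argmax(np.abs(dz)))]
            rows.append(
                {
                    "contrast": cr.name,
                    "band": cr.band,
                    "tail": tail,
                    "size": mc.size,
                    "sum": mc.total,
                    "peak_dz": float(cr.result.dz[peak]),
                    "peak_x": geometry.coords[peak][0],
                    "peak_y": geometry.coords[peak][1],
                    "peak_z_mm": geometry.coords[peak][2],
                    "p": cr.result.p_values.get(tail, np.nan),
                    "fdr_pass": cr.fdr_pass.get(tail, False),
                }
            )
    return pd.DataFrame.from_records(
        rows,
        columns=["contrast", "band", "tail", "size", "sum", "peak_dz",
                 "peak_x", "peak_y", "peak_z_mm", "p", "fdr_pass"],
    )


def run_pipeline(config: AnalysisConfig, cohorts: dict[str, CohortDataset]) -> ReportBundle:
    """Execute every configured stage in a deterministic order."""
    envsets = stage_envelopes(cohorts, config)
    maps = stage_maps(envsets, config)
    ref = envsets.get("ephys") or next(iter(envsets.values()))
    graph = adjacency_from_coords(ref.geometry)
    contrasts = stage_contrasts(maps, config, graph) if config.contrasts else []
    bundle = ReportBundle(
        reliability=_reliability_table(maps),
        clusters=_cluster_table(contrasts, ref.geometry),
        provenance={"config_hash": config.config_hash(), "seed": config.seed},
    )
    return bundle
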