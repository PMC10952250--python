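"""End-to-end orchestration: masked extraction -> ICA sweep -> selection ->
reconstruction -> PSE products -> summaries, per echo, with a reproducibility
manifest.

Echoes are processed independently throughout: nothing computed for one echo
ever reads the other's data.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import DynamicSeries, GasProtocol, MaskSet, PSEResult
from .ica import (
    OEComponent,
    build_reference,
    extract_masked_matrix,
    reconstruct_oe,
    run_ica_sweep,
    select_oe_component,
)
from .pse import SpectralBands, band_amplitude, pse_map, pse_timeseries, spectrum, summarize_lung

logger = logging.getLogger("oeica")


@dataclass
class EchoResult:
    """Everything the pipeline produces for one echo."""

    component: OEComponent
    reconstruction: DynamicSeries
    pse_map_mri: np.ndarray
    pse_map_ica: np.ndarray
    summary_mri: PSEResult
    summary_ica: PSEResult
    median_pse_ts_mri: np.ndarray
    median_pse_ts_ica: np.ndarray
    n_ica_instances: int


@dataclass
class PipelineResult:
    echoes: list[EchoResult]
    manifest: dict = field(default_factory=dict)


def median_lung_pse_timeseries(
    series: DynamicSeries, lung_mask: np.ndarray, baseline_n: int
) -> np.ndarray:
    """Median PSE over lung voxels at each dynamic; percent, length T."""
    pse, valid = pse_timeseries(series, baseline_n)
    mask = np.asarray(lung_mask, bool) & valid
    vox = pse.transpose(1, 0, 2, 3)[:, mask]  # (T, n_lung_voxels)
    return np.median(vox, axis=1)


def process_echo(
    series: DynamicSeries,
    masks: MaskSet,
    protocol: GasProtocol,
    k_min: int = 22,
    k_max: int = 72,
    seed: int = 0,
    threshold: float = 0.4,
    max_retries: int = 5,
) -> EchoResult:
    """Run the full ICA-based analysis on one echo's dynamic series."""
    t0 = time.time()
    baseline_n = protocol.baseline_n()
    matrix, coords, removed = extract_masked_matrix(series, masks.thoracic)
    logger.info(
        "echo %d: %d thoracic voxels (%d constant removed), T=%d",
        series.echo_index, matrix.shape[0], removed.shape[0], matrix.shape[1],
    )
    reference = build_reference(protocol, series.n_dynamics)
    attempts = {"count": 0}

    def sweep(s: int):
        attempts["count"] += 1
        logger.info("echo %d: ICA sweep K=%d..%d (attempt %d, seed %d)",
                    series.echo_index, k_min, k_max, attempts["count"], s)
        return run_ica_sweep(matrix, k_min, k_max, s)

    runs = sweep(seed)
    component = select_oe_component(
        runs, reference, threshold=threshold, max_retries=max_retries, seed=seed, resweep=sweep
    )
    if component.below_threshold:
        logger.warning(
            "echo %d: best |rho| = %.3f below threshold %.2f after %d retries",
            series.echo_index, component.rho, threshold, component.retries,
        )
    logger.info(
        "echo %d: selected component %d of K=%d run (rho=%.3f, retries=%d)",
        series.echo_index, component.index, component.k, component.rho, component.retries,
    )
    recon = reconstruct_oe(series, coords, component)

    map_mri, _ = pse_map(series, protocol, baseline_n)
    map_ica, _ = pse_map(recon, protocol, baseline_n)
    summary_mri = summarize_lung(map_mri, masks.lung, per_slice=True, source="MRI",
                                 echo_index=series.echo_index)
    summary_ica = summarize_lung(map_ica, masks.lung, per_slice=True, source="ICA",
                                 echo_index=series.echo_index)
    ts_mri = median_lung_pse_timeseries(series, masks.lung, baseline_n)
    ts_ica = median_lung_pse_timeseries(recon, masks.lung, baseline_n)
    logger.info("echo %d: done in %.1f s (%d ICA instances)",
                series.echo_index, time.time() - t0,
                attempts["count"] * (k_max - k_min + 1))
    return EchoResult(
        component=component,
        reconstruction=recon,
        pse_map_mri=map_mri,
        pse_map_ica=map_ica,
        summary_mri=summary_mri,
        summary_ica=summary_ica,
        median_pse_ts_mri=ts_mri,
        median_pse_ts_ica=ts_ica,
        n_ica_instances=attempts["count"] * (k_max - k_min + 1),
    )


def pipeline_run(
    echoes: list[DynamicSeries],
    masks: MaskSet,
    protocol: GasProtocol,
    k_min: int = 22,
    k_max: int = 72,
    seed: int = 0,
    threshold: float = 0.4,
    max_retries: int = 5,
) -> PipelineResult:
    """Process every echo separately and assemble a run manifest."""
    results = [
        process_echo(s, masks, protocol, k_min, k_max, seed, threshold, max_retries)
        for s in echoes
    ]
    manifest = {
        "tool_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {
            "k_min": k_min,
            "k_max": k_max,
            "seed": seed,
            "threshold": threshold,
            "max_retries": max_retries,
            "protocol": {
                "baseline_s": protocol.baseline_s,
                "gas_period_s": protocol.gas_period_s,
                "n_cycles": protocol.n_cycles,
                "dynamic_interval_s": protocol.dynamic_interval_s,
            },
        },
        "echoes": [
            {
                "echo_index": echoes[i].echo_index,
                "selected_k": e.component.k,
                "component_index": e.component.index,
                "rho": e.component.rho,
                "run_seed": e.component.seed,
                "retries": e.component.retries,
                "below_threshold": e.component.below_threshold,
                "n_ica_instances": e.n_ica_instances,
                "median_lung_pse_ica": e.summary_ica.median_lung_pse,
                "median_lung_pse_mri": e.summary_mri.median_lung_pse,
                "iqr_lung_pse_ica": e.summary_ica.iqr_lung_pse,
            }
            for i, e in enumerate(results)
        ],
    }
    return PipelineResult(echoes=results, manifest=manifest)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write NIfTI reconstructions/maps, CSV summaries, and the JSON manifest."""
    from .io import save_json, save_map, save_series

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for e in result.echoes:
        echo = e.summary_ica.echo_index
        save_series(e.reconstruction, out / f"recon_echo{echo + 1}.nii.gz")
        save_map(e.pse_map_mri, out / f"pse_mri_echo{echo + 1}.nii.gz")
        save_map(e.pse_map_ica, out / f"pse_ica_echo{echo + 1}.nii.gz")
        comp = pd.DataFrame(
            {
                "dynamic": np.arange(e.component.time_course.size),
                "time_course": e.component.time_course,
                "rho": e.component.rho,
                "k": e.component.k,
                "seed": e.component.seed,
                "retries": e.component.retries,
            }
        )
        comp.to_csv(out / f"oe_component_echo{echo + 1}.csv", index=False)
        dt = e.reconstruction.dynamic_interval_s
        spec_rows = []
        for src, ts in (("MRI", e.median_pse_ts_mri), ("ICA", e.median_pse_ts_ica)):
            freqs, amps = spectrum(ts, dt)
            spec_rows.append(pd.DataFrame(
                {"source": src, "echo": echo + 1, "freq_hz": freqs, "amplitude": amps}
            ))
        pd.concat(spec_rows).to_csv(out / f"spectra_echo{echo + 1}.csv", index=False)
        for summ in (e.summary_mri, e.summary_ica):
            rows.append(
                {
                    "source": summ.source,
                    "echo": echo + 1,
                    "slice": "all",
                    "median_pse": summ.median_lung_pse,
                    "iqr_pse": summ.iqr_lung_pse,
                }
            )
            for si, m in enumerate(summ.per_slice_median):
                rows.append(
                    {
                        "source": summ.source,
                        "echo": echo + 1,
                        "slice": si + 1,
                        "median_pse": m,
                        "iqr_pse": np.nan,
                    }
                )
    pd.DataFrame(rows).to_csv(out / "summaries.csv", index=False)
    save_json(result.manifest, out / "manifest.json")


def spectral_ratios(
    median_pse_ts: np.ndarray,
    dynamic_interval_s: float,
    bands: SpectralBands = SpectralBands(),
) -> dict:
    """Respiratory- and cardiac-band amplitudes relative to the gas peak."""
    freqs, amps = spectrum(median_pse_ts, dynamic_interval_s)
    gas = band_amplitude(freqs, amps, bands.gas)
    resp = band_amplitude(freqs, amps, bands.respiratory)
    card = band_amplitude(freqs, amps, bands.cardiac)
    return {
        "gas_peak": gas,
        "respiratory_over_gas": resp / gas if gas > 0 else np.inf,
        "cardiac_over_gas": card / gas if gas > 0 else np.inf,
    }


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
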