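"""File formats of the pipeline.

Traces travel either as one NPZ per embryo (arrays ``values``
(n_clips, n_frames), ``clip_times``, scalar ``fps``) or as a long CSV
(embryo_id, clip_time_h, frame_index, mean_brightness); frame stacks as
one multi-page TIFF per clip under ``clips/<embryo_id>/t<HHHH>.tif``.
Spectra and statistics are long/tidy CSVs. Every run writes a JSON
manifest echoing the configuration, the master seed and a config hash.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .containers import BrightnessTrace, ClipStack
from .spectral import BAND_WIDTH_HZ, N_BANDS, EPTSpectrum
from .synthetic import SyntheticEmbryo, events_table, metadata_table
from .timeline import EmbryoRecord

logger = logging.getLogger(__name__)

__all__ = [
    "write_cohorts",
    "read_traces",
    "read_metadata",
    "read_events",
    "write_spectra",
    "read_spectra_records",
    "write_analysis",
    "write_manifest",
]


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_manifest(path: Path, config, seed) -> None:
    """Echo the full configuration, seed, version and config hash to JSON."""
    payload = _jsonable(config)
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
    manifest = {
        "eptools_version": __version__,
        "seed": seed,
        "config": payload,
        "config_sha256": digest,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def write_cohorts(
    cohorts: list[list[SyntheticEmbryo]],
    outdir: Path,
    trace_format: str = "npz",
) -> None:
    """Write cohorts to disk: traces (NPZ or CSV) or TIFF clips + tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_embryos = [emb for cohort in cohorts for emb in cohort]
    metadata = pd.concat([metadata_table(c) for c in cohorts], ignore_index=True)
    events = pd.concat([events_table(c) for c in cohorts], ignore_index=True)
    metadata.to_csv(outdir / "metadata.csv", index=False)
    events.to_csv(outdir / "events.csv", index=False)

    csv_rows = []
    for emb in all_embryos:
        if emb.clips is not None:
            clip_dir = outdir / "clips" / emb.embryo_id
            clip_dir.mkdir(parents=True, exist_ok=True)
            for clip in emb.clips:
                tifffile.imwrite(clip_dir / f"t{int(round(clip.clip_time)):04d}.tif", clip.frames)
            continue
        if trace_format == "npz":
            trace_dir = outdir / "traces"
            trace_dir.mkdir(exist_ok=True)
            np.savez(
                trace_dir / f"{emb.embryo_id}.npz",
                values=np.stack([t.values for t in emb.traces]),
                clip_times=np.array([t.clip_time for t in emb.traces]),
                fps=np.array(emb.acquisition.fps),
            )
        elif trace_format == "csv":
            for t in emb.traces:
                csv_rows.append(
                    pd.DataFrame(
                        {
                            "embryo_id": emb.embryo_id,
                            "clip_time_h": t.clip_time,
                            "frame_index": np.arange(t.n_frames),
                            "mean_brightness": t.values,
                        }
                    )
                )
        else:
            raise ValueError(f"unknown trace format {trace_format!r}")
    if csv_rows:
        pd.concat(csv_rows, ignore_index=True).to_csv(outdir / "traces.csv", index=False)


def read_metadata(datadir: Path) -> pd.DataFrame:
    path = Path(datadir) / "metadata.csv"
    if not path.exists():
        raise FileNotFoundError(f"no metadata.csv in {datadir}")
    return pd.read_csv(path)


def read_events(datadir: Path) -> pd.DataFrame:
    """Events as a wide table (index embryo_id, one column per event)."""
    path = Path(datadir) / "events.csv"
    if not path.exists():
        raise FileNotFoundError(f"no events.csv in {datadir}")
    long = pd.read_csv(path)
    return long.pivot(index="embryo_id", columns="event", values="time_h")


def read_traces(
    datadir: Path, metadata: pd.DataFrame, box_log: list | None = None
) -> dict[str, list[BrightnessTrace]]:
    """Load per-embryo traces from NPZ files, a traces.csv or TIFF clips.

    When reading TIFF clips, the detected bounding box of every clip is
    appended to ``box_log`` (if given) for audit.
    """
    from .segmentation import detect_bbox, extract_trace

    datadir = Path(datadir)
    out: dict[str, list[BrightnessTrace]] = {}
    meta = metadata.set_index("embryo_id")
    npz_dir, csv_path, clip_root = datadir / "traces", datadir / "traces.csv", datadir / "clips"
    if npz_dir.is_dir() and any(npz_dir.glob("*.npz")):
        for embryo_id in meta.index:
            path = npz_dir / f"{embryo_id}.npz"
            if not path.exists():
                raise FileNotFoundError(f"metadata lists {embryo_id} but {path} is missing")
            with np.load(path) as data:
                fps = float(data["fps"])
                out[embryo_id] = [
                    BrightnessTrace(v, fps=fps, clip_time=float(ct), embryo_id=embryo_id)
                    for v, ct in zip(data["values"], data["clip_times"])
                ]
    elif csv_path.exists():
        long = pd.read_csv(csv_path)
        for embryo_id, per_emb in long.groupby("embryo_id"):
            fps = float(meta.loc[embryo_id, "fps"])
            out[embryo_id] = [
                BrightnessTrace(
                    grp.sort_values("frame_index")["mean_brightness"].to_numpy(),
                    fps=fps,
                    clip_time=float(ct),
                    embryo_id=str(embryo_id),
                )
                for ct, grp in per_emb.groupby("clip_time_h")
            ]
    elif clip_root.is_dir():
        for embryo_id in meta.index:
            emb_dir = clip_root / str(embryo_id)
            if not emb_dir.is_dir():
                raise FileNotFoundError(f"metadata lists {embryo_id} but {emb_dir} is missing")
            fps = float(meta.loc[embryo_id, "fps"])
            traces = []
            for tif in sorted(emb_dir.glob("t*.tif")):
                clip_time = float(int(tif.stem[1:]))
                stack = ClipStack(
                    tifffile.imread(tif), fps=fps, clip_time=clip_time, embryo_id=str(embryo_id)
                )
                box = detect_bbox(stack)
                if box_log is not None:
                    box_log.append(
                        {
                            "embryo_id": str(embryo_id),
                            "clip_time_h": clip_time,
                            "row_min": box.row_min,
                            "col_min": box.col_min,
                            "row_max": box.row_max,
                            "col_max": box.col_max,
                        }
                    )
                traces.append(extract_trace(stack, box))
            out[embryo_id] = traces
    else:
        raise FileNotFoundError(f"no traces or clips found under {datadir}")
    missing = set(meta.index) - set(out)
    if missing:
        raise FileNotFoundError(f"metadata rows without data: {sorted(missing)}")
    return out


def write_spectra(records: list[EmbryoRecord], outdir: Path) -> None:
    """Write spectra.csv (long, one row per band) and total_energy.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    band_low = np.round(np.arange(N_BANDS) * BAND_WIDTH_HZ, 1)
    spectra_rows, total_rows = [], []
    for rec in records:
        for spec in rec.spectra:
            spectra_rows.append(
                pd.DataFrame(
                    {
                        "embryo_id": rec.embryo_id,
                        "clip_time_h": spec.clip_time,
                        "rel_time": spec.rel_time,
                        "band_low_hz": band_low,
                        "energy": spec.band_energy,
                    }
                )
            )
            total_rows.append(
                (rec.embryo_id, spec.clip_time, spec.rel_time, spec.total_energy)
            )
    pd.concat(spectra_rows, ignore_index=True).to_csv(outdir / "spectra.csv", index=False)
    pd.DataFrame(
        total_rows, columns=["embryo_id", "clip_time_h", "rel_time", "total_energy"]
    ).to_csv(outdir / "total_energy.csv", index=False)


def read_spectra_records(
    datadir: Path, metadata: pd.DataFrame, events_wide: pd.DataFrame
) -> list[EmbryoRecord]:
    """Rebuild EmbryoRecords from spectra.csv + events + metadata."""
    path = Path(datadir) / "spectra.csv"
    if not path.exists():
        raise FileNotFoundError(f"no spectra.csv in {datadir}")
    long = pd.read_csv(path)
    meta = metadata.set_index("embryo_id")
    records = []
    for embryo_id, per_emb in long.groupby("embryo_id", sort=False):
        spectra = [
            EPTSpectrum(
                grp.sort_values("band_low_hz")["energy"].to_numpy(),
                embryo_id=str(embryo_id),
                clip_time=float(ct),
            )
            for ct, grp in per_emb.groupby("clip_time_h")
        ]
        events = events_wide.loc[embryo_id].dropna().to_dict()
        records.append(
            EmbryoRecord(
                embryo_id=str(embryo_id),
                species=str(meta.loc[embryo_id, "species_preset"]),
                temperature_label=str(meta.loc[embryo_id, "temperature_label"]),
                spectra=spectra,
                events=events,
            )
        )
    return records


def write_analysis(result, outdir: Path) -> None:
    """Write the statistics and ordination tables of one analysis run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj = result.trajectory
    pd.DataFrame(
        [
            {
                "F": traj.F,
                "df_num": traj.df_num,
                "df_den": traj.df_den,
                "p": traj.p,
                "n_grid_points": traj.n_points,
            }
        ]
    ).to_csv(outdir / "trajectory_test.csv", index=False)
    pd.DataFrame(
        [
            {
                "rel_start": r.rel_start,
                "rel_end": r.rel_end,
                "direction": r.direction,
                "min_p": r.min_p,
            }
            for r in traj.regions
        ],
        columns=["rel_start", "rel_end", "direction", "min_p"],
    ).to_csv(outdir / "posthoc_regions.csv", index=False)

    band_low = np.round(np.arange(N_BANDS) * BAND_WIDTH_HZ, 1)
    band_rows = []
    for window, bt in result.bandwise.items():
        for k in range(N_BANDS):
            band_rows.append(
                {
                    "window": window,
                    "band_low_hz": band_low[k],
                    "H": bt.H[k],
                    "p": bt.p[k],
                    "significant": k in bt.significant_bands,
                    "direction": bt.directions[k],
                }
            )
    pd.DataFrame(band_rows).to_csv(outdir / "bandwise.csv", index=False)

    pd.DataFrame(
        [
            {"event": event, "H": t.H, "p": t.p, "direction": t.direction}
            for event, t in result.event_test.tests.items()
        ],
        columns=["event", "H", "p", "direction"],
    ).to_csv(outdir / "event_tests.csv", index=False)

    k = result.pca.scores.shape[1]
    pc_cols = [f"PC{j + 1}" for j in range(k)]
    scores = pd.concat(
        [result.pca_rows.reset_index(drop=True), pd.DataFrame(result.pca.scores, columns=pc_cols)],
        axis=1,
    )
    scores.to_csv(outdir / "pca_scores.csv", index=False)
    loadings = pd.DataFrame(result.pca.loadings, columns=pc_cols)
    loadings.insert(0, "band_low_hz", band_low)
    loadings.to_csv(outdir / "pca_loadings.csv", index=False)
    pd.DataFrame(
        {
            "component": pc_cols,
            "variance_explained_pct": result.pca.variance_explained,
            "cumulative_pct": result.pca.cumulative_variance,
        }
    ).to_csv(outdir / "pca_variance.csv", index=False)
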