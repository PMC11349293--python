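"""CSV/JSON readers and writers for the pipeline's file interfaces.

All data tables are plain CSV with fixed column order; manifests and
ground truth are JSON.  Spike data travel as a spike-times table
(segment_id, patient_id, disease, spike_time_s) plus a segment metadata
table (segment_id, duration_s).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from pallidyn.features import SpikeSegment
from pallidyn.plasticity import FEPSession, N_LFS, N_TRAINS, PULSES_PER_TRAIN

SPIKE_COLUMNS = ["segment_id", "patient_id", "disease", "spike_time_s"]
SEGMENT_META_COLUMNS = ["segment_id", "duration_s"]


def write_spike_tables(segments: Iterable[SpikeSegment], outdir: Path,
                       prefix: str = "") -> tuple[Path, Path]:
    """Write spike times + segment metadata CSVs; returns both paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, meta = [], []
    for seg in segments:
        meta.append({"segment_id": seg.segment_id, "duration_s": seg.duration_s,
                     "patient_id": seg.patient_id, "disease": seg.disease})
        for t in seg.spike_times:
            rows.append({"segment_id": seg.segment_id,
                         "patient_id": seg.patient_id,
                         "disease": seg.disease, "spike_time_s": t})
    spikes_path = outdir / f"{prefix}spike_times.csv"
    meta_path = outdir / f"{prefix}segments.csv"
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(spikes_path, index=False)
    pd.DataFrame(meta).to_csv(meta_path, index=False)
    return spikes_path, meta_path


def read_spike_tables(spikes_path: Path, meta_path: Path) -> list[SpikeSegment]:
    """Read segments back from the spike-times + metadata CSV pair."""
    spikes = pd.read_csv(spikes_path)
    meta = pd.read_csv(meta_path)
    segments = []
    grouped = dict(iter(spikes.groupby("segment_id")))
    for _, m in meta.iterrows():
        g = grouped.get(m["segment_id"])
        times = np.sort(g["spike_time_s"].to_numpy()) if g is not None else []
        pid = g["patient_id"].iloc[0] if g is not None else m.get("patient_id", "")
        disease = g["disease"].iloc[0] if g is not None else m.get("disease", "")
        segments.append(SpikeSegment(
            times, float(m["duration_s"]), patient_id=str(pid),
            disease=str(disease), segment_id=str(m["segment_id"])))
    return segments


def write_fep_sessions(sessions: Iterable[FEPSession], path: Path) -> Path:
    """Write fEP sessions as a long CSV (one row per pulse) + baselines."""
    path = Path(path)
    rows = []
    for s in sessions:
        epochs = ([("pre", s.pre_lfs_amps)]
                  + [(f"hfs{i+1}", s.hfs_trains[i]) for i in range(N_TRAINS)]
                  + [("post", s.post_lfs_amps)])
        for epoch, amps in epochs:
            for j, a in enumerate(amps, start=1):
                rows.append({"site_id": s.site_id, "patient_id": s.patient_id,
                             "disease": s.disease, "epoch": epoch,
                             "pulse_index": j, "amplitude": a,
                             "baseline_rms": s.baseline_rms,
                             "normalized": s.normalized})
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_fep_sessions(path: Path) -> list[FEPSession]:
    """Read fEP sessions from the long CSV produced by write_fep_sessions."""
    df = pd.read_csv(path)
    sessions = []
    for site, g in df.groupby("site_id", sort=True):
        def amps(epoch, n):
            sub = g[g["epoch"] == epoch].sort_values("pulse_index")
            if len(sub) != n:
                raise ValueError(f"site {site}: epoch {epoch} has {len(sub)} "
                                 f"pulses, expected {n}")
            return sub["amplitude"].to_numpy()
        trains = np.stack([amps(f"hfs{i+1}", PULSES_PER_TRAIN)
                           for i in range(N_TRAINS)])
        sessions.append(FEPSession(
            patient_id=str(g["patient_id"].iloc[0]),
            disease=str(g["disease"].iloc[0]),
            site_id=str(site),
            pre_lfs_amps=amps("pre", N_LFS),
            post_lfs_amps=amps("post", N_LFS),
            hfs_trains=trains,
            baseline_rms=float(g["baseline_rms"].iloc[0]),
            normalized=bool(g["normalized"].iloc[0]),
        ))
    return sessions


def write_json(obj, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.random.SeedSequence):
            return {"entropy": o.entropy, "spawn_key": list(o.spawn_key)}
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
    return path


def load_osf_dataset(path: Path):  # pragma: no cover - adapter stub
    """Adapter stub for the public intraoperative dataset deposit.

    Ingestion of the original recordings is out of scope for this
    package; this hook documents where a reader would plug in.
    """
    raise NotImplementedError(
        "Reading the archived intraoperative dataset is not implemented; "
        "convert it to the spike-times/segments CSV schema and use "
        "read_spike_tables instead.")
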