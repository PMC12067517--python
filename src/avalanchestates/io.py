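"""Readers and writers for the pipeline's interchange formats.

TSV is the core interchange format (no binary dependency): signals as a
region x sample table, avalanche patterns as one row per avalanche with
subject/start/end columns, intervals as BED-like 3-column TSV, labels,
topographies and transition matrices as labelled tables. An optional HDF5
container holds a cohort's signals plus ground truth in one file. Every
writer's output is re-readable by the matching reader (closed round trip).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AvalancheInterval, PatternSequence, SignalSet

__all__ = [
    "read_signals",
    "write_signals",
    "read_patterns",
    "write_patterns",
    "write_intervals",
    "read_labels",
    "write_labels",
    "write_topography",
    "write_transition_matrix",
    "write_signals_hdf5",
    "read_signals_hdf5",
    "PipelineConfig",
    "RunManifest",
]

ANALYSIS_DEFAULTS = {
    "threshold": 3.0,
    "binarize_mode": "absolute",
    "n_pca": 5,
    "knn": 5,
    "alpha": 1.0,
    "n_dims": 3,
    "k": 7,
    "n_perm": 10000,
}


def write_signals(sig: SignalSet, path) -> Path:
    """Region x time TSV: header row of sample indices, first column region
    label; sampling rate and subject id in ``#``-prefixed header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate={sig.sampling_rate}\n")
        fh.write(f"# subject_id={sig.subject_id}\n")
        fh.write("region\t" + "\t".join(map(str, range(sig.n_samples))) + "\n")
        for label, row in zip(sig.region_labels, sig.values):
            fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    return path


def read_signals(path) -> SignalSet:
    """Read a signals TSV written by :func:`write_signals`.

    Malformed headers, non-numeric cells and duplicate region labels raise
    with line-numbered messages.
    """
    path = Path(path)
    meta = {"sampling_rate": None, "subject_id": path.stem}
    labels: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lineno = 0
        header_seen = False
        n_cols = None
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts[0] != "region":
                    raise ValueError(
                        f"{path}:{lineno}: malformed header (expected 'region\\t0\\t1...')"
                    )
                n_cols = len(parts) - 1
                header_seen = True
                continue
            if len(parts) - 1 != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} samples, got {len(parts) - 1}"
                )
            label = parts[0]
            if label in labels:
                raise ValueError(f"{path}:{lineno}: duplicate region label '{label}'")
            try:
                rows.append(np.array([float(v) for v in parts[1:]]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            labels.append(label)
    if not header_seen or not rows:
        raise ValueError(f"{path}: no signal rows found")
    if meta["sampling_rate"] is None:
        raise ValueError(f"{path}: missing '# sampling_rate=' header")
    return SignalSet(
        values=np.vstack(rows),
        region_labels=labels,
        sampling_rate=float(meta["sampling_rate"]),
        subject_id=str(meta["subject_id"]),
    )


def write_patterns(seq: PatternSequence, path) -> Path:
    """Patterns TSV: one row per avalanche with subject_id, start, end and
    one 0/1 column per region."""
    path = Path(path)
    regions = seq.region_labels or [f"R{i:03d}" for i in range(seq.n_regions)]
    df = pd.DataFrame(seq.patterns, columns=regions)
    df.insert(0, "end", [iv.end for iv in seq.intervals])
    df.insert(0, "start", [iv.start for iv in seq.intervals])
    df.insert(0, "subject_id", seq.subject_ids)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_patterns(path) -> PatternSequence:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = ["subject_id", "start", "end"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: expected leading columns {required}")
    regions = list(df.columns[3:])
    intervals = [
        AvalancheInterval(int(s), int(e), str(sid))
        for sid, s, e in zip(df["subject_id"], df["start"], df["end"])
    ]
    return PatternSequence(
        patterns=df[regions].to_numpy(dtype=np.uint8),
        intervals=intervals,
        subject_ids=[str(s) for s in df["subject_id"]],
        region_labels=regions,
    )


def write_intervals(intervals: list[AvalancheInterval], path) -> Path:
    """BED-like 3-column TSV: subject, start, end (half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.subject_id}\t{iv.start}\t{iv.end}\n")
    return path


def write_labels(labels: np.ndarray, path) -> Path:
    pd.DataFrame(
        {"pattern_index": np.arange(len(labels)), "label": np.asarray(labels, int)}
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_labels(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["pattern_index", "label"]:
        raise ValueError(f"{path}: expected columns pattern_index, label")
    if not (df["pattern_index"].to_numpy() == np.arange(len(df))).all():
        raise ValueError(f"{path}: pattern_index column is not 0..P-1 (tampered file?)")
    return df["label"].to_numpy(dtype=int)


def write_topography(topo, path, what: str = "fractions") -> Path:
    values = getattr(topo, what)
    regions = topo.region_labels or [f"R{i:03d}" for i in range(topo.n_regions)]
    df = pd.DataFrame(values, columns=regions)
    df.insert(0, "state", [f"state_{i}" for i in range(topo.n_states)])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_transition_matrix(tm, path) -> Path:
    k = tm.k
    names = [f"state_{i}" for i in range(k)]
    df = pd.DataFrame(tm.probs, columns=names)
    df.insert(0, "from", names)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_signals_hdf5(signals: list[SignalSet], path, ground_truth=None) -> Path:
    """Single-file HDF5 container for a cohort (optionally with ground truth
    as a JSON attribute)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as h5:
        for sig in signals:
            grp = h5.create_group(f"signals/{sig.subject_id}")
            grp.create_dataset("values", data=sig.values, compression="gzip")
            grp.attrs["sampling_rate"] = sig.sampling_rate
            grp.attrs["region_labels"] = json.dumps(sig.region_labels)
        if ground_truth is not None:
            h5.attrs["ground_truth"] = ground_truth.to_json()
    return path


def read_signals_hdf5(path) -> tuple[list[SignalSet], "object | None"]:
    import h5py

    from .synthetic import GroundTruth

    signals = []
    with h5py.File(path, "r") as h5:
        for sid in sorted(h5["signals"]):
            grp = h5[f"signals/{sid}"]
            signals.append(
                SignalSet(
                    values=grp["values"][()],
                    region_labels=json.loads(grp.attrs["region_labels"]),
                    sampling_rate=float(grp.attrs["sampling_rate"]),
                    subject_id=sid,
                )
            )
        truth = (
            GroundTruth.from_json(h5.attrs["ground_truth"])
            if "ground_truth" in h5.attrs
            else None
        )
    return signals, truth


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults are the analysis defaults."""

    threshold: float = 3.0
    binarize_mode: str = "absolute"
    n_pca: int = 5
    knn: int = 5
    alpha: float = 1.0
    n_dims: int = 3
    t: int | str = "auto"
    k: int = 7
    kmeans_n_init: int = 50
    n_perm: int = 10000
    n_perm_region_null: int = 999
    boundary_policy: str = "exclude"
    seed: int = 0

    def __post_init__(self):
        if self.binarize_mode not in ("absolute", "positive"):
            raise ValueError("binarize_mode must be 'absolute' or 'positive'")
        if self.boundary_policy not in ("exclude", "include"):
            raise ValueError("boundary_policy must be 'exclude' or 'include'")
        if self.threshold <= 0 or self.k < 1 or self.n_perm < 1:
            raise ValueError("invalid pipeline configuration")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def embedding_params(self):
        from .embedding import EmbeddingParams

        return EmbeddingParams(
            n_pca=self.n_pca,
            knn=self.knn,
            alpha=self.alpha,
            n_dims=self.n_dims,
            t=self.t,
            mds_seed=self.seed,
        )


@dataclass
class RunManifest:
    """Provenance record emitted for every pipeline run."""

    config_hash: str
    package_version: str
    seed: int
    stage_counts: dict
    created: str

    @classmethod
    def create(cls, config: PipelineConfig, stage_counts: dict) -> "RunManifest":
        import datetime

        from . import __version__

        return cls(
            config_hash=hashlib.sha256(config.to_json().encode()).hexdigest()[:16],
            package_version=__version__,
            seed=config.seed,
            stage_counts=dict(stage_counts),
            created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)
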