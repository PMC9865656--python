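"""Session containers, checkpoints, run configuration and reporting statistics.

Sessions are HDF5 files with datasets ``/radar/frames``, ``/belt/force`` and
(when synthetic) ``/truth/displacement``, ``/truth/motion_mask``, plus the
attributes ``user_id``, ``distance_class``, ``frame_rate``, ``fc_true`` and
``schema_version``.  Dataset manifests are CSV.  Reporting utilities compute
the box-plot statistics used to monitor episodic learning, density histograms
of the loss, and the loss-versus-respiration-rate binning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from radarbreath.synthetic_scene import SessionRecord

SCHEMA_VERSION = 1

DEFAULT_RR_BIN_EDGES: Tuple[Tuple[int, int], ...] = ((1, 4), (5, 6), (7, 9), (10, 11), (12, 14))
"""Peak-count-per-session bins; non-uniform so sparse edge rates keep >=4 examples."""


class SchemaError(ValueError):
    """A session container is missing a dataset or has an unsupported version."""


# ---------------------------------------------------------------------------
# session containers


def write_session(path: str | Path, record: SessionRecord) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("radar/frames", data=record.frames)
        f.create_dataset("belt/force", data=record.belt)
        if record.displacement is not None:
            f.create_dataset("truth/displacement", data=record.displacement)
        if record.motion_mask is not None:
            f.create_dataset("truth/motion_mask", data=record.motion_mask)
        f.attrs["user_id"] = record.user_id
        f.attrs["distance_class"] = record.distance_class
        f.attrs["frame_rate"] = record.frame_rate
        if record.fc_true is not None:
            f.attrs["fc_true"] = record.fc_true
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_session(path: str | Path) -> SessionRecord:
    import h5py

    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(f"{path}: unsupported schema_version {version}")
        for ds in ("radar/frames", "belt/force"):
            if ds not in f:
                raise SchemaError(f"{path}: missing dataset /{ds}")
        return SessionRecord(
            frames=f["radar/frames"][...],
            belt=f["belt/force"][...],
            user_id=str(f.attrs["user_id"]),
            distance_class=int(f.attrs["distance_class"]),
            frame_rate=float(f.attrs["frame_rate"]),
            displacement=f["truth/displacement"][...] if "truth/displacement" in f else None,
            motion_mask=f["truth/motion_mask"][...] if "truth/motion_mask" in f else None,
            fc_true=float(f.attrs["fc_true"]) if "fc_true" in f.attrs else None,
        )


def read_manifest(path: str | Path):
    import pandas as pd

    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str | Path, theta: np.ndarray, arch) -> None:
    """Flat parameter vector plus a JSON architecture header."""
    from dataclasses import asdict

    header = json.dumps({k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in asdict(arch).items()})
    np.savez(path, theta=theta, arch_json=np.array(header))


def load_checkpoint(path: str | Path):
    from radarbreath.cvae import CvaeArchitecture

    with np.load(path, allow_pickle=False) as f:
        theta = f["theta"]
        spec = json.loads(str(f["arch_json"]))
    spec["enc_filters"] = tuple(spec["enc_filters"])
    return theta, CvaeArchitecture(**spec)


# ---------------------------------------------------------------------------
# run configuration


def load_run_config(path: str | Path) -> Dict:
    """YAML run config with sections radar/scene/preprocess/filter/metrics/model/meta."""
    import yaml

    with open(path) as f:
        return yaml.safe_load(f) or {}


def radar_config_from_dict(d: Dict):
    from radarbreath.radar_model import RadarConfig

    return RadarConfig(**d)


# ---------------------------------------------------------------------------
# reporting statistics


@dataclass
class EvalRecord:
    """Box-plot summary of one evaluation block of episodic losses."""

    episode_index: int
    split: str                  # "train_task" | "test_task"
    losses: np.ndarray
    median: float = field(init=False)
    q1: float = field(init=False)
    q3: float = field(init=False)
    whisker_lo: float = field(init=False)
    whisker_hi: float = field(init=False)
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        stats = boxplot_stats(self.losses)
        for k, v in stats.items():
            setattr(self, k, v)


def boxplot_stats(values: Sequence[float]) -> Dict[str, float]:
    """Median, quartiles (linear interpolation), 1.5*IQR whiskers clipped to
    the most extreme data inside the fences, and the mean."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "mean": float(v.mean()),
    }


def loss_histogram(values: Sequence[float], n_bins: int = 20):
    """Density histogram plus the Gaussian-overlay parameters (mean, std).

    The loss distribution along episodic learning is generally *not* Gaussian
    (multimodal early, positively skewed late); the overlay parameters are
    reported so the mismatch can be shown.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(v) == 0:
        edges = np.linspace(v[0] - 0.5, v[0] + 0.5, n_bins + 1)
        density, edges = np.histogram(v, bins=edges, density=True)
    else:
        density, edges = np.histogram(v, bins=n_bins, density=True)
    return {"density": density, "bin_edges": edges,
            "gauss_mean": float(v.mean()), "gauss_std": float(v.std())}


@dataclass
class RrBinReport:
    """Loss statistics binned by per-session breathing-peak count."""

    bin_edges: Tuple[Tuple[int, int], ...]
    stats: List[Dict[str, float]]       # boxplot_stats per bin (None-> empty dict)
    n_per_bin: List[int]
    overflow: List[Tuple[int, float]]   # (peak_count, loss) outside all bins


def rr_binned_losses(
    per_session: Sequence[Tuple[int, float]],
    edges: Tuple[Tuple[int, int], ...] = DEFAULT_RR_BIN_EDGES,
) -> RrBinReport:
    """Assign (peak_count, loss) pairs to respiration-rate bins and summarize."""
    if len(per_session) == 0:
        raise ValueError("no sessions")
    binned: List[List[float]] = [[] for _ in edges]
    overflow: List[Tuple[int, float]] = []
    for count, loss in per_session:
        for i, (lo, hi) in enumerate(edges):
            if lo <= count <= hi:
                binned[i].append(loss)
                break
        else:
            overflow.append((int(count), float(loss)))
    stats = [boxplot_stats(b) if b else {} for b in binned]
    return RrBinReport(
        bin_edges=tuple(edges),
        stats=stats,
        n_per_bin=[len(b) for b in binned],
        overflow=overflow,
    )
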