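"""Readers/writers for signal files and refined-dataset directories.

Signal files are plain text, one numeric value per line (a single header
line is tolerated and skipped), matching common single-column sensor exports.
A refined dataset is written as one file per subsequence plus a copy of the
source signal and a JSON manifest recording subcluster centers, time shifts,
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dynamics import SignalSeries
from .errors import SignalParseError
from .refine import RefineConfig, RefinedSet

TOOL_VERSION = "0.1.0"
#: text precision for sample values; 17 significant digits round-trips
#: IEEE doubles exactly
FLOAT_FMT = "%.17g"


@dataclass
class DatasetManifest:
    """Inventory of a written refined-dataset directory."""

    entries: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    subcluster_centers: list[list[float]] = field(default_factory=list)
    coverage_met: bool = True
    seed: int = 0
    version: str = TOOL_VERSION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetManifest":
        return cls(**{k: d[k] for k in
                      ("entries", "config", "subcluster_centers",
                       "coverage_met", "seed", "version") if k in d})

    def validate(self, directory: str | Path) -> None:
        """Check every listed file exists and has the recorded sample count."""
        directory = Path(directory)
        for e in self.entries:
            path = directory / e["path"]
            if not path.exists():
                raise FileNotFoundError(f"manifest entry missing on disk: {path}")
            n_lines = sum(1 for line in path.open() if line.strip())
            if n_lines != e["n_samples"]:
                raise ValueError(
                    f"{path}: {n_lines} samples on disk, manifest says {e['n_samples']}")


def read_signal(path: str | Path, dt: float = 1.0, label: str = "unknown",
                name: str | None = None) -> SignalSeries:
    """Read a one-value-per-line signal file.

    A single non-numeric first line is treated as a header and skipped; any
    other non-numeric line raises :class:`SignalParseError` with its line
    number.  Blank lines are ignored.
    """
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                if lineno == 1 and not values:
                    continue  # header
                raise SignalParseError(f"non-numeric value {text!r}", line=lineno) from None
    if not values:
        raise SignalParseError(f"no numeric samples found in {path}")
    return SignalSeries(samples=np.asarray(values), dt=dt,
                        name=name or path.stem, label=label,
                        source={"path": str(path)})


def write_signal(samples: np.ndarray, path: str | Path) -> None:
    """Write samples one per line at full double precision."""
    np.savetxt(path, np.asarray(samples, dtype=float), fmt=FLOAT_FMT)


def write_portrait(portrait, path: str | Path) -> None:
    """Export a phase portrait for inspection: time index + one row per
    reconstructed state vector, tab-delimited."""
    data = np.column_stack([portrait.time_index, portrait.vectors])
    header = "time_index\t" + "\t".join(f"x{j + 1}" for j in range(portrait.order))
    np.savetxt(path, data, fmt=FLOAT_FMT, delimiter="\t",
               header=header, comments="")


def write_cluster_centers(model, path: str | Path) -> None:
    """Export FCM cluster centers, one center per row, tab-delimited."""
    header = "\t".join(f"x{j + 1}" for j in range(model.centers.shape[1]))
    np.savetxt(path, model.centers, fmt=FLOAT_FMT, delimiter="\t",
               header=header, comments="")


def write_refined_set(refined: RefinedSet, out_dir: str | Path) -> DatasetManifest:
    """Write a refined dataset directory: subsequence files, source copy,
    manifest.  File naming is deterministic (subcluster id + time shift), so
    re-running with identical inputs overwrites byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = DatasetManifest(
        config=_config_to_dict(refined.config),
        subcluster_centers=[[float(v) for v in row] for row in refined.subcluster_centers],
        coverage_met=bool(refined.coverage_met),
        seed=int(refined.config.seed),
    )

    source_file = f"source_{refined.source.name}.txt"
    write_signal(refined.source.samples, out_dir / source_file)
    manifest.entries.append({
        "path": source_file, "role": "source", "label": refined.source.label,
        "subcluster_id": None, "time_shift": None,
        "n_samples": int(len(refined.source)),
    })
    for sub in sorted(refined.subsequences, key=lambda s: (s.subcluster_id, s.time_shift)):
        fname = f"refined_w{sub.subcluster_id:02d}_t{sub.time_shift:05d}.txt"
        write_signal(sub.samples, out_dir / fname)
        manifest.entries.append({
            "path": fname, "role": "refined", "label": refined.source.label,
            "subcluster_id": int(sub.subcluster_id),
            "time_shift": int(sub.time_shift),
            "n_samples": int(sub.samples.size),
        })

    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def read_manifest(out_dir: str | Path) -> DatasetManifest:
    with (Path(out_dir) / "manifest.json").open() as fh:
        return DatasetManifest.from_dict(json.load(fh))


def _config_to_dict(config: RefineConfig) -> dict:
    return dataclasses.asdict(config)


def load_refine_config(path: str | Path) -> RefineConfig:
    """Load a RefineConfig from a YAML key-value file (unknown keys rejected)."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a key-value mapping")
    valid = {f.name for f in dataclasses.fields(RefineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RefineConfig(**data)
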