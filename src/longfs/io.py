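"""Reading and writing cohorts, configs and run artefacts.

Exchange format is plain delimited text: one subjects x features CSV per
(modality, time point) cell with a header row of feature names, a
``labels.csv`` with columns ``subject_id,label``, and optional
``ground_truth.json`` (planted support) and ROI-name map (two columns:
1-based feature index, region name).  Missing cells are a hard error —
imputation of absent visits is out of scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .solver import CohortTable, Hyperparams

__all__ = [
    "RunConfig",
    "load_cohort",
    "save_cohort",
    "load_roi_map",
    "dump_incidence",
    "write_manifest",
]

log = logging.getLogger("longfs")


@dataclass
class RunConfig:
    """Everything one run needs: where the data live, the hyperparameters,
    and evaluation flags."""

    data_dir: Path
    modalities: list[str]
    timepoints: list[str]
    labels_file: str = "labels.csv"
    matrix_template: str = "{modality}_{timepoint}.csv"
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    folds: int = 10
    seed: int = 0
    output_dir: Path = Path("longfs_out")
    weight_grid_step: float = 0.1
    svm_c: float = 1.0
    selection_threshold: float = 1e-8
    top_k: int = 10
    inner_folds: int = 10
    roi_map: Path | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        hp = Hyperparams(**raw.pop("hyperparams", {}))
        data = raw.pop("data")
        roi_map = raw.pop("roi_map", None)
        return cls(
            data_dir=Path(data.get("dir", path.parent)),
            modalities=list(data["modalities"]),
            timepoints=list(data["timepoints"]),
            labels_file=data.get("labels", "labels.csv"),
            matrix_template=data.get("matrix_template", "{modality}_{timepoint}.csv"),
            hyperparams=hp,
            roi_map=Path(roi_map) if roi_map else None,
            output_dir=Path(raw.pop("output_dir", "longfs_out")),
            **raw,
        )

    def cell_path(self, modality: str, timepoint: str) -> Path:
        return self.data_dir / self.matrix_template.format(
            modality=modality, timepoint=timepoint
        )


def _coerce_labels(values: np.ndarray) -> np.ndarray:
    """Map raw labels onto {-1, +1}; {0, 1} maps 0 -> -1, logged."""
    uniq = sorted(set(np.unique(values).tolist()))
    if set(uniq) <= {-1, 1}:
        return values.astype(int)
    if set(uniq) <= {0, 1}:
        log.info("labels coerced: 0 -> -1, 1 -> +1")
        return np.where(values == 0, -1, 1).astype(int)
    raise ValueError(f"non-binary labels: found values {uniq}")


def load_cohort(config: RunConfig) -> CohortTable:
    """Read and validate every (modality, time point) matrix plus labels."""
    labels_path = config.data_dir / config.labels_file
    if not labels_path.exists():
        raise FileNotFoundError(f"labels file not found: {labels_path}")
    lab = pd.read_csv(labels_path)
    y = _coerce_labels(lab["label"].to_numpy())
    n = y.size

    cells: dict[tuple[int, int], np.ndarray] = {}
    feature_names: tuple[str, ...] | None = None
    for m, mod in enumerate(config.modalities):
        for t, tp in enumerate(config.timepoints):
            path = config.cell_path(mod, tp)
            if not path.exists():
                raise FileNotFoundError(f"missing cell: {path}")
            df = pd.read_csv(path)
            if df.shape[0] != n:
                raise ValueError(
                    f"dimension mismatch in {path}: {df.shape[0]} rows, "
                    f"expected {n} subjects"
                )
            names = tuple(df.columns)
            if feature_names is None:
                feature_names = names
            elif len(names) != len(feature_names):
                raise ValueError(
                    f"dimension mismatch in {path}: {len(names)} columns, "
                    f"expected {len(feature_names)}"
                )
            cells[(m, t)] = df.to_numpy(dtype=float)

    return CohortTable(
        cells, y,
        modality_names=tuple(config.modalities),
        timepoint_names=tuple(config.timepoints),
        feature_names=feature_names or (),
    )


def save_cohort(
    table: CohortTable,
    out_dir: str | Path,
    ground_truth: list[np.ndarray] | None = None,
) -> None:
    """Write one CSV per cell plus labels.csv (and ground_truth.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = list(table.feature_names) or [f"f{j+1}" for j in range(table.n_features)]
    mods = list(table.modality_names) or [f"mod{m+1}" for m in range(table.n_modalities)]
    tps = list(table.timepoint_names) or [f"t{t+1}" for t in range(table.n_timepoints)]
    for (m, t), X in table.features.items():
        pd.DataFrame(X, columns=cols).to_csv(out / f"{mods[m]}_{tps[t]}.csv", index=False)
    pd.DataFrame(
        {"subject_id": np.arange(table.n_subjects), "label": np.asarray(table.labels)}
    ).to_csv(out / "labels.csv", index=False)
    if ground_truth is not None:
        with open(out / "ground_truth.json", "w") as fh:
            json.dump({mods[m]: np.asarray(s).tolist()
                       for m, s in enumerate(ground_truth)}, fh, indent=2)


def load_roi_map(path: str | Path) -> dict[int, str]:
    """Two-column delimited file (1-based feature index, region name)."""
    df = pd.read_csv(path, header=None, names=["index", "roi"])
    return {int(i): str(r) for i, r in zip(df["index"], df["roi"])}


def dump_incidence(hg, path: str | Path) -> None:
    """Debug dump of a hypergraph incidence matrix as a dense 0/1 CSV
    (rows = vertices, columns = hyperedges)."""
    cols = [f"e{e}" for e in range(hg.n_edges)]
    pd.DataFrame(hg.incidence.astype(int), columns=cols).to_csv(path, index=False)


def write_manifest(out_dir: str | Path, payload: dict) -> Path:
    """Persist a reproducibility manifest (config echo, seed, version,
    timings) next to the run outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return path
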