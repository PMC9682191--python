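"""File formats: CSV feature tables, JSON model artifacts, graph archives.

Interchange format for data is deliberately plain: one CSV per modality with
a header row and a sample-ID first column, plus a two-column labels CSV.
Model states and ground truth are JSON (diff-able, schema-versioned); anchor
graphs round-trip through an .npz archive storing Z as sparse triplets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .anchor import AnchorGraph
from .data import MultiModalDataset, one_hot
from .errors import SchemaError, ValidationError
from .optim import ModelState
from .synthetic import GroundTruth

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1

__all__ = [
    "write_dataset",
    "read_multimodal",
    "write_model",
    "read_model",
    "write_graph",
    "read_graph",
    "write_ground_truth",
    "read_ground_truth",
    "MODEL_SCHEMA_VERSION",
]


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def write_dataset(
    data: MultiModalDataset, out_dir: str | Path, truth: GroundTruth | None = None
) -> None:
    """Write one ``modality_<name>.csv`` per block plus ``labels.csv``.

    Optionally writes ``ground_truth.json`` when the generator's truth is
    supplied.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = data.sample_ids or [f"S{i:04d}" for i in range(data.n)]
    for name, X in zip(data.modality_names, data.blocks):
        cols = [f"{name}_f{j}" for j in range(X.shape[1])]
        df = pd.DataFrame(X, columns=cols)
        df.insert(0, "sample_id", ids)
        df.to_csv(out / f"modality_{name}.csv", index=False)
    labels = data.labels
    class_order = data.class_order or sorted(set(labels.tolist()))
    lab = pd.DataFrame(
        {"sample_id": ids, "label": [class_order[i] for i in labels]}
    )
    lab.to_csv(out / "labels.csv", index=False)
    if truth is not None:
        write_ground_truth(truth, out / "ground_truth.json")


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need a sample-ID column plus features")
    return df


def read_multimodal(
    source: str | Path | list[str | Path],
    labels_file: str | Path | None = None,
    n_classes: int | None = None,
) -> MultiModalDataset:
    """Load modality tables + labels, aligning rows by sample ID.

    ``source`` is either a directory containing ``modality_*.csv`` and
    ``labels.csv`` (as written by :func:`write_dataset`), or an explicit
    list of modality files with ``labels_file`` given separately.  Samples
    missing from any modality are dropped everywhere with a logged count.
    """
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        src = Path(source)
        files = sorted(src.glob("modality_*.csv")) + sorted(src.glob("modality_*.tsv"))
        if not files:
            raise ValidationError(f"no modality_*.csv files found in {src}")
        if labels_file is None:
            labels_file = src / "labels.csv"
    else:
        files = [Path(p) for p in (source if isinstance(source, list) else [source])]
        if labels_file is None:
            raise ValidationError("labels_file required with explicit modality files")
    labels_file = Path(labels_file)
    if not labels_file.exists():
        raise ValidationError(f"labels file not found: {labels_file}")

    tables = []
    names = []
    for path in files:
        df = _read_table(path)
        id_col = df.columns[0]
        feats = df.set_index(id_col)
        bad = feats.columns[~feats.dtypes.map(
            lambda t: np.issubdtype(t, np.number))]
        if len(bad):
            first = bad[0]
            row = feats.index[feats[first].map(
                lambda x: not isinstance(x, (int, float, np.number))
            )].tolist()[:1]
            raise ValidationError(
                f"{path}: non-numeric cell in column {first!r}"
                + (f" at sample {row[0]!r}" if row else "")
            )
        tables.append(feats)
        stem = path.stem
        names.append(stem[len("modality_"):] if stem.startswith("modality_") else stem)

    lab = _read_table(labels_file)
    lab = lab.set_index(lab.columns[0])
    label_col = lab.columns[0]

    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    common = common.intersection(lab.index)
    if len(common) == 0:
        raise ValidationError("no sample IDs shared by all modality/label files")
    n_total = max(len(t) for t in tables)
    dropped = n_total - len(common)
    if dropped > 0:
        logger.warning("read_multimodal: dropped %d unmatched sample ID(s)", dropped)
    common = list(common)

    blocks = [t.loc[common].to_numpy(dtype=float) for t in tables]
    raw_labels = lab.loc[common, label_col].tolist()
    class_order = sorted(set(raw_labels), key=lambda x: str(x))
    if n_classes is not None and len(class_order) > n_classes:
        extra = [c for c in class_order][n_classes:]
        raise ValidationError(
            f"labels contain unexpected class(es) {extra} for a "
            f"{n_classes}-class configuration"
        )
    idx = {c: i for i, c in enumerate(class_order)}
    y = np.array([idx[v] for v in raw_labels])
    return MultiModalDataset(
        blocks=blocks,
        Y=one_hot(y, len(class_order)),
        modality_names=names,
        sample_ids=[str(s) for s in common],
        class_order=class_order,
    )


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def write_model(state: ModelState, path: str | Path, hp=None) -> None:
    """JSON-serialize a fitted state (full float precision, versioned)."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "W": [w.tolist() for w in state.W],
        "b": state.b.tolist(),
        "theta": state.theta.tolist(),
        "objective_history": list(state.objective_history),
        "dims": list(state.dims),
        "modality_names": list(state.modality_names),
        "converged": bool(state.converged),
        "n_sweeps": int(state.n_sweeps),
    }
    if hp is not None:
        payload["hyperparams"] = asdict(hp)
    if state.scale_mean is not None:
        payload["scale_mean"] = [m.tolist() for m in state.scale_mean]
        payload["scale_std"] = [s.tolist() for s in state.scale_std]
    Path(path).write_text(json.dumps(payload))


def read_model(path: str | Path) -> ModelState:
    """Inverse of :func:`write_model`; errors on truncated or foreign files."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"model file {path} is not valid JSON: {e}") from e
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise SchemaError(
            f"model schema version {version!r} unsupported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    required = {"W", "b", "theta", "objective_history", "dims", "modality_names"}
    missing = required - payload.keys()
    if missing:
        raise SchemaError(f"model file {path} missing keys: {sorted(missing)}")
    state = ModelState(
        W=[np.asarray(w, dtype=float) for w in payload["W"]],
        b=np.asarray(payload["b"], dtype=float),
        theta=np.asarray(payload["theta"], dtype=float),
        objective_history=[float(x) for x in payload["objective_history"]],
        dims=[int(d) for d in payload["dims"]],
        modality_names=list(payload["modality_names"]),
        converged=bool(payload.get("converged", False)),
        n_sweeps=int(payload.get("n_sweeps", 0)),
    )
    if "scale_mean" in payload:
        state.scale_mean = [np.asarray(m, float) for m in payload["scale_mean"]]
        state.scale_std = [np.asarray(s, float) for s in payload["scale_std"]]
    return state


# ---------------------------------------------------------------------------
# anchor graphs
# ---------------------------------------------------------------------------

def write_graph(graph: AnchorGraph, path: str | Path) -> None:
    """Archive anchors, Z (as COO triplets), delta, and k_nn in one .npz."""
    rows, cols = np.nonzero(graph.Z)
    np.savez(
        path,
        anchors=graph.anchors,
        z_rows=rows,
        z_cols=cols,
        z_vals=graph.Z[rows, cols],
        n=np.array([graph.Z.shape[0]]),
        m=np.array([graph.Z.shape[1]]),
        delta=graph.delta,
        k_nn=np.array([graph.k_nn]),
    )


def read_graph(path: str | Path) -> AnchorGraph:
    with np.load(path) as arc:
        n = int(arc["n"][0])
        m = int(arc["m"][0])
        Z = np.zeros((n, m))
        Z[arc["z_rows"], arc["z_cols"]] = arc["z_vals"]
        delta = arc["delta"]
        B = Z / np.sqrt(delta)[None, :]
        return AnchorGraph(
            anchors=arc["anchors"],
            Z=Z,
            delta=delta,
            B=B,
            k_nn=int(arc["k_nn"][0]),
        )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "informative_index_sets": truth.informative_index_sets,
        "class_assignments": truth.class_assignments.tolist(),
        "true_modality_strength": truth.true_modality_strength,
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        informative_index_sets=payload["informative_index_sets"],
        class_assignments=np.asarray(payload["class_assignments"]),
        true_modality_strength=payload["true_modality_strength"],
    )
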