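"""Dense neural TF-family classifier.

The classifier consumes the normalized-bit-score feature matrix (one
column per database sequence) and propagates it through four dense
hidden layers to a softmax over TF families, trained with cross-entropy.
Widths taper geometrically from the input dimension (fractions 0.5 /
0.25 / 0.1 / 0.05, floored at 16 units) since only the depth of the
network is fixed by design. Class imbalance is handled with
inverse-frequency sample weights in the loss (on by default).

A query with no surviving alignment hit against the database is called
non-TF before the network is consulted; a query whose best family
probability falls below ``prob_threshold`` is called TF-unclassified.

The network is implemented directly on numpy (ReLU hidden activations,
softmax output, Adam optimizer) so that training is bit-reproducible
given (database, config, seed) and model bundles round-trip exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .database import TFDatabase, write_db, read_db
from .errors import (
    ConsistencyError,
    DegenerateTrainingError,
    IncompatibilityError,
    NumericError,
)
from .features import AlignerParams, FeatureMatrix, align_all, build_feature_matrix
from .translate import Region

logger = logging.getLogger(__name__)

_BUNDLE_FORMAT = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization settings.

    hidden_sizes overrides the fraction-based taper when given. All
    values are recorded in the model's training provenance.
    """

    n_hidden_layers: int = 4
    hidden_fractions: tuple = (0.5, 0.25, 0.1, 0.05)
    hidden_sizes: Optional[tuple] = None
    min_hidden: int = 16
    activation: str = "relu"
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    prob_threshold: float = 0.5
    class_weighting: bool = True
    include_self_hits: bool = True

    def resolve_hidden_sizes(self, n_features: int) -> list[int]:
        if self.hidden_sizes is not None:
            sizes = list(self.hidden_sizes)
        else:
            sizes = [
                max(int(round(f * n_features)), self.min_hidden)
                for f in self.hidden_fractions[: self.n_hidden_layers]
            ]
        if len(sizes) != self.n_hidden_layers:
            raise ValueError(
                f"expected {self.n_hidden_layers} hidden sizes, got {len(sizes)}"
            )
        return sizes


@dataclass(frozen=True)
class Prediction:
    """Final per-query TF call."""

    query_id: str
    call: str  # TF | non-TF | TF-unclassified
    family: Optional[str] = None
    probability: Optional[float] = None
    best_hit: Optional[str] = None
    identity_pct: Optional[float] = None
    evalue: Optional[float] = None
    region: Optional[Region] = None


@dataclass
class TFModel:
    """Trained classifier plus the index maps frozen at training time."""

    config: ModelConfig
    weights: list  # [(W, b), ...] input->hidden...->softmax
    family_index: list[str]
    feature_index: list[str]
    training_provenance: dict = field(default_factory=dict)
    db: Optional[TFDatabase] = None
    params: AlignerParams = field(default_factory=AlignerParams)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(weights, x: np.ndarray) -> np.ndarray:
    """Probabilities for a batch; hidden layers are ReLU, output softmax."""
    a = x
    for W, b in weights[:-1]:
        a = np.maximum(a @ W + b, 0.0)
    W, b = weights[-1]
    return _softmax(a @ W + b)


def _train_network(
    x: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    config: ModelConfig,
) -> tuple[list, list[float]]:
    n, d = x.shape
    rng = np.random.default_rng(config.seed)
    sizes = [d] + config.resolve_hidden_sizes(d) + [n_classes]
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        weights.append([W, np.zeros(fan_out)])

    if config.class_weighting:
        counts = np.bincount(y, minlength=n_classes).astype(float)
        cw = np.where(counts > 0, n / (n_classes * np.maximum(counts, 1.0)), 0.0)
        sample_w = cw[y]
        sample_w = sample_w / sample_w.mean()
    else:
        sample_w = np.ones(n)

    # Adam state
    m = [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights]
    v = [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    losses: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb, wb = x[idx], y[idx], sample_w[idx]
            # forward with cached activations
            acts = [xb]
            a = xb
            for W, b in weights[:-1]:
                a = np.maximum(a @ W + b, 0.0)
                acts.append(a)
            W, b = weights[-1]
            probs = _softmax(a @ W + b)
            p_true = probs[np.arange(len(yb)), yb]
            loss = float(-(wb * np.log(np.maximum(p_true, 1e-300))).sum())
            epoch_loss += loss
            # backward
            delta = probs
            delta[np.arange(len(yb)), yb] -= 1.0
            delta *= wb[:, None] / len(idx)
            grads = []
            for layer in range(len(weights) - 1, -1, -1):
                a_prev = acts[layer]
                gW = a_prev.T @ delta
                gb = delta.sum(axis=0)
                grads.append((gW, gb))
                if layer > 0:
                    delta = delta @ weights[layer][0].T
                    delta *= (acts[layer] > 0)
            grads.reverse()
            t += 1
            for layer, (gW, gb) in enumerate(grads):
                for slot, g in ((0, gW), (1, gb)):
                    m[layer][slot] = beta1 * m[layer][slot] + (1 - beta1) * g
                    v[layer][slot] = beta2 * v[layer][slot] + (1 - beta2) * g * g
                    mhat = m[layer][slot] / (1 - beta1**t)
                    vhat = v[layer][slot] / (1 - beta2**t)
                    weights[layer][slot] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        mean_loss = epoch_loss / n
        if not np.isfinite(mean_loss):
            raise NumericError(f"training loss became non-finite ({mean_loss})")
        losses.append(mean_loss)
    return [(W.copy(), b.copy()) for W, b in weights], losses


def train(
    db: TFDatabase,
    config: ModelConfig | None = None,
    params: AlignerParams | None = None,
) -> TFModel:
    """Train the family classifier on a curated database.

    Features are the database aligned against itself (self-hits retained
    unless configured off). Requires at least two families.
    """
    config = config or ModelConfig()
    params = params or AlignerParams()
    families = sorted({r.family for r in db.records})
    if len(families) < 2:
        raise DegenerateTrainingError(
            f"training requires >= 2 TF families, database has {len(families)}"
        )
    small = [f for f in families if sum(r.family == f for r in db.records) < 2]
    if small:
        logger.warning("families with a single training record: %s", small)

    queries = [(r.record_id, r.sequence) for r in db.records]
    hits = align_all(queries, db, params)
    fm = build_feature_matrix(queries, db, hits, params)
    x = fm.values.to_numpy(dtype=float)
    if not config.include_self_hits:
        for i, r in enumerate(db.records):
            x[i, i] = 0.0
    family_of = {r.record_id: r.family for r in db.records}
    fam_pos = {f: i for i, f in enumerate(families)}
    y = np.array([fam_pos[family_of[qid]] for qid in fm.query_ids])

    weights, losses = _train_network(x, y, len(families), config)
    train_probs = _forward(weights, x)
    train_acc = float((train_probs.argmax(axis=1) == y).mean())
    provenance = {
        "db_label": db.label,
        "n_records": len(db),
        "n_families": len(families),
        "seed": config.seed,
        "epochs": config.epochs,
        "final_loss": losses[-1] if losses else None,
        "training_accuracy": train_acc,
    }
    logger.info("trained on %d records / %d families; training accuracy %.3f",
                len(db), len(families), train_acc)
    return TFModel(
        config=config,
        weights=weights,
        family_index=families,
        feature_index=list(fm.feature_index),
        training_provenance=provenance,
        db=db,
        params=params,
    )


def predict_proba(model: TFModel, features: FeatureMatrix) -> pd.DataFrame:
    """Per-query probability distribution over the model's family index.

    The feature columns must equal the model's feature index exactly.
    No-hit queries pass through (their rows are still valid softmax
    distributions) and stay flagged in ``features.no_hit``.
    """
    cols = list(features.feature_index)
    if cols != model.feature_index:
        for a, b in zip(cols, model.feature_index):
            if a != b:
                raise ConsistencyError(
                    f"feature column mismatch: matrix has {a!r} where model expects {b!r}"
                )
        raise ConsistencyError(
            f"feature matrix has {len(cols)} columns, model expects {len(model.feature_index)}"
        )
    probs = _forward(model.weights, features.values.to_numpy(dtype=float))
    return pd.DataFrame(probs, index=features.query_ids, columns=model.family_index)


def classify(
    model: TFModel,
    queries,
    params: AlignerParams | None = None,
) -> list[Prediction]:
    """Full per-query pipeline: align, encode, score, call.

    Zero surviving hits => non-TF. Otherwise TF with the argmax family
    when its probability reaches the threshold, else TF-unclassified.
    """
    params = params or model.params
    if model.db is None:
        raise ConsistencyError("model carries no database; cannot align queries")
    from .features import _as_query_items  # local import to keep surface tidy

    items = _as_query_items(queries)
    if not items:
        return []
    hits = align_all(items, model.db, params)
    fm = build_feature_matrix(items, model.db, hits, params)
    probs = predict_proba(model, fm)
    best_hit: dict[str, object] = {}
    for h in hits:  # hits are ordered best-first per query
        best_hit.setdefault(h.query_id, h)
    predictions: list[Prediction] = []
    no_hit = set(fm.no_hit)
    for qid, _ in items:
        if qid in no_hit:
            predictions.append(Prediction(query_id=qid, call="non-TF"))
            continue
        row = probs.loc[qid]
        family = str(row.idxmax())
        p = float(row.max())
        h = best_hit[qid]
        call = "TF" if p >= model.config.prob_threshold else "TF-unclassified"
        predictions.append(
            Prediction(
                query_id=qid,
                call=call,
                family=family if call == "TF" else None,
                probability=p,
                best_hit=h.subject_id,
                identity_pct=h.identity_pct,
                evalue=h.evalue,
            )
        )
    return predictions


PREDICTION_COLUMNS = ["query_id", "call", "family", "probability", "best_hit", "identity_pct", "evalue"]


def predictions_to_frame(predictions: list[Prediction]) -> pd.DataFrame:
    """Tabular view of predictions (the published-example output layout)."""
    rows = []
    for p in predictions:
        rows.append(
            {
                "query_id": p.query_id,
                "call": p.call,
                "family": p.family if p.family is not None else "",
                "probability": "" if p.probability is None else f"{p.probability:.4f}",
                "best_hit": p.best_hit or "",
                "identity_pct": "" if p.identity_pct is None else f"{p.identity_pct:.2f}",
                "evalue": "" if p.evalue is None else f"{p.evalue:.3e}",
            }
        )
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def _weights_digest(weights) -> str:
    h = hashlib.sha256()
    for W, b in weights:
        for arr in (W, b):
            h.update(str(arr.shape).encode())
            h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
    return h.hexdigest()


def save_model(model: TFModel, path) -> Path:
    """Persist a model as a single-directory bundle.

    Layout: manifest.json (config, indices, provenance, weight digest),
    weights.npz, and the training database under db/ so that prediction
    is self-contained.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, (W, b) in enumerate(model.weights):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(path / "weights.npz", **arrays)
    manifest = {
        "format_version": _BUNDLE_FORMAT,
        "tool_version": __version__,
        "config": asdict(model.config),
        "aligner_params": asdict(model.params),
        "family_index": model.family_index,
        "feature_index": model.feature_index,
        "training_provenance": model.training_provenance,
        "n_layers": len(model.weights),
        "weights_sha256": _weights_digest(model.weights),
    }
    with open(path / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if model.db is not None:
        write_db(model.db, path / "db")
    return path


def load_model(path) -> TFModel:
    """Load a bundle written by :func:`save_model`; verifies integrity."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise IncompatibilityError(f"not a model bundle (no manifest.json): {path}")
    try:
        with open(manifest_path, encoding="utf-8") as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as exc:
        raise IncompatibilityError(f"corrupt manifest in {path}: {exc}") from exc
    if manifest.get("format_version") != _BUNDLE_FORMAT:
        raise IncompatibilityError(
            f"bundle format {manifest.get('format_version')} unsupported "
            f"(expected {_BUNDLE_FORMAT})"
        )
    try:
        npz = np.load(path / "weights.npz")
        weights = [
            (npz[f"W{i}"], npz[f"b{i}"]) for i in range(manifest["n_layers"])
        ]
    except (OSError, KeyError, ValueError, zipfile.BadZipFile) as exc:
        raise IncompatibilityError(f"corrupt or truncated weights in {path}: {exc}") from exc
    if _weights_digest(weights) != manifest["weights_sha256"]:
        raise IncompatibilityError(f"weight digest mismatch in {path}")
    config_d = dict(manifest["config"])
    for key in ("hidden_fractions", "hidden_sizes"):
        if config_d.get(key) is not None:
            config_d[key] = tuple(config_d[key])
    db_dir = path / "db"
    return TFModel(
        config=ModelConfig(**config_d),
        weights=weights,
        family_index=list(manifest["family_index"]),
        feature_index=list(manifest["feature_index"]),
        training_provenance=dict(manifest["training_provenance"]),
        db=read_db(db_dir) if db_dir.exists() else None,
        params=AlignerParams(**manifest["aligner_params"]),
    )
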