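"""The screening engine.

A compound library is scored attribute-by-attribute by the trained
dual-path models, each probability is binarized at the decision
threshold, and the binarized activity attributes are summed into a
cumulative score.  The funnel then runs in fixed order: BBB gate ->
cumulative score >= threshold -> optional toxicity filter.  Hits are
ranked by (score desc, mean activity probability desc, compound_id asc),
a total order, so re-running yields an identical hit list.

Chemical-space applicability is assessed two ways: a k-NN distance
coverage score against the training descriptors, and a 2-D t-SNE map for
visual overlap checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .compound_io import AttributeSchema, CompoundDataset, ValidationError
from .descriptors import featurize_table
from .models import GraphBatch, TrainedAttributeModel, predict
from .molgraph import batch_featurize


@dataclass
class ScreenConfig:
    gate_attribute: str
    score_attributes: tuple[str, ...]
    score_threshold: int = 5
    apply_toxicity_filter: bool = True
    decision_threshold: float = 0.5
    include_gate_in_score: bool = False  # switch to the 10-attribute convention

    def __post_init__(self) -> None:
        if self.include_gate_in_score and self.gate_attribute not in self.score_attributes:
            self.score_attributes = (self.gate_attribute, *self.score_attributes)
        if not self.include_gate_in_score and self.gate_attribute in self.score_attributes:
            raise ValidationError("gate attribute in score_attributes requires include_gate_in_score")
        if self.score_threshold > len(self.score_attributes):
            raise ValidationError(
                f"score_threshold {self.score_threshold} exceeds the "
                f"{len(self.score_attributes)} scored attributes"
            )
        if not 0 < self.decision_threshold < 1:
            raise ValidationError("decision_threshold must be in (0, 1)")

    @classmethod
    def from_schema(cls, schema: AttributeSchema, **kwargs) -> "ScreenConfig":
        return cls(
            gate_attribute=schema.gate_attribute.attribute_id,
            score_attributes=tuple(a.attribute_id for a in schema.activity_attributes),
            **kwargs,
        )


@dataclass
class ScreenResult:
    frame: pd.DataFrame            # per-compound probabilities + funnel columns
    hits: list[str]                # ranked final hit ids
    stage_counts: dict[str, int]   # n_input, n_gate_pass, n_score_pass, n_nontoxic
    config: ScreenConfig


def predict_attributes(
    models: Mapping[str, TrainedAttributeModel],
    dataset: CompoundDataset,
) -> pd.DataFrame:
    """Probability table (n_compounds x n_attributes, schema order).

    Tabular models see the 12-descriptor matrix, graph models see
    molecular graphs; featurization happens once per path.
    """
    schema = dataset.schema
    for attr in schema:
        if attr.attribute_id not in models:
            raise ValidationError(f"no model supplied for attribute {attr.attribute_id!r}")
        if models[attr.attribute_id].path != attr.path:
            raise ValidationError(
                f"attribute {attr.attribute_id!r} routes to {attr.path!r} but the model "
                f"is {models[attr.attribute_id].path!r}"
            )
    needs_tabular = any(a.path == "tabular" for a in schema)
    needs_graph = any(a.path == "graph" for a in schema)
    descriptors = featurize_table(dataset).to_numpy() if needs_tabular else None
    batch = GraphBatch.from_graphs(batch_featurize(dataset)) if needs_graph else None
    columns = {}
    for attr in schema:
        inputs = descriptors if attr.path == "tabular" else batch
        columns[attr.attribute_id] = predict(models[attr.attribute_id], inputs)
    return pd.DataFrame(columns, index=pd.Index(dataset.compound_ids, name="compound_id"))


def cumulative_score(table: pd.DataFrame, config: ScreenConfig) -> pd.Series:
    """Integer score: count of scored attributes with p >= threshold."""
    missing = [a for a in config.score_attributes if a not in table.columns]
    if missing:
        raise ValidationError(f"probability table lacks scored attributes {missing}")
    binarized = table[list(config.score_attributes)] >= config.decision_threshold
    return binarized.sum(axis=1).astype(int)


def run_screen(
    table: pd.DataFrame,
    toxic: pd.Series | None,
    config: ScreenConfig,
) -> ScreenResult:
    """Run the funnel: gate -> score threshold -> toxicity filter."""
    if config.gate_attribute not in table.columns:
        raise ValidationError(f"gate attribute {config.gate_attribute!r} missing from table")
    if config.apply_toxicity_filter and toxic is None:
        raise ValidationError("toxicity filter enabled but no toxicity flags supplied")
    n = len(table)
    frame = table.copy()
    score = cumulative_score(table, config)
    gate_pass = table[config.gate_attribute] >= config.decision_threshold
    score_pass = gate_pass & (score >= config.score_threshold)
    if config.apply_toxicity_filter:
        tox = toxic.reindex(table.index)
        if tox.isna().any():
            bad = list(tox.index[tox.isna()])[:3]
            raise ValidationError(f"toxicity flags missing for compounds {bad}")
        final = score_pass & ~tox.astype(bool)
    else:
        tox = toxic.reindex(table.index) if toxic is not None else pd.Series(pd.NA, index=table.index)
        final = score_pass

    frame["gate_pass"] = gate_pass
    frame["score"] = score
    frame["toxic"] = tox
    frame["final_hit"] = final

    mean_prob = table[list(config.score_attributes)].mean(axis=1) if n else pd.Series(dtype=float)
    hit_ids = list(frame.index[final])
    hit_ids.sort(key=lambda cid: (-int(score[cid]), -float(mean_prob[cid]), cid))
    frame["rank"] = pd.Series(
        {cid: r + 1 for r, cid in enumerate(hit_ids)}, dtype="Int64"
    ).reindex(frame.index)

    counts = {
        "n_input": n,
        "n_gate_pass": int(gate_pass.sum()),
        "n_score_pass": int(score_pass.sum()),
        "n_nontoxic": int(final.sum()),
    }
    return ScreenResult(frame=frame, hits=hit_ids, stage_counts=counts, config=config)


# ---------------------------------------------------------------------------
# applicability domain


def applicability_domain(
    train_descriptors: np.ndarray,
    query_descriptors: np.ndarray,
    k: int = 5,
) -> pd.DataFrame:
    """k-NN coverage check in z-scored descriptor space.

    coverage = mean Euclidean distance to the k nearest training points
    (z-scored by training statistics); a query is in-domain iff its
    coverage is at most the 95th percentile of the training set's own
    leave-one-out k-NN coverages.
    """
    train = np.asarray(train_descriptors, dtype=float)
    query = np.asarray(query_descriptors, dtype=float)
    if train.shape[1] != query.shape[1]:
        raise ValueError("train and query matrices must share feature width")
    if not 1 <= k <= len(train) - 1:
        raise ValueError(f"k must be in [1, n_train-1={len(train) - 1}]")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    train_z = (train - mean) / sd
    query_z = (query - mean) / sd
    nn = NearestNeighbors(n_neighbors=k + 1).fit(train_z)
    loo_dist, _ = nn.kneighbors(train_z)
    loo_cover = loo_dist[:, 1:].mean(axis=1)  # drop self-distance
    cutoff = float(np.percentile(loo_cover, 95))
    q_dist, _ = nn.kneighbors(query_z, n_neighbors=k)
    coverage = q_dist.mean(axis=1)
    return pd.DataFrame(
        {"coverage": coverage, "in_domain": coverage <= cutoff},
    ).assign(cutoff=cutoff)


# ---------------------------------------------------------------------------
# t-SNE chemical-space map


def perplexity_calibration(
    x: np.ndarray, perplexity: float, tol: float = 1e-4, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point Gaussian bandwidth calibration by bisection.

    Returns the row-normalized conditional affinity matrix P (rows sum to
    1, zero diagonal) and the achieved per-row perplexity 2^H(P_i).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    d2 = np.square(x[:, None, :] - x[None, :, :]).sum(-1)
    np.fill_diagonal(d2, np.inf)
    target_h = np.log2(perplexity)
    p = np.zeros((n, n))
    achieved = np.zeros(n)
    for i in range(n):
        lo, hi = 0.0, np.inf
        beta = 1.0
        row = np.zeros(n)
        for _ in range(max_iter):
            w = np.exp(-beta * (d2[i] - d2[i].min()))
            w[i] = 0.0
            row = w / w.sum()
            nz = row > 0
            h = -np.sum(row[nz] * np.log2(row[nz]))
            if abs(2**h - perplexity) <= 1e-3 or abs(h - target_h) <= tol * 1e-2:
                break
            if h > target_h:  # too flat: increase beta
                lo = beta
                beta = beta * 2 if not np.isfinite(hi) else (lo + hi) / 2
            else:
                hi = beta
                beta = beta / 2 if lo == 0.0 else (lo + hi) / 2
        p[i] = row
        achieved[i] = 2**h
    return p, achieved


def embed_map(
    descriptors: np.ndarray,
    perplexity: float = 30.0,
    iterations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """2-D t-SNE embedding (exact gradient, O(n^2)).

    Input affinities are perplexity-calibrated Gaussians, symmetrized;
    output affinities are Student-t with one degree of freedom.  Gradient
    descent with momentum and early exaggeration; deterministic given the
    seed.
    """
    x = np.asarray(descriptors, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 points to embed")
    if n <= 3 * perplexity:
        warnings.warn(
            f"n={n} is small for perplexity {perplexity}; recommend n > {int(3 * perplexity)}",
            stacklevel=2,
        )
        perplexity = min(perplexity, (n - 1) / 3)
    cond, _ = perplexity_calibration(x, perplexity)
    p = (cond + cond.T) / (2 * n)
    p = np.maximum(p, 1e-12)

    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, 1e-4, size=(n, 2))
    velocity = np.zeros_like(y)
    gains = np.ones_like(y)
    exaggeration_until = min(250, iterations // 4)
    lr = max(n / 48.0, 50.0)
    for it in range(iterations):
        pij = p * 12.0 if it < exaggeration_until else p
        d2 = np.square(y[:, None, :] - y[None, :, :]).sum(-1)
        num = 1.0 / (1.0 + d2)
        np.fill_diagonal(num, 0.0)
        q = np.maximum(num / num.sum(), 1e-12)
        coeff = (pij - q) * num
        grad = 4.0 * ((np.diag(coeff.sum(axis=1)) - coeff) @ y)
        momentum = 0.5 if it < 250 else 0.8
        # adaptive per-coordinate gains, as in the reference implementation
        gains = np.maximum(
            np.where(np.sign(grad) != np.sign(velocity), gains + 0.2, gains * 0.8), 0.01
        )
        velocity = momentum * velocity - lr * gains * grad
        y = y + velocity
        y = y - y.mean(axis=0)
    return y
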