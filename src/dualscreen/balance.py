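"""Class-imbalance remediation for per-attribute training sets.

Tabular path: SMOTE / ADASYN oversampling on (z-scored) descriptor
vectors.  Graph path: random majority downsampling, since interpolated
feature vectors do not correspond to valid molecular graphs.  Both paths
can alternatively train with the focal loss, which down-weights easy
examples via a (1-p_t)^gamma factor.

Oversampling belongs AFTER splitting, on training folds only; applying
it before the split leaks synthetic near-duplicates of training points
into validation and test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

EPS = 1e-7


@dataclass
class LabeledMatrix:
    """A feature matrix with binary labels and row identifiers."""

    x: np.ndarray          # (n, d)
    y: np.ndarray          # (n,) in {0, 1}
    ids: list[str]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.x.ndim != 2:
            raise ValueError("x must be 2-D")
        if not (len(self.x) == len(self.y) == len(self.ids)):
            raise ValueError("x, y and ids must have equal length")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, indices: np.ndarray) -> "LabeledMatrix":
        indices = np.asarray(indices, dtype=int)
        return LabeledMatrix(self.x[indices], self.y[indices], [self.ids[i] for i in indices])


@dataclass(frozen=True)
class FocalParams:
    gamma: float = 2.0   # focusing exponent, >= 0
    alpha: float = 1.0   # positive-class weight, (0, 1]

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


def _round_allocation(counts_exact: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding preserving the (integer) total."""
    total = int(round(counts_exact.sum()))
    base = np.floor(counts_exact).astype(int)
    short = total - base.sum()
    if short > 0:
        remainders = counts_exact - base
        # ties broken toward lower index (stable argsort on negated remainder)
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return base


def stratified_split(
    data: LabeledMatrix, test_frac: float, val_frac: float, seed: int
) -> tuple[LabeledMatrix, LabeledMatrix, LabeledMatrix]:
    """Deterministic stratified train/val/test partition.

    ``test_frac`` of the whole set is reserved for testing; ``val_frac``
    of the remainder for validation.  Per-class counts in each part are
    proportional allocations rounded to nearest.
    """
    if not (0 < test_frac < 1 and 0 < val_frac < 1):
        raise ValueError("fractions must be in (0, 1)")
    classes, counts = np.unique(data.y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 3:
        raise ValueError("each class needs at least 3 members to populate three parts")
    rng = np.random.default_rng(seed)
    parts: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    for c in classes:
        idx = np.flatnonzero(data.y == c)
        rng.shuffle(idx)
        n_c = len(idx)
        n_test = int(round(n_c * test_frac))
        n_val = int(round((n_c - n_test) * val_frac))
        parts["test"].extend(idx[:n_test])
        parts["val"].extend(idx[n_test : n_test + n_val])
        parts["train"].extend(idx[n_test + n_val :])
    out = tuple(data.subset(np.sort(parts[k])) for k in ("train", "val", "test"))
    if any(len(np.unique(p.y)) < 2 for p in out):
        raise ValueError("a split part ended up single-class; adjust fractions or data")
    return out


def smote(minority: np.ndarray, k: int, n_synthetic: int, seed: int) -> np.ndarray:
    """Synthesize ``n_synthetic`` points, each p + lam*(q - p) for a random
    minority point p, one of its k nearest minority neighbors q (Euclidean)
    and lam ~ Uniform[0, 1]."""
    minority = np.asarray(minority, dtype=float)
    m = len(minority)
    if m < 2:
        raise ValueError("SMOTE needs at least 2 minority points")
    if not 1 <= k < m:
        raise ValueError(f"k must satisfy 1 <= k < {m}, got {k}")
    if n_synthetic == 0:
        return np.empty((0, minority.shape[1]))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    neighbors = nn.kneighbors(minority, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    p_idx = rng.integers(0, m, size=n_synthetic)
    q_idx = neighbors[p_idx, rng.integers(0, k, size=n_synthetic)]
    lam = rng.uniform(0.0, 1.0, size=n_synthetic)[:, None]
    p = minority[p_idx]
    return p + lam * (minority[q_idx] - p)


def adasyn(data: LabeledMatrix, k: int, target_ratio: float, seed: int) -> LabeledMatrix:
    """Adaptive synthetic oversampling.

    Per minority point, hardness r_i = fraction of majority points among
    its k nearest neighbors in the full data; synthesis is allocated
    proportionally to r_i (largest-remainder rounding) until the
    minority:majority ratio reaches ``target_ratio``.  When every r_i is
    zero (minority isolated from majority) allocation falls back to
    uniform.  Interpolation partners are minority neighbors, as in SMOTE.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    classes, counts = np.unique(data.y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    minority_class = classes[np.argmin(counts)]
    min_idx = np.flatnonzero(data.y == minority_class)
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("ADASYN needs at least 2 minority points")
    total = int(round(target_ratio * n_maj)) - n_min
    if total <= 0:
        return LabeledMatrix(data.x.copy(), data.y.copy(), list(data.ids))

    k_full = min(k, len(data) - 1)
    nn_full = NearestNeighbors(n_neighbors=k_full + 1).fit(data.x)
    neigh = nn_full.kneighbors(data.x[min_idx], return_distance=False)[:, 1:]
    hardness = (data.y[neigh] != minority_class).mean(axis=1)
    if hardness.sum() == 0:
        weights = np.full(n_min, 1.0 / n_min)
    else:
        weights = hardness / hardness.sum()
    allocation = _round_allocation(weights * total)

    minority = data.x[min_idx]
    k_min = min(k, n_min - 1)
    nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(minority)
    neighbors = nn_min.kneighbors(minority, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    synth = []
    for i, g_i in enumerate(allocation):
        for _ in range(g_i):
            q = neighbors[i, rng.integers(0, k_min)]
            lam = rng.uniform()
            synth.append(minority[i] + lam * (minority[q] - minority[i]))
    synth_x = np.vstack(synth) if synth else np.empty((0, data.x.shape[1]))
    new_ids = list(data.ids) + [f"adasyn_{i:05d}" for i in range(len(synth_x))]
    new_x = np.vstack([data.x, synth_x])
    new_y = np.concatenate([data.y, np.full(len(synth_x), minority_class, dtype=int)])
    return LabeledMatrix(new_x, new_y, new_ids)


def downsample_majority(y: np.ndarray, seed: int, indices: np.ndarray | None = None) -> np.ndarray:
    """Keep all minority indices plus a uniform random majority subset of
    equal size.  Returns sorted positional indices (into ``indices`` when
    given, else into ``y``)."""
    y = np.asarray(y, dtype=int)
    if indices is None:
        indices = np.arange(len(y))
    indices = np.asarray(indices, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    minority_class = classes[np.argmin(counts)]
    min_pos = np.flatnonzero(y == minority_class)
    maj_pos = np.flatnonzero(y != minority_class)
    rng = np.random.default_rng(seed)
    keep_maj = rng.choice(maj_pos, size=len(min_pos), replace=False)
    return np.sort(indices[np.concatenate([min_pos, keep_maj])])


def focal_loss(
    p: np.ndarray, y: np.ndarray, params: FocalParams
) -> tuple[np.ndarray, np.ndarray]:
    """Focal loss FL = -alpha_t (1 - p_t)^gamma log(p_t) and its gradient
    in p, elementwise.

    alpha weights the positive term only (negatives keep weight 1), so
    gamma=0, alpha=1 reduces exactly to binary cross-entropy.  p is
    clamped to [1e-7, 1 - 1e-7].
    """
    p = np.clip(np.asarray(p, dtype=float), EPS, 1 - EPS)
    y = np.asarray(y)
    g, a = params.gamma, params.alpha
    pos = y == 1
    loss = np.where(
        pos,
        -a * (1 - p) ** g * np.log(p),
        -(p**g) * np.log(1 - p),
    )
    grad_pos = a * (g * (1 - p) ** (g - 1) * np.log(p) - (1 - p) ** g / p) if g > 0 else -a / p
    grad_neg = (
        -(g * p ** (g - 1) * np.log(1 - p)) + p**g / (1 - p) if g > 0 else 1.0 / (1 - p)
    )
    grad = np.where(pos, grad_pos, grad_neg)
    return loss, grad
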