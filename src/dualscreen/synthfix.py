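"""Synthetic chemistry fixtures with machine-readable planted truth.

Every benchmark every other module is tested against is generated here:
labeled SMILES libraries with planted structure-property rules and
controlled class imbalance, screening probability tables with a known
gate/score/toxicity funnel, and meta-analysis study sets drawn around a
known pooled effect.  Each generator persists the ground truth needed to
score downstream recovery without re-deriving it.

Molecules come from a fixed combinatorial vocabulary (ring scaffolds x
substituents, deduplicated by canonical SMILES), so every entry is a
valid single-fragment structure and substructure truth is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.optimize import bisect
from scipy.special import expit

from .compound_io import Attribute, AttributeSchema, CompoundDataset, CompoundRecord
from .descriptors import DESCRIPTOR_NAMES, compute_descriptors
from .metaanalysis import StudyEffect

# scaffold templates; "{}" is the substitution slot ("[H]" = unsubstituted)
_TEMPLATES_1 = (
    "c1ccc({})cc1",      # benzene
    "c1ccc({})nc1",      # pyridine
    "c1ncc({})cn1",      # pyrimidine
    "c1cc({})oc1",       # furan
    "c1cc({})sc1",       # thiophene
    "c1cc({})[nH]c1",    # pyrrole
    "C1CCC({})CC1",      # cyclohexane
    "C1CCC({})OC1",      # oxane
    "CCC{}",             # propyl chain
)
_TEMPLATES_2 = (
    "c1cc({})cc({})c1",  # disubstituted benzene
    "c1cc({})nc({})c1",  # disubstituted pyridine
)
_SUBSTITUENTS = (
    "[H]", "C", "CC", "CCC", "C(C)C", "O", "OC", "N", "NC", "N(C)C",
    "C(=O)O", "C(=O)N", "C(=O)C", "F", "Cl", "Br", "C#N", "C(F)(F)F",
    "CO", "C=C", "S", "SC", "OCC",
)


@lru_cache(maxsize=1)
def molecule_vocabulary() -> tuple[str, ...]:
    """>= 500 valid single-fragment canonical SMILES spanning molecules
    with and without aromatic nitrogens and a broad MW/LogP range."""
    out = set()
    for t in _TEMPLATES_1:
        for s in _SUBSTITUENTS:
            mol = Chem.MolFromSmiles(t.format(s))
            if mol is not None and len(Chem.GetMolFrags(mol)) == 1:
                out.add(Chem.MolToSmiles(mol))
    for t in _TEMPLATES_2:
        for s1 in _SUBSTITUENTS:
            for s2 in _SUBSTITUENTS:
                mol = Chem.MolFromSmiles(t.format(s1, s2))
                if mol is not None and len(Chem.GetMolFrags(mol)) == 1:
                    out.add(Chem.MolToSmiles(mol))
    return tuple(sorted(out))


# ---------------------------------------------------------------------------
# substructure rule registry (graph-path planted rules)


def _has_aromatic_nitrogen(mol: Chem.Mol) -> bool:
    return any(a.GetSymbol() == "N" and a.GetIsAromatic() for a in mol.GetAtoms())


def _has_halogen(mol: Chem.Mol) -> bool:
    return any(a.GetSymbol() in ("F", "Cl", "Br", "I") for a in mol.GetAtoms())


def _has_carboxyl(mol: Chem.Mol) -> bool:
    return mol.HasSubstructMatch(Chem.MolFromSmarts("C(=O)[OH]"))


RULE_REGISTRY: dict[str, Callable[[Chem.Mol], bool]] = {
    "aromatic_nitrogen": _has_aromatic_nitrogen,
    "halogen": _has_halogen,
    "carboxylic_acid": _has_carboxyl,
}


def default_schema() -> AttributeSchema:
    """The 10-attribute panel the screening fixtures use: one tabular BBB
    gate, six tabular anti-inflammatory attributes, three graph
    antioxidative attributes."""
    attrs = [Attribute("bbb", "BBB permeability", "tabular", "bbb_gate")]
    attrs += [
        Attribute(f"infl{i}", f"Anti-inflammatory pathway {i}", "tabular", "activity")
        for i in range(1, 7)
    ]
    attrs += [
        Attribute(f"antiox{i}", f"Antioxidative pathway {i}", "graph", "activity")
        for i in range(1, 4)
    ]
    return AttributeSchema(tuple(attrs))


# ---------------------------------------------------------------------------
# tabular benchmark: labels planted on a logistic model over descriptors


@dataclass(frozen=True)
class TabularBenchSpec:
    n: int = 2000
    # coefficients on z-scored descriptors, aligned to DESCRIPTOR_NAMES;
    # default: lipophilicity helps, polar surface area hurts
    coefficients: tuple[float, ...] = tuple(
        {"mol_logp": 3.0, "tpsa": -3.0}.get(name, 0.0) for name in DESCRIPTOR_NAMES
    )
    flip_rate: float = 0.05
    minority_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.flip_rate < 0.5:
            raise ValueError("flip_rate must be in [0, 0.5)")
        if not 0 < self.minority_fraction <= 0.5:
            raise ValueError("minority_fraction must be in (0, 0.5]")
        if len(self.coefficients) != len(DESCRIPTOR_NAMES):
            raise ValueError(f"need {len(DESCRIPTOR_NAMES)} coefficients")


@dataclass
class TabularBenchmark:
    ids: list[str]
    smiles: list[str]
    descriptors: np.ndarray       # (n, 12) raw panel
    y: np.ndarray                 # observed labels (after flips)
    truth: dict                   # beta, intercept, clean labels, flips, ...

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"compound_id": self.ids, "smiles": self.smiles, "label": self.y}
        )


@lru_cache(maxsize=4)
def _vocabulary_descriptors() -> np.ndarray:
    return np.vstack([compute_descriptors(s).to_array() for s in molecule_vocabulary()])


def generate_tabular_benchmark(spec: TabularBenchSpec) -> TabularBenchmark:
    """Sample molecules, plant label = Bernoulli(logistic(beta . z + c))
    then flip with ``flip_rate``.  The intercept c is calibrated by
    bisection so the expected realized (post-flip) positive fraction
    equals ``minority_fraction``; with the default n the realized
    fraction lands within +-2% of it."""
    vocab = molecule_vocabulary()
    rng = np.random.default_rng(spec.seed)
    idx = rng.integers(0, len(vocab), size=spec.n)
    desc = _vocabulary_descriptors()[idx]
    sd = desc.std(axis=0)
    sd[sd == 0] = 1.0
    z = (desc - desc.mean(axis=0)) / sd
    beta = np.asarray(spec.coefficients, dtype=float)
    eta = z @ beta

    # post-flip E[y] = E[p](1-f) + (1-E[p])f  =>  target E[p]
    f = spec.flip_rate
    target = (spec.minority_fraction - f) / (1 - 2 * f)
    if not 0 < target < 1:
        raise ValueError(
            f"minority_fraction {spec.minority_fraction} unattainable at flip_rate {f}"
        )
    intercept = bisect(lambda c: expit(eta + c).mean() - target, -60.0, 60.0, xtol=1e-12)
    p = expit(eta + intercept)
    clean = (rng.uniform(size=spec.n) < p).astype(int)
    flips = rng.uniform(size=spec.n) < f
    y = clean ^ flips
    return TabularBenchmark(
        ids=[f"cmpd{i:05d}" for i in range(spec.n)],
        smiles=[vocab[i] for i in idx],
        descriptors=desc,
        y=y.astype(int),
        truth={
            "beta": beta,
            "intercept": float(intercept),
            "probabilities": p,
            "clean_labels": clean,
            "flips": flips,
            "realized_positive_fraction": float(y.mean()),
        },
    )


# ---------------------------------------------------------------------------
# graph benchmark: labels planted on a substructure rule


@dataclass(frozen=True)
class GraphBenchSpec:
    n: int = 500
    rule: str = "aromatic_nitrogen"
    flip_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule not in RULE_REGISTRY:
            raise KeyError(f"rule {self.rule!r} not in registry {sorted(RULE_REGISTRY)}")
        if not 0 <= self.flip_rate < 0.5:
            raise ValueError("flip_rate must be in [0, 0.5)")


@dataclass
class GraphBenchmark:
    ids: list[str]
    smiles: list[str]
    y: np.ndarray
    truth: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"compound_id": self.ids, "smiles": self.smiles, "label": self.y}
        )


def generate_graph_benchmark(spec: GraphBenchSpec) -> GraphBenchmark:
    """Sample molecules and plant label = rule(molecule) XOR flip."""
    vocab = molecule_vocabulary()
    rule = RULE_REGISTRY[spec.rule]
    rule_bits = np.array([rule(Chem.MolFromSmiles(s)) for s in vocab], dtype=int)
    if rule_bits.sum() == 0 or rule_bits.sum() == len(vocab):
        raise ValueError(f"rule {spec.rule!r} is constant on the vocabulary")
    rng = np.random.default_rng(spec.seed)
    idx = rng.integers(0, len(vocab), size=spec.n)
    clean = rule_bits[idx]
    flips = rng.uniform(size=spec.n) < spec.flip_rate
    y = clean ^ flips
    return GraphBenchmark(
        ids=[f"cmpd{i:05d}" for i in range(spec.n)],
        smiles=[vocab[i] for i in idx],
        y=y.astype(int),
        truth={"rule": spec.rule, "clean_labels": clean, "flips": flips},
    )


# ---------------------------------------------------------------------------
# screening fixture: planted gate/score/toxicity funnel


@dataclass(frozen=True)
class ScreenFixtureSpec:
    n: int = 50
    gate_rate: float = 0.5
    activity_rate: float = 0.5
    toxicity_rate: float = 0.3
    score_threshold: int = 5
    seed: int = 7

    def __post_init__(self) -> None:
        for r in (self.gate_rate, self.activity_rate, self.toxicity_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class ScreenFixture:
    schema: AttributeSchema
    table: pd.DataFrame           # (n, n_attributes) probabilities
    toxic: pd.Series              # bool per compound
    truth: dict                   # planted bits and expected stage counts


def generate_screen_fixture(spec: ScreenFixtureSpec) -> ScreenFixture:
    """Draw planted binary truths per attribute, then probabilities that
    binarize back to the truth exactly at 0.5 (positives in (0.5, 1],
    negatives in [0, 0.5)); expected stage counts come from brute-force
    evaluation of the gate -> score -> toxicity funnel on those bits."""
    schema = default_schema()
    rng = np.random.default_rng(spec.seed)
    ids = [f"cand{i:04d}" for i in range(spec.n)]
    gate_id = schema.gate_attribute.attribute_id
    activity_ids = [a.attribute_id for a in schema.activity_attributes]

    bits = {gate_id: (rng.uniform(size=spec.n) < spec.gate_rate).astype(int)}
    for a in activity_ids:
        bits[a] = (rng.uniform(size=spec.n) < spec.activity_rate).astype(int)
    toxic = rng.uniform(size=spec.n) < spec.toxicity_rate

    probs = {}
    for a in schema.attribute_ids:
        pos = rng.uniform(0.55, 0.95, size=spec.n)
        neg = rng.uniform(0.05, 0.45, size=spec.n)
        probs[a] = np.where(bits[a] == 1, pos, neg)
    table = pd.DataFrame(probs, index=pd.Index(ids, name="compound_id"))

    score = np.sum([bits[a] for a in activity_ids], axis=0)
    gate_pass = bits[gate_id] == 1
    score_pass = gate_pass & (score >= spec.score_threshold)
    final = score_pass & ~toxic
    truth = {
        "bits": bits,
        "score": score,
        "toxic": toxic,
        "stage_counts": {
            "n_input": spec.n,
            "n_gate_pass": int(gate_pass.sum()),
            "n_score_pass": int(score_pass.sum()),
            "n_nontoxic": int(final.sum()),
        },
        "final_hits": [i for i, keep in zip(ids, final) if keep],
        "score_threshold": spec.score_threshold,
    }
    return ScreenFixture(
        schema=schema,
        table=table,
        toxic=pd.Series(toxic, index=table.index, name="toxic"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# meta-analysis fixture


def generate_meta_fixture(
    k: int, true_log_effect: float, se_range: tuple[float, float] = (0.05, 0.3), seed: int = 0
) -> tuple[list[StudyEffect], dict]:
    """k studies with theta_i ~ Normal(true_log_effect, se_i^2) and
    se_i ~ Uniform(se_range)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    se = rng.uniform(se_range[0], se_range[1], size=k)
    theta = rng.normal(true_log_effect, se)
    studies = [StudyEffect(f"study{i:03d}", float(theta[i]), float(se[i])) for i in range(k)]
    return studies, {"true_log_effect": true_log_effect, "se": se}


# ---------------------------------------------------------------------------
# dataset assembly helpers


def benchmark_to_dataset(
    benchmark: TabularBenchmark | GraphBenchmark,
    schema: AttributeSchema,
    attribute_id: str,
) -> CompoundDataset:
    """Wrap a single-attribute benchmark as a schema-valid compound
    dataset (other attribute columns all-missing)."""
    j = schema.attribute_ids.index(attribute_id)
    records = []
    for cid, smi, label in zip(benchmark.ids, benchmark.smiles, benchmark.y):
        labels: list[int | None] = [None] * len(schema)
        labels[j] = int(label)
        records.append(CompoundRecord(cid, smi, tuple(labels)))
    return CompoundDataset(schema, records)
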