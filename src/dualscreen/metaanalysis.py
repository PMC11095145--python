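"""Common-effect (fixed-effect) meta-analysis of log hazard ratios.

Studies are pooled by inverse-variance weighting on the log scale and
exponentiated for reporting.  Heterogeneity is quantified by Cochran's Q
and I^2 = max(0, (Q - df)/Q) * 100, classified into the (deliberately
overlapping) Cochrane bands: minor (<= 40%), moderate (30-60%),
substantial (50-90%), considerable (> 75%); every band containing the
observed I^2 is reported.  Small-study / publication bias is assessed by
the Egger regression of standardized effects on precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = 1.96  # conventional 95% normal quantile

HETEROGENEITY_BANDS = (
    ("minor", 0.0, 40.0),
    ("moderate", 30.0, 60.0),
    ("substantial", 50.0, 90.0),
    ("considerable", 75.0, 100.0),
)


@dataclass(frozen=True)
class StudyEffect:
    study_id: str
    log_effect: float  # log hazard ratio
    se: float          # standard error of the log effect

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"study {self.study_id!r}: se must be > 0, got {self.se}")


@dataclass
class MetaResult:
    pooled_log_effect: float
    pooled_se: float
    pooled_effect: float
    ci_low: float
    ci_high: float
    q: float
    df: int
    i2: float                       # percent, [0, 100]
    heterogeneity_bands: tuple[str, ...]
    k: int


def pool_fixed(studies: list[StudyEffect]) -> MetaResult:
    """Inverse-variance common-effect pooling.

    weights w_i = 1/se_i^2; pooled = sum(w_i theta_i)/sum(w_i);
    pooled_se = sum(w_i)^{-1/2}; 95% CI = exp(pooled +/- 1.96 se);
    Q = sum w_i (theta_i - pooled)^2.
    """
    if not studies:
        raise ValueError("need at least one study")
    theta = np.array([s.log_effect for s in studies], dtype=float)
    se = np.array([s.se for s in studies], dtype=float)
    w = 1.0 / se**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(studies) - 1
    i2 = 0.0 if q <= df or q == 0 else (q - df) / q * 100.0
    return MetaResult(
        pooled_log_effect=pooled,
        pooled_se=pooled_se,
        pooled_effect=math.exp(pooled),
        ci_low=math.exp(pooled - Z_95 * pooled_se),
        ci_high=math.exp(pooled + Z_95 * pooled_se),
        q=q,
        df=df,
        i2=i2,
        heterogeneity_bands=classify_heterogeneity(i2),
        k=len(studies),
    )


def egger_test(studies: list[StudyEffect]) -> tuple[float, float, float]:
    """Egger regression: OLS of theta_i/se_i on 1/se_i with intercept.

    Returns (intercept, intercept_se, two-sided p from a t-test with k-2
    degrees of freedom).  A nonzero intercept suggests small-study bias.
    """
    k = len(studies)
    if k < 3:
        raise ValueError("Egger test needs at least 3 studies")
    se = np.array([s.se for s in studies], dtype=float)
    theta = np.array([s.log_effect for s in studies], dtype=float)
    x = 1.0 / se
    if np.allclose(x, x[0]):
        raise ValueError("all standard errors equal: precision has no variance")
    y = theta / se
    design = np.column_stack([np.ones(k), x])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = k - 2
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    intercept = float(beta[0])
    intercept_se = float(math.sqrt(cov[0, 0]))
    if intercept_se == 0.0:
        p_value = 0.0 if intercept != 0 else 1.0
    else:
        t = intercept / intercept_se
        p_value = float(2 * stats.t.sf(abs(t), dof))
    return intercept, intercept_se, p_value


def classify_heterogeneity(i2: float) -> tuple[str, ...]:
    """All Cochrane bands whose interval contains ``i2`` (in percent)."""
    if not 0 <= i2 <= 100:
        raise ValueError(f"I^2 must be in [0, 100], got {i2}")
    bands = []
    for name, low, high in HETEROGENEITY_BANDS:
        if name == "considerable":
            if i2 > low:
                bands.append(name)
        elif low <= i2 <= high:
            bands.append(name)
    return tuple(bands)


def read_studies(path: str | Path) -> list[StudyEffect]:
    """Read a study table.  Either (log_effect, se) columns or (effect,
    ci_low, ci_high) on the hazard-ratio scale; in the latter case
    se = (log ci_high - log ci_low) / (2 * 1.96)."""
    frame = pd.read_csv(path)
    if "study_id" not in frame.columns:
        raise ValueError("study table needs a study_id column")
    studies = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        if "log_effect" in d and "se" in d and pd.notna(d.get("log_effect")):
            log_effect, se = float(d["log_effect"]), float(d["se"])
        elif {"effect", "ci_low", "ci_high"} <= d.keys():
            log_effect = math.log(float(d["effect"]))
            se = (math.log(float(d["ci_high"])) - math.log(float(d["ci_low"]))) / (2 * Z_95)
        else:
            raise ValueError(
                "study table needs (log_effect, se) or (effect, ci_low, ci_high) columns"
            )
        studies.append(StudyEffect(str(d["study_id"]), log_effect, se))
    return studies
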