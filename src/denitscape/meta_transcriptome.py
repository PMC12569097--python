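"""Effect-size meta-analysis of metatranscriptome delta statistics.

Soil studies manipulated carbon availability in paired designs, so the
carbon effect on transcript deltas is summarized as a bias-corrected
standardized mean difference (Hedges g, carbon-enriched treatment vs.
lower-carbon reference) pooled by inverse variance. Aquatic studies
were observational: per-study Spearman correlations between deltas and
environmental variables are pooled sample-size-weighted, with two
filter fractions of the same study first averaged into a single
study-level effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

Z95 = 1.959963984540054


@dataclass(frozen=True)
class EffectSize:
    study_id: str
    kind: str  # "smd" or "correlation"
    value: float
    variance: float
    n: int
    fraction_group: str | None = None

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("sampling variance must be positive")
        if self.kind == "correlation" and abs(self.value) > 1:
            raise ValueError("|r| must not exceed 1")


@dataclass(frozen=True)
class PooledEffect:
    value: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    k_studies: int
    q: float = float("nan")
    i_squared: float = float("nan")
    tau_squared: float = 0.0


def hedges_g(
    treat: Sequence[float], ctrl: Sequence[float], study_id: str = ""
) -> EffectSize:
    """Bias-corrected standardized mean difference (treatment - control).

    g = J * (mean_t - mean_c) / s_pooled with the small-sample
    correction J = 1 - 3 / (4 * (n_t + n_c - 2) - 1); the sampling
    variance uses the standard large-sample formula.
    """
    t = np.asarray(treat, dtype=float)
    c = np.asarray(ctrl, dtype=float)
    if len(t) < 2 or len(c) < 2:
        raise ValueError("both groups need at least two values")
    n1, n2 = len(t), len(c)
    df = n1 + n2 - 2
    s_pooled = math.sqrt(
        ((n1 - 1) * t.var(ddof=1) + (n2 - 1) * c.var(ddof=1)) / df
    )
    if s_pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    j = 1 - 3 / (4 * df - 1)
    g = j * (t.mean() - c.mean()) / s_pooled
    variance = (n1 + n2) / (n1 * n2) + g**2 / (2 * (n1 + n2))
    return EffectSize(
        study_id=study_id, kind="smd", value=g, variance=variance, n=n1 + n2
    )


def pool_smd(
    effects: Sequence[EffectSize], random_effects: bool = False
) -> PooledEffect:
    """Inverse-variance pooled standardized mean difference.

    Fixed-effect by default; ``random_effects`` switches to
    DerSimonian-Laird, adding the moment estimate of the between-study
    variance tau^2 to every study's variance. Heterogeneity (Cochran's
    Q and I^2) is always reported.
    """
    if not effects:
        raise ValueError("no effects to pool")
    kinds = {e.kind for e in effects}
    if kinds != {"smd"}:
        raise ValueError(f"pool_smd requires smd effects only, got {sorted(kinds)}")
    g = np.array([e.value for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / v
    fixed = (w * g).sum() / w.sum()
    q = float((w * (g - fixed) ** 2).sum())
    k = len(effects)
    dfree = k - 1
    i2 = max(0.0, (q - dfree) / q) if q > 0 and dfree > 0 else 0.0
    tau2 = 0.0
    if random_effects and dfree > 0:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - dfree) / denom) if denom > 0 else 0.0
        w = 1.0 / (v + tau2)
    pooled = float((w * g).sum() / w.sum())
    se = float(math.sqrt(1.0 / w.sum()))
    z = pooled / se
    p = float(2 * stats.norm.sf(abs(z)))
    return PooledEffect(
        value=pooled,
        se=se,
        ci_low=pooled - Z95 * se,
        ci_high=pooled + Z95 * se,
        p_value=p,
        k_studies=k,
        q=q,
        i_squared=i2,
        tau_squared=tau2,
    )


def pool_correlations(effects: Sequence[EffectSize]) -> PooledEffect:
    """Sample-size weighted mean of study-level Spearman correlations.

    Effects sharing a study_id but differing in fraction_group (two
    filter sizes from one sample) are first averaged into one
    study-level effect, so a study never counts twice. The CI is a
    normal approximation from the weighted SE of the study effects; for
    a single study the large-sample variance of r is used instead.
    """
    if not effects:
        raise ValueError("no effects to pool")
    kinds = {e.kind for e in effects}
    if kinds != {"correlation"}:
        raise ValueError(
            f"pool_correlations requires correlation effects, got {sorted(kinds)}"
        )
    by_study: dict[str, list[EffectSize]] = {}
    for e in effects:
        if e.n is None or e.n <= 0:
            raise ValueError(f"study {e.study_id!r}: sample size missing")
        by_study.setdefault(e.study_id, []).append(e)
    r = np.array([np.mean([e.value for e in grp]) for grp in by_study.values()])
    n = np.array([np.mean([e.n for e in grp]) for grp in by_study.values()])
    k = len(by_study)
    mean_r = float((n * r).sum() / n.sum())
    if k == 1:
        se = float((1 - r[0] ** 2) / math.sqrt(max(n[0] - 1, 1)))
    else:
        weighted_var = float((n * (r - mean_r) ** 2).sum() / n.sum()) * k / (k - 1)
        se = math.sqrt(weighted_var / k)
    z = mean_r / se if se > 0 else float("inf")
    p = float(2 * stats.norm.sf(abs(z)))
    return PooledEffect(
        value=mean_r,
        se=se,
        ci_low=mean_r - Z95 * se,
        ci_high=mean_r + Z95 * se,
        p_value=p,
        k_studies=k,
    )
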