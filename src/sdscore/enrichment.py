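"""Statistical comparison of causal (positive) vs. neutral (negative)
variants: one-tailed Fisher's exact tests on categorical features,
two-tailed pooled-variance t-tests on continuous measures, and selection of
the deleterious-direction feature set."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("sdscore.enrichment")

ENRICHED_IN_POSITIVE = "enriched_in_positive"
ENRICHED_IN_NEGATIVE = "enriched_in_negative"

#: canonical deleterious-direction feature order
DELETERIOUS_FEATURES = (
    "high_del_count", "large_grantham", "gly_pro_change", "buried",
    "on_patch", "in_domain", "destabilizing",
)
#: neutral-compatible features, tested for enrichment in negatives
NEUTRAL_FEATURES = ("fully_conserved", "highly_dynamic_site",
                    "highly_flexible_site")
#: additional causal-direction candidates, reported but never scored
EXTRA_CAUSAL_FEATURES = ("disulfide_change", "conformationally_rigid",
                         "strong_destabilizing")


@dataclass
class EnrichmentResult:
    """One 2x2 feature-by-class test.

    ``a``/``b`` count positives with/without the feature, ``c``/``d`` the
    negatives; the one-tailed p is in the declared direction.
    """

    feature_name: str
    a: int
    b: int
    c: int
    d: int
    direction: str
    p_one_tailed: float
    significant: bool


@dataclass
class TTestResult:
    parameter_name: str
    t_ratio: float
    df: int
    p_two_tailed: float


def fisher_one_tailed(a: int, b: int, c: int, d: int,
                      direction: str = ENRICHED_IN_POSITIVE) -> float:
    """Exact one-tailed hypergeometric p for a 2x2 table.

    Rows are (positive, negative) classes, columns (feature present,
    absent).  ``enriched_in_positive`` sums tables at least as extreme
    toward a higher feature rate among positives; equals brute-force
    enumeration over all tables with the same margins.  An all-zero table
    gives p = 1 by convention (logged).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b + c + d == 0:
        logger.warning("empty 2x2 table; p = 1 by convention")
        return 1.0
    alternative = "greater" if direction == ENRICHED_IN_POSITIVE else "less"
    return float(stats.fisher_exact([[a, b], [c, d]],
                                    alternative=alternative).pvalue)


def ttest_unpaired(x: Sequence[float], y: Sequence[float],
                   parameter_name: str = "") -> TTestResult:
    """Pooled-variance two-sample t-test with df = n1 + n2 - 2.

    Zero pooled variance with equal means gives t = 0, p = 1.
    """
    x = np.asarray([v for v in x if v is not None], dtype=float)
    y = np.asarray([v for v in y if v is not None], dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 non-missing values")
    df = len(x) + len(y) - 2
    res = stats.ttest_ind(x, y, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t):  # degenerate: no variance in either sample
        t, p = 0.0, 1.0
    return TTestResult(parameter_name, t, df, p)


_FEATURE_DIRECTIONS = {
    **{f: ENRICHED_IN_POSITIVE
       for f in DELETERIOUS_FEATURES + EXTRA_CAUSAL_FEATURES},
    **{f: ENRICHED_IN_NEGATIVE for f in NEUTRAL_FEATURES},
}


def compute_feature_enrichment(
    flag_table: pd.DataFrame,
    alpha: float = 0.05,
    bonferroni: bool = False,
    features: Optional[Sequence[str]] = None,
) -> list:
    """Fisher tests for every feature column of a per-variant flag table.

    ``flag_table`` needs a ``class`` column ("positive"/"negative"; other
    labels ignored) and one boolean-or-missing column per feature.  Each
    feature is tested one-tailed in its a-priori direction; rows with a
    missing flag are excluded from that feature's table only.
    """
    if features is None:
        features = [f for f in _FEATURE_DIRECTIONS if f in flag_table.columns]
    pos = flag_table[flag_table["class"] == "positive"]
    neg = flag_table[flag_table["class"] == "negative"]
    threshold = alpha / len(features) if (bonferroni and features) else alpha
    results = []
    for feat in features:
        direction = _FEATURE_DIRECTIONS.get(feat, ENRICHED_IN_POSITIVE)
        pv, nv = pos[feat].dropna(), neg[feat].dropna()
        a, b = int((pv == True).sum()), int((pv == False).sum())  # noqa: E712
        c, d = int((nv == True).sum()), int((nv == False).sum())  # noqa: E712
        p = fisher_one_tailed(a, b, c, d, direction)
        results.append(EnrichmentResult(feat, a, b, c, d, direction, p,
                                        p <= threshold))
    return results


def select_deleterious_features(results: Sequence[EnrichmentResult],
                                alpha: float = 0.05) -> tuple:
    """Split significant features into the deleterious-direction set (in
    canonical order) and the neutral-compatible set.

    Only the canonical seven are eligible for the deleterious set; an empty
    set is logged (the composite score is then undefined and the pipeline
    may fall back to the canonical seven from config).  Conservation is
    never part of the deleterious set regardless of direction — its
    direction is inconsistent across cohorts and is only reported.
    """
    by_name = {}
    for r in results:
        sig = r.significant if alpha is None else r.p_one_tailed <= alpha
        by_name[r.feature_name] = (r, sig)
    selected = [f for f in DELETERIOUS_FEATURES
                if f in by_name and by_name[f][1]
                and by_name[f][0].direction == ENRICHED_IN_POSITIVE]
    neutral = [f for f in NEUTRAL_FEATURES + ("fully_conserved",)
               if f in by_name and by_name[f][1]
               and by_name[f][0].direction == ENRICHED_IN_NEGATIVE]
    neutral = list(dict.fromkeys(neutral))
    if not selected:
        logger.warning("no feature significantly enriched in positives; "
                       "deleterious feature set is empty")
    return selected, neutral
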