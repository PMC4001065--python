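"""The structural disruption score (SDS) and the priority list.

Each missense variant receives seven boolean deleterious-direction flags
(high deleteriousness count, large Grantham change, Gly/Pro involvement,
buried site, conserved surface patch, protein domain, destabilizing ddG);
the SDS is the number of true flags (0-7).  Variants scoring at or above
the priority threshold are partitioned by gene tolerance (RVIS), pruned of
neutral-compatible cases (highly flexible sites), and — for low-tolerance
genes — admitted only with supporting disease curation.  A step-wise
leave-one-component-out regression measures how each flag contributes to
the correlation with an external composite deleteriousness score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import seqfeat, structfeat
from .enrichment import DELETERIOUS_FEATURES, NEUTRAL_FEATURES
from .io_formats import AnnotationBundle, VariantRecord
from .structfeat import DynamicsCutoffs, ThresholdConfig

logger = logging.getLogger("sdscore.score")

TOLERANCE_HIGH, TOLERANCE_LOW, TOLERANCE_UNKNOWN = "high", "low", "unknown"


@dataclass
class FeatureVector:
    """Seven deleterious-direction flags plus the neutral-direction ones.

    ``None`` means the upstream measurement was missing; a missing flag
    counts as false in the score but is tallied separately.
    """

    high_del_count: Optional[bool] = None
    large_grantham: Optional[bool] = None
    gly_pro_change: Optional[bool] = None
    buried: Optional[bool] = None
    on_patch: Optional[bool] = None
    in_domain: Optional[bool] = None
    destabilizing: Optional[bool] = None
    highly_flexible_site: Optional[bool] = None
    highly_dynamic_site: Optional[bool] = None
    fully_conserved: Optional[bool] = None

    def deleterious_flags(self) -> dict:
        return {name: getattr(self, name) for name in DELETERIOUS_FEATURES}


@dataclass
class SDSRecord:
    variant: VariantRecord
    bundle: AnnotationBundle
    feature_vector: FeatureVector
    sds: int
    n_missing_features: int
    priority: bool
    tolerance_class: str = TOLERANCE_UNKNOWN
    excluded: bool = False
    final_priority: bool = False


def build_feature_vector(
    variant: VariantRecord,
    bundle: AnnotationBundle,
    config: ThresholdConfig,
    dynamics_cutoffs: Optional[DynamicsCutoffs] = None,
    rsa_percent: Optional[float] = None,
) -> FeatureVector:
    """Boundary-inclusive thresholding of the merged annotations.

    ``rsa_percent`` computed from a structure overrides the consumed RSA
    column; missing upstream values give missing flags.
    """
    if dynamics_cutoffs is None:
        dynamics_cutoffs = DynamicsCutoffs(
            bfactor=config.bfactor_fixed_cutoffs,
            rmsf=config.rmsf_fixed_cutoffs,
            p_flexible=config.pflexible_fixed_cutoffs)
    del_count = seqfeat.deleterious_count(bundle)
    cons_count = seqfeat.conservation_count(bundle)
    rsa = rsa_percent if rsa_percent is not None else bundle.rsa_percent
    dyn_b, _, flex = structfeat.classify_dynamics_and_flexibility(
        bundle, dynamics_cutoffs)
    return FeatureVector(
        high_del_count=(None if del_count.n_available == 0
                        else del_count.count >= config.del_count_min),
        large_grantham=(seqfeat.grantham_distance(variant.ref_aa,
                                                  variant.alt_aa)
                        >= config.grantham_min),
        gly_pro_change=seqfeat.is_gly_pro_change(variant.ref_aa,
                                                 variant.alt_aa),
        buried=(None if rsa is None
                else rsa <= config.rsa_buried_max_percent),
        on_patch=bundle.on_patch,
        in_domain=bundle.in_domain,
        destabilizing=(None if bundle.ddg is None
                       else bundle.ddg >= config.ddg_destabilizing_min),
        highly_flexible_site=(None if flex is None
                              else flex == structfeat.CONF_FLEXIBLE),
        highly_dynamic_site=(None if dyn_b is None
                             else dyn_b == structfeat.HIGHLY_DYNAMIC),
        fully_conserved=(None if cons_count.n_available == 0
                         else cons_count.count == 3),
    )


def compute_sds(fv: FeatureVector) -> int:
    """Count of true deleterious-direction flags (0-7)."""
    return sum(bool(v) for v in fv.deleterious_flags().values() if v is True)


def n_missing_features(fv: FeatureVector) -> int:
    return sum(v is None for v in fv.deleterious_flags().values())


def score_variants(
    pairs: Sequence[tuple],
    config: Optional[ThresholdConfig] = None,
    dynamics_cutoffs: Optional[DynamicsCutoffs] = None,
    rsa_by_variant: Optional[dict] = None,
) -> list:
    """Score a cohort: derive pooled dynamics cutoffs, build the feature
    vector of every variant and flag those meeting the priority threshold.

    ``rsa_by_variant`` optionally maps a variant key to a structure-derived
    RSA that overrides the annotation column.
    """
    config = config or ThresholdConfig()
    if dynamics_cutoffs is None:
        dynamics_cutoffs = structfeat.derive_dynamics_cutoffs(
            [b for _, b in pairs], config)
    records = []
    for variant, bundle in pairs:
        rsa = (rsa_by_variant or {}).get(variant.key)
        fv = build_feature_vector(variant, bundle, config, dynamics_cutoffs,
                                  rsa_percent=rsa)
        sds = compute_sds(fv)
        records.append(SDSRecord(
            variant=variant, bundle=bundle, feature_vector=fv, sds=sds,
            n_missing_features=n_missing_features(fv),
            priority=sds >= config.sds_priority_min))
    logger.info("scored %d variants; %d at priority threshold >= %d",
                len(records), sum(r.priority for r in records),
                config.sds_priority_min)
    return records


def partition_by_tolerance(records: Sequence[SDSRecord]) -> list:
    """Assign the gene-tolerance class from RVIS.

    Positive RVIS (more common variation than expected) is high tolerance;
    negative is low; exactly zero means "as expected" and is classed high
    (logged); missing RVIS gives unknown.
    """
    for rec in records:
        rvis = rec.bundle.rvis
        if rvis is None:
            rec.tolerance_class = TOLERANCE_UNKNOWN
        elif rvis > 0:
            rec.tolerance_class = TOLERANCE_HIGH
        elif rvis < 0:
            rec.tolerance_class = TOLERANCE_LOW
        else:
            logger.info("%s: RVIS exactly 0 classed as high tolerance",
                        rec.variant.gene_symbol)
            rec.tolerance_class = TOLERANCE_HIGH
    return list(records)


def apply_neutral_exclusion(records: Sequence[SDSRecord]) -> list:
    """Disregard priority variants whose site is highly flexible — the one
    structural feature characteristic of neutral variants.  Exclusion only
    prunes the priority list; non-priority records are never marked."""
    for rec in records:
        rec.excluded = bool(rec.priority
                            and rec.feature_vector.highly_flexible_site is True)
    return list(records)


def finalize_priority(records: Sequence[SDSRecord]) -> list:
    """Resolve the final priority list after tolerance partition/exclusion.

    High-tolerance priority variants survive unless excluded; low-tolerance
    priority variants additionally need an explicit "likely" disease
    curation.  Returns all records sorted by descending score (gene and
    position break ties).
    """
    if not any(rec.bundle.epilepsy_curation is not None for rec in records):
        logger.warning("no curation column present; low-tolerance variants "
                       "cannot enter the final list")
    for rec in records:
        high_ok = (rec.priority and not rec.excluded
                   and rec.tolerance_class == TOLERANCE_HIGH)
        low_ok = (rec.priority and rec.tolerance_class == TOLERANCE_LOW
                  and rec.bundle.epilepsy_curation == "likely")
        rec.final_priority = bool(high_ok or low_ok)
    ordered = sorted(records, key=lambda r: (-r.sds, r.variant.gene_symbol,
                                             r.variant.protein_position))
    logger.info("final priority list: %d of %d records",
                sum(r.final_priority for r in ordered), len(ordered))
    return ordered


def run_pipeline(pairs: Sequence[tuple],
                 config: Optional[ThresholdConfig] = None) -> list:
    """Score, partition, exclude and finalize in the fixed stage order."""
    records = score_variants(pairs, config)
    partition_by_tolerance(records)
    apply_neutral_exclusion(records)
    return finalize_priority(records)


def flags_table(records: Sequence[SDSRecord]) -> pd.DataFrame:
    """Per-variant flag table (class + all feature columns) for enrichment."""
    rows = []
    for rec in records:
        fv = rec.feature_vector
        rows.append({
            "gene": rec.variant.gene_symbol,
            "class": rec.variant.class_label,
            **{f: getattr(fv, f) for f in DELETERIOUS_FEATURES},
            **{f: getattr(fv, f) for f in NEUTRAL_FEATURES},
        })
    return pd.DataFrame(rows)


def stepwise_correlation(records: Sequence[SDSRecord]) -> pd.DataFrame:
    """Leave-one-component-out regression of the SDS on a composite score.

    Row 0 regresses the full SDS against the external composite score
    (simple linear least squares; R^2 and the two-tailed p of the slope);
    each further row drops one component, recomputes the score from the
    remaining six flags, and reports how many records' scores changed.
    """
    paired = [r for r in records if r.bundle.composite_score is not None]
    if len(paired) < 3:
        raise ValueError("need >= 3 records with a composite score")
    composite = np.array([r.bundle.composite_score for r in paired])

    def regress(scores, label, n_affected):
        if np.ptp(scores) == 0:
            logger.warning("constant score when dropping %s; correlation "
                           "undefined", label)
            return {"dropped_component": label, "r_squared": np.nan,
                    "p_value": np.nan, "n_affected": n_affected}
        fit = stats.linregress(scores, composite)
        return {"dropped_component": label,
                "r_squared": float(fit.rvalue ** 2),
                "p_value": float(fit.pvalue),
                "n_affected": n_affected}

    full = np.array([r.sds for r in paired], dtype=float)
    rows = [regress(full, "none", 0)]
    for feat in DELETERIOUS_FEATURES:
        drop = np.array([bool(getattr(r.feature_vector, feat) is True)
                         for r in paired])
        rows.append(regress(full - drop, feat, int(drop.sum())))
    return pd.DataFrame(rows)
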