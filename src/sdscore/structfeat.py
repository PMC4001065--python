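"""Structure-derived residue features and their categorization.

Relative solvent accessibility (rolling-probe SASA against an extended
Ala-X-Ala tripeptide reference) and burial, DSSP secondary-structure
grouping, long-range stabilization-center detection, and the
stability / sequence-optimality / dynamics / flexibility categories with
their empirical percentile thresholds.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import biotite.structure as bst
import numpy as np

from .io_formats import AnnotationBundle, Structure

logger = logging.getLogger("sdscore.structfeat")

# burial / secondary structure / stability class labels
BURIED, EXPOSED = "buried", "exposed"
SS_GROUPS = ("GHI", "E", "TB", "S", "C")
NO_CHANGE = "no_change"
MILD_STABILIZING = "mild_stabilizing"
STRONG_STABILIZING = "strong_stabilizing"
MILD_DESTABILIZING = "mild_destabilizing"
STRONG_DESTABILIZING = "strong_destabilizing"
NORMAL = "normal"
HIGHLY_NONOPTIMAL = "highly_nonoptimal"
HIGHLY_RIGID = "highly_rigid"
HIGHLY_DYNAMIC = "highly_dynamic"
CONF_RIGID = "conformationally_rigid"
CONF_FLEXIBLE = "conformationally_flexible"

#: per-element van der Waals radii (Angstrom), used for SASA and contacts
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
VDW_DEFAULT = 1.70

PROBE_RADIUS = 1.4      # Angstrom, rolling probe for SASA
SASA_POINTS = 2000      # sphere points per atom in the production setting


@dataclass
class ThresholdConfig:
    """Every cutoff of the scoring scheme, with the published defaults.

    Stability bands are in kcal/mol; the dynamics/flexibility fixed cutoffs
    are the published fallbacks used when too few pooled values exist to
    derive empirical percentiles.
    """

    del_count_min: int = 4
    grantham_min: float = 100.0
    rsa_buried_max_percent: float = 20.0
    ddg_destabilizing_min: float = 0.5      # mild band [0.5, 4)
    ddg_strong_destabilizing_min: float = 4.0
    ddg_stabilizing_max: float = -0.5       # mild band (-2, -0.5]
    ddg_strong_stabilizing_max: float = -2.0
    gamma_nonoptimal_max: float = -5.0
    bfactor_tails: tuple = (2.5, 97.5)      # percent
    rmsf_tails: tuple = (0.5, 99.5)
    pflexible_tails: tuple = (2.5, 97.5)
    bfactor_fixed_cutoffs: tuple = (-0.537, 1.17)
    rmsf_fixed_cutoffs: tuple = (-0.607, 1.195)
    pflexible_fixed_cutoffs: tuple = (0.158, 0.860)
    flexible_site_rigid_max: float = 0.74
    sds_priority_min: int = 4
    alpha: float = 0.05
    bonferroni: bool = False
    min_values_for_percentiles: int = 40
    max_asa_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ddg_strong_stabilizing_max < self.ddg_stabilizing_max
                < self.ddg_destabilizing_min < self.ddg_strong_destabilizing_min):
            raise ValueError("stability bands out of order")
        for lo, hi in (self.bfactor_tails, self.rmsf_tails, self.pflexible_tails):
            if not (0 < lo < 50 < hi < 100):
                raise ValueError("tail percentiles must bracket the median")

    @classmethod
    def from_dict(cls, data: Optional[dict]) -> "ThresholdConfig":
        data = dict(data or {})
        for key in ("bfactor_tails", "rmsf_tails", "pflexible_tails",
                    "bfactor_fixed_cutoffs", "rmsf_fixed_cutoffs",
                    "pflexible_fixed_cutoffs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


class ResidueStructuralFeatures(NamedTuple):
    rsa_percent: Optional[float]
    burial_class: Optional[str]
    ss_group: Optional[str]
    sc_residue: Optional[bool]
    stability_class: Optional[str]
    optimality_class: Optional[str]
    dynamics_class_b: Optional[str]
    dynamics_class_rmsf: Optional[str]
    flexibility_class: Optional[str]


# ---------------------------------------------------------------------------
# solvent accessibility
# ---------------------------------------------------------------------------

def _atom_radii(structure: Structure) -> np.ndarray:
    return np.array([VDW_RADII.get(el, VDW_DEFAULT) for el in structure.element])


def compute_sasa(structure: Structure, probe_radius: float = PROBE_RADIUS,
                 n_points: int = SASA_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley, Angstrom^2)."""
    arr = bst.AtomArray(structure.n_atoms)
    arr.coord = structure.coords.astype(np.float32)
    arr.chain_id = np.array(structure.chain_id)
    arr.res_id = structure.res_seq
    arr.res_name = np.array(structure.res_name)
    arr.atom_name = np.array(structure.atom_name)
    arr.element = np.array(structure.element)
    arr.hetero = np.zeros(structure.n_atoms, dtype=bool)
    return bst.sasa(arr, probe_radius=probe_radius, point_number=n_points,
                    vdw_radii=_atom_radii(structure))


@functools.lru_cache(maxsize=None)
def max_asa(residue_name: str, probe_radius: float = PROBE_RADIUS,
            n_points: int = SASA_POINTS) -> float:
    """Maximal accessibility of residue X, from an extended Ala-X-Ala
    tripeptide built with ideal geometry and the same probe and radii as
    :func:`compute_sasa`.  Cached per residue type."""
    from .synthetic_data import build_peptide  # deferred: avoids module cycle

    tri = build_peptide(["ALA", residue_name, "ALA"], phi=180.0, psi=180.0)
    per_atom = compute_sasa(tri, probe_radius=probe_radius, n_points=n_points)
    return float(per_atom[tri.atom_mask("A", 2)].sum())


def compute_rsa(structure: Structure, chain: str, residue_seq: int,
                config: Optional[ThresholdConfig] = None,
                sasa_per_atom: Optional[np.ndarray] = None) -> Optional[float]:
    """Relative solvent accessibility (%) of one residue.

    Residue SASA divided by the Ala-X-Ala reference maximum for its type,
    times 100; uncapped (extended conformations may exceed 100).  Returns
    ``None`` (logged) if the residue is absent from the structure.
    """
    mask = structure.atom_mask(chain, residue_seq)
    if not mask.any():
        logger.warning("residue %s/%d absent from structure; RSA missing",
                       chain, residue_seq)
        return None
    if sasa_per_atom is None:
        sasa_per_atom = compute_sasa(structure)
    res_name = structure.res_name[int(np.flatnonzero(mask)[0])]
    overrides = config.max_asa_overrides if config else {}
    reference = overrides.get(res_name, None)
    if reference is None:
        reference = max_asa(res_name)
    return float(sasa_per_atom[mask].sum()) / reference * 100.0


def compute_rsa_table(structure: Structure,
                      config: Optional[ThresholdConfig] = None) -> dict:
    """RSA for every residue, computing the structure SASA once."""
    per_atom = compute_sasa(structure)
    return {
        (ch, seq): compute_rsa(structure, ch, seq, config, per_atom)
        for ch, seq, _ in structure.residues()
    }


def classify_burial(rsa_percent: Optional[float],
                    config: ThresholdConfig) -> Optional[str]:
    """Buried iff RSA <= the cutoff (boundary inclusive), else exposed."""
    if rsa_percent is None:
        return None
    if rsa_percent < 0:
        raise ValueError("rsa_percent must be >= 0")
    return BURIED if rsa_percent <= config.rsa_buried_max_percent else EXPOSED


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

_SS_GROUPING = {"G": "GHI", "H": "GHI", "I": "GHI", "E": "E",
                "T": "TB", "B": "TB", "S": "S", "C": "C"}


def group_secondary_structure(ss_code: str) -> str:
    """Collapse the 8 DSSP letters into 5 groups: helices (G/H/I), strand
    (E), short-bonded turns/bridges (T/B), bend (S) and coil (C)."""
    try:
        return _SS_GROUPING[ss_code]
    except KeyError:
        raise ValueError(f"unknown DSSP code {ss_code!r}")


# ---------------------------------------------------------------------------
# stabilization centers
# ---------------------------------------------------------------------------

def detect_stabilization_centers(
    structure: Structure,
    min_separation: int = 10,
    contact_margin: float = 1.0,
) -> tuple:
    """Long-range stabilization-center candidate pairs.

    A residue pair within one chain is a candidate iff the residues are at
    least ``min_separation`` apart in sequence and some heavy-atom pair
    between them lies closer than the sum of the two van der Waals radii
    plus ``contact_margin`` (Angstrom).  Returns the set of pairs
    ``((chain, seq_i), (chain, seq_j))`` with ``seq_i < seq_j`` and the
    flattened set of member residues.
    """
    from scipy.spatial import cKDTree

    radii = _atom_radii(structure)
    max_contact = 2 * max(VDW_RADII.values()) + contact_margin
    tree = cKDTree(structure.coords)
    pairs: set = set()
    for i, j in tree.query_pairs(max_contact):
        if structure.chain_id[i] != structure.chain_id[j]:
            continue
        si, sj = int(structure.res_seq[i]), int(structure.res_seq[j])
        if abs(si - sj) < min_separation:
            continue
        dist = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
        if dist < radii[i] + radii[j] + contact_margin:
            ch = structure.chain_id[i]
            pairs.add(((ch, min(si, sj)), (ch, max(si, sj))))
    residues = {r for pair in pairs for r in pair}
    return pairs, residues


# ---------------------------------------------------------------------------
# categorization of continuous measures
# ---------------------------------------------------------------------------

def classify_stability(ddg: Optional[float],
                       config: ThresholdConfig) -> Optional[str]:
    """Four-level stability-change category from a predicted ddG.

    no change within (-0.5, 0.5); mildly stabilizing (-2, -0.5]; strongly
    stabilizing <= -2; mildly destabilizing [0.5, 4); strongly
    destabilizing >= 4 (all kcal/mol, defaults).
    """
    if ddg is None:
        return None
    if ddg <= config.ddg_strong_stabilizing_max:
        return STRONG_STABILIZING
    if ddg <= config.ddg_stabilizing_max:
        return MILD_STABILIZING
    if ddg < config.ddg_destabilizing_min:
        return NO_CHANGE
    if ddg < config.ddg_strong_destabilizing_min:
        return MILD_DESTABILIZING
    return STRONG_DESTABILIZING


def classify_optimality(gamma: Optional[float],
                        config: ThresholdConfig) -> Optional[str]:
    """Highly non-optimal iff the summed stabilizing-mutation energy at the
    site is <= -5 kcal/mol (default), a proxy for catalytic/binding sites."""
    if gamma is None:
        return None
    return HIGHLY_NONOPTIMAL if gamma <= config.gamma_nonoptimal_max else NORMAL


def derive_empirical_thresholds(
    values: Iterable,
    lower_tail_pct: float,
    upper_tail_pct: float,
    fallback: Optional[tuple] = None,
    min_values: int = 40,
) -> tuple:
    """Tail cutoffs as percentiles of the pooled score distribution.

    Linear interpolation between order statistics.  With fewer than
    ``min_values`` non-missing values the fixed ``fallback`` cutoffs are
    returned instead (logged); without a fallback this is an error.
    """
    arr = np.array([v for v in values if v is not None and np.isfinite(v)],
                   dtype=float)
    if arr.size < min_values:
        if fallback is not None:
            logger.warning(
                "only %d values pooled (< %d); using fixed fallback cutoffs %s",
                arr.size, min_values, fallback)
            return tuple(fallback)
        raise ValueError(f"need >= {min_values} values, got {arr.size}")
    lo = float(np.percentile(arr, lower_tail_pct, method="linear"))
    hi = float(np.percentile(arr, upper_tail_pct, method="linear"))
    return lo, hi


class DynamicsCutoffs(NamedTuple):
    """Lower/upper tail cutoffs for the three dynamics measures."""
    bfactor: tuple
    rmsf: tuple
    p_flexible: tuple


def derive_dynamics_cutoffs(bundles: Sequence[AnnotationBundle],
                            config: ThresholdConfig) -> DynamicsCutoffs:
    """Pool all given variants and derive the three cutoff pairs, falling
    back to the fixed published cutoffs when the pool is too small."""
    def tails(attr, pcts, fallback):
        return derive_empirical_thresholds(
            [getattr(b, attr) for b in bundles], pcts[0], pcts[1],
            fallback=fallback, min_values=config.min_values_for_percentiles)

    return DynamicsCutoffs(
        bfactor=tails("bfactor_norm", config.bfactor_tails,
                      config.bfactor_fixed_cutoffs),
        rmsf=tails("rmsf_norm", config.rmsf_tails, config.rmsf_fixed_cutoffs),
        p_flexible=tails("p_flexible", config.pflexible_tails,
                         config.pflexible_fixed_cutoffs),
    )


def classify_dynamics_and_flexibility(
    bundle: AnnotationBundle,
    cutoffs: DynamicsCutoffs,
) -> tuple:
    """Tail-membership classes for B-factor, RMSF and P(Flexible).

    Boundary inclusive on both tails (<= lower, >= upper); missing inputs
    give missing classes.
    """
    def dyn(value, pair):
        if value is None:
            return None
        lo, hi = pair
        if value <= lo:
            return HIGHLY_RIGID
        if value >= hi:
            return HIGHLY_DYNAMIC
        return NORMAL

    flex = None
    if bundle.p_flexible is not None:
        lo, hi = cutoffs.p_flexible
        if bundle.p_flexible <= lo:
            flex = CONF_RIGID
        elif bundle.p_flexible >= hi:
            flex = CONF_FLEXIBLE
        else:
            flex = NORMAL
    return (dyn(bundle.bfactor_norm, cutoffs.bfactor),
            dyn(bundle.rmsf_norm, cutoffs.rmsf),
            flex)


def characterize_residue(
    bundle: AnnotationBundle,
    config: ThresholdConfig,
    cutoffs: DynamicsCutoffs,
    rsa_percent: Optional[float] = None,
    sc_residue: Optional[bool] = None,
) -> ResidueStructuralFeatures:
    """Merge all structural categorizations for one variant residue.

    RSA and stabilization-center membership computed from a structure take
    precedence over the consumed annotation columns when supplied.
    """
    rsa = rsa_percent if rsa_percent is not None else bundle.rsa_percent
    sc = sc_residue if sc_residue is not None else bundle.sc_residue
    dyn_b, dyn_r, flex = classify_dynamics_and_flexibility(bundle, cutoffs)
    return ResidueStructuralFeatures(
        rsa_percent=rsa,
        burial_class=classify_burial(rsa, config),
        ss_group=(group_secondary_structure(bundle.ss_code)
                  if bundle.ss_code else None),
        sc_residue=sc,
        stability_class=classify_stability(bundle.ddg, config),
        optimality_class=classify_optimality(bundle.gamma, config),
        dynamics_class_b=dyn_b,
        dynamics_class_rmsf=dyn_r,
        flexibility_class=flex,
    )
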