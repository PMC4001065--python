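"""Sequence-level features of an amino acid substitution.

Grantham physico-chemical distance, aggregation of the six deleteriousness
and three conservation predictor calls, glycine/proline involvement, and
the disulfide-bond change indicator.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import NamedTuple, Optional

import numpy as np

from .io_formats import (
    AnnotationBundle, Structure, VariantRecord,
    AA1, CONSERVED, DELETERIOUS,
    CONSERVATION_CALL_FIELDS, DELETERIOUS_CALL_FIELDS,
)

logger = logging.getLogger("sdscore.seqfeat")

# ---------------------------------------------------------------------------
# Grantham distance
# ---------------------------------------------------------------------------
# The published 20x20 matrix (Grantham 1974) is primary; it is what
# downstream annotation tools cite.  The composition/polarity/volume formula
# below reproduces it to integer rounding and serves as a cross-check.

_GRANTHAM_ORDER = "SRLPTAVGIFYCHQNKDEMW"

# upper triangle in _GRANTHAM_ORDER, row by row
_GRANTHAM_UPPER = (
    (110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177),   # S
    (102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101),            # R
    (98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61),                # L
    (38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147),                    # P
    (58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128),                           # T
    (64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148),                          # A
    (109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88),                                 # V
    (135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184),                                   # G
    (21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61),                                        # I
    (22, 205, 100, 116, 158, 102, 177, 140, 28, 40),                                           # F
    (194, 83, 99, 143, 85, 160, 122, 36, 37),                                                  # Y
    (174, 154, 139, 202, 154, 170, 196, 215),                                                  # C
    (24, 68, 32, 81, 40, 87, 115),                                                             # H
    (46, 53, 61, 29, 101, 130),                                                                # Q
    (94, 23, 42, 142, 174),                                                                    # N
    (101, 56, 95, 110),                                                                        # K
    (45, 160, 181),                                                                            # D
    (126, 152),                                                                                # E
    (67,),                                                                                     # M
)

GRANTHAM_MATRIX: dict = {}
for _i, _a in enumerate(_GRANTHAM_ORDER):
    GRANTHAM_MATRIX[(_a, _a)] = 0
    for _j, _d in enumerate(_GRANTHAM_UPPER[_i] if _i < len(_GRANTHAM_UPPER)
                            else ()):
        _b = _GRANTHAM_ORDER[_i + 1 + _j]
        GRANTHAM_MATRIX[(_a, _b)] = _d
        GRANTHAM_MATRIX[(_b, _a)] = _d
GRANTHAM_MATRIX[("W", "W")] = 0

# per-residue composition (c), polarity (p) and molecular volume (v)
GRANTHAM_COMPOSITION = dict(
    S=1.42, R=0.65, L=0.0, P=0.39, T=0.71, A=0.0, V=0.0, G=0.74, I=0.0,
    F=0.0, Y=0.20, C=2.75, H=0.58, Q=0.89, N=1.33, K=0.33, D=1.38, E=0.92,
    M=0.0, W=0.13)
GRANTHAM_POLARITY = dict(
    S=9.2, R=10.5, L=4.9, P=8.0, T=8.6, A=8.1, V=5.9, G=9.0, I=5.2, F=5.2,
    Y=6.2, C=5.5, H=10.4, Q=10.5, N=11.6, K=11.3, D=13.0, E=12.3, M=5.7,
    W=5.4)
GRANTHAM_VOLUME = dict(
    S=32, R=124, L=111, P=32.5, T=61, A=31, V=84, G=3, I=111, F=132, Y=136,
    C=55, H=96, Q=85, N=56, K=119, D=54, E=83, M=105, W=170)

# weighting constants; the global scale is fixed so the mean over all 190
# unordered pairs equals 100
_ALPHA, _BETA, _GAMMA = 1.833, 0.1018, 0.000399


def _unscaled(a: str, b: str) -> float:
    return math.sqrt(
        _ALPHA * (GRANTHAM_COMPOSITION[a] - GRANTHAM_COMPOSITION[b]) ** 2
        + _BETA * (GRANTHAM_POLARITY[a] - GRANTHAM_POLARITY[b]) ** 2
        + _GAMMA * (GRANTHAM_VOLUME[a] - GRANTHAM_VOLUME[b]) ** 2)


_RHO = 100.0 / np.mean([_unscaled(a, b)
                        for a, b in itertools.combinations(_GRANTHAM_ORDER, 2)])


def grantham_distance(ref_aa: str, alt_aa: str) -> int:
    """Grantham (1974) physico-chemical distance between two residues.

    Returns the published matrix entry exactly; ``distance(a, a) == 0``.
    """
    try:
        return GRANTHAM_MATRIX[(ref_aa, alt_aa)]
    except KeyError:
        raise ValueError(f"non-standard amino acid pair ({ref_aa}, {alt_aa})")


def grantham_distance_from_properties(ref_aa: str, alt_aa: str) -> float:
    """Recompute the distance from the c/p/v property formula (cross-check).

    Agrees with the published matrix to integer rounding for 188 of the 190
    pairs; N-E and D-W deviate in the original publication itself.
    """
    if ref_aa not in AA1 or alt_aa not in AA1:
        raise ValueError(f"non-standard amino acid pair ({ref_aa}, {alt_aa})")
    return _RHO * _unscaled(ref_aa, alt_aa)


# ---------------------------------------------------------------------------
# predictor call aggregation
# ---------------------------------------------------------------------------

class PredictorCount(NamedTuple):
    """A call count together with how many calls were available."""
    count: int
    n_available: int


def deleterious_count(bundle: AnnotationBundle) -> PredictorCount:
    """Number of the six deleteriousness predictors calling the variant
    deleterious (maximum 6); missing calls contribute 0 to the count but are
    reflected in ``n_available`` so low-coverage variants can be filtered."""
    calls = [getattr(bundle, f) for f in DELETERIOUS_CALL_FIELDS]
    return PredictorCount(sum(c == DELETERIOUS for c in calls),
                          sum(c is not None for c in calls))


def conservation_count(bundle: AnnotationBundle) -> PredictorCount:
    """Number of the three conservation scores calling the site conserved
    (maximum 3); missing calls contribute 0."""
    calls = [getattr(bundle, f) for f in CONSERVATION_CALL_FIELDS]
    return PredictorCount(sum(c == CONSERVED for c in calls),
                          sum(c is not None for c in calls))


def is_gly_pro_change(ref_aa: str, alt_aa: str) -> bool:
    """True iff the substitution involves glycine or proline on either side."""
    if ref_aa not in AA1 or alt_aa not in AA1:
        raise ValueError(f"non-standard amino acid pair ({ref_aa}, {alt_aa})")
    return ref_aa in "GP" or alt_aa in "GP"


# ---------------------------------------------------------------------------
# disulfide change
# ---------------------------------------------------------------------------

#: two cysteine S-gamma atoms this close (Angstrom) are considered bonded
DISULFIDE_SG_CUTOFF = 2.5


def bonded_cysteines(structure: Structure, cutoff: float = DISULFIDE_SG_CUTOFF) -> set:
    """Residue numbers of cysteines whose SG lies within ``cutoff`` of
    another cysteine SG (any chain)."""
    idx = [i for i in range(structure.n_atoms)
           if structure.res_name[i] == "CYS" and structure.atom_name[i] == "SG"]
    bonded: set = set()
    for i, j in itertools.combinations(idx, 2):
        if np.linalg.norm(structure.coords[i] - structure.coords[j]) < cutoff:
            bonded.add(int(structure.res_seq[i]))
            bonded.add(int(structure.res_seq[j]))
    return bonded


def disulfide_change(
    variant: VariantRecord,
    bonded_cys_positions: Optional[set] = None,
    structure: Optional[Structure] = None,
) -> Optional[bool]:
    """Does the substitution create or remove a bonded cysteine?

    True iff the variant gains or loses a Cys at a position in the bonded
    set.  The bonded set comes from an upstream connectivity prediction
    column, or — when absent and a structure is given — from SG-SG geometry
    (< 2.5 Angstrom).  If neither source exists and Cys is involved, the
    result is missing (``None``), not ``False``.
    """
    if variant.ref_aa != "C" and variant.alt_aa != "C":
        return False
    if bonded_cys_positions is None and structure is not None:
        bonded_cys_positions = bonded_cysteines(structure)
    if bonded_cys_positions is None:
        logger.warning(
            "%s %s%d%s involves Cys but no disulfide prediction or structure "
            "is available; disulfide change is missing",
            variant.gene_symbol, variant.ref_aa, variant.protein_position,
            variant.alt_aa)
        return None
    return variant.protein_position in bonded_cys_positions
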