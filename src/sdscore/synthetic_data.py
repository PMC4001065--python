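"""Synthetic cohorts and toy structures for download-free testing.

The cohort generator plants class-conditional feature enrichment with the
contrasts the scoring scheme assumes (causal variants carry each
deleterious-direction feature more often than neutral ones), and keeps the
ground-truth flag states in a side table so tests can check parameter
recovery.  Where a feature is thresholded from a continuous measure (ddG,
RSA, P(Flexible)) the continuous value is drawn and the flag derived from
it, never sampled separately.

The structure generator builds idealized peptides from standard bond
geometry, with full heavy-atom side chains taken from the chemical
component dictionary and superimposed on the backbone.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import biotite.structure.info as bstinfo
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import seqfeat
from .io_formats import (
    AnnotationBundle, Structure, VariantRecord,
    AA1, AA1_TO_3, CONSERVED, NOT_CONSERVED, DELETERIOUS, TOLERATED,
    CONSERVATION_CALL_FIELDS, DELETERIOUS_CALL_FIELDS, DSSP_CODES,
)
from .structfeat import ThresholdConfig

# ---------------------------------------------------------------------------
# idealized peptide geometry
# ---------------------------------------------------------------------------

# standard backbone internal coordinates (Angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position atom d from three predecessors and internal coordinates."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  bond * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _ccd_heavy(res_name: str):
    """Ideal heavy-atom template for one residue from the bundled CCD."""
    arr = bstinfo.residue(res_name)
    arr = arr[(arr.element != "H") & (arr.atom_name != "OXT")]
    return arr


def build_peptide(sequence: Sequence[str], phi: float, psi: float,
                  omega: float = 180.0, chain: str = "A") -> Structure:
    """Build a peptide with uniform backbone torsions and ideal side chains.

    ``sequence`` is a list of 3-letter (or 1-letter) residue codes.  The
    N/CA/C trace comes from standard bond lengths and angles; the remaining
    heavy atoms of each residue are superimposed from its ideal chemical-
    component geometry via its own N/CA/C triad.  phi = psi = 180 gives a
    fully extended chain; phi = -57, psi = -47 an alpha helix (1.5 Angstrom
    rise, ~100 degrees twist per residue).
    """
    names = [AA1_TO_3[r] if len(r) == 1 else r.upper() for r in sequence]
    n_res = len(names)
    backbone = np.zeros((n_res, 3, 3))  # (residue, [N, CA, C], xyz)
    backbone[0, 0] = (0.0, 0.0, 0.0)
    backbone[0, 1] = (_B_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - _A_N_CA_C)
    backbone[0, 2] = backbone[0, 1] + _B_CA_C * np.array(
        [math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[i - 1]
        n_i = _place(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_i = _place(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, omega)
        c_i = _place(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        backbone[i] = (n_i, ca_i, c_i)

    chain_id, res_seq, res_name, atom_name, element, coords = ([], [], [], [],
                                                               [], [])
    for i, name in enumerate(names):
        template = _ccd_heavy(name)
        t_names = list(template.atom_name)
        triad_idx = [t_names.index(a) for a in ("N", "CA", "C")]
        t_triad = template.coord[triad_idx].astype(float)
        b_triad = backbone[i]
        rot, _ = Rotation.align_vectors(b_triad - b_triad.mean(axis=0),
                                        t_triad - t_triad.mean(axis=0))
        placed = rot.apply(template.coord.astype(float) - t_triad.mean(axis=0)) \
            + b_triad.mean(axis=0)
        for k, aname in enumerate(t_names):
            if aname == "N":
                xyz = backbone[i, 0]
            elif aname == "CA":
                xyz = backbone[i, 1]
            elif aname == "C":
                xyz = backbone[i, 2]
            else:
                xyz = placed[k]
            chain_id.append(chain)
            res_seq.append(i + 1)
            res_name.append(name)
            atom_name.append(aname)
            element.append(str(template.element[k]).upper())
            coords.append(xyz)
    return Structure(chain_id, np.array(res_seq), res_name, atom_name,
                     element, np.array(coords))


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi_angle = np.arccos(1 - 2 * k / n)
    theta = math.pi * (1 + 5 ** 0.5) * k
    return radius * np.stack([np.cos(theta) * np.sin(phi_angle),
                              np.sin(theta) * np.sin(phi_angle),
                              np.cos(phi_angle)], axis=1)


def generate_toy_structure(kind: str, n_residues: int = 12,
                           sequence: Optional[Sequence[str]] = None) -> Structure:
    """Idealized test structures: "helix", "extended" or "shell".

    helix/extended are poly-alanine unless ``sequence`` is given; shell is
    one full alanine residue enclosed by a dense sphere of carbon dummy
    atoms (one single-atom glycine per point) so its accessibility is ~0.
    """
    if n_residues < 3:
        raise ValueError("n_residues must be >= 3")
    seq = list(sequence) if sequence is not None else ["ALA"] * n_residues
    if kind == "helix":
        return build_peptide(seq, phi=-57.0, psi=-47.0)
    if kind == "extended":
        return build_peptide(seq, phi=180.0, psi=180.0)
    if kind == "shell":
        core = build_peptide(["ALA"], phi=180.0, psi=180.0)
        points = _fibonacci_sphere(400, radius=6.0)
        chain_id = list(core.chain_id) + ["A"] * len(points)
        res_seq = np.concatenate([core.res_seq,
                                  np.arange(2, 2 + len(points))])
        res_name = list(core.res_name) + ["GLY"] * len(points)
        atom_name = list(core.atom_name) + ["CA"] * len(points)
        element = list(core.element) + ["C"] * len(points)
        coords = np.vstack([core.coords, points])
        return Structure(chain_id, res_seq, res_name, atom_name, element,
                         coords)
    raise ValueError(f"unknown toy structure kind {kind!r}")


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

#: deleterious-direction features the generator plants
PLANTED_FEATURES = ("high_del_count", "large_grantham", "gly_pro_change",
                    "buried", "on_patch", "in_domain", "destabilizing")

_DEFAULT_THRESHOLDS = ThresholdConfig()


def _aa_pair_buckets() -> dict:
    """Ordered amino-acid pairs bucketed by (gly/pro involved, Grantham>=100)."""
    buckets = {(gp, big): [] for gp in (False, True) for big in (False, True)}
    for a, b in itertools.permutations(AA1, 2):
        gp = a in "GP" or b in "GP"
        big = seqfeat.grantham_distance(a, b) >= _DEFAULT_THRESHOLDS.grantham_min
        buckets[(gp, big)].append((a, b))
    return buckets


_PAIR_BUCKETS = _aa_pair_buckets()


@dataclass
class SyntheticSpec:
    """Generator settings; the defaults emulate the study conditions of a
    small exome-derived cohort (30 case / 1674 neutral / 100 causal
    variants with structural annotations)."""

    n_case: int = 30
    n_negative: int = 1674
    n_positive: int = 100
    #: per-feature probability of each deleterious-direction flag
    p_flag_positive: float = 0.5
    p_flag_negative: float = 0.1
    #: probability of the highly-flexible (neutral-compatible) flag
    p_flexible_positive: float = 0.01
    p_flexible_negative: float = 0.08
    #: fully-conserved (conservation count 3/3), enriched in neutrals
    p_conserved_positive: float = 0.10
    p_conserved_negative: float = 0.25
    ddg_mu_positive: float = 1.5     # kcal/mol
    ddg_mu_negative: float = 0.3
    ddg_sigma: float = 1.0
    rvis_sigma: float = 0.5
    #: fraction of case variants drawn with causal-like feature probabilities
    p_case_causal: float = 0.3
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_flag_positive", "p_flag_negative",
                     "p_flexible_positive", "p_flexible_negative",
                     "p_conserved_positive", "p_conserved_negative",
                     "p_case_causal"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_case, self.n_negative, self.n_positive) < 0:
            raise ValueError("cohort sizes must be >= 0")


class Cohort(NamedTuple):
    pairs: list       # (VariantRecord, AnnotationBundle)
    truth: pd.DataFrame


def _beta_b(tail_prob: float, threshold: float) -> float:
    # Beta(1, b) has P(X >= t) = (1 - t)^b
    return math.log(max(tail_prob, 1e-12)) / math.log(1.0 - threshold)


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Deterministic labelled cohort with planted feature enrichment.

    Every column the pipeline consumes is populated; continuous values are
    drawn first and thresholded flags derived from them.  The truth table
    records the planted flag states per variant.
    """
    rng = np.random.default_rng(spec.random_seed)
    cfg = _DEFAULT_THRESHOLDS
    flex_cut = cfg.pflexible_fixed_cutoffs[1]
    pairs, truth_rows = [], []
    classes = (["case"] * spec.n_case + ["negative"] * spec.n_negative
               + ["positive"] * spec.n_positive)
    for idx, label in enumerate(classes):
        causal_like = (label == "positive"
                       or (label == "case"
                           and rng.random() < spec.p_case_causal))
        p_flag = spec.p_flag_positive if causal_like else spec.p_flag_negative
        p_flex = (spec.p_flexible_positive if causal_like
                  else spec.p_flexible_negative)
        p_cons = (spec.p_conserved_positive if causal_like
                  else spec.p_conserved_negative)
        ddg_mu = spec.ddg_mu_positive if causal_like else spec.ddg_mu_negative

        # sequence identity: amino-acid pair chosen to realize the planted
        # gly/pro and Grantham flags exactly
        glypro = rng.random() < p_flag
        large_grantham = rng.random() < p_flag
        bucket = _PAIR_BUCKETS[(glypro, large_grantham)]
        ref_aa, alt_aa = bucket[rng.integers(len(bucket))]

        high_del = rng.random() < p_flag
        del_count = int(rng.integers(4, 7) if high_del else rng.integers(0, 4))
        del_idx = rng.permutation(6)[:del_count]
        del_calls = {f: (DELETERIOUS if i in del_idx else TOLERATED)
                     for i, f in enumerate(DELETERIOUS_CALL_FIELDS)}

        conserved = rng.random() < p_cons
        cons_count = 3 if conserved else int(rng.integers(0, 3))
        cons_idx = rng.permutation(3)[:cons_count]
        cons_calls = {f: (CONSERVED if i in cons_idx else NOT_CONSERVED)
                      for i, f in enumerate(CONSERVATION_CALL_FIELDS)}

        buried = rng.random() < p_flag
        # values are rounded before the flag is derived so the emitted table
        # and the truth table can never disagree at a threshold boundary
        rsa = round(float(rng.uniform(0, cfg.rsa_buried_max_percent) if buried
                          else rng.uniform(cfg.rsa_buried_max_percent + 0.01,
                                           100)), 2)
        ddg = round(float(rng.normal(ddg_mu, spec.ddg_sigma)), 3)
        destabilizing = ddg >= cfg.ddg_destabilizing_min
        p_flexible = float(rng.beta(1.0, _beta_b(p_flex, flex_cut)))
        on_patch = bool(rng.random() < p_flag)
        in_domain = bool(rng.random() < p_flag)

        flags = {
            "high_del_count": del_count >= cfg.del_count_min,
            "large_grantham": large_grantham,
            "gly_pro_change": glypro,
            "buried": buried,
            "on_patch": on_patch,
            "in_domain": in_domain,
            "destabilizing": destabilizing,
        }
        composite = sum(flags.values()) / 7.0 + float(rng.normal(0, 0.15))

        variant = VariantRecord(
            gene_symbol=f"GENE{idx:04d}",
            protein_position=int(rng.integers(1, 501)),
            ref_aa=ref_aa, alt_aa=alt_aa, class_label=label,
            maf_afr=float(rng.uniform(0, 0.05)),
            maf_eur=float(rng.uniform(0, 0.05)),
        )
        bundle = AnnotationBundle(
            **del_calls, **cons_calls,
            ddg=ddg,
            gamma=round(float(rng.normal(-1.0, 1.5)), 3),
            bfactor_norm=round(float(rng.normal(0, 1)), 3),
            rmsf_norm=round(float(rng.normal(0, 1)), 3),
            p_flexible=round(min(p_flexible, 1.0), 4),
            rsa_percent=rsa,
            ss_code=DSSP_CODES[rng.integers(len(DSSP_CODES))],
            on_patch=on_patch, in_domain=in_domain,
            sc_residue=bool(rng.random() < 0.05),
            disulfide_involved=bool(rng.random() < 0.02),
            rvis=round(float(rng.normal(0, spec.rvis_sigma)), 3),
            composite_score=round(composite, 4),
            epilepsy_curation=(lambda lvl: None if lvl == "na" else lvl)(
                str(rng.choice(["likely", "maybe", "less_likely", "no", "na"],
                               p=[0.10, 0.15, 0.15, 0.40, 0.20]))),
        )
        truth_rows.append({"gene": variant.gene_symbol, "class": label,
                           "causal_like": causal_like, **flags})
        pairs.append((variant, bundle))
    return Cohort(pairs, pd.DataFrame(truth_rows))
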