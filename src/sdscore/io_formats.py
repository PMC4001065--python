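"""Readers and writers for the external representations of the pipeline.

Variant annotation tables are tab-separated files with a header row; every
column beyond the five required ones (gene, position, ref/alt amino acid,
class label) is optional and may be missing per cell ("NA" or empty).
Protein structures are read from PDB v3 ATOM records.  Configuration is a
nestable key-value (YAML) file holding thresholds, a column-dialect mapping
and optional raw-score-to-call conversions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("sdscore.io")

# categorical call values
DELETERIOUS = "deleterious"
TOLERATED = "tolerated"
CONSERVED = "conserved"
NOT_CONSERVED = "not_conserved"

CLASS_LABELS = ("case", "negative", "positive")

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# "na"/empty curation cells are read as missing — no recorded opinion
CURATION_LEVELS = ("likely", "maybe", "less_likely", "no")

DSSP_CODES = "GHIETBSC"


@dataclass
class VariantRecord:
    """One missense substitution with class label and identifiers."""

    gene_symbol: str
    protein_position: int
    ref_aa: str
    alt_aa: str
    class_label: str
    transcript_id: Optional[str] = None
    nucleotide_change: Optional[str] = None
    maf_afr: Optional[float] = None
    maf_eur: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref_aa not in AA1 or self.alt_aa not in AA1:
            raise ValueError(
                f"non-standard amino acid code in {self.gene_symbol} "
                f"{self.ref_aa}{self.protein_position}{self.alt_aa}"
            )
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"{self.gene_symbol} position {self.protein_position}: "
                "reference and alternate amino acids are identical (not missense)"
            )
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.protein_position < 1:
            raise ValueError("protein_position must be >= 1")

    @property
    def key(self) -> tuple:
        return (self.gene_symbol, self.protein_position, self.ref_aa, self.alt_aa)


#: six sequence-based deleteriousness call fields, in canonical order
DELETERIOUS_CALL_FIELDS = (
    "sift_call", "pp2_hdiv_call", "pp2_hvar_call",
    "lrt_call", "mutation_taster_call", "mutation_assessor_call",
)
#: three conservation call fields
CONSERVATION_CALL_FIELDS = ("gerp_call", "phylop_call", "siphy_call")


@dataclass
class AnnotationBundle:
    """All per-variant predictor and structure measurements.

    Every field is optional; ``None`` means missing and is distinct from
    zero / ``False``.  Calls are categorical strings, never raw scores.
    """

    sift_call: Optional[str] = None
    pp2_hdiv_call: Optional[str] = None
    pp2_hvar_call: Optional[str] = None
    lrt_call: Optional[str] = None
    mutation_taster_call: Optional[str] = None
    mutation_assessor_call: Optional[str] = None
    gerp_call: Optional[str] = None
    phylop_call: Optional[str] = None
    siphy_call: Optional[str] = None
    ddg: Optional[float] = None            # kcal/mol, positive = destabilizing
    gamma: Optional[float] = None          # kcal/mol, sequence non-optimality
    bfactor_norm: Optional[float] = None
    rmsf_norm: Optional[float] = None
    p_flexible: Optional[float] = None     # probability in [0, 1]
    rsa_percent: Optional[float] = None    # percent, >= 0, may exceed 100
    ss_code: Optional[str] = None          # one of the 8 DSSP letters
    on_patch: Optional[bool] = None
    in_domain: Optional[bool] = None
    sc_residue: Optional[bool] = None
    disulfide_involved: Optional[bool] = None
    rvis: Optional[float] = None           # gene-level tolerance score
    composite_score: Optional[float] = None
    epilepsy_curation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.p_flexible is not None and not 0.0 <= self.p_flexible <= 1.0:
            raise ValueError("p_flexible must be in [0, 1]")
        if self.rsa_percent is not None and self.rsa_percent < 0:
            raise ValueError("rsa_percent must be >= 0")
        if self.ss_code is not None and self.ss_code not in DSSP_CODES:
            raise ValueError(f"unknown DSSP code {self.ss_code!r}")
        if (self.epilepsy_curation is not None
                and self.epilepsy_curation not in CURATION_LEVELS):
            raise ValueError(f"unknown curation level {self.epilepsy_curation!r}")


@dataclass
class Structure:
    """Flat atom table for one PDB structure (model 1, heavy atoms only).

    Residue numbering follows the source PDB verbatim; no renumbering.
    """

    chain_id: list
    res_seq: np.ndarray          # int, per atom
    res_name: list               # 3-letter codes, per atom
    atom_name: list
    element: list
    coords: np.ndarray           # (n_atoms, 3) float, Angstrom

    def __post_init__(self) -> None:
        self.res_seq = np.asarray(self.res_seq, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def residues(self) -> list:
        """Unique (chain_id, res_seq, res_name) in order of appearance."""
        seen, out = set(), []
        for ch, seq, name in zip(self.chain_id, self.res_seq, self.res_name):
            key = (ch, int(seq))
            if key not in seen:
                seen.add(key)
                out.append((ch, int(seq), name))
        return out

    def atom_mask(self, chain: str, residue_seq: int) -> np.ndarray:
        return np.array(
            [c == chain and s == residue_seq
             for c, s in zip(self.chain_id, self.res_seq)], dtype=bool)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigid-body-moved copy (used by invariance tests)."""
        return Structure(
            chain_id=list(self.chain_id),
            res_seq=self.res_seq.copy(),
            res_name=list(self.res_name),
            atom_name=list(self.atom_name),
            element=list(self.element),
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
        )


# ---------------------------------------------------------------------------
# variant annotation tables
# ---------------------------------------------------------------------------

#: canonical (dbNSFP-style snake case) column names; a dialect maps canonical
#: name -> actual header in the file.
CANONICAL_COLUMNS = (
    "gene", "transcript", "position", "ref_aa", "alt_aa", "nt_change",
    "class", "maf_afr", "maf_eur",
    "sift", "pp2_hdiv", "pp2_hvar", "lrt", "mutation_taster",
    "mutation_assessor", "gerp", "phylop", "siphy",
    "ddg", "gamma", "bfactor_norm", "rmsf_norm", "p_flexible",
    "rsa_percent", "ss_code", "on_patch", "in_domain", "sc_residue",
    "disulfide_involved", "rvis", "composite_score", "epilepsy_curation",
)

REQUIRED_COLUMNS = ("gene", "position", "ref_aa", "alt_aa", "class")

_CALL_COLUMN_TO_FIELD = {
    "sift": "sift_call", "pp2_hdiv": "pp2_hdiv_call",
    "pp2_hvar": "pp2_hvar_call", "lrt": "lrt_call",
    "mutation_taster": "mutation_taster_call",
    "mutation_assessor": "mutation_assessor_call",
    "gerp": "gerp_call", "phylop": "phylop_call", "siphy": "siphy_call",
}
_FLOAT_COLUMNS = ("ddg", "gamma", "bfactor_norm", "rmsf_norm", "p_flexible",
                  "rsa_percent", "rvis", "composite_score",
                  "maf_afr", "maf_eur")
_BOOL_COLUMNS = ("on_patch", "in_domain", "sc_residue", "disulfide_involved")

_TRUE = {"yes", "y", "true", "1"}
_FALSE = {"no", "n", "false", "0"}

MISSING_TOKENS = {"", "na"}


def _is_missing(cell: str) -> bool:
    return cell.strip().lower() in MISSING_TOKENS


def _parse_float(cell: str, column: str, row: int):
    if _is_missing(cell):
        return None
    try:
        return float(cell)
    except ValueError:
        logger.warning("row %d: unparseable %s value %r treated as missing",
                       row, column, cell)
        return None


def _parse_bool(cell: str, column: str, row: int):
    token = cell.strip().lower()
    if token in MISSING_TOKENS:
        return None
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    logger.warning("row %d: unparseable %s value %r treated as missing",
                   row, column, cell)
    return None


def _parse_call(cell: str, positive: str, negative: str, column: str, row: int):
    token = cell.strip().lower()
    if token in MISSING_TOKENS:
        return None
    if token == positive:
        return positive
    if token == negative:
        return negative
    logger.warning("row %d: unknown %s call %r treated as missing",
                   row, column, cell)
    return None


def _apply_score_conversion(raw, rule: dict):
    """Dichotomize a raw predictor score using a config rule.

    ``rule`` holds ``cutoff`` plus ``op`` ("le" or "ge") selecting the
    deleterious/conserved side, e.g. SIFT ``{"op": "le", "cutoff": 0.05}``.
    """
    if raw is None:
        return None
    hit = raw <= rule["cutoff"] if rule.get("op", "le") == "le" else raw >= rule["cutoff"]
    positive = rule.get("positive", DELETERIOUS)
    negative = rule.get("negative",
                        TOLERATED if positive == DELETERIOUS else NOT_CONSERVED)
    return positive if hit else negative


def read_variant_table(
    path,
    dialect: Optional[dict] = None,
    score_conversions: Optional[dict] = None,
) -> list:
    """Read a variant annotation TSV into (VariantRecord, AnnotationBundle) pairs.

    ``dialect`` maps canonical column names to the actual file headers.
    ``score_conversions`` maps a predictor column to a dichotomization rule,
    applied only when the categorical call column is absent from the file
    (the conversion is logged).  Unparseable numeric cells become missing
    values and are logged with their row number; row order is preserved.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                     keep_default_na=False)
    colmap = {canon: dialect.get(canon, canon) for canon in CANONICAL_COLUMNS}
    for canon in REQUIRED_COLUMNS:
        if colmap[canon] not in df.columns:
            raise ValueError(
                f"required column {colmap[canon]!r} (for {canon!r}) "
                f"missing from {path}")

    def cell(row, canon):
        name = colmap[canon]
        return row[name] if name in df.columns else ""

    conversions = score_conversions or {}
    pairs = []
    seen_keys = {}
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        variant = VariantRecord(
            gene_symbol=cell(row, "gene").strip(),
            transcript_id=(None if _is_missing(cell(row, "transcript"))
                           else cell(row, "transcript").strip()),
            protein_position=int(cell(row, "position")),
            ref_aa=cell(row, "ref_aa").strip().upper(),
            alt_aa=cell(row, "alt_aa").strip().upper(),
            nucleotide_change=(None if _is_missing(cell(row, "nt_change"))
                               else cell(row, "nt_change").strip()),
            class_label=cell(row, "class").strip().lower(),
            maf_afr=_parse_float(cell(row, "maf_afr"), "maf_afr", i),
            maf_eur=_parse_float(cell(row, "maf_eur"), "maf_eur", i),
        )
        kwargs = {}
        for col, fld in _CALL_COLUMN_TO_FIELD.items():
            positive = CONSERVED if fld in CONSERVATION_CALL_FIELDS else DELETERIOUS
            negative = NOT_CONSERVED if positive == CONSERVED else TOLERATED
            if colmap[col] in df.columns:
                kwargs[fld] = _parse_call(cell(row, col), positive, negative, col, i)
            elif col in conversions:
                raw_col = dialect.get(col + "_score", col + "_score")
                raw = (_parse_float(row[raw_col], raw_col, i)
                       if raw_col in df.columns else None)
                kwargs[fld] = _apply_score_conversion(raw, conversions[col])
                if kwargs[fld] is not None:
                    logger.info("row %d: %s call derived from raw score", i, col)
        for col in _FLOAT_COLUMNS:
            if col in ("maf_afr", "maf_eur"):
                continue
            if colmap[col] in df.columns:
                kwargs[col] = _parse_float(cell(row, col), col, i)
        for col in _BOOL_COLUMNS:
            if colmap[col] in df.columns:
                kwargs[col] = _parse_bool(cell(row, col), col, i)
        if colmap["ss_code"] in df.columns and not _is_missing(cell(row, "ss_code")):
            kwargs["ss_code"] = cell(row, "ss_code").strip().upper()
        if colmap["epilepsy_curation"] in df.columns:
            token = cell(row, "epilepsy_curation").strip().lower().replace(" ", "_")
            if not _is_missing(token):
                # free-text like "likely (drug response)" normalizes to its head
                for level in CURATION_LEVELS:
                    if token.startswith(level):
                        kwargs["epilepsy_curation"] = level
                        break
                else:
                    logger.warning("row %d: unknown curation %r treated as missing",
                                   i, token)
        bundle = AnnotationBundle(**kwargs)
        if variant.key in seen_keys:
            logger.warning("duplicate variant %s at rows %d and %d (both kept)",
                           variant.key, seen_keys[variant.key], i)
        seen_keys.setdefault(variant.key, i)
        pairs.append((variant, bundle))
    logger.info("read %d variant rows from %s", len(pairs), path)
    return pairs


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        return repr(value) if value == value else "NA"
    return str(value)


def write_variant_table(pairs: Iterable[tuple], path) -> None:
    """Write (VariantRecord, AnnotationBundle) pairs back to canonical TSV.

    Non-missing values round-trip exactly through :func:`read_variant_table`;
    missing values are written as "NA".
    """
    rows = []
    for variant, bundle in pairs:
        rows.append({
            "gene": variant.gene_symbol,
            "transcript": _fmt(variant.transcript_id),
            "position": variant.protein_position,
            "ref_aa": variant.ref_aa,
            "alt_aa": variant.alt_aa,
            "nt_change": _fmt(variant.nucleotide_change),
            "class": variant.class_label,
            "maf_afr": _fmt(variant.maf_afr),
            "maf_eur": _fmt(variant.maf_eur),
            **{col: _fmt(getattr(bundle, fld))
               for col, fld in _CALL_COLUMN_TO_FIELD.items()},
            **{col: _fmt(getattr(bundle, col)) for col in _FLOAT_COLUMNS
               if col not in ("maf_afr", "maf_eur")},
            "ss_code": _fmt(bundle.ss_code),
            **{col: _fmt(getattr(bundle, col)) for col in _BOOL_COLUMNS},
            "epilepsy_curation": _fmt(bundle.epilepsy_curation),
        })
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Parse ATOM records of standard residues from a PDB file.

    HETATM records, waters and hydrogens are ignored; of alternate locations
    the first is kept; multi-model files contribute model 1 only.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    model = st[0]
    chain_id, res_seq, res_name, atom_name, element, coords = [], [], [], [], [], []
    for chain in model:
        for residue in chain:
            if residue.het_flag != "A" or residue.name not in AA3_TO_1:
                continue
            seen_names = set()
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                if atom.name in seen_names:   # keep first altloc only
                    continue
                seen_names.add(atom.name)
                chain_id.append(chain.name)
                res_seq.append(residue.seqid.num)
                res_name.append(residue.name)
                atom_name.append(atom.name)
                element.append(atom.element.name.upper())
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not atom_name:
        raise ValueError(f"{path}: no ATOM records of standard residues")
    return Structure(chain_id, np.array(res_seq), res_name, atom_name,
                     element, np.array(coords))


_PDB_ATOM = ("ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
             "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
             "{b:6.2f}          {element:>2s}\n")


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure as PDB v3 ATOM records (plus END)."""
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            name = structure.atom_name[i]
            # PDB atom-name column convention: 1-letter elements start col 14
            padded = f" {name:<3s}" if len(name) < 4 else name
            fh.write(_PDB_ATOM.format(
                serial=i + 1, name=padded, altloc=" ",
                resname=structure.res_name[i], chain=structure.chain_id[i],
                resseq=int(structure.res_seq[i]), icode=" ",
                x=structure.coords[i, 0], y=structure.coords[i, 1],
                z=structure.coords[i, 2], occ=1.0, b=0.0,
                element=structure.element[i]))
        fh.write("END\n")


# ---------------------------------------------------------------------------
# ranked output and enrichment tables
# ---------------------------------------------------------------------------

RANKED_COLUMNS = (
    "gene", "position", "ref_aa", "alt_aa", "class",
    "high_del_count", "large_grantham", "gly_pro_change", "buried",
    "on_patch", "in_domain", "destabilizing",
    "highly_flexible_site", "highly_dynamic_site", "fully_conserved",
    "sds", "n_missing_features", "priority", "tolerance_class",
    "excluded", "final_priority",
)


def write_ranked_table(records: Sequence, path, header_comment: str = "") -> None:
    """Write scored records as a ranked TSV.

    Sorted by descending SDS, ties broken by gene then position.  Output is
    byte-deterministic for a fixed input.
    """
    ordered = sorted(
        records,
        key=lambda r: (-r.sds, r.variant.gene_symbol, r.variant.protein_position))
    rows = []
    for rec in ordered:
        fv = rec.feature_vector
        rows.append({
            "gene": rec.variant.gene_symbol,
            "position": rec.variant.protein_position,
            "ref_aa": rec.variant.ref_aa,
            "alt_aa": rec.variant.alt_aa,
            "class": rec.variant.class_label,
            **{name: _fmt(getattr(fv, name)) for name in (
                "high_del_count", "large_grantham", "gly_pro_change", "buried",
                "on_patch", "in_domain", "destabilizing",
                "highly_flexible_site", "highly_dynamic_site", "fully_conserved")},
            "sds": rec.sds,
            "n_missing_features": rec.n_missing_features,
            "priority": _fmt(rec.priority),
            "tolerance_class": rec.tolerance_class,
            "excluded": _fmt(rec.excluded),
            "final_priority": _fmt(rec.final_priority),
        })
    df = pd.DataFrame(rows, columns=list(RANKED_COLUMNS))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_enrichment_table(results: Sequence, path, header_comment: str = "") -> None:
    """Write feature-enrichment results (feature, 2x2 counts, direction, p)."""
    rows = [{
        "feature": r.feature_name, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
        "direction": r.direction, "p_one_tailed": repr(r.p_one_tailed),
        "significant": _fmt(r.significant),
    } for r in results]
    df = pd.DataFrame(rows, columns=["feature", "a", "b", "c", "d",
                                     "direction", "p_one_tailed", "significant"])
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML run configuration.

    Recognized top-level blocks: ``thresholds`` (cutoff overrides),
    ``dialect`` (column renaming), ``score_conversions`` and ``structures``
    (per-gene PDB file / chain / position offset).  Unknown keys are kept.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
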