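"""Bundled example cohort: 14 candidate epilepsy variants.

These are published homozygous case-exclusive missense substitutions from
an exome study of epilepsy disorders, with their externally predicted
annotations (deleteriousness calls, ddG, RSA, patch/domain membership,
gene-level RVIS, disease curation).  They exercise the full pipeline:
scored with the default thresholds they split into 9 high- and 5
low-tolerance priority variants and yield a 9-variant final list.

Cells whose exact values were not published are filled with representative
values consistent with the published class: exposed-site accessibilities
are set > 20%, and the baseline flexibility probability is 0.30 (below the
flexible cutoff) everywhere except the one variant reported at the 97.75th
flexibility percentile, which gets 0.91 (above the 0.860 cutoff).
"""

from __future__ import annotations

from .io_formats import (
    AnnotationBundle, VariantRecord, DELETERIOUS, TOLERATED,
    DELETERIOUS_CALL_FIELDS,
)

# gene, position, nt_change, ref, alt, del_count, rsa%, patch, domain,
# ddg, gamma, p_flexible, rvis, sc, disulfide, curation
_ROWS = (
    ("ABCA6",   1359, "(4075)TGC > CGC", "C", "R", 6,  2.05, False, True,
     1.64,  None,  0.30,  0.26, None, False, None),
    ("ABHD14A",  227, "(685)CGA > GGA",  "R", "G", 0, 45.00, False, True,
     0.87, -0.58,  0.30,  0.77, None, None,  "less_likely"),
    ("ALOX12",   404, "(1211)CGG > CAG", "R", "Q", 4, 10.55, True,  True,
     0.90,  None,  0.30,  0.80, None, None,  "likely"),
    ("DDX52",    463, "(1064)ATC > ACC", "I", "T", 4,  4.42, False, True,
     1.37,  None,  0.30,  0.05, True, None,  "maybe"),
    ("EPYC",     150, "(449)TCC > TGC",  "S", "C", 5,  0.77, False, True,
     -0.41, None,  0.30,  0.51, True, None,  "no"),
    ("HELB",     506, "(1517)GAT > GGT", "D", "G", 4, 18.27, False, False,
     1.40, -4.14,  0.30,  1.08, None, None,  "likely"),
    ("IAH1",      43, "(127)CTG > GTG",  "L", "V", 4,  4.66, False, True,
     2.06,  None,  0.30,  0.17, None, None,  "likely"),
    ("NMUR1",    137, "(409)CGC > TGC",  "R", "C", 4,  1.17, False, True,
     1.83,  None,  0.30,  0.27, None, None,  "no"),
    ("PALB2",    998, "(2993)GGA > GAA", "G", "E", 5,  2.27, False, False,
     3.23,  None,  0.91,  0.32, None, None,  "no"),
    ("EXOG",     277, "(830)GGA > GTA",  "G", "V", 6, 30.00, False, True,
     1.64,  None,  0.30, -0.45, None, None,  None),
    ("FAAH2",    274, "(821)CGT > CAT",  "R", "H", 4,  0.00, False, True,
     0.95,  None,  0.30, -0.29, None, None,  "maybe"),
    ("MAOA",     125, "(374)AAT > AGT",  "N", "S", 4,  6.65, False, True,
     1.36,  None,  0.30, -0.14, None, None,  "no"),
    ("PPP1R27",  112, "(336)ATA > ATG",  "I", "M", 5,  0.00, False, True,
     1.41,  None,  0.30, -0.32, None, None,  "likely"),
    ("PTPN14",   189, "(566)GAA > GGA",  "E", "G", 4, 35.00, False, True,
     1.79,  None,  0.30, -0.30, None, None,  "no"),
)


def load_example_cohort() -> list:
    """The 14-variant example as (VariantRecord, AnnotationBundle) pairs."""
    pairs = []
    for (gene, pos, nt, ref, alt, del_count, rsa, patch, domain, ddg, gamma,
         p_flex, rvis, sc, disulf, curation) in _ROWS:
        calls = {f: (DELETERIOUS if i < del_count else TOLERATED)
                 for i, f in enumerate(DELETERIOUS_CALL_FIELDS)}
        pairs.append((
            VariantRecord(gene_symbol=gene, protein_position=pos,
                          ref_aa=ref, alt_aa=alt, class_label="case",
                          nucleotide_change=nt),
            AnnotationBundle(**calls, ddg=ddg, gamma=gamma,
                             p_flexible=p_flex, rsa_percent=rsa,
                             on_patch=patch, in_domain=domain,
                             sc_residue=sc, disulfide_involved=disulf,
                             rvis=rvis, epilepsy_curation=curation),
        ))
    return pairs
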