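"""Worked example inputs: the discovery family and its chromosome-12q peak.

`family_a_pedigree` encodes the published four-generation metachondromatosis
discovery pedigree (Family A): an affected founder, nine affected
descendants over three further generations, and one unexamined connector
assumed to be an obligate carrier.  Restricted to founders plus affected
individuals it carries nine phase-resolvable informative meioses, capping
the attainable parametric LOD at 9*log10(2) ~ 2.7.

`chr12_lod_track` encodes the published chromosome-12q peak geometry: a
plateau at the maximum LOD running 107,603,157-116,182,525 (GRCh37), flanked
proximally at 107,595,567 (LOD -5.8) and distally at 116,187,660 (-4.3),
giving a maximum linked interval of 8,592,092 bp.
"""

from __future__ import annotations

import pandas as pd

from .linkage import AFFECTED, UNAFFECTED, UNKNOWN, Individual, Pedigree


def family_a_pedigree() -> Pedigree:
    """Four-generation dominant pedigree with 9 affected non-founders."""
    A, U, K = AFFECTED, UNAFFECTED, UNKNOWN
    inds = [
        # generation I: transmitting founder couple
        Individual("I-1", sex="male", affection=A),
        Individual("I-2", sex="female", affection=U),
        # generation II
        Individual("II-1", sex="female", affection=U),                      # spouse
        Individual("II-2", "I-1", "I-2", sex="male", affection=A),
        Individual("II-3", "I-1", "I-2", sex="male", affection=A),
        Individual("II-4", sex="female", affection=U),                      # spouse
        Individual("II-5", "I-1", "I-2", sex="female", affection=K),       # obligate carrier, not examined
        Individual("II-6", sex="male", affection=U),                       # spouse
        # generation III
        Individual("III-1", "II-2", "II-1", sex="female", affection=A),
        Individual("III-2", "II-2", "II-1", sex="male", affection=A),
        Individual("III-4", sex="female", affection=U),                    # spouse
        Individual("III-5", "II-3", "II-4", sex="female", affection=A),
        Individual("III-9", sex="female", affection=U),                    # unaffected spouse
        Individual("III-10", "II-6", "II-5", sex="male", affection=A),
        # generation IV
        Individual("IV-2", "III-2", "III-4", sex="male", affection=A),
        Individual("IV-5", "III-10", "III-9", sex="female", affection=A),
        Individual("IV-8", "III-10", "III-9", sex="male", affection=A),
    ]
    return Pedigree(inds, family_id="A")


def family_a_informative_marker(pedigree: Pedigree) -> dict[str, float]:
    """A fully informative, co-segregating biallelic marker for Family A.

    The transmitting founder is heterozygous with allele 1 on the disease
    haplotype; every married-in founder is homozygous for allele 0, so each
    affected individual is heterozygous.  Unexamined connectors are untyped.
    Only individuals present in ``pedigree`` are returned, so the same
    genotypes serve the full and the restricted pedigree.
    """
    geno = {
        "I-1": 1, "I-2": 0,
        "II-1": 0, "II-2": 1, "II-3": 1, "II-4": 0, "II-5": None, "II-6": 0,
        "III-1": 1, "III-2": 1, "III-4": 0, "III-5": 1, "III-9": 0, "III-10": 1,
        "IV-2": 1, "IV-5": 1, "IV-8": 1,
    }
    return {iid: g for iid, g in geno.items() if iid in pedigree}


def chr12_lod_track(max_lod: float = 2.7) -> pd.DataFrame:
    """LOD track reproducing the published chromosome-12q peak geometry."""
    rows = [
        ("rs12422243", 120.9, 107_595_567, -5.8),   # proximal flank (excluded)
        ("rs1861693", 121.5, 107_603_157, max_lod),  # first marker of the plateau
        ("rs_mid1", 124.0, 110_000_000, max_lod),
        ("rs_mid2", 128.0, 113_000_000, max_lod),
        ("rs1520173", 132.3, 116_182_525, max_lod),  # last marker of the plateau
        ("rs2460488", 132.9, 116_187_660, -4.3),     # distal flank (excluded)
    ]
    return pd.DataFrame(rows, columns=["marker", "cm", "bp", "lod"])
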