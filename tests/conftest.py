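import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from famseq.examples import family_a_informative_marker, family_a_pedigree
from famseq.linkage import (AFFECTED, UNAFFECTED, DiseaseModel, Individual,
                            Pedigree, restrict_founders_affected)


@pytest.fixture(scope="session")
def family_a():
    return family_a_pedigree()


@pytest.fixture(scope="session")
def family_a_sub(family_a):
    return restrict_founders_affected(family_a)


@pytest.fixture(scope="session")
def family_a_marker(family_a_sub):
    return family_a_informative_marker(family_a_sub)


@pytest.fixture(scope="session")
def model():
    return DiseaseModel()


def nuclear(n_children: int, affected_children: int,
            father_affected=True, genotyped=True) -> tuple[Pedigree, dict]:
    """Founder couple with a carrier father and n children; marker co-segregates."""
    inds = [
        Individual("F", sex="male",
                   affection=AFFECTED if father_affected else UNAFFECTED),
        Individual("M", sex="female", affection=UNAFFECTED),
    ]
    geno = {"F": 1, "M": 0}
    for i in range(n_children):
        aff = AFFECTED if i < affected_children else UNAFFECTED
        inds.append(Individual(f"C{i}", "F", "M", affection=aff))
        geno[f"C{i}"] = 1 if i < affected_children else 0
    if not genotyped:
        geno = {}
    return Pedigree(inds), geno


def make_reads(rows) -> pd.DataFrame:
    """rows: (sample, contig, start, length, strand, qual[, aligned])."""
    recs = []
    for r in rows:
        sample, contig, start, length, strand, qual = r[:6]
        aligned = r[6] if len(r) > 6 else True
        recs.append(dict(sample=sample, contig=contig, start=start,
                         length=length, strand=strand, qual=float(qual),
                         aligned=aligned, duplicate=False))
    return pd.DataFrame(recs)
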