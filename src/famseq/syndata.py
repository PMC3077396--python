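"""Synthetic cohorts with the statistical structure the pipeline assumes.

Every downstream stage — demultiplexing, capture QC, linkage, the filter
cascade, read-depth CNV calling, LOH statistics — is exercised against
cohorts drawn here, so the generator encodes the study design it emulates:
an autosomal-dominant, fully penetrant skeletal trait segregating in small
multigeneration families (with de novo and mosaic-founder options), targeted
capture of a single candidate region sequenced as short single-end barcoded
reads with PCR duplicates and off-target carryover, one causal
loss-of-function variant per family in a shared disease gene plus background
variation, an optional heterozygous multi-kb deletion, and subclone allele
counts drawn from the LOH mixture Binomial(n, (1+f)/2).

Scaling stands in for the real experiment: a single toy contig (default
200 kb) replaces the multi-Mb linked interval, and read counts are scaled to
desk-size depth.  Sequencing error and base-quality structure are not
simulated.  All randomness flows from one seed through named substreams, so
identical configurations give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import yaml

from .capture import TargetRegion, pad_and_merge
from .linkage import AFFECTED, UNAFFECTED, Individual, Pedigree
from .variants import GeneModel, VariantCall, annotate_consequence, normalize_call

DNA = np.array(list("ACGT"))
STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_SPECTRUM = ("frameshift", "nonsense", "splice-acceptor")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class TraitModel:
    dominant: bool = True
    penetrance: float = 1.0
    de_novo: bool = False
    mosaic_founder: bool = False   # founder carries the mutation in a cell fraction
    mosaic_fraction: float = 0.0   # ... and transmits with mosaic_fraction / 2

    def validate(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ValueError("mosaic_fraction must be in [0, 1]")


@dataclass
class PedigreeSpec:
    generations: int = 3
    offspring: int = 2  # children per couple

    def validate(self) -> None:
        if self.generations < 2 or self.offspring < 1:
            raise ValueError("pedigree spec needs >= 2 generations and >= 1 offspring")


@dataclass
class DeletionSpec:
    start: int  # 1-based inclusive
    end: int
    heterozygous: bool = True

    def validate(self, region_length: int) -> None:
        if not 1 <= self.start <= self.end <= region_length:
            raise ValueError("deletion span outside the contig")


@dataclass
class SimConfig:
    """All simulation knobs; defaults are the emulated study conditions."""
    seed: int = 0
    n_families: int = 3
    pedigree: PedigreeSpec = field(default_factory=PedigreeSpec)
    trait: TraitModel = field(default_factory=TraitModel)
    contig: str = "chrSim"
    region_length: int = 200_000
    n_exons: int = 15
    read_length: int = 80
    mean_depth: float = 60.0
    duplicate_rate: float = 0.25
    off_target_fraction: float = 0.39
    barcode_length: int = 3
    deletion: DeletionSpec | None = None
    deletion_sample: str | None = None  # defaults to the first sequenced sample
    loh_fraction: float = 0.69
    subclone_n: int = 52
    n_known_per_family: int = 8
    n_novel_per_individual: float = 3.0  # Poisson mean, private artifact calls

    def validate(self) -> None:
        self.trait.validate()
        self.pedigree.validate()
        for name in ("duplicate_rate", "off_target_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.loh_fraction <= 1.0:
            raise ValueError("loh_fraction must be in [0, 1]")
        if self.region_length < 60:
            raise ValueError("region_length must be >= 60")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.subclone_n < 1:
            raise ValueError("subclone_n must be >= 1")
        if self.deletion is not None:
            self.deletion.validate(self.region_length)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        if raw.get("pedigree") is not None:
            raw["pedigree"] = PedigreeSpec(**raw["pedigree"])
        if raw.get("trait") is not None:
            raw["trait"] = TraitModel(**raw["trait"])
        if raw.get("deletion") is not None:
            raw["deletion"] = DeletionSpec(**raw["deletion"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic named substream of the master seed.

    Stage and sample names are hashed (crc32, stable across runs and
    platforms) into the SeedSequence spawn key, so adding a stage never
    perturbs the draws of another.
    """
    spawn = tuple(zlib.crc32(str(k).encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn))


# --------------------------------------------------------------------------
# Pedigree simulation
# --------------------------------------------------------------------------

def simulate_pedigree(
    spec: PedigreeSpec,
    trait: TraitModel,
    rng: np.random.Generator,
    family_id: str = "FAM",
) -> tuple[Pedigree, dict[str, bool]]:
    """Simulate a multigeneration pedigree and its carrier map.

    One founder couple starts the family; every child marries a new founder
    spouse and has ``spec.offspring`` children until ``spec.generations``
    generations exist.  The disease allele enters through founder ``G1-1``
    (or de novo in a random second-generation child when ``trait.de_novo``),
    transmits with probability 1/2 per meiosis from a constitutional carrier
    — or ``mosaic_fraction/2`` from a mosaic founder — and affection is
    carrier AND uniform < penetrance.  A mosaic founder is not counted as a
    constitutional carrier and is never affected.
    """
    spec.validate()
    trait.validate()
    inds: list[Individual] = []
    carriers: dict[str, bool] = {}
    mosaic: set[str] = set()

    def affection(iid: str) -> str:
        if carriers[iid] and rng.uniform() < trait.penetrance:
            return AFFECTED
        return UNAFFECTED

    founder_carrier = not trait.de_novo and not trait.mosaic_founder
    carriers["G1-1"] = founder_carrier
    carriers["G1-2"] = False
    if trait.mosaic_founder and not trait.de_novo:
        mosaic.add("G1-1")
    inds.append(Individual("G1-1", sex="male", affection=affection("G1-1")))
    inds.append(Individual("G1-2", sex="female", affection=affection("G1-2")))

    couples = [("G1-1", "G1-2")]
    de_novo_pick: str | None = None
    for gen in range(2, spec.generations + 1):
        next_couples = []
        child_ids = []
        for ci, (father, mother) in enumerate(couples):
            for k in range(spec.offspring):
                iid = f"G{gen}-{ci * spec.offspring + k + 1}"
                child_ids.append((iid, father, mother))
        if gen == 2 and trait.de_novo and child_ids:
            de_novo_pick = child_ids[int(rng.integers(len(child_ids)))][0]
        for iid, father, mother in child_ids:
            p_not = 1.0
            for parent in (father, mother):
                if parent in mosaic:
                    p_not *= 1.0 - trait.mosaic_fraction / 2.0
                elif carriers[parent]:
                    p_not *= 0.5
            inherited = rng.uniform() < 1.0 - p_not
            carriers[iid] = inherited or iid == de_novo_pick
            sex = "male" if rng.uniform() < 0.5 else "female"
            inds.append(Individual(iid, father, mother, sex=sex,
                                   affection=affection(iid)))
            if gen < spec.generations:
                spouse = f"{iid}s"
                carriers[spouse] = False
                sp_sex = "female" if sex == "male" else "male"
                inds.append(Individual(spouse, sex=sp_sex,
                                       affection=affection(spouse)))
                next_couples.append((iid, spouse) if sex == "male"
                                    else (spouse, iid))
        couples = next_couples
    return Pedigree(inds, family_id=family_id), carriers


# --------------------------------------------------------------------------
# Reference contig and gene models
# --------------------------------------------------------------------------

def _place_exons(lo: int, hi: int, n_exons: int, rng: np.random.Generator,
                 exon_bp: tuple[int, int] = (96, 180),
                 intron_bp: tuple[int, int] = (700, 1500)) -> tuple[tuple[int, int], ...]:
    lengths = rng.integers(exon_bp[0], exon_bp[1] + 1, size=n_exons)
    # keep the CDS a whole number of codons
    total = int(lengths.sum())
    lengths[-1] -= total % 3
    introns = rng.integers(intron_bp[0], intron_bp[1] + 1, size=max(0, n_exons - 1))
    span = int(lengths.sum() + introns.sum())
    if hi - lo + 1 < span:
        raise ValueError(f"cannot place {n_exons} exons in [{lo}, {hi}]")
    start = lo + int(rng.integers(0, hi - lo + 2 - span))
    exons = []
    pos = start
    for i, ln in enumerate(lengths):
        exons.append((pos, pos + int(ln) - 1))
        if i < n_exons - 1:
            pos += int(ln) + int(introns[i])
    return tuple(exons)


def simulate_reference_and_genemodel(
    region_length: int,
    n_exons: int,
    rng: np.random.Generator,
    contig: str = "chrSim",
    gene_name: str = "GENE1",
) -> tuple[str, GeneModel]:
    """Random toy contig plus a single gene model placed on it.

    Exon coordinates are 1-based inclusive, disjoint and ordered; the CDS
    (concatenated exons) has whole-codon length.  Raises when the exons
    cannot fit in the region.
    """
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    seq = "".join(rng.choice(DNA, size=region_length))
    margin = max(1, region_length // 20)
    exons = _place_exons(margin, region_length - margin, n_exons, rng)
    return seq, GeneModel(name=gene_name, contig=contig, exons=exons)


def simulate_gene_models(
    region_length: int,
    n_genes: int,
    n_exons: int,
    rng: np.random.Generator,
    contig: str = "chrSim",
) -> tuple[str, list[GeneModel]]:
    """Toy contig carrying several disjoint genes (for recurrence analyses)."""
    seq = "".join(rng.choice(DNA, size=region_length))
    block = region_length // n_genes
    models = []
    for i in range(n_genes):
        lo = i * block + max(1, block // 20)
        hi = (i + 1) * block - max(1, block // 20)
        exons = _place_exons(lo, hi, n_exons, rng)
        models.append(GeneModel(name=f"GENE{i + 1}", contig=contig, exons=exons))
    return seq, models


# --------------------------------------------------------------------------
# Read simulation
# --------------------------------------------------------------------------

def simulate_reads(
    sample: str,
    targets: list[TargetRegion],
    config: SimConfig,
    rng: np.random.Generator,
    deletion: DeletionSpec | None = None,
) -> pd.DataFrame:
    """Aligned single-end reads for one sample of a capture pool.

    On-target reads start uniformly at unique (position, strand) pairs that
    overlap a target; off-target reads land elsewhere on the contig at rate
    ``off_target_fraction`` of all aligned reads.  Over a heterozygous
    deletion span, reads are thinned by 1/2 (the deleted haplotype yields no
    fragments), halving depth.  PCR duplicates are exact-coordinate copies
    appended at rate ``duplicate_rate`` of the final read count.  With
    ``duplicate_rate = 0`` all records are unique by (contig, start, strand).
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    L = config.read_length
    for t in targets:
        if t.start < 1 or t.end > config.region_length:
            raise ValueError("targets outside contig")
    target_bp = sum(t.length for t in targets)
    n_on = int(round(config.mean_depth * target_bp / L))

    on_positions = np.unique(np.concatenate([
        np.arange(max(1, t.start - L + 1), t.end + 1) for t in targets]))
    is_target = np.zeros(config.region_length + 1, dtype=bool)
    for t in targets:
        is_target[t.start:t.end + 1] = True

    def sample_unique(positions: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
        # candidate space = positions x strands; sample without replacement
        n_cand = 2 * positions.size
        n = min(n, n_cand)
        idx = rng.choice(n_cand, size=n, replace=False)
        return positions[idx // 2], np.where(idx % 2 == 0, "+", "-")

    starts_on, strands_on = sample_unique(on_positions, n_on)

    off = config.off_target_fraction
    n_off = int(round(n_on * off / (1.0 - off))) if off < 1.0 else 0
    all_pos = np.arange(1, config.region_length - L + 2)
    off_mask = ~np.array([is_target[p:p + L].any() for p in all_pos]) \
        if n_off else np.array([], dtype=bool)
    if n_off and off_mask.any():
        starts_off, strands_off = sample_unique(all_pos[off_mask], n_off)
    else:
        starts_off = np.array([], dtype=int)
        strands_off = np.array([], dtype="<U1")

    starts = np.concatenate([starts_on, starts_off]).astype(np.int64)
    strands = np.concatenate([strands_on, strands_off])

    if deletion is not None:
        ends = starts + L - 1
        overlaps = (starts <= deletion.end) & (ends >= deletion.start)
        if deletion.heterozygous:
            drop = overlaps & (rng.uniform(size=starts.size) < 0.5)
        else:
            drop = overlaps
        starts, strands = starts[~drop], strands[~drop]

    quals = rng.uniform(2000.0, 2400.0, size=starts.size)
    reads = pd.DataFrame({
        "sample": sample, "contig": config.contig,
        "start": starts, "length": L, "strand": strands,
        "qual": quals, "aligned": True, "duplicate": False,
    })

    rate = config.duplicate_rate
    if rate > 0 and len(reads):
        n_dup = int(round(len(reads) * rate / (1.0 - rate)))
        src = rng.integers(0, len(reads), size=n_dup)
        dups = reads.iloc[src].copy()
        dups["qual"] = rng.uniform(2000.0, 2400.0, size=n_dup)
        reads = pd.concat([reads, dups], ignore_index=True)
        order = rng.permutation(len(reads))
        reads = reads.iloc[order].reset_index(drop=True)
    return reads


def pooled_fastq(
    reads: pd.DataFrame,
    barcodes: dict[str, str],
    refseq: str,
    path,
) -> None:
    """Write a pooled FASTQ: each read's sequence = its sample's inline barcode
    followed by reference sequence from the alignment start."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for i, row in enumerate(reads.itertuples(index=False)):
        bc = barcodes[row.sample]
        insert_len = int(row.length)
        body = refseq[row.start - 1: row.start - 1 + insert_len]
        seq = (bc + body)[: insert_len + len(bc)]
        rec = SeqRecord(Seq(seq), id=f"read{i}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def default_barcodes(samples: list[str], barcode_length: int = 3) -> dict[str, str]:
    """Assign pairwise-distinct fixed-length inline barcodes."""
    pool = ["".join(p) for p in product("ACGT", repeat=barcode_length)]
    if len(samples) > len(pool):
        raise ValueError("barcode length too short for the number of samples")
    # spread across the pool for >1 mismatch between consecutive assignments
    step = max(1, len(pool) // max(1, len(samples)))
    return {s: pool[(i * step) % len(pool)] for i, s in enumerate(samples)}


# --------------------------------------------------------------------------
# Variant injection
# --------------------------------------------------------------------------

@dataclass
class TruthVariant:
    family: str
    contig: str
    pos: int
    ref: str
    alt: str
    consequence: str
    gene: str


@dataclass
class TruthSet:
    """Ground truth of a simulated cohort; round-trips through JSON."""
    causal: dict[str, TruthVariant]
    carriers: dict[str, dict[str, bool]]
    deletion: DeletionSpec | None
    loh_fraction: float

    def to_json(self, path) -> None:
        payload = {
            "causal": {f: dataclasses.asdict(v) for f, v in self.causal.items()},
            "carriers": self.carriers,
            "deletion": dataclasses.asdict(self.deletion) if self.deletion else None,
            "loh_fraction": self.loh_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            causal={f: TruthVariant(**v) for f, v in raw["causal"].items()},
            carriers=raw["carriers"],
            deletion=DeletionSpec(**raw["deletion"]) if raw["deletion"] else None,
            loh_fraction=raw["loh_fraction"],
        )


def _frameshift_site(gene: GeneModel, refseq: str, rng) -> tuple[int, str, str, str]:
    exon = gene.exons[int(rng.integers(gene.n_exons))]
    del_len = int(rng.choice([1, 2, 4, 5]))
    lo, hi = exon[0] + 1, exon[1] - del_len - 1
    if hi < lo:
        lo, hi = exon[0], exon[0]
        del_len = 1
    pos = int(rng.integers(lo, hi + 1))
    ref = refseq[pos - 1: pos + del_len]
    return pos, ref, ref[0], "frameshift"


def _nonsense_site(gene: GeneModel, refseq: str, rng) -> tuple[int, str, str, str]:
    cds = gene.cds_sequence(refseq)
    candidates = []
    for ci in range(len(cds) // 3):
        codon = cds[ci * 3: ci * 3 + 3]
        if codon in STOP_CODONS:
            continue
        for off in range(3):
            for alt in "ACGT":
                if alt == codon[off]:
                    continue
                mutated = codon[:off] + alt + codon[off + 1:]
                if mutated in STOP_CODONS:
                    candidates.append((ci * 3 + off, alt))
    if not candidates:
        raise ValueError("no stop-creating substitution available")
    idx, alt = candidates[int(rng.integers(len(candidates)))]
    # map CDS index back to a genomic position (forward-strand toy genes)
    offset = 0
    for s, e in gene.exons:
        if idx < offset + (e - s + 1):
            pos = s + (idx - offset)
            break
        offset += e - s + 1
    return pos, refseq[pos - 1], alt, "nonsense"


def _acceptor_site(gene: GeneModel, refseq: str, rng) -> tuple[int, str, str, str]:
    if gene.n_exons < 2:
        raise ValueError("splice-acceptor site needs >= 2 exons")
    exon = gene.exons[int(rng.integers(1, gene.n_exons))]
    pos = exon[0] - 1  # intronic position -1 of the acceptor
    ref = refseq[pos - 1]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return pos, ref, alt, "splice-acceptor"


_CLASS_SITES = {"frameshift": _frameshift_site, "nonsense": _nonsense_site,
                "splice-acceptor": _acceptor_site}


def inject_variants(
    carriers_by_family: dict[str, dict[str, bool]],
    gene_models: list[GeneModel] | GeneModel,
    refseq: str,
    rng: np.random.Generator,
    classes: list[str] | None = None,
    causal_gene: str | None = None,
    n_known_per_family: int = 8,
    n_novel_per_individual: float = 3.0,
) -> tuple[dict[str, dict[str, list[VariantCall]]], set[tuple], TruthSet]:
    """Variant call sets per individual, the known-site catalog, and the truth.

    Each family receives one causal loss-of-function variant in the shared
    disease gene — consequence classes cycle through ``classes`` (default
    frameshift / nonsense / splice-acceptor) — present in every carrier's
    call set.  Background structure: catalog-listed inherited SNVs shared by
    the whole family, and private novel artifact calls per individual (drawn
    at distinct sites cohort-wide, as sequencing artifacts do not recur).
    Set both background rates to zero to emit only causal variants.
    """
    if isinstance(gene_models, GeneModel):
        gene_models = [gene_models]
    gene = next((g for g in gene_models if g.name == causal_gene), gene_models[0])
    if gene.end > len(refseq):
        raise ValueError("gene model outside contig")
    classes = list(classes) if classes else list(DEFAULT_SPECTRUM)

    used_pos: set[int] = set()
    catalog: set[tuple] = set()
    calls: dict[str, dict[str, list[VariantCall]]] = {}
    truth_causal: dict[str, TruthVariant] = {}
    contig = gene.contig

    def annotate(call: VariantCall) -> VariantCall:
        return annotate_consequence(normalize_call(call, refseq), gene_models, refseq)

    for fi, (family, carriers) in enumerate(sorted(carriers_by_family.items())):
        klass = classes[fi % len(classes)]
        for _ in range(50):
            pos, ref, alt, conseq = _CLASS_SITES[klass](gene, refseq, rng)
            if pos not in used_pos:
                break
        used_pos.update(range(pos, pos + len(ref)))
        causal = VariantCall(contig=contig, pos=pos, ref=ref, alt=alt,
                             qual=99.0, support=int(rng.integers(8, 25)))
        causal = annotate(causal)
        truth_causal[family] = TruthVariant(
            family=family, contig=contig, pos=causal.pos, ref=causal.ref,
            alt=causal.alt, consequence=causal.consequence, gene=causal.gene)

        fam_calls: dict[str, list[VariantCall]] = {iid: [] for iid in carriers}
        # inherited, catalog-listed SNVs shared by the family
        for _ in range(n_known_per_family):
            site = _random_snv(refseq, rng, used_pos)
            if site is None:
                break
            p, r, a = site
            used_pos.add(p)
            catalog.add((contig, p, r, a))
            for iid in carriers:
                fam_calls[iid].append(annotate(VariantCall(
                    contig=contig, pos=p, ref=r, alt=a, qual=90.0,
                    support=int(rng.integers(8, 25)), sample=iid)))
        # private novel artifacts, distinct sites cohort-wide
        for iid in carriers:
            n_art = int(rng.poisson(n_novel_per_individual))
            for _ in range(n_art):
                site = _random_snv(refseq, rng, used_pos)
                if site is None:
                    break
                p, r, a = site
                used_pos.add(p)
                fam_calls[iid].append(annotate(VariantCall(
                    contig=contig, pos=p, ref=r, alt=a, qual=80.0,
                    support=int(rng.integers(3, 12)), sample=iid)))
        for iid, is_carrier in carriers.items():
            if is_carrier:
                fam_calls[iid].append(dataclasses.replace(causal, sample=iid))
        calls[family] = fam_calls

    truth = TruthSet(causal=truth_causal,
                     carriers={f: dict(c) for f, c in carriers_by_family.items()},
                     deletion=None, loh_fraction=0.0)
    return calls, catalog, truth


def _random_snv(refseq: str, rng, used: set[int]):
    for _ in range(100):
        p = int(rng.integers(2, len(refseq)))
        if p in used:
            continue
        ref = refseq[p - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return p, ref, alt
    return None


# --------------------------------------------------------------------------
# Marker panel simulation (linkage inputs)
# --------------------------------------------------------------------------

def _haldane_theta(d_cm: float) -> float:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def simulate_marker_panel(
    pedigree: Pedigree,
    carriers: dict[str, bool],
    rng: np.random.Generator,
    n_markers: int = 21,
    spacing_bp: int = 100_000,
    start_bp: int = 1_000_000,
    causal_bp: int | None = None,
    freq: float = 0.5,
    cm_per_mb: float = 1.0,
    informative: bool = True,
):
    """Biallelic marker genotypes segregating around a causal disease locus.

    With ``informative`` (the default), every marker is fully informative
    for the disease lineage: carrier founders are heterozygous with the
    disease allele phased onto marker allele 1 and married-in founders are
    homozygous 0, so a marker co-segregating without recombination attains
    the pedigree's LOD ceiling.  Otherwise founder haplotypes draw marker
    alleles at the population frequency, giving realistic partial
    informativeness.  The disease locus sits at ``causal_bp`` (default:
    mid-panel, between two markers).  Each meiosis is a crossover walk
    along the map (Haldane, ``cm_per_mb`` resolution), constrained so the
    disease-allele transmission reproduces the supplied carrier map.
    Returns (MarkerPanel, causal_bp).

    De novo or mosaic carrier maps are not supported here: a child marked
    carrier must have a constitutional carrier parent.
    """
    from .linkage import MarkerPanel

    positions = start_bp + spacing_bp * np.arange(n_markers)
    if causal_bp is None:
        causal_bp = int(positions[n_markers // 2] + spacing_bp // 2)
    loci = np.sort(np.append(positions.astype(float), causal_bp))
    causal_idx = int(np.searchsorted(loci, causal_bp))
    marker_idx = [i for i in range(len(loci)) if i != causal_idx]
    cm = loci / 1e6 * cm_per_mb
    theta = _haldane_theta(np.diff(cm))

    haps: dict[str, list[np.ndarray]] = {}   # alleles per locus incl. disease slot
    for iid in pedigree.topological_order:
        ind = pedigree[iid]
        if ind.is_founder:
            pair = []
            is_carrier = carriers.get(iid, False)
            for h in range(2):
                if informative:
                    fill = 1 if (is_carrier and h == 0) else 0
                    alleles = np.full(len(loci), fill, dtype=np.int8)
                else:
                    alleles = (rng.uniform(size=len(loci)) < freq).astype(np.int8)
                alleles[causal_idx] = 1 if (is_carrier and h == 0) else 0
                pair.append(alleles)
            haps[iid] = pair
        else:
            pair = [_gamete(haps[ind.father], theta, rng),
                    _gamete(haps[ind.mother], theta, rng)]
            # enforce the carrier map by rejection on the disease slot
            child_d = bool(pair[0][causal_idx] or pair[1][causal_idx])
            want = bool(carriers.get(iid, False))
            tries = 0
            while child_d != want and tries < 1000:
                pair = [_gamete(haps[ind.father], theta, rng),
                        _gamete(haps[ind.mother], theta, rng)]
                child_d = bool(pair[0][causal_idx] or pair[1][causal_idx])
                tries += 1
            if child_d != want:
                raise ValueError(
                    f"carrier map for {iid} inconsistent with parental genotypes")
            haps[iid] = pair

    geno = {
        iid: np.array([haps[iid][0][i] + haps[iid][1][i] for i in marker_idx])
        for iid in pedigree.topological_order
    }
    info = pd.DataFrame({
        "marker": [f"m{i + 1}" for i in range(n_markers)],
        "cm": cm[marker_idx],
        "bp": loci[marker_idx].astype(int),
        "freq": freq,
    })
    genotypes = pd.DataFrame(geno, index=info["marker"], dtype=float)
    info = info.set_index("marker", drop=False)
    return MarkerPanel(info, genotypes), int(causal_bp)


def _gamete(parent_haps, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    strand = int(rng.integers(2))
    crossover = rng.uniform(size=theta.size) < theta
    out = np.empty(len(parent_haps[0]), dtype=np.int8)
    out[0] = parent_haps[strand][0]
    for i, x in enumerate(crossover):
        if x:
            strand = 1 - strand
        out[i + 1] = parent_haps[strand][i + 1]
    return out


# --------------------------------------------------------------------------
# Subclone counts
# --------------------------------------------------------------------------

def simulate_subclone_counts(n: int, f: float, rng: np.random.Generator,
                             size: int | None = None):
    """Mutant subclone count k ~ Binomial(n, (1+f)/2).

    Cells with loss of the wild-type allele contribute only mutant template;
    the remaining cells are heterozygous, so a subclone is mutant with
    probability f + (1-f)/2 = (1+f)/2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    k = rng.binomial(n, (1.0 + f) / 2.0, size=size)
    return int(k) if size is None else k


# --------------------------------------------------------------------------
# End-to-end cohort assembly
# --------------------------------------------------------------------------

@dataclass
class Cohort:
    config: SimConfig
    refseq: str
    gene_model: GeneModel
    targets: list[TargetRegion]
    pedigrees: dict[str, Pedigree]
    carriers: dict[str, dict[str, bool]]
    sequenced: dict[str, list[str]]       # family -> sample ids in the pool
    barcodes: dict[str, str]
    reads: pd.DataFrame                    # all samples, concatenated
    calls: dict[str, dict[str, list[VariantCall]]]
    catalog: set
    truth: TruthSet
    subclone_counts: dict[str, int]


def generate_cohort(config: SimConfig) -> Cohort:
    """Simulate the full study: pedigrees, reference, reads, variants, LOH counts.

    Per family the sequencing pool receives up to two affected individuals
    and one unaffected relative (the trio design that powers the
    intersection filter).  The optional deletion is carried by
    ``config.deletion_sample`` (default: the first sequenced sample).
    """
    config.validate()
    seed = config.seed
    refseq, gene_model = simulate_reference_and_genemodel(
        config.region_length, config.n_exons, substream(seed, "reference"),
        contig=config.contig)
    exon_targets = [TargetRegion(config.contig, s, e, "exon")
                    for s, e in gene_model.exons]
    targets = pad_and_merge(exon_targets, pad_bp=60,
                            contig_length=config.region_length)

    pedigrees: dict[str, Pedigree] = {}
    carriers: dict[str, dict[str, bool]] = {}
    sequenced: dict[str, list[str]] = {}
    seq_carrier_maps: dict[str, dict[str, bool]] = {}
    for fi in range(config.n_families):
        family = f"F{fi + 1}"
        ped, carr = simulate_pedigree(config.pedigree, config.trait,
                                      substream(seed, "pedigree", family),
                                      family_id=family)
        pedigrees[family] = ped
        carriers[family] = carr
        affected = [i for i in ped.topological_order
                    if ped[i].affection == AFFECTED][:2]
        unaffected = [i for i in ped.topological_order
                      if ped[i].affection == UNAFFECTED][:1]
        ids = affected + unaffected
        sequenced[family] = [f"{family}.{iid}" for iid in ids]
        seq_carrier_maps[family] = {f"{family}.{iid}": carr[iid] for iid in ids}

    all_samples = [s for fam in sorted(sequenced) for s in sequenced[fam]]
    barcodes = default_barcodes(all_samples, config.barcode_length)

    del_sample = config.deletion_sample
    if config.deletion is not None and del_sample is None and all_samples:
        del_sample = all_samples[0]
    read_frames = []
    for s in all_samples:
        deletion = config.deletion if s == del_sample else None
        read_frames.append(simulate_reads(
            s, targets, config, substream(seed, "reads", s), deletion=deletion))
    reads = pd.concat(read_frames, ignore_index=True) if read_frames \
        else pd.DataFrame()

    calls, catalog, truth = inject_variants(
        seq_carrier_maps, gene_model, refseq, substream(seed, "variants"),
        n_known_per_family=config.n_known_per_family,
        n_novel_per_individual=config.n_novel_per_individual)
    truth = dataclasses.replace(truth, deletion=config.deletion,
                                loh_fraction=config.loh_fraction)

    subclones = {
        "lesion": simulate_subclone_counts(
            config.subclone_n, config.loh_fraction, substream(seed, "loh", "lesion")),
        "control": simulate_subclone_counts(
            config.subclone_n, 0.0, substream(seed, "loh", "control")),
    }
    return Cohort(config=config, refseq=refseq, gene_model=gene_model,
                  targets=targets, pedigrees=pedigrees, carriers=carriers,
                  sequenced=sequenced, barcodes=barcodes, reads=reads,
                  calls=calls, catalog=catalog, truth=truth,
                  subclone_counts=subclones)
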