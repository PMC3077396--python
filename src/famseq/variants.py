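"""Novel-variant filter cascade and consequence annotation.

The discovery logic for a dominant family disorder sequenced by targeted
capture: per-individual variant calls are filtered on call quality, read
support, coding status, and absence from known-variant catalogs; the
survivors are intersected across affected family members and purged of
anything seen in an unaffected member; genes recurrently hit by independent
candidates in multiple families rise to the top.

Variants are matched by their normalized (contig, pos, ref, alt) —
left-aligned, minimal representation — never by overlap, so indels compare
canonically across individuals and against catalogs.

Consequence classes: a coding indel of length not divisible by 3 is a
frameshift, divisible an inframe-indel; an SNV creating a stop codon is
nonsense, otherwise missense/synonymous by codon comparison; substitutions
at intronic positions -1/-2 of an exon boundary are splice-acceptor, +1/+2
splice-donor (the +-2 window covers the essentially invariant splice
dinucleotides); other intronic calls carry their distance to the nearest
exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd

from Bio.Seq import Seq

CONSEQUENCES = ("frameshift", "nonsense", "missense", "synonymous",
                "splice-acceptor", "splice-donor", "inframe-indel", "noncoding")

SPLICE_WINDOW = 2  # bp of intron adjacent to each exon boundary


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene model: ordered, disjoint exons forming the CDS."""
    name: str
    contig: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive
    strand: str = "+"

    def __post_init__(self):
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"{self.name}: exon start {s} > end {e}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.name}: exons overlap or are unordered")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def contains_coding(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def cds_index(self, pos: int) -> int:
        """0-based CDS coordinate (transcript orientation) of a genomic position."""
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                fwd = offset + (pos - s)
                return fwd if self.strand == "+" else self.cds_length - 1 - fwd
            offset += e - s + 1
        raise ValueError(f"position {pos} not exonic in {self.name}")

    def cds_sequence(self, refseq: str) -> str:
        seq = "".join(refseq[s - 1:e] for s, e in self.exons)
        return seq if self.strand == "+" else str(Seq(seq).reverse_complement())

    def distance_to_exon(self, pos: int) -> int:
        """bp to the nearest exon base (0 if exonic)."""
        best = None
        for s, e in self.exons:
            if s <= pos <= e:
                return 0
            d = s - pos if pos < s else pos - e
            best = d if best is None else min(best, d)
        return best

    def splice_site_class(self, pos: int) -> str | None:
        """'splice-acceptor'/'splice-donor' for intronic positions within +-2 bp."""
        for i, (s, e) in enumerate(self.exons):
            upstream = i > 0 and s - SPLICE_WINDOW <= pos <= s - 1
            downstream = i < len(self.exons) - 1 and e + 1 <= pos <= e + SPLICE_WINDOW
            if upstream:
                return "splice-acceptor" if self.strand == "+" else "splice-donor"
            if downstream:
                return "splice-donor" if self.strand == "+" else "splice-acceptor"
        return None


@dataclass(frozen=True)
class VariantCall:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float = 50.0
    support: int = 10
    sample: str = ""
    region: str | None = None        # coding / intronic / intergenic
    consequence: str | None = None
    distance_to_exon: int | None = None
    known: bool = False
    gene: str | None = None

    def __post_init__(self):
        if self.support < 1:
            raise ValueError("supporting reads must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty (anchored representation)")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        return len(self.alt) - len(self.ref)


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

def normalize_variant(pos: int, ref: str, alt: str,
                      refseq: str) -> tuple[int, str, str]:
    """Left-align and minimalize an allele pair against the reference.

    The canonical form that makes catalog matching and family intersection
    well defined: trailing shared bases are trimmed (extending left through
    the reference when an allele would empty, which shifts indels through
    repeat tracts), then leading shared bases are trimmed.
    """
    ref, alt = ref.upper(), alt.upper()
    while ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos <= 1:
                raise ValueError("cannot left-extend past the contig start")
            pos -= 1
            base = refseq[pos - 1].upper()
            ref, alt = base + ref, base + alt
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_call(call: VariantCall, refseq: str) -> VariantCall:
    pos, ref, alt = normalize_variant(call.pos, call.ref, call.alt, refseq)
    return replace(call, pos=pos, ref=ref, alt=alt)


# --------------------------------------------------------------------------
# Filters
# --------------------------------------------------------------------------

def filter_quality(calls: Iterable[VariantCall], min_q: float = 20.0) -> list[VariantCall]:
    """Retain calls with quality strictly greater than ``min_q``."""
    if min_q < 0:
        raise ValueError("min_q must be >= 0")
    return [c for c in calls if c.qual > min_q]


def filter_min_support(calls: Iterable[VariantCall], min_reads: int,
                       mode: str = "ge") -> list[VariantCall]:
    """Retain calls by read support: mode 'ge' keeps >= min_reads, 'gt' keeps >."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if mode == "ge":
        return [c for c in calls if c.support >= min_reads]
    if mode == "gt":
        return [c for c in calls if c.support > min_reads]
    raise ValueError(f"unknown support mode {mode!r} (expected 'ge' or 'gt')")


def filter_known(calls: Iterable[VariantCall],
                 catalogs: Iterable[Iterable[tuple]]) -> list[VariantCall]:
    """Drop calls whose normalized (contig,pos,ref,alt) appears in any catalog."""
    sites: set[tuple] = set()
    for cat in catalogs:
        sites.update(cat)
    return [replace(c, known=False) for c in calls if c.key not in sites]


def filter_coding(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Retain annotated calls overlapping CDS."""
    return [c for c in calls if c.region == "coding"]


# --------------------------------------------------------------------------
# Consequence annotation
# --------------------------------------------------------------------------

def annotate_consequence(call: VariantCall, gene_models: list[GeneModel] | GeneModel,
                         refseq: str) -> VariantCall:
    """Classify a call against gene models on its contig.

    The call is attributed to the first model whose footprint (first to last
    exon) it touches; splice-window hits take precedence within the intron.
    """
    if isinstance(gene_models, GeneModel):
        gene_models = [gene_models]
    if not 1 <= call.pos <= len(refseq):
        raise ValueError(f"position {call.pos} outside contig (len {len(refseq)})")

    for gm in gene_models:
        if gm.contig != call.contig:
            continue
        if call.pos < gm.start - SPLICE_WINDOW or call.pos > gm.end + SPLICE_WINDOW:
            continue
        if gm.contains_coding(call.pos):
            return replace(call, region="coding", gene=gm.name,
                           distance_to_exon=0,
                           consequence=_coding_consequence(call, gm, refseq))
        splice = gm.splice_site_class(call.pos)
        if splice is not None and call.is_snv:
            return replace(call, region="intronic", gene=gm.name,
                           distance_to_exon=gm.distance_to_exon(call.pos),
                           consequence=splice)
        return replace(call, region="intronic", gene=gm.name,
                       distance_to_exon=gm.distance_to_exon(call.pos),
                       consequence="noncoding")
    return replace(call, region="intergenic", consequence="noncoding",
                   distance_to_exon=None)


def _coding_consequence(call: VariantCall, gm: GeneModel, refseq: str) -> str:
    if not call.is_snv:
        return "frameshift" if call.indel_length % 3 != 0 else "inframe-indel"
    cds = gm.cds_sequence(refseq)
    idx = gm.cds_index(call.pos)
    base = call.alt if gm.strand == "+" else str(Seq(call.alt).reverse_complement())
    codon_i = idx // 3
    codon = list(cds[codon_i * 3:codon_i * 3 + 3])
    if len(codon) < 3:  # trailing partial codon in a toy model
        return "synonymous"
    codon[idx % 3] = base
    aa_ref = str(Seq(cds[codon_i * 3:codon_i * 3 + 3]).translate())
    aa_alt = str(Seq("".join(codon)).translate())
    if aa_alt == "*" and aa_ref != "*":
        return "nonsense"
    return "synonymous" if aa_alt == aa_ref else "missense"


# --------------------------------------------------------------------------
# Family intersection and the filter ledger
# --------------------------------------------------------------------------

@dataclass
class FilterLedger:
    """Ordered per-stage survivor counts, one column per individual.

    Stage rows follow the classic discovery table: total (quality-filtered)
    variants, coding, not listed in catalogs, shared among affected family
    members, and not present in the unaffected member.  Shared counts are
    recorded both after the novelty filter (``shared``) and before it
    (``shared_before_novelty``), since either ordering is defensible.
    Counts are non-increasing down the cascade within an individual.
    """
    family_id: str
    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def family_intersection(
    affected_sets: dict[str, Iterable[VariantCall]],
    unaffected_sets: dict[str, Iterable[VariantCall]] | None = None,
) -> list[VariantCall]:
    """Candidates = intersection of affected call sets minus union of unaffected.

    Matching is by normalized (contig, pos, ref, alt); annotations are taken
    from the first affected individual's call.
    """
    if not affected_sets:
        raise ValueError("at least one affected call set required")
    iter_aff = iter(affected_sets.items())
    first_sample, first_calls = next(iter_aff)
    first_calls = list(first_calls)
    shared_keys = {c.key for c in first_calls}
    for _, calls in iter_aff:
        shared_keys &= {c.key for c in calls}
    if unaffected_sets:
        for calls in unaffected_sets.values():
            shared_keys -= {c.key for c in calls}
    return [c for c in first_calls if c.key in shared_keys]


def run_cascade(
    family_id: str,
    affected_calls: dict[str, list[VariantCall]],
    unaffected_calls: dict[str, list[VariantCall]] | None,
    catalogs: list[set[tuple]],
    min_q: float = 20.0,
    min_support: int = 3,
    support_mode: str = "ge",
) -> tuple[list[VariantCall], FilterLedger]:
    """Run the full per-family cascade and record the ledger.

    Input calls must already be normalized and consequence-annotated.
    Stages per individual: quality (> min_q) + support -> coding -> novel
    (absent from all catalogs).  Family stages: shared among all affected,
    then absent from every unaffected individual.
    """
    unaffected_calls = unaffected_calls or {}
    stages: dict[str, dict[str, list[VariantCall]]] = {}
    everyone = {**affected_calls, **unaffected_calls}
    for sample, calls in everyone.items():
        passed = filter_quality(calls, min_q)
        passed = filter_min_support(passed, min_support, support_mode)
        coding = filter_coding(passed)
        novel = filter_known(coding, catalogs)
        stages[sample] = {"total": passed, "coding": coding, "novel": novel}

    aff_novel = {s: stages[s]["novel"] for s in affected_calls}
    aff_coding = {s: stages[s]["coding"] for s in affected_calls}
    una_all = {s: stages[s]["total"] for s in unaffected_calls}

    shared = family_intersection(aff_novel)
    shared_pre = family_intersection(aff_coding)
    candidates = family_intersection(aff_novel, una_all)

    rows = ["total", "coding", "not_in_catalog", "shared_before_novelty",
            "shared", "not_in_unaffected"]
    table = pd.DataFrame(index=rows, columns=list(everyone), dtype="object")
    for sample in everyone:
        table.loc["total", sample] = len(stages[sample]["total"])
        table.loc["coding", sample] = len(stages[sample]["coding"])
        table.loc["not_in_catalog", sample] = len(stages[sample]["novel"])
    for sample in affected_calls:
        table.loc["shared_before_novelty", sample] = len(shared_pre)
        table.loc["shared", sample] = len(shared)
        table.loc["not_in_unaffected", sample] = (
            len(candidates) if unaffected_calls else pd.NA)
    table.index.name = "stage"
    return candidates, FilterLedger(family_id=family_id, table=table)


def recurrence_across_families(
    per_family_candidates: dict[str, list[VariantCall]],
) -> pd.DataFrame:
    """Rank genes by the number of families with an independent candidate.

    Genes hit in >= 2 families sort first (descending family count, then
    name); each row carries the contributing family list.  Candidates
    without a gene attribution are ignored.
    """
    hits: dict[str, set[str]] = {}
    for family, calls in per_family_candidates.items():
        for c in calls:
            if c.gene is not None:
                hits.setdefault(c.gene, set()).add(family)
    rows = [{"gene": g, "n_families": len(fams), "families": sorted(fams)}
            for g, fams in hits.items()]
    df = pd.DataFrame(rows, columns=["gene", "n_families", "families"])
    return df.sort_values(["n_families", "gene"], ascending=[False, True],
                          ignore_index=True)


# --------------------------------------------------------------------------
# VCF-style I/O
# --------------------------------------------------------------------------

_INFO_FIELDS = ("region", "consequence", "distance_to_exon", "gene")


def write_vcf(calls: Iterable[VariantCall], path) -> None:
    """Write calls as minimal VCF with cascade annotations in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">\n')
        for f in _INFO_FIELDS:
            fh.write(f'##INFO=<ID={f.upper()},Number=1,Type=String,Description="{f}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = [f"SUPPORT={c.support}", f"SAMPLE={c.sample}"]
            for f in _INFO_FIELDS:
                v = getattr(c, f)
                if v is not None:
                    info.append(f"{f.upper()}={v}")
            fh.write(f"{c.contig}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t"
                     f"{c.qual:g}\t.\t{';'.join(info)}\n")


def read_vcf(path) -> list[VariantCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            contig, pos, _, ref, alt, qual, _, info = line.rstrip("\n").split("\t")[:8]
            kv = dict(item.split("=", 1) for item in info.split(";") if "=" in item)
            calls.append(VariantCall(
                contig=contig, pos=int(pos), ref=ref, alt=alt, qual=float(qual),
                support=int(kv.get("SUPPORT", 1)), sample=kv.get("SAMPLE", ""),
                region=kv.get("REGION"), consequence=kv.get("CONSEQUENCE"),
                distance_to_exon=(int(kv["DISTANCE_TO_EXON"])
                                  if "DISTANCE_TO_EXON" in kv else None),
                gene=kv.get("GENE"),
            ))
    return calls


def write_catalog(sites: Iterable[tuple], path) -> None:
    """Known-site catalog as TSV: contig, pos, ref, alt."""
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\n")
        for contig, pos, ref, alt in sorted(sites):
            fh.write(f"{contig}\t{pos}\t{ref}\t{alt}\n")


def read_catalog(path) -> set[tuple]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    return {(r.contig, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False)}
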