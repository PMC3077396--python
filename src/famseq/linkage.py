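"""Pedigree-restricted parametric linkage analysis.

Implements single-marker parametric LOD scores for a rare, fully penetrant
dominant disease model by *exact enumeration* of the two-locus (disease +
marker) genotype space of a pedigree.  The likelihood sums over founder
disease genotypes (Hardy-Weinberg prior from the disease allele frequency
q), founder haplotype phases, and all transmission vectors; linkage is
evaluated at recombination fraction theta = 0 ("linked": marker and disease
allele co-transmit) against theta = 1/2 ("unlinked": independent
transmission).  The sum is computed by factor elimination on the pedigree's
Bayesian network, which is exact and fast for the small pedigrees this
package targets (enumeration refused above 22 meioses).

The analysis strategy mirrors family studies of incompletely ascertained
dominant traits: unaffected non-founders are dropped before analysis
(non-penetrance and non-ascertainment would otherwise confound the model),
retaining founders, affected individuals, and the minimal unexamined
connectors, who are treated as obligate carriers of unknown genotype.

A multipoint HMM (MERLIN-style Lander-Green) is deliberately not
implemented; single-marker enumeration plus plateau extraction over a dense
track reproduces the same decision outputs at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coords import span_bp

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

MAX_MEIOSES = 22  # enumeration bound
LOG10_2 = math.log10(2.0)


class EnumerationBoundError(ValueError):
    """Raised when a pedigree exceeds the exact-enumeration meiosis bound."""


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


# --------------------------------------------------------------------------
# Pedigree
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None = None
    mother: str | None = None
    sex: str = "unknown"  # 'male' / 'female' / 'unknown'
    affection: str = UNKNOWN

    def __post_init__(self):
        if (self.father is None) != (self.mother is None):
            raise PedigreeError(f"{self.iid}: must have both parents or neither")
        if self.affection not in (AFFECTED, UNAFFECTED, UNKNOWN):
            raise PedigreeError(f"{self.iid}: bad affection {self.affection!r}")

    @property
    def is_founder(self) -> bool:
        return self.father is None


class Pedigree:
    """A validated pedigree: acyclic, parents present, founder <=> no parents."""

    def __init__(self, individuals: list[Individual], family_id: str = "FAM"):
        self.family_id = family_id
        self.members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self.members:
                raise PedigreeError(f"duplicate individual id {ind.iid}")
            self.members[ind.iid] = ind
        for ind in individuals:
            for p in (ind.father, ind.mother):
                if p is not None and p not in self.members:
                    raise PedigreeError(f"{ind.iid}: parent {p} not in pedigree")
        self._topo = self._toposort()

    def _toposort(self) -> list[str]:
        order, seen, onpath = [], set(), set()

        def visit(iid: str):
            if iid in seen:
                return
            if iid in onpath:
                raise PedigreeError(f"pedigree cycle through {iid}")
            onpath.add(iid)
            ind = self.members[iid]
            if ind.father is not None:
                visit(ind.father)
                visit(ind.mother)
            onpath.discard(iid)
            seen.add(iid)
            order.append(iid)

        for iid in self.members:
            visit(iid)
        return order

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, iid: str) -> bool:
        return iid in self.members

    def __getitem__(self, iid: str) -> Individual:
        return self.members[iid]

    @property
    def topological_order(self) -> list[str]:
        return list(self._topo)

    @property
    def founders(self) -> list[str]:
        return [i for i in self._topo if self.members[i].is_founder]

    @property
    def nonfounders(self) -> list[str]:
        return [i for i in self._topo if not self.members[i].is_founder]

    @property
    def n_meioses(self) -> int:
        return 2 * len(self.nonfounders)

    @property
    def affected(self) -> list[str]:
        return [i for i in self._topo if self.members[i].affection == AFFECTED]

    def children_of(self, iid: str) -> list[str]:
        return [c for c in self._topo
                if self.members[c].father == iid or self.members[c].mother == iid]

    def ancestors_of(self, iid: str) -> set[str]:
        out: set[str] = set()
        stack = [iid]
        while stack:
            ind = self.members[stack.pop()]
            for p in (ind.father, ind.mother):
                if p is not None and p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def descendants_of(self, iid: str) -> set[str]:
        out: set[str] = set()
        stack = [iid]
        while stack:
            cur = stack.pop()
            for c in self.children_of(cur):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    # ---- PED file I/O ----------------------------------------------------

    _SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
    _AFF_OUT = {UNAFFECTED: "1", AFFECTED: "2", UNKNOWN: "0"}

    def to_ped(self, path) -> None:
        with open(path, "w") as fh:
            for iid in self._topo:
                ind = self.members[iid]
                fh.write("\t".join([
                    self.family_id, iid,
                    ind.father or "0", ind.mother or "0",
                    self._SEX_OUT[ind.sex], self._AFF_OUT[ind.affection],
                ]) + "\n")

    @classmethod
    def from_ped(cls, path) -> "Pedigree":
        sex_in = {"1": "male", "2": "female"}
        aff_in = {"1": UNAFFECTED, "2": AFFECTED}
        inds, fam = [], "FAM"
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.split()
                fam = f[0]
                inds.append(Individual(
                    iid=f[1],
                    father=None if f[2] == "0" else f[2],
                    mother=None if f[3] == "0" else f[3],
                    sex=sex_in.get(f[4], "unknown"),
                    affection=aff_in.get(f[5], UNKNOWN),
                ))
        return cls(inds, family_id=fam)


# --------------------------------------------------------------------------
# Disease model and markers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiseaseModel:
    """Parametric model: disease allele frequency and penetrance vector.

    Defaults encode a rare, fully penetrant dominant trait with no
    phenocopies: q = 1e-7 and affection probabilities (f0, f1, f2) =
    (0, 1, 1) for carrying 0/1/2 disease alleles.
    """
    q: float = 1e-7
    penetrance: tuple[float, float, float] = (0.0, 1.0, 1.0)

    def __post_init__(self):
        if not 0.0 < self.q < 1.0:
            raise ValueError("disease allele frequency q must be in (0, 1)")
        if any(not 0.0 <= f <= 1.0 for f in self.penetrance):
            raise ValueError("penetrances must be in [0, 1]")


@dataclass
class MarkerPanel:
    """Biallelic marker panel: map positions, allele frequencies, genotypes.

    ``info`` has one row per marker (columns: marker, cm, bp, freq) where
    ``freq`` is the population frequency of allele 1; ``genotypes`` is
    indexed by marker with one column per individual, values 0/1/2 =
    allele-1 dosage, NaN = missing.  Frequencies and map positions are
    inputs (array-vendor and genetic-map annotations), never computed.
    """
    info: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self):
        self.info = self.info.set_index("marker", drop=False) \
            if "marker" in self.info.columns and self.info.index.name != "marker" \
            else self.info
        bp = self.info["bp"].to_numpy()
        if np.any(np.diff(bp) <= 0):
            raise ValueError("marker bp positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.info)

    def subset(self, marker_ids) -> "MarkerPanel":
        return MarkerPanel(self.info.loc[marker_ids].copy(),
                           self.genotypes.loc[marker_ids].copy())

    def to_tsv(self, path) -> None:
        merged = self.info.join(self.genotypes, how="left")
        merged.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t")
        meta = ["marker", "cm", "bp", "freq"]
        geno = df.drop(columns=meta).set_index(df["marker"])
        return cls(df[meta], geno)


def _mendelian_possible(child: float, father: float, mother: float) -> bool:
    alleles = {0.0: (0,), 1.0: (0, 1), 2.0: (1,)}
    return any(tf + tm == child for tf in alleles[father] for tm in alleles[mother])


def marker_qc(
    panel: MarkerPanel,
    pedigree: Pedigree,
    analyzed: list[str] | None = None,
) -> tuple[MarkerPanel, pd.DataFrame]:
    """QC the panel the way a linkage run pre-filters its SNPs.

    Mendelian-inconsistent trio genotypes are first blanked (the child call
    is set missing), then markers are removed if they have any missing call
    among the analyzed individuals (<100% sample call rate) or a pedigree
    minor-allele frequency of 0 (monomorphic, hence uninformative).

    Returns the filtered panel and a per-marker report of the decision.
    An empty surviving panel is a valid result, not an error.

    ``analyzed`` defaults to the pedigree members of known phenotype among
    the genotype columns — unexamined connectors carry no DNA sample, so
    their (absent) calls must not count against the call-rate rule.
    """
    if analyzed is None:
        analyzed = [c for c in panel.genotypes.columns
                    if c in pedigree and pedigree[c].affection != UNKNOWN]
    geno = panel.genotypes[analyzed].astype(float).copy()

    trios = [(iid, ind.father, ind.mother) for iid, ind in pedigree.members.items()
             if not ind.is_founder
             and iid in geno.columns and ind.father in geno.columns
             and ind.mother in geno.columns]
    n_blanked = pd.Series(0, index=geno.index)
    for child, fa, mo in trios:
        sub = geno[[child, fa, mo]]
        complete = sub.notna().all(axis=1)
        for mid in sub.index[complete]:
            c, f, m = sub.loc[mid]
            if not _mendelian_possible(c, f, m):
                geno.loc[mid, child] = np.nan
                n_blanked.loc[mid] += 1

    complete = geno.notna().all(axis=1)
    dosage = geno.sum(axis=1)
    n_alleles = 2 * geno.notna().sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq1 = dosage / n_alleles
    maf = np.minimum(freq1, 1.0 - freq1)
    polymorphic = complete & (maf > 0)

    report = pd.DataFrame({
        "marker": panel.info["marker"],
        "n_blanked": n_blanked,
        "complete": complete,
        "pedigree_maf": maf,
        "retained": polymorphic,
    })
    kept = report.index[report["retained"]]
    return panel.subset(kept), report


# --------------------------------------------------------------------------
# Restriction to founders + affected individuals
# --------------------------------------------------------------------------

def restrict_founders_affected(pedigree: Pedigree) -> Pedigree:
    """Drop unaffected non-founders, keeping the minimal connecting ancestors.

    Retains every affected individual, all of their ancestors (which
    includes the founders of each affected lineage), and nothing else.
    Retained non-founders who are not themselves affected are connectors:
    they are re-marked with unknown affection, since they are assumed
    obligate carriers whose phenotype must not enter the likelihood.
    """
    affected = pedigree.affected
    if not affected:
        raise PedigreeError("no affected individuals to analyze")
    keep: set[str] = set(affected)
    for iid in affected:
        keep |= pedigree.ancestors_of(iid)
    inds = []
    for iid in pedigree.topological_order:
        if iid not in keep:
            continue
        ind = pedigree.members[iid]
        if not ind.is_founder and ind.affection != AFFECTED:
            ind = replace(ind, affection=UNKNOWN)
        inds.append(ind)
    return Pedigree(inds, family_id=pedigree.family_id)


def obligate_carriers(pedigree: Pedigree) -> set[str]:
    """Non-founders of unknown affection standing between affected relatives."""
    aff = set(pedigree.affected)
    out = set()
    for iid, ind in pedigree.members.items():
        if ind.is_founder or ind.affection != UNKNOWN:
            continue
        if pedigree.descendants_of(iid) & aff:
            out.add(iid)
    return out


# --------------------------------------------------------------------------
# Exact two-locus likelihood by factor elimination
# --------------------------------------------------------------------------
#
# Per-individual state = ordered pair of haplotypes (paternal, maternal);
# haplotype = (disease allele d, marker allele a), encoded h = 2 d + a,
# state = 4 * h_pat + h_mat, giving 16 states per individual.

def _gamete_matrix(theta: float) -> np.ndarray:
    """g[parent_state, gamete_hap]: transmission distribution of one meiosis."""
    g = np.zeros((16, 4))
    for h1 in range(4):
        for h2 in range(4):
            s = 4 * h1 + h2
            d1, a1 = divmod(h1, 2)
            d2, a2 = divmod(h2, 2)
            g[s, h1] += 0.5 * (1.0 - theta)
            g[s, 2 * d1 + a2] += 0.5 * theta
            g[s, h2] += 0.5 * (1.0 - theta)
            g[s, 2 * d2 + a1] += 0.5 * theta
    return g


def _founder_prior(q: float, p: float) -> np.ndarray:
    # haplotype index h = 2d + a; linkage equilibrium between the loci
    hap = np.array([(1 - q) * (1 - p), (1 - q) * p, q * (1 - p), q * p])
    return np.outer(hap, hap).reshape(16)


def _evidence(ind: Individual, genotype: float | None,
              model: DiseaseModel) -> np.ndarray:
    ev = np.ones(16)
    for s in range(16):
        hp, hm = divmod(s, 4)
        n_d = hp // 2 + hm // 2
        n_a = hp % 2 + hm % 2
        w = 1.0
        if ind.affection == AFFECTED:
            w *= model.penetrance[n_d]
        elif ind.affection == UNAFFECTED:
            w *= 1.0 - model.penetrance[n_d]
        if genotype is not None and not (isinstance(genotype, float) and math.isnan(genotype)):
            w *= 1.0 if n_a == int(genotype) else 0.0
        ev[s] = w
    return ev


def _multiply_into(union: list[str], acc: np.ndarray,
                   vars_: tuple[str, ...], arr: np.ndarray) -> np.ndarray:
    pos = [union.index(v) for v in vars_]
    order = np.argsort(pos)
    arr = np.transpose(arr, axes=order)
    spos = sorted(pos)
    slicer = tuple(slice(None) if i in spos else None for i in range(len(union)))
    return acc * arr[slicer]


def pedigree_likelihood(
    pedigree: Pedigree,
    genotypes: dict[str, float | None],
    model: DiseaseModel,
    linked: bool,
    marker_freq: float = 0.5,
) -> float:
    """log10 likelihood of the marker data + phenotypes under the model.

    ``linked`` evaluates theta = 0 (marker co-transmits with the disease
    allele); otherwise theta = 1/2.  Genotypes are allele-1 dosages (0/1/2)
    or None/NaN for untyped individuals.  Returns -inf for an impossible
    configuration (e.g. an obligate recombinant at theta = 0).
    """
    if pedigree.n_meioses > MAX_MEIOSES:
        raise EnumerationBoundError(
            f"pedigree has {pedigree.n_meioses} meioses; exact enumeration "
            f"is limited to {MAX_MEIOSES}")
    theta = 0.0 if linked else 0.5
    g = _gamete_matrix(theta)
    prior = _founder_prior(model.q, marker_freq)

    factors: list[tuple[tuple[str, ...], np.ndarray]] = []
    for iid in pedigree.topological_order:
        ind = pedigree[iid]
        if ind.is_founder:
            factors.append(((iid,), prior.copy()))
        else:
            # T[child, father, mother]
            t = np.zeros((16, 16, 16))
            for c in range(16):
                hp, hm = divmod(c, 4)
                t[c, :, :] = np.outer(g[:, hp], g[:, hm])
            factors.append(((iid, ind.father, ind.mother), t))
        factors.append(((iid,), _evidence(ind, genotypes.get(iid), model)))

    # eliminate children before parents to keep factor arity small
    for v in reversed(pedigree.topological_order):
        group = [f for f in factors if v in f[0]]
        factors = [f for f in factors if v not in f[0]]
        union: list[str] = []
        for vars_, _ in group:
            for u in vars_:
                if u not in union:
                    union.append(u)
        union = [u for u in union if u != v] + [v]
        acc = np.ones((16,) * len(union))
        for vars_, arr in group:
            acc = _multiply_into(union, acc, vars_, arr)
        factors.append((tuple(union[:-1]), acc.sum(axis=-1)))

    like = 1.0
    for _, arr in factors:
        like *= float(arr)
    if like <= 0.0:
        return -math.inf
    return math.log10(like)


# --------------------------------------------------------------------------
# LOD scores
# --------------------------------------------------------------------------

class _Excluded:
    """Sentinel for LOD = -infinity (an obligate recombinant excludes linkage)."""
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "EXCLUDED"


EXCLUDED = _Excluded()
LodValue = float | _Excluded


def lod_score(
    pedigree: Pedigree,
    genotypes: dict[str, float | None],
    model: DiseaseModel,
    marker_freq: float = 0.5,
) -> LodValue:
    """LOD = log10 L(theta=0) - log10 L(theta=1/2) at a single marker.

    Returns the EXCLUDED sentinel (never a float) when the marker carries an
    obligate recombinant, i.e. L(linked) = 0.
    """
    l_linked = pedigree_likelihood(pedigree, genotypes, model, linked=True,
                                   marker_freq=marker_freq)
    l_unlinked = pedigree_likelihood(pedigree, genotypes, model, linked=False,
                                     marker_freq=marker_freq)
    if math.isinf(l_unlinked):
        raise ValueError("phenotypes impossible under the disease model")
    if math.isinf(l_linked):
        return EXCLUDED
    return l_linked - l_unlinked


def informative_meioses(pedigree: Pedigree) -> int:
    """Count phase-resolvable carrier transmissions in a restricted pedigree.

    A transmission contributes to the attainable LOD when both parent and
    child are carriers under the dominant model: affected individuals, or
    unexamined connectors with affected descendants (obligate carriers).
    Each founder carrier tops a lineage with unknown phase, which consumes
    one transmission to establish, so one is subtracted per transmitting
    founder carrier.
    """
    carriers = set(pedigree.affected) | obligate_carriers(pedigree)
    n_edges = 0
    apex = set()
    for child in pedigree.nonfounders:
        if child not in carriers:
            continue
        ind = pedigree[child]
        for parent in (ind.father, ind.mother):
            if parent in carriers:
                n_edges += 1
                if pedigree[parent].is_founder:
                    apex.add(parent)
    return n_edges - len(apex)


def max_attainable_lod(pedigree: Pedigree) -> float:
    """Ceiling on the LOD score: m * log10(2) for m informative meioses.

    Attained exactly by a fully informative, co-segregating marker; round to
    one decimal for display.
    """
    return informative_meioses(pedigree) * LOG10_2


def lod_track(
    pedigree: Pedigree,
    panel: MarkerPanel,
    model: DiseaseModel,
) -> pd.DataFrame:
    """Per-marker LOD scores: columns marker, cm, bp, lod (float or EXCLUDED)."""
    rows = []
    for mid in panel.info.index:
        info = panel.info.loc[mid]
        geno = panel.genotypes.loc[mid].to_dict()
        lod = lod_score(pedigree, geno, model, marker_freq=float(info["freq"]))
        rows.append({"marker": info["marker"], "cm": info.get("cm", np.nan),
                     "bp": int(info["bp"]), "lod": lod})
    return pd.DataFrame(rows)


def write_lod_track(path, track: pd.DataFrame) -> None:
    out = track.copy()
    out["lod"] = [("excluded" if isinstance(v, _Excluded) else f"{v:.6g}")
                  for v in out["lod"]]
    out.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Candidate interval extraction
# --------------------------------------------------------------------------

@dataclass
class CandidateInterval:
    """A linkage peak: the minimum and maximum linked intervals.

    The minimum interval spans the contiguous run of markers attaining the
    maximum LOD.  The maximum interval spans the positions strictly between
    the nearest flanking markers whose LOD falls below the maximum (flanks
    excluded), so its bp length is flank_right - flank_left - 1.
    """
    max_lod: float
    min_start_bp: int
    min_end_bp: int
    flank_left_bp: int | None
    flank_right_bp: int | None
    n_markers: int
    min_start_cm: float = math.nan
    min_end_cm: float = math.nan

    @property
    def min_length_bp(self) -> int:
        return span_bp(self.min_start_bp, self.min_end_bp)

    @property
    def max_length_bp(self) -> int | None:
        if self.flank_left_bp is None or self.flank_right_bp is None:
            return None
        return self.flank_right_bp - self.flank_left_bp - 1

    @property
    def cm_span(self) -> float:
        return self.min_end_cm - self.min_start_cm

    def to_dict(self) -> dict:
        return {
            "max_lod": self.max_lod,
            "min_interval_bp": [self.min_start_bp, self.min_end_bp],
            "min_length_bp": self.min_length_bp,
            "flanking_markers_bp": [self.flank_left_bp, self.flank_right_bp],
            "max_length_bp": self.max_length_bp,
            "n_markers": self.n_markers,
            "cm_span": None if math.isnan(self.cm_span) else self.cm_span,
        }


def extract_interval(
    track: pd.DataFrame,
    min_cm: float | None = None,
    tol: float = 1e-9,
) -> list[CandidateInterval]:
    """Extract candidate intervals from a LOD track.

    All maximal plateaus (contiguous marker runs attaining the global
    maximum LOD) are returned, longest maximum-interval first.  Excluded
    markers rank below every finite LOD.  ``min_cm`` drops plateaus whose
    cM span is not larger than the cutoff — the report-level heuristic that
    intervals under ~1 cM are genotyping errors or ancestral haplotypes
    rather than familial linkage; pass None (the default here) to keep all.
    """
    if len(track) == 0:
        raise ValueError("empty LOD track")
    lods = np.array([(-math.inf if isinstance(v, _Excluded) else float(v))
                     for v in track["lod"]])
    bp = track["bp"].to_numpy()
    cm = track["cm"].to_numpy(dtype=float) if "cm" in track.columns \
        else np.full(len(track), math.nan)
    peak = lods.max()
    if math.isinf(peak):
        raise ValueError("all markers excluded; no linked interval")
    at_max = lods >= peak - tol

    intervals: list[CandidateInterval] = []
    i = 0
    while i < len(lods):
        if not at_max[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(lods) and at_max[j + 1]:
            j += 1
        intervals.append(CandidateInterval(
            max_lod=peak,
            min_start_bp=int(bp[i]), min_end_bp=int(bp[j]),
            flank_left_bp=int(bp[i - 1]) if i > 0 else None,
            flank_right_bp=int(bp[j + 1]) if j + 1 < len(lods) else None,
            n_markers=j - i + 1,
            min_start_cm=float(cm[i]), min_end_cm=float(cm[j]),
        ))
        i = j + 1
    if min_cm is not None:
        kept = [iv for iv in intervals
                if not math.isnan(iv.cm_span) and iv.cm_span > min_cm]
        intervals = kept if kept else intervals
    intervals.sort(key=lambda iv: (-(iv.max_length_bp or iv.min_length_bp)))
    return intervals
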