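"""Independent oracles: deliberately naive reimplementations used only by tests.

The pedigree-likelihood oracle enumerates complete per-individual two-locus
genotype configurations depth-first with no factorization — every nonzero
configuration's probability is formed as an explicit product and the results
are summed.  The binomial oracle sums exact integer binomial-coefficient
tails.  Neither shares code with the package implementations they check.
"""

from __future__ import annotations

import math

from famseq.linkage import AFFECTED, UNAFFECTED, DiseaseModel, Pedigree


def _gamete_prob(state: int, g: int, theta: float) -> float:
    h1, h2 = divmod(state, 4)
    d1, a1 = divmod(h1, 2)
    d2, a2 = divmod(h2, 2)
    p = 0.0
    if g == h1:
        p += 0.5 * (1 - theta)
    if g == 2 * d1 + a2:
        p += 0.5 * theta
    if g == h2:
        p += 0.5 * (1 - theta)
    if g == 2 * d2 + a1:
        p += 0.5 * theta
    return p


def brute_force_likelihood(
    pedigree: Pedigree,
    genotypes: dict,
    model: DiseaseModel,
    linked: bool,
    marker_freq: float = 0.5,
) -> float:
    """log10 likelihood by unfactorized enumeration of all configurations."""
    theta = 0.0 if linked else 0.5
    q, p = model.q, marker_freq
    hap_prior = [(1 - q) * (1 - p), (1 - q) * p, q * (1 - p), q * p]
    order = pedigree.topological_order
    total = 0.0
    assign: dict[str, int] = {}

    def state_weight(iid: str, s: int) -> float:
        ind = pedigree[iid]
        hp, hm = divmod(s, 4)
        n_d = hp // 2 + hm // 2
        n_a = hp % 2 + hm % 2
        g = genotypes.get(iid)
        if g is not None and not (isinstance(g, float) and math.isnan(g)):
            if n_a != int(g):
                return 0.0
        if ind.affection == AFFECTED:
            pen = model.penetrance[n_d]
        elif ind.affection == UNAFFECTED:
            pen = 1.0 - model.penetrance[n_d]
        else:
            pen = 1.0
        if pen == 0.0:
            return 0.0
        if ind.is_founder:
            return hap_prior[hp] * hap_prior[hm] * pen
        tf = _gamete_prob(assign[ind.father], hp, theta)
        tm = _gamete_prob(assign[ind.mother], hm, theta)
        return tf * tm * pen

    def rec(i: int, weight: float) -> None:
        nonlocal total
        if i == len(order):
            total += weight
            return
        iid = order[i]
        for s in range(16):
            w = state_weight(iid, s)
            if w == 0.0:
                continue
            assign[iid] = s
            rec(i + 1, weight * w)
            del assign[iid]

    rec(0, 1.0)
    return -math.inf if total <= 0.0 else math.log10(total)


def exact_binomial_p(k: int, n: int) -> float:
    """Two-sided doubled-smaller-tail binomial p at p0=1/2, by integer sums."""
    lower = sum(math.comb(n, i) for i in range(0, k + 1))
    upper = sum(math.comb(n, i) for i in range(k, n + 1))
    p = 2 * min(lower, upper) / (2 ** n)
    return min(1.0, p)
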