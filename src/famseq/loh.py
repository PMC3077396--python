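"""Loss-of-heterozygosity statistics on subclone allele counts.

A germline-heterozygous mutation is expected in half of the PCR subclones
amplified from a tissue.  If a fraction f of the tissue's cells has lost
the wild-type allele (the somatic "second hit"), subclones carry the mutant
allele with probability (1+f)/2: LOH cells contribute only mutant template
while the remainder stay heterozygous.  The observed mutant count k of n
subclones is therefore tested against the null proportion 1/2, and f is
estimated by inverting the mixture: f = 2(k/n) - 1.

The default test is the normal approximation without continuity correction
(two-sided, 2*(1 - Phi(|z|))); an exact binomial test (doubled smaller
tail, capped at 1) is available as ``method="exact-binomial"``.  The
original analysis does not name its test; the z approximation is the
reconstruction that reproduces the printed p-values from the printed
counts, and is flagged as such here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

METHODS = ("z-approx", "exact-binomial")


@dataclass(frozen=True)
class SubcloneCount:
    """Mutant subclones k of n from one tissue compartment."""
    k: int
    n: int
    tissue: str = ""

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.k <= self.n:
            raise ValueError("k must satisfy 0 <= k <= n")

    @property
    def proportion(self) -> float:
        return self.k / self.n


@dataclass
class LohResult:
    tissue: str
    k: int
    n: int
    proportion: float
    p_value: float
    method: str
    f_hat: float             # clipped to [0, 1]
    f_hat_raw: float         # 2k/n - 1, may be negative
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def proportion_test(k: int, n: int, p0: float = 0.5,
                    method: str = "z-approx") -> float:
    """Two-sided test of k/n against the null proportion p0.

    ``z-approx``: normal approximation without continuity correction,
    p = 2*(1 - Phi(|p_hat - p0| / sqrt(p0*(1-p0)/n))).
    ``exact-binomial``: doubled smaller tail of the Binomial(n, p0) mass,
    capped at 1.  The observed value equal to the null expectation gives
    p = 1 under both methods.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require n >= 1 and 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if method == "z-approx":
        z = (k / n - p0) / math.sqrt(p0 * (1.0 - p0) / n)
        return float(2.0 * stats.norm.sf(abs(z)))
    if method == "exact-binomial":
        lower = float(stats.binom.cdf(k, n, p0))
        upper = float(stats.binom.sf(k - 1, n, p0))
        return min(1.0, 2.0 * min(lower, upper))
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def estimate_loh_fraction(k: int, n: int,
                          confidence: float = 0.95) -> tuple[float, float, tuple[float, float]]:
    """Invert the subclone mixture: f_hat = 2*(k/n) - 1.

    Returns (f_hat clipped to [0, 1], raw unclipped estimate, CI).  The
    confidence interval transforms an exact (Clopper-Pearson) binomial CI
    for k/n through f = 2p - 1 and clips it to [0, 1].  The raw estimate is
    unbiased for f under the mixture model; the clipped one is what is
    reported, since a cell fraction cannot be negative.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require n >= 1 and 0 <= k <= n")
    raw = 2.0 * k / n - 1.0
    clipped = min(1.0, max(0.0, raw))
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=confidence,
                                             method="exact")
    lo = min(1.0, max(0.0, 2.0 * ci.low - 1.0))
    hi = min(1.0, max(0.0, 2.0 * ci.high - 1.0))
    return clipped, raw, (lo, hi)


def loh_result(count: SubcloneCount, p0: float = 0.5,
               method: str = "z-approx") -> LohResult:
    f_hat, raw, (lo, hi) = estimate_loh_fraction(count.k, count.n)
    return LohResult(
        tissue=count.tissue, k=count.k, n=count.n,
        proportion=count.proportion,
        p_value=proportion_test(count.k, count.n, p0, method),
        method=method, f_hat=f_hat, f_hat_raw=raw, ci_low=lo, ci_high=hi)


@dataclass
class TissueComparison:
    lesion: LohResult
    control: LohResult
    z: float
    p_value: float
    low_power: bool

    def to_dict(self) -> dict:
        return {"lesion": self.lesion.to_dict(),
                "control": self.control.to_dict(),
                "two_proportion_z": self.z,
                "two_proportion_p": self.p_value,
                "low_power": self.low_power}


def compare_tissues(lesion: SubcloneCount, control: SubcloneCount,
                    method: str = "z-approx") -> TissueComparison:
    """Direct lesion-vs-control contrast plus both one-sample results.

    Pooled two-proportion z-test; groups with n < 5 are flagged low-power
    (identical proportions give p = 1 regardless).  The one-sample tests
    against 1/2 are bundled since they are the primary published contrast.
    """
    p1, p2 = lesion.proportion, control.proportion
    pooled = (lesion.k + control.k) / (lesion.n + control.n)
    var = pooled * (1.0 - pooled) * (1.0 / lesion.n + 1.0 / control.n)
    if var == 0.0:
        z, p = 0.0, 1.0
    else:
        z = (p1 - p2) / math.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return TissueComparison(
        lesion=loh_result(lesion, method=method),
        control=loh_result(control, method=method),
        z=z, p_value=p,
        low_power=lesion.n < 5 or control.n < 5)


# --------------------------------------------------------------------------
# TSV I/O
# --------------------------------------------------------------------------

def read_subclone_counts(path) -> list[SubcloneCount]:
    """TSV with columns tissue, k, n."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    return [SubcloneCount(k=int(r.k), n=int(r.n), tissue=str(r.tissue))
            for r in df.itertuples(index=False)]


def write_loh_results(results: list[LohResult], path) -> None:
    import json
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)
        fh.write("\n")
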