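"""Alpha-diversity suite and feature-accumulation curves.

Implements the classical univariate diversity battery used for comparing
inocula with cultured colony arrays: richness S (= Hill number N0),
Margalef's d, Pielou's J', Brillouin's H, Fisher's alpha, Shannon H'
(natural log), Simpson 1-lambda and the unbiased 1-lambda', the Hill numbers
N1 = exp(H'), N2 = 1/sum(p^2), N_inf = 1/p_max and the derived ratios
N10, N10', N21, N21', Hurlbert's expected richness ES(m) in a random
subsample of m reads (hypergeometric), and Good's coverage 1 - F1/N.

Quantities undefined for a given input (e.g. J' when S = 1) are reported as
``None`` rather than NaN, so downstream code must handle them explicitly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .profiles import TaxonProfile, aggregate


@dataclass
class DiversityRecord:
    """One sample's full index suite. ``None`` marks undefined quantities."""

    S: int
    N: int
    d: float | None                 # Margalef (S-1)/ln N
    J_prime: float | None           # Pielou H'/ln S
    brillouin: float
    fisher_alpha: float | None
    H_prime: float                  # Shannon, natural log
    one_minus_lambda: float         # 1 - sum p^2
    one_minus_lambda_prime: float | None  # unbiased, needs N > 1
    N1: float
    N2: float
    N_inf: float
    N10: float
    N10_prime: float | None
    N21: float | None
    N21_prime: float | None
    ES_m: float | None              # Hurlbert expected richness at m
    m: int
    goods_coverage: float


def _fisher_alpha(S: int, N: int) -> float | None:
    """Solve S = alpha * ln(1 + N/alpha) by bracketed root finding."""
    if S <= 0 or N <= 0 or S >= N:
        # alpha diverges as S -> N (every read its own feature)
        return None
    f = lambda a: a * math.log1p(N / a) - S
    lo, hi = 1e-8, 1e8
    if f(lo) > 0 or f(hi) < 0:
        return None
    return float(brentq(f, lo, hi, xtol=1e-10))


def hurlbert_es(counts: np.ndarray, m: int) -> float:
    """Expected feature count in a without-replacement subsample of m reads.

    ES(m) = sum_i [1 - C(N - n_i, m) / C(N, m)], evaluated with log-gamma.
    """
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if m > N:
        raise ValueError(f"subsample size m={m} exceeds total reads N={N}")
    if m <= 0:
        raise ValueError("m must be positive")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    log_cNm = log_choose(N, m)
    es = 0.0
    for n_i in counts:
        if N - n_i < m:
            es += 1.0
        else:
            es += 1.0 - math.exp(log_choose(N - n_i, m) - log_cNm)
    return float(es)


def diversity_suite(counts: np.ndarray, m: int = 100) -> DiversityRecord:
    """Compute the full index suite for one sample of integer read counts."""
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (counts < 0).any():
        raise ValueError("negative counts")
    counts = counts[counts > 0].astype(np.int64)
    if counts.size == 0:
        raise ValueError("all-zero count vector")

    S = int(counts.size)
    N = int(counts.sum())
    p = counts / N

    H_prime = float(-(p * np.log(p)).sum())
    lam = float((p**2).sum())
    N1 = math.exp(H_prime)
    N2 = 1.0 / lam
    N_inf = 1.0 / float(p.max())

    d = (S - 1) / math.log(N) if N > 1 else None
    J = H_prime / math.log(S) if S > 1 else None
    brillouin = float((gammaln(N + 1) - gammaln(counts + 1).sum()) / N)
    lam_prime = (
        float((counts * (counts - 1)).sum() / (N * (N - 1))) if N > 1 else None
    )
    one_minus_lp = 1.0 - lam_prime if lam_prime is not None else None

    N10 = N1 / S
    N10p = (N1 - 1) / (S - 1) if S > 1 else None
    N21 = N2 / N1
    N21p = (N2 - 1) / (N1 - 1) if abs(N1 - 1) > 1e-12 else None

    es = hurlbert_es(counts, min(m, N))
    singletons = int((counts == 1).sum())
    goods = 1.0 - singletons / N

    return DiversityRecord(
        S=S, N=N, d=d, J_prime=J, brillouin=brillouin,
        fisher_alpha=_fisher_alpha(S, N),
        H_prime=H_prime,
        one_minus_lambda=1.0 - lam,
        one_minus_lambda_prime=one_minus_lp,
        N1=N1, N2=N2, N_inf=N_inf,
        N10=N10, N10_prime=N10p, N21=N21, N21_prime=N21p,
        ES_m=es, m=min(m, N), goods_coverage=goods,
    )


def diversity_table(profile: TaxonProfile, level: str | None = None, m: int = 100):
    """One DiversityRecord per sample, optionally after rank aggregation."""
    import pandas as pd

    prof = aggregate(profile, level) if level else profile
    rows = {}
    for j, sample in enumerate(prof.samples):
        rec = diversity_suite(prof.counts[:, j], m=m)
        rows[sample] = vars(rec)
    return pd.DataFrame(rows).T


def accumulation_curve(
    profile: TaxonProfile,
    level: str | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean +/- sd of cumulative unique features over sample-order permutations.

    Returns ``(mean, sd)`` arrays of length n_samples.  With k or fewer
    samples such that all orderings can be enumerated cheaply
    (n_samples! <= n_perm), enumeration replaces random permutation.
    """
    if profile.n_samples < 2:
        raise ValueError("accumulation curve needs >= 2 samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    prof = aggregate(profile, level) if level else profile
    present = prof.counts > 0  # features x samples
    n = prof.n_samples
    rng = np.random.default_rng(seed)
    if math.factorial(n) <= n_perm:
        orders = [np.array(o) for o in itertools.permutations(range(n))]
    else:
        orders = [rng.permutation(n) for _ in range(n_perm)]
    curves = np.empty((len(orders), n))
    for r, order in enumerate(orders):
        seen = np.zeros(prof.n_features, dtype=bool)
        for step, j in enumerate(order):
            seen |= present[:, j]
            curves[r, step] = seen.sum()
    return curves.mean(axis=0), curves.std(axis=0)
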