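"""Six entropy estimators for short RR-interval series.

Five irregularity measures (ApEn, SampEn, FuzzyEn, conditional entropy,
permutation entropy) and one complexity measure (distribution entropy),
with the embedding/distance primitives they share.

Conventions
-----------
* Embedded vectors are ``u_m(i) = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})``
  for ``i = 0 .. N - m*tau - 1`` — i.e. ``N - m*tau`` vectors at dimension
  ``m``, and ``N - (m+1)*tau`` at ``m+1``.  Permutation entropy uses the
  classical ``N - (m-1)*tau`` ordinal windows instead, since it needs no
  matching template at ``m+1``.
* Similarity uses the Chebyshev (max-component) distance.
* The tolerance is ``r = r_coeff * sigma`` with ``sigma`` the *sample*
  standard deviation (N-1 denominator) of the analyzed series, making
  ApEn/SampEn/FuzzyEn invariant under affine rescaling of the input.
* ApEn counts self-matches with ``d <= r``; SampEn excludes self-matches
  and counts ``d < r`` (the classical conventions).
* DistEn and PermEn are normalized to [0, 1] (log base 2 over their
  maximal entropies); conditional entropy is reported unnormalized in nats.

Degenerate inputs (constant series, series with no template matches) yield
NaN with a named flag rather than raising, so whole-night feature extraction
never aborts; the staging layer decides imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "EntropyParams",
    "EntropyFeatures",
    "ENTROPY_FEATURES",
    "embed",
    "apen",
    "sampen",
    "fuzzyen",
    "disten",
    "cond_entropy",
    "permen",
    "entropy_features",
]

ENTROPY_FEATURES = ("apen", "sampen", "fuzzyen", "disten", "ce", "permen")


@dataclass
class EntropyParams:
    """Estimator parameters.

    m : embedding dimension for ApEn/SampEn/FuzzyEn/DistEn/CE (default 2)
    tau : embedding delay in beats (default 1)
    r_coeff : tolerance multiplier; r = r_coeff * sigma (default 0.2)
    n_bins : histogram bins for DistEn (default 64)
    xi : quantization levels for conditional entropy (default 6)
    m_perm : embedding dimension for permutation entropy (default 3)
    sd_ddof : delta degrees of freedom for sigma (1 = sample SD)
    """

    m: int = 2
    tau: int = 1
    r_coeff: float = 0.2
    n_bins: int = 64
    xi: int = 6
    m_perm: int = 3
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1 or self.m_perm < 2:
            raise ValueError("m >= 1, tau >= 1, m_perm >= 2 required")
        if self.r_coeff <= 0 or self.n_bins < 2 or self.xi < 2:
            raise ValueError("r_coeff > 0, n_bins >= 2, xi >= 2 required")


@dataclass
class EntropyFeatures:
    """The six per-epoch entropy values plus degenerate-input flags."""

    apen: float
    sampen: float
    fuzzyen: float
    disten: float
    ce: float
    permen: float
    flags: Dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in ENTROPY_FEATURES}


def embed(x: np.ndarray, m: int, tau: int, n_vectors: int | None = None) -> np.ndarray:
    """Time-delay embedding: rows are u_m(i), i = 0 .. n_vectors - 1.

    By default ``n_vectors = N - m*tau`` (the template-matching convention
    used by ApEn/SampEn/FuzzyEn/DistEn).
    """
    x = np.asarray(x, dtype=float)
    n = len(x) - m * tau if n_vectors is None else n_vectors
    if n < 1:
        raise ValueError(f"series too short to embed: N={len(x)}, m={m}, tau={tau}")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _chebyshev_matrix(emb: np.ndarray) -> np.ndarray:
    if emb.shape[1] == 1:
        return np.abs(emb - emb.T)
    return squareform(pdist(emb, metric="chebyshev"))


def _tolerance(x: np.ndarray, p: EntropyParams) -> float:
    """r = r_coeff * sample SD; 0 for an (exactly) constant series."""
    if len(x) < 2 or np.ptp(x) == 0.0:
        return 0.0
    return p.r_coeff * float(np.std(x, ddof=p.sd_ddof))


def apen(x, p: EntropyParams | None = None) -> float:
    """Approximate entropy: Phi_m(r) - Phi_{m+1}(r), self-matches included.

    ``C_i = (# j with d(u_i, u_j) <= r) / (N - m*tau)`` and ``Phi`` is the
    mean of ``ln C_i``.  NaN when sigma (hence r) is zero.
    """
    p = p or EntropyParams()
    x = np.asarray(x, dtype=float)
    r = _tolerance(x, p)
    if r == 0.0 or not np.isfinite(r):
        return float("nan")

    def phi(m: int) -> float:
        emb = embed(x, m, p.tau)
        d = _chebyshev_matrix(emb)
        c = (d <= r).sum(axis=1) / emb.shape[0]
        return float(np.mean(np.log(c)))

    return phi(p.m) - phi(p.m + 1)


def _sampen_psi(x: np.ndarray, m: int, tau: int, r: float) -> float:
    emb = embed(x, m, tau)
    n = emb.shape[0]
    if n < 2:
        return float("nan")
    d = _chebyshev_matrix(emb)
    counts = (d < r).sum(axis=1) - 1  # drop the self-match on the diagonal
    return float(np.mean(counts / (n - 1)))


def sampen(x, p: EntropyParams | None = None) -> float:
    """Sample entropy: -ln(Psi_{m+1} / Psi_m), self-matches excluded, d < r.

    NaN (flagged upstream as ``no_matches``) when either template stage has
    no within-tolerance pairs; NaN when sigma = 0.
    """
    p = p or EntropyParams()
    x = np.asarray(x, dtype=float)
    r = _tolerance(x, p)
    if r == 0.0 or not np.isfinite(r):
        return float("nan")
    psi_m = _sampen_psi(x, p.m, p.tau, r)
    psi_m1 = _sampen_psi(x, p.m + 1, p.tau, r)
    if not (psi_m > 0.0) or not (psi_m1 > 0.0):
        return float("nan")
    return -math.log(psi_m1 / psi_m)


def _fuzzy_psi(x: np.ndarray, m: int, tau: int, r: float) -> float:
    emb = embed(x, m, tau)
    n = emb.shape[0]
    if n < 2:
        return float("nan")
    d = _chebyshev_matrix(emb)
    mem = np.exp(-math.log(2.0) * (d / r) ** 2)
    np.fill_diagonal(mem, 0.0)
    return float(np.mean(mem.sum(axis=1) / (n - 1)))


def fuzzyen(x, p: EntropyParams | None = None) -> float:
    """Fuzzy entropy: SampEn with the hard match replaced by the fuzzy
    membership ``exp(-ln(2) (d/r)^2)`` (membership 1/2 exactly at d = r).

    Always finite for sigma > 0 because memberships are strictly positive.
    """
    p = p or EntropyParams()
    x = np.asarray(x, dtype=float)
    r = _tolerance(x, p)
    if r == 0.0 or not np.isfinite(r):
        return float("nan")
    return -math.log(_fuzzy_psi(x, p.m + 1, p.tau, r) / _fuzzy_psi(x, p.m, p.tau, r))


def disten(x, p: EntropyParams | None = None) -> float:
    """Distribution entropy: normalized Shannon entropy of the histogram of
    all off-diagonal inter-vector Chebyshev distances.

    ``B = n_bins`` equal-width bins span [min, max] of the distances; empty
    bins contribute nothing; the result lies in [0, 1].  All-equal distances
    occupy a single bin, giving 0.
    """
    p = p or EntropyParams()
    x = np.asarray(x, dtype=float)
    emb = embed(x, p.m, p.tau)
    if emb.shape[0] < 2:
        return float("nan")
    d = pdist(emb, metric="chebyshev")
    lo, hi = float(d.min()), float(d.max())
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(d, bins=p.n_bins, range=(lo, hi))
    prob = counts / counts.sum()
    prob = prob[prob > 0]
    return float(-(prob * np.log2(prob)).sum() / np.log2(p.n_bins))


def _quantize(x: np.ndarray, xi: int) -> np.ndarray:
    """Uniform coarse-graining of the full range into xi integer levels."""
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros(len(x), dtype=np.int64)
    q = np.floor((x - lo) / (hi - lo) * xi).astype(np.int64)
    return np.minimum(q, xi - 1)  # the maximum maps to level xi - 1


def _shannon_nats(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    prob = counts / counts.sum()
    return float(-(prob * np.log(prob)).sum())


def _pattern_codes(q: np.ndarray, m: int, tau: int, xi: int) -> np.ndarray:
    """Decimal codes of the ``m``-symbol patterns ending at each index."""
    n = len(q) - (m - 1) * tau
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    weights = xi ** np.arange(m - 1, -1, -1)
    return (q[idx] * weights).sum(axis=1)


def cond_entropy(x, p: EntropyParams | None = None) -> float:
    """Corrected conditional entropy of the quantized series (in nats).

    The series is coarse-grained into ``xi`` uniform levels over its full
    range; ``CE = SE(z) - SE(w) + perc(m) * SE(1)`` where ``w``/``z`` are
    the m- and (m+1)-symbol pattern codes, ``perc(m)`` the fraction of
    m-patterns occurring exactly once (the single-pattern correction), and
    ``SE(1)`` the Shannon entropy of the quantized samples.  A constant
    series gives 0.
    """
    p = p or EntropyParams()
    x = np.asarray(x, dtype=float)
    if len(x) <= p.m * p.tau:
        raise ValueError("series too short for conditional entropy")
    q = _quantize(x, p.xi)
    w = _pattern_codes(q, p.m, p.tau, p.xi)
    z = _pattern_codes(q, p.m + 1, p.tau, p.xi)
    _, counts = np.unique(w, return_counts=True)
    perc = float(counts[counts == 1].sum() / len(w))
    se1 = _shannon_nats(q)
    return _shannon_nats(z) - _shannon_nats(w) + perc * se1


def permen(x, p: EntropyParams | None = None) -> float:
    """Normalized permutation entropy of ordinal m-tuples (m = m_perm).

    Each window of ``m`` consecutive values (delay tau) is reduced to the
    permutation that sorts it ascending; ties are broken by order of
    occurrence (stable sort).  The Shannon entropy (base 2) of the pattern
    frequencies is divided by ``log2(m!)``, so the result lies in [0, 1]:
    0 for a monotone series, 1 for uniformly distributed patterns.
    """
    p = p or EntropyParams()
    x = np.asarray(x, dtype=float)
    m = p.m_perm
    n = len(x) - (m - 1) * p.tau
    if n < 1:
        raise ValueError(f"series too short for permutation entropy: N={len(x)}")
    idx = np.arange(n)[:, None] + p.tau * np.arange(m)[None, :]
    windows = x[idx]
    patterns = np.argsort(windows, axis=1, kind="stable")
    weights = (m ** np.arange(m)).astype(np.int64)
    codes = patterns @ weights
    _, counts = np.unique(codes, return_counts=True)
    prob = counts / counts.sum()
    h = float(-(prob * np.log2(prob)).sum())
    return h / math.log2(math.factorial(m))


def entropy_features(x, p: EntropyParams | None = None) -> EntropyFeatures:
    """All six entropy measures of one preprocessed epoch.

    Accepts a plain array or a :class:`~somnentropy.preprocess.CleanRR`.
    Degenerate results carry named flags (``degenerate_tolerance`` for a
    zero-variance series, ``no_matches`` when SampEn finds no template
    pairs) and NaN values; the record is still returned.
    """
    p = p or EntropyParams()
    rr = np.asarray(getattr(x, "rr", x), dtype=float)
    flags: Dict[str, str] = {}
    degenerate = len(rr) < 2 or np.ptp(rr) == 0.0

    if degenerate:
        a = s = f = float("nan")
        d = 0.0 if len(rr) > p.m * p.tau + 1 else float("nan")
        for name in ("apen", "sampen", "fuzzyen"):
            flags[name] = "degenerate_tolerance"
    else:
        # the four distance-based measures share the same embeddings and
        # Chebyshev matrices at m and m+1; computing them once roughly
        # halves per-epoch cost relative to the standalone functions
        r = _tolerance(rr, p)
        d2 = _chebyshev_matrix(embed(rr, p.m, p.tau))
        d3 = _chebyshev_matrix(embed(rr, p.m + 1, p.tau))
        a = s = f = float("nan")
        phis = []
        psis_hard = []
        psis_fuzzy = []
        for dm in (d2, d3):
            n = dm.shape[0]
            c_incl = (dm <= r).sum(axis=1) / n
            phis.append(float(np.mean(np.log(c_incl))))
            psis_hard.append(float(np.mean(((dm < r).sum(axis=1) - 1) / (n - 1))))
            mem = np.exp(-math.log(2.0) * (dm / r) ** 2)
            np.fill_diagonal(mem, 0.0)
            psis_fuzzy.append(float(np.mean(mem.sum(axis=1) / (n - 1))))
        a = phis[0] - phis[1]
        if psis_hard[0] > 0.0 and psis_hard[1] > 0.0:
            s = -math.log(psis_hard[1] / psis_hard[0])
        else:
            flags["sampen"] = "no_matches"
        f = -math.log(psis_fuzzy[1] / psis_fuzzy[0])
        dist_upper = d2[np.triu_indices_from(d2, k=1)]
        lo, hi = float(dist_upper.min()), float(dist_upper.max())
        if hi == lo:
            d = 0.0
        else:
            counts, _ = np.histogram(dist_upper, bins=p.n_bins, range=(lo, hi))
            prob = counts / counts.sum()
            prob = prob[prob > 0]
            d = float(-(prob * np.log2(prob)).sum() / np.log2(p.n_bins))
    c = cond_entropy(rr, p)
    pe = permen(rr, p)
    return EntropyFeatures(apen=a, sampen=s, fuzzyen=f, disten=d, ce=c, permen=pe, flags=flags)
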