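"""Tajima's D and Fu's Fs with coalescent significance.

Tajima's D contrasts two estimators of the scaled mutation rate θ — the mean
pairwise difference π and Watterson's S/a1 — normalized by the variance
expected under the standard neutral model:

    D = (π − S/a1) / sqrt(e1·S + e2·S·(S−1))

Fu's Fs asks how surprising the observed number of distinct haplotypes k is
under the Ewens sampling formula given θ̂ = π:

    S' = P(K ≥ k | θ̂, n),    Fs = ln( S' / (1 − S') )

Both statistics are strongly negative for star-like genealogies (excess rare
variants / excess haplotypes), the classic signature of demographic
expansion.  Significance is assessed against empirical null distributions
built from isochronous constant-size coalescent genealogies conditioned on
the observed number of segregating sites (fixed-S placement, infinite sites),
mirroring the approach of standard population-genetics packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb, log

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "SiteSummary",
    "TajimaConstants",
    "NeutralityResult",
    "EmpiricalNull",
    "summarize_alignment",
    "tajima_constants",
    "tajima_d",
    "log_stirling_first",
    "ewens_k_pmf",
    "fu_fs",
    "null_distribution",
    "significance",
    "evaluate_alignment",
]


@dataclass(frozen=True)
class SiteSummary:
    """Per-alignment summaries feeding the neutrality statistics."""

    n: int
    S: int
    pi: float
    k: int
    pairwise_diffs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two sequences")
        if self.S < 0 or not 0 <= self.pi <= self.S + 1e-9:
            raise ValueError("invalid S or pi (need 0 <= pi <= S)")
        if not 1 <= self.k <= self.n:
            raise ValueError("k must be in [1, n]")
        if (self.S == 0) != (self.k == 1) or (self.S == 0) != (self.pi == 0):
            raise ValueError("S == 0, k == 1 and pi == 0 must coincide")


@dataclass(frozen=True)
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@dataclass
class NeutralityResult:
    """A statistic value with its one-sided empirical p-values and calls."""

    D: float
    Fs: float
    d_defined: bool
    fs_defined: bool
    p_neg_D: float = np.nan
    p_pos_D: float = np.nan
    p_neg_Fs: float = np.nan
    p_pos_Fs: float = np.nan
    sig_neg_D: bool = False
    sig_pos_D: bool = False
    sig_neg_Fs: bool = False
    sig_pos_Fs: bool = False


@dataclass
class EmpiricalNull:
    """Sorted null draws of D and Fs conditioned on (n, S)."""

    n: int
    S: int
    reps: int
    d_values: np.ndarray
    fs_values: np.ndarray


def summarize_alignment(aln) -> SiteSummary:
    """Segregating sites, mean pairwise differences, haplotype count.

    Accepts a :class:`~serialcoal.sim_core.HaplotypeAlignment` (finite or
    infinite sites) or a plain 2-D integer matrix of states.
    """
    mat = aln if isinstance(aln, np.ndarray) else aln.to_matrix()
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    # segregating: columns with >= 2 observed states
    S = int((mat != mat[0]).any(axis=0).sum())
    diffs = (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(float)
    iu = np.triu_indices(n, k=1)
    pi = float(diffs[iu].mean())
    k = len({row.tobytes() for row in np.ascontiguousarray(mat)})
    return SiteSummary(n=n, S=S, pi=pi, k=k, pairwise_diffs=diffs)


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> TajimaConstants:
    """The Tajima variance coefficients, functions of the sample size only."""
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def tajima_d(summary: SiteSummary) -> tuple[float, bool]:
    """Tajima's D; returns ``(value, defined)`` — (0.0, False) when S = 0."""
    if summary.S == 0:
        return 0.0, False
    c = tajima_constants(summary.n)
    S = summary.S
    var = c.e1 * S + c.e2 * S * (S - 1)
    return float((summary.pi - S / c.a1) / np.sqrt(var)), True


@lru_cache(maxsize=None)
def log_stirling_first(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind, |S_n^k| for k=0..n.

    Recurrence |S_n^k| = |S_{n-1}^{k-1}| + (n-1)·|S_{n-1}^k|, evaluated in
    log space for numerical stability up to large n.
    """
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |S_0^0| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1 : m + 1] = np.logaddexp(row[0:m], log(m - 1) + row[1 : m + 1] if m > 1 else -np.inf)
        row = new
    return row


def ewens_k_pmf(n: int, theta: float) -> np.ndarray:
    """P(K = k | θ, n) for k = 1..n under the Ewens sampling formula.

    P(K=k) = |S_n^k| θ^k / (θ (θ+1) ⋯ (θ+n−1)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not theta > 0:
        raise ValueError("theta must be > 0")
    ls = log_stirling_first(n)[1 : n + 1]
    k = np.arange(1, n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    logp = ls + k * log(theta) - log_rising
    return np.exp(logp)


def _fs_from_k(n: int, theta: float, k_obs: int) -> tuple[float, bool]:
    ls = log_stirling_first(n)[1 : n + 1]
    k = np.arange(1, n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    logp = ls + k * log(theta) - log_rising
    log_tail = logsumexp(logp[k_obs - 1 :])  # P(K >= k_obs)
    if k_obs == 1:
        return 0.0, False  # S' = 1, Fs undefined
    log_head = logsumexp(logp[: k_obs - 1])  # P(K < k_obs) = 1 - S'
    return float(log_tail - log_head), True


def fu_fs(summary: SiteSummary) -> tuple[float, bool]:
    """Fu's Fs; returns ``(value, defined)`` — (0.0, False) when monomorphic.

    θ̂ is the mean pairwise difference π; S' = P(K ≥ k_obs | θ̂, n) from the
    Ewens sampling formula; Fs = ln(S'/(1−S')), computed as a log-odds of the
    complementary tail sums so the ratio stays stable in both tails.
    """
    if summary.k == 1 or summary.pi <= 0:
        return 0.0, False
    return _fs_from_k(summary.n, summary.pi, summary.k)


def _sim_iso_tree(n: int, rng: np.random.Generator):
    """Isochronous Kingman tree (N = 1 units): branch lengths + tip masks."""
    masks = [np.zeros(n, dtype=bool) for _ in range(n)]
    for i in range(n):
        masks[i][i] = True
    node_time = [0.0] * n
    active = list(range(n))
    times = []
    lens = np.empty(2 * n - 2)
    all_masks = np.zeros((2 * n - 2, n), dtype=bool)
    t = 0.0
    nxt = n
    node_masks = list(masks)
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(2.0 / (j * (j - 1)))
        i = int(rng.integers(j))
        a = active.pop(i)
        b = active.pop(int(rng.integers(j - 1)))
        for child in (a, b):
            lens[child] = t - node_time[child]
            all_masks[child] = node_masks[child]
        node_masks.append(node_masks[a] | node_masks[b])
        node_time.append(t)
        active.append(nxt)
        nxt += 1
    return lens, all_masks[: 2 * n - 2]


def _fixed_s_replicate(n: int, S: int, rng: np.random.Generator) -> tuple[float, int]:
    """One fixed-S infinite-sites replicate: returns (pi, k)."""
    lens, masks = _sim_iso_tree(n, rng)
    probs = lens / lens.sum()
    counts = rng.multinomial(S, probs)
    hit = np.repeat(np.arange(len(lens)), counts)
    site_masks = masks[hit]  # (S, n)
    c = site_masks.sum(axis=1)
    pi = float((c * (n - c)).sum()) / comb(n, 2)
    geno = np.ascontiguousarray(site_masks.T)  # (n, S)
    k = len({row.tobytes() for row in geno})
    return pi, k


_NULL_CACHE: dict[tuple, EmpiricalNull] = {}


def null_distribution(n: int, S: int, reps: int = 1000, seed: int = 0) -> EmpiricalNull:
    """Empirical null of D and Fs conditioned on (n, S).

    Simulates ``reps`` isochronous constant-size coalescent genealogies and
    places exactly S mutations on branches with probability proportional to
    branch length (infinite sites), as significance machinery for observed
    statistics.  Memoized on (n, S, reps, seed); the null for a given key is
    derived from its own seed stream, so results do not depend on call order.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if S < 0:
        raise ValueError("S must be >= 0")
    key = (n, S, reps, int(seed))
    hit = _NULL_CACHE.get(key)
    if hit is not None:
        return hit
    if S == 0:
        null = EmpiricalNull(n, S, reps, np.zeros(reps), np.zeros(reps))
        _NULL_CACHE[key] = null
        return null
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(n, S)))
    d = np.empty(reps)
    fs = np.empty(reps)
    for r in range(reps):
        pi, k = _fixed_s_replicate(n, S, rng)
        summ = SiteSummary(n=n, S=S, pi=pi, k=k)
        d[r], _ = tajima_d(summ)
        fs[r], _ = fu_fs(summ)
    null = EmpiricalNull(n, S, reps, np.sort(d), np.sort(fs))
    _NULL_CACHE[key] = null
    return null


def _tail_p(null_sorted: np.ndarray, obs: float) -> tuple[float, float]:
    reps = len(null_sorted)
    n_le = int(np.searchsorted(null_sorted, obs, side="right"))
    n_ge = reps - int(np.searchsorted(null_sorted, obs, side="left"))
    return (n_le + 1) / (reps + 1), (n_ge + 1) / (reps + 1)


def significance(
    result: NeutralityResult,
    null: EmpiricalNull,
    alpha_d: float = 0.05,
    alpha_fs: float = 0.05,
) -> NeutralityResult:
    """Attach plus-one empirical p-values and one-sided calls to a result.

    ``p_neg = (#{null ≤ obs} + 1)/(reps + 1)`` and symmetrically for the
    upper tail; a statistic is called significantly negative only when it is
    itself negative and its lower-tail p-value is ≤ α (and mirrored for
    positive).  Undefined statistics get no call.
    """
    if null.reps < 1:
        raise ValueError("empty null")
    if result.d_defined:
        result.p_neg_D, result.p_pos_D = _tail_p(null.d_values, result.D)
        result.sig_neg_D = result.D < 0 and result.p_neg_D <= alpha_d
        result.sig_pos_D = result.D > 0 and result.p_pos_D <= alpha_d
    if result.fs_defined:
        result.p_neg_Fs, result.p_pos_Fs = _tail_p(null.fs_values, result.Fs)
        result.sig_neg_Fs = result.Fs < 0 and result.p_neg_Fs <= alpha_fs
        result.sig_pos_Fs = result.Fs > 0 and result.p_pos_Fs <= alpha_fs
    return result


def evaluate_alignment(aln, null_reps: int = 1000, null_seed: int = 0,
                   alpha_d: float = 0.05, alpha_fs: float = 0.05) -> NeutralityResult:
    """Convenience: summarize, compute D and Fs, and test both against nulls."""
    summ = summarize_alignment(aln)
    d, d_def = tajima_d(summ)
    fs, fs_def = fu_fs(summ)
    res = NeutralityResult(D=d, Fs=fs, d_defined=d_def, fs_defined=fs_def)
    if summ.S > 0:
        null = null_distribution(summ.n, summ.S, null_reps, null_seed)
        res = significance(res, null, alpha_d, alpha_fs)
    return res
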