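"""Group statistics: Welch's t-test, Kruskal-Wallis, Conover's post hoc.

Mid-ranks are used for ties throughout; the Kruskal-Wallis H statistic is
tie-corrected, and the Conover pairwise statistics reuse that corrected H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, ParameterError

__all__ = [
    "TestResult",
    "welch_test",
    "kruskal_wallis",
    "conover_posthoc",
    "holm_adjust",
]


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    method: str
    pairwise_p: pd.DataFrame | None = None
    flags: dict = field(default_factory=dict)


def _as_groups(groups: dict[str, list] | list) -> dict[str, np.ndarray]:
    if not isinstance(groups, dict):
        groups = {f"g{i}": g for i, g in enumerate(groups)}
    out = {}
    for k, v in groups.items():
        arr = np.asarray(v, dtype=float)
        if arr.ndim != 1 or len(arr) == 0:
            raise ConfigurationError(f"group {k!r} must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ConfigurationError(f"group {k!r} contains non-finite values")
        out[str(k)] = arr
    return out


def welch_test(
    x,
    y,
    mode: str = "t",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Welch unequal-variance t-test, two-sided.

    ``mode='t'`` gives the classical test (Welch-Satterthwaite df);
    ``mode='permutation'`` replaces the p-value with a seeded label-permutation
    p on the same statistic; ``mode='both'`` reports the t p-value and stores
    the permutation p in ``flags['permutation_p']``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigurationError("welch_test needs n >= 2 per group")
    if mode not in ("t", "permutation", "both"):
        raise ParameterError(f"unknown mode {mode!r}")

    def t_stat(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / len(a) + vb / len(b)
        if se2 == 0:
            return 0.0, float(len(a) + len(b) - 2)
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        return float(t), float(df)

    flags: dict = {}
    t, df = t_stat(x, y)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        flags["degenerate"] = True
        p = 1.0 if x.mean() == y.mean() else 0.0
    else:
        p = float(2.0 * sps.t.sf(abs(t), df))

    if mode in ("permutation", "both"):
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x, y])
        n = len(x)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            tp, _ = t_stat(perm[:n], perm[n:])
            if abs(tp) >= abs(t) - 1e-12:
                count += 1
        perm_p = (count + 1) / (n_permutations + 1)
        if mode == "permutation":
            p = float(perm_p)
            flags["permutation"] = True
        else:
            flags["permutation_p"] = float(perm_p)

    return TestResult(statistic=t, df=df, p_value=p, method="welch", flags=flags)


def _midranks_and_h(groups: dict[str, np.ndarray]) -> tuple[dict, np.ndarray, float, dict]:
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    n = len(pooled)
    ranks = sps.rankdata(pooled, method="average")
    rank_groups: dict[str, np.ndarray] = {}
    start = 0
    for k in labels:
        m = len(groups[k])
        rank_groups[k] = ranks[start : start + m]
        start += m
    h = (12.0 / (n * (n + 1))) * sum(
        rank_groups[k].sum() ** 2 / len(rank_groups[k]) for k in labels
    ) - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    correction = 1.0 - tie_term / (n**3 - n)
    flags = {}
    if correction == 0.0:  # all observations identical
        h_corr = 0.0
        flags["all_tied"] = True
    else:
        h_corr = h / correction
    return rank_groups, ranks, float(h_corr), flags


def kruskal_wallis(groups: dict[str, list] | list) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared p (k-1 df)."""
    g = _as_groups(groups)
    if len(g) < 2:
        raise ConfigurationError("need at least 2 groups")
    n = sum(len(v) for v in g.values())
    if n < 3:
        raise ConfigurationError("need at least 3 observations in total")
    _, _, h, flags = _midranks_and_h(g)
    k = len(g)
    p = 1.0 if flags.get("all_tied") else float(sps.chi2.sf(h, k - 1))
    return TestResult(statistic=h, df=float(k - 1), p_value=p, method="kruskal_wallis", flags=flags)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a flat array of p-values."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def conover_posthoc(
    groups: dict[str, list] | list, adjust: str = "holm"
) -> TestResult:
    """Conover-Iman pairwise comparisons after a Kruskal-Wallis test.

    For each pair (i, j):
    ``t = (Rbar_i - Rbar_j) / sqrt(S2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))``
    with ``S2 = (sum R^2 - N(N+1)^2/4) / (N-1)`` on mid-ranks and the
    tie-corrected H; two-sided p from Student's t with N-k df, adjusted per
    ``adjust`` (holm | bonferroni | none).
    """
    if adjust not in ("holm", "bonferroni", "none"):
        raise ParameterError(f"unknown adjustment {adjust!r}")
    g = _as_groups(groups)
    labels = list(g)
    k = len(labels)
    n = sum(len(v) for v in g.values())
    if n - k <= 0:
        raise ConfigurationError("need N > k observations for Conover's post hoc")
    rank_groups, ranks, h, flags = _midranks_and_h(g)

    s2 = (float(np.sum(ranks**2)) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    scale = (n - 1.0 - h) / (n - k)
    raw = np.ones((k, k))
    stat = np.zeros((k, k))
    if s2 > 0 and scale > 0:
        for i in range(k):
            for j in range(i + 1, k):
                ni, nj = len(rank_groups[labels[i]]), len(rank_groups[labels[j]])
                denom = np.sqrt(s2 * scale * (1.0 / ni + 1.0 / nj))
                t = (rank_groups[labels[i]].mean() - rank_groups[labels[j]].mean()) / denom
                p = float(2.0 * sps.t.sf(abs(t), n - k))
                stat[i, j] = stat[j, i] = float(t) if i < j else float(-t)
                raw[i, j] = raw[j, i] = p
    else:
        flags["degenerate"] = True

    iu = np.triu_indices(k, 1)
    flat = raw[iu]
    if adjust == "holm":
        flat = holm_adjust(flat)
    elif adjust == "bonferroni":
        flat = np.minimum(1.0, flat * len(flat))
    adj = np.ones((k, k))
    adj[iu] = flat
    adj.T[iu] = flat

    pairwise = pd.DataFrame(adj, index=labels, columns=labels)
    omnibus = kruskal_wallis(g)
    return TestResult(
        statistic=omnibus.statistic,
        df=float(n - k),
        p_value=omnibus.p_value,
        method=f"conover[{adjust}]",
        pairwise_p=pairwise,
        flags=flags,
    )
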