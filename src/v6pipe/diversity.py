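"""Richness and diversity estimation from OTU abundance vectors.

Exact (hypergeometric) rarefaction, rank-abundance curves and the Chao1
and ACE nonparametric richness estimators.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass(frozen=True)
class AbundanceVector:
    """Positive per-OTU counts with their frequency-of-frequencies summary."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("abundance vector must contain at least one OTU")
        if any(c < 1 or int(c) != c for c in self.counts):
            raise ValueError("abundances must be positive integers")

    @classmethod
    def from_counts(cls, counts) -> "AbundanceVector":
        arr = [int(c) for c in counts if c > 0]
        return cls(tuple(arr))

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    def f(self, k: int) -> int:
        """Number of OTUs observed exactly k times."""
        return sum(1 for c in self.counts if c == k)

    @property
    def freq_counts(self) -> Counter:
        return Counter(self.counts)


def rarefaction_curve(
    a: AbundanceVector, depths: list[int]
) -> list[tuple[int, float]]:
    """Expected OTU richness in random subsamples of the stated depths.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)], evaluated through
    log-gamma so large N does not overflow.
    """
    N = a.n
    counts = np.asarray(a.counts, dtype=float)
    out = []
    for n in depths:
        if not 1 <= n <= N:
            raise ValueError(f"rarefaction depth {n} outside [1, {N}]")
        # log C(N - Ni, n) - log C(N, n); OTUs with Ni > N - n always appear
        reachable = counts <= N - n
        ln_ratio = (
            gammaln(N - counts[reachable] + 1)
            - gammaln(n + 1)
            - gammaln(N - counts[reachable] - n + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
        )
        expected = a.s_obs - float(np.exp(ln_ratio).sum())
        out.append((n, expected))
    return out


def auto_depths(N: int, n_points: int = 20) -> list[int]:
    """Evenly spaced rarefaction depths from 1 to N."""
    return sorted(set(np.linspace(1, N, min(n_points, N)).astype(int).tolist()))


def chao1(a: AbundanceVector, bias_corrected: bool = False) -> float:
    """Chao1 richness estimate.

    Classic form S_obs + F1^2 / (2 F2); the bias-corrected form
    S_obs + F1(F1 - 1) / (2 (F2 + 1)) is used when requested or
    automatically when F2 = 0.
    """
    f1, f2 = a.f(1), a.f(2)
    if bias_corrected or f2 == 0:
        return a.s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return a.s_obs + f1 * f1 / (2.0 * f2)


def ace(a: AbundanceVector, rare_cutoff: int = 10) -> float:
    """ACE (abundance-based coverage) richness estimate.

    OTUs with counts above ``rare_cutoff`` are "abundant" and enter only
    additively.  When every rare OTU is a singleton the coverage estimate
    is zero and the bias-corrected Chao1 is returned instead (with a
    warning).
    """
    counts = np.asarray(a.counts)
    rare = counts[counts <= rare_cutoff]
    s_abund = int((counts > rare_cutoff).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(a.s_obs)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        warnings.warn(
            "ACE coverage is zero (all rare OTUs are singletons); "
            "falling back to bias-corrected Chao1",
            stacklevel=2,
        )
        return chao1(a, bias_corrected=True)
    ks = np.arange(1, rare_cutoff + 1)
    fk = np.array([int((rare == k).sum()) for k in ks])
    sum_kk1 = float((ks * (ks - 1) * fk).sum())
    if n_rare > 1:
        gamma2 = max((s_rare / c_ace) * sum_kk1 / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    else:
        gamma2 = 0.0
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def rank_abundance(
    a: AbundanceVector, max_ranks: int | None = None
) -> list[tuple[int, int]]:
    """(rank, count) pairs with counts sorted descending, 1-based ranks."""
    ordered = sorted(a.counts, reverse=True)
    if max_ranks is not None:
        ordered = ordered[:max_ranks]
    return list(enumerate(ordered, start=1))


def richness_summary(
    vectors: dict[str, AbundanceVector], rare_cutoff: int = 10
) -> pd.DataFrame:
    """Per-sample table of S_obs, N, Chao1 and ACE."""
    rows = []
    for name, vec in vectors.items():
        rows.append(
            {
                "sample": name,
                "n_tags": vec.n,
                "s_obs": vec.s_obs,
                "chao1": round(chao1(vec), 4),
                "ace": round(ace(vec, rare_cutoff), 4),
            }
        )
    return pd.DataFrame(rows, columns=["sample", "n_tags", "s_obs", "chao1", "ace"])
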