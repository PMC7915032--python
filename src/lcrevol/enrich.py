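"""Exact enrichment of feature-containing proteins against a background proteome.

The test is the one-sided Fisher exact test: the upper tail
P(X >= k) of a hypergeometric distribution with population N (background
proteome, foreground included), K feature-positive proteins in the
population, and n draws (the foreground set). The tail is accumulated in
log space for numerical stability at very small p. Raw p-values are
reported; a Benjamini-Hochberg column is available as optional extra output
but plays no role in the per-kind results.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom


@dataclass(frozen=True)
class EnrichmentResult:
    name: str  # feature kind or domain name
    k_fore: int
    n_fore: int
    K_bg: int
    N_bg: int
    p_value: float

    def __post_init__(self):
        if not (0 <= self.k_fore <= min(self.n_fore, self.K_bg)):
            raise ValueError("inconsistent contingency counts")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value out of (0, 1]")


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), accumulated in log space.

    ``k`` foreground successes out of ``n`` drawn, ``K`` successes among the
    ``N``-protein population (which includes the foreground).
    """
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError("require 0 <= n <= N and 0 <= K <= N")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValueError(
            f"impossible count k={k} for n={n}, K={K}, N={N}"
        )
    if k <= max(0, n + K - N):
        return 1.0  # certain event, exactly
    support = np.arange(k, min(n, K) + 1)
    logp = hypergeom.logpmf(support, N, K, n)
    p = float(np.exp(logsumexp(logp)))
    if p == 0.0:
        p = 5e-324  # tail smaller than the float range: saturate, stay >0
    return min(1.0, p)


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def enrich_feature_kinds(
    fore_presence: pd.DataFrame, bg_presence: pd.DataFrame
) -> list[EnrichmentResult]:
    """One enrichment result per feature kind.

    ``fore_presence``: binary presence matrix restricted to the foreground's
    human proteins (rows = kinds, columns = protein ids; a protein counts as
    positive when it has >= 1 feature of the kind). ``bg_presence``: the
    background table with columns ``protein``, ``kind``, ``present`` — the
    whole proteome, foreground included.
    """
    required = {"protein", "kind", "present"}
    if not required <= set(bg_presence.columns):
        raise ValueError(f"background table needs columns {sorted(required)}")
    N = int(bg_presence["protein"].nunique())
    n = int(fore_presence.shape[1])
    if n > N:
        raise ValueError("foreground larger than the background population")
    bg_pos = (
        bg_presence[bg_presence["present"] == 1].groupby("kind")["protein"].nunique()
    )
    out = []
    for kind in fore_presence.index:
        k = int((fore_presence.loc[kind] > 0).sum())
        K = int(bg_pos.get(kind, 0))
        if k > K:
            raise ValueError(
                f"{kind}: foreground positives ({k}) exceed background positives "
                f"({K}); the background must include the foreground"
            )
        p = hypergeom_upper_tail(k, n, K, N) if K > 0 else 1.0
        out.append(EnrichmentResult(kind, k, n, K, N, p))
    return out


def enrich_domain_sets(
    counts: Iterable[tuple[str, int, int, int, int]]
) -> list[EnrichmentResult]:
    """Enrichment from explicit (name, k_fore, n_fore, K_bg, N_bg) counts,
    e.g. WW- or SH3-domain containing proteins."""
    return [
        EnrichmentResult(name, k, n, K, N, hypergeom_upper_tail(k, n, K, N))
        for name, k, n, K, N in counts
    ]


def read_background_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"protein", "kind", "present"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    return df


def write_enrichment_table(
    results: Iterable[EnrichmentResult], path: str | Path, adjust: bool = True
) -> None:
    rows = [
        {
            "name": r.name,
            "k_fore": r.k_fore,
            "n_fore": r.n_fore,
            "K_bg": r.K_bg,
            "N_bg": r.N_bg,
            "p_value": r.p_value,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if adjust and not df.empty:
        df["q_bh"] = benjamini_hochberg(df["p_value"].to_numpy())
    df.sort_values(["p_value", "name"], kind="mergesort").to_csv(
        path, sep="\t", index=False
    )
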