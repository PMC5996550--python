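"""Differential expression and multiple-testing statistics.

Implements a two-sample moderated t-test with empirical-Bayes variance
shrinkage (per-gene residual variances are shrunk toward a common prior
variance s0^2 with prior degrees of freedom d0, both estimated by moment
matching on the log residual variances), Storey-style q-values with a
Benjamini-Hochberg fallback, and one-sided Fisher enrichment of gene sets.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

# ---------------------------------------------------------------------------
# moderated t-test


@dataclass
class DifferentialExpressionResult:
    """Per-gene moderated t-test output plus the shared prior estimates.

    ``table`` columns: ``delta`` (mean log-ratio difference, group1 minus
    group2), ``s2`` (pooled residual variance, ``df`` residual df), ``s2_post``
    (moderated variance), ``t`` (moderated statistic), ``p`` (two-sided),
    ``q`` and ``direction`` in {"up", "down", "ns"}.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    df_residual: float
    pi0: float = 1.0

    def genes(self, direction: str) -> list[str]:
        return list(self.table.index[self.table["direction"] == direction])


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/x scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from per-gene variances.

    Under the hierarchical model s2_g | sigma_g^2 ~ sigma_g^2 * chi^2_df / df
    with 1/sigma_g^2 ~ chi^2_d0 / (d0 s0^2), the statistic
    e_g = log s2_g - digamma(df/2) + log(df/2) has mean
    log s0^2 + digamma(d0/2) - log(d0/2) and variance
    trigamma(df/2) + trigamma(d0/2).
    """
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all per-gene variances are zero; cannot estimate prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_var = np.var(e, ddof=1) if e.size > 1 else 0.0
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    return float(d0), s0_sq


def moderated_t_test(
    group1: pd.DataFrame,
    group2: pd.DataFrame,
    d0: float | None = None,
    s0_sq: float | None = None,
    q_method: str = "storey",
    q_cutoff: float = 0.05,
) -> DifferentialExpressionResult:
    """Two-sample moderated t-test across genes (group1 vs group2).

    Per gene, the pooled residual variance s2_g (df = n1 + n2 - 2) is
    replaced by the posterior variance
    ``s2_post = (d0 * s0^2 + df * s2_g) / (d0 + df)`` and the statistic
    ``t = delta / sqrt(s2_post * (1/n1 + 1/n2))`` is referred to a t
    distribution with ``d0 + df`` degrees of freedom (two-sided p).

    ``d0``/``s0_sq`` are estimated by moment matching unless given;
    ``d0=0`` recovers the ordinary pooled two-sample t-test and
    ``d0=inf`` the fully shrunk statistic with variance ``s0^2``.
    """
    if not group1.index.equals(group2.index):
        raise ValueError("group matrices must share the same gene index")
    n1, n2 = group1.shape[1], group2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    x1, x2 = group1.to_numpy(float), group2.to_numpy(float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    df = float(n1 + n2 - 2)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    delta = m1 - m2

    if d0 is None or s0_sq is None:
        d0_est, s0_est = _fit_variance_prior(s2, df)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(delta == 0.0, 0.0, delta / se)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)

    qres = compute_qvalues(p, method=q_method)
    direction = np.where(
        qres.qvalues < q_cutoff, np.where(delta > 0, "up", "down"), "ns"
    )
    direction = np.where((qres.qvalues < q_cutoff) & (delta == 0), "ns", direction)
    table = pd.DataFrame(
        {
            "delta": delta,
            "s2": s2,
            "df": df,
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "q": qres.qvalues,
            "direction": direction,
        },
        index=group1.index,
    )
    return DifferentialExpressionResult(
        table=table, d0=float(d0), s0_sq=float(s0_sq), df_residual=df, pi0=qres.pi0
    )


# ---------------------------------------------------------------------------
# q-values


@dataclass
class QValueResult:
    pvalues: np.ndarray
    qvalues: np.ndarray
    pi0: float
    method: str


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Smoother estimate of the null proportion pi0.

    Computes pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a grid and
    extrapolates to lambda -> 1 with a cubic polynomial fit. Returns a
    value outside (0, 1] unchanged so the caller can fall back.
    """
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_grid = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_grid, deg=3)
    return float(np.polyval(coeffs, lambdas.max()))


def compute_qvalues(
    pvalues, method: str = "storey", lambdas: np.ndarray | None = None
) -> QValueResult:
    """q-values from p-values.

    ``storey``: q = pi0_hat * BH with pi0_hat from the cubic-smoother grid
    extrapolation; falls back to BH (pi0 = 1) when the estimate leaves
    (0, 1] or when fewer than 20 p-values are available (the smoother
    extrapolation is unstable for tiny families). ``bh``: plain
    Benjamini-Hochberg (pi0 = 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    if method not in ("storey", "bh"):
        raise ValueError("method must be 'storey' or 'bh'")

    bh = _bh_adjust(p)
    pi0 = 1.0
    used = "bh"
    if method == "storey" and p.size >= 20:
        pi0_hat = estimate_pi0(p, lambdas)
        if 0.0 < pi0_hat <= 1.0:
            pi0 = pi0_hat
            used = "storey"
    q = np.minimum(pi0 * bh, 1.0)
    return QValueResult(pvalues=p, qvalues=q, pi0=pi0, method=used)


# ---------------------------------------------------------------------------
# Fisher enrichment


def pathway_enrichment(
    de: DifferentialExpressionResult,
    gene_sets: dict[str, list[str]],
    direction: str = "up",
) -> pd.DataFrame:
    """One-sided Fisher enrichment of differential genes in each gene set.

    For every set, builds the 2x2 table (in-set vs not) x (DE in the given
    direction vs not) over the tested gene universe and reports the
    one-sided (enrichment) Fisher exact p-value.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    universe = set(de.table.index)
    de_genes = set(de.genes(direction))
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & universe
        if not inset:
            raise ValueError(f"gene set {name!r} is disjoint from the tested universe")
        a = len(inset & de_genes)
        b = len(inset) - a
        c = len(de_genes) - a
        d = len(universe) - a - b - c
        _, pval = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "set": name,
                "set_size": len(inset),
                "n_de_in_set": a,
                "n_de_total": len(de_genes),
                "universe": len(universe),
                "odds_ratio": (a * d) / (b * c) if b * c > 0 else np.inf,
                "p": pval,
            }
        )
    return pd.DataFrame(rows).set_index("set")
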