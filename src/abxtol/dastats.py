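"""Differential-abundance statistics from first principles.

The workhorse is a beta-binomial likelihood-ratio test per taxon: counts W at
depths M follow a beta-binomial with mean proportion mu and intra-class
correlation phi (alpha = mu (1 - phi) / phi, beta = (1 - mu)(1 - phi) / phi).
The null model shares one mu and one phi across both groups; the alternative
allows group-specific mus with a shared phi; Lambda = 2 (l_alt - l_null) is
referred to chi-square with 1 df.  Mann-Whitney U (exact for small untied
samples) and Benjamini-Hochberg step-up adjustment complete the toolbox.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "betabinom_loglik",
    "fit_betabinom",
    "BetaBinomFit",
    "bb_lrt",
    "LrtEntry",
    "da_test_table",
    "mann_whitney",
    "bh_adjust",
]

_PHI_FLOOR = 1e-8  # below this the model is evaluated as a plain binomial
_MIN_MU_DEFAULT = 0.001


def betabinom_loglik(counts, depths, mu: float, phi: float) -> float:
    """Exact beta-binomial log-likelihood of ``counts`` at ``depths``.

    ``phi`` below 1e-8 is evaluated as the binomial limit for numerical
    continuity.
    """
    w = np.asarray(counts, dtype=float)
    m = np.asarray(depths, dtype=float)
    if np.any(w > m):
        raise ValueError("count exceeds depth")
    if np.any(w < 0) or np.any(m < 1):
        raise ValueError("counts must be >= 0 and depths >= 1")
    if not (0.0 < mu < 1.0) or not (0.0 <= phi < 1.0):
        raise ValueError(f"invalid parameters mu={mu}, phi={phi}")
    choose = special.gammaln(m + 1) - special.gammaln(w + 1) - special.gammaln(m - w + 1)
    if phi < _PHI_FLOOR:
        return float(np.sum(choose + w * math.log(mu) + (m - w) * math.log1p(-mu)))
    a = mu * (1 - phi) / phi
    b = (1 - mu) * (1 - phi) / phi
    return float(np.sum(choose + special.betaln(w + a, m - w + b) - special.betaln(a, b)))


@dataclass(frozen=True)
class BetaBinomFit:
    mu: float
    phi: float
    loglik: float
    converged: bool


def _moment_start(w: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    mu0 = float(np.clip(w.sum() / m.sum(), 1e-6, 1 - 1e-6))
    props = w / m
    s2 = float(props.var(ddof=1)) if len(props) > 1 else 0.0
    base = mu0 * (1 - mu0)
    phi0 = (s2 / base - float(np.mean(1.0 / m))) if base > 0 else 0.0
    return mu0, float(np.clip(phi0, 1e-5, 0.5))


def _logit(x: float) -> float:
    return math.log(x / (1 - x))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def fit_betabinom(counts, depths) -> BetaBinomFit:
    """Maximum-likelihood (mu, phi) on the logit scale with deterministic restarts.

    Optimization runs on (logit mu, logit phi) with Nelder-Mead from the
    moment estimate and two logit-perturbed starts.  A phi estimate at the
    1e-8 floor is reported as 0 (binomial).  All-zero counts are a boundary
    case flagged non-converged with mu at machine scale.
    """
    w = np.asarray(counts, dtype=float)
    m = np.asarray(depths, dtype=float)
    if len(w) < 3:
        raise ValueError(f"need >= 3 observations, got {len(w)}")
    if np.any(w > m):
        raise ValueError("count exceeds depth")
    if w.sum() == 0:
        mu = 1.0 / (m.sum() + 1.0)
        return BetaBinomFit(mu=mu, phi=0.0, loglik=betabinom_loglik(w, m, mu, 0.0),
                            converged=False)

    mu0, phi0 = _moment_start(w, m)

    def neg_ll(theta) -> float:
        mu = _expit(float(np.clip(theta[0], -30, 30)))
        phi = _expit(float(np.clip(theta[1], -30, 30)))
        mu = min(max(mu, 1e-9), 1 - 1e-9)
        phi = min(phi, 1 - 1e-6)
        return -betabinom_loglik(w, m, mu, phi)

    starts = [
        (_logit(mu0), _logit(phi0)),
        (_logit(mu0) + 1.0, _logit(phi0)),
        (_logit(mu0) - 1.0, _logit(phi0)),
    ]
    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            converged = True
            if res.fun <= best.fun:
                best = res
            break
    mu = _expit(float(np.clip(best.x[0], -30, 30)))
    phi = _expit(float(np.clip(best.x[1], -30, 30)))
    if phi < _PHI_FLOOR * 10:
        phi = 0.0
    return BetaBinomFit(mu=mu, phi=phi, loglik=-float(best.fun),
                        converged=converged or best.success)


@dataclass(frozen=True)
class LrtEntry:
    """Two-group beta-binomial LRT result for a single taxon."""

    mu_a: float
    mu_b: float
    mu_null: float
    phi: float
    statistic: float
    p: float
    converged: bool


def bb_lrt(counts_a, depths_a, counts_b, depths_b,
           null_fit: BetaBinomFit | None = None) -> LrtEntry:
    """Beta-binomial likelihood-ratio test of a group effect on the mean.

    Null: one (mu, phi) shared by both groups.  Alternative: group-specific
    mus, shared phi.  Lambda = 2 (l_alt - l_null), p from chi2(1).  A
    non-converged fit yields p = NaN so callers can drop the taxon from the
    multiple-testing denominator.
    """
    wa, ma = np.asarray(counts_a, float), np.asarray(depths_a, float)
    wb, mb = np.asarray(counts_b, float), np.asarray(depths_b, float)
    if len(wa) < 3 or len(wb) < 3:
        raise ValueError("each group needs >= 3 samples")

    null = null_fit if null_fit is not None else fit_betabinom(
        np.concatenate([wa, wb]), np.concatenate([ma, mb]))

    mu_a0, _ = _moment_start(wa, ma) if wa.sum() else (1e-6, 1e-5)
    mu_b0, _ = _moment_start(wb, mb) if wb.sum() else (1e-6, 1e-5)
    phi0 = max(null.phi, 1e-5)

    def neg_ll(theta) -> float:
        mu_a = min(max(_expit(float(np.clip(theta[0], -30, 30))), 1e-9), 1 - 1e-9)
        mu_b = min(max(_expit(float(np.clip(theta[1], -30, 30))), 1e-9), 1 - 1e-9)
        phi = min(_expit(float(np.clip(theta[2], -30, 30))), 1 - 1e-6)
        return -(betabinom_loglik(wa, ma, mu_a, phi) + betabinom_loglik(wb, mb, mu_b, phi))

    starts = [
        (_logit(mu_a0), _logit(mu_b0), _logit(phi0)),
        (_logit(mu_a0) + 1.0, _logit(mu_b0) - 1.0, _logit(phi0)),
        (_logit(mu_a0) - 1.0, _logit(mu_b0) + 1.0, _logit(phi0)),
    ]
    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            converged = True
            if res.fun <= best.fun:
                best = res
            break
    ll_alt = -float(best.fun)
    lam = max(0.0, 2.0 * (ll_alt - null.loglik))
    ok = converged and null.converged
    p = float(stats.chi2.sf(lam, df=1)) if ok else float("nan")
    return LrtEntry(
        mu_a=_expit(float(np.clip(best.x[0], -30, 30))),
        mu_b=_expit(float(np.clip(best.x[1], -30, 30))),
        mu_null=null.mu,
        phi=_expit(float(np.clip(best.x[2], -30, 30))),
        statistic=lam,
        p=p,
        converged=ok,
    )


def da_test_table(
    table,
    groups,
    test: str = "bblrt",
    min_mu: float = _MIN_MU_DEFAULT,
    depths=None,
) -> pd.DataFrame:
    """Per-taxon two-group differential-abundance tests with BH adjustment.

    ``table`` is a CountTable (or samples x taxa DataFrame); ``groups`` is a
    per-sample label vector with exactly two levels.  Taxa whose pooled
    fitted mu is <= ``min_mu`` are excluded before testing (low-abundance
    prefilter).  ``test`` is ``"bblrt"`` or ``"mwu"`` (Mann-Whitney on
    proportions).  ``depths`` overrides the per-sample depths (nominal
    sequencing depth) when the table rows are not closed compositions.
    """
    data = table.data if hasattr(table, "data") else pd.DataFrame(table)
    labels = np.asarray(list(groups))
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(uniq)}")
    mask_a = labels == uniq[0]
    w = data.to_numpy(dtype=float)
    m = (np.full(w.shape[0], float(depths)) if np.isscalar(depths)
         else np.asarray(depths, float) if depths is not None
         else w.sum(axis=1))

    rows = []
    for j, taxon in enumerate(data.columns):
        pooled = fit_betabinom(w[:, j], m)
        if pooled.mu <= min_mu:
            continue
        if test == "bblrt":
            entry = bb_lrt(w[mask_a, j], m[mask_a], w[~mask_a, j], m[~mask_a],
                           null_fit=pooled)
            rows.append({"taxon_id": taxon, "mu_a": entry.mu_a, "mu_b": entry.mu_b,
                         "phi": entry.phi, "statistic": entry.statistic, "p": entry.p,
                         "converged": entry.converged})
        elif test == "mwu":
            u, p = mann_whitney(w[mask_a, j] / m[mask_a], w[~mask_a, j] / m[~mask_a])
            rows.append({"taxon_id": taxon,
                         "mu_a": float(np.mean(w[mask_a, j] / m[mask_a])),
                         "mu_b": float(np.mean(w[~mask_a, j] / m[~mask_a])),
                         "phi": float("nan"), "statistic": u, "p": p, "converged": True})
        else:
            raise ValueError(f"unknown test {test!r}")
    result = pd.DataFrame(rows).set_index("taxon_id") if rows else pd.DataFrame(
        columns=["mu_a", "mu_b", "phi", "statistic", "p", "converged"]).rename_axis("taxon_id")
    result["q"] = bh_adjust(result["p"].to_numpy()) if len(result) else []
    return result


# -- Mann-Whitney ----------------------------------------------------------

def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (rank-sum form of the first sample) with two-sided p.

    Exact enumeration over rank assignments when n1 + n2 <= 12 and there are
    no ties; otherwise normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = len(np.unique(combined)) < n1 + n2

    if n1 + n2 <= 12 and not has_ties:
        mean_u = n1 * n2 / 2.0
        obs_dev = abs(u - mean_u)
        all_ranks = np.arange(1, n1 + n2 + 1)
        extreme = 0
        total = 0
        for comb in itertools.combinations(all_ranks, n1):
            u_c = sum(comb) - n1 * (n1 + 1) / 2.0
            if abs(u_c - mean_u) >= obs_dev - 1e-12:
                extreme += 1
            total += 1
        return u, extreme / total

    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    mean_u = n1 * n2 / 2.0
    z = (u - mean_u - math.copysign(0.5, u - mean_u)) / math.sqrt(sigma2) if u != mean_u else 0.0
    return u, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


# -- multiple testing ------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    NaN entries (non-converged tests) are excluded from the denominator and
    returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv <= 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    out[valid] = q
    return out
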