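"""Responder phenotyping from organelle read fractions.

When antibiotics collapse gut bacterial biomass, the constant background of
host mitochondrial and dietary chloroplast DNA takes over a growing share of
16S reads.  The fraction of reads with "Mitochondria" or "Chloroplast" in
their lineage therefore acts as an inverse biomass proxy and is the basis of
the responder / non-responder phenotype call: a treated mouse whose organelle
fraction reaches 10% during antibiotic exposure has responded (community
collapse); one that stays below 10% carries an antibiotic-tolerant community.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import CountTable

logger = logging.getLogger(__name__)

ORGANELLE_TOKENS = ("Mitochondria", "Chloroplast")

RESPONDER_THRESHOLD = 0.10


def organelle_taxa(taxonomy: pd.DataFrame) -> pd.Index:
    """Taxa whose lineage contains an organelle token at any rank (case-sensitive)."""
    mask = taxonomy.apply(
        lambda row: any(tok in str(v) for v in row for tok in ORGANELLE_TOKENS), axis=1
    )
    return taxonomy.index[mask]


def organelle_fraction(table: CountTable, taxonomy: pd.DataFrame) -> pd.Series:
    """Per-sample organelle read fraction, computed on unrarefied counts.

    Zero-depth samples are excluded with a warning (the fraction is
    undefined there).
    """
    missing = [t for t in table.taxon_ids if t not in taxonomy.index]
    if missing:
        raise ValueError(f"taxa missing from taxonomy: {missing[:5]}")
    org = [t for t in table.taxon_ids if t in set(organelle_taxa(taxonomy))]
    depths = table.depths()
    zero = depths == 0
    if zero.any():
        logger.warning("organelle_fraction: excluding zero-depth samples %s",
                       list(depths.index[zero]))
    kept = table.data.loc[~zero]
    frac = kept[org].sum(axis=1) / kept.sum(axis=1) if org else pd.Series(0.0, index=kept.index)
    return frac.rename("organelle_fraction")


@dataclass
class ResponderStatus:
    """Per-mouse phenotype calls plus the per-sample evidence behind them."""

    per_mouse: pd.DataFrame  # index mouse_id; label, max_window_fraction, n_window_samples
    per_sample: pd.DataFrame  # index sample_id; fraction, window flag, sample-level call

    def counts(self) -> pd.Series:
        return self.per_mouse["label"].value_counts()


def classify_response(
    fractions: pd.Series,
    metadata: pd.DataFrame,
    threshold: float = RESPONDER_THRESHOLD,
) -> ResponderStatus:
    """Call each mouse control / responder / non-responder.

    A treated mouse is a responder iff its *maximum* organelle fraction over
    during-window samples reaches ``threshold`` (inclusive); one excursion to
    10% is a collapse.  Untreated mice are controls regardless of fraction.
    Per-sample calls are also emitted so within-treatment phenotype switching
    is visible.  Treated mice with no during-window sample are labelled
    ``indeterminate`` with a warning.
    """
    joined = metadata.join(fractions, how="inner")
    per_sample = joined[["mouse_id", "day", "group", "antibiotic_window",
                         "organelle_fraction"]].copy()
    per_sample["sample_call"] = np.where(
        per_sample["organelle_fraction"] >= threshold, "responder", "non-responder"
    )

    records = []
    for mouse, sub in joined.groupby("mouse_id", sort=True):
        treated = (sub["group"] != "control").any()
        window = sub[sub["antibiotic_window"].astype(bool)]
        max_f = float(window["organelle_fraction"].max()) if len(window) else float("nan")
        if not treated:
            label = "control"
        elif len(window) == 0:
            label = "indeterminate"
            logger.warning("classify_response: treated mouse %s has no in-window sample", mouse)
        else:
            label = "responder" if max_f >= threshold else "non-responder"
        records.append({"mouse_id": mouse, "label": label,
                        "max_window_fraction": max_f, "n_window_samples": len(window)})
    per_mouse = pd.DataFrame(records).set_index("mouse_id")
    return ResponderStatus(per_mouse=per_mouse, per_sample=per_sample)


def pooled_phenotype_rate(counts_per_experiment: list[tuple[int, int]]) -> float:
    """Pooled non-responder percentage from per-experiment (non-responders, treated) counts."""
    k = sum(c[0] for c in counts_per_experiment)
    n = sum(c[1] for c in counts_per_experiment)
    if n == 0:
        raise ValueError("no treated mice")
    return 100.0 * k / n


# -- exact frequency test --------------------------------------------------

def phenotype_frequency_test(table) -> float:
    """Two-sided Fisher exact p for a 2 x k contingency table of phenotype counts.

    2 x 2 tables use the analytic hypergeometric test; wider tables are
    handled by full enumeration of tables with the observed margins
    (probability-ordered two-sided p, as in R's ``fisher.test``), which is
    feasible for the small mouse-count tables this is meant for.
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.ndim != 2 or tab.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
        raise ValueError("empty row or column margin")
    if tab.shape[1] == 2:
        return float(stats.fisher_exact(tab, alternative="two-sided")[1])
    return _fisher_exact_2xk(tab)


def _log_table_prob(tab: np.ndarray, lgf: np.ndarray, const: float) -> float:
    return const - lgf[tab].sum()


def _fisher_exact_2xk(tab: np.ndarray) -> float:
    row = tab.sum(axis=1)
    col = tab.sum(axis=0)
    n = tab.sum()
    lgf = np.array([math.lgamma(i + 1) for i in range(n + 1)])
    const = lgf[row].sum() + lgf[col].sum() - lgf[n]
    obs_lp = _log_table_prob(tab, lgf, const)
    total = 0.0
    # enumerate first rows consistent with the margins; second row is implied
    ranges = [range(min(row[0], c) + 1) for c in col]
    for first in itertools.product(*ranges):
        if sum(first) != row[0]:
            continue
        cand = np.array([first, col - np.array(first)])
        lp = _log_table_prob(cand, lgf, const)
        if lp <= obs_lp + 1e-10:
            total += math.exp(lp)
    return min(1.0, total)


# -- biomass proxy ---------------------------------------------------------

def biomass_correlation(
    qpcr: pd.DataFrame,
    fractions: pd.Series,
    exact_max_n: int = 10,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman correlation between the qPCR biomass proxy 1/Ct and the
    organelle read fraction over paired samples.

    Exact permutation p for n <= ``exact_max_n`` (all n! pairings of the rank
    vectors, enumerated in chunks), t-approximation otherwise.  Returns
    ``(rho, p)``.
    """
    paired = pd.DataFrame({"ct": qpcr["ct"]}).join(fractions, how="inner").dropna()
    n = len(paired)
    if n < 4:
        raise ValueError(f"need >= 4 paired samples, got {n}")
    x = 1.0 / paired["ct"].to_numpy()
    y = paired["organelle_fraction"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector: Spearman rho undefined")
    rho, p_t = stats.spearmanr(x, y)
    if n > exact_max_n:
        return float(rho), float(p_t)

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    obs = abs(float(rx_c @ ry_c) / denom)
    count = 0
    total = 0
    chunk = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            count += _count_extreme(np.array(chunk), rx_c, ry_c, denom, obs)
            total += len(chunk)
            chunk = []
    if chunk:
        count += _count_extreme(np.array(chunk), rx_c, ry_c, denom, obs)
        total += len(chunk)
    return float(rho), count / total


def _count_extreme(perms: np.ndarray, rx_c, ry_c, denom, obs) -> int:
    stats_ = np.abs(perms_dot(perms, rx_c, ry_c) / denom)
    return int((stats_ >= obs - 1e-12).sum())


def perms_dot(perms: np.ndarray, rx_c: np.ndarray, ry_c: np.ndarray) -> np.ndarray:
    return ry_c[perms] @ rx_c


# -- dose arithmetic -------------------------------------------------------

def dose_mg_per_kg(volume_ml: float, concentration_mg_per_ml: float, weight_g: float) -> float:
    """Daily antibiotic dose in mg/kg from water intake, drug concentration and body weight."""
    if weight_g <= 0:
        raise ValueError("weight must be positive")
    if volume_ml < 0 or concentration_mg_per_ml < 0:
        raise ValueError("volume and concentration must be non-negative")
    return volume_ml * concentration_mg_per_ml / (weight_g / 1000.0)
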