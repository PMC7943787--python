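"""Community ecology statistics: diversity, ordination, PERMANOVA, turnover.

PERMANOVA is implemented from its sums-of-squares definition on the distance
matrix (the classical one-way pseudo-F of the `adonis` family), with a seeded
label-permutation null.  PCoA is classical metric scaling (Gower double
centering + eigendecomposition) keeping positive-eigenvalue axes only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .io_tables import CountTable

logger = logging.getLogger(__name__)


# -- alpha diversity -------------------------------------------------------

def shannon(counts, base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i for one sample's counts.

    Natural log (nats) by default, the vegan convention; pass ``base=2``
    for bits.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero sample has no diversity")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base is not None else h


def shannon_profile(table: CountTable) -> pd.Series:
    """Shannon index per sample."""
    return pd.Series(
        [shannon(row) for row in table.counts], index=table.sample_ids, name="shannon"
    )


# -- beta diversity --------------------------------------------------------

def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, d(A,B) = 1 - 2 sum min(a,b) / (sum a + sum b)."""
    if table.shape[0] < 2:
        raise ValueError("need >= 2 samples for a distance matrix")
    depths = table.depths()
    if (depths == 0).any():
        raise ValueError(f"zero-depth samples: {list(depths.index[depths == 0])}")
    if depths.nunique() > 1:
        warnings.warn("unequal sample depths; consider rarefying before Bray-Curtis",
                      stacklevel=2)
    condensed = pdist(table.counts.astype(float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding with per-axis explained variance."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Double-centers -0.5 * d^2, eigendecomposes, and returns the axes for
    positive eigenvalues sorted descending.  Negative eigenvalues (from
    non-Euclidean distances such as Bray-Curtis) are dropped and explained
    fractions are computed over the positive spectrum only.
    """
    d = dm.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals[0])) if n else 0.0
    pos = evals > tol
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalue(s); truncating n_axes={n_axes}",
                      stacklevel=2)
        n_axes = n_pos
    lam = evals[:n_axes]
    coords = evecs[:, :n_axes] * np.sqrt(lam)
    frame = pd.DataFrame(coords, index=list(dm.ids),
                         columns=[f"PC{k + 1}" for k in range(n_axes)])
    explained = evals[:n_axes] / evals[pos].sum() if n_pos else np.array([])
    return OrdinationResult(coordinates=frame, eigenvalues=evals[:n_axes],
                            proportion_explained=explained)


# -- PERMANOVA -------------------------------------------------------------

@dataclass
class PermanovaResult:
    """One-way PERMANOVA on a distance matrix."""

    r2: float
    f: float
    p: float
    n_perm: int


def _ss_within(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    ssw = 0.0
    for g in range(k):
        mask = codes == g
        ssw += d2[np.ix_(mask, mask)].sum() / (2.0 * mask.sum())
    return ssw


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA (pseudo-F) for a single factor.

    SST = sum_{i<j} d_ij^2 / N; SSW sums the within-group analogue per group;
    F = (SSB / (k-1)) / (SSW / (N-k)); the p-value counts permuted F values
    at least as large as the observed one, with the +1 "observed permutation"
    convention, so the smallest attainable p is 1 / (n_perm + 1).
    """
    labels = np.asarray(list(grouping))
    n = len(labels)
    if n != dm.shape[0]:
        raise ValueError("grouping length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("need >= 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = uniq[sizes < 2]
        raise ValueError(f"group(s) with fewer than 2 samples: {list(small)}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    d2 = dm.data ** 2
    sst = d2.sum() / (2.0 * n)
    ssw = _ss_within(d2, codes, k)
    ssb = sst - ssw
    f_obs = (ssb / (k - 1)) / (ssw / (n - k))
    r2 = ssb / sst if sst > 0 else 0.0

    rng = np.random.default_rng(seed)
    hits = 0
    perm_codes = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_codes)
        ssw_p = _ss_within(d2, perm_codes, k)
        ssb_p = sst - ssw_p
        f_p = (ssb_p / (k - 1)) / (ssw_p / (n - k))
        if f_p >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermanovaResult(r2=float(r2), f=float(f_obs), p=float(p), n_perm=n_perm)


# -- ASV turnover ----------------------------------------------------------

def asv_dynamics(
    table: CountTable,
    metadata: pd.DataFrame,
    presence_min: int = 1,
) -> pd.DataFrame:
    """Gained / lost / persistent ASV counts per mouse between its first and
    final sampled time points.

    Presence means count >= ``presence_min``.  Fractions are relative to
    first-time-point richness for lost/persistent and final-time-point
    richness for gained.  Mice with a single time point are skipped with a
    warning.
    """
    meta = metadata.loc[metadata.index.intersection(table.sample_ids)]
    rows = []
    for mouse, sub in meta.groupby("mouse_id", sort=True):
        sub = sub.sort_values("day")
        if sub["day"].nunique() < 2:
            logger.warning("asv_dynamics: mouse %s has one time point; skipped", mouse)
            continue
        first_ids = sub.index[sub["day"] == sub["day"].iloc[0]]
        last_ids = sub.index[sub["day"] == sub["day"].iloc[-1]]
        first = table.data.loc[first_ids].sum(axis=0) >= presence_min
        last = table.data.loc[last_ids].sum(axis=0) >= presence_min
        persistent = int((first & last).sum())
        lost = int((first & ~last).sum())
        gained = int((~first & last).sum())
        rich_first = int(first.sum())
        rich_last = int(last.sum())
        rows.append({
            "mouse_id": mouse,
            "persistent": persistent, "lost": lost, "gained": gained,
            "richness_first": rich_first, "richness_last": rich_last,
            "frac_persistent": persistent / rich_first if rich_first else np.nan,
            "frac_lost": lost / rich_first if rich_first else np.nan,
            "frac_gained": gained / rich_last if rich_last else np.nan,
        })
    return pd.DataFrame(rows).set_index("mouse_id") if rows else pd.DataFrame(
        columns=["persistent", "lost", "gained", "richness_first", "richness_last",
                 "frac_persistent", "frac_lost", "frac_gained"]).rename_axis("mouse_id")
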