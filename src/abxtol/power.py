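"""Power and FDR analysis for 16S differential-abundance and beta-diversity tests.

The framework mirrors a standard amplicon study-design workflow: fit
per-taxon beta-binomial parameters to a reference count table (or use the
synthetic community defaults), simulate two-group experiments with fold-change
effects injected into a known fraction of taxa, run the test of interest with
Benjamini-Hochberg correction, and summarize the true positive rate (power)
and false discovery rate over a grid of per-group sample sizes and effect
sizes.

For PERMANOVA the natural effect axis is the fraction of community variance
the group explains (R^2).  Because the sample R^2 of a 2-group PERMANOVA has
a null expectation of 1 / (N - 1) — far above small population effects at
small N — cells are indexed by a *population* R^2 estimated once per effect
size from a large calibration simulation, while each replicate's realized
R^2 is also recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dastats import da_test_table, fit_betabinom
from .ecology import _ss_within, bray_curtis, permanova
from .io_tables import CountTable
from .synthetic import (
    BetaBinomParams,
    CommunityParams,
    TaxonSpec,
    inject_effects,
    inject_effects_independent,
    make_baseline_community,
    sample_community_table,
    sample_independent_table,
)

__all__ = [
    "PowerGrid",
    "fit_reference",
    "default_reference_params",
    "da_power_scan",
    "permanova_power_scan",
    "permanova_power_replicates",
    "report_power",
    "plot_power",
]

_MIN_MU_DEFAULT = 0.001


@dataclass
class PowerGrid:
    """TPR/FDR (or rejection-rate) cells over (per-group n, effect size).

    ``cells`` holds one row per grid cell with its replicate count;
    ``replicates`` (PERMANOVA scans) holds one row per simulated experiment.
    """

    cells: pd.DataFrame
    test: str
    replicates: pd.DataFrame | None = None


def fit_reference(table: CountTable, min_mu: float = _MIN_MU_DEFAULT,
                  depths=None) -> list[tuple[str, BetaBinomParams]]:
    """Per-taxon beta-binomial MLEs from a reference table, dropping taxa with
    fitted mu <= ``min_mu``.

    ``depths`` overrides the per-sample depths (e.g. the nominal sequencing
    depth) when the table rows are not closed compositions; by default the
    row sums are used, which is correct for rarefied tables.
    """
    n = table.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 samples to fit, got {n}")
    if n < 10:
        warnings.warn(f"only {n} samples; beta-binomial fits will be noisy", stacklevel=2)
    if depths is None:
        depths = table.depths().to_numpy(dtype=float)
    elif np.isscalar(depths):
        depths = np.full(n, float(depths))
    else:
        depths = np.asarray(depths, dtype=float)
    out = []
    for taxon in table.taxon_ids:
        fit = fit_betabinom(table.data[taxon].to_numpy(dtype=float), depths)
        if fit.mu > min_mu:
            out.append((taxon, BetaBinomParams(fit.mu, max(fit.phi, 0.0))))
    return out


def default_reference_params(seed: int = 0, n_taxa: int = 100) -> list[tuple[str, BetaBinomParams]]:
    """Bacterial taxa of the default synthetic community, as (id, params) pairs."""
    community = make_baseline_community(n_taxa=n_taxa, seed=seed)
    return [(t.taxon_id, t.params) for t in community.bacterial_taxa]


def _as_community(params: list[tuple[str, BetaBinomParams]]) -> CommunityParams:
    total = sum(p.mu for _, p in params)
    scale = 0.99 / total if total >= 1.0 else 1.0
    taxa = tuple(
        TaxonSpec(tid, BetaBinomParams(p.mu * scale, p.phi), organelle=False)
        for tid, p in params
    )
    return CommunityParams(taxa=taxa)


def _rep_rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), 17, *map(int, path)]))


def _rep_seed(seed: int, *path: int) -> int:
    return int(np.random.SeedSequence([int(seed), 23, *map(int, path)]).generate_state(1)[0] % (2 ** 31))


# -- differential-abundance scan ------------------------------------------

def da_power_scan(
    params: list[tuple[str, BetaBinomParams]],
    n_values=(4, 8, 16, 32, 64),
    effect_values=(1.1, 1.5, 2.0, 3.0, 5.0, 10.0),
    frac_da: float = 0.5,
    test: str = "bblrt",
    alpha: float = 0.05,
    n_reps: int = 100,
    seed: int = 0,
    depth: int = 10_000,
    min_mu: float = _MIN_MU_DEFAULT,
) -> PowerGrid:
    """TPR and FDR of a per-taxon test over a (n, effect) grid.

    Per replicate, group A is drawn from the reference parameters and group B
    from a copy with ``frac_da`` of taxa multiplied (alternately divided) by
    the cell's fold change; each taxon is an independent beta-binomial at the
    nominal ``depth`` so null taxa are exactly null.  Discoveries are BH
    q <= ``alpha``; TPR counts detected injected taxa over all injected,
    FDR counts false discoveries over max(1, discoveries), both averaged
    over replicates.
    """
    if n_reps < 10:
        warnings.warn("n_reps < 10 gives noisy power estimates", stacklevel=2)
    base = _as_community(params)
    rows = []
    for ei, effect in enumerate(effect_values):
        # an (lo, hi) entry draws per-taxon folds uniform in that range
        erange = tuple(effect) if np.ndim(effect) == 1 else (effect, effect)
        for ni, n in enumerate(n_values):
            tprs, fdrs = [], []
            taxa_a = [(t.taxon_id, t.params) for t in base.bacterial_taxa]
            for rep in range(n_reps):
                inj_seed = _rep_seed(seed, 1, ei, ni, rep)
                taxa_b, spec = inject_effects_independent(
                    taxa_a, frac_da, effect_range=erange, seed=inj_seed)
                rng = _rep_rng(seed, 1, ei, ni, rep)
                ta = sample_independent_table(taxa_a, n, depth, rng,
                                              sample_ids=[f"a{i}" for i in range(n)])
                tb = sample_independent_table(taxa_b, n, depth, rng,
                                              sample_ids=[f"b{i}" for i in range(n)])
                combined = CountTable(pd.concat([ta.data, tb.data]))
                labels = ["A"] * n + ["B"] * n
                res = da_test_table(combined, labels, test=test, min_mu=min_mu, depths=depth)
                truth = set(spec.true_taxa)
                hits = set(res.index[(res["q"] <= alpha).fillna(False)])
                n_true = len(truth)
                tprs.append(len(hits & truth) / n_true if n_true else 0.0)
                fdrs.append(len(hits - truth) / max(1, len(hits)))
            label = effect if np.ndim(effect) == 0 else f"{erange[0]:g}-{erange[1]:g}"
            rows.append({"n": n, "effect": label, "tpr": float(np.mean(tprs)),
                         "fdr": float(np.mean(fdrs)), "n_replicates": n_reps})
    return PowerGrid(cells=pd.DataFrame(rows), test=test)


# -- PERMANOVA scan --------------------------------------------------------

def _adjusted_r2(r2: float, n_samples: int, k: int = 2) -> float:
    """Bias-adjusted R^2 (the vegan ``RsquareAdj`` correction): removes the
    null expectation (k - 1) / (N - 1) so large-n calibration R^2 estimates
    the population effect."""
    return 1.0 - (1.0 - r2) * (n_samples - 1) / (n_samples - k)


def _r2_of(dm, labels) -> float:
    codes = pd.factorize(np.asarray(labels))[0]
    d2 = dm.data ** 2
    n = d2.shape[0]
    sst = d2.sum() / (2.0 * n)
    ssw = _ss_within(d2, codes, codes.max() + 1)
    return float((sst - ssw) / sst) if sst > 0 else 0.0


def permanova_power_scan(
    params: list[tuple[str, BetaBinomParams]],
    n_values=(4, 5, 8, 16),
    effect_values=(1.1, 1.25, 1.5, 2.0, 3.0, 5.0, 10.0),
    frac_da: float = 0.1,
    n_perm: int = 999,
    alpha: float = 0.05,
    n_reps: int = 100,
    seed: int = 0,
    depth: int = 10_000,
    calibration_n: int = 64,
    r2_bin_width: float = 0.01,
) -> PowerGrid:
    """PERMANOVA rejection rate over sample sizes, indexed by population R^2.

    Per effect size, ``frac_da`` of taxa receive the fold change (alternating
    direction, remaining taxa renormalized) and the effect's population R^2
    is estimated once from a Bray-Curtis PERMANOVA on a large calibration
    draw of ``calibration_n`` samples per group.  Per replicate at each n the
    scan records the permutation p and the realized sample R^2; cell power is
    the fraction of replicates with p <= ``alpha``.
    """
    if n_reps < 10:
        warnings.warn("n_reps < 10 gives noisy power estimates", stacklevel=2)
    base = _as_community(params)
    taxa_a = [(t.taxon_id, t.params) for t in base.bacterial_taxa]
    cells, reps_out = [], []
    for ei, effect in enumerate(effect_values):
        inj_seed = _rep_seed(seed, 2, ei)
        group_b, _spec = inject_effects(base, frac_da, effect_range=(effect, effect),
                                        seed=inj_seed)
        taxa_b = [(t.taxon_id, t.params) for t in group_b.bacterial_taxa]

        cal_rng = _rep_rng(seed, 2, ei, 0)
        ca = sample_community_table(taxa_a, calibration_n, depth, cal_rng,
                                    sample_ids=[f"a{i}" for i in range(calibration_n)])
        cb = sample_community_table(taxa_b, calibration_n, depth, cal_rng,
                                    sample_ids=[f"b{i}" for i in range(calibration_n)])
        cal_dm = bray_curtis(CountTable(pd.concat([ca.data, cb.data])))
        pop_r2 = _adjusted_r2(_r2_of(cal_dm, ["A"] * calibration_n + ["B"] * calibration_n),
                              2 * calibration_n)

        for ni, n in enumerate(n_values):
            if n < 2:
                continue
            hits = 0
            realized = []
            for rep in range(n_reps):
                rng = _rep_rng(seed, 2, ei, ni + 1, rep)
                ta = sample_community_table(taxa_a, n, depth, rng,
                                            sample_ids=[f"a{i}" for i in range(n)])
                tb = sample_community_table(taxa_b, n, depth, rng,
                                            sample_ids=[f"b{i}" for i in range(n)])
                dm = bray_curtis(CountTable(pd.concat([ta.data, tb.data])))
                labels = ["A"] * n + ["B"] * n
                res = permanova(dm, labels, n_perm=n_perm,
                                seed=_rep_seed(seed, 2, ei, ni + 1, rep))
                hits += res.p <= alpha
                realized.append(res.r2)
                reps_out.append({"n": n, "effect": effect, "rep": rep,
                                 "p": res.p, "r2_realized": res.r2, "r2_pop": pop_r2})
            cells.append({
                "n": n, "effect": effect, "r2_pop": pop_r2,
                "r2_bin": float(np.floor(pop_r2 / r2_bin_width) * r2_bin_width),
                "power": hits / n_reps, "mean_r2_realized": float(np.mean(realized)),
                "n_replicates": n_reps,
            })
    return PowerGrid(cells=pd.DataFrame(cells), test="permanova",
                     replicates=pd.DataFrame(reps_out))


def permanova_power_replicates(
    params: list[tuple[str, BetaBinomParams]],
    n: int = 5,
    n_reps: int = 200,
    effect_range: tuple[float, float] = (1.1, 10.0),
    frac_da: float = 0.1,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    depth: int = 10_000,
    calibration_n: int = 64,
    r2_screen: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-replicate PERMANOVA benchmark with a fresh effect draw each time.

    Each replicate draws one fold change log-uniform in ``effect_range``,
    injects it into a fresh random ``frac_da`` of taxa, estimates the
    effect's population R^2 from a ``calibration_n``-per-group draw, then
    simulates ``n`` per group and records the permutation p, the realized
    sample R^2 and the population R^2.  Binning the rows by ``r2_pop`` gives
    power as a function of effect size on the R^2 scale.

    When ``r2_screen`` is set, candidate effects are drawn until ``n_reps``
    of them have a population R^2 inside the window; the small-n experiment
    runs only for those.  Screening on the calibration draw leaves the
    conditional rejection rate unchanged (the calibration and the
    experiment are independent) while concentrating all replicates in the
    R^2 range of interest.
    """
    base = _as_community(params)
    taxa_a = [(t.taxon_id, t.params) for t in base.bacterial_taxa]
    lo, hi = effect_range
    rows = []
    accepted = 0
    max_candidates = 200 * n_reps
    for rep in range(max_candidates):
        if accepted >= n_reps:
            break
        rng = _rep_rng(seed, 3, rep)
        effect = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        group_b, _spec = inject_effects(base, frac_da, effect_range=(effect, effect),
                                        seed=_rep_seed(seed, 3, rep))
        taxa_b = [(t.taxon_id, t.params) for t in group_b.bacterial_taxa]

        ca = sample_community_table(taxa_a, calibration_n, depth, rng,
                                    sample_ids=[f"a{i}" for i in range(calibration_n)])
        cb = sample_community_table(taxa_b, calibration_n, depth, rng,
                                    sample_ids=[f"b{i}" for i in range(calibration_n)])
        cal_dm = bray_curtis(CountTable(pd.concat([ca.data, cb.data])))
        pop_r2 = _adjusted_r2(_r2_of(cal_dm, ["A"] * calibration_n + ["B"] * calibration_n),
                              2 * calibration_n)
        if r2_screen is not None and not (r2_screen[0] <= pop_r2 <= r2_screen[1]):
            continue
        accepted += 1

        ta = sample_community_table(taxa_a, n, depth, rng,
                                    sample_ids=[f"a{i}" for i in range(n)])
        tb = sample_community_table(taxa_b, n, depth, rng,
                                    sample_ids=[f"b{i}" for i in range(n)])
        dm = bray_curtis(CountTable(pd.concat([ta.data, tb.data])))
        res = permanova(dm, ["A"] * n + ["B"] * n, n_perm=n_perm,
                        seed=_rep_seed(seed, 3, rep, 1))
        rows.append({"rep": rep, "effect": effect, "r2_pop": pop_r2,
                     "r2_realized": res.r2, "p": res.p,
                     "reject": bool(res.p <= alpha)})
        if r2_screen is None and len(rows) >= n_reps:
            break
    return pd.DataFrame(rows)


def report_power(
    grid: PowerGrid,
    power_target: float = 0.5,
    fdr_target: float = 0.05,
) -> pd.DataFrame:
    """Smallest per-group n meeting the power (and, if present, FDR) targets
    per effect size; NaN where no n on the grid reaches them."""
    cells = grid.cells
    if cells.empty:
        raise ValueError("empty power grid")
    power_col = "tpr" if "tpr" in cells.columns else "power"
    rows = []
    for effect, sub in cells.groupby("effect"):
        ok = sub[power_col] >= power_target
        if "fdr" in sub.columns:
            ok &= sub["fdr"] <= fdr_target
        reached = sub.loc[ok, "n"]
        rows.append({"effect": effect,
                     "min_n": float(reached.min()) if len(reached) else float("nan")})
    return pd.DataFrame(rows).set_index("effect")


def plot_power(grid: PowerGrid, path) -> None:
    """Power curves (one line per effect size) written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = grid.cells
    power_col = "tpr" if "tpr" in cells.columns else "power"
    fig, ax = plt.subplots(figsize=(5, 4))
    for effect, sub in cells.groupby("effect"):
        sub = sub.sort_values("n")
        ax.plot(sub["n"], sub[power_col], marker="o", label=f"effect {effect:g}")
    ax.axhline(0.5, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("samples per group")
    ax.set_ylabel("power")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
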