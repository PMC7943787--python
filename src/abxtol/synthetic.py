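"""Synthetic 16S experiment generator.

Emulates the count structure of a murine antibiotic-perturbation study so the
whole pipeline is testable without sequencing data:

* per-taxon read counts follow beta-binomial laws (mean proportion ``mu``,
  intra-class correlation / overdispersion ``phi``);
* a fixed pool of organelle-derived contaminant DNA (host mitochondria, diet
  chloroplasts) whose *relative* share of reads rises as bacterial biomass
  collapses under antibiotics — the signal used to phenotype mice;
* qPCR cycle thresholds log-linear in total 16S copies;
* optional injected fold-change effects with exact ground truth for
  differential-abundance benchmarking.

All randomness flows from one master seed through named substreams
(community, effects, mice, counts, qpcr) so factorial sweeps are reproducible
and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_tables import RANKS, CountTable

__all__ = [
    "BetaBinomParams",
    "TaxonSpec",
    "CommunityParams",
    "EffectSpec",
    "ExperimentDesign",
    "make_baseline_community",
    "sample_betabinom",
    "inject_effects",
    "inject_effects_independent",
    "simulate_experiment",
    "sample_community_table",
    "sample_independent_table",
    "make_taxonomy",
]

# fixed integer codes for named substreams of the master seed
_STREAMS = {"community": 1, "effects": 2, "mice": 3, "counts": 4, "qpcr": 5}


def substream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Independent generator for the named substream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name], *extra]))


@dataclass(frozen=True)
class BetaBinomParams:
    """Beta-binomial taxon parameters: mean proportion and overdispersion.

    ``phi`` is the intra-class correlation; the count W at depth M has
    variance ``M * mu * (1 - mu) * (1 + (M - 1) * phi)``.  ``phi = 0``
    reduces to the binomial.
    """

    mu: float
    phi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < 1.0):
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")
        if not (0.0 <= self.phi < 1.0):
            raise ValueError(f"phi must lie in [0, 1), got {self.phi}")

    @property
    def alpha(self) -> float:
        return self.mu * (1.0 - self.phi) / self.phi

    @property
    def beta(self) -> float:
        return (1.0 - self.mu) * (1.0 - self.phi) / self.phi

    def variance(self, depth: int) -> float:
        return depth * self.mu * (1 - self.mu) * (1 + (depth - 1) * self.phi)


@dataclass(frozen=True)
class TaxonSpec:
    taxon_id: str
    params: BetaBinomParams
    organelle: bool = False
    phylum: str = "Bacteroidetes"


@dataclass(frozen=True)
class CommunityParams:
    """Generative description of a gut community plus its contaminant background.

    ``biomass_baseline`` and ``contaminant_copies`` are 16S copies per sample;
    the contaminant pool (organelle DNA) is constant while bacterial biomass
    varies, which is what turns a biomass collapse into an organelle-read
    enrichment.  ``ct_intercept``/``ct_slope`` parameterize
    ``Ct = a - b * log10(copies)``.
    """

    taxa: tuple[TaxonSpec, ...]
    biomass_baseline: float = 1e9
    contaminant_copies: float = 1e5
    ct_intercept: float = 38.0
    ct_slope: float = 3.3

    def __post_init__(self) -> None:
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate taxon_ids in community")
        if self.biomass_baseline <= self.contaminant_copies:
            raise ValueError("healthy gut must be dominated by bacteria "
                             "(biomass_baseline > contaminant_copies)")
        if sum(t.params.mu for t in self.bacterial_taxa) > 1.0 + 1e-9:
            raise ValueError("bacterial mean proportions exceed 1")

    @property
    def bacterial_taxa(self) -> tuple[TaxonSpec, ...]:
        return tuple(t for t in self.taxa if not t.organelle)

    @property
    def organelle_taxa(self) -> tuple[TaxonSpec, ...]:
        return tuple(t for t in self.taxa if t.organelle)

    def organelle_fraction_at(self, biomass: float) -> float:
        """Expected organelle read share when bacterial biomass is ``biomass``."""
        return self.contaminant_copies / (biomass + self.contaminant_copies)


@dataclass(frozen=True)
class EffectSpec:
    """Ground truth of injected differential-abundance effects.

    ``table`` maps taxon_id -> (fold_change, truth); ``fold_change`` is the
    multiplicative change applied to group B's mu (values < 1 are
    depletions), and ``truth`` is True iff the taxon is genuinely
    differentially abundant (fold_change != 1).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        fc = self.table["fold_change"]
        truth = self.table["truth"]
        if ((fc == 1.0) != ~truth).any():
            raise ValueError("fold_change == 1 must coincide with truth == False")

    @property
    def true_taxa(self) -> list[str]:
        return list(self.table.index[self.table["truth"]])


@dataclass(frozen=True)
class ExperimentDesign:
    """Study layout for :func:`simulate_experiment`."""

    n_treated: int = 16
    n_control: int = 6
    days: tuple[int, ...] = (0, 2, 4, 6, 8, 10, 12)
    window: tuple[int, int] = (2, 8)
    nonresponder_frac: float = 0.3125
    collapse_magnitude: float = 3.5
    depth: int = 10_000
    ct_noise_sd: float = 0.5
    biomass_sd_log10: float = 0.3
    diet: str = "chow"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (min(self.days) <= lo <= hi <= max(self.days)):
            raise ValueError(f"antibiotic window {self.window} outside sampling days")
        if self.collapse_magnitude < 0:
            raise ValueError("collapse_magnitude must be >= 0")
        if not (0.0 <= self.nonresponder_frac <= 1.0):
            raise ValueError("nonresponder_frac must lie in [0, 1]")


# -- community construction ------------------------------------------------

_BACTERIAL_PHYLA = ("Bacteroidetes", "Firmicutes", "Actinobacteria",
                    "Verrucomicrobia", "Tenericutes")

#: SILVA-132 style lineages for the two contaminant taxa.
_ORGANELLE_SPECS = (
    ("organelle_mito", "Proteobacteria",
     ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales",
      "Mitochondria", "Unassigned", "Unassigned")),
    ("organelle_chloro", "Cyanobacteria",
     ("Bacteria", "Cyanobacteria", "Oxyphotobacteria", "Chloroplast",
      "Unassigned", "Unassigned", "Unassigned")),
)

_BACTERIAL_MASS = 0.95  # share of the healthy composition held by bacteria-by-construction


def make_baseline_community(
    n_taxa: int = 100,
    seed: int = 0,
    mu_range: tuple[float, float] = (0.001, 0.1),
    phi_range: tuple[float, float] = (0.005, 0.05),
    **community_kwargs,
) -> CommunityParams:
    """Draw a baseline community of ``n_taxa`` bacterial taxa plus 2 organelle taxa.

    Mean proportions are log-uniform in ``mu_range`` then renormalized so the
    bacterial block sums to 0.95, with a floor at the lower bound of
    ``mu_range`` so every taxon stays above the abundance cutoff used by the
    differential-abundance prefilter; overdispersions are uniform in
    ``phi_range``.  Deterministic per seed.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    lo, hi = mu_range
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"mu_range must satisfy 0 < lo < hi < 1, got {mu_range}")
    plo, phi_hi = phi_range
    if not (0.0 <= plo <= phi_hi < 1.0):
        raise ValueError(f"phi_range must lie within [0, 1), got {phi_range}")

    rng = substream(seed, "community")
    mus = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_taxa))
    mus *= _BACTERIAL_MASS / mus.sum()
    # floor-and-rebalance: keep every taxon above the cutoff without changing the total
    for _ in range(100):
        low = mus < lo
        if not low.any():
            break
        mus[low] = lo * 1.0001
        free = ~low
        budget = _BACTERIAL_MASS - mus[low].sum()
        mus[free] *= budget / mus[free].sum()
    phis = rng.uniform(plo, phi_hi, size=n_taxa)
    phyla = rng.choice(_BACTERIAL_PHYLA, size=n_taxa, p=(0.45, 0.4, 0.07, 0.05, 0.03))

    width = len(str(n_taxa))
    taxa = [
        TaxonSpec(f"asv_{i + 1:0{width}d}", BetaBinomParams(float(mus[i]), float(phis[i])),
                  organelle=False, phylum=str(phyla[i]))
        for i in range(n_taxa)
    ]
    remainder = 1.0 - _BACTERIAL_MASS
    for name, phylum, _lineage in _ORGANELLE_SPECS:
        taxa.append(TaxonSpec(name, BetaBinomParams(remainder / 2, float(np.mean(phi_range))),
                              organelle=True, phylum=phylum))
    return CommunityParams(taxa=tuple(taxa), **community_kwargs)


def make_taxonomy(params: CommunityParams) -> pd.DataFrame:
    """SILVA-style lineage table for a synthetic community."""
    organelle_lineages = {name: lin for name, _ph, lin in _ORGANELLE_SPECS}
    rows = {}
    for t in params.taxa:
        if t.organelle:
            rows[t.taxon_id] = organelle_lineages[t.taxon_id]
        else:
            rows[t.taxon_id] = ("Bacteria", t.phylum, f"{t.phylum}_class",
                                f"{t.phylum}_order", f"{t.phylum}_family",
                                f"genus_{t.taxon_id}", "Unassigned")
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)).rename_axis("taxon_id")


# -- sampling primitives ---------------------------------------------------

def _rng_of(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_betabinom(mu: float, phi: float, depth: int, n: int, seed) -> np.ndarray:
    """``n`` beta-binomial draws at ``depth``; phi = 0 is exactly binomial."""
    BetaBinomParams(mu, phi)  # validates
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng_of(seed)
    if phi == 0.0:
        return rng.binomial(depth, mu, size=n)
    a = mu * (1 - phi) / phi
    b = (1 - mu) * (1 - phi) / phi
    p = rng.beta(a, b, size=n)
    return rng.binomial(depth, p)


def _latent_proportions(mus: np.ndarray, phis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One latent composition: independent Beta draws per taxon, closed to sum 1."""
    p = np.where(
        phis > 0,
        rng.beta(np.maximum(mus * (1 - phis) / np.maximum(phis, 1e-12), 1e-12),
                 np.maximum((1 - mus) * (1 - phis) / np.maximum(phis, 1e-12), 1e-12)),
        mus,
    )
    total = p.sum()
    if total <= 0:
        p = mus.copy()
        total = p.sum()
    return p / total


def sample_community_table(
    taxa: list[tuple[str, BetaBinomParams]],
    n_samples: int,
    depth: int,
    seed,
    sample_ids: list[str] | None = None,
) -> CountTable:
    """Compositional sampler: latent Beta proportions closed to 1, then a
    multinomial draw, so every sample sums to ``depth`` exactly.

    Marginal taxon counts are approximately beta-binomial with the requested
    (mu, phi) when the mus are a near-complete composition.
    """
    rng = _rng_of(seed)
    mus = np.array([p.mu for _, p in taxa])
    phis = np.array([p.phi for _, p in taxa])
    mus = mus / mus.sum()
    rows = np.empty((n_samples, len(taxa)), dtype=np.int64)
    for i in range(n_samples):
        rows[i] = rng.multinomial(depth, _latent_proportions(mus, phis, rng))
    ids = sample_ids if sample_ids is not None else [f"s{i + 1}" for i in range(n_samples)]
    return CountTable(pd.DataFrame(rows, index=ids, columns=[t for t, _ in taxa]))


def sample_independent_table(
    taxa: list[tuple[str, BetaBinomParams]],
    n_samples: int,
    depth: int,
    seed,
    sample_ids: list[str] | None = None,
) -> CountTable:
    """Per-taxon independent beta-binomial draws at a fixed nominal depth.

    Marginals are exactly beta-binomial (no compositional closure); row sums
    are not constrained.  This is the sampler used for per-taxon
    differential-abundance benchmarking, where exact null marginals matter.
    """
    rng = _rng_of(seed)
    cols = np.empty((n_samples, len(taxa)), dtype=np.int64)
    for j, (_, p) in enumerate(taxa):
        cols[:, j] = sample_betabinom(p.mu, p.phi, depth, n_samples, rng)
    ids = sample_ids if sample_ids is not None else [f"s{i + 1}" for i in range(n_samples)]
    return CountTable(pd.DataFrame(cols, index=ids, columns=[t for t, _ in taxa]))


# -- effect injection ------------------------------------------------------

def _draw_effects(n_taxa: int, frac_da: float, effect_range: tuple[float, float],
                  rng: np.random.Generator) -> np.ndarray:
    """Per-taxon applied fold changes: floor(frac_da * n_taxa) taxa get a fold
    drawn uniform in ``effect_range``, alternately as enrichment (x f) and
    depletion (/ f); everyone else gets 1."""
    if not (0.0 <= frac_da <= 1.0):
        raise ValueError("frac_da must lie in [0, 1]")
    flo, fhi = effect_range
    if flo < 1.0 or fhi < flo:
        raise ValueError(f"effect_range must satisfy 1 <= lo <= hi, got {effect_range}")
    n_da = int(np.floor(frac_da * n_taxa))
    fold_col = np.ones(n_taxa)
    if n_da:
        chosen = sorted(rng.choice(n_taxa, size=n_da, replace=False))
        folds = rng.uniform(flo, fhi, size=n_da)
        for k, (idx, f) in enumerate(zip(chosen, folds)):
            fold_col[idx] = f if k % 2 == 0 else 1.0 / f
    return fold_col


def inject_effects(
    params: CommunityParams,
    frac_da: float,
    effect_range: tuple[float, float] = (1.1, 10.0),
    seed: int = 0,
) -> tuple[CommunityParams, EffectSpec]:
    """Create a group-B community with fold-change effects on a fraction of taxa.

    ``floor(frac_da * n_bacterial)`` bacterial taxa are selected; fold changes
    are drawn uniform in ``effect_range`` and applied alternately as
    enrichment (x f) and depletion (/ f) so the composition stays roughly
    balanced.  Untouched taxa are rescaled proportionally so the bacterial
    block keeps its total mass, leaving the injected fold changes exact; if
    the injected mass alone exceeds that budget the whole block is closed
    instead (folds then exact only up to a common scale).
    """
    bacterial = params.bacterial_taxa
    rng = substream(seed, "effects")
    fold_col = _draw_effects(len(bacterial), frac_da, effect_range, rng)

    mus = np.array([t.params.mu for t in bacterial])
    new_mus = mus * fold_col
    touched = fold_col != 1.0
    if touched.any():
        target = mus.sum()
        budget = target - new_mus[touched].sum()
        if budget > 0 and (~touched).any():
            new_mus[~touched] *= budget / new_mus[~touched].sum()
        else:
            new_mus *= target / new_mus.sum()
    new_mus = np.clip(new_mus, 1e-12, 1 - 1e-9)

    new_taxa = [replace(t, params=replace(t.params, mu=float(m)))
                for t, m in zip(bacterial, new_mus)] + list(params.organelle_taxa)
    group_b = replace(params, taxa=tuple(new_taxa))

    spec_rows = pd.DataFrame(
        {"fold_change": fold_col, "truth": touched},
        index=[t.taxon_id for t in bacterial],
    ).rename_axis("taxon_id")
    for t in params.organelle_taxa:
        spec_rows.loc[t.taxon_id] = [1.0, False]
    return group_b, EffectSpec(spec_rows)


def inject_effects_independent(
    taxa: list[tuple[str, BetaBinomParams]],
    frac_da: float,
    effect_range: tuple[float, float] = (1.1, 10.0),
    seed: int = 0,
) -> tuple[list[tuple[str, BetaBinomParams]], EffectSpec]:
    """Fold-change injection for per-taxon independent sampling.

    Each selected taxon's mu is multiplied (or divided, alternating) by its
    fold with no compositional closure, so unselected taxa keep *exactly*
    their group-A law — the property that makes false-discovery bookkeeping
    exact in differential-abundance benchmarks.
    """
    rng = substream(seed, "effects")
    fold_col = _draw_effects(len(taxa), frac_da, effect_range, rng)
    out = [
        (tid, replace(p, mu=float(np.clip(p.mu * f, 1e-12, 1 - 1e-9))))
        for (tid, p), f in zip(taxa, fold_col)
    ]
    spec_rows = pd.DataFrame(
        {"fold_change": fold_col, "truth": fold_col != 1.0},
        index=[tid for tid, _ in taxa],
    ).rename_axis("taxon_id")
    return out, EffectSpec(spec_rows)


# -- full experiment -------------------------------------------------------

def simulate_experiment(
    design: ExperimentDesign,
    params: CommunityParams | None = None,
) -> tuple[CountTable, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the longitudinal antibiotic experiment.

    Returns ``(counts, taxonomy, metadata, qpcr)``.  Per mouse and day the
    bacterial biomass is the baseline except in responder mice from the start
    of the antibiotic window onward, where it is divided by
    ``10 ** collapse_magnitude``; on top of that, every sample's biomass gets
    log10-normal variability (``biomass_sd_log10`` orders), the sample-to-sample
    spread real fecal communities show.  The expected organelle read share is
    ``contaminant / (biomass + contaminant)``; bacterial mean proportions are
    rescaled by the bacterial share and counts drawn compositionally at the
    design depth.  Ct values follow ``a - b * log10(total copies)`` plus
    Gaussian noise.
    """
    if params is None:
        params = make_baseline_community(seed=design.seed)
    seed = design.seed

    mouse_rng = substream(seed, "mice")
    treated = [f"T{i + 1:02d}" for i in range(design.n_treated)]
    controls = [f"C{i + 1:02d}" for i in range(design.n_control)]
    n_nonresp = int(round(design.nonresponder_frac * design.n_treated))
    shuffled = list(treated)
    mouse_rng.shuffle(shuffled)
    nonresponders = set(shuffled[:n_nonresp])

    bacterial = params.bacterial_taxa
    organelle = params.organelle_taxa
    taxon_ids = [t.taxon_id for t in params.taxa]
    mus_b = np.array([t.params.mu for t in bacterial])
    phis = np.array([t.params.phi for t in params.taxa])
    org_w = np.array([t.params.mu for t in organelle])
    org_w = org_w / org_w.sum()

    lo, _hi = design.window
    rows, meta_rows, ct_rows = [], [], []
    qpcr_rng = substream(seed, "qpcr")
    for m_idx, mouse in enumerate(treated + controls):
        treated_flag = mouse in treated
        responder = treated_flag and mouse not in nonresponders
        count_rng = substream(seed, "counts", m_idx)
        for day in design.days:
            collapsed = responder and day >= lo
            log_b = (np.log10(params.biomass_baseline)
                     - (design.collapse_magnitude if collapsed else 0.0)
                     + count_rng.normal(0.0, design.biomass_sd_log10))
            biomass = 10.0 ** log_b
            g = params.organelle_fraction_at(biomass)
            mus = np.concatenate([(1 - g) * mus_b / mus_b.sum(), g * org_w])
            p = _latent_proportions(mus, phis, count_rng)
            rows.append(count_rng.multinomial(design.depth, p))
            sid = f"{mouse}_d{day:02d}"
            meta_rows.append({
                "sample_id": sid,
                "mouse_id": mouse,
                "day": day,
                "group": "antibiotic" if treated_flag else "control",
                "antibiotic_window": bool(design.window[0] <= day <= design.window[1]),
                "diet": design.diet,
            })
            ct = (params.ct_intercept
                  - params.ct_slope * np.log10(biomass + params.contaminant_copies)
                  + qpcr_rng.normal(0.0, design.ct_noise_sd))
            ct_rows.append({"sample_id": sid, "ct": float(ct)})

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    counts = CountTable(pd.DataFrame(np.asarray(rows, dtype=np.int64),
                                     index=metadata.index.copy(), columns=taxon_ids))
    qpcr = pd.DataFrame(ct_rows).set_index("sample_id")
    return counts, make_taxonomy(params), metadata, qpcr
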