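"""Synthetic multi-season endophyte study generator.

Emulates the sampled study design — 2 radiation levels x 4 seasons x
2 tissue types x 5 replicates, a few hundred taxa, samples at a common
read depth — with the statistical structure the analysis pipeline
assumes:

* a neutral-assembly backbone: per-sample compositions drawn from a
  Dirichlet with concentration Nm * p (the exact finite counterpart of
  the Sloan beta approximation), counts multinomial at the target depth;
* planted non-neutral taxa: "selected" taxa forced present in every
  sample (occupancy above the neutral prediction) and "limited" taxa
  zeroed in a fraction of samples (occupancy below);
* planted season-persistent correlated pairs: in their active seasons a
  pair's counts are monotone transforms of a shared latent sample
  factor, so the within-season Spearman correlation is exactly +/-1.

Every generated truth is written into a manifest so that recovery can
be scored end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import SEASONS, SITES, TISSUES, AbundanceTable

__all__ = [
    "PlantedPair",
    "SyntheticDesign",
    "default_design",
    "make_pool",
    "make_seasonal_pools",
    "simulate_neutral_group",
    "plant_signals",
    "generate_study",
]


@dataclass(frozen=True)
class PlantedPair:
    taxon_a: str
    taxon_b: str
    seasons: frozenset[str]
    sign: str = "positive"  # positive | negative


@dataclass
class SyntheticDesign:
    """Parameters of the generated study.

    Defaults mirror the emulated design: 2 sites x 2 tissues x 4 seasons
    x 5 replicates, ~300 taxa, samples at 7,500 reads, a lognormal
    metacommunity pool and migration parameter Nm = 500 (a mid-range
    value producing a clear occupancy-abundance relationship at this
    depth). Seasonal pools drift by 10% multiplicative lognormal jitter.
    """

    n_taxa: int = 300
    pool_distribution: str = "lognormal"  # lognormal | logseries
    pool_params: dict = field(default_factory=lambda: {"mu": 0.0, "sigma": 1.5})
    Nm: float = 500.0
    sites: tuple[str, ...] = SITES
    tissues: tuple[str, ...] = TISSUES
    seasons: tuple[str, ...] = SEASONS
    replicates: int = 5
    depth: int = 7500
    drift: float = 0.1
    selected_taxa: tuple[str, ...] = ()
    selected_min_count: int = 9
    limited_taxa: tuple[str, ...] = ()
    limited_zero_fraction: float = 0.6
    persistent_pairs: tuple[PlantedPair, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        universe = set(self.taxon_ids())
        planted = set(self.selected_taxa) | set(self.limited_taxa)
        for pair in self.persistent_pairs:
            if not pair.seasons:
                raise ValueError("persistent pair with empty season subset")
            if not pair.seasons <= set(self.seasons):
                raise ValueError("pair seasons outside the design's seasons")
            planted |= {pair.taxon_a, pair.taxon_b}
        if not planted <= universe:
            raise ValueError("planted taxon ids outside the taxon universe")

    def taxon_ids(self) -> list[str]:
        return [f"T{i:04d}" for i in range(self.n_taxa)]

    def groups(self) -> list[tuple[str, str]]:
        return [(s, t) for s in self.sites for t in self.tissues]


def default_design(seed: int = 0, **overrides) -> SyntheticDesign:
    """The default study: planted signals chosen from realistic abundance strata.

    Selected taxa are drawn from the rare tail of the pool (their neutral
    predicted occupancy is low, so forced presence is detectably
    non-neutral); limited taxa from the abundant head (predicted
    occupancy near 1, so planted absences are detectable); correlated
    pairs from rare taxa, matching the observation that persistently
    networked endophytes are rare (< 0.005 relative abundance).
    Five pairs are active in >= 2 seasons (persistent) and three in a
    single season (transient).
    """
    base = SyntheticDesign(seed=seed, **{k: v for k, v in overrides.items()
                                         if k not in ("selected_taxa",
                                                      "limited_taxa",
                                                      "persistent_pairs")})
    pool = make_pool(base)
    order = np.argsort(pool)  # ascending abundance
    ids = np.asarray(base.taxon_ids())
    rare = ids[order[:60]]
    abundant = ids[order[-20:]]
    selected = tuple(rare[:8])
    limited = tuple(abundant[-8:])
    pair_taxa = rare[8:8 + 16]
    seas = base.seasons
    pair_specs = [
        (frozenset(seas), "positive"),
        (frozenset(seas[:3]), "positive"),
        (frozenset(seas[1:]), "negative"),
        (frozenset({seas[0], seas[2]}), "positive"),
        (frozenset({seas[1], seas[3]}), "positive"),
        (frozenset({seas[0]}), "positive"),
        (frozenset({seas[2]}), "negative"),
        (frozenset({seas[3]}), "positive"),
    ]
    pairs = tuple(
        PlantedPair(pair_taxa[2 * i], pair_taxa[2 * i + 1], s, g)
        for i, (s, g) in enumerate(pair_specs)
    )
    return SyntheticDesign(
        seed=seed,
        selected_taxa=selected,
        limited_taxa=limited,
        persistent_pairs=pairs,
        **{k: v for k, v in overrides.items()
           if k not in ("selected_taxa", "limited_taxa", "persistent_pairs")},
    )


# ---------------------------------------------------------------------------
# pools
# ---------------------------------------------------------------------------

def make_pool(design: SyntheticDesign) -> np.ndarray:
    """Base metacommunity relative-abundance vector (sums to 1)."""
    rng = np.random.default_rng(design.seed)
    if design.pool_distribution == "lognormal":
        mu = float(design.pool_params.get("mu", 0.0))
        sigma = float(design.pool_params.get("sigma", 1.5))
        if sigma <= 0:
            raise ValueError("lognormal sigma must be positive")
        raw = rng.lognormal(mu, sigma, size=design.n_taxa)
    elif design.pool_distribution == "logseries":
        alpha = float(design.pool_params.get("alpha", 0.99))
        if not 0 < alpha < 1:
            raise ValueError("logseries alpha must be in (0, 1)")
        raw = rng.logseries(alpha, size=design.n_taxa).astype(float)
    else:
        raise ValueError(f"unknown pool distribution: {design.pool_distribution}")
    return raw / raw.sum()


def make_seasonal_pools(design: SyntheticDesign) -> dict[str, np.ndarray]:
    """Seasonal pools by bounded multiplicative drift from the base pool."""
    rng = np.random.default_rng(design.seed + 1)
    pools = {}
    current = make_pool(design)
    for season in design.seasons:
        pools[season] = current
        jitter = np.clip(
            rng.normal(0.0, design.drift, size=design.n_taxa),
            -3 * design.drift,
            3 * design.drift,
        )
        nxt = current * np.exp(jitter)
        current = nxt / nxt.sum()
    return pools


# ---------------------------------------------------------------------------
# neutral backbone
# ---------------------------------------------------------------------------

def simulate_neutral_group(
    p: np.ndarray,
    Nm: float,
    n_samples: int,
    depth: int,
    seed: int,
    taxon_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> AbundanceTable:
    """Neutral-assembly count table for one group of samples.

    Per sample a composition is drawn from Dirichlet(Nm * p) — whose
    marginals are the Beta(Nm p_i, Nm (1-p_i)) of the Sloan model — and
    counts are multinomial at ``depth``.
    """
    p = np.asarray(p, dtype=float)
    if Nm <= 0 or depth < 1 or n_samples < 1:
        raise ValueError("Nm, depth, n_samples must be positive")
    rng = np.random.default_rng(seed)
    alpha = Nm * p
    counts = np.empty((p.size, n_samples), dtype=np.int64)
    for s in range(n_samples):
        comp = rng.dirichlet(alpha)
        counts[:, s] = rng.multinomial(depth, comp)
    if taxon_ids is None:
        taxon_ids = [f"T{i:04d}" for i in range(p.size)]
    if sample_ids is None:
        sample_ids = [f"S{s:03d}" for s in range(n_samples)]
    return AbundanceTable(pd.DataFrame(counts, index=taxon_ids, columns=sample_ids))


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

def _stage_seed(design_seed: int, *parts: str) -> int:
    import hashlib

    digest = hashlib.sha256(("|".join(parts) + f"|{design_seed}").encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def plant_signals(
    table: AbundanceTable,
    design: SyntheticDesign,
    season: str,
    seed: int | None = None,
) -> AbundanceTable:
    """Inject the designed non-neutral and correlated-pair signals.

    Order: limited zeroing -> pair latent-factor rewrite -> selected
    presence injection -> exact renormalisation of every column to the
    design depth.
    """
    if seed is None:
        seed = _stage_seed(design.seed, "plant", season, *table.sample_ids)
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy().copy()
    taxon_index = {t: i for i, t in enumerate(table.taxon_ids)}
    n_samples = counts.shape[1]

    active_pairs = [p for p in design.persistent_pairs if season in p.seasons]
    pair_taxa = {t for p in active_pairs for t in (p.taxon_a, p.taxon_b)}
    for p in active_pairs:
        if {p.taxon_a, p.taxon_b} & set(design.limited_taxa):
            raise ValueError(
                f"pair ({p.taxon_a}, {p.taxon_b}) overlaps a limited taxon "
                f"in its active season {season}"
            )

    # 1. limited taxa: zero a configured fraction of samples
    n_zero = int(round(design.limited_zero_fraction * n_samples))
    for taxon in design.limited_taxa:
        cols = rng.choice(n_samples, size=n_zero, replace=False)
        counts[taxon_index[taxon], cols] = 0

    # 2. planted pair taxa are seasonal specialists: absent outside the
    # seasons where one of their associations is active (otherwise sparse
    # background counts could fake the association in an off season)
    all_pair_taxa = {
        t for p in design.persistent_pairs for t in (p.taxon_a, p.taxon_b)
    }
    for taxon in all_pair_taxa - pair_taxa:
        counts[taxon_index[taxon]] = 0
    # active pairs: counts as monotone transforms of a shared latent
    # factor -> |rho| = 1 within the season; values distinct and small
    # (the pair taxa stay rare)
    for p in active_pairs:
        latent = rng.permutation(n_samples)  # latent sample ranks 0..n-1
        a_vals = 10 * (latent + 1)
        b_vals = a_vals if p.sign == "positive" else 10 * (n_samples - latent)
        counts[taxon_index[p.taxon_a]] = a_vals
        counts[taxon_index[p.taxon_b]] = b_vals

    # 3. selected taxa: force presence everywhere; the injected floor keeps
    # them above the dataset-wide relative-abundance filter and makes their
    # occupancy robust to subsequent rarefaction, while staying rare
    for taxon in design.selected_taxa:
        row = counts[taxon_index[taxon]]
        counts[taxon_index[taxon]] = np.maximum(row, max(1, design.selected_min_count))

    # 4. renormalise columns exactly to depth using unplanted taxa
    protected = (
        {taxon_index[t] for t in design.selected_taxa}
        | {taxon_index[t] for t in design.limited_taxa}
        | {taxon_index[t] for t in all_pair_taxa}
    )
    free = np.array([i for i in range(counts.shape[0]) if i not in protected])
    for s in range(n_samples):
        excess = int(counts[:, s].sum()) - design.depth
        if excess == 0:
            continue
        order = free[np.argsort(-counts[free, s])]
        if excess > 0:
            for i in order:
                take = min(excess, int(counts[i, s]))
                counts[i, s] -= take
                excess -= take
                if excess == 0:
                    break
            if excess != 0:
                raise ValueError("cannot renormalise sample to depth")
        else:
            counts[order[0], s] += -excess
    out = pd.DataFrame(counts, index=table.counts.index, columns=table.counts.columns)
    return AbundanceTable(out, table.metadata)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def generate_study(
    design: SyntheticDesign,
) -> tuple[dict[tuple[str, str, str], AbundanceTable], dict]:
    """Generate the full site x tissue x season grid plus a truth manifest.

    Returns a mapping (site, tissue, season) -> AbundanceTable with
    metadata, every column summing to the design depth, and a manifest
    recording planted selected/limited taxa and pairs (with season sets)
    for recovery scoring.
    """
    pools = make_seasonal_pools(design)
    taxa = design.taxon_ids()
    tables: dict[tuple[str, str, str], AbundanceTable] = {}
    for site in design.sites:
        for tissue in design.tissues:
            for season in design.seasons:
                seed = _stage_seed(design.seed, "group", site, tissue, season)
                sample_ids = [
                    f"{site[:4]}-{tissue[:3]}-{season[:3]}-r{i + 1}"
                    for i in range(design.replicates)
                ]
                tab = simulate_neutral_group(
                    pools[season],
                    design.Nm,
                    design.replicates,
                    design.depth,
                    seed,
                    taxon_ids=taxa,
                    sample_ids=sample_ids,
                )
                meta = pd.DataFrame(
                    {
                        "site": site,
                        "tissue": tissue,
                        "season": season,
                        "replicate": range(1, design.replicates + 1),
                    },
                    index=pd.Index(sample_ids, name="sample_id"),
                )
                tab = AbundanceTable(tab.counts, meta)
                tables[(site, tissue, season)] = plant_signals(tab, design, season)
    manifest = {
        "seed": design.seed,
        "Nm": design.Nm,
        "depth": design.depth,
        "replicates": design.replicates,
        "selected_taxa": list(design.selected_taxa),
        "limited_taxa": list(design.limited_taxa),
        "pairs": [
            {
                "taxon_a": p.taxon_a,
                "taxon_b": p.taxon_b,
                "seasons": sorted(p.seasons),
                "sign": p.sign,
            }
            for p in design.persistent_pairs
        ],
        "persistent_pairs": [
            sorted((p.taxon_a, p.taxon_b))
            for p in design.persistent_pairs
            if len(p.seasons) >= 2
        ],
        "transient_pairs": [
            sorted((p.taxon_a, p.taxon_b))
            for p in design.persistent_pairs
            if len(p.seasons) == 1
        ],
    }
    return tables, manifest


def concat_tables(tables: dict, keys: list | None = None) -> AbundanceTable:
    """Column-concatenate generated group tables into one study table."""
    use = keys if keys is not None else list(tables)
    counts = pd.concat([tables[k].counts for k in use], axis=1)
    meta = pd.concat([tables[k].metadata for k in use], axis=0)
    return AbundanceTable(counts, meta)
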