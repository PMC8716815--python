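"""Raup-Crick null-model beta-diversity and the stochasticity fraction.

For each sample pair the observed number of shared taxa is compared
with a null distribution obtained by repeatedly drawing the two
samples' richnesses from the regional taxon pool (selection probability
proportional to occurrence frequency by default). The Raup-Crick index

    RCI = 2 * [#(null < obs) + 0.5 * #(null = obs)] / n_reps - 1

lies in [-1, 1]; pairs with |RCI| below a threshold (0.95 by
convention) share no more and no fewer taxa than expected by chance,
and their compositional difference is read as stochastic. The fraction
of such pairs is the community-level stochasticity summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AbundanceTable

__all__ = ["RaupCrickResult", "raup_crick", "stochastic_fraction"]


@dataclass
class RaupCrickResult:
    labels: list[str]
    rci: np.ndarray  # symmetric, NaN diagonal
    n_reps: int
    seed: int
    weighted: bool
    threshold: float = 0.95

    @property
    def stochastic_fraction(self) -> float:
        return stochastic_fraction(self, self.threshold)

    def pair_values(self) -> np.ndarray:
        n = len(self.labels)
        iu = np.triu_indices(n, 1)
        return self.rci[iu]


def _null_members(weights: np.ndarray, richness: int, n_reps: int, rng) -> np.ndarray:
    """Boolean (n_reps, pool) membership of weighted draws without replacement.

    Uses the Gumbel-top-k trick: perturb log-weights with Gumbel noise
    and take the top ``richness`` keys per replicate.
    """
    pool = weights.size
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    keys = logw[None, :] + rng.gumbel(size=(n_reps, pool))
    top = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    members = np.zeros((n_reps, pool), dtype=bool)
    np.put_along_axis(members, top, True, axis=1)
    return members


def raup_crick(
    table: AbundanceTable,
    n_reps: int = 999,
    weighted: bool = True,
    seed: int = 0,
    threshold: float = 0.95,
) -> RaupCrickResult:
    """Pairwise Raup-Crick indices for all samples of ``table``.

    The regional pool is the full taxon universe of the table (rows).
    With ``weighted=True`` taxa enter null draws with probability
    proportional to their occurrence frequency across the table's
    samples; taxa never observed then have zero draw probability.
    With ``weighted=False`` all pool taxa are drawn uniformly.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    presence = table.counts.to_numpy() > 0
    n_taxa, n_samples = presence.shape
    occ = presence.sum(axis=1).astype(float)
    if weighted:
        weights = occ.copy()
    else:
        weights = np.ones(n_taxa)
    drawable = int(np.sum(weights > 0))
    richness = presence.sum(axis=0)
    if np.any(richness > drawable):
        raise ValueError("sample richness exceeds drawable pool size")

    rng = np.random.default_rng(seed)
    rci = np.full((n_samples, n_samples), np.nan)
    for j in range(n_samples):
        for k in range(j + 1, n_samples):
            n1, n2 = int(richness[j]), int(richness[k])
            if n1 == 0 or n2 == 0:
                warnings.warn(
                    f"sample pair ({table.sample_ids[j]}, {table.sample_ids[k]}) "
                    "has an empty sample; pair skipped"
                )
                continue
            ss_obs = int(np.sum(presence[:, j] & presence[:, k]))
            m1 = _null_members(weights, n1, n_reps, rng)
            m2 = _null_members(weights, n2, n_reps, rng)
            ss_null = np.sum(m1 & m2, axis=1)
            below = np.sum(ss_null < ss_obs)
            ties = np.sum(ss_null == ss_obs)
            val = 2.0 * (below + 0.5 * ties) / n_reps - 1.0
            rci[j, k] = rci[k, j] = val
    return RaupCrickResult(table.sample_ids, rci, n_reps, seed, weighted, threshold)


def stochastic_fraction(
    result: RaupCrickResult,
    threshold: float = 0.95,
    within_group: pd.Series | dict | None = None,
) -> float:
    """Fraction of sample pairs with |RCI| below ``threshold``.

    With ``within_group`` (sample id -> group label) only pairs inside
    the same group are counted, matching per-season summaries.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n = len(result.labels)
    iu, ju = np.triu_indices(n, 1)
    vals = result.rci[iu, ju]
    if within_group is not None:
        grp = pd.Series(within_group)
        glab = grp.loc[result.labels].to_numpy()
        mask = glab[iu] == glab[ju]
        vals = vals[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid sample pairs for the requested grouping")
    return float(np.mean(np.abs(vals) < threshold))
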