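"""Sloan neutral community model fit and cross-season deviation persistence.

The Sloan model predicts, for a taxon with metacommunity mean relative
abundance p, the expected fraction of local communities in which it is
detected above a detection limit d:

    freq_hat(p) = 1 - B(d; Nm*p, Nm*(1-p))

where B is the regularized incomplete beta CDF and Nm (metacommunity
size x migration rate) is the single free parameter, estimated by
nonlinear least squares of observed occupancy on predicted occupancy.
Taxa whose observed occupancy falls outside a 95% binomial (Wilson)
band around the prediction are labelled "above" (plant selection
candidates) or "below" (dispersal limitation candidates); taxa
deviating in the same direction in all four seasons are the
persistently non-neutral members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import beta as beta_dist
from statsmodels.stats.proportion import proportion_confint

from .data_model import TaxonStats

__all__ = [
    "NCMFit",
    "PersistenceRecord",
    "ncm_predicted_freq",
    "fit_ncm",
    "persistence_across_seasons",
]

_LOG_NM_BOUNDS = (0.0, np.log(1e7))
_N_MULTISTART = 5


class NCMFitError(RuntimeError):
    """Raised when the Nm optimizer fails across all restarts."""


@dataclass
class NCMFit:
    Nm: float
    r2: float
    d: float
    n_samples: int
    per_taxon: pd.DataFrame  # p, freq, freq_hat, ci_lower, ci_upper, label
    Nm_ci: tuple[float, float] = (float("nan"), float("nan"))
    r2_ci: tuple[float, float] = (float("nan"), float("nan"))
    n_boot: int = 0
    seed: int = 0

    @property
    def n_taxa(self) -> int:
        return len(self.per_taxon)

    def labels(self) -> pd.Series:
        return self.per_taxon["label"]


@dataclass
class PersistenceRecord:
    taxon_id: str
    direction: str  # above | below
    seasons_deviating: tuple[str, ...]
    count: int = field(init=False)
    persistent: bool = False

    def __post_init__(self) -> None:
        self.count = len(self.seasons_deviating)


def ncm_predicted_freq(p, Nm: float, d: float):
    """Expected occupancy of a taxon with mean relative abundance ``p``.

    Survival function of Beta(Nm*p, Nm*(1-p)) at the detection limit
    ``d`` (= 1/rarefaction depth). Accepts scalar or array ``p``.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if not 0 < d < 1:
        raise ValueError("detection limit d must be in (0, 1)")
    out = beta_dist.sf(d, Nm * p_arr, Nm * (1.0 - p_arr))
    return float(out) if np.isscalar(p) else out


def _fit_nm_point(
    p: np.ndarray, freq: np.ndarray, d: float, fast: bool = False
) -> float:
    """Least-squares Nm by bounded 1-D search on log(Nm), multistarted.

    ``fast`` uses a single bounded search at looser tolerance (bootstrap
    replicates; the SSE is unimodal in log Nm in practice).
    """

    def sse(log_nm: float) -> float:
        pred = beta_dist.sf(d, np.exp(log_nm) * p, np.exp(log_nm) * (1.0 - p))
        return float(np.sum((freq - pred) ** 2))

    lo, hi = _LOG_NM_BOUNDS
    if fast:
        intervals = [(lo, hi)]
        xatol = 1e-6
    else:
        edges = np.linspace(lo, hi, _N_MULTISTART + 1)
        intervals = list(zip(edges[:-1], edges[1:]))
        xatol = 1e-8
    best = None
    for a, b in intervals:
        try:
            res = minimize_scalar(
                sse, bounds=(a, b), method="bounded", options={"xatol": xatol}
            )
        except Exception:
            continue
        if res is not None and np.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise NCMFitError("Nm optimization failed in every restart")
    return float(np.exp(best.x))


def _r2(freq: np.ndarray, pred: np.ndarray) -> float:
    sse = np.sum((freq - pred) ** 2)
    sst = np.sum((freq - freq.mean()) ** 2)
    if sst == 0:
        return float("nan")  # all occupancies equal: R2 undefined
    return float(1.0 - sse / sst)


def fit_ncm(
    stats: TaxonStats,
    depth: int,
    n_boot: int = 1000,
    seed: int = 0,
) -> NCMFit:
    """Fit the neutral model to one community group.

    Parameters
    ----------
    stats
        Per-taxon mean relative abundance and occupancy (from
        :func:`endopersist.data_model.taxon_stats`).
    depth
        Rarefaction depth; the detection limit is d = 1/depth.
    n_boot
        Taxon-resampling bootstrap replicates for 95% intervals on Nm
        and R^2 (0 disables the bootstrap).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    d = 1.0 / depth
    mask = (stats.p > 0) & (stats.p < 1)
    p = np.asarray(stats.p, dtype=float)[mask]
    freq = np.asarray(stats.freq, dtype=float)[mask]
    ids = [t for t, m in zip(stats.taxon_ids, mask) if m]
    if p.size < 10:
        raise ValueError("need at least 10 taxa with 0 < p < 1 to fit the model")
    S = stats.n_samples

    nm = _fit_nm_point(p, freq, d)
    pred = ncm_predicted_freq(p, nm, d)
    r2 = _r2(freq, pred)

    # 95% Wilson score band around the predicted occupancy at S samples
    lower, upper = proportion_confint(pred * S, S, alpha=0.05, method="wilson")
    label = np.where(freq > upper, "above", np.where(freq < lower, "below", "neutral"))

    per_taxon = pd.DataFrame(
        {
            "p": p,
            "freq": freq,
            "freq_hat": pred,
            "ci_lower": lower,
            "ci_upper": upper,
            "label": label,
        },
        index=pd.Index(ids, name="taxon_id"),
    )

    nm_ci = (float("nan"), float("nan"))
    r2_ci = (float("nan"), float("nan"))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        nms = np.empty(n_boot)
        r2s = np.empty(n_boot)
        n = p.size
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            nb = _fit_nm_point(p[idx], freq[idx], d, fast=True)
            nms[b] = nb
            r2s[b] = _r2(freq[idx], ncm_predicted_freq(p[idx], nb, d))
        nm_ci = tuple(np.percentile(nms, [2.5, 97.5]))
        r2_ci = tuple(np.percentile(r2s[np.isfinite(r2s)], [2.5, 97.5]))

    return NCMFit(nm, r2, d, S, per_taxon, nm_ci, r2_ci, n_boot, seed)


def persistence_across_seasons(
    fits: dict[str, NCMFit],
    min_count: int = 4,
) -> list[PersistenceRecord]:
    """Count per-taxon neutral-model deviations across seasonal fits.

    ``fits`` maps season label -> NCMFit (2-4 seasons). For every taxon
    and direction the set of seasons with that label is recorded; taxa
    missing from a season's fit count as non-deviating there. Records
    with ``count >= min_count`` are flagged persistent.
    """
    seasons = list(fits)
    if len(seasons) != len(set(seasons)):
        raise ValueError("duplicated season labels")
    if not 2 <= len(seasons) <= 4:
        raise ValueError("need 2-4 seasonal fits")
    records: list[PersistenceRecord] = []
    all_taxa: list[str] = []
    seen = set()
    for fit in fits.values():
        for t in fit.per_taxon.index:
            if t not in seen:
                seen.add(t)
                all_taxa.append(t)
    for taxon in all_taxa:
        for direction in ("above", "below"):
            devs = tuple(
                s
                for s in seasons
                if taxon in fits[s].per_taxon.index
                and fits[s].per_taxon.loc[taxon, "label"] == direction
            )
            if devs:
                rec = PersistenceRecord(taxon, direction, devs)
                rec.persistent = rec.count >= min_count
                records.append(rec)
    return records


def persistence_frame(records: list[PersistenceRecord]) -> pd.DataFrame:
    """Long-format table of deviation persistence (taxon, direction, seasons, count)."""
    return pd.DataFrame(
        {
            "taxon_id": [r.taxon_id for r in records],
            "direction": [r.direction for r in records],
            "seasons": [",".join(r.seasons_deviating) for r in records],
            "count": [r.count for r in records],
            "persistent": [r.persistent for r in records],
        }
    )
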