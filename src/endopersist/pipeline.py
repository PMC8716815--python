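"""Configuration-driven orchestration of the full analysis graph.

load -> filter -> rarefy -> (diversity | beta tests | NCM + persistence
| Raup-Crick | networks) -> reports. Every stochastic stage receives a
seed derived deterministically from the global seed and the stage name,
so re-running an identical configuration is bit-identical and adding a
stage never perturbs another stage's stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import beta_composition as beta
from . import cooccurrence_network as net
from . import data_model as dm
from . import diversity as div
from . import neutral_model as ncm
from . import synthetic_data as syn
from .raup_crick import raup_crick as _raup_crick
from .raup_crick import stochastic_fraction as _stochastic_fraction

logger = logging.getLogger("endopersist")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (stage-name hashing, < 2^31)."""
    digest = hashlib.sha256(f"{stage}|{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All pipeline inputs and stage parameters.

    ``counts_path``/``metadata_path`` may be omitted, in which case the
    default synthetic study is generated from the global seed. The
    stage parameter defaults are the analysis constants of the emulated
    study: min_total_count=3 and min_rel_abund=0.001 filtering, 999
    permutations, 1000 bootstrap replicates, |rho| > 0.8 with p < 0.01
    network gates, and edges kept when present in >= 2 seasons.
    """

    counts_path: str | None = None
    metadata_path: str | None = None
    table_format: str | None = None
    outdir: str = "results"
    seed: int = 0
    min_total_count: int = 3
    min_rel_abund: float = 0.001
    depth_policy: str = "min_sample_sum"  # or "fixed"
    depth: int | None = None
    group_columns: tuple[str, ...] = ("site", "tissue")
    season_column: str = "season"
    n_perm: int = 999
    n_boot: int = 1000
    n_reps: int = 999
    rho_threshold: float = 0.8
    p_threshold: float = 0.01
    fdr_bh: bool = False
    min_seasons: int = 2
    rci_threshold: float = 0.95
    hill_orders: tuple[int, ...] = (0, 1, 2)
    n_boot_curve: int = 200
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("group_columns", "hill_orders"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _load_or_generate(config: PipelineConfig) -> dm.AbundanceTable:
    if config.counts_path:
        table = dm.load_table(
            config.counts_path, config.table_format, config.metadata_path
        )
    else:
        design = syn.default_design(
            seed=stage_seed(config.seed, "simulate"), **config.synthetic
        )
        tables, _ = syn.generate_study(design)
        table = syn.concat_tables(tables)
    if table.metadata is None:
        raise dm.TableValidationError("pipeline requires sample metadata")
    for col in (*config.group_columns, config.season_column):
        if col not in table.metadata.columns:
            raise dm.TableValidationError(f"metadata column not found: {col}")
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write outputs under ``config.outdir``.

    Returns the machine-readable summary (also written as
    ``summary.json``) indexing every produced artifact.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "outputs": {}, "stages": {}}

    def emit(name: str, path: Path) -> None:
        summary["outputs"][name] = str(path)

    # ---- load / simulate, filter, rarefy --------------------------------
    table = _load_or_generate(config)
    table = dm.filter_taxa(table, config.min_total_count, config.min_rel_abund)
    if config.depth_policy == "fixed":
        if not config.depth:
            raise ValueError("depth_policy=fixed requires depth")
        depth = int(config.depth)
    else:
        depth = int(table.sample_sums().min())
    table = dm.rarefy(table, depth, stage_seed(config.seed, "rarefy"))
    table = table.drop_empty_taxa()
    summary["stages"]["preprocess"] = {
        "n_taxa": table.shape[0],
        "n_samples": table.shape[1],
        "depth": depth,
    }
    dm.save_table(table, out / "table.tsv")
    dm.save_metadata(table, out / "metadata.tsv")
    emit("table", out / "table.tsv")
    emit("metadata", out / "metadata.tsv")

    meta = table.metadata
    group_keys = sorted(
        {tuple(meta.loc[s, list(config.group_columns)]) for s in meta.index}
    )
    seasons = [s for s in dm.SEASONS if s in set(meta[config.season_column])] or sorted(
        set(meta[config.season_column])
    )

    def slice_table(gkey, season=None):
        crit = dict(zip(config.group_columns, gkey))
        if season is not None:
            crit[config.season_column] = season
        return table.select(**crit)

    # ---- diversity -------------------------------------------------------
    rows = []
    for gkey in group_keys:
        for season in seasons:
            sl = slice_table(gkey, season).drop_empty_taxa()
            inc = sl.counts.to_numpy() > 0
            T = inc.shape[1]
            sizes = list(range(1, 2 * T + 1))
            for q in config.hill_orders:
                for est in div.incidence_re_curve(
                    inc, sizes, q=q,
                    n_boot=config.n_boot_curve,
                    seed=stage_seed(config.seed, f"diversity|{gkey}|{season}|{q}"),
                ):
                    rows.append(
                        {
                            "group": "/".join(gkey),
                            "season": season,
                            "q": q,
                            "size": est.size,
                            "method": est.method,
                            "estimate": est.estimate,
                            "lower": est.lower,
                            "upper": est.upper,
                        }
                    )
    div_frame = pd.DataFrame(rows)
    div_frame.to_csv(out / "diversity.tsv", sep="\t", index=False)
    emit("diversity", out / "diversity.tsv")
    summary["stages"]["diversity"] = {"n_rows": len(div_frame)}

    # ---- beta: distances, ordination, permutation tests ------------------
    beta_results = []
    for gkey in group_keys:
        sl = slice_table(gkey)
        d = beta.bray_curtis(sl)
        pd.DataFrame(d.d, index=d.labels, columns=d.labels).to_csv(
            out / f"braycurtis_{'_'.join(gkey)}.tsv", sep="\t"
        )
        groups = sl.metadata[config.season_column].to_numpy()
        seed_b = stage_seed(config.seed, f"beta|{gkey}")
        res_p = beta.permanova(d, groups, n_perm=config.n_perm, seed=seed_b)
        res_a = beta.anosim(d, groups, n_perm=config.n_perm, seed=seed_b)
        ord_res = beta.nmds(d, seed=seed_b)
        ord_res.coords.to_csv(out / f"nmds_{'_'.join(gkey)}.tsv", sep="\t")
        beta_results.append(
            {
                "group": "/".join(gkey),
                "factor": config.season_column,
                "permanova_F": res_p.statistic,
                "permanova_R2": res_p.r2,
                "permanova_p": res_p.p,
                "anosim_R": res_a.statistic,
                "anosim_p": res_a.p,
                "nmds_stress": ord_res.stress,
                "n_perm": config.n_perm,
                "seed": seed_b,
            }
        )
    (out / "beta_tests.json").write_text(json.dumps(beta_results, indent=2))
    emit("beta_tests", out / "beta_tests.json")
    summary["stages"]["beta"] = beta_results

    # ---- NCM + persistence ----------------------------------------------
    ncm_summaries = {}
    persistence_frames = []
    for gkey in group_keys:
        fits = {}
        for season in seasons:
            sl = slice_table(gkey, season).drop_empty_taxa()
            stats = dm.taxon_stats(sl)
            fits[season] = ncm.fit_ncm(
                stats,
                depth,
                n_boot=config.n_boot,
                seed=stage_seed(config.seed, f"ncm|{gkey}|{season}"),
            )
        gname = "/".join(gkey)
        ncm_summaries[gname] = {
            season: {
                "Nm": fit.Nm,
                "Nm_ci": list(fit.Nm_ci),
                "r2": fit.r2,
                "r2_ci": list(fit.r2_ci),
                "d": fit.d,
                "n_taxa": fit.n_taxa,
            }
            for season, fit in fits.items()
        }
        fits[seasons[0]].per_taxon.to_csv(
            out / f"ncm_per_taxon_{'_'.join(gkey)}_{seasons[0]}.tsv", sep="\t"
        )
        records = ncm.persistence_across_seasons(fits, min_count=len(seasons))
        pframe = ncm.persistence_frame(records)
        pframe.insert(0, "group", gname)
        persistence_frames.append(pframe)
    (out / "ncm.json").write_text(json.dumps(ncm_summaries, indent=2))
    emit("ncm", out / "ncm.json")
    persistence = pd.concat(persistence_frames, ignore_index=True)
    persistence.to_csv(out / "persistence.tsv", sep="\t", index=False)
    emit("persistence", out / "persistence.tsv")
    summary["stages"]["ncm"] = {
        g: {s: v["Nm"] for s, v in d.items()} for g, d in ncm_summaries.items()
    }

    # ---- Raup-Crick ------------------------------------------------------
    rci_summaries = []
    for gkey in group_keys:
        sl = slice_table(gkey).drop_empty_taxa()
        result = _raup_crick(
            sl,
            n_reps=config.n_reps,
            seed=stage_seed(config.seed, f"raupcrick|{gkey}"),
            threshold=config.rci_threshold,
        )
        pd.DataFrame(result.rci, index=result.labels, columns=result.labels).to_csv(
            out / f"rci_{'_'.join(gkey)}.tsv", sep="\t"
        )
        frac = _stochastic_fraction(
            result,
            config.rci_threshold,
            within_group=sl.metadata[config.season_column],
        )
        rci_summaries.append(
            {
                "group": "/".join(gkey),
                "stochastic_fraction_within_season": frac,
                "stochastic_fraction_all_pairs": result.stochastic_fraction,
                "threshold": config.rci_threshold,
                "n_reps": config.n_reps,
            }
        )
    (out / "raupcrick.json").write_text(json.dumps(rci_summaries, indent=2))
    emit("raupcrick", out / "raupcrick.json")
    summary["stages"]["raupcrick"] = rci_summaries

    # ---- networks --------------------------------------------------------
    all_seasonal = {}
    property_rows = []
    for gkey in group_keys:
        seasonal = {}
        for season in seasons:
            sl = slice_table(gkey, season)
            seasonal[season] = net.season_network(
                sl, config.rho_threshold, config.p_threshold,
                fdr_bh=config.fdr_bh,
            )
            all_seasonal[("/".join(gkey), season)] = seasonal[season]
        combined = net.combine_networks(seasonal, min_seasons=config.min_seasons)
        net.combined_frame(combined).to_csv(
            out / f"network_{'_'.join(gkey)}.tsv", sep="\t", index=False
        )
        try:
            import networkx as nx

            nx.write_graphml(
                combined.to_graph(), out / f"network_{'_'.join(gkey)}.graphml"
            )
        except Exception:  # pragma: no cover
            logger.warning("GraphML export failed for %s", gkey)
        props = net.network_properties(combined)
        row = props.to_series()
        row["group"] = "/".join(gkey)
        row["kept"] = combined.kept_ratio[0]
        row["candidates"] = combined.kept_ratio[1]
        property_rows.append(row)
    props_frame = pd.DataFrame(property_rows)
    props_frame.to_csv(out / "network_properties.tsv", sep="\t", index=False)
    emit("network_properties", out / "network_properties.tsv")
    nonempty = {k: v for k, v in all_seasonal.items() if v}
    if len(nonempty) >= 4:
        try:
            ordn = net.ordinate_networks(
                {"/".join(map(str, k)): v for k, v in nonempty.items()},
                seed=stage_seed(config.seed, "network_nmds"),
            )
            ordn.coords.to_csv(out / "network_nmds.tsv", sep="\t")
            emit("network_nmds", out / "network_nmds.tsv")
        except ValueError:
            pass
    summary["stages"]["network"] = {
        "/".join(gkey): int(row["edge_no"])
        for gkey, row in zip(group_keys, property_rows)
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
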