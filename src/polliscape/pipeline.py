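"""End-to-end orchestration: visitation CSVs in, network metrics and models out.

Stage order: build matrix -> d'/strength -> module search -> null ensemble ->
modularity z-score and critical thresholds -> node roles -> reproduction,
land-use, distance and AICc models.  A single run seed feeds a splittable
generator per stage, so toggling one stage does not perturb the random
streams of the others.  Every stage is logged with its timing.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as fm
from .io import (
    IncidenceMatrix,
    PlantRecord,
    RunConfig,
    SiteReproduction,
    ValidationError,
    VisitationTable,
    build_matrix,
    read_plants,
    read_visitation,
    standardize_reproduction,
    write_outputs,
    write_plants,
)
from .modularity import ModulePartition, modularity_zscore, optimize_modules
from .nullmodels import NullDistributions, ThresholdSet, derive_thresholds, null_distributions
from .roles import node_roles, participation_coefficients, within_module_degrees
from .specialization import dprime_all, node_strength
from .synthetic import SyntheticConfig, generate_landscape

logger = logging.getLogger("polliscape")

#: predictors of the pollinator-community candidate set for AICc selection
COMMUNITY_PREDICTORS = (
    "total_visits",
    "richness",
    "hymenoptera_visits",
    "syrphidae_visits",
    "other_diptera_visits",
    "coleoptera_visits",
)


@dataclass
class PipelineResult:
    paths: dict[str, Path]
    run_summary: dict
    matrix: IncidenceMatrix
    partition: ModulePartition
    node_metrics: pd.DataFrame
    thresholds: dict[str, ThresholdSet]
    nulls: NullDistributions
    fits: dict[str, fm.GlmFit] = field(default_factory=dict)
    selection: dict[str, fm.ModelSelectionTable] = field(default_factory=dict)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.2f s", name, dt)
            else:
                logger.error("stage %s: failed after %.2f s (%s)", name, dt, exc)
            return False

    return _Timer()


def community_summaries(table: VisitationTable) -> pd.DataFrame:
    """Per-site pollinator-community summaries used as predictors/responses."""
    df = table.records
    grp = df.groupby("site_id", sort=False)
    out = pd.DataFrame(
        {
            "site_id": list(grp.groups),
            "total_visits": grp["visits"].sum().to_numpy(),
            "richness": grp["species_id"].nunique().to_numpy(),
        }
    )

    def _sel(mask) -> np.ndarray:
        s = df[mask].groupby("site_id")["visits"].sum()
        return np.array([float(s.get(sid, 0.0)) for sid in out["site_id"]])

    fam = df["family_name"].fillna("")
    out["syrphidae_visits"] = _sel(fam == "Syrphidae")
    out["other_diptera_visits"] = _sel((df["order_name"] == "Diptera") & (fam != "Syrphidae"))
    out["hymenoptera_visits"] = _sel(df["order_name"] == "Hymenoptera")
    out["coleoptera_visits"] = _sel(df["order_name"] == "Coleoptera")
    out["lepidoptera_visits"] = _sel(df["order_name"] == "Lepidoptera")
    return out.merge(table.sites, on="site_id")


def run_analysis(
    visitation: str | Path | VisitationTable,
    plants: str | Path | list[PlantRecord] | None = None,
    out_dir: str | Path | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full network-to-function analysis; write artifacts if out_dir."""
    config = config or RunConfig()

    with _stage("read+build"):
        table = visitation if isinstance(visitation, VisitationTable) else read_visitation(visitation)
        matrix = build_matrix(table)
        plant_records: list[PlantRecord] | None
        if plants is None:
            plant_records = None
        elif isinstance(plants, (str, Path)):
            plant_records = read_plants(plants)
        else:
            plant_records = plants

    with _stage("specialization+strength"):
        spec_lower = dprime_all(matrix, "lower", config.dmax_unconstrained)
        spec_higher = dprime_all(matrix, "higher", config.dmax_unconstrained)
        strength_lower = node_strength(matrix, "lower")
        strength_higher = node_strength(matrix, "higher")

    with _stage("modularity"):
        seed_ss = np.random.SeedSequence(entropy=config.random_seed, spawn_key=(0x6D6F,))
        opt_seed = int(seed_ss.generate_state(1)[0] % (2**31))
        partition = optimize_modules(matrix, sa_params=config.sa_params, seed=opt_seed)

    with _stage("null-models"):
        nulls = null_distributions(matrix, config)
        z_mod, significant = modularity_zscore(partition.q, nulls.q_null)

    with _stage("thresholds+roles"):
        thresholds = {
            lv: derive_thresholds(
                nulls.c_null[lv], nulls.z_null[lv], config.threshold_quantile, lv
            )
            for lv in ("lower", "higher")
        }
        roles = node_roles(matrix, partition, thresholds, binary=config.binary_roles)

    node_metrics = _node_metrics_frame(
        matrix, spec_lower + spec_higher, strength_lower + strength_higher, roles
    )

    fits: dict[str, fm.GlmFit] = {}
    selection: dict[str, fm.ModelSelectionTable] = {}
    site_stats = community_summaries(table)
    site_metrics = node_metrics[node_metrics["level"] == "lower"].rename(
        columns={"node_id": "site_id"}
    )
    site_df = site_stats.merge(site_metrics[["site_id", "d_prime", "c"]], on="site_id")

    repro: list[SiteReproduction] = []
    if plant_records is not None:
        with _stage("reproduction-models"):
            repro = standardize_reproduction(plant_records)
            fits.update(
                fm.reproduction_models(
                    site_metrics[["site_id", "c", "d_prime"]],
                    repro,
                    weight_scheme=config.weight_scheme,
                )
            )

    with _stage("landuse-comparisons"):
        responses = {
            "richness": "quasipoisson_log",
            "total_visits": "quasipoisson_log",
            "d_prime": "gaussian_identity",
            "c": "gaussian_identity",
        }
        weights: dict[str, np.ndarray] = {}
        lu_df = site_df
        if repro:
            repro_df = pd.DataFrame([vars(r) for r in repro])
            lu_df = site_df.merge(repro_df, on="site_id", how="inner")
            responses["mean_fert_prop"] = "quasibinomial_logit"
            responses["mean_seeds"] = "quasipoisson_log"
            wf, _ = fm._pick_weights(lu_df["var_fert_prop"].to_numpy(), config.weight_scheme)
            ws, _ = fm._pick_weights(lu_df["var_seeds"].to_numpy(), config.weight_scheme)
            weights = {"mean_fert_prop": wf, "mean_seeds": ws}
        for name, fit in fm.landuse_comparisons(lu_df, responses, weights or None).items():
            fits[f"landuse:{name}"] = fit

    with _stage("distance-similarity"):
        for name, fit in fm.distance_similarity(
            site_df[["site_id", "latitude", "longitude", "c", "d_prime"]]
        ).items():
            fits[f"distance:{name}"] = fit

    with _stage("aicc-selection"):
        predictors = {p: site_df[p].to_numpy(dtype=float) for p in COMMUNITY_PREDICTORS}
        for metric in ("c", "d_prime"):
            selection[f"{metric}~community"] = fm.aicc_selection(
                site_df[metric].to_numpy(dtype=float), predictors
            )

    run_summary = {
        "seed": config.random_seed,
        "n_null": config.n_null,
        "fast_null": config.fast_null,
        "threshold_quantile": config.threshold_quantile,
        "weight_scheme": config.weight_scheme,
        "dmax_unconstrained": config.dmax_unconstrained,
        "binary_roles": config.binary_roles,
        "sa_params": vars(config.sa_params),
        "n_sites": matrix.n_rows,
        "n_species": matrix.n_cols,
        "total_visits": matrix.F,
        "n_links": matrix.n_links,
        "Q": partition.q,
        "z": z_mod,
        "significantly_modular": bool(significant),
        "n_modules": partition.n_modules,
        "optimizer_seed": partition.seed,
        "thresholds": {
            lv: {"c_crit": t.c_crit, "z_crit": t.z_crit, "quantile": t.quantile}
            for lv, t in thresholds.items()
        },
        "role_counts": _role_counts(node_metrics),
        "models": {
            name: {
                "family": f.family,
                "terms": {t: f.coefficients[t] for t in f.terms},
                "dispersion": f.dispersion,
            }
            for name, f in fits.items()
        },
        "aicc_best": {k: v.best for k, v in selection.items()},
    }

    paths: dict[str, Path] = {}
    if out_dir is not None:
        partition_df = pd.DataFrame(
            {
                "node_id": matrix.row_labels + matrix.col_labels,
                "level": ["lower"] * matrix.n_rows + ["higher"] * matrix.n_cols,
                "module_label": np.concatenate(
                    [partition.row_modules, partition.col_modules]
                ),
            }
        )
        paths = write_outputs(
            out_dir,
            node_metrics,
            partition_df,
            _null_summary_frame(nulls, config.threshold_quantile),
            _models_frame(fits, selection),
            run_summary,
        )

    return PipelineResult(
        paths=paths,
        run_summary=run_summary,
        matrix=matrix,
        partition=partition,
        node_metrics=node_metrics,
        thresholds=thresholds,
        nulls=nulls,
        fits=fits,
        selection=selection,
    )


def _node_metrics_frame(matrix, specs, strengths, roles) -> pd.DataFrame:
    spec_by = {(s.level, s.node_id): s for s in specs}
    str_by = {(s.level, s.node_id): s for s in strengths}
    role_by = {(r.level, r.node_id): r for r in roles}
    lu = {}
    if matrix.row_meta is not None:
        lu = dict(zip(matrix.row_meta["site_id"], matrix.row_meta["land_use"]))
    rows = []
    for level, labels in (("lower", matrix.row_labels), ("higher", matrix.col_labels)):
        for lab in labels:
            s = spec_by[(level, lab)]
            r = role_by[(level, lab)]
            rows.append(
                {
                    "node_id": lab,
                    "level": level,
                    "land_use": lu.get(lab, ""),
                    "d_raw": s.d_raw,
                    "d_prime": s.d_prime,
                    "strength": str_by[(level, lab)].strength,
                    "c": r.c,
                    "z_wmd": r.z_wmd,
                    "role": r.role,
                }
            )
    return pd.DataFrame(rows)


def _role_counts(node_metrics: pd.DataFrame) -> dict:
    return {
        lv: node_metrics[node_metrics["level"] == lv]["role"].value_counts().to_dict()
        for lv in ("lower", "higher")
    }


def _null_summary_frame(nulls: NullDistributions, quantile: float) -> pd.DataFrame:
    rows = []
    for k, q in enumerate(nulls.q_null):
        row = {"replicate": k, "Q": float(q)}
        for lv in ("lower", "higher"):
            row[f"c_q{quantile}_{lv}"] = float(
                np.quantile(nulls.c_by_replicate[k][lv], quantile)
            )
            row[f"z_q{quantile}_{lv}"] = float(
                np.quantile(nulls.z_by_replicate[k][lv], quantile)
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _models_frame(fits: dict[str, fm.GlmFit], selection: dict[str, fm.ModelSelectionTable]) -> pd.DataFrame:
    rows = []
    for name, f in fits.items():
        for term in f.terms:
            rows.append(
                {
                    "kind": "glm",
                    "model": name,
                    "response": f.response,
                    "family": f.family,
                    "term": term,
                    "estimate": f.coefficients[term],
                    "se": f.se[term],
                    "t": f.t_values[term],
                    "p": f.p_values[term],
                    "dispersion": f.dispersion,
                    "weight_scheme": f.weights_used,
                    "f_stat": f.f_stat,
                    "f_p": f.f_p,
                    "aicc": np.nan,
                    "delta_aicc": np.nan,
                    "rank": np.nan,
                    "note": "; ".join(f.notes),
                }
            )
    for name, sel in selection.items():
        for _, r in sel.table.iterrows():
            rows.append(
                {
                    "kind": "aicc",
                    "model": name,
                    "response": name.split("~")[0],
                    "family": "gaussian_identity",
                    "term": r["model"],
                    "estimate": np.nan,
                    "se": np.nan,
                    "t": np.nan,
                    "p": np.nan,
                    "dispersion": np.nan,
                    "weight_scheme": "unit",
                    "f_stat": np.nan,
                    "f_p": np.nan,
                    "aicc": r["aicc"],
                    "delta_aicc": r["delta_aicc"],
                    "rank": r["rank"],
                    "note": "intercept_only_best" if sel.best_is_intercept_only else "",
                }
            )
    return pd.DataFrame(rows)


def run_simulation(
    config: SyntheticConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Generate a landscape and write visitation.csv, plants.csv, truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, plants, truth = generate_landscape(config)
    paths = {
        "visitation": table.to_csv(out_dir / "visitation.csv"),
        "plants": write_plants(plants, out_dir / "plants.csv"),
        "truth": truth.to_json(out_dir / "truth.json"),
    }
    logger.info("simulated landscape written to %s", out_dir)
    return paths
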