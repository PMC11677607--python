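"""End-to-end pipeline: validate inputs, run every analysis stage, write CSVs.

Stage order mirrors the analysis workflow:

1. per-site species richness and SES indices (PDI, NRI, NTI; 999 nulls),
2. Hellinger transform of the community table,
3. pairwise bedrock contrasts for SR/NRI/NTI/PDI (Welch t),
4. OLS of richness on elevation,
5. collinearity screen of the climate block (|r| > threshold),
6. range normalization of quantitative predictors,
7. stepwise-AIC Gaussian GLM per response,
8. SAR (spatial lag, k-NN weights) refit of each selected model, with
   Nagelkerke pseudo-R² and residual Moran's I.

Every output CSV starts with a '#'-prefixed metadata block (seed, n_null,
weights scheme, version) sufficient to reproduce it; given the same seed the
outputs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .nulls import ses_table
from .preprocess import drop_collinear, hellinger_transform, range_normalize
from .regression import group_contrasts, ols_r2, stepwise_glm_aic
from .spatial import fit_sar_lag, knn_weights
from .trees import Phylogeny, read_newick

logger = logging.getLogger("phylospat")

__all__ = ["PipelineConfig", "ValidatedBundle", "validate_inputs", "run_pipeline",
           "read_community_csv", "read_table_csv", "write_csv_with_metadata"]

RESPONSES = ("SR", "NRI", "NTI", "PDI")
_CLIMATE_PREFIX = "BIO"


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; flags mirror the CLI options."""

    tree_path: str | Path
    community_path: str | Path
    environment_path: str | Path
    coordinates_path: str | Path
    output_dir: str | Path = "results"
    n_null: int = 999
    seed: int = 0
    collinearity_threshold: float = 0.95
    weights_k: int = 4
    sar_variant: str = "lag"                # 'lag' or 'error'
    pseudo_r2_variant: str = "nagelkerke"   # 'nagelkerke' or 'corr'
    drop_missing: bool = False              # drop community species absent from the tree
    climate_columns: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_null < 99:
            raise ValueError("n_null must be >= 99")
        if not 0 < self.collinearity_threshold <= 1:
            raise ValueError("collinearity threshold must be in (0, 1]")
        if self.sar_variant not in ("lag", "error"):
            raise ValueError("sar_variant must be 'lag' or 'error'")


@dataclass
class ValidatedBundle:
    tree: Phylogeny
    community: pd.DataFrame
    env: pd.DataFrame
    coords: pd.DataFrame
    dropped_species: list[str] = field(default_factory=list)


def read_community_csv(path) -> pd.DataFrame:
    """Site x species table: first column site_id, remaining columns species."""
    df = pd.read_csv(path, comment="#")
    df = df.set_index(df.columns[0])
    df.index.name = "site_id"
    return df.astype(float)


def read_table_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    return df.set_index(df.columns[0])


def write_csv_with_metadata(df: pd.DataFrame, path, meta: dict, index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=index)


def validate_inputs(config: PipelineConfig) -> ValidatedBundle:
    """Load and cross-reference the tree, community, environment and coordinates.

    Community species must be a subset of the tree tips unless
    ``drop_missing`` is set (then offenders are dropped and logged).  Site
    ids must align across the three site-level tables.
    """
    for p in (config.tree_path, config.community_path, config.environment_path,
              config.coordinates_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    tree = read_newick(config.tree_path)
    community = read_community_csv(config.community_path)
    env = read_table_csv(config.environment_path)
    coords = read_table_csv(config.coordinates_path)

    tips = set(tree.tip_labels)
    missing = [s for s in community.columns if s not in tips]
    dropped: list[str] = []
    if missing:
        if not config.drop_missing:
            raise ValueError(
                f"{len(missing)} community species absent from the tree: {sorted(missing)}; "
                "pass drop_missing=True (--drop-missing) to drop them")
        logger.warning("dropping %d species absent from tree: %s", len(missing), sorted(missing))
        community = community.drop(columns=missing)
        dropped = sorted(missing)

    sites = list(community.index)
    for name, table in (("environment", env), ("coordinates", coords)):
        if set(table.index) != set(sites):
            extra = sorted(set(table.index) ^ set(sites))
            raise ValueError(f"site ids in {name} table do not match community table: {extra}")
    env = env.loc[sites]
    coords = coords.loc[sites]

    richness = (community.to_numpy() > 0).sum(axis=1)
    if (richness < 2).any():
        low = list(np.asarray(sites)[richness < 2])
        raise ValueError(f"sites with richness < 2 cannot be analyzed: {low}")
    return ValidatedBundle(tree=tree, community=community, env=env, coords=coords,
                           dropped_species=dropped)


def _climate_cols(env: pd.DataFrame, config: PipelineConfig) -> list[str]:
    if config.climate_columns:
        return [c for c in config.climate_columns if c in env.columns]
    return [c for c in env.columns if c.upper().startswith(_CLIMATE_PREFIX)]


def run_pipeline(config: PipelineConfig, bundle: ValidatedBundle | None = None) -> dict:
    """Run every stage and write the result CSVs; returns the in-memory bundle."""
    bundle = bundle or validate_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "phylospat_version": __version__,
        "seed": config.seed,
        "n_null": config.n_null,
        "null_model": "taxa_label",
        "weights_scheme": f"knn(k={config.weights_k}, row_standardized)",
        "sar_variant": config.sar_variant,
        "pseudo_r2": config.pseudo_r2_variant,
        "collinearity_threshold": config.collinearity_threshold,
    }
    results: dict = {"config": config, "bundle": bundle}

    logger.info("stage 1/8: SES indices (%d sites, n_null=%d)", len(bundle.community), config.n_null)
    ses = ses_table(bundle.tree, bundle.community, n_null=config.n_null, seed=config.seed)
    results["ses"] = ses
    write_csv_with_metadata(ses, outdir / "ses_indices.csv", meta, index=False)

    richness = pd.Series((bundle.community.to_numpy() > 0).sum(axis=1),
                         index=bundle.community.index, name="SR")
    site = pd.DataFrame({"SR": richness})
    for metric in ("NRI", "NTI", "PDI"):
        sub = ses[ses.metric == metric].set_index("site_id")["ses"]
        site[metric] = sub.reindex(site.index)
    results["site_metrics"] = site
    write_csv_with_metadata(site, outdir / "site_metrics.csv", meta)

    logger.info("stage 2/8: Hellinger transform")
    hel = hellinger_transform(bundle.community)
    results["hellinger"] = hel
    write_csv_with_metadata(hel, outdir / "community_hellinger.csv", meta)

    logger.info("stage 3/8: bedrock contrasts")
    contrasts = []
    for resp in RESPONSES:
        tab = group_contrasts(site[resp], bundle.env["bedrock"].astype(str))
        tab.insert(0, "response", resp)
        contrasts.append(tab)
    contrasts = pd.concat(contrasts, ignore_index=True)
    results["contrasts"] = contrasts
    write_csv_with_metadata(contrasts, outdir / "bedrock_contrasts.csv", meta, index=False)

    logger.info("stage 4/8: elevation OLS")
    elev_rows = []
    for resp in RESPONSES:
        ok = site[resp].notna()
        fit = ols_r2(site.loc[ok, resp], bundle.env.loc[ok, "elevation"],
                     response=resp, covariate="elevation")
        elev_rows.append({"response": resp, "slope": fit.params["elevation"],
                          "intercept": fit.params["intercept"], "r2": fit.r2,
                          "p_slope": fit.pvalues["elevation"], "n": fit.n})
    elev = pd.DataFrame(elev_rows)
    results["elevation_ols"] = elev
    write_csv_with_metadata(elev, outdir / "elevation_ols.csv", meta, index=False)

    logger.info("stage 5/8: collinearity screen")
    climate_cols = _climate_cols(bundle.env, config)
    retained, decisions = drop_collinear(bundle.env[climate_cols],
                                         threshold=config.collinearity_threshold)
    dec = pd.DataFrame([{"dropped": d.dropped, "against": d.against, "r": d.r}
                        for d in decisions]) if decisions else pd.DataFrame(
        columns=["dropped", "against", "r"])
    results["climate_retained"] = retained
    results["collinearity_log"] = dec
    write_csv_with_metadata(dec, outdir / "collinearity_log.csv", meta, index=False)

    logger.info("stage 6/8: range normalization")
    predictors = pd.DataFrame(index=bundle.env.index)
    for col in ["elevation", "slope", "aspect", *retained.columns]:
        predictors[col] = range_normalize(bundle.env[col].astype(float))
    predictors["bedrock"] = bundle.env["bedrock"].astype(str)
    results["predictors"] = predictors

    logger.info("stage 7/8: stepwise GLM (AIC)")
    w = knn_weights(bundle.coords, k=config.weights_k)
    glm_rows, sar_rows = [], []
    results["glm_fits"], results["sar_fits"] = {}, {}
    for resp in RESPONSES:
        ok = site[resp].notna()
        yv = site.loc[ok, resp].astype(float)
        Xv = predictors.loc[ok]
        fit = stepwise_glm_aic(yv, Xv, response=resp, categorical=("bedrock",),
                               reference={"bedrock": "granite"})
        results["glm_fits"][resp] = fit
        gtab = fit.summary_frame()
        gtab.insert(0, "response", resp)
        gtab["aic"] = fit.aic
        gtab["r2"] = fit.r2
        glm_rows.append(gtab)

        sel_cols = [c for c in fit.terms if c != "bedrock"]
        Xsar = Xv[sel_cols].copy()
        if "bedrock" in fit.terms:
            levels = ["granite"] + [l for l in pd.unique(Xv["bedrock"]) if l != "granite"]
            dm = pd.get_dummies(pd.Categorical(Xv["bedrock"], categories=levels),
                                prefix="bedrock", dtype=float).iloc[:, 1:]
            dm.index = Xv.index
            Xsar = pd.concat([Xsar, dm], axis=1)
        # undefined SES rows propagate as missing: SAR runs on complete cases,
        # with neighbour weights rebuilt on the retained sites
        w_resp = w if ok.all() else knn_weights(bundle.coords.loc[ok], k=config.weights_k)
        sfit = fit_sar_lag(yv, Xsar, w_resp, model=config.sar_variant,
                           pseudo_r2_variant=config.pseudo_r2_variant)
        results["sar_fits"][resp] = sfit
        stab = sfit.summary_frame()
        stab.insert(0, "response", resp)
        stab["rho"] = sfit.rho
        stab["aic"] = sfit.aic
        stab["pseudo_r2"] = sfit.pseudo_r2
        stab["resid_moran_I"] = sfit.resid_moran.I if sfit.resid_moran else np.nan
        stab["resid_moran_p"] = sfit.resid_moran.p_value if sfit.resid_moran else np.nan
        sar_rows.append(stab)

    glm_table = pd.concat(glm_rows, ignore_index=True)
    sar_table = pd.concat(sar_rows, ignore_index=True)
    results["glm_table"], results["sar_table"] = glm_table, sar_table
    write_csv_with_metadata(glm_table, outdir / "stepwise_glm.csv", meta, index=False)
    write_csv_with_metadata(sar_table, outdir / "sar_models.csv", meta, index=False)

    logger.info("stage 8/8: spatial weights export")
    write_csv_with_metadata(w.to_triplets(), outdir / "spatial_weights.csv", meta, index=False)
    results["weights"] = w
    return results
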