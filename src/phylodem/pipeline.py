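"""End-to-end comparative-demography pipeline.

select -> annualize -> grand-mean -> per-species traits and summaries ->
body-mass-corrected PGLS residuals -> phylogenetic ANOVA with post hoc
letters per demographic variable -> collinearity pruning, missingness
screening and iterative-PCA imputation -> phylogenetic PCA with Kaiser
retention and per-axis post hoc letters.

Univariate tests use only the species observed for each variable (tree
pruned per variable); imputation feeds the multivariate ordination alone.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .impute import iterative_pca_impute, missingness_screen
from .io import read_bundle, write_trait_table
from .life_history import TRAIT_NAMES, compute_all_traits
from .mpm import grand_mean, rescale_to_annual, select_mpms
from .perturbation import SUMMARY_FIELDS, summarize
from .phylo import pgls_residuals, phylo_anova, bonferroni_adjust, ppca, prune_tree, spearman_prune
from .synthetic import SOCIALITY_LEVELS, SpeciesRecord, SyntheticStudy

#: Table-1-style blocks: analysis variables grouped into the five families
BLOCKS: dict[str, list[str]] = {
    "life history traits": list(TRAIT_NAMES),
    "vital rates": ["sigma_bar", "gamma_bar", "rho_bar", "phi_bar"],
    "elasticities": ["E_sigma", "E_gamma", "E_rho", "E_phi"],
    "asymptotics": ["lam", "deviance"],
    "transients": ["zeta", "Pi", "reactivity", "attenuation"],
}

#: traits measured in time units, candidates for the ordination
TIME_TRAITS = ["T", "eta_e", "var_eta_e", "L_max", "L_alpha", "L_alpha_omega"]


@dataclass
class PipelineConfig:
    seed: int
    bundle_path: str | Path | None = None
    output_dir: str | Path = "pipeline_out"
    nsim: int = 1000
    bonferroni: bool = True
    spearman_threshold: float = 0.70
    missingness_cap: float = 0.40
    ncomp: int = 2
    n_imputation_sets: int = 20
    min_species_per_trait: int = 10

    def __post_init__(self):
        if not 0 < self.spearman_threshold <= 1:
            raise ValueError("spearman_threshold must lie in (0, 1]")
        if not 0 < self.missingness_cap <= 1:
            raise ValueError("missingness_cap must lie in (0, 1]")
        if self.nsim < 100:
            raise ValueError("nsim must be at least 100")


def species_tables(records: list[SpeciesRecord]):
    """Grand-mean annual MPM per species, plus trait and summary tables.

    Records sharing a species are annualized and averaged element by
    element; life-history traits are computed for every species, while
    asymptotic/elasticity/transient summaries respect the ergodicity gate
    (failures carry NaNs and a ``gate_reason``).
    """
    by_species: dict[str, list] = {}
    meta: dict[str, SpeciesRecord] = {}
    for rec in records:
        by_species.setdefault(rec.species_id, []).append(
            rescale_to_annual(rec.mpm)
        )
        meta[rec.species_id] = rec
    traits, summaries = {}, {}
    for sp, mpms in by_species.items():
        m = grand_mean(mpms)
        traits[sp] = compute_all_traits(m).as_dict()
        summaries[sp] = summarize(m).as_dict()
    trait_df = pd.DataFrame.from_dict(traits, orient="index")[list(TRAIT_NAMES)]
    summary_df = pd.DataFrame.from_dict(summaries, orient="index")
    extra = pd.DataFrame(
        {
            "sociality": {s: meta[s].sociality for s in by_species},
            "log_body_mass": {s: meta[s].log_body_mass for s in by_species},
        }
    )
    return trait_df, summary_df, extra


def run_pipeline(
    config: PipelineConfig, study: SyntheticStudy | None = None
) -> dict:
    """Run the full pipeline and write the result bundle to
    ``config.output_dir``.

    Input is either a matrix bundle on disk (``config.bundle_path``) or an
    in-memory :class:`~phylodem.synthetic.SyntheticStudy`.  Returns a dict
    with the main tables; the same content goes to CSV/JSON files.  All
    randomness derives from ``config.seed``.
    """
    if study is not None:
        records, tree = study.records, study.tree
    elif config.bundle_path is not None:
        records, tree = read_bundle(config.bundle_path)
    else:
        raise ValueError("either a bundle path or a study is required")
    if tree is None:
        raise ValueError("a phylogeny is required")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    retained, rejection_log = select_mpms(records)
    trait_df, summary_df, extra = species_tables(retained)
    if study is not None and study.trait_table is not None:
        # the study's own trait table (e.g. with observational gaps)
        trait_df = study.trait_table.loc[trait_df.index, list(TRAIT_NAMES)]

    tree_tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    common = [s for s in trait_df.index if s in tree_tips]
    dropped_species = sorted(set(trait_df.index) - set(common))
    trait_df = trait_df.loc[common]
    summary_df = summary_df.loc[common]
    extra = extra.loc[common]
    tree = prune_tree(tree, common)

    data = pd.concat([trait_df, summary_df.drop(columns="gate_reason")], axis=1)
    data = data.replace([np.inf, -np.inf], np.nan)
    sociality = extra["sociality"].map(lambda k: SOCIALITY_LEVELS[int(k)])
    log_mass = extra["log_body_mass"]

    ss = np.random.SeedSequence(config.seed)
    all_vars = [v for block in BLOCKS.values() for v in block]
    child_seeds = {
        v: int(c.generate_state(1)[0] % (2**31))
        for v, c in zip(all_vars + ["ppca"], ss.spawn(len(all_vars) + 1))
    }

    rows, letters_rows = [], []
    for block, variables in BLOCKS.items():
        for var in variables:
            y = data[var].dropna()
            if len(y) < config.min_species_per_trait or y.nunique() < 3:
                continue
            resid, fit = pgls_residuals(y, log_mass[y.index], tree, ci=True)
            res = phylo_anova(
                resid,
                sociality[resid.index],
                tree,
                nsim=config.nsim,
                seed=child_seeds[var],
            )
            rows.append(
                {
                    "block": block,
                    "variable": var,
                    "n": len(y),
                    "R2": res.r_squared,
                    "F": res.F_obs,
                    "df1": res.df[0],
                    "df2": res.df[1],
                    "p": res.p_phylo,
                    "pagel_lambda": fit.lambda_hat,
                    "lambda_ci_lo": fit.lambda_ci[0],
                    "lambda_ci_hi": fit.lambda_ci[1],
                }
            )
            for lvl, letter in res.letters.items():
                letters_rows.append(
                    {
                        "variable": var,
                        "sociality": lvl,
                        "letters": letter,
                        "group_mean_residual": res.group_means.get(lvl, np.nan),
                    }
                )
    table1 = pd.DataFrame(rows)
    if config.bonferroni and len(table1):
        table1["p_bonferroni"] = bonferroni_adjust(table1["p"].to_numpy())
    letters = pd.DataFrame(letters_rows)

    # ---- multivariate: prune -> screen -> log -> residuals -> impute -> pPCA
    time_traits = trait_df[TIME_TRAITS]
    kept, dropped_pairs = spearman_prune(
        time_traits, threshold=config.spearman_threshold
    )
    kept = missingness_screen(time_traits[kept], config.missingness_cap)
    resid_cols = {}
    for var in kept:
        y = np.log(trait_df[var].where(trait_df[var] > 0)).dropna()
        if len(y) < config.min_species_per_trait:
            continue
        r, _ = pgls_residuals(y, log_mass[y.index], tree, ci=False)
        resid_cols[var] = r
    resid_df = pd.DataFrame(resid_cols).reindex(trait_df.index)
    resid_df = (resid_df - resid_df.mean()) / resid_df.std(ddof=1)

    # auxiliary complete columns lend covariation strength to the imputation
    aux = pd.concat([data[[c for c in SUMMARY_FIELDS]], log_mass], axis=1)
    aux = aux.loc[:, aux.notna().all()]
    aux = (aux - aux.mean()) / aux.std(ddof=1).replace(0.0, 1.0)
    imp_input = pd.concat([resid_df, aux], axis=1)
    imp_input = imp_input[imp_input[resid_df.columns].notna().any(axis=1)]
    imp = iterative_pca_impute(
        imp_input,
        ncomp=config.ncomp,
        seed=child_seeds["ppca"],
        n_sets=config.n_imputation_sets,
    )
    completed = imp.completed[resid_df.columns]

    ppca_res = ppca(completed, tree)
    score_sd = None
    if len(imp.imputation_sets) > 1:
        stacked = []
        for s in imp.imputation_sets:
            stacked.append(ppca(s[resid_df.columns], tree).scores.abs())
        score_sd = (
            pd.concat(stacked).groupby(level=0).std(ddof=1).mean().to_dict()
        )

    ppca_letters_rows = []
    for ax in range(ppca_res.retained_axes):
        col = f"PC{ax + 1}"
        res = phylo_anova(
            ppca_res.scores[col],
            sociality[ppca_res.scores.index],
            tree,
            nsim=config.nsim,
            seed=child_seeds["ppca"] + ax + 1,
        )
        for lvl, letter in res.letters.items():
            ppca_letters_rows.append(
                {
                    "axis": col,
                    "sociality": lvl,
                    "letters": letter,
                    "p_axis": res.p_phylo,
                    "group_mean_score": res.group_means.get(lvl, np.nan),
                }
            )
    ppca_letters = pd.DataFrame(ppca_letters_rows)

    # ---- outputs
    write_trait_table(trait_df, outdir / "species_traits.csv")
    summary_df.to_csv(outdir / "species_summaries.csv", index_label="species_id")
    table1.to_csv(outdir / "table1.csv", index=False)
    letters.to_csv(outdir / "posthoc_letters.csv", index=False)
    ppca_res.loadings.to_csv(outdir / "ppca_loadings.csv")
    ppca_res.scores.to_csv(outdir / "ppca_scores.csv", index_label="species_id")
    axes_df = pd.DataFrame(
        {
            "axis": [f"PC{i + 1}" for i in range(len(ppca_res.eigenvalues))],
            "eigenvalue": ppca_res.eigenvalues,
            "pct_variance": ppca_res.pct_variance,
        }
    )
    axes_df.to_csv(outdir / "ppca_axes.csv", index=False)
    ppca_letters.to_csv(outdir / "ppca_letters.csv", index=False)

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "nsim": config.nsim,
        "n_records_in": len(records),
        "n_retained": len(retained),
        "rejections": [list(t) for t in rejection_log],
        "n_species": len(common),
        "species_dropped_from_tree": dropped_species,
        "gate_failures": summary_df["gate_reason"].dropna().to_dict(),
        "spearman_dropped": [list(t) for t in dropped_pairs],
        "ppca_traits": list(resid_df.columns),
        "ppca_lambda": ppca_res.lambda_hat,
        "ppca_retained_axes": ppca_res.retained_axes,
        "imputation": {
            "iterations": imp.n_iterations,
            "converged": imp.converged,
            "n_sets": len(imp.imputation_sets),
            "between_set_score_sd": score_sd,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {
        "table1": table1,
        "letters": letters,
        "ppca": ppca_res,
        "ppca_letters": ppca_letters,
        "traits": trait_df,
        "summaries": summary_df,
        "manifest": manifest,
    }


def report_table1(table1: pd.DataFrame) -> pd.DataFrame:
    """Order the per-variable statistics into the five standard blocks
    (life history traits, vital rates, elasticities, asymptotics,
    transients), warning about empty blocks."""
    import warnings

    out = []
    for block, variables in BLOCKS.items():
        sub = table1[table1["block"] == block]
        if sub.empty:
            warnings.warn(f"block {block!r} has no computed variables")
            continue
        order = {v: i for i, v in enumerate(variables)}
        out.append(sub.sort_values("variable", key=lambda s: s.map(order)))
    return pd.concat(out, ignore_index=True) if out else table1.iloc[0:0]
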