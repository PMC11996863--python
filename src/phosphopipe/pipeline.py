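"""End-to-end orchestration of the analysis stages.

The canonical order: log2 transform -> class-I filter -> KNN-TN imputation
-> median normalization -> surrogate-variable estimation -> moderated
differential statistics -> signaling classification and sex-dimorphism
calls -> F-test-selected hierarchical clustering with variable-height
cutting -> per-cluster over-representation analysis -> kinome enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify as _classify
from . import diffstats, kinome, ora, patterns, preprocess
from .io import GeneSetCollection, PhosphoSiteTable, PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class PreprocessResult:
    table: PhosphoSiteTable  # class-I filtered, log2, imputed, normalized
    matrix: pd.DataFrame
    sv: preprocess.SurrogateVariable
    shifts: pd.Series
    pca: pd.DataFrame
    adjusted_matrix: pd.DataFrame  # SV-subtracted, for clustering/heatmaps


def preprocess_table(
    table: PhosphoSiteTable,
    design: pd.DataFrame,
    config: PipelineConfig,
) -> PreprocessResult:
    """Raw intensities to the analysis-ready log2 matrix plus SV and PCA QC."""
    table = preprocess.log2_transform(table)
    table = preprocess.filter_class1(table, config.loc_prob_min)
    logger.info("class-I filter retained %d sites", table.n_sites)
    imputed = preprocess.impute_knn_tn(
        table.intensities, k=config.knn_k, min_shared=config.knn_min_shared
    )
    matrix, shifts = preprocess.median_normalize(imputed)
    X = diffstats.build_design_matrix(design, ["treatment", "phenotype", "sex"])
    # full-interaction group coding for the residualization
    X["treatment:phenotype"] = X["treatment"] * X["phenotype"]
    sv = preprocess.estimate_surrogate_variable(matrix, X)
    adjusted = preprocess.adjust_matrix_for_sv(matrix, X, sv)
    pca = preprocess.pca_qc(adjusted)
    table = table.with_intensities(matrix)
    return PreprocessResult(
        table=table, matrix=matrix, sv=sv, shifts=shifts, pca=pca,
        adjusted_matrix=adjusted,
    )


def differential(
    matrix: pd.DataFrame, design: pd.DataFrame, sv: preprocess.SurrogateVariable
) -> pd.DataFrame:
    """Long differential table over all canonical contrasts."""
    return diffstats.run_contrasts(matrix, design, sv.model_scores)


def classification(
    diff_results: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Signaling classes, strict emergent flags and sex dominance per site."""
    cls = _classify.classify_sites(
        diff_results,
        stim_p=config.stim_p,
        stim_fold=config.stim_fold,
        interaction_p=config.interaction_p,
    )
    cls["sex_dominance"] = _classify.call_sex_dimorphism(
        diff_results, config.sex_fdr
    ).reindex(cls.index)
    return cls


def group_f_test(
    matrix: pd.DataFrame, design: pd.DataFrame, sv: preprocess.SurrogateVariable
) -> pd.DataFrame:
    """Moderated F over the treatment/phenotype group structure, used to
    select sites for pattern clustering."""
    X = diffstats.build_design_matrix(design, ["treatment", "phenotype"], sv.scores)
    X.insert(3, "treatment:phenotype", X["treatment"] * X["phenotype"])
    fit = diffstats.fit_linear_model(matrix, X)
    params = diffstats.fit_moderation(fit.s2.to_numpy(), fit.df)
    contrasts = np.zeros((3, X.shape[1]))
    for i, name in enumerate(["treatment", "phenotype", "treatment:phenotype"]):
        contrasts[i, list(X.columns).index(name)] = 1.0
    return diffstats.moderated_f(fit, params, contrasts)


def cluster_patterns(
    pre: PreprocessResult,
    design: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.Series, pd.DataFrame]:
    """Variable-height clusters of F-significant sites on the SV-adjusted,
    z-scored matrix.  Returns (labels, F-test table)."""
    ftab = group_f_test(pre.matrix, design, pre.sv)
    selected = ftab.index[ftab["fdr"] < config.cluster_fdr]
    logger.info("%d sites at F-test FDR < %g", len(selected), config.cluster_fdr)
    if len(selected) < 2:
        return pd.Series(dtype=int, name="cluster"), ftab
    z = patterns.zscore_rows(pre.adjusted_matrix.loc[selected])
    dend = patterns.hcluster(z, linkage=config.linkage)
    labels = patterns.cut_variable_height(
        dend, min_size=config.min_cluster_size, split_fraction=config.split_fraction
    )
    return labels, ftab


def cluster_ora(
    labels: pd.Series,
    table: PhosphoSiteTable,
    gene_sets: GeneSetCollection,
) -> pd.DataFrame:
    """ORA of every cluster against the gene sets; universe = genes of the
    analyzed site table."""
    universe = ora.map_sites_to_genes(table.site_ids)
    pieces = []
    for cid in sorted(labels.unique()):
        query = ora.map_sites_to_genes(labels.index[labels == cid])
        res = ora.ora_test(query, gene_sets, universe)
        res.insert(0, "cluster", cid)
        pieces.append(res)
    if not pieces:
        return pd.DataFrame()
    return pd.concat(pieces, ignore_index=True)


@dataclass
class KinomeResult:
    predictions: pd.DataFrame  # boolean sites x kinases
    percentiles: pd.DataFrame
    basal: pd.DataFrame  # enrichment, basal CTL-vs-T2D regulated sets
    treated: pd.DataFrame  # enrichment, insulin-state CTL-vs-T2D


def kinome_stage(
    table: PhosphoSiteTable,
    diff_results: pd.DataFrame,
    atlas: kinome.KinaseAtlas,
    config: PipelineConfig,
) -> KinomeResult:
    """Score S/T sites, predict top-k kinases, and test per-kinase motif
    enrichment among regulated vs unregulated sites for the basal and
    insulin-state phenotype comparisons."""
    windows = table.meta["window"]
    raw, pct = kinome.score_all_sites(windows, atlas)
    predictions = kinome.predict_all(raw, pct, top_k=config.top_k)

    out = {}
    for name, contrast, cut in (
        ("basal", "t2d_vs_ctl_basal", config.kinome_regulated_fdr_basal),
        ("treated", "t2d_vs_ctl_ins", config.kinome_regulated_fdr_treated),
    ):
        diff = diffstats.contrast_frame(diff_results, contrast)
        diff = diff.loc[diff.index.intersection(predictions.index)]
        up, down, unreg = kinome.define_regulated_sets(diff, cut)
        out[name] = kinome.kinome_enrichment(
            predictions, up, down, unreg, display_adjp=config.kinome_display_adjp
        )
    return KinomeResult(
        predictions=predictions, percentiles=pct, basal=out["basal"],
        treated=out["treated"],
    )
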