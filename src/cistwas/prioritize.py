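"""Gene filtering, multiple testing, rank-product scoring and the drivers.

A gene enters association testing only if its cis variance component is
significant at a Bonferroni threshold.  For each response (an agronomic
trait, or a target gene's expression treated as an e-trait) the cis-EC and
trans-EC of every tested gene are associated separately under kinship
correction; each gene is then scored by the geometric mean of its two
p-value ranks (rank_product), so strong dual-evidence candidates sort to
the top.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .assoc import dual_association, fit_null
from .io import ExpressionMatrix, KinshipMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "RESULT_COLUMNS",
    "bonferroni_threshold",
    "filter_heritable_genes",
    "compute_qvalues",
    "rank_product",
    "run_twas",
    "run_etwas",
    "stringent_candidate_filter",
    "edge_list",
]

RESULT_COLUMNS = [
    "Gene", "chr", "start", "end", "strand", "cis_Vg", "cis_p",
    "beta_cis", "se_cis", "zscore_cis", "p-value_cis", "q-value_cis",
    "beta_trans", "se_trans", "zscore_trans", "p-value_trans", "q-value_trans",
    "cis_rank", "trans_rank", "rank_product", "Note",
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test p-value threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def filter_heritable_genes(vc: pd.DataFrame, p_threshold: float) -> list[str]:
    """Gene ids with significant cis variance: cis_p strictly below threshold."""
    keep = vc.index[vc["cis_p"] < p_threshold].tolist()
    logger.info("heritability filter: %d of %d genes kept at p < %g",
                len(keep), len(vc), p_threshold)
    if not keep:
        logger.warning("no genes pass the cis-heritability filter at p < %g", p_threshold)
    return keep


def compute_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def rank_product(p_cis: np.ndarray, p_trans: np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene ranks of the two p-value vectors and their geometric mean.

    Ranks are ascending with average ranks on ties;
    rank_product = sqrt(cis_rank * trans_rank).
    """
    p_cis = np.asarray(p_cis, dtype=float)
    p_trans = np.asarray(p_trans, dtype=float)
    if p_cis.shape != p_trans.shape:
        raise ValueError("p-value vectors are not aligned")
    cis_rank = rankdata(p_cis, method="average")
    trans_rank = rankdata(p_trans, method="average")
    return cis_rank, trans_rank, np.sqrt(cis_rank * trans_rank)


def _associate_genes(response: np.ndarray, K: KinshipMatrix, genes: list[str],
                     cis: pd.DataFrame, trans: pd.DataFrame, vc: pd.DataFrame,
                     annotation: pd.DataFrame, trait_name: str) -> pd.DataFrame:
    """Dual association of every gene with one response; returns a result table."""
    null = fit_null(response, K, trait_name=trait_name)
    ids = null.individual_ids
    cis_m = cis.loc[genes, ids].to_numpy(dtype=float)
    trans_m = trans.loc[genes, ids].to_numpy(dtype=float)
    rows = []
    for i, g in enumerate(genes):
        a_cis, a_trans = dual_association(null, cis_m[i], trans_m[i])
        rows.append((a_cis.beta, a_cis.se, a_cis.zscore, a_cis.p,
                     a_trans.beta, a_trans.se, a_trans.zscore, a_trans.p))
    stats_df = pd.DataFrame(rows, index=genes, columns=[
        "beta_cis", "se_cis", "zscore_cis", "p-value_cis",
        "beta_trans", "se_trans", "zscore_trans", "p-value_trans"])
    stats_df["q-value_cis"] = compute_qvalues(stats_df["p-value_cis"].to_numpy())
    stats_df["q-value_trans"] = compute_qvalues(stats_df["p-value_trans"].to_numpy())
    cr, tr, rp = rank_product(stats_df["p-value_cis"].to_numpy(),
                              stats_df["p-value_trans"].to_numpy())
    stats_df["cis_rank"] = cr
    stats_df["trans_rank"] = tr
    stats_df["rank_product"] = rp

    ann = annotation.set_index("Gene").loc[genes]
    out = pd.DataFrame({
        "Gene": genes,
        "chr": ann["chr"].to_numpy(),
        "start": ann["start"].to_numpy(),
        "end": ann["end"].to_numpy(),
        "strand": ann["strand"].to_numpy(),
        "cis_Vg": vc.loc[genes, "cis_Vg"].to_numpy(),
        "cis_p": vc.loc[genes, "cis_p"].to_numpy(),
        "Note": ann["Note"].to_numpy(),
    })
    for c in stats_df.columns:
        out[c] = stats_df[c].to_numpy()
    out = out[RESULT_COLUMNS]
    # reproducible ordering: rank_product, then trans p-value, then gene id
    out = out.sort_values(["rank_product", "p-value_trans", "Gene"],
                          kind="mergesort").reset_index(drop=True)
    return out


def run_twas(vc: pd.DataFrame, cis: pd.DataFrame, trans: pd.DataFrame,
             K: KinshipMatrix, phenotypes: PhenotypeTable, annotation: pd.DataFrame,
             p_threshold: float, out_dir: str | Path | None = None,
             min_n: int = 30) -> dict[str, pd.DataFrame]:
    """Dual-evidence TWAS of every heritable gene against each trait.

    Per trait: heritability filter -> null model on the trait -> cis/trans
    association per gene -> BH q-values per component -> rank product.
    Traits with fewer than ``min_n`` non-missing individuals are skipped.
    Writes one ``<trait>.csv`` per trait when ``out_dir`` is given.
    """
    genes = filter_heritable_genes(vc, p_threshold)
    results: dict[str, pd.DataFrame] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for trait in phenotypes.trait_names:
        y = phenotypes.data[trait]
        keep = y.notna()
        if int(keep.sum()) < min_n:
            logger.warning("trait %s has %d non-missing individuals (< %d); skipped",
                           trait, int(keep.sum()), min_n)
            continue
        ids = [s for s in phenotypes.individual_ids if keep.loc[s]]
        if not genes:
            results[trait] = pd.DataFrame(columns=RESULT_COLUMNS)
        else:
            results[trait] = _associate_genes(
                y.loc[ids].to_numpy(dtype=float), K.subset_individuals(ids),
                genes, cis, trans, vc, annotation, trait)
        if out is not None:
            results[trait].to_csv(out / f"{trait}.csv", index=False)
    return results


def run_etwas(vc: pd.DataFrame, cis: pd.DataFrame, trans: pd.DataFrame,
              K: KinshipMatrix, expr: ExpressionMatrix, target_genes: list[str],
              annotation: pd.DataFrame, p_threshold: float,
              out_dir: str | Path | None = None,
              ) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """e-TWAS: associate every heritable gene with each target's expression.

    Each target gene's expression row is the response (e-trait); the target
    itself is excluded from the tested set.  Output files are named
    ``<target>_cis_trans_TWAS_result.csv``.  Returns (results, errors);
    a missing target is recorded in ``errors`` and the rest proceed.
    """
    genes = filter_heritable_genes(vc, p_threshold)
    results: dict[str, pd.DataFrame] = {}
    errors: dict[str, str] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for target in target_genes:
        if target not in expr.data.index:
            errors[target] = "target gene absent from expression matrix"
            logger.error("target %s absent from expression matrix; skipped", target)
            continue
        tested = [g for g in genes if g != target]
        ids = expr.individual_ids
        if not tested:
            results[target] = pd.DataFrame(columns=RESULT_COLUMNS)
        else:
            results[target] = _associate_genes(
                expr.gene(target), K.subset_individuals(ids),
                tested, cis, trans, vc, annotation, target)
        if out is not None:
            results[target].to_csv(out / f"{target}_cis_trans_TWAS_result.csv", index=False)
    return results, errors


def stringent_candidate_filter(table: pd.DataFrame, p_cis_max: float = 1e-3,
                               fdr_trans_max: float = 1e-3) -> pd.DataFrame:
    """High-confidence subset: p_cis < p_cis_max AND trans FDR < fdr_trans_max."""
    keep = (table["p-value_cis"] < p_cis_max) & (table["q-value_trans"] < fdr_trans_max)
    out = table.loc[keep]
    return out.sort_values(["rank_product", "p-value_trans", "Gene"],
                           kind="mergesort").reset_index(drop=True)


def edge_list(etwas_results: dict[str, pd.DataFrame], p_cis_max: float = 1e-3,
              fdr_trans_max: float = 1e-3) -> pd.DataFrame:
    """Regulatory edges (target, regulator, rank_product, p_cis, q_trans)."""
    rows = []
    for target, table in etwas_results.items():
        hits = stringent_candidate_filter(table, p_cis_max, fdr_trans_max)
        for _, r in hits.iterrows():
            rows.append({"target": target, "regulator": r["Gene"],
                         "rank_product": r["rank_product"],
                         "p_cis": r["p-value_cis"], "q_trans": r["q-value_trans"]})
    return pd.DataFrame(rows, columns=["target", "regulator", "rank_product",
                                       "p_cis", "q_trans"])
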