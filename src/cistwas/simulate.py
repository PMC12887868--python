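"""Synthetic populations with planted cis/trans regulatory architecture.

The generator emulates every input the pipeline consumes: a genotype panel
with a Balding–Nichols subpopulation structure and first-order
autoregressive LD, a genome-wide kinship matrix, an expression matrix with
per-gene planted cis-heritability and a DAG of trans-regulatory edges, and
phenotypes driven by chosen genes.  A truth record of all planted values is
kept so downstream tests can assert recovery.

Gene ids follow ``G<chrom>_<index>`` (1-based, e.g. ``G1_001``); the single
simulated trait is named ``trait``.  All randomness flows from one
``numpy.random.default_rng(seed)`` stream with the draw order fixed by the
code path: ancestral frequencies, subpopulation frequencies, haplotypes,
then per-gene effect vectors and noise in gene order, then the phenotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .decompose import compute_grm
from .io import (ANNOTATION_COLUMNS, ExpressionMatrix, GenotypePanel, KinshipMatrix,
                 PhenotypeTable, cis_window, select_cis_variants, write_plink_binary)

__all__ = [
    "SimulationConfig",
    "SimulatedData",
    "simulate_annotation",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_phenotype",
    "simulate_dataset",
    "write_dataset",
    "planted_twas_scenario",
    "planted_etwas_scenario",
]


@dataclass
class SimulationConfig:
    """Declarative description of a synthetic population.

    ``trans_edges`` are (regulator, target, effect) triples and must form a
    DAG; ``phenotype_effects`` are (gene, component, effect) triples with
    component one of {"cis", "trans", "both"}.  ``shared_window_pairs``
    places the second gene of each pair inside the first gene's cis window
    and correlates their cis effect vectors (LD-confounder scenarios).
    A seed is mandatory: there is no silent nondeterminism.
    """

    n_individuals: int = 300
    n_chromosomes: int = 2
    genes_per_chromosome: int = 50
    variants_per_gene_window: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.5
    n_subpopulations: int = 2
    divergence: float = 0.1
    cis_h2: float | dict[str, float] = 0.3
    trans_edges: list[tuple[str, str, float]] = field(default_factory=list)
    phenotype_effects: list[tuple[str, str, float]] = field(default_factory=list)
    polygenic_sd: float = 0.5
    noise_sd: float = 1.0
    extend: int = 100_000
    gene_length: int = 5_000
    gene_spacing: int = 300_000
    shared_window_pairs: list[tuple[str, str]] = field(default_factory=list)
    cis_effect_correlation: float = 0.9
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required; there is no default randomness")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        for h2 in ([self.cis_h2] if np.isscalar(self.cis_h2) else self.cis_h2.values()):
            if not 0.0 <= h2 < 1.0:
                raise ValueError("cis_h2 values must be in [0, 1)")

    def h2_of(self, gene_id: str) -> float:
        if np.isscalar(self.cis_h2):
            return float(self.cis_h2)
        return float(self.cis_h2.get(gene_id, 0.0))


@dataclass
class SimulatedData:
    config: SimulationConfig
    annotation: pd.DataFrame
    panel: GenotypePanel
    kinship: KinshipMatrix
    expression: ExpressionMatrix
    phenotypes: PhenotypeTable
    truth: dict


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene layout on the simulated chromosomes.

    Genes are spaced ``gene_spacing`` apart so cis windows are disjoint by
    default; genes named in ``shared_window_pairs`` are relocated to sit
    inside their partner's window.
    """
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        for i in range(1, config.genes_per_chromosome + 1):
            start = 100_000 + (i - 1) * config.gene_spacing
            rows.append({"Gene": f"G{c}_{i:03d}", "chr": str(c), "start": start,
                         "end": start + config.gene_length - 1, "strand": "+",
                         "Note": "simulated"})
    ann = pd.DataFrame(rows)
    idx = ann.set_index("Gene")
    for a, b in config.shared_window_pairs:
        if str(idx.loc[a, "chr"]) != str(idx.loc[b, "chr"]):
            raise ValueError(f"shared-window pair {a},{b} not on one chromosome")
        new_start = int(idx.loc[a, "start"]) + config.gene_length + 1_000
        ann.loc[ann["Gene"] == b, ["start", "end"]] = (
            new_start, new_start + config.gene_length - 1)
    return ann[ANNOTATION_COLUMNS]


def simulate_genotypes(config: SimulationConfig,
                       annotation: pd.DataFrame | None = None,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[GenotypePanel, KinshipMatrix, pd.DataFrame]:
    """Dosage panel with population structure and AR(1) LD, plus kinship.

    Ancestral allele frequencies are uniform on ``maf_range``; subpopulation
    frequencies follow the Balding–Nichols model at Fst ``divergence``.
    Within a chromosome each haplotype copies the previous variant's allele
    with probability ``ld_decay``, otherwise draws fresh.  The kinship is
    the genome-wide GRM of the panel.
    """
    if annotation is None:
        annotation = simulate_annotation(config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    ids = [f"IND_{i:04d}" for i in range(1, n + 1)]
    subpop = np.repeat(np.arange(config.n_subpopulations),
                       int(np.ceil(n / config.n_subpopulations)))[:n]

    var_rows = []
    dosage_cols = []
    for c in range(1, config.n_chromosomes + 1):
        genes_c = annotation[annotation["chr"] == str(c)]
        positions: list[int] = []
        for _, g in genes_c.iterrows():
            _, lo, hi = cis_window(g, config.extend)
            span = hi - lo
            pos = lo + (span * (2 * np.arange(config.variants_per_gene_window) + 1)
                        // (2 * config.variants_per_gene_window))
            positions.extend(int(p) for p in pos)
        positions = sorted(set(positions))
        m = len(positions)
        p_anc = rng.uniform(*config.maf_range, size=m)
        if config.n_subpopulations > 1 and config.divergence > 0:
            f = config.divergence
            p_sub = rng.beta(p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f,
                             size=(config.n_subpopulations, m))
            p_sub = np.clip(p_sub, 0.01, 0.99)
        else:
            p_sub = np.tile(p_anc, (config.n_subpopulations, 1))
        p_ind = p_sub[subpop]  # n x m

        haps = np.zeros((2, n, m), dtype=np.int8)
        for h in range(2):
            fresh = (rng.random((n, m)) < p_ind).astype(np.int8)
            haps[h, :, 0] = fresh[:, 0]
            if config.ld_decay > 0:
                copy = rng.random((n, m)) < config.ld_decay
                for j in range(1, m):
                    haps[h, :, j] = np.where(copy[:, j], haps[h, :, j - 1], fresh[:, j])
            else:
                haps[h] = fresh
        dos = (haps[0] + haps[1]).astype(float)
        if config.missing_rate > 0:
            dos[rng.random(dos.shape) < config.missing_rate] = np.nan
        dosage_cols.append(dos)
        for j, pos in enumerate(positions):
            var_rows.append({"variant_id": f"snp{c}_{j + 1:05d}", "chromosome": str(c),
                             "position": pos, "allele_ref": "A", "allele_alt": "T"})

    panel = GenotypePanel(ids, pd.DataFrame(var_rows), np.concatenate(dosage_cols, axis=1))
    poly = panel.subset_variants(np.nanvar(panel.dosage, axis=0) > 0)
    kinship = compute_grm(poly)
    return panel, kinship, annotation


def _toposort(genes: list[str], edges: list[tuple[str, str, float]]) -> list[str]:
    children: dict[str, list[str]] = {g: [] for g in genes}
    indeg = {g: 0 for g in genes}
    for reg, tgt, _ in edges:
        if reg not in indeg or tgt not in indeg:
            raise ValueError(f"trans edge references unknown gene: {reg} -> {tgt}")
        children[reg].append(tgt)
        indeg[tgt] += 1
    queue = [g for g in genes if indeg[g] == 0]
    order: list[str] = []
    while queue:
        g = queue.pop(0)
        order.append(g)
        for c in children[g]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != len(genes):
        raise ValueError("trans_edges contain a cycle; only DAGs are supported")
    return order


def simulate_expression(config: SimulationConfig, panel: GenotypePanel,
                        annotation: pd.DataFrame,
                        rng: np.random.Generator,
                        ) -> tuple[ExpressionMatrix, dict]:
    """Expression with planted cis-heritability and trans-regulatory edges.

    Per gene g (in topological order over the trans DAG):
    ``y_g = cis_g + sum(effect * y_regulator) + eps`` with ``eps ~ N(0, 1)``
    and ``cis_g = Z a`` (standardized cis dosages, normal effects) rescaled
    so the in-sample variance ratio var(cis_g)/var(y_g) equals the gene's
    cis_h2 exactly.  Returns the matrix and a truth record holding each
    gene's realized cis values and edge contributions.
    """
    genes = list(annotation["Gene"])
    order = _toposort(genes, config.trans_edges)
    n = panel.n_individuals
    ann_idx = annotation.set_index("Gene")

    # draw per-gene effect vectors in annotation order for a stable stream
    cis_sets: dict[str, GenotypePanel] = {}
    effects: dict[str, np.ndarray] = {}
    for g in genes:
        window = cis_window(ann_idx.loc[g], config.extend)
        sub = select_cis_variants(panel, window, maf_min=0.0)
        cis_sets[g] = sub
        effects[g] = rng.standard_normal(sub.n_variants)
    for a, b in config.shared_window_pairs:
        rho = config.cis_effect_correlation
        ids_a = dict(zip(cis_sets[a].variants["variant_id"], effects[a]))
        vb = cis_sets[b].variants["variant_id"]
        shared = vb.isin(ids_a).to_numpy()
        blended = effects[b].copy()
        blended[shared] = (rho * np.array([ids_a[v] for v in vb[shared]])
                           + np.sqrt(1 - rho ** 2) * blended[shared])
        effects[b] = blended
    noise = {g: rng.standard_normal(n) for g in genes}

    incoming: dict[str, list[tuple[str, float]]] = {g: [] for g in genes}
    for reg, tgt, eff in config.trans_edges:
        incoming[tgt].append((reg, eff))

    y: dict[str, np.ndarray] = {}
    cis_truth: dict[str, np.ndarray] = {}
    trans_truth: dict[str, np.ndarray] = {}
    realized_h2: dict[str, float] = {}
    for g in order:
        sub = cis_sets[g]
        h2 = config.h2_of(g)
        trans_sum = np.zeros(n)
        for reg, eff in incoming[g]:
            trans_sum += eff * y[reg]
        other = trans_sum + noise[g]
        if sub.n_variants > 0 and h2 > 0:
            x = sub.imputed_dosage()
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            z = (x - mu) / np.where(sd > 0, sd, 1.0)
            raw = z @ effects[g]
            sd_raw = raw.std()
            if sd_raw > 0:
                scale = np.sqrt(h2 / (1 - h2)) * other.std() / sd_raw
                cis_val = scale * raw
            else:
                cis_val = np.zeros(n)
        else:
            cis_val = np.zeros(n)
        y[g] = cis_val + other
        cis_truth[g] = cis_val
        trans_truth[g] = other
        tot = y[g].var()
        realized_h2[g] = float(cis_val.var() / tot) if tot > 0 else 0.0

    data = pd.DataFrame({g: y[g] for g in genes}).T
    data.columns = panel.individual_ids
    data.index.name = "Gene"
    truth = {"cis": pd.DataFrame(cis_truth).T.set_axis(panel.individual_ids, axis=1),
             "trans": pd.DataFrame(trans_truth).T.set_axis(panel.individual_ids, axis=1),
             "realized_h2": pd.Series(realized_h2),
             "edges": list(config.trans_edges)}
    return ExpressionMatrix(data), truth


def simulate_phenotype(config: SimulationConfig, expr: ExpressionMatrix,
                       expr_truth: dict, kinship: KinshipMatrix,
                       rng: np.random.Generator) -> tuple[PhenotypeTable, dict]:
    """One trait driven by chosen gene components plus structure and noise.

    ``trait = sum(effect * component_of_gene) + polygenic + N(0, noise_sd^2)``
    where the polygenic term is ``polygenic_sd * L z`` with ``K = L L'``.
    """
    n = len(expr.individual_ids)
    total = np.zeros(n)
    contributions: dict[str, np.ndarray] = {}
    for gene, comp, eff in config.phenotype_effects:
        if gene not in expr.data.index:
            raise ValueError(f"phenotype effect references unknown gene {gene}")
        if comp == "cis":
            v = expr_truth["cis"].loc[gene].to_numpy(dtype=float)
        elif comp == "trans":
            v = expr_truth["trans"].loc[gene].to_numpy(dtype=float)
        elif comp == "both":
            v = expr.gene(gene)
        else:
            raise ValueError(f"unknown component {comp!r} (use cis/trans/both)")
        contributions[f"{gene}:{comp}"] = eff * v
        total = total + eff * v
    k = kinship.values + 1e-6 * np.eye(n)
    polygenic = config.polygenic_sd * (np.linalg.cholesky(k) @ rng.standard_normal(n))
    noise = config.noise_sd * rng.standard_normal(n)
    trait = total + polygenic + noise
    table = PhenotypeTable(pd.DataFrame({"trait": trait}, index=expr.individual_ids))
    truth = {"contributions": contributions, "polygenic": polygenic, "noise": noise}
    return table, truth


def simulate_dataset(config: SimulationConfig) -> SimulatedData:
    """Full synthetic dataset: genotypes, kinship, expression, phenotype, truth."""
    rng = np.random.default_rng(config.seed)
    annotation = simulate_annotation(config)
    panel, kinship, annotation = simulate_genotypes(config, annotation, rng)
    expression, expr_truth = simulate_expression(config, panel, annotation, rng)
    phenotypes, pheno_truth = simulate_phenotype(config, expression, expr_truth,
                                                 kinship, rng)
    truth = {"expression": expr_truth, "phenotype": pheno_truth}
    return SimulatedData(config, annotation, panel, kinship, expression,
                         phenotypes, truth)


def write_dataset(data: SimulatedData, out_dir: str | Path,
                  gfile_prefix: str = "%s_sim") -> None:
    """Write the dataset in the pipeline's input formats.

    PLINK trios per chromosome (named by ``gfile_prefix`` with ``%s`` as the
    chromosome label), TSVs for annotation/expression/phenotypes/kinship,
    and a ``truth.json`` ledger of the planted parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for c in data.annotation["chr"].unique():
        mask = (data.panel.variants["chromosome"] == c).to_numpy()
        write_plink_binary(data.panel.subset_variants(mask), out / (gfile_prefix % c))
    data.annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    data.expression.data.to_csv(out / "expression.tsv", sep="\t")
    data.phenotypes.data.to_csv(out / "phenotypes.tsv", sep="\t")
    data.kinship.data.to_csv(out / "kinship.tsv", sep="\t")
    cfg = asdict(data.config)
    planted = {
        "config": cfg,
        "realized_h2": {k: float(v)
                        for k, v in data.truth["expression"]["realized_h2"].items()},
    }
    (out / "truth.json").write_text(json.dumps(planted, indent=2, default=str))


def planted_twas_scenario(n_genes: int = 200, n_individuals: int = 300,
                          seed: int = 0, effect: float = 1.0,
                          cis_h2: float = 0.5) -> tuple[SimulationConfig, str, str]:
    """One causal gene driving the trait plus an LD-linked cis confounder.

    The causal gene's full expression (cis and trans parts) feeds the trait;
    the confounder shares the causal gene's cis window and cis effects but
    has no trans link to the trait.  Returns (config, causal, confounder).
    """
    causal, confounder = "G1_001", "G1_002"
    config = SimulationConfig(
        n_individuals=n_individuals, n_chromosomes=1,
        genes_per_chromosome=n_genes, variants_per_gene_window=12,
        cis_h2=cis_h2, shared_window_pairs=[(causal, confounder)],
        phenotype_effects=[(causal, "both", effect)],
        polygenic_sd=0.5, noise_sd=0.5, seed=seed)
    return config, causal, confounder


def planted_etwas_scenario(n_genes: int = 200, n_individuals: int = 300,
                           seed: int = 0, effect: float = 0.8,
                           cis_h2: float = 0.5) -> tuple[SimulationConfig, str, str]:
    """A directed regulatory edge A -> B for the e-trait mode.

    Gene A's expression drives gene B with the given effect; querying B as
    an e-trait should rank A first.  Returns (config, regulator, target).
    """
    regulator, target = "G1_001", "G1_010"
    config = SimulationConfig(
        n_individuals=n_individuals, n_chromosomes=1,
        genes_per_chromosome=n_genes, variants_per_gene_window=12,
        cis_h2=cis_h2, trans_edges=[(regulator, target, effect)],
        polygenic_sd=0.0, noise_sd=1.0, seed=seed)
    return config, regulator, target
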