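"""Readers, writers and coordinate logic for the pipeline's standard inputs.

Genotypes come in as PLINK 1.9 binary trios (.bed/.bim/.fam, SNP-major).
Annotation, expression, phenotype and kinship tables are tab-delimited text
with a header row.  All genomic coordinates are 1-based and fully inclusive,
matching .bim and the usual GFF convention.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "ExpressionMatrix",
    "PhenotypeTable",
    "KinshipMatrix",
    "read_plink_binary",
    "write_plink_binary",
    "read_annotation",
    "read_expression",
    "read_phenotypes",
    "read_kinship",
    "cis_window",
    "select_cis_variants",
    "align_samples",
]

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# PLINK v1 2-bit genotype codes -> copies of the A1 (effect) allele.
# 00 -> hom A1 (2), 01 -> missing, 10 -> het (1), 11 -> hom A2 (0).
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

ANNOTATION_COLUMNS = ["Gene", "chr", "start", "end", "strand", "Note"]


@dataclass
class GenotypePanel:
    """Individuals x variants dosage matrix with variant coordinates.

    ``dosage[i, j]`` is the number of copies of the effect allele (PLINK A1,
    stored in ``allele_alt``) carried by individual *i* at variant *j*;
    missing calls are NaN.
    """

    individual_ids: list[str]
    variants: pd.DataFrame  # variant_id, chromosome, position, allele_ref, allele_alt
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.individual_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.variants)} variants"
            )
        vid = self.variants["variant_id"]
        if vid.duplicated().any():
            dups = vid[vid.duplicated()].unique()[:5]
            raise ValueError(f"duplicate variant ids: {list(dups)}")
        # canonical order: position-sorted within chromosome (stable across chroms)
        order = np.lexsort(
            (self.variants["position"].to_numpy(),
             self.variants["chromosome"].astype(str).to_numpy())
        )
        if not np.array_equal(order, np.arange(len(order))):
            self.variants = self.variants.iloc[order].reset_index(drop=True)
            self.dosage = self.dosage[:, order]
        else:
            self.variants = self.variants.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_frequency(self) -> np.ndarray:
        """Effect-allele frequency per variant, over non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def imputed_dosage(self) -> np.ndarray:
        """Dosage with missing entries mean-imputed per variant."""
        x = self.dosage.copy()
        if np.isnan(x).any():
            col_mean = np.nanmean(x, axis=0)
            idx = np.where(np.isnan(x))
            x[idx] = col_mean[idx[1]]
        return x

    def subset_individuals(self, ids: list[str]) -> "GenotypePanel":
        pos = {s: i for i, s in enumerate(self.individual_ids)}
        rows = [pos[s] for s in ids]
        return GenotypePanel(list(ids), self.variants.copy(), self.dosage[rows])

    def subset_variants(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask)
        return GenotypePanel(
            list(self.individual_ids),
            self.variants.loc[mask].reset_index(drop=True),
            self.dosage[:, mask],
        )


@dataclass
class ExpressionMatrix:
    """Genes x individuals matrix of normalized expression."""

    data: pd.DataFrame  # index = gene ids, columns = individual ids

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data.columns)

    def gene(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy(dtype=float)

    def subset_individuals(self, ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(ids)])


@dataclass
class PhenotypeTable:
    """Individuals x traits table; missing values allowed."""

    data: pd.DataFrame  # index = individual ids, columns = trait names

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    def subset_individuals(self, ids: list[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(ids)])


@dataclass
class KinshipMatrix:
    """n x n relatedness matrix used as the random-effect covariance."""

    data: pd.DataFrame  # index == columns == individual ids
    sym_tol: float = field(default=1e-8, repr=False)
    psd_tol: float = field(default=1e-8, repr=False)

    def __post_init__(self) -> None:
        v = self.data.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValueError("kinship matrix is not square")
        if list(self.data.index) != list(self.data.columns):
            raise ValueError("kinship row/column ids differ")
        if np.abs(v - v.T).max(initial=0.0) > self.sym_tol * max(1.0, np.abs(v).max()):
            raise ValueError("kinship matrix is not symmetric")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def check_psd(self) -> None:
        w = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        scale = max(1.0, abs(w[-1]))
        if w[0] < -self.psd_tol * scale:
            raise ValueError(f"kinship matrix not positive semidefinite (min eigenvalue {w[0]:.3g})")

    def subset_individuals(self, ids: list[str]) -> "KinshipMatrix":
        ids = list(ids)
        return KinshipMatrix(self.data.loc[ids, ids])


# ---------------------------------------------------------------------------
# PLINK 1.9 binary trio
# ---------------------------------------------------------------------------

def read_plink_binary(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK binary trio ``prefix``.bed/.bim/.fam into a GenotypePanel.

    The .bed must be SNP-major PLINK v1.  Dosages count the .bim A1 allele
    (column 5) as the effect allele.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chromosome", "variant_id", "cm", "position", "a1", "a2"],
                      dtype={"chromosome": str, "variant_id": str})
    n_ind = len(fam)
    n_var = len(bim)

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise ValueError(f"{bed_path}: not a PLINK v1 .bed file (bad magic bytes)")
    if raw[2:3] != _BED_SNP_MAJOR:
        raise ValueError(f"{bed_path}: only SNP-major mode (0x01) is supported")
    bytes_per_variant = (n_ind + 3) // 4
    expected = 3 + bytes_per_variant * n_var
    if len(raw) != expected:
        raise ValueError(
            f"{bed_path}: payload length {len(raw) - 3} does not match "
            f"{n_ind} individuals x {n_var} variants ({expected - 3} bytes expected)"
        )

    if n_var == 0 or n_ind == 0:
        dosage = np.zeros((n_ind, n_var))
    else:
        payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
        payload = payload.reshape(n_var, bytes_per_variant)
        # unpack 2-bit codes, little-endian within each byte
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        codes = (payload[:, :, None] >> shifts[None, None, :]) & 0b11
        codes = codes.reshape(n_var, bytes_per_variant * 4)[:, :n_ind]
        dosage = _CODE_TO_DOSAGE[codes].T.copy()

    variants = pd.DataFrame({
        "variant_id": bim["variant_id"],
        "chromosome": bim["chromosome"],
        "position": bim["position"].astype(int),
        "allele_ref": bim["a2"],
        "allele_alt": bim["a1"],
    })
    return GenotypePanel(list(fam["iid"]), variants, dosage)


def write_plink_binary(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a GenotypePanel as a PLINK v1 SNP-major binary trio."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n_ind = panel.n_individuals
    n_var = panel.n_variants

    fam = pd.DataFrame({
        "fid": panel.individual_ids, "iid": panel.individual_ids,
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bim = pd.DataFrame({
        "chromosome": panel.variants["chromosome"],
        "variant_id": panel.variants["variant_id"],
        "cm": 0,
        "position": panel.variants["position"],
        "a1": panel.variants["allele_alt"],
        "a2": panel.variants["allele_ref"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    # dosage -> 2-bit codes (inverse of _CODE_TO_DOSAGE)
    d = panel.dosage
    codes = np.full(d.shape, 1, dtype=np.uint8)  # missing
    codes[d == 2.0] = 0
    codes[d == 1.0] = 2
    codes[d == 0.0] = 3

    bytes_per_variant = (n_ind + 3) // 4
    padded = np.ones((n_var, bytes_per_variant * 4), dtype=np.uint8) * 3  # pad = hom A2
    padded[:, :n_ind] = codes.T
    packed = (padded[:, 0::4] | (padded[:, 1::4] << 2)
              | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Tab-delimited tables
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV with columns Gene, chr, start, end[, strand, Note]."""
    gff = pd.read_csv(path, sep="\t", dtype={"Gene": str, "chr": str})
    missing = [c for c in ("Gene", "chr", "start", "end") if c not in gff.columns]
    if missing:
        raise ValueError(f"annotation file missing columns: {missing}")
    if "strand" not in gff.columns:
        gff["strand"] = "unknown"
    if "Note" not in gff.columns:
        gff["Note"] = ""
    gff["Note"] = gff["Note"].fillna("")
    gff["start"] = gff["start"].astype(int)
    gff["end"] = gff["end"].astype(int)
    if (gff["start"] > gff["end"]).any():
        bad = gff.loc[gff["start"] > gff["end"], "Gene"].tolist()[:5]
        raise ValueError(f"annotation rows with start > end: {bad}")
    if gff["Gene"].duplicated().any():
        raise ValueError("duplicate gene ids in annotation")
    return gff[ANNOTATION_COLUMNS]


def read_expression(path: str | Path) -> ExpressionMatrix:
    return ExpressionMatrix(pd.read_csv(path, sep="\t", index_col=0))


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", index_col=0))


def read_kinship(path: str | Path) -> KinshipMatrix:
    return KinshipMatrix(pd.read_csv(path, sep="\t", index_col=0))


# ---------------------------------------------------------------------------
# Cis-window logic and sample alignment
# ---------------------------------------------------------------------------

def cis_window(gene: pd.Series, extend: int) -> tuple[str, int, int]:
    """Inclusive cis window (chrom, lo, hi) around a gene body.

    ``lo = max(1, start - extend)``, ``hi = end + extend``.  The window is
    symmetric around the gene body and strand-agnostic.
    """
    if extend < 0:
        raise ValueError("extend must be >= 0")
    extend = int(extend)
    return (str(gene["chr"]), max(1, int(gene["start"]) - extend), int(gene["end"]) + extend)


def select_cis_variants(panel: GenotypePanel, window: tuple[str, int, int],
                        maf_min: float = 0.01) -> GenotypePanel:
    """Subset a panel to polymorphic variants inside an inclusive window.

    Keeps variants on ``window[0]`` with lo <= position <= hi, minor-allele
    frequency >= ``maf_min`` (computed on non-missing dosages) and non-zero
    dosage variance.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    chrom, lo, hi = window
    v = panel.variants
    in_window = ((v["chromosome"].astype(str) == str(chrom))
                 & (v["position"] >= lo) & (v["position"] <= hi)).to_numpy()
    if not in_window.any():
        return panel.subset_variants(in_window)
    sub = panel.subset_variants(in_window)
    maf = sub.minor_allele_frequency()
    with np.errstate(invalid="ignore"):
        var = np.nanvar(sub.dosage, axis=0)
    keep = (maf >= maf_min) & (var > 0) & np.isfinite(maf)
    return sub.subset_variants(keep)


def align_samples(objs: list) -> tuple[list, list[int]]:
    """Restrict/reorder sample-indexed objects to their common individuals.

    Order follows the first object's id sequence.  Returns the aligned
    objects and the number of individuals dropped from each.
    """
    if not objs:
        return [], []
    common = set(objs[0].individual_ids)
    for o in objs[1:]:
        common &= set(o.individual_ids)
    if not common:
        raise ValueError("no individuals shared across inputs")
    order = [s for s in objs[0].individual_ids if s in common]
    dropped = [len(o.individual_ids) - len(order) for o in objs]
    return [o.subset_individuals(order) for o in objs], dropped
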