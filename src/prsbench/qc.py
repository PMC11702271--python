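"""Variant- and sample-level quality control, plus PCA covariates.

Variant filters (INFO, MAF, missingness, Hardy-Weinberg) mirror the standard
post-imputation QC of case/control genotype cohorts; relatedness pruning uses
the KING-robust kinship coefficient. Hard-calling for the HWE and kinship
statistics rounds dosages to the nearest integer, leaving dosages in the
uncertainty bands (0.4, 0.6) and (1.4, 1.6) missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .geno_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; permissive defaults are overridden from config.

    ``kinship_max`` is on the KING kinship scale (phi); a PLINK-style
    pi-hat threshold t maps to phi = t / 2.
    """

    maf_min: float = 0.05
    miss_max: float = 0.05
    hwe_p_min: float = 1e-6
    info_min: float = 0.7
    kinship_max: float = 0.125

    def __post_init__(self):
        for name in ("maf_min", "miss_max", "hwe_p_min", "info_min", "kinship_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    n_variants_in: int = 0
    n_samples_in: int = 0
    removed: dict = field(default_factory=dict)  # filter name -> count
    n_variants_out: int = 0
    n_samples_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"filter": "retained_variants", "removed": self.n_variants_out})
        rows.append({"filter": "retained_samples", "removed": self.n_samples_out})
        return pd.DataFrame(rows)


def hard_call(dosage: np.ndarray) -> np.ndarray:
    """Round dosages to {0,1,2}; guard-band and missing dosages become NaN."""
    d = np.asarray(dosage, dtype=float)
    out = np.round(d)
    uncertain = ((d > 0.4) & (d < 0.6)) | ((d > 1.4) & (d < 1.6))
    out = np.where(uncertain, np.nan, out)
    return out


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test conditional on allele counts.

    Sums, over all heterozygote counts of the observed parity compatible with
    the observed allele counts, the conditional probabilities that do not
    exceed the observed table's probability.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts zero")
    n_a = 2 * n_aa + n_Aa  # minor-or-not does not matter: symmetric in alleles
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    n_hom_rare = (rare - hets) // 2
    n_hom_common = n - hets - n_hom_rare
    # log P(het = h | allele counts) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(n_hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_common + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_Aa][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def allele_freq(dosage_col: np.ndarray) -> float:
    """Alt-allele frequency from non-missing dosages."""
    d = dosage_col[~np.isnan(dosage_col)]
    if d.size == 0:
        return np.nan
    return float(d.mean() / 2.0)


def variant_qc(
    gm: GenotypeMatrix,
    thresholds: QcThresholds,
    hwe_scope: str = "all",
    case_status: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove variants failing INFO, MAF, missingness or HWE filters.

    Each removed variant is attributed to the *first* failing filter in the
    fixed order INFO, MAF, missingness, HWE so reports are deterministic.
    MAF is computed from non-missing dosages and folded to the minor allele;
    HWE uses hard-calls, over all samples or controls only (``hwe_scope``).
    """
    if hwe_scope not in ("all", "controls"):
        raise ValueError(f"hwe_scope must be 'all' or 'controls', got {hwe_scope!r}")
    report = QcReport(n_variants_in=gm.n_variants, n_samples_in=gm.n_samples)
    removed = {"INFO": 0, "MAF": 0, "missingness": 0, "HWE": 0}
    keep = np.ones(gm.n_variants, dtype=bool)

    if hwe_scope == "controls":
        if case_status is None:
            raise ValueError("hwe_scope='controls' requires case_status")
        hwe_rows = np.asarray(case_status) == 0
    else:
        hwe_rows = np.ones(gm.n_samples, dtype=bool)

    for j, v in enumerate(gm.variants):
        col = gm.dosage[:, j]
        if v.info_score is not None and v.info_score < thresholds.info_min:
            removed["INFO"] += 1
            keep[j] = False
            continue
        freq = allele_freq(col)
        maf = np.nan if np.isnan(freq) else min(freq, 1 - freq)
        if np.isnan(maf) or maf < thresholds.maf_min:
            removed["MAF"] += 1
            keep[j] = False
            continue
        miss = float(np.isnan(col).mean())
        if miss > thresholds.miss_max:
            removed["missingness"] += 1
            keep[j] = False
            continue
        hc = hard_call(col[hwe_rows])
        hc = hc[~np.isnan(hc)]
        if hc.size:
            n_AA = int((hc == 0).sum())
            n_Aa = int((hc == 1).sum())
            n_aa = int((hc == 2).sum())
            if hwe_exact_test(n_AA, n_Aa, n_aa) < thresholds.hwe_p_min:
                removed["HWE"] += 1
                keep[j] = False
    report.removed = removed
    out = gm.subset_variants(keep)
    report.n_variants_out = out.n_variants
    report.n_samples_out = out.n_samples
    if out.n_variants == 0:
        logger.warning("variant_qc: no variants survive filtering")
    return out, report


def king_kinship(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """KING-robust kinship estimate from two hard-callable dosage vectors.

    phi-hat = (N_het,het - 2 * N_opposite-hom) / (N_het(i) + N_het(j)) over
    jointly non-missing sites; ~0.5 for duplicates/MZ twins, ~0.25 first
    degree, ~0 for unrelated pairs.
    """
    gi = hard_call(np.asarray(dosage_i, float))
    gj = hard_call(np.asarray(dosage_j, float))
    ok = ~(np.isnan(gi) | np.isnan(gj))
    if not ok.any():
        raise ValueError("no overlapping non-missing sites")
    gi, gj = gi[ok], gj[ok]
    het_i = gi == 1
    het_j = gj == 1
    n_het_het = int((het_i & het_j).sum())
    n_opp = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
    denom = int(het_i.sum()) + int(het_j.sum())
    if denom == 0:
        raise ValueError("kinship undefined: no heterozygous sites in either sample")
    return (n_het_het - 2 * n_opp) / denom


def kinship_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Symmetric KING kinship matrix (diagonal set to 0.5)."""
    n = gm.n_samples
    K = np.full((n, n), 0.5)
    for i in range(n):
        for j in range(i + 1, n):
            K[i, j] = K[j, i] = king_kinship(gm.dosage[i], gm.dosage[j])
    return K


def prune_related(
    kinship: np.ndarray,
    threshold: float,
    missingness: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy relatedness pruning; returns indices of retained samples.

    While any pair exceeds the threshold, drop the member with the larger
    number of over-threshold partners (ties: higher missingness, then the
    later sample index).
    """
    K = np.asarray(kinship, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n):
        raise ValueError("kinship matrix must be square")
    miss = np.zeros(n) if missingness is None else np.asarray(missingness, float)
    active = np.ones(n, dtype=bool)
    over = (K > threshold).astype(int)
    np.fill_diagonal(over, 0)
    while True:
        deg = np.where(active, (over[:, active]).sum(axis=1), -1)
        if deg.max() <= 0:
            break
        worst = deg.max()
        cands = np.flatnonzero(deg == worst)
        # tie-breaks: higher missingness, then later sample order
        cands = cands[miss[cands] == miss[cands].max()]
        drop = int(cands.max())
        active[drop] = False
    return np.flatnonzero(active)


def genotype_pca(gm: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k principal components of the standardized dosage matrix.

    Variants are mean-imputed, centered at 2*p-hat and scaled by
    sqrt(2*p-hat*(1-p-hat)); monomorphic variants are skipped. Each PC's sign
    is fixed so its largest-magnitude sample loading is positive. Returns an
    (n_samples, k) array.
    """
    X = gm.dosage.copy()
    n, m = X.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n_samples, n_variants)={min(n, m)}")
    cols = []
    for j in range(m):
        col = X[:, j]
        mean = np.nanmean(col)
        col = np.where(np.isnan(col), mean, col)
        p = mean / 2.0
        var = 2 * p * (1 - p)
        if var <= 0:
            continue  # monomorphic
        cols.append((col - 2 * p) / np.sqrt(var))
    if not cols:
        raise ValueError("no polymorphic variants for PCA")
    Z = np.column_stack(cols)
    # eigenvectors of the sample-sample covariance via SVD of Z
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    if k > (s > 1e-10).sum():
        raise ValueError(f"k={k} exceeds matrix rank {(s > 1e-10).sum()}")
    pcs = U[:, :k] * s[:k]
    for c in range(k):
        imax = np.argmax(np.abs(pcs[:, c]))
        if pcs[imax, c] < 0:
            pcs[:, c] = -pcs[:, c]
    return pcs
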