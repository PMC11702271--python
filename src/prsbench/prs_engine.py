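"""Polygenic score construction: harmonization, clumping + thresholding,
region restriction, and scoring of external per-SNP weights.

The clumping rule is the standard greedy one: repeatedly take the unassigned
variant with the smallest GWAS p-value as an index and remove all unassigned
same-chromosome variants within the distance window whose in-sample r^2 with
the index exceeds the threshold. The r^2 comparison is strict (> r2_max
removed); the p-value threshold is inclusive (p <= pT). Scores are
sum_j beta_j * dosage_sj with per-variant mean imputation of missing dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix, RegionSet, SummaryStats, WeightFile

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: The p-value threshold grid the benchmark sweeps.
DEFAULT_PT_GRID = (5e-8, 1e-6, 1e-5, 1e-3, 1e-2, 0.05, 0.1, 0.5)


@dataclass(frozen=True)
class ClumpParams:
    r2_max: float = 0.1
    window_kb: float = 1000.0
    pt_grid: tuple = DEFAULT_PT_GRID

    def __post_init__(self):
        if not (0.0 < self.r2_max <= 1.0):
            raise ValueError(f"r2_max {self.r2_max} outside (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        grid = tuple(self.pt_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("pt_grid must be strictly increasing")


@dataclass
class AlignedWeights:
    """GWAS effects matched to genotype columns, signed to the alt allele."""

    index: np.ndarray  # genotype column indices
    beta: np.ndarray
    p: np.ndarray | None
    se: np.ndarray | None
    gwas_id: str = "gwas"
    log: dict = field(default_factory=dict)

    def __post_init__(self):
        self.index = np.asarray(self.index, dtype=int)
        self.beta = np.asarray(self.beta, dtype=float)
        if len(np.unique(self.index)) != len(self.index):
            raise ValueError("duplicate genotype indices in aligned weights")

    def __len__(self) -> int:
        return len(self.index)

    def take(self, sel) -> "AlignedWeights":
        sel = np.asarray(sel)
        return AlignedWeights(
            index=self.index[sel],
            beta=self.beta[sel],
            p=None if self.p is None else self.p[sel],
            se=None if self.se is None else self.se[sel],
            gwas_id=self.gwas_id,
            log=dict(self.log),
        )


@dataclass
class ScoreSet:
    """Per-sample PRS with provenance."""

    samples: list[str]
    values: np.ndarray
    method: str = "C+T"
    gwas_id: str = "gwas"
    region_mode: str = "full"  # full | noAPOE | APOEonly | microglia
    pt: float | None = None
    n_snps: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.samples):
            raise ValueError("score length does not match samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite scores")
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.samples,
                "score": self.values,
                "method": self.method,
                "gwas": self.gwas_id,
                "region_mode": self.region_mode,
                "pt": np.nan if self.pt is None else self.pt,
                "n_snps": self.n_snps,
            }
        )

    @property
    def label(self) -> str:
        pt = "" if self.pt is None else f"@pT={self.pt:g}"
        return f"{self.method}:{self.gwas_id}:{self.region_mode}{pt}"


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    sumstats: SummaryStats,
    genotypes: GenotypeMatrix,
    drop_ambiguous: bool = True,
) -> AlignedWeights:
    """Match GWAS rows to genotype columns on (chrom, pos) and sign betas to
    the cohort's alt allele.

    Effect allele == alt keeps beta; effect allele == ref flips its sign;
    any other pairing is dropped as an allele mismatch. A/T and C/G
    strand-ambiguous pairs are dropped when ``drop_ambiguous`` is set.
    """
    vf = genotypes.variant_frame()
    lookup = {(c, p): j for j, (c, p) in enumerate(zip(vf["chrom"], vf["pos"]))}
    idx, beta, pvals, ses = [], [], [], []
    counts = {"matched": 0, "flipped": 0, "mismatch": 0, "ambiguous": 0, "unmatched": 0}
    t = sumstats.table
    has_p = "p" in t.columns
    has_se = "se" in t.columns
    for row in t.itertuples(index=False):
        j = lookup.get((row.chrom, row.pos))
        if j is None:
            counts["unmatched"] += 1
            continue
        if drop_ambiguous and _is_ambiguous(row.effect_allele, row.other_allele):
            counts["ambiguous"] += 1
            continue
        ref, alt = vf["ref"][j], vf["alt"][j]
        if row.effect_allele == alt and row.other_allele == ref:
            b = row.beta
        elif row.effect_allele == ref and row.other_allele == alt:
            b = -row.beta
            counts["flipped"] += 1
        else:
            counts["mismatch"] += 1
            continue
        counts["matched"] += 1
        idx.append(j)
        beta.append(b)
        if has_p:
            pvals.append(row.p)
        if has_se:
            ses.append(row.se)
    if not idx:
        raise ValueError(
            f"harmonization produced zero matches "
            f"(unmatched={counts['unmatched']}, mismatch={counts['mismatch']}, "
            f"ambiguous={counts['ambiguous']})"
        )
    logger.info("harmonize(%s): %s", sumstats.gwas_id, counts)
    return AlignedWeights(
        index=np.array(idx),
        beta=np.array(beta),
        p=np.array(pvals) if has_p else None,
        se=np.array(ses) if has_se else None,
        gwas_id=sumstats.gwas_id,
        log=counts,
    )


def ld_r2(genotypes: GenotypeMatrix, idx_a: int, idx_b: int) -> float:
    """Squared Pearson correlation of two dosage columns over jointly
    non-missing samples."""
    a = genotypes.dosage[:, idx_a]
    b = genotypes.dosage[:, idx_b]
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("zero-variance dosage column in r^2 computation")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(1.0, r * r))


def clump(
    weights: AlignedWeights,
    genotypes: GenotypeMatrix,
    params: ClumpParams,
) -> AlignedWeights:
    """Greedy LD clumping; returns the index-variant subset of ``weights``.

    Deterministic under p-value ties: smaller SE first, then lower genomic
    position. Output order follows the original weight order. Pairwise r^2 is
    computed on mean-imputed dosage columns (identical to :func:`ld_r2` when
    no dosages are missing).
    """
    if len(weights) == 0:
        return weights.take(np.array([], dtype=int))
    if weights.p is None:
        raise ValueError("clumping requires p-values")
    vf = genotypes.variant_frame()
    chrom = vf["chrom"].to_numpy()[weights.index]
    pos = vf["pos"].to_numpy()[weights.index]
    se = weights.se if weights.se is not None else np.zeros(len(weights))
    order = sorted(range(len(weights)), key=lambda i: (weights.p[i], se[i], pos[i]))
    # unit-normalized, mean-imputed columns so r = u_i . u_j
    D = genotypes.dosage[:, weights.index].copy()
    if np.isnan(D).any():
        mu = np.nanmean(D, axis=0)
        D = np.where(np.isnan(D), mu[None, :], D)
    D -= D.mean(axis=0)
    norms = np.linalg.norm(D, axis=0)
    norms[norms == 0] = np.inf  # zero-variance column: r^2 = 0 against anything
    U = D / norms
    assigned = np.zeros(len(weights), dtype=bool)
    keep = np.zeros(len(weights), dtype=bool)
    window = params.window_kb * 1000.0
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        keep[i] = True
        near = np.flatnonzero(
            ~assigned & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        )
        if near.size:
            r2 = (U[:, near].T @ U[:, i]) ** 2
            assigned[near[r2 > params.r2_max]] = True
    return weights.take(np.flatnonzero(keep))


def threshold(weights: AlignedWeights, pt: float) -> AlignedWeights:
    """Subset to variants with p <= pT (inclusive)."""
    if weights.p is None:
        raise ValueError("thresholding requires p-values")
    return weights.take(weights.p <= pt)


def restrict_region(
    weights: AlignedWeights,
    genotypes: GenotypeMatrix,
    regions: RegionSet,
    mode: str = "exclude",
) -> AlignedWeights:
    """Keep (``include``) or drop (``exclude``) variants inside ``regions``;
    bounds are inclusive on both ends."""
    if mode not in ("include", "exclude"):
        raise ValueError(f"mode must be 'include' or 'exclude', got {mode!r}")
    vf = genotypes.variant_frame()
    chroms = vf["chrom"].to_numpy()[weights.index]
    pos = vf["pos"].to_numpy()[weights.index]
    member = regions.contains_mask(chroms, pos)
    return weights.take(member if mode == "include" else ~member)


def score(
    genotypes: GenotypeMatrix,
    weights: AlignedWeights,
    method: str = "C+T",
    region_mode: str = "full",
    pt: float | None = None,
) -> ScoreSet:
    """score_s = sum_j beta_j * dosage_sj, with missing dosages replaced by
    the variant's mean dosage over non-missing samples."""
    if len(weights) == 0:
        logger.warning("score: empty weight set, returning all-zero scores")
        return ScoreSet(
            samples=list(genotypes.samples),
            values=np.zeros(genotypes.n_samples),
            method=method,
            gwas_id=weights.gwas_id,
            region_mode=region_mode,
            pt=pt,
            n_snps=0,
        )
    D = genotypes.dosage[:, weights.index]
    if np.isnan(D).any():
        col_mean = np.nanmean(D, axis=0)
        n_imputed = int(np.isnan(D).any(axis=0).sum())
        logger.info("score: mean-imputed missing dosages in %d variant(s)", n_imputed)
        D = np.where(np.isnan(D), col_mean[None, :], D)
    values = D @ weights.beta
    return ScoreSet(
        samples=list(genotypes.samples),
        values=values,
        method=method,
        gwas_id=weights.gwas_id,
        region_mode=region_mode,
        pt=pt,
        n_snps=len(weights),
    )


def ct_pipeline(
    sumstats: SummaryStats,
    genotypes: GenotypeMatrix,
    params: ClumpParams | None = None,
    regions: RegionSet | None = None,
    region_mode: str = "full",
    drop_ambiguous: bool = True,
) -> list[ScoreSet]:
    """Clumping + thresholding: harmonize, optionally restrict to/from
    ``regions``, clump once, then score at every pT in the grid."""
    params = params or ClumpParams()
    aligned = harmonize(sumstats, genotypes, drop_ambiguous=drop_ambiguous)
    if regions is not None:
        mode = "include" if region_mode in ("APOEonly", "microglia", "include") else "exclude"
        aligned = restrict_region(aligned, genotypes, regions, mode=mode)
    clumped = clump(aligned, genotypes, params)
    out = []
    for pt in params.pt_grid:
        sub = threshold(clumped, pt)
        out.append(
            score(genotypes, sub, method="C+T", region_mode=region_mode, pt=pt)
        )
    return out


def external_scores(
    genotypes: GenotypeMatrix,
    weightfile: WeightFile,
    region_mode: str = "full",
    regions: RegionSet | None = None,
    drop_ambiguous: bool = True,
) -> ScoreSet:
    """Score externally supplied per-SNP weights (no clumping/thresholding)."""
    t = weightfile.table
    if len(t) == 0:
        raise ValueError("empty weight file")
    other = t["other_allele"] if "other_allele" in t.columns else None
    ss_table = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "pos": t["pos"],
            "id": t["id"],
            "effect_allele": t["effect_allele"],
            "other_allele": other if other is not None else "N",
            "beta": t["weight"],
            "se": 1.0,
            "p": 0.5,
        }
    )
    if other is None:
        # no other-allele column: infer it from the cohort so matching can proceed
        vf = genotypes.variant_frame()
        lookup = {(c, p): (r, a) for c, p, r, a in zip(vf["chrom"], vf["pos"], vf["ref"], vf["alt"])}
        inferred = []
        for c, p, ea in zip(ss_table["chrom"], ss_table["pos"], ss_table["effect_allele"]):
            ref, alt = lookup.get((c, p), ("N", "N"))
            inferred.append(ref if ea == alt else alt)
        ss_table["other_allele"] = inferred
    ss = SummaryStats(table=ss_table, gwas_id=weightfile.method)
    aligned = harmonize(ss, genotypes, drop_ambiguous=drop_ambiguous)
    if regions is not None:
        mode = "include" if region_mode in ("APOEonly", "microglia", "include") else "exclude"
        aligned = restrict_region(aligned, genotypes, regions, mode=mode)
    return score(genotypes, aligned, method=weightfile.method, region_mode=region_mode)
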