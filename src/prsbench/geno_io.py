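"""Readers/writers for the on-disk formats the pipeline touches.

Internal conventions, enforced at every boundary:

* chromosome labels are normalized strings: no ``chr`` prefix, ``M``/``MT``
  unified to ``MT``;
* positions are 1-based; region intervals are 1-based **inclusive** on both
  ends (only the BED reader converts from 0-based half-open);
* dosages live in ``[0, 2]`` with missingness as ``NaN`` (never a sentinel);
* only biallelic SNPs are supported — multi-allelic records are rejected,
  indels dropped with logged counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SNP_ALLELES = frozenset("ACGT")

#: Columns a summary-statistics table must provide (after column mapping).
SUMSTATS_REQUIRED = ("chrom", "pos", "id", "effect_allele", "other_allele", "beta", "se", "p")
SUMSTATS_OPTIONAL = ("freq", "n", "info")

WEIGHTS_REQUIRED = ("chrom", "pos", "id", "effect_allele", "weight")


def normalize_chrom(label) -> str:
    """Strip any ``chr`` prefix and unify mitochondrial labels to ``MT``."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in ("M", "MT"):
        return "MT"
    return s


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic site with normalized coordinates."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    info_score: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos} at {self.id}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.info_score is not None and not (0.0 <= self.info_score <= 1.0):
            raise ValueError(f"INFO score {self.info_score} outside [0,1] at {self.id}")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix (0..2, NaN = missing) plus metadata."""

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray  # shape (n_samples, n_variants), float, NaN missing

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        present = self.dosage[~np.isnan(self.dosage)]
        if present.size and (present.min() < 0 or present.max() > 2):
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_frame(self) -> pd.DataFrame:
        """Variant metadata as a DataFrame (chrom, pos, id, ref, alt, info_score)."""
        return pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "id": [v.id for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "info_score": [v.info_score for v in self.variants],
            }
        )

    def subset_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            dosage=self.dosage[:, idx],
        )

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=list(self.variants),
            dosage=self.dosage[idx, :],
        )


@dataclass
class SummaryStats:
    """Per-variant GWAS effects: signed beta on the effect allele, SE, p."""

    table: pd.DataFrame
    gwas_id: str = "gwas"

    def __post_init__(self):
        missing = [c for c in SUMSTATS_REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        self.table["chrom"] = self.table["chrom"].map(normalize_chrom)

    def __len__(self) -> int:
        return len(self.table)

    @staticmethod
    def validate_rows(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
        """Drop rows violating invariants; return (clean table, removal counts)."""
        counts = {}
        t = table.copy()
        n0 = len(t)
        ok = np.isfinite(t["beta"]) & np.isfinite(t["se"]) & (t["se"] > 0)
        counts["bad_se_or_beta"] = int(n0 - ok.sum())
        t = t[ok]
        ok = (t["p"] > 0) & (t["p"] <= 1)
        counts["bad_p"] = int(len(t) - ok.sum())
        t = t[ok]
        ok = t["effect_allele"] != t["other_allele"]
        counts["identical_alleles"] = int(len(t) - ok.sum())
        t = t[ok]
        snp = t["effect_allele"].isin(_SNP_ALLELES) & t["other_allele"].isin(_SNP_ALLELES)
        counts["non_snp"] = int(len(t) - snp.sum())
        t = t[snp]
        return t.reset_index(drop=True), counts


@dataclass
class RegionSet:
    """Sorted, merged, non-overlapping 1-based inclusive intervals."""

    regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        cleaned = []
        for chrom, start, end in self.regions:
            if start > end:
                raise ValueError(f"region start {start} > end {end} on {chrom}")
            cleaned.append((normalize_chrom(chrom), int(start), int(end)))
        self.regions = _merge_regions(cleaned)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def contains(self, chrom, pos: int) -> bool:
        chrom = normalize_chrom(chrom)
        return any(c == chrom and s <= pos <= e for c, s, e in self.regions)

    def contains_mask(self, chroms, positions) -> np.ndarray:
        """Vectorized membership for parallel chrom/pos arrays."""
        chroms = [normalize_chrom(c) for c in chroms]
        positions = np.asarray(positions)
        mask = np.zeros(len(positions), dtype=bool)
        for c, s, e in self.regions:
            sel = np.array([cc == c for cc in chroms])
            mask |= sel & (positions >= s) & (positions <= e)
        return mask

    def variant_fraction(self, chroms, positions) -> float:
        mask = self.contains_mask(chroms, positions)
        return float(mask.mean()) if len(mask) else 0.0


def _merge_regions(regions):
    out = []
    for chrom, start, end in sorted(regions, key=lambda r: (r[0], r[1], r[2])):
        if out and out[-1][0] == chrom and start <= out[-1][2] + 1:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
        else:
            out.append((chrom, start, end))
    return out


@dataclass
class WeightFile:
    """Externally derived per-SNP weights (e.g. shrinkage-posterior effects)."""

    table: pd.DataFrame
    method: str = "external"

    def __post_init__(self):
        missing = [c for c in WEIGHTS_REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"weight file missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        self.table["chrom"] = self.table["chrom"].map(normalize_chrom)
        self.table["weight"] = self.table["weight"].astype(float)
        if not np.isfinite(self.table["weight"]).all():
            raise ValueError("non-finite weights in weight file")
        bad = ~(
            self.table["effect_allele"].isin(_SNP_ALLELES)
        )
        if bad.any():
            raise ValueError(
                f"unknown allele code(s) in weight file: "
                f"{sorted(self.table.loc[bad, 'effect_allele'].unique())}"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic VCF 4.x into a GenotypeMatrix.

    Dosage comes from the ``DS`` FORMAT field when present, otherwise from the
    GT alternate-allele count; a missing GT yields NaN. Multi-allelic records
    are rejected with their location; indels are dropped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants, columns = [], []
    n_indels = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} not supported"
            )
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            n_indels += 1
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            gts = rec.genotype.array()  # rows: (a1, a2, phased)
            a = gts[:, :2].astype(float)
            a[a < 0] = np.nan
            col = a.sum(axis=1)
        info = rec.INFO.get("INFO", None)
        variants.append(
            VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                id=rec.ID or f"{normalize_chrom(rec.CHROM)}:{rec.POS}",
                ref=ref,
                alt=alt,
                info_score=float(info) if info is not None else None,
            )
        )
        columns.append(col)
    if n_indels:
        logger.info("read_vcf: dropped %d indel record(s)", n_indels)
    dosage = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF with GT and DS fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation accuracy">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        chroms = sorted({v.chrom for v in gm.variants})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        order = sorted(range(gm.n_variants), key=lambda j: (gm.variants[j].chrom, gm.variants[j].pos))
        for j in order:
            v = gm.variants[j]
            info = f"INFO={v.info_score:.4f}" if v.info_score is not None else "."
            cells = []
            for d in gm.dosage[:, j]:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    hard = int(round(d))
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[hard]
                    cells.append(f"{gt}:{d:.10g}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t{info}\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Summary statistics / weights / regions / tables
# ---------------------------------------------------------------------------

def read_sumstats(path, column_map: dict | None = None, gwas_id: str = "gwas") -> SummaryStats:
    """Read a tab-separated summary-statistics file.

    ``column_map`` maps internal names (chrom, pos, id, effect_allele,
    other_allele, beta, se, p, and optionally freq/n/info) to the file's
    column headers. Rows violating invariants (p outside (0,1], se <= 0,
    identical alleles, non-SNP alleles) are dropped with counts logged.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"#CHROM": str})
    column_map = column_map or {k: k for k in SUMSTATS_REQUIRED}
    missing = [v for k, v in column_map.items() if k in SUMSTATS_REQUIRED and v not in raw.columns]
    if missing:
        raise ValueError(f"summary statistics file lacks required column(s): {missing}")
    table = pd.DataFrame()
    for internal in SUMSTATS_REQUIRED + SUMSTATS_OPTIONAL:
        src = column_map.get(internal, internal)
        if src in raw.columns:
            table[internal] = raw[src]
    table["chrom"] = table["chrom"].astype(str)
    table["pos"] = table["pos"].astype(int)
    clean, counts = SummaryStats.validate_rows(table)
    dropped = sum(counts.values())
    if dropped:
        logger.info("read_sumstats(%s): dropped %d row(s): %s", path, dropped, counts)
    return SummaryStats(table=clean, gwas_id=gwas_id)


def write_sumstats(ss: SummaryStats, path) -> None:
    ss.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_bed(path) -> RegionSet:
    """Read BED3+ (0-based half-open) into internal 1-based inclusive regions."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: BED end {end} <= start {start}")
            regions.append((chrom, start + 1, end))
    return RegionSet(regions=regions)


def write_bed(rs: RegionSet, path) -> None:
    """Write regions as BED3 (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in rs.regions:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def read_weights(path, method: str = "external") -> WeightFile:
    table = pd.read_csv(path, sep="\t")
    table["chrom"] = table["chrom"].astype(str)
    return WeightFile(table=table, method=method)


def write_weights(wf: WeightFile, path) -> None:
    wf.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    """Generic TSV-with-header reader (scores, covariates, reports)."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
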