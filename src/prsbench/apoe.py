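"""APOE epsilon2/epsilon4 allele counting and diplotype calling.

The APOE diplotype is determined by two coding SNPs: the rs429358-role site
(alternate allele defines epsilon4) and the rs7412-role site (alternate allele
defines epsilon2). Unphased dosages at the two sites give additive allele
counts; the double heterozygote is phase-ambiguous (epsilon2/epsilon4 vs the
rare epsilon1/epsilon3) and is counted as (1, 1) with an ambiguity flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geno_io import RegionSet

#: chr19 interval (GRCh38), 1-based inclusive, that the region-restricted
#: scores exclude or isolate.
APOE_REGION_START = 43_900_000
APOE_REGION_END = 46_000_000

# dosage bands in which a fractional imputed call is deemed too uncertain
_GUARD_BANDS = ((0.4, 0.6), (1.4, 1.6))


@dataclass(frozen=True)
class ApoeCall:
    n_e2: int
    n_e4: int
    diplotype: str
    ambiguous: bool = False
    failed: bool = False

    def __post_init__(self):
        if not self.failed and self.n_e2 + self.n_e4 > 2:
            raise ValueError(f"impossible allele counts e2={self.n_e2}, e4={self.n_e4}")


def _hard_call(dosage: float) -> int | None:
    """Nearest-integer call; None inside the uncertainty guard bands or NaN."""
    if np.isnan(dosage):
        return None
    if not 0.0 <= dosage <= 2.0:
        raise ValueError(f"dosage {dosage} outside [0, 2]")
    for lo, hi in _GUARD_BANDS:
        if lo < dosage < hi:
            return None
    return int(round(dosage))


_DIPLOTYPE = {
    (0, 0): "e3e3",
    (1, 0): "e2e3",
    (2, 0): "e2e2",
    (0, 1): "e3e4",
    (0, 2): "e4e4",
    (1, 1): "e2e4/ambiguous",
}


def apoe_call(dos_e4: float, dos_e2: float) -> ApoeCall:
    """Call epsilon2/epsilon4 counts from the two defining-site alt dosages.

    ``dos_e4`` is the alternate-allele dosage at the rs429358-role site,
    ``dos_e2`` at the rs7412-role site. Returns a failed call (excluded from
    APOE-dependent models) if either dosage falls in the fractional guard band.
    """
    c4 = _hard_call(dos_e4)
    c2 = _hard_call(dos_e2)
    if c4 is None or c2 is None:
        return ApoeCall(n_e2=0, n_e4=0, diplotype="failed", failed=True)
    if c2 + c4 > 2:
        # two haplotypes cannot carry >2 defining alleles under the e1-free model
        return ApoeCall(n_e2=0, n_e4=0, diplotype="failed", failed=True)
    ambiguous = c2 == 1 and c4 == 1
    label = _DIPLOTYPE.get((c2, c4), f"e2x{c2}_e4x{c4}")
    return ApoeCall(n_e2=c2, n_e4=c4, diplotype=label, ambiguous=ambiguous)


def call_cohort(dos_e4: np.ndarray, dos_e2: np.ndarray) -> list[ApoeCall]:
    """Vector convenience: one ApoeCall per sample."""
    return [apoe_call(a, b) for a, b in zip(np.asarray(dos_e4, float), np.asarray(dos_e2, float))]


def e33_mask(calls) -> np.ndarray:
    """True for samples with the reference epsilon3/epsilon3 diplotype."""
    return np.array([(not c.failed) and c.n_e2 == 0 and c.n_e4 == 0 for c in calls])


def apoe_region() -> RegionSet:
    """The fixed chr19 APOE interval used for region-restricted scoring."""
    return RegionSet(regions=[("19", APOE_REGION_START, APOE_REGION_END)])
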