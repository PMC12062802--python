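"""Single-locus population-genetics summaries.

Per locus: allele and genotype frequencies, the chi-square goodness-of-fit
test against Hardy-Weinberg proportions, and the classical marker-diversity
indices — expected homozygosity Ho = p² + q², expected heterozygosity
He = 1 − Ho, effective allele number Ne = 1/Ho, and Botstein's polymorphic
information content, which for a biallelic locus reduces to

    PIC = 1 − (p² + q²) − 2 p² q²  =  He − 2 p² q².

Two degrees-of-freedom conventions are supported for the HWE test: the
``standard`` biallelic convention (df = 1: three genotype classes minus one
estimated allele frequency minus one) and the ``paper`` convention
(df = 2: genotype classes minus one), common in livestock candidate-gene
reports.  The latter is the default so that published tables using it
reproduce verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GenotypeMatrix, SnpLocus

__all__ = [
    "GenotypeCounts",
    "AlleleStats",
    "DiversityIndices",
    "HweResult",
    "summarize_locus",
    "diversity_indices",
    "pic_botstein",
    "hwe_test",
    "counts_from_matrix",
    "locus_summary_table",
    "pic_class",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed tables conventionally do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GenotypeCounts:
    locus: SnpLocus
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        for c in (self.n_hom_ref, self.n_het, self.n_hom_alt):
            if c < 0 or int(c) != c:
                raise ValueError("genotype counts must be non-negative integers")
        if self.n == 0:
            raise ValueError(f"locus {self.locus.locus_id!r}: no genotyped individuals")

    @property
    def n(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_hom_ref, self.n_het, self.n_hom_alt)


@dataclass(frozen=True)
class AlleleStats:
    """Ref-allele frequency p (q = 1 − p derived) and genotype frequencies."""

    counts: GenotypeCounts
    p: float
    genotype_freqs: tuple[float, float, float]

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass(frozen=True)
class DiversityIndices:
    Ho: float
    He: float
    Ne: float
    PIC: float


@dataclass(frozen=True)
class HweResult:
    chi2: float
    df: int
    p_value: float
    expected: tuple[float, float, float]


def summarize_locus(counts: GenotypeCounts) -> AlleleStats:
    """Allele and genotype frequencies computed directly from counts."""
    n = counts.n
    p = (2 * counts.n_hom_ref + counts.n_het) / (2 * n)
    freqs = tuple(c / n for c in counts.as_tuple())
    return AlleleStats(counts, p, freqs)


def pic_botstein(allele_freqs: np.ndarray | list[float]) -> float:
    """Botstein's polymorphic information content for k alleles.

    PIC = 1 − Σ pᵢ² − Σ_{i<j} 2 pᵢ² pⱼ².  For k = 2 this is He − 2p²q².
    """
    f = np.asarray(allele_freqs, dtype=float)
    if not np.isclose(f.sum(), 1.0, atol=1e-9):
        raise ValueError("allele frequencies must sum to 1")
    sq = f**2
    cross = (sq.sum() ** 2 - (sq**2).sum()) / 2.0
    return float(1.0 - sq.sum() - 2.0 * cross)


def diversity_indices(stats_: AlleleStats | float) -> DiversityIndices:
    """Ho/He/Ne/PIC from allele frequencies (biallelic).

    Accepts an :class:`AlleleStats` or the ref-allele frequency directly.
    A monomorphic locus gives Ho = 1, He = 0, Ne = 1, PIC = 0.
    """
    p = stats_.p if isinstance(stats_, AlleleStats) else float(stats_)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    q = 1.0 - p
    ho = p * p + q * q
    return DiversityIndices(Ho=ho, He=1.0 - ho, Ne=1.0 / ho, PIC=pic_botstein([p, q]))


def hwe_test(counts: GenotypeCounts, df_mode: str = "paper") -> HweResult:
    """Chi-square goodness-of-fit test against Hardy-Weinberg proportions.

    Expected counts are (n p², 2 n p q, n q²) at the observed allele
    frequency; the statistic is the plain Pearson chi-square over the three
    genotype classes (no continuity correction).  ``df_mode="paper"`` uses
    df = 2, ``"standard"`` df = 1.
    """
    if df_mode not in {"paper", "standard"}:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    st = summarize_locus(counts)
    p, q, n = st.p, st.q, counts.n
    if p in (0.0, 1.0):
        raise ValueError(
            f"locus {counts.locus.locus_id!r} is monomorphic; HWE test degenerate"
        )
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts.as_tuple(), expected))
    df = 2 if df_mode == "paper" else 1
    return HweResult(chi2, df, float(stats.chi2.sf(chi2, df)), expected)


def counts_from_matrix(matrix: GenotypeMatrix, locus: str | SnpLocus) -> GenotypeCounts:
    """Tally genotype classes at one locus, dropping missing calls."""
    j = matrix.locus_index(locus)
    col = matrix.dosage[:, j]
    col = col[col != MISSING]
    return GenotypeCounts(
        matrix.loci[j],
        int(np.sum(col == 0)),
        int(np.sum(col == 1)),
        int(np.sum(col == 2)),
    )


def pic_class(pic: float) -> str:
    """Marker-informativeness class: low < 0.25 ≤ moderate ≤ 0.50 < high."""
    if pic < 0.25:
        return "low"
    if pic <= 0.50:
        return "moderate"
    return "high"


def locus_summary_table(
    matrix: GenotypeMatrix, df_mode: str = "paper", ndigits: int | None = 2
) -> pd.DataFrame:
    """One row per locus with counts, frequencies, HWE test and diversity
    indices; the layout of a standard marker-characterisation table.

    ``ndigits`` rounds report columns half-up; ``None`` keeps full precision.
    Observed heterozygosity is included as an extra diagnostic column.
    """
    rows = []
    rnd = (lambda x: round_half_up(x, ndigits)) if ndigits is not None else (lambda x: x)
    for locus in matrix.loci:
        c = counts_from_matrix(matrix, locus)
        st = summarize_locus(c)
        div = diversity_indices(st)
        hwe = hwe_test(c, df_mode=df_mode)
        r, a = locus.ref_allele, locus.alt_allele
        rows.append(
            {
                "locus": locus.locus_id,
                "genotypes": f"{r}{r}/{r}{a}/{a}{a}",
                "n_hom_ref": c.n_hom_ref,
                "n_het": c.n_het,
                "n_hom_alt": c.n_hom_alt,
                "freq_hom_ref": rnd(st.genotype_freqs[0]),
                "freq_het": rnd(st.genotype_freqs[1]),
                "freq_hom_alt": rnd(st.genotype_freqs[2]),
                "alleles": f"{r}/{a}",
                "freq_ref": rnd(st.p),
                "freq_alt": rnd(st.q),
                "chi2": rnd(hwe.chi2),
                "p_value": rnd(hwe.p_value),
                "Ho": rnd(div.Ho),
                "He": rnd(div.He),
                "Ne": rnd(div.Ne),
                "PIC": rnd(div.PIC),
                "PIC_class": pic_class(div.PIC),
                "obs_het": rnd(c.n_het / c.n),
            }
        )
    return pd.DataFrame(rows)
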