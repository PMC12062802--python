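"""Data model and plain-text I/O for genotype and trait tables.

The native genotype format is a delimited table (TSV by default) with columns
``individual_id``, ``sex``, then one column per SNP locus holding the genotype
as a two-letter allele pair (``TT``, ``TC`` ...; ``CT`` and ``TC`` are the same
heterozygote).  Missing genotypes may be written ``NA``, ``./.``, ``--`` or
left blank.  Trait tables are delimited numeric tables with the individual id
in the first column.

Internally genotypes are stored as alt-allele dosage (0/1/2, -1 for missing)
against each locus's declared ref/alt alleles.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "SnpLocus",
    "GenotypeMatrix",
    "TraitTable",
    "GenotypeParseError",
    "TraitParseError",
    "read_genotype_table",
    "write_genotype_table",
    "read_trait_table",
    "write_trait_table",
    "read_vcf",
]

VALID_BASES = frozenset("ACGT")
MISSING_CODES = frozenset({"", "NA", "N/A", "./.", ".|.", "--", ".", "NAN"})
MISSING = -1

_SEX_SYNONYMS = {
    "male": "male", "m": "male", "1": "male",
    "female": "female", "f": "female", "2": "female",
}

# locus labels like "g.18413T>C" carry their ref/alt alleles in the suffix
_REF_ALT_SUFFIX = re.compile(r"([ACGT])>([ACGT])$")


class GenotypeParseError(ValueError):
    """Raised when a genotype table cell or header cannot be interpreted."""


class TraitParseError(ValueError):
    """Raised when a trait table cell cannot be coerced to a number."""


@dataclass(frozen=True)
class SnpLocus:
    """A biallelic SNP locus identified by an opaque label.

    Positions are never used numerically; the label (e.g. ``g.18413T>C``)
    is only an identifier, though ref/alt can be recovered from an
    HGVS-like ``REF>ALT`` suffix when present.
    """

    locus_id: str
    ref_allele: str
    alt_allele: str
    region: str = "unknown"

    def __post_init__(self) -> None:
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(
                f"locus {self.locus_id!r}: alleles must be in A/C/G/T, "
                f"got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"locus {self.locus_id!r}: ref and alt alleles are equal")
        if self.region not in {"exon", "intron", "promoter", "unknown"}:
            raise ValueError(f"locus {self.locus_id!r}: unknown region {self.region!r}")

    @classmethod
    def from_label(cls, label: str, region: str = "unknown") -> "SnpLocus":
        """Build a locus from a label with a ``REF>ALT`` suffix."""
        m = _REF_ALT_SUFFIX.search(label.replace(" ", ""))
        if m is None:
            raise GenotypeParseError(
                f"cannot infer ref/alt alleles from locus label {label!r}; "
                "declare the locus explicitly"
            )
        return cls(label, m.group(1), m.group(2), region)

    def genotype_string(self, dosage: int) -> str:
        if dosage == MISSING:
            return "NA"
        if dosage == 0:
            return self.ref_allele * 2
        if dosage == 1:
            return self.ref_allele + self.alt_allele
        if dosage == 2:
            return self.alt_allele * 2
        raise ValueError(f"invalid dosage {dosage}")


def _normalize_sex(raw: str, row: object) -> str:
    try:
        return _SEX_SYNONYMS[str(raw).strip().lower()]
    except KeyError:
        raise GenotypeParseError(
            f"row {row!r}: sex value {raw!r} not recognized "
            "(expected male/female or a synonym)"
        ) from None


@dataclass
class GenotypeMatrix:
    """Unphased genotypes of a cohort: individuals x biallelic SNP loci.

    ``dosage[i, j]`` is the alt-allele count of individual ``i`` at locus
    ``j`` (0, 1, 2), or -1 for a missing call.
    """

    loci: list[SnpLocus]
    individual_ids: list[str]
    sex: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, L = len(self.individual_ids), len(self.loci)
        if self.dosage.shape != (n, L):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != ({n} individuals, {L} loci)"
            )
        if len(self.sex) != n:
            raise ValueError("sex must be given for every individual")
        bad = set(self.sex) - {"male", "female"}
        if bad:
            raise ValueError(f"invalid sex values: {sorted(bad)}")
        if len(set(self.individual_ids)) != n:
            seen, dups = set(), set()
            for iid in self.individual_ids:
                (dups if iid in seen else seen).add(iid)
            raise ValueError(f"duplicate individual ids: {sorted(dups)}")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != L:
            raise ValueError("duplicate locus ids")
        vals = np.unique(self.dosage)
        if not np.all(np.isin(vals, [-1, 0, 1, 2])):
            raise ValueError(f"invalid dosage values {vals}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def locus_index(self, locus: str | SnpLocus) -> int:
        lid = locus.locus_id if isinstance(locus, SnpLocus) else locus
        try:
            return self.locus_ids.index(lid)
        except ValueError:
            raise KeyError(f"locus {lid!r} not in matrix") from None

    def sex_indicator(self) -> np.ndarray:
        """1 for male, 0 for female, per individual."""
        return np.array([1 if s == "male" else 0 for s in self.sex], dtype=int)

    def complete_rows(self, locus_indices: Sequence[int] | None = None) -> np.ndarray:
        """Boolean mask of individuals fully called at the given loci."""
        idx = range(self.n_loci) if locus_indices is None else locus_indices
        sub = self.dosage[:, list(idx)]
        return np.all(sub != MISSING, axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"individual_id": self.individual_ids, "sex": self.sex}
        for j, locus in enumerate(self.loci):
            data[locus.locus_id] = [
                locus.genotype_string(int(d)) for d in self.dosage[:, j]
            ]
        return pd.DataFrame(data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.individual_ids == other.individual_ids
            and self.sex == other.sex
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class TraitTable:
    """Continuous trait measurements per individual.

    Wraps a float DataFrame indexed by individual id, one column per trait,
    with an optional unit tag per trait (parsed from a parenthesised suffix
    in the column name, e.g. ``Live weight (kg)``).
    """

    values: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate individual ids in trait table")
        self.values = self.values.astype(float)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.values.index)

    def trait(self, name: str) -> pd.Series:
        return self.values[name]

    def validate_against(self, genotypes: GenotypeMatrix) -> list[str]:
        """Cross-check against the companion genotype matrix.

        Returns human-readable warnings for individuals missing from the
        genotype matrix and for percentage traits outside [0, 100];
        non-finite (missing) cells are allowed.
        """
        warnings: list[str] = []
        known = set(genotypes.individual_ids)
        orphans = [i for i in self.individual_ids if i not in known]
        if orphans:
            warnings.append(
                f"{len(orphans)} individuals absent from genotype matrix: "
                + ", ".join(orphans[:5])
                + ("..." if len(orphans) > 5 else "")
            )
        for name in self.trait_names:
            if self.units.get(name) == "%":
                col = self.values[name].dropna()
                bad = col[(col < 0) | (col > 100)]
                if len(bad):
                    warnings.append(
                        f"trait {name!r}: {len(bad)} percentage values outside [0, 100]"
                    )
        return warnings


_UNIT_SUFFIX = re.compile(r"\s*\(([^)]+)\)\s*$")


def _split_unit(column: str) -> tuple[str, str | None]:
    m = _UNIT_SUFFIX.search(column)
    if m:
        return column[: m.start()].rstrip(), m.group(1)
    return column, None


import contextlib


@contextlib.contextmanager
def _as_text_stream(source: str | TextIO):
    """Yield a readable text stream; close it only if opened here."""
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            yield fh
    else:
        yield source


def read_genotype_table(
    source: str | TextIO,
    loci: Sequence[SnpLocus] | None = None,
    sep: str = "\t",
) -> GenotypeMatrix:
    """Read the native genotype table.

    If ``loci`` is not given, each locus column header must carry a
    ``REF>ALT`` suffix (e.g. ``g.18413T>C``) from which the alleles are
    inferred.  Heterozygote order is ignored (``TC`` == ``CT``).
    """
    with _as_text_stream(source) as fh:
        df = pd.read_csv(fh, sep=sep, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "individual_id" or cols[1] != "sex":
        raise GenotypeParseError(
            "expected header: individual_id, sex, then one column per locus; "
            f"got {cols[:3]}..."
        )
    locus_cols = cols[2:]
    if loci is None:
        loci = [SnpLocus.from_label(c) for c in locus_cols]
    else:
        loci = list(loci)
        by_id = {l.locus_id: l for l in loci}
        missing = [c for c in locus_cols if c not in by_id]
        if missing:
            raise GenotypeParseError(f"columns not among declared loci: {missing}")
        loci = [by_id[c] for c in locus_cols]

    ids = [str(x).strip() for x in df["individual_id"]]
    if len(set(ids)) != len(ids):
        raise GenotypeParseError("duplicate individual_id in genotype table")
    sex = [_normalize_sex(s, iid) for s, iid in zip(df["sex"], ids)]

    dosage = np.full((len(ids), len(loci)), MISSING, dtype=np.int8)
    for j, (col, locus) in enumerate(zip(locus_cols, loci)):
        alleles = {locus.ref_allele, locus.alt_allele}
        for i, raw in enumerate(df[col]):
            cell = str(raw).strip().upper()
            if cell in MISSING_CODES:
                continue
            if len(cell) != 2 or not set(cell) <= alleles:
                raise GenotypeParseError(
                    f"individual {ids[i]!r}, locus {col!r}: genotype {raw!r} "
                    f"is not a pair of {locus.ref_allele}/{locus.alt_allele} alleles"
                )
            dosage[i, j] = cell.count(locus.alt_allele)
    return GenotypeMatrix(loci, ids, sex, dosage)


def write_genotype_table(
    matrix: GenotypeMatrix, dest: str | TextIO, sep: str = "\t"
) -> None:
    df = matrix.to_dataframe()
    if isinstance(dest, str):
        df.to_csv(dest, sep=sep, index=False)
    else:
        df.to_csv(dest, sep=sep, index=False)


def read_trait_table(source: str | TextIO, sep: str = ",") -> TraitTable:
    """Read a delimited trait table (first column: individual id).

    Blank cells become missing values; any other non-numeric cell raises
    :class:`TraitParseError` naming its coordinates.
    """
    with _as_text_stream(source) as fh:
        df = pd.read_csv(fh, sep=sep, dtype=str, keep_default_na=False)
    if df.columns[0] != "individual_id":
        raise TraitParseError("first column must be individual_id")
    ids = [str(x).strip() for x in df["individual_id"]]
    if len(set(ids)) != len(ids):
        raise TraitParseError("duplicate individual_id in trait table")
    out: dict[str, list[float]] = {}
    units: dict[str, str] = {}
    for col in df.columns[1:]:
        name, unit = _split_unit(col)
        if unit is not None:
            units[name] = unit
        vals: list[float] = []
        for iid, raw in zip(ids, df[col]):
            cell = str(raw).strip()
            if cell == "" or cell.upper() in {"NA", "NAN"}:
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise TraitParseError(
                    f"individual {iid!r}, trait {col!r}: cell {raw!r} is not numeric"
                ) from None
        out[name] = vals
    values = pd.DataFrame(out, index=pd.Index(ids, name="individual_id"))
    return TraitTable(values, units)


def write_trait_table(table: TraitTable, dest: str | TextIO, sep: str = ",") -> None:
    df = table.values.copy()
    df.columns = [
        f"{c} ({table.units[c]})" if c in table.units else c for c in df.columns
    ]
    df.to_csv(dest, sep=sep, index=True)


def read_vcf(
    path: str,
    sex: Mapping[str, str],
    regions: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Ingest biallelic SNP records (GT field only) from a VCF file.

    ``sex`` maps each VCF sample name to male/female (synonyms accepted).
    Record IDs (or ``CHROM:POS`` when ID is missing) become locus labels.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(path)
    samples = list(vcf.samples)
    missing_sex = [s for s in samples if s not in sex]
    if missing_sex:
        raise GenotypeParseError(f"no sex given for VCF samples: {missing_sex}")
    loci: list[SnpLocus] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            continue
        label = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        region = (regions or {}).get(label, "unknown")
        loci.append(SnpLocus(label, rec.REF.upper(), rec.ALT[0].upper(), region))
        # gt_types: 0=hom_ref 1=het 2=unknown 3=hom_alt
        gt = rec.gt_types
        row = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING)))
        rows.append(row.astype(np.int8))
    if not loci:
        raise GenotypeParseError(f"no biallelic SNP records in {path}")
    dosage = np.stack(rows, axis=1)
    sexes = [_normalize_sex(sex[s], s) for s in samples]
    return GenotypeMatrix(loci, samples, sexes, dosage)
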