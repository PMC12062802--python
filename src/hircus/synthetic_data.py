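"""Synthetic goat-like cohorts for exercising the whole pipeline.

No individual-level data accompany the study this package emulates, so the
generator reproduces its printed *marginal* structure and nothing more:

* a cohort of 153 animals (78 male, 75 female) by default;
* four tightly linked biallelic SNPs in the HMGCS1 candidate gene, produced
  by random union of gametes drawn from a haplotype frequency table whose
  defaults are the two published haplotypes, CCCA (0.5759) and TGTG (0.4241),
  with a small ``leak`` of mass spread over recombinant haplotypes so that
  LD is strong but imperfect;
* sex-dimorphic Gaussian traits generated from the genotype-by-sex linear
  model, calibrated so the per-sex means and standard errors land on the
  published slaughter / meat-quality / organ-coefficient summaries.

Because haplotype pairs are drawn independently, the cohort satisfies
multi-locus Hardy-Weinberg equilibrium by construction.  Traits are
conditionally independent given sex and genotype, which understates the
correlations (e.g. live weight vs carcass weight) of real cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .association import build_design
from .core_io import GenotypeMatrix, SnpLocus, TraitTable, write_genotype_table, write_trait_table

__all__ = [
    "TraitModel",
    "SimConfig",
    "default_loci",
    "default_trait_models",
    "simulate_genotypes",
    "simulate_traits",
    "generate_study_fixture",
]


def default_loci() -> list[SnpLocus]:
    """The four HMGCS1 SNPs; wild-type allele as ref, mutant as alt."""
    return [
        SnpLocus("g.15523T>C", "T", "C", region="intron"),
        SnpLocus("g.15530G>C", "G", "C", region="intron"),
        SnpLocus("g.18413T>C", "T", "C", region="exon"),
        SnpLocus("g.19711G>A", "G", "A", region="intron"),
    ]


@dataclass
class TraitModel:
    """Generative model for one trait: identity- or log-link linear predictor
    over the genotype-by-sex dummies of one locus, plus Gaussian noise.

    ``betas`` maps model terms (G1, G2, S1, G1S1, G2S1) to effects; absent
    terms are zero.  ``bounds`` clips the simulated values to a physical
    range (percentages to [0, 100], weights to >= 0).
    """

    name: str
    unit: str = ""
    beta0: float = 0.0
    betas: dict[str, float] = field(default_factory=dict)
    sd: float = 1.0
    link: str = "identity"
    locus: str | None = None  # None -> first locus of the matrix
    bounds: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"trait {self.name!r}: residual SD must be >= 0")
        bad = set(self.betas) - {"G1", "G2", "S1", "G1S1", "G2S1"}
        if bad:
            raise ValueError(f"trait {self.name!r}: unknown terms {sorted(bad)}")
        if self.link not in {"identity", "log"}:
            raise ValueError(f"trait {self.name!r}: unknown link {self.link!r}")


# Published per-sex summaries (male mean, male SE, female mean, female SE)
# used to calibrate the default trait models.  The printed dispersions are
# standard errors of the mean; residual SDs are recovered as SE * sqrt(n).
_TRAIT_CALIBRATION: dict[str, tuple[str, float, float, float, float]] = {
    "Live weight": ("kg", 37.13, 0.55, 29.86, 0.58),
    "Carcass weight": ("kg", 16.37, 0.25, 12.23, 0.26),
    "Dressing percentage": ("%", 44.12, 0.43, 41.07, 0.45),
    "Net meat weight": ("kg", 12.71, 0.24, 8.98, 0.25),
    "Net meat percentage": ("%", 34.16, 0.46, 30.12, 0.49),
    "Carcass net meat rate": ("%", 77.38, 0.78, 73.28, 0.82),
    "Loin eye muscle area": ("cm2", 10.15, 0.28, 9.90, 0.29),
    "GR value": ("mm", 7.29, 0.20, 6.39, 0.21),
    "Back fat thickness": ("cm", 0.71, 0.02, 0.63, 0.02),
    "Tail weight": ("g", 29.07, 0.43, 22.41, 0.45),
    "Meat color L": ("", 28.82, 0.24, 28.74, 0.25),
    "Meat color A": ("", 9.23, 0.08, 9.16, 0.08),
    "Meat color B": ("", 7.09, 0.08, 7.15, 0.08),
    "pH value 45min": ("pH", 7.04, 0.05, 6.87, 0.05),
    "Dry matter": ("%", 25.20, 0.27, 26.32, 0.28),
    "Protein content": ("%", 21.33, 0.22, 22.09, 0.23),
    "Fat content": ("%", 6.31, 0.16, 6.43, 0.17),
    "Drip loss rate": ("%", 1.52, 0.08, 1.53, 0.09),
    "Cooked meat rate": ("%", 62.39, 0.62, 60.68, 0.65),
    "Shear force": ("N", 90.67, 1.84, 86.50, 1.94),
    "Heart coefficient": ("%", 0.56, 0.02, 0.47, 0.02),
    "Liver coefficient": ("%", 1.89, 0.03, 1.58, 0.03),
    "Spleen coefficient": ("%", 0.17, 0.01, 0.18, 0.01),
    "Lung coefficient": ("%", 1.30, 0.02, 1.41, 0.02),
    "Kidney coefficient": ("%", 0.36, 0.01, 0.37, 0.01),
    "Small intestine coefficient": ("%", 1.63, 0.03, 1.54, 0.03),
    "Large intestine coefficient": ("%", 1.97, 0.06, 2.39, 0.06),
    "Stomach coefficient": ("%", 4.19, 0.06, 4.50, 0.07),
    "Head coefficient": ("%", 6.94, 0.08, 6.63, 0.09),
    "Hoof coefficient": ("%", 2.47, 0.05, 2.03, 0.05),
}


def default_trait_models(n_male: int = 78, n_female: int = 75) -> list[TraitModel]:
    """Sex-dimorphic models for every published trait: intercept at the
    female mean, a sex effect equal to the male-female difference, no
    genotype effects by default, residual SD recovered from the printed
    standard errors."""
    models = []
    for name, (unit, m_mean, m_se, f_mean, f_se) in _TRAIT_CALIBRATION.items():
        sd = 0.5 * (m_se * np.sqrt(n_male) + f_se * np.sqrt(n_female))
        lo = 0.0
        hi = 100.0 if unit == "%" else (14.0 if unit == "pH" else None)
        models.append(
            TraitModel(
                name,
                unit=unit,
                beta0=f_mean,
                betas={"S1": m_mean - f_mean},
                sd=float(sd),
                bounds=(lo, hi),
            )
        )
    return models


@dataclass
class SimConfig:
    """Full generative description of a synthetic cohort."""

    n_male: int = 78
    n_female: int = 75
    loci: list[SnpLocus] = field(default_factory=default_loci)
    haplotypes: dict[str, float] = field(
        default_factory=lambda: {"CCCA": 0.5759, "TGTG": 0.4241}
    )
    leak: float = 0.02
    trait_models: list[TraitModel] = field(default_factory=default_trait_models)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0 or self.n_individuals == 0:
            raise ValueError("need a positive number of individuals")
        if not 0.0 <= self.leak < 1.0:
            raise ValueError("leak must be in [0, 1)")
        total = sum(self.haplotypes.values())
        if total <= 0:
            raise ValueError("haplotype frequencies must carry positive mass")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("named haplotype frequencies must sum to 1")
        alleles_ok = all(
            len(h) == len(self.loci)
            and all(c in (l.ref_allele, l.alt_allele) for c, l in zip(h, self.loci))
            for h in self.haplotypes
        )
        if not alleles_ok:
            raise ValueError("haplotype strings must use each locus's two alleles")
        known = {l.locus_id for l in self.loci}
        for tm in self.trait_models:
            if tm.locus is not None and tm.locus not in known:
                raise ValueError(f"trait {tm.name!r} references unknown locus {tm.locus!r}")

    @property
    def n_individuals(self) -> int:
        return self.n_male + self.n_female

    def haplotype_distribution(self) -> tuple[list[tuple[int, ...]], np.ndarray]:
        """Full 2^L haplotype space with the named mass scaled by (1-leak)
        and the leak spread uniformly over the remaining haplotypes."""
        import itertools

        L = len(self.loci)
        space = [tuple(h) for h in itertools.product((0, 1), repeat=L)]
        named = {}
        for s, fr in self.haplotypes.items():
            key = tuple(int(c == l.alt_allele) for c, l in zip(s, self.loci))
            named[key] = named.get(key, 0.0) + fr
        freqs = np.zeros(len(space))
        others = [i for i, h in enumerate(space) if h not in named]
        for i, h in enumerate(space):
            if h in named:
                freqs[i] = named[h] * (1.0 - self.leak)
        if others and self.leak > 0:
            freqs[others] = self.leak / len(others)
        elif not others:
            freqs /= freqs.sum()
        return space, freqs / freqs.sum()

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loci"] = [dataclasses.asdict(l) for l in self.loci]
        d["trait_models"] = [dataclasses.asdict(t) for t in self.trait_models]
        for t in d["trait_models"]:
            t["bounds"] = list(t["bounds"])
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "loci" in d:
            d["loci"] = [SnpLocus(**l) for l in d["loci"]]
        if "trait_models" in d:
            tms = []
            for t in d["trait_models"]:
                t = dict(t)
                if "bounds" in t:
                    t["bounds"] = tuple(t["bounds"])
                tms.append(TraitModel(**t))
            d["trait_models"] = tms
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def simulate_genotypes(config: SimConfig, seed: int | None = None) -> GenotypeMatrix:
    """Draw two gametes per individual from the haplotype distribution and
    project to unphased genotypes; deterministic under a fixed seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    space, freqs = config.haplotype_distribution()
    n = config.n_individuals
    picks = rng.choice(len(space), size=(n, 2), p=freqs)
    H = np.asarray(space, dtype=np.int8)
    dosage = H[picks[:, 0]] + H[picks[:, 1]]
    width = len(str(n))
    ids = [f"GWG{str(i + 1).zfill(width)}" for i in range(n)]
    sex = ["male"] * config.n_male + ["female"] * config.n_female
    return GenotypeMatrix(list(config.loci), ids, sex, dosage)


def simulate_traits(
    genotypes: GenotypeMatrix, config: SimConfig, seed: int | None = None
) -> TraitTable:
    """Traits from the genotype-by-sex linear model plus Gaussian noise.

    The trait's locus supplies the genotype dummies (wild-type homozygote
    as reference); values are clipped to the trait's physical bounds.
    """
    base = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([base & 0x7FFFFFFF, 7]))
    s1 = genotypes.sex_indicator()
    cols: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for tm in config.trait_models:
        j = genotypes.locus_index(tm.locus) if tm.locus else 0
        dos = genotypes.dosage[:, j]
        eta = np.full(genotypes.n_individuals, tm.beta0, dtype=float)
        for i in range(genotypes.n_individuals):
            if dos[i] < 0:
                eta[i] = np.nan
                continue
            row = build_design(int(dos[i]), int(s1[i]))
            eta[i] += sum(coef * row[term] for term, coef in tm.betas.items())
        mu = np.exp(eta) if tm.link == "log" else eta
        vals = mu + rng.normal(0.0, tm.sd, size=len(mu))
        lo, hi = tm.bounds
        vals = np.clip(vals, lo if lo is not None else -np.inf,
                       hi if hi is not None else np.inf)
        cols[tm.name] = vals
        if tm.unit:
            units[tm.name] = tm.unit
    values = pd.DataFrame(cols, index=pd.Index(genotypes.individual_ids,
                                               name="individual_id"))
    return TraitTable(values, units)


def generate_study_fixture(
    seed: int = 0,
    config: SimConfig | None = None,
    out_dir: str | None = None,
) -> tuple[GenotypeMatrix, TraitTable]:
    """A full default cohort (genotypes + all published traits), optionally
    written to ``out_dir`` as genotypes.tsv / traits.csv / config.yaml."""
    config = config or SimConfig(seed=seed)
    gm = simulate_genotypes(config, seed=seed)
    traits = simulate_traits(gm, config, seed=seed)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_genotype_table(gm, os.path.join(out_dir, "genotypes.tsv"))
        write_trait_table(traits, os.path.join(out_dir, "traits.csv"))
        cfg = dataclasses.replace(config, seed=seed)
        cfg.to_yaml(os.path.join(out_dir, "config.yaml"))
    return gm, traits
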