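"""EM haplotype-frequency estimation, pairwise LD, and diplotype assignment.

Haplotype frequencies are estimated from unphased multi-locus genotypes by
expectation-maximization over the full 2^L haplotype space, assuming random
union of gametes (the multi-locus Hardy-Weinberg assumption): the probability
of an ordered haplotype pair (h1, h2) is f(h1)·f(h2).  The E-step distributes
each individual's genotype over the haplotype pairs consistent with it; the
M-step re-estimates frequencies by expected gamete counting.  Initialization
is the deterministic linkage-equilibrium start (product of single-locus allele
frequencies); seeded random restarts are available as a safeguard.

Pairwise linkage disequilibrium between two biallelic loci is summarised by
D = f(AB) − pA·pB, its normalised absolute value D′ = |D|/Dmax, and the
squared allelic correlation r² = D²/(pA(1−pA)pB(1−pB)); r² > 0.33 is the
conventional threshold for "strong" LD in candidate-gene work.

Haplotypes are encoded as tuples of alt-allele indicators (0 = ref, 1 = alt)
ordered as the loci; genotypes as alt dosages 0/1/2 with -1 missing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix, SnpLocus

__all__ = [
    "HaplotypeTable",
    "LdResult",
    "Diplotype",
    "em_haplotype_frequencies",
    "pairwise_ld",
    "ld_from_genotypes",
    "ld_matrix",
    "classify_ld",
    "assign_diplotypes",
    "filter_rare",
    "STRONG_LD_R2",
]

logger = logging.getLogger(__name__)

STRONG_LD_R2 = 0.33

Haplotype = tuple[int, ...]


@dataclass
class HaplotypeTable:
    """Estimated haplotype frequencies over an ordered set of loci.

    ``haplotypes`` and ``frequencies`` are aligned; names (Hap1 = most
    frequent) are assigned by descending frequency with the haplotype tuple
    as a deterministic tie-break.
    """

    loci: list[SnpLocus]
    haplotypes: list[Haplotype]
    frequencies: np.ndarray
    log_likelihood: float = float("nan")
    n_iterations: int = 0
    converged: bool = True
    raw_frequencies: np.ndarray | None = None  # before rare-haplotype exclusion
    dropped_mass: float = 0.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("haplotypes and frequencies differ in length")
        if np.any(self.frequencies < -1e-12):
            raise ValueError("negative haplotype frequency")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        L = len(self.loci)
        for h in self.haplotypes:
            if len(h) != L or not set(h) <= {0, 1}:
                raise ValueError(f"bad haplotype {h} for {L} loci")

    def allele_string(self, hap: Haplotype) -> str:
        return "".join(
            l.alt_allele if a else l.ref_allele for l, a in zip(self.loci, hap)
        )

    def ranking(self) -> list[int]:
        """Indices sorted by descending frequency (haplotype as tie-break)."""
        return sorted(
            range(len(self.haplotypes)),
            key=lambda i: (-self.frequencies[i], self.haplotypes[i]),
        )

    def names(self) -> dict[Haplotype, str]:
        return {
            self.haplotypes[i]: f"Hap{rank + 1}"
            for rank, i in enumerate(self.ranking())
        }

    def frequency_of(self, hap: Haplotype) -> float:
        try:
            return float(self.frequencies[self.haplotypes.index(hap)])
        except ValueError:
            return 0.0

    def to_dataframe(self) -> pd.DataFrame:
        names = self.names()
        rows = []
        for i in self.ranking():
            h = self.haplotypes[i]
            row = {"haplotype": names[h]}
            for locus, a in zip(self.loci, h):
                row[locus.locus_id] = locus.alt_allele if a else locus.ref_allele
            row["frequency_pct"] = 100.0 * self.frequencies[i]
            if self.raw_frequencies is not None:
                row["raw_frequency_pct"] = 100.0 * self.raw_frequencies[i]
            rows.append(row)
        return pd.DataFrame(rows)


def _consistent_pairs(pattern: tuple[int, ...]) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs consistent with a complete genotype.

    Heterozygous loci contribute a binary phase choice each; fixing the first
    heterozygous locus's assignment avoids double-counting unordered pairs.
    """
    het = [j for j, g in enumerate(pattern) if g == 1]
    base1 = [0] * len(pattern)
    base2 = [0] * len(pattern)
    for j, g in enumerate(pattern):
        if g == 2:
            base1[j] = base2[j] = 1
    if not het:
        h = tuple(base1)
        return [(h, h)]
    pairs = []
    first, rest = het[0], het[1:]
    for bits in itertools.product((0, 1), repeat=len(rest)):
        h1, h2 = base1.copy(), base2.copy()
        h1[first], h2[first] = 1, 0
        for j, b in zip(rest, bits):
            h1[j], h2[j] = b, 1 - b
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def em_haplotype_frequencies(
    genotypes: GenotypeMatrix,
    loci: Sequence[str | SnpLocus] | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    restarts: int = 0,
    seed: int | None = None,
) -> HaplotypeTable:
    """Maximum-likelihood haplotype frequencies by EM over 2^L haplotypes.

    Individuals with a missing call at any analysed locus are excluded
    (complete-case), with the count logged.  Convergence is declared when
    the largest absolute frequency change falls below ``tol``; otherwise a
    result is still returned with ``converged=False``.

    ``restarts`` adds that many random initializations (Dirichlet, seeded)
    on top of the deterministic linkage-equilibrium start; the best final
    likelihood wins.
    """
    idx = (
        list(range(genotypes.n_loci))
        if loci is None
        else [genotypes.locus_index(l) for l in loci]
    )
    L = len(idx)
    if L == 0:
        raise ValueError("no loci selected")
    if L > 12:
        raise ValueError(f"{L} loci: 2^L haplotype enumeration not practical")
    sel_loci = [genotypes.loci[j] for j in idx]
    mask = genotypes.complete_rows(idx)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("EM: excluded %d individuals with missing calls", n_dropped)
    G = genotypes.dosage[np.asarray(mask), :][:, idx]
    if G.shape[0] == 0:
        raise ValueError("no individuals with complete calls at the selected loci")

    patterns, counts = np.unique(G, axis=0, return_counts=True)
    haplist = [tuple(h) for h in itertools.product((0, 1), repeat=L)]
    hap_index = {h: i for i, h in enumerate(haplist)}
    # per pattern: arrays of pair indices and homozygosity weights
    expansions = []
    for pat in patterns:
        prs = _consistent_pairs(tuple(int(g) for g in pat))
        i1 = np.array([hap_index[a] for a, _ in prs])
        i2 = np.array([hap_index[b] for _, b in prs])
        w = np.where(i1 == i2, 1.0, 2.0)  # unordered pair multiplicity
        expansions.append((i1, i2, w))

    # allele frequencies at the selected loci for the deterministic start
    p_alt = (patterns * counts[:, None]).sum(axis=0) / (2.0 * counts.sum())
    le_start = np.array(
        [np.prod([p_alt[j] if h[j] else 1 - p_alt[j] for j in range(L)]) for h in haplist]
    )
    starts = [le_start]
    if restarts:
        rng = np.random.default_rng(seed)
        starts += [rng.dirichlet(np.ones(len(haplist))) for _ in range(restarts)]

    def run(f0: np.ndarray) -> tuple[np.ndarray, float, int, bool]:
        f = np.maximum(f0, 1e-300)
        f = f / f.sum()
        ll_prev = -np.inf
        for it in range(1, max_iter + 1):
            new = np.zeros_like(f)
            ll = 0.0
            for (i1, i2, w), cnt in zip(expansions, counts):
                pp = w * f[i1] * f[i2]
                tot = pp.sum()
                if tot <= 0.0:
                    # all consistent pairs have zero mass; respread tiny weight
                    pp = w / w.sum()
                    tot = 1.0
                    ll += cnt * np.log(1e-300)
                else:
                    ll += cnt * np.log(tot)
                post = pp / tot
                np.add.at(new, i1, cnt * post)
                np.add.at(new, i2, cnt * post)
            new /= new.sum()
            assert ll >= ll_prev - 1e-9, "EM likelihood decreased"
            delta = np.max(np.abs(new - f))
            f, ll_prev = new, ll
            if delta < tol:
                return f, ll, it, True
        return f, ll_prev, max_iter, False

    best = None
    for f0 in starts:
        res = run(f0)
        if best is None or res[1] > best[1]:
            best = res
    f, ll, iters, conv = best
    if not conv:
        logger.warning("EM did not converge in %d iterations", max_iter)
    return HaplotypeTable(sel_loci, haplist, f, ll, iters, conv)


@dataclass(frozen=True)
class LdResult:
    locus_a: str
    locus_b: str
    D: float
    D_prime: float
    r2: float
    strong_ld: bool


def classify_ld(r2: float, threshold: float = STRONG_LD_R2) -> bool:
    """Strong LD iff r² strictly exceeds the threshold (default 0.33)."""
    if not 0.0 <= r2 <= 1.0 + 1e-12:
        raise ValueError(f"r2 {r2} outside [0, 1]")
    return r2 > threshold


def pairwise_ld(
    freqs: np.ndarray,
    locus_a: str = "A",
    locus_b: str = "B",
    threshold: float = STRONG_LD_R2,
) -> LdResult:
    """D, D′ and r² from a 2x2 table of two-locus haplotype frequencies.

    ``freqs[i, j]`` is the frequency of the haplotype carrying allele class
    ``i`` (0 = ref) at the first locus and ``j`` at the second; the four
    entries must sum to 1.
    """
    f = np.asarray(freqs, dtype=float).reshape(2, 2)
    if abs(f.sum() - 1.0) > 1e-9 or np.any(f < -1e-12):
        raise ValueError("haplotype frequencies must be non-negative and sum to 1")
    pA = f[0, :].sum()  # ref-class frequency at first locus
    pB = f[:, 0].sum()
    if min(pA, 1 - pA, pB, 1 - pB) <= 0.0:
        raise ValueError("LD undefined: a locus is monomorphic")
    D = f[0, 0] - pA * pB
    if abs(D) < 1e-14:  # snap float noise so independence reports exact zeros
        D = 0.0
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if D == 0 else abs(D) / dmax
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LdResult(locus_a, locus_b, D, min(d_prime, 1.0), min(r2, 1.0),
                    classify_ld(min(r2, 1.0), threshold))


def _two_locus_freqs(table: HaplotypeTable, ja: int, jb: int) -> np.ndarray:
    f = np.zeros((2, 2))
    for h, fr in zip(table.haplotypes, table.frequencies):
        f[h[ja], h[jb]] += fr
    return f


def ld_from_genotypes(
    genotypes: GenotypeMatrix,
    locus_a: str | SnpLocus,
    locus_b: str | SnpLocus,
    **em_kwargs,
) -> LdResult:
    """Two-locus EM, then LD summaries, for one locus pair."""
    table = em_haplotype_frequencies(genotypes, [locus_a, locus_b], **em_kwargs)
    ids = [l.locus_id for l in table.loci]
    return pairwise_ld(_two_locus_freqs(table, 0, 1), ids[0], ids[1])


def ld_matrix(genotypes: GenotypeMatrix, **em_kwargs) -> pd.DataFrame:
    """Square matrix with D′ above and r² below the diagonal.

    Each pair's haplotype frequencies come from a dedicated two-locus EM,
    mirroring how pairwise LD is conventionally reported.
    """
    ids = genotypes.locus_ids
    out = pd.DataFrame(np.nan, index=ids, columns=ids)
    for a, b in itertools.combinations(ids, 2):
        res = ld_from_genotypes(genotypes, a, b, **em_kwargs)
        out.loc[a, b] = res.D_prime
        out.loc[b, a] = res.r2
    return out


@dataclass(frozen=True)
class Diplotype:
    individual_id: str
    haplotype_pair: tuple[Haplotype, Haplotype]  # sorted, unordered
    posterior: float
    label: str  # e.g. "Hap1/2"
    low_confidence: bool = False


def _pairs_for_genotype(
    row: np.ndarray, haplotypes: list[Haplotype]
) -> list[tuple[Haplotype, Haplotype]]:
    """Unordered haplotype pairs consistent with a genotype row; missing
    loci (dosage -1) are unconstrained (marginalized)."""
    pairs = []
    for h1, h2 in itertools.combinations_with_replacement(haplotypes, 2):
        ok = True
        for g, a1, a2 in zip(row, h1, h2):
            if g != MISSING and a1 + a2 != g:
                ok = False
                break
        if ok:
            pairs.append((h1, h2))
    return pairs


def assign_diplotypes(
    genotypes: GenotypeMatrix,
    haps: HaplotypeTable,
    floor: float = 1e-6,
) -> list[Diplotype]:
    """Maximum-posterior haplotype pair per individual.

    Posterior of an unordered pair (h1, h2) ∝ (2 − δ_{h1 h2}) f(h1) f(h2)
    over the pairs consistent with the individual's genotype; missing loci
    are marginalized.  Ties prefer the pair containing the more frequent
    haplotype.  If no positive-frequency pair is consistent, the posterior
    is recomputed over the full haplotype space with a pseudo-frequency
    floor and the call is flagged low-confidence.
    """
    idx = [genotypes.locus_index(l) for l in haps.loci]
    names = haps.names()
    full_space = [tuple(h) for h in itertools.product((0, 1), repeat=len(haps.loci))]
    freq = {h: haps.frequency_of(h) for h in full_space}
    rank = {h: int(names.get(h, f"Hap{len(full_space)}")[3:]) if h in names else 10**9
            for h in full_space}

    def hap_name(h: Haplotype) -> str:
        return names.get(h, haps.allele_string(h) + "*")

    out: list[Diplotype] = []
    for i, iid in enumerate(genotypes.individual_ids):
        row = genotypes.dosage[i, idx]
        pairs = _pairs_for_genotype(row, full_space)
        weights = np.array(
            [(1.0 if a == b else 2.0) * freq[a] * freq[b] for a, b in pairs]
        )
        low = False
        if weights.sum() <= 0.0:
            low = True
            weights = np.array(
                [
                    (1.0 if a == b else 2.0)
                    * max(freq[a], floor)
                    * max(freq[b], floor)
                    for a, b in pairs
                ]
            )
        post = weights / weights.sum()
        # max posterior; ties broken toward the pair with the best-ranked
        # (most frequent) haplotype, then lexicographically
        order = sorted(
            range(len(pairs)),
            key=lambda k: (
                -post[k],
                min(rank[pairs[k][0]], rank[pairs[k][1]]),
                pairs[k],
            ),
        )
        k = order[0]
        a, b = sorted(pairs[k])
        if a in names and b in names:
            na, nb = sorted((names[a], names[b]), key=lambda s: int(s[3:]))
            label = f"{na}/{nb[3:]}"
        else:
            label = f"{hap_name(a)}/{hap_name(b)}"
        out.append(Diplotype(iid, (a, b), float(post[k]), label, low))
    return out


def filter_rare(haps: HaplotypeTable, min_freq: float = 0.05) -> HaplotypeTable:
    """Drop haplotypes below ``min_freq`` and renormalize the remainder.

    The pre-exclusion frequencies are retained in ``raw_frequencies`` and the
    removed mass in ``dropped_mass``, so reports can show both.
    """
    if not 0.0 <= min_freq < 1.0:
        raise ValueError("min_freq must be in [0, 1)")
    keep = haps.frequencies >= min_freq
    if not keep.any():
        raise ValueError(f"all haplotypes below frequency {min_freq}")
    kept_haps = [h for h, k in zip(haps.haplotypes, keep) if k]
    raw = haps.frequencies[keep]
    dropped = float(haps.frequencies[~keep].sum())
    if dropped:
        logger.info(
            "rare-haplotype exclusion: dropped %d haplotypes, mass %.4f",
            int((~keep).sum()), dropped,
        )
    return replace(
        haps,
        haplotypes=kept_haps,
        frequencies=raw / raw.sum(),
        raw_frequencies=raw,
        dropped_mass=dropped,
    )
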