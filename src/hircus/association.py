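"""Genotype-by-sex trait association.

The core model is the generalized linear model

    g(E(Y_ijk)) = b0 + b1*G1 + b2*G2 + b3*S1 + b4*G1*S1 + b5*G2*S1 + e

with dummy-coded genotype (G1 = heterozygote, G2 = variant homozygote,
reference = wild-type homozygote), S1 = 1 for males, and a Gaussian family
with identity link by default (equivalent to ordinary least squares; a log
link is available).  Around it: stepwise model reduction with the main-effect
/ interaction hierarchy enforced, sex-stratified one-way ANOVA across
genotype (or diplotype) levels with Bonferroni-adjusted pairwise comparisons
and compact-letter displays, between-sex t-tests per genotype with the
conventional star marks (* p<0.05, ** p<0.01), and the Bonferroni adjustment
itself.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SingularDesignError",
    "GlmFit",
    "ComparisonResult",
    "GroupSummary",
    "TERMS",
    "build_design",
    "design_matrix",
    "fit_glm",
    "stepwise_select",
    "compare_within_sex",
    "compare_between_sex",
    "adjust_bonferroni",
    "compact_letter_display",
    "significance_stars",
]

logger = logging.getLogger(__name__)

TERMS = ("G1", "G2", "S1", "G1S1", "G2S1")
_PARENTS = {"G1S1": ("G1", "S1"), "G2S1": ("G2", "S1")}


class SingularDesignError(ValueError):
    """Raised when a genotype-by-sex cell is empty and the design is singular."""


def build_design(dosage: int, sex_is_male: int, reference_dosage: int = 0) -> dict:
    """Dummy-code one individual: G1 = heterozygote, G2 = the non-reference
    homozygote, relative to the reference genotype (wild-type homozygote by
    default), plus the sex indicator and interaction products."""
    if dosage not in (0, 1, 2):
        raise ValueError(f"genotype dosage {dosage} not in 0/1/2")
    if reference_dosage not in (0, 1, 2):
        raise ValueError(f"reference dosage {reference_dosage} not in 0/1/2")
    non_ref = [d for d in (1, 0, 2) if d != reference_dosage]  # het first
    g1 = int(dosage == non_ref[0])
    g2 = int(dosage == non_ref[1])
    s1 = int(sex_is_male)
    return {"G1": g1, "G2": g2, "S1": s1, "G1S1": g1 * s1, "G2S1": g2 * s1}


def design_matrix(
    dosages: np.ndarray,
    sex_male: np.ndarray,
    reference_dosage: int = 0,
) -> pd.DataFrame:
    """Full design (const + the five model terms) for a cohort."""
    rows = [
        build_design(int(d), int(s), reference_dosage)
        for d, s in zip(dosages, sex_male)
    ]
    X = pd.DataFrame(rows)
    X.insert(0, "const", 1.0)
    return X


@dataclass
class GlmFit:
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    aic: float
    bic: float
    n: int
    resid_var: float
    fitted: np.ndarray

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues}
        )


def _check_cells(X: pd.DataFrame) -> None:
    """With interactions in the model, every genotype-by-sex cell must be
    occupied or the design is rank-deficient; name the empty cell."""
    has_inter = any(t in X.columns for t in ("G1S1", "G2S1"))
    if not {"G1", "G2", "S1"} <= set(X.columns) or not has_inter:
        return
    geno = np.select([X["G1"] == 1, X["G2"] == 1], ["G1", "G2"], default="G3")
    sex = np.where(X["S1"] == 1, "male", "female")
    for g in ("G1", "G2", "G3"):
        for s in ("male", "female"):
            if not np.any((geno == g) & (sex == s)):
                raise SingularDesignError(f"empty design cell: genotype {g}, sex {s}")


def fit_glm(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    link: str = "identity",
) -> GlmFit:
    """Gaussian GLM with identity (default) or log link.

    With the identity link this is exactly the least-squares fit of the
    genotype-by-sex model.  Rows with a missing response are dropped.
    """
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    y, X = y[keep], X.loc[keep].reset_index(drop=True)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} observations for {k} parameters")
    _check_cells(X)
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        raise SingularDesignError("design matrix is rank-deficient")
    links = {"identity": sm.families.links.Identity(), "log": sm.families.links.Log()}
    try:
        fam = sm.families.Gaussian(links[link])
    except KeyError:
        raise ValueError(f"unknown link {link!r}") from None
    res = sm.GLM(y, X, family=fam).fit()
    resid = y - res.fittedvalues
    return GlmFit(
        terms=[c for c in X.columns if c != "const"],
        params=res.params,
        bse=res.bse,
        pvalues=pd.Series(res.pvalues, index=res.params.index),
        llf=float(res.llf),
        aic=float(res.aic),
        bic=float(res.bic_llf),
        n=int(n),
        resid_var=float(resid @ resid / (n - k)),
        fitted=np.asarray(res.fittedvalues),
    )


def _hierarchy_ok(terms: set[str]) -> bool:
    return all(set(_PARENTS[t]) <= terms for t in terms if t in _PARENTS)


def stepwise_select(
    y: np.ndarray | pd.Series,
    X_full: pd.DataFrame,
    candidates: tuple[str, ...] = TERMS,
    enter_alpha: float = 0.05,
    criterion: str = "aic",
    link: str = "identity",
) -> tuple[GlmFit, list[str]]:
    """Forward-backward term selection with the interaction hierarchy.

    Forward step: among hierarchy-eligible candidates, add the term with the
    smallest Wald p-value, provided its Bonferroni-adjusted p (adjusted for
    the size of the candidate family) is below ``enter_alpha``; the
    adjustment keeps the family-wise error of a pure-noise trait at
    ``enter_alpha`` rather than letting it grow with the number of
    candidates.
    Backward step: drop any in-model term (interactions first) that is no
    longer significant or whose removal improves the criterion (AIC by
    default, BIC by flag), never breaking the hierarchy.  Returns the final
    fit and the step-by-step trace.
    """
    if criterion not in {"aic", "bic"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    score = lambda f: f.aic if criterion == "aic" else f.bic

    def fit_terms(terms: list[str]) -> GlmFit:
        return fit_glm(y, X_full[["const", *terms]], link=link)

    current: list[str] = []
    trace: list[str] = []
    while True:
        changed = False
        # forward
        eligible = [
            t
            for t in candidates
            if t not in current and _hierarchy_ok(set(current) | {t})
        ]
        best: tuple[float, str, GlmFit] | None = None
        for t in eligible:
            try:
                f = fit_terms(current + [t])
            except SingularDesignError:
                continue
            p = float(f.pvalues[t])
            if best is None or p < best[0]:
                best = (p, t, f)
        if best is not None:
            p_adj = min(1.0, len(candidates) * best[0])
            if p_adj < enter_alpha:
                current.append(best[1])
                trace.append(f"add {best[1]} (p={best[0]:.4g}, adj={p_adj:.4g})")
                changed = True
        # backward
        if current:
            fit_now = fit_terms(current)
            droppable = [
                t for t in sorted(current, key=lambda t: t not in _PARENTS)
                if _hierarchy_ok(set(current) - {t})
            ]
            for t in droppable:
                f_wo = fit_terms([u for u in current if u != t])
                if float(fit_now.pvalues[t]) >= enter_alpha and score(f_wo) <= score(
                    fit_now
                ):
                    current.remove(t)
                    trace.append(f"drop {t} ({criterion} {score(fit_now):.3f}"
                                 f" -> {score(f_wo):.3f})")
                    changed = True
                    break
        if not changed:
            break
    return fit_terms(current), trace


def adjust_bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni family-wise adjustment: p_adj = min(1, m*p)."""
    ps = [float(p) for p in p_values]
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError("p-values must be in [0, 1]")
    m = len(ps) if m is None else m
    if m < len(ps):
        raise ValueError("family size m smaller than the number of p-values")
    return [min(1.0, m * p) for p in ps]


def significance_stars(p: float) -> str:
    """'**' for p < 0.01, '*' for p < 0.05, else ''."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compact_letter_display(
    levels: list[str],
    sig: dict[tuple[str, str], bool],
    letters: str = "abcdefghijklmnopqrstuvwxyz",
    order: list[str] | None = None,
) -> dict[str, str]:
    """Letters such that two levels share a letter iff their difference is
    not significant.

    Letters are assigned to the maximal cliques of the non-significance
    graph (levels ordered as given, typically by descending mean), the
    textbook construction behind the letter superscripts of livestock
    association tables.
    """
    order = levels if order is None else order
    pos = {l: i for i, l in enumerate(order)}
    # maximal cliques of the "not significantly different" graph
    adj = {
        l: {
            m
            for m in levels
            if m != l and not sig.get((l, m), sig.get((m, l), False))
        }
        for l in levels
    }

    cliques: list[set[str]] = []

    def grow(r: set[str], p_: set[str], x: set[str]) -> None:  # Bron-Kerbosch
        if not p_ and not x:
            cliques.append(r)
            return
        for v in list(p_):
            grow(r | {v}, p_ & adj[v], x & adj[v])
            p_ = p_ - {v}
            x = x | {v}

    grow(set(), set(levels), set())
    cliques.sort(key=lambda c: min(pos[l] for l in c))
    out = {l: "" for l in levels}
    for letter, clique in zip(letters, cliques):
        for l in sorted(clique, key=pos.get):
            out[l] += letter
    return {l: "".join(sorted(v, key=letters.index)) for l, v in out.items()}


@dataclass
class GroupSummary:
    level: str
    n: int
    mean: float
    sd: float
    letter_05: str = ""
    letter_01: str = ""
    star: str = ""


@dataclass
class ComparisonResult:
    groups: list[GroupSummary]
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)  # adjusted
    warnings: list[str] = field(default_factory=list)

    def group(self, level: str) -> GroupSummary:
        return next(g for g in self.groups if g.level == level)


def _summaries(groups: dict[str, np.ndarray]) -> list[GroupSummary]:
    return [
        GroupSummary(lvl, len(v), float(np.mean(v)), float(np.std(v, ddof=1)))
        for lvl, v in groups.items()
    ]


def compare_within_sex(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    alpha_high: float = 0.01,
    equal_var: bool = False,
) -> ComparisonResult:
    """One-way ANOVA across genotype/diplotype levels within one sex, with
    Bonferroni-adjusted pairwise t-tests and compact-letter displays at both
    significance levels (lowercase 0.05, uppercase 0.01).

    Groups with fewer than 2 observations are excluded with a warning.
    """
    warnings = []
    clean = {}
    for lvl, v in groups.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            warnings.append(f"group {lvl!r} excluded: {len(v)} observation(s)")
        else:
            clean[lvl] = v
    if len(clean) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    levels = sorted(clean, key=lambda l: -np.mean(clean[l]))
    F, p_anova = stats.f_oneway(*[clean[l] for l in levels])
    pairs = list(itertools.combinations(levels, 2))
    raw = [
        stats.ttest_ind(clean[a], clean[b], equal_var=equal_var).pvalue
        for a, b in pairs
    ]
    adj = adjust_bonferroni(raw, m=len(pairs))
    pairwise = dict(zip(pairs, adj))
    sig05 = {pr: padj < alpha for pr, padj in pairwise.items()}
    sig01 = {pr: padj < alpha_high for pr, padj in pairwise.items()}
    low = compact_letter_display(levels, sig05)
    up = compact_letter_display(levels, sig01, letters="ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    summaries = _summaries({l: clean[l] for l in levels})
    for g in summaries:
        g.letter_05 = low[g.level]
        g.letter_01 = up[g.level]
    return ComparisonResult(summaries, float(F), float(p_anova), pairwise, warnings)


def compare_between_sex(
    male: np.ndarray,
    female: np.ndarray,
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sample t-test, male vs female, for one genotype level.

    Welch's unequal-variance test by default; ``equal_var=True`` gives the
    pooled-variance test.  Star marks follow the * p<0.05 / ** p<0.01
    convention.
    """
    male = np.asarray(male, dtype=float)
    female = np.asarray(female, dtype=float)
    male, female = male[np.isfinite(male)], female[np.isfinite(female)]
    if len(male) < 2 or len(female) < 2:
        raise ValueError("both sexes need >= 2 observations")
    t, p = stats.ttest_ind(male, female, equal_var=equal_var)
    groups = _summaries({"male": male, "female": female})
    star = significance_stars(float(p))
    for g in groups:
        g.star = star
    return ComparisonResult(groups, float(t), float(p))
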