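"""Nonparametric per-marker linkage scanning with permutation thresholds.

The scan compares trait values of B- versus G-allele carriers at every
marker with a two-sided Wilcoxon-Mann-Whitney test; genome-wide significance
cutoffs come from the max-statistic permutation construction (Churchill &
Doerge style), reported at the 5% and 10% levels. Variance decomposition
uses Type-II ANOVA on one- or two-locus linear models.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenotypeMatrix, MarkerPanel, PhenotypeTable

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
DEFAULT_LEVELS = (0.05, 0.10)
EXACT_MAX_N = 30


@dataclass
class QcReport:
    per_marker: pd.DataFrame      # b_count, g_count, chi2, p, passed, callable
    per_segregant: pd.DataFrame   # call_rate, passed
    call_rate: float
    alpha: float

    def all_markers_pass(self) -> bool:
        return bool(self.per_marker.loc[self.per_marker["callable"], "passed"].all())


@dataclass
class LinkageResult:
    """Per-marker scan for one trait plus genome-wide permutation thresholds."""

    trait: str
    table: pd.DataFrame  # marker, statistic, p, neglog10_p, direction, n_b, n_g
    thresholds: dict[float, float] = field(default_factory=dict)
    n_permutations: int = 0
    panel: Optional[MarkerPanel] = None

    def significant(self, level: float = 0.05) -> pd.DataFrame:
        thr = self.thresholds[level]
        return self.table[self.table["neglog10_p"] >= thr]

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["trait"] = self.trait
        chrom, pos = [], []
        for mid in out["marker"]:
            if self.panel is not None:
                m = self.panel.by_id(mid)
                chrom.append(m.position.chrom)
                pos.append(m.position.pos)
            else:
                chrom.append("NA")
                pos.append(-1)
        out["chrom"], out["pos"] = chrom, pos
        out["threshold5"] = self.thresholds.get(0.05, np.nan)
        out["threshold10"] = self.thresholds.get(0.10, np.nan)
        out["significant5"] = out["neglog10_p"] >= out["threshold5"]
        out["significant10"] = out["neglog10_p"] >= out["threshold10"]
        return out


@dataclass
class VarianceDecomposition:
    model: str  # "one_way" | "two_locus" | "two_locus_interaction"
    terms: pd.DataFrame  # term, percent, p

    def percent(self, term: str) -> float:
        row = self.terms[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["percent"].iloc[0])


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

def qc_genotypes(matrix: GenotypeMatrix, alpha: float = 0.05) -> QcReport:
    """Mendelian segregation and completeness checks.

    Per marker: chi-square with 1 df against 1:1 B:G on called genotypes
    (``(nB - nG)^2 / n``); markers with ``p < alpha`` are flagged distorted.
    Per segregant: call rate, flagged below 99%.
    """
    if len(matrix.segregants) < 10:
        raise ValueError("need >= 10 segregants for QC")
    b = matrix.b_mask().sum(axis=0).astype(int)
    called = matrix.called_mask().sum(axis=0).astype(int)
    g = called - b
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(called > 0, (b - g) ** 2 / called.replace(0, 1), np.nan)
    p = stats.chi2.sf(chi2, df=1)
    per_marker = pd.DataFrame(
        {
            "b_count": b,
            "g_count": g,
            "chi2": chi2,
            "p": p,
            "callable": called > 0,
        }
    )
    per_marker["passed"] = (per_marker["p"] >= alpha) & per_marker["callable"]
    seg_rate = matrix.called_mask().mean(axis=1)
    per_segregant = pd.DataFrame({"call_rate": seg_rate, "passed": seg_rate >= 0.99})
    return QcReport(
        per_marker=per_marker,
        per_segregant=per_segregant,
        call_rate=float(matrix.called_mask().to_numpy().mean()),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Wilcoxon-Mann-Whitney scan
# ---------------------------------------------------------------------------

def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p: exact for small tie-free samples, else normal
    approximation with tie and continuity corrections."""
    n = len(x) + len(y)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 0.5 * len(x) * len(y), 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < n
    method = "exact" if (n <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_scan(
    matrix: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    min_per_class: int = 2,
) -> pd.DataFrame:
    """Per-marker two-sided Wilcoxon-Mann-Whitney scan of one trait.

    Replicates are averaged per segregant before testing. Markers with fewer
    than ``min_per_class`` segregants in either genotype class are skipped
    with a log message. ``direction`` names the allele whose carriers have
    the lower mean trait value (the favorable side for RS-like traits).
    """
    means = pheno.trait_means(trait)
    common = [s for s in matrix.segregants if s in means.index]
    if not common:
        raise ValueError("no segregants shared between genotypes and phenotypes")
    sub = matrix.subset(common)
    y = means.loc[common].to_numpy(float)
    rows = []
    for mid in sub.marker_ids:
        calls = sub.calls(mid).to_numpy(object)
        mask_b = calls == "B"
        mask_g = calls == "G"
        if mask_b.sum() < min_per_class or mask_g.sum() < min_per_class:
            log.info("marker %s skipped: <%d segregants per class", mid, min_per_class)
            continue
        xb, xg = y[mask_b], y[mask_g]
        stat, p = _rank_sum_p(xb, xg)
        rows.append(
            {
                "marker": mid,
                "statistic": stat,
                "p": p,
                "neglog10_p": -np.log10(p) if p > 0 else np.inf,
                "direction": "B" if xb.mean() <= xg.mean() else "G",
                "n_b": int(mask_b.sum()),
                "n_g": int(mask_g.sum()),
            }
        )
    return pd.DataFrame(
        rows, columns=["marker", "statistic", "p", "neglog10_p", "direction", "n_b", "n_g"]
    )


def _approx_scan_pvalues(masks_b: np.ndarray, masks_g: np.ndarray, ranks: np.ndarray,
                         tie_term: float) -> np.ndarray:
    """Vectorized tie/continuity-corrected normal-approximation p-values.

    ``masks_b``/``masks_g``: (m, n) boolean genotype indicators;
    ``ranks``: (n,) or (n_perm, n) midranks of the trait vector(s).
    Returns p with shape (m,) or (m, n_perm).
    """
    ranks = np.atleast_2d(ranks)  # (P, n)
    n_b = masks_b.sum(axis=1).astype(float)  # (m,)
    n_g = masks_g.sum(axis=1).astype(float)
    n = n_b + n_g
    u1 = masks_b @ ranks.T - (n_b * (n_b + 1) / 2)[:, None]  # (m, P)
    mean = (n_b * n_g / 2)[:, None]
    var = (n_b * n_g / 12) * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(var)[:, None]
    num = np.clip(np.abs(u1 - mean) - 0.5, 0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, num / np.where(sd > 0, sd, 1.0), 0.0)
    p = np.minimum(2 * stats.norm.sf(z), 1.0)
    p = np.where(sd > 0, p, 1.0)
    return p.squeeze(axis=1) if p.shape[1] == 1 else p


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def permutation_thresholds(
    matrix: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    n_perm: int = DEFAULT_N_PERM,
    levels: Sequence[float] = DEFAULT_LEVELS,
    seed: Optional[int] = None,
    min_per_class: int = 2,
) -> dict[float, float]:
    """Genome-wide -log10(p) cutoffs from the max-statistic permutation null.

    The trait vector is shuffled jointly across segregants (one shared
    shuffle for all markers, preserving inter-marker correlation); each
    permutation records the maximum -log10(p) over markers, and the cutoff at
    ``level`` is the (1 - level) empirical quantile of that distribution.
    Permutation p-values use the tie/continuity-corrected normal
    approximation (the scan's large-sample branch).
    """
    if n_perm < 100:
        raise ValueError("need >= 100 permutations")
    rng = np.random.default_rng(seed)
    means = pheno.trait_means(trait)
    common = [s for s in matrix.segregants if s in means.index]
    sub = matrix.subset(common)
    y = means.loc[common].to_numpy(float)
    n = len(y)

    calls = sub.frame.to_numpy(object).T  # (m, n)
    masks_b = calls == "B"
    masks_g = calls == "G"
    keep = (masks_b.sum(axis=1) >= min_per_class) & (masks_g.sum(axis=1) >= min_per_class)
    masks_b, masks_g = masks_b[keep], masks_g[keep]
    if masks_b.shape[0] == 0:
        raise ValueError("no testable markers")

    ranks = stats.rankdata(y)
    tie = _tie_term(y)
    perm_ranks = np.empty((n_perm, n))
    for i in range(n_perm):
        perm_ranks[i] = ranks[rng.permutation(n)]
    p = _approx_scan_pvalues(masks_b, masks_g, perm_ranks, tie)  # (m, n_perm)
    with np.errstate(divide="ignore"):
        max_neglog = -np.log10(p.min(axis=0))
    return {
        float(level): float(np.quantile(max_neglog, 1 - level))
        for level in levels
    }


def scan_with_thresholds(
    matrix: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    n_perm: int = DEFAULT_N_PERM,
    levels: Sequence[float] = DEFAULT_LEVELS,
    seed: Optional[int] = None,
    panel: Optional[MarkerPanel] = None,
) -> LinkageResult:
    """Run the scan and attach permutation thresholds in one call."""
    table = wilcoxon_scan(matrix, pheno, trait)
    thresholds = permutation_thresholds(
        matrix, pheno, trait, n_perm=n_perm, levels=levels, seed=seed
    )
    return LinkageResult(
        trait=trait, table=table, thresholds=thresholds,
        n_permutations=n_perm, panel=panel,
    )


# ---------------------------------------------------------------------------
# variance decomposition
# ---------------------------------------------------------------------------

def variance_explained(
    matrix: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    loci: Sequence[str],
    with_interaction: bool = True,
) -> VarianceDecomposition:
    """Type-II ANOVA percent-of-variance for one or two marker loci.

    Percentages are ``100 * SS_term / SS_total`` with ``SS_total`` the total
    (corrected) sum of squares including the residual. With two loci the
    model is ``trait ~ locus1 + locus2 (+ locus1:locus2)``; the interaction
    is dropped with a log message when a genotype cell is empty.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if not 1 <= len(loci) <= 2:
        raise ValueError("loci must name 1 or 2 markers")
    means = pheno.trait_means(trait)
    common = [s for s in matrix.segregants if s in means.index]
    sub = matrix.subset(common)
    data = pd.DataFrame({"y": means.loc[common].to_numpy(float)}, index=common)
    for i, locus in enumerate(loci, start=1):
        if locus not in sub.marker_ids:
            raise KeyError(f"unknown locus {locus!r}")
        calls = sub.calls(locus)
        if calls.notna().mean() < 0.90:
            raise ValueError(f"locus {locus!r} called in <90% of segregants")
        data[f"locus{i}"] = calls
    data = data.dropna()

    if len(loci) == 1:
        model_name = "one_way"
        formula = "y ~ C(locus1)"
        rename = {"C(locus1)": loci[0]}
    else:
        cells = data.groupby(["locus1", "locus2"], observed=True).size()
        if with_interaction and len(cells) < 4:
            log.warning("empty genotype cell: dropping interaction term")
            with_interaction = False
        if with_interaction:
            model_name = "two_locus_interaction"
            formula = "y ~ C(locus1) + C(locus2) + C(locus1):C(locus2)"
        else:
            model_name = "two_locus"
            formula = "y ~ C(locus1) + C(locus2)"
        rename = {
            "C(locus1)": loci[0],
            "C(locus2)": loci[1],
            "C(locus1):C(locus2)": f"{loci[0]}:{loci[1]}",
        }

    fit = smf.ols(formula, data=data).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    ss_total = float(np.sum((data["y"] - data["y"].mean()) ** 2))
    rows = []
    for term, row in anova.iterrows():
        name = rename.get(term, "residual" if term == "Residual" else term)
        percent = 100.0 * float(row["sum_sq"]) / ss_total if ss_total > 0 else 0.0
        pval = float(row["PR(>F)"]) if np.isfinite(row.get("F", np.nan)) else np.nan
        rows.append({"term": name, "percent": percent, "p": pval})
    return VarianceDecomposition(model=model_name, terms=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# extreme selection and sequential cross design
# ---------------------------------------------------------------------------

def select_extremes(
    pheno: PhenotypeTable,
    trait: str,
    fraction: float = 0.1,
    direction: str = "lowest",
) -> list[str]:
    """Ids of the ``floor(fraction * n)`` most extreme segregants by trait mean.

    Ties are broken by segregant id for determinism.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if direction not in ("lowest", "highest"):
        raise ValueError("direction must be 'lowest' or 'highest'")
    means = pheno.trait_means(trait)
    k = max(1, int(np.floor(fraction * len(means))))
    ordered = sorted(
        means.items(), key=lambda kv: (kv[1] if direction == "lowest" else -kv[1], kv[0])
    )
    return [seg for seg, _ in ordered[:k]]


def design_sequential_cross(
    matrix: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    fixed_loci: Sequence[str],
    required_allele: str = "B",
) -> tuple[tuple[str, str], list[str]]:
    """Pick the parent pair for a follow-up cross removing known QTL effects.

    Among segregants homozygous for ``required_allele`` at every fixed locus,
    returns the pair maximizing the absolute trait-mean difference (ties
    broken by id pair), plus the markers at which the virtual hybrid of that
    pair would be heterozygous (i.e., where the two differ) - the residual
    segregating map for the next scan.
    """
    means = pheno.trait_means(trait)
    qualifying = [
        s
        for s in matrix.segregants
        if s in means.index
        and all(matrix.frame.at[s, l] == required_allele for l in fixed_loci)
    ]
    if len(qualifying) < 2:
        raise ValueError(
            f"need >= 2 segregants carrying {required_allele} at all fixed loci, "
            f"got {len(qualifying)}"
        )
    best = max(
        itertools.combinations(sorted(qualifying), 2),
        key=lambda pair: (abs(means[pair[0]] - means[pair[1]]), pair),
    )
    a, b = best
    het = [
        mid
        for mid in matrix.marker_ids
        if pd.notna(matrix.frame.at[a, mid])
        and pd.notna(matrix.frame.at[b, mid])
        and matrix.frame.at[a, mid] != matrix.frame.at[b, mid]
    ]
    return best, het
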