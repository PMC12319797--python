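"""Permutation and multiple-comparison machinery.

Houses the Mantel test relating subject-similarity matrices (e.g. Dice
similarity of parcellations vs Spearman similarity of anatomy), the
Benjamini-Hochberg step-up adjustment, and the Friedman + pairwise Wilcoxon
battery used to compare metric values across parcellation conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import SimilarityMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError("permutation p-value must lie in (0, 1]")


def _rank_rows(x):
    return sps.rankdata(x, axis=-1)


def mantel_test(mat_a: SimilarityMatrix, mat_b: SimilarityMatrix,
                n_perm: int = 10000, seed: int = 0) -> PermutationResult:
    """Spearman correlation of upper triangles with a row/column permutation null.

    The observed statistic is the Spearman correlation between the strictly
    upper-triangular entries of the two matrices.  The null jointly permutes
    rows and columns of ``mat_a`` by a random subject relabeling and
    recomputes the statistic; the two-sided p-value uses the add-one
    convention (1 + #{|null| >= |observed|}) / (1 + n_perm).
    """
    a, b = mat_a.values, mat_b.values
    n = a.shape[0]
    if b.shape[0] != n:
        raise ValidationError("similarity matrices must cover the same subjects")
    if mat_a.subject_ids != mat_b.subject_ids:
        raise ValidationError("similarity matrices must share subject order")
    if n < 4:
        raise ValidationError("Mantel test needs at least 4 subjects")
    iu = np.triu_indices(n, k=1)
    ua, ub = a[iu], b[iu]
    if np.ptp(ua) == 0 or np.ptp(ub) == 0:
        raise ValidationError("constant upper triangle: correlation undefined")
    rng = np.random.default_rng(seed)
    rb = sps.rankdata(ub)
    rb_c = rb - rb.mean()

    def spearman_vs_b(rows):
        ranks = _rank_rows(rows)
        rc = ranks - ranks.mean(axis=-1, keepdims=True)
        num = rc @ rb_c
        den = np.sqrt((rc**2).sum(axis=-1) * (rb_c**2).sum())
        return num / den

    observed = float(spearman_vs_b(ua[None, :])[0])
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    permuted = np.stack([a[p][:, p][iu] for p in perms])
    null = spearman_vs_b(permuted)
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (1.0 + n_perm)
    return PermutationResult(observed, null, float(p), n_perm, seed)


def bh_adjust(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values in the original order, rejection flags at
    ``adjusted <= alpha``).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, adjusted <= alpha


@dataclass
class PairedComparisonReport:
    """Friedman omnibus plus BH-adjusted pairwise Wilcoxon signed-rank tests."""

    friedman_stat: float
    friedman_p: float
    pairwise: list = field(default_factory=list)
    # each entry: dict(pair, p_raw, p_adjusted, direction, n_zero_diffs)


def paired_compare(values: np.ndarray, condition_names=None,
                   alpha: float = 0.05) -> PairedComparisonReport:
    """Compare >= 2 conditions measured on the same subjects.

    ``values`` is subject x condition with no missing cells.  Pairwise
    Wilcoxon tests drop zero differences (standard zero-difference
    exclusion, counts logged); pairwise p-values are BH-adjusted.
    """
    values = np.asarray(values, dtype=float)
    n_sub, n_cond = values.shape
    if n_cond < 2:
        raise ValidationError("need at least 2 conditions")
    if n_sub < 6:
        raise ValidationError("need at least 6 subjects for paired comparison")
    if not np.all(np.isfinite(values)):
        raise ValidationError("missing cells are not allowed")
    names = list(condition_names) if condition_names else [
        f"cond{j + 1}" for j in range(n_cond)
    ]
    if n_cond >= 3:
        with np.errstate(invalid="ignore"):
            stat, p = sps.friedmanchisquare(*(values[:, j] for j in range(n_cond)))
        if np.isnan(stat):  # complete ties: no evidence of any difference
            stat, p = 0.0, 1.0
    else:  # Friedman needs 3 groups; a 2-condition omnibus is the Wilcoxon itself
        d = values[:, 0] - values[:, 1]
        stat, p = _wilcoxon_safe(d)
    entries = []
    raw = []
    for i in range(n_cond):
        for j in range(i + 1, n_cond):
            d = values[:, i] - values[:, j]
            w_stat, w_p = _wilcoxon_safe(d)
            n_zero = int(np.sum(d == 0))
            direction = (
                f"{names[i]} > {names[j]}" if np.median(d) > 0
                else f"{names[j]} > {names[i]}" if np.median(d) < 0
                else "tied"
            )
            entries.append({"pair": (names[i], names[j]), "p_raw": w_p,
                            "direction": direction, "n_zero_diffs": n_zero})
            raw.append(w_p)
    adjusted, _ = bh_adjust(raw, alpha=alpha)
    for e, pa in zip(entries, adjusted):
        e["p_adjusted"] = float(pa)
    return PairedComparisonReport(float(stat), float(p), entries)


def _wilcoxon_safe(d):
    d = np.asarray(d, dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        log.info("all paired differences are zero; p set to 1")
        return 0.0, 1.0
    res = sps.wilcoxon(d, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)
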