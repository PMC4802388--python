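"""Group statistics for the longitudinal network analysis.

The centrepiece is an exact 2x2 mixed-design ANOVA (one between-subject
factor, surgical outcome; one within-subject factor, treatment = pre/post),
vectorised over features, built on the difference-score / subject-mean
decomposition:

* interaction  — pooled two-sample t between groups on the per-subject
  post-minus-pre differences; F = t^2 with df (1, n1+n2-2);
* treatment    — t on the unweighted grand mean of the group difference
  means against zero, using the same pooled difference variance;
* outcome      — pooled two-sample t between groups on the per-subject
  session means.

For a 2x2 design this decomposition is algebraically exact (Type III) and
handles unbalanced groups.  Simple t / chi-square / correlation machinery is
delegated to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "two_sample_t",
    "t_from_summary",
    "chi_square_2x2",
    "pearson_corr",
    "false_positive_adjust",
    "MixedAnovaResult",
    "mixed_anova_2x2",
    "edge_screen",
    "exclude_damaged",
    "edge_keep_mask",
]


def two_sample_t(x, y, variant: str = "pooled") -> tuple[float, float, float]:
    """Two-sided two-sample t-test. Returns (t, df, p).

    ``variant='pooled'`` assumes equal variances (df = n1+n2-2);
    ``variant='welch'`` uses the Welch-Satterthwaite df.  A zero pooled
    variance yields an infinite t (flagged as +/-inf, p=0) unless the means
    are also equal, in which case t=0, p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        diff = x.mean() - y.mean()
        df = float(len(x) + len(y) - 2)
        if diff == 0:
            return 0.0, df, 1.0
        return float(np.sign(diff) * np.inf), df, 0.0
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from printed summary statistics (mean, SD, n).

    Identical to :func:`two_sample_t` applied to any raw data with these
    summaries.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table, df = 1.

    Continuity correction is off by default; ``yates=True`` enables it.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"table must be 2x2, got {table.shape}")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("every row and column margin must be positive")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned samples of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def false_positive_adjust(n_features: int) -> float:
    """Significance threshold 1/n: under the null, expect <1 false positive."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return 1.0 / n_features


@dataclass
class MixedAnovaResult:
    """Vectorised 2x2 mixed-ANOVA results (one entry per feature)."""

    f_interaction: np.ndarray
    p_interaction: np.ndarray
    f_outcome: np.ndarray
    p_outcome: np.ndarray
    f_treatment: np.ndarray
    p_treatment: np.ndarray
    df_between: tuple[int, int]
    df_within: tuple[int, int]
    cell_means: dict[str, np.ndarray]  # "SF_pre", "SF_post", "NSF_pre", "NSF_post"


def _as_2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def mixed_anova_2x2(sf_pre, sf_post, nsf_pre, nsf_post) -> MixedAnovaResult:
    """2x2 mixed ANOVA over features.

    Inputs are (n_subjects x n_features) arrays; ``sf_pre``/``sf_post`` (and
    the NSF pair) must hold the same subjects in the same row order — the
    within-subject pairing is by row.
    """
    sf_pre, sf_post = _as_2d(sf_pre), _as_2d(sf_post)
    nsf_pre, nsf_post = _as_2d(nsf_pre), _as_2d(nsf_post)
    if sf_pre.shape != sf_post.shape:
        raise ValueError("SF pre/post shapes differ: unpaired subject rows")
    if nsf_pre.shape != nsf_post.shape:
        raise ValueError("NSF pre/post shapes differ: unpaired subject rows")
    n1, n_feat = sf_pre.shape
    n2 = nsf_pre.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    if nsf_pre.shape[1] != n_feat:
        raise ValueError("feature dimension differs between groups")

    df2 = n1 + n2 - 2

    d1 = sf_post - sf_pre
    d2 = nsf_post - nsf_pre
    ss_d = ((d1 - d1.mean(axis=0)) ** 2).sum(axis=0) + ((d2 - d2.mean(axis=0)) ** 2).sum(axis=0)
    var_d = ss_d / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        se_int = np.sqrt(var_d * (1.0 / n1 + 1.0 / n2))
        t_int = (d1.mean(axis=0) - d2.mean(axis=0)) / se_int
        # treatment: unweighted grand mean of the group difference means
        grand_d = 0.5 * (d1.mean(axis=0) + d2.mean(axis=0))
        t_treat = grand_d / (0.5 * se_int)

    m1 = 0.5 * (sf_pre + sf_post)
    m2 = 0.5 * (nsf_pre + nsf_post)
    ss_m = ((m1 - m1.mean(axis=0)) ** 2).sum(axis=0) + ((m2 - m2.mean(axis=0)) ** 2).sum(axis=0)
    var_m = ss_m / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_out = (m1.mean(axis=0) - m2.mean(axis=0)) / np.sqrt(var_m * (1.0 / n1 + 1.0 / n2))

    def f_and_p(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = t**2
        p = sps.f.sf(f, 1, df2)
        return f, p

    f_int, p_int = f_and_p(t_int)
    f_out, p_out = f_and_p(t_out)
    f_tr, p_tr = f_and_p(t_treat)
    return MixedAnovaResult(
        f_interaction=f_int,
        p_interaction=p_int,
        f_outcome=f_out,
        p_outcome=p_out,
        f_treatment=f_tr,
        p_treatment=p_tr,
        df_between=(1, df2),
        df_within=(1, df2),
        cell_means={
            "SF_pre": sf_pre.mean(axis=0),
            "SF_post": sf_post.mean(axis=0),
            "NSF_pre": nsf_pre.mean(axis=0),
            "NSF_post": nsf_post.mean(axis=0),
        },
    )


def edge_screen(datasets: dict[str, np.ndarray], alpha: float = 0.05) -> np.ndarray:
    """Keep features whose values differ from zero in at least one dataset.

    ``datasets`` maps a cell label to an (n_subjects x n_features) array of
    Fisher-Z values; a feature is retained when a two-sided one-sample t-test
    against 0 has p < alpha in any cell.  Returns a boolean mask.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    mask = None
    for label, arr in datasets.items():
        arr = _as_2d(arr)
        if arr.shape[0] < 2:
            raise ValueError(f"dataset {label!r} needs at least 2 subjects")
        res = sps.ttest_1samp(arr, 0.0, axis=0)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        hit = p < alpha
        mask = hit if mask is None else (mask | hit)
    return mask


def exclude_damaged(lesion_fractions: np.ndarray | list) -> np.ndarray:
    """Boolean keep-mask over regions: drop every region damaged in ANY subject.

    ``lesion_fractions`` is (n_subjects x n_rois) of damage fractions; a
    region is excluded as soon as one subject has a positive fraction there.
    """
    fr = np.atleast_2d(np.asarray(lesion_fractions, dtype=float))
    return ~(fr > 0).any(axis=0)


def edge_keep_mask(node_keep: np.ndarray) -> np.ndarray:
    """Lift a node keep-mask to the upper-triangle edge vector: an edge
    survives only if both endpoints do."""
    node_keep = np.asarray(node_keep, dtype=bool)
    iu, ju = np.triu_indices(len(node_keep), k=1)
    return node_keep[iu] & node_keep[ju]
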