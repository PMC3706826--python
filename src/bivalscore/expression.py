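"""Microarray expression processing and differential expression.

The processing chain mirrors a standard bead-array workflow: background
subtraction against negative-control probes, quantile normalisation across
samples, then a per-probe error-weighted one-way ANOVA for each pairwise
group contrast with Benjamini–Hochberg FDR control at alpha = 0.05 within
each contrast.  Fold changes are linear-scale ratios of group means with
the signed display convention (|FC| >= 1; down-regulation negative).

The error-weighted ANOVA weights each observation by the inverse square of
its measurement standard error:

    w_i = 1 / se_i**2
    F = [ sum_g W_g (ybar_g - ybar)^2 / (k-1) ]
      / [ sum_i w_i (y_i - ybar_g(i))^2 / (N-k) ]

with weighted group means ybar_g, weighted grand mean ybar, and p from the
F(k-1, N-k) upper tail.  With all standard errors equal this reduces
exactly to ordinary one-way ANOVA, which is the compatibility anchor for
the vendor statistic it replaces; with correctly specified per-observation
noise the F statistic is exactly F-distributed under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("bivalscore")

DEFAULT_ALPHA = 0.05
DEFAULT_CONTRASTS = (("day0", "day2"), ("day0", "day4"), ("day0", "day10"))


@dataclass
class ExpressionMatrix:
    """Probe x sample linear intensities with matching standard errors.

    ``groups`` maps sample id -> group label (e.g. day0/day2/day4/day10
    plus a mature-endothelial reference group).
    """

    intensities: pd.DataFrame
    ses: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.intensities.columns.equals(self.ses.columns) or \
                not self.intensities.index.equals(self.ses.index):
            raise ValueError("intensities and ses must share labels")
        missing = set(self.intensities.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def copy_with(self, intensities: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(intensities, self.ses.copy(), self.groups.copy())

    # -- TSV round trip: per-sample "<sample>" and "<sample>.se" columns ----
    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(index=self.intensities.index)
        for s in self.sample_ids:
            out[s] = self.intensities[s]
            out[f"{s}.se"] = self.ses[s]
        out.rename_axis("probe_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, samples: pd.Series) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        df.index.name = None
        value_cols = [c for c in df.columns if not c.endswith(".se")]
        ses = df[[f"{c}.se" for c in value_cols]].copy()
        ses.columns = value_cols
        return cls(df[value_cols], ses, samples)


def read_sample_sheet(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["group"].values, index=df["sample"].values, name="group")


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean empirical distribution.

    After normalisation every column's sorted values equal the
    across-column mean of sorted values; ties share the mean of their rank
    range.  Idempotent; a single column is returned unchanged.
    """
    X = matrix.intensities.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values are not supported")
    n, m = X.shape
    if m < 2:
        return matrix.copy_with(matrix.intensities.copy())
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(n, dtype=float)
    for j in range(m):
        ranks = stats.rankdata(X[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, ref)
    return matrix.copy_with(pd.DataFrame(out, index=matrix.intensities.index,
                                         columns=matrix.intensities.columns))


def background_subtract(matrix: ExpressionMatrix,
                        negctrl_probe_ids: list[str],
                        floor: float = 1.0) -> ExpressionMatrix:
    """Subtract each sample's mean negative-control intensity, flooring at a
    small positive constant so ratios stay defined."""
    if not negctrl_probe_ids:
        raise ValueError("negative-control probe list is empty")
    missing = set(negctrl_probe_ids) - set(matrix.probe_ids)
    if missing:
        raise ValueError(f"control probes absent from matrix: {sorted(missing)}")
    bg = matrix.intensities.loc[negctrl_probe_ids].mean(axis=0)
    out = (matrix.intensities - bg).clip(lower=floor)
    # columns with zero control signal stay exactly unchanged (no flooring)
    zero_cols = [c for c in out.columns if bg[c] == 0]
    out[zero_cols] = matrix.intensities[zero_cols]
    return matrix.copy_with(out)


# ---------------------------------------------------------------------------
# error-weighted ANOVA
# ---------------------------------------------------------------------------

def _ewanova_matrix(values: np.ndarray, ses: np.ndarray,
                    group_codes: np.ndarray,
                    n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised weighted one-way ANOVA over probe rows.

    ``values``/``ses`` are (probes x samples); returns (F, p) arrays.  Rows
    with zero within-group variability get F = inf, p = 0.
    """
    w = 1.0 / ses**2
    N = values.shape[1]
    k = n_groups
    if N <= k:
        raise ValueError("need more samples than groups")
    W_g = np.stack([w[:, group_codes == g].sum(axis=1) for g in range(k)], axis=1)
    Swy_g = np.stack([(w * values)[:, group_codes == g].sum(axis=1)
                      for g in range(k)], axis=1)
    ybar_g = Swy_g / W_g
    grand = Swy_g.sum(axis=1) / W_g.sum(axis=1)
    ssb = (W_g * (ybar_g - grand[:, None])**2).sum(axis=1)
    resid = values - ybar_g[:, group_codes]
    ssw = (w * resid**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (N - k))
    F = np.where(ssw == 0, np.inf, F)
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 1.0, F),
                                              k - 1, N - k))
    # no group effect and no residual: define F = 0, p = 1
    degenerate = (ssw == 0) & (ssb == 0)
    F = np.where(degenerate, 0.0, F)
    p = np.where(degenerate, 1.0, p)
    return F, p


def error_weighted_anova(values, ses, groups) -> tuple[float, float]:
    """Weighted one-way ANOVA for a single probe; see module docstring.

    Returns (F, p).  Zero within-group variability with a real group effect
    is reported as (inf, 0.0) rather than raising.
    """
    values = np.asarray(values, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    labels = pd.Series(list(groups))
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise ValueError("need at least two groups")
    F, p = _ewanova_matrix(values[None, :], ses[None, :], codes, len(uniques))
    return float(F[0]), float(p[0])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean_a: float, mean_b: float) -> float:
    """Signed linear ratio: b/a if b >= a, else -(a/b); |result| >= 1."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("group means must be positive")
    return mean_b / mean_a if mean_b >= mean_a else -(mean_a / mean_b)


# ---------------------------------------------------------------------------
# pairwise differential expression
# ---------------------------------------------------------------------------

def pairwise_de(matrix: ExpressionMatrix,
                contrasts=DEFAULT_CONTRASTS,
                alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-probe weighted ANOVA for each two-group contrast.

    FDR adjustment is applied within each contrast separately.  Fold change
    uses inverse-variance-weighted group means, consistent with the test.
    Returns a tidy frame with one row per probe per contrast.
    """
    frames = []
    V = matrix.intensities.to_numpy(dtype=float)
    S = matrix.ses.to_numpy(dtype=float)
    for group_a, group_b in contrasts:
        cols_a = [matrix.sample_ids.get_loc(s) for s in matrix.samples_in(group_a)]
        cols_b = [matrix.sample_ids.get_loc(s) for s in matrix.samples_in(group_b)]
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise ValueError(f"contrast {group_a} vs {group_b}: "
                             "every group needs >= 2 samples")
        cols = cols_a + cols_b
        codes = np.array([0] * len(cols_a) + [1] * len(cols_b))
        F, p = _ewanova_matrix(V[:, cols], S[:, cols], codes, 2)
        q = bh_fdr(p)
        w = 1.0 / S[:, cols]**2
        wm = lambda sel: ((w[:, sel] * V[:, cols][:, sel]).sum(axis=1)
                          / w[:, sel].sum(axis=1))
        mean_a = wm(codes == 0)
        mean_b = wm(codes == 1)
        fc = np.where(mean_b >= mean_a, mean_b / mean_a, -(mean_a / mean_b))
        frames.append(pd.DataFrame({
            "probe_id": matrix.probe_ids,
            "contrast": f"{group_b}:{group_a}",
            "group_a": group_a,
            "group_b": group_b,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "F": F,
            "p": p,
            "q": q,
            "significant": q <= alpha,
        }))
    return pd.concat(frames, ignore_index=True)


def timepoint_specific_set(results: pd.DataFrame,
                           focal: str = "day2:day0",
                           mode: str = "specific") -> set[str]:
    """Probes significant in the focal contrast, filtered by ``mode``.

    specific: significant in the focal contrast and in no other contrast
    present in ``results`` (the default reading of a timepoint-specific
    set); intersection: significant in every contrast; union: significant
    in any contrast.  The rule used is recorded by callers in run metadata.
    """
    contrasts = set(results["contrast"].unique())
    if focal not in contrasts:
        raise ValueError(f"focal contrast {focal!r} missing from results")
    sig = {c: set(results.loc[(results["contrast"] == c)
                              & results["significant"], "probe_id"])
           for c in contrasts}
    if mode == "specific":
        out = set(sig[focal])
        for c in contrasts - {focal}:
            out -= sig[c]
        return out
    if mode == "intersection":
        out = set(sig[focal])
        for c in contrasts - {focal}:
            out &= sig[c]
        return out
    if mode == "union":
        return set().union(*sig.values())
    raise ValueError(f"unknown mode {mode!r}")


def pca_scores(matrix: ExpressionMatrix, n_components: int = 2,
               scale: bool = False) -> tuple[pd.DataFrame, np.ndarray]:
    """Centred principal-component scores per sample (reporting only).

    Returns (scores, variance_explained_fraction); scores carry the group
    label as a column for plotting.
    """
    X = matrix.intensities.to_numpy(dtype=float).T  # samples x probes
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd == 0, 1.0, sd)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xc)
    df = pd.DataFrame(scores, index=matrix.sample_ids,
                      columns=[f"PC{i + 1}" for i in range(n_components)])
    df["group"] = [matrix.groups[s] for s in matrix.sample_ids]
    return df, pca.explained_variance_ratio_
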