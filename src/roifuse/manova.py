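"""Wilks-lambda MANOVA screening of ROIs, plus simple cohort-matching tests.

For each ROI the m-dimensional measurement vectors of the G groups are
compared through the dispersion matrices

    W  within-group,  B  between-group,  T = W + B  total,

and Wilks' lambda = |W| / |T| in (0, 1]; smaller lambda means stronger
group separation.  P-values use Bartlett's large-sample transform
chi2 = -(n - 1 - (G + m)/2) * ln(lambda) on m*(G-1) degrees of freedom.

The module also provides the pooled two-sample t-test (accepting summary
statistics) and the 2x2 Pearson chi-square used to check demographic
matching of two cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FusionFeatureSet

# fixed precedence for "smallest p" ties, most inclusive measure first
MEASURE_PRECEDENCE = ("fusion", "fmri", "smri", "dti")

DEFAULT_MEASURE_SETS = {
    "fmri": ["fmri"],
    "smri": ["smri"],
    "dti": ["dti"],
    "fusion": ["fmri", "smri", "dti"],
}


@dataclass
class DispersionMatrices:
    W: np.ndarray
    B: np.ndarray
    T: np.ndarray
    n: int
    G: int
    m: int


def _split_groups(X: np.ndarray, groups: np.ndarray) -> list[np.ndarray]:
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != groups.shape[0]:
        raise ValueError("X and groups must have one row per sample")
    if X.shape[1] == 0:
        raise ValueError("no measurements (m = 0)")
    parts = [X[groups == g] for g in np.unique(groups)]
    if len(parts) < 2:
        raise ValueError("need at least two groups")
    for part in parts:
        if part.shape[0] < 2:
            raise ValueError("every group needs at least two samples")
    return parts


def dispersion_matrices(X: np.ndarray, groups: np.ndarray) -> DispersionMatrices:
    """Within/between/total dispersion matrices of grouped measurement vectors.

    Entries are the raw cross-product sums (not divided by degrees of
    freedom), so T = W + B holds exactly.
    """
    parts = _split_groups(X, groups)
    m = parts[0].shape[1]
    n = sum(p.shape[0] for p in parts)
    grand = np.concatenate(parts).mean(axis=0)
    W = np.zeros((m, m))
    B = np.zeros((m, m))
    for part in parts:
        mu = part.mean(axis=0)
        centred = part - mu
        W += centred.T @ centred
        d = mu - grand
        B += part.shape[0] * np.outer(d, d)
    return DispersionMatrices(W=W, B=B, T=W + B, n=n, G=len(parts), m=m)


def wilks_lambda(d: DispersionMatrices) -> float:
    """Wilks' lambda |W|/|T| via log-determinants of the two factors."""
    sign_t, logdet_t = np.linalg.slogdet(d.T)
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise np.linalg.LinAlgError(
            "total dispersion matrix is singular; reduce m, enlarge n, or use "
            "the ridge-regularized path (wilks_test(..., ridge=True))"
        )
    sign_w, logdet_w = np.linalg.slogdet(d.W)
    if sign_w <= 0 or not np.isfinite(logdet_w):
        raise np.linalg.LinAlgError(
            "within-group dispersion matrix is singular; reduce m, enlarge n, or use "
            "the ridge-regularized path (wilks_test(..., ridge=True))"
        )
    return float(min(np.exp(logdet_w - logdet_t), 1.0))


def bartlett_chi2_p(lam: float, n: int, G: int, m: int) -> tuple[float, int, float]:
    """Bartlett's chi-square approximation for Wilks' lambda.

    chi2 = -(n - 1 - (G + m)/2) * ln(lambda), df = m*(G - 1), upper-tail p.
    """
    if not 0 < lam <= 1:
        raise ValueError(f"lambda must lie in (0, 1], got {lam}")
    scale = n - 1 - (G + m) / 2.0
    if scale <= 0:
        raise ValueError(
            f"sample too small for Bartlett's approximation (n={n}, G={G}, m={m})"
        )
    chi2 = -scale * np.log(lam)
    df = m * (G - 1)
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def wilks_test(
    X: np.ndarray, groups: np.ndarray, ridge: bool = False
) -> tuple[float, float, int, float]:
    """(lambda, chi2, df, p) for one grouped sample.

    With ``ridge=True`` a small diagonal load eps = 1e-8 * trace(T)/m is
    added to W and T before the determinants, rescuing nearly singular
    cases at the cost of a slight bias; off by default.
    """
    d = dispersion_matrices(X, groups)
    if ridge:
        eps = 1e-8 * np.trace(d.T) / d.m
        d = DispersionMatrices(
            W=d.W + eps * np.eye(d.m), B=d.B, T=d.T + eps * np.eye(d.m),
            n=d.n, G=d.G, m=d.m,
        )
    lam = wilks_lambda(d)
    chi2, df, p = bartlett_chi2_p(lam, d.n, d.G, d.m)
    return lam, chi2, df, p


def screen_rois(
    fs: FusionFeatureSet,
    labels: np.ndarray,
    measure_sets: dict[str, list[str]] | None = None,
    ridge: bool = False,
) -> pd.DataFrame:
    """Per-ROI Wilks-lambda screen for each requested measure set.

    ``measure_sets`` maps a measure name to the modality blocks it uses
    (default: fmri, smri, dti and their fusion).  ROIs where the test is
    infeasible (e.g. n <= m + G) are recorded with NaN statistics and a
    reason, never silently dropped.
    """
    labels = np.asarray(labels)
    if fs.n_subjects != labels.shape[0]:
        raise ValueError("labels must have one entry per subject")
    measure_sets = DEFAULT_MEASURE_SETS if measure_sets is None else measure_sets
    G = np.unique(labels).size
    rows = []
    for measure, blocks in measure_sets.items():
        cols = np.flatnonzero(np.isin(fs.blocks, blocks))
        if cols.size == 0:
            raise ValueError(f"measure set {measure!r} selects no columns ({blocks})")
        m = cols.size
        for r in range(fs.n_roi):
            roi_name = fs.roi_names[r] if fs.roi_names is not None else f"ROI{r + 1}"
            rec = {"roi": r, "roi_name": roi_name, "measure": measure, "m": m}
            if fs.n_subjects <= m + G:
                rec.update(
                    lam=np.nan, chi2=np.nan, df=m * (G - 1), p=np.nan,
                    neglog10p=np.nan, reason=f"n={fs.n_subjects} <= m+G={m + G}",
                )
            else:
                try:
                    lam, chi2, df, p = wilks_test(fs.data[:, r, cols], labels, ridge=ridge)
                    rec.update(
                        lam=lam, chi2=chi2, df=df, p=p,
                        neglog10p=-np.log10(max(p, np.finfo(float).tiny)), reason="",
                    )
                except np.linalg.LinAlgError as err:
                    rec.update(
                        lam=np.nan, chi2=np.nan, df=m * (G - 1), p=np.nan,
                        neglog10p=np.nan, reason=str(err),
                    )
            rows.append(rec)
    return pd.DataFrame(rows)


def tally_best_measure(screen: pd.DataFrame) -> pd.Series:
    """Count, per measure set, the ROIs where it attains the smallest p.

    Exact ties are broken by the fixed precedence fusion > fmri > smri >
    dti (then alphabetically for other names), with a warning.
    """
    def rank(measure: str) -> int:
        try:
            return MEASURE_PRECEDENCE.index(measure)
        except ValueError:
            return len(MEASURE_PRECEDENCE)

    measures = list(screen["measure"].unique())
    counts = {m: 0 for m in measures}
    for roi, grp in screen.groupby("roi"):
        if grp["p"].isna().any():
            raise ValueError(f"ROI {roi} has missing p-values; cannot tally")
        best_p = grp["p"].min()
        best = sorted(
            grp.loc[grp["p"] == best_p, "measure"], key=lambda m: (rank(m), m)
        )
        if len(best) > 1:
            warnings.warn(
                f"p-value tie at ROI {roi} among {best}; assigned to {best[0]!r}",
                stacklevel=2,
            )
        counts[best[0]] += 1
    return pd.Series(counts, name="n_best_rois")


# ---------------------------------------------------------------------------
# univariate cohort-matching tests


def _summary(x) -> tuple[float, float, int]:
    if isinstance(x, tuple) and len(x) == 3:
        mean, sd, n = x
        if n < 2:
            raise ValueError("summary n must be >= 2")
        return float(mean), float(sd), int(n)
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two observations per sample")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def pooled_t_test(x1, x2) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test; accepts raw samples or (mean, sd, n).

    Returns (t, df, two-sided p) with df = n1 + n2 - 2, so printed cohort
    tables (mean +/- SD and group sizes) can be checked directly.
    """
    m1, s1, n1 = _summary(x1)
    m2, s2, n2 = _summary(x2)
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    t = (m1 - m2) / np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) for the 2x2 table [[a,b],[c,d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column marginal")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
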