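"""Per-ROI multi-index fusion features.

For each ROI of a 90-region parcellation the multi-index vector
concatenates three modality blocks:

* fMRI — the ROI's Fisher-z functional connectivity with every other ROI
  (``n_roi - 1`` coefficients, 89 for the standard atlas);
* sMRI — grey- and white-matter volume (2 features);
* DTI  — FA, RD and MD (3 features);

for 94 features per ROI in the full fusion vector, or 10 when the fMRI
block is reduced to its first five principal components.

Transformers operate on the subjects x ROI x feature array and follow
scikit-learn fit/transform semantics so that, inside cross-validation,
normalisation and PCA can be fitted on the training subjects only.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

FMRI, SMRI, DTI = "fmri", "smri", "dti"
BLOCKS = (FMRI, SMRI, DTI)

# r this close to +/-1 is clipped before atanh to keep z finite
_R_CLIP = 1.0 - 1e-7


def aal90_names() -> list[str]:
    """The 90 AAL cortical/subcortical region names, in atlas order."""
    path = importlib.resources.files("roifuse.data") / "aal90.tsv"
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")["name"].tolist()


@dataclass
class ModalityFeatures:
    """One modality's subjects x ROI x feature block."""

    modality: str  # fmri | smri | dti
    data: np.ndarray  # (n_subjects, n_roi, n_features)
    feature_names: list[list[str]]  # per ROI (fMRI features name the partner ROI)

    def __post_init__(self) -> None:
        if self.modality not in BLOCKS:
            raise ValueError(f"modality must be one of {BLOCKS}, got {self.modality!r}")
        expected = {FMRI: self.data.shape[1] - 1, SMRI: 2, DTI: 3}[self.modality]
        if self.data.shape[2] != expected:
            raise ValueError(
                f"{self.modality} block must have {expected} features per ROI, "
                f"got {self.data.shape[2]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.modality} block contains non-finite values")


@dataclass
class FusionFeatureSet:
    """Per-ROI subjects x m feature matrices with modality-block tags.

    ``data[s, r]`` is the length-m measurement vector of subject ``s`` at
    ROI ``r``; ``blocks`` tags each of the m columns with its modality.
    """

    data: np.ndarray  # (n_subjects, n_roi, m)
    blocks: np.ndarray  # (m,) of {fmri, smri, dti}
    feature_names: list[list[str]]  # per ROI, length m
    subject_ids: list[str] | None = None
    roi_names: list[str] | None = None
    normalized: bool = False
    fit_subjects: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    def block_columns(self, block: str) -> np.ndarray:
        return np.flatnonzero(self.blocks == block)

    def restrict(self, blocks: list[str]) -> "FusionFeatureSet":
        """Keep only the columns of the requested modality blocks."""
        keep = np.flatnonzero(np.isin(self.blocks, blocks))
        if keep.size == 0:
            raise ValueError(f"no columns left after restricting to {blocks}")
        return replace(
            self,
            data=self.data[:, :, keep],
            blocks=self.blocks[keep],
            feature_names=[[names[j] for j in keep] for names in self.feature_names],
        )


# ---------------------------------------------------------------------------
# functional connectivity


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clipping of |r| >= 1-1e-7 (warns when clipping occurs)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= _R_CLIP):
        warnings.warn(
            "correlation(s) with |r| ~ 1 clipped before Fisher z", stacklevel=2
        )
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def _check_timeseries(ts: np.ndarray) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-d (ROI x time) array")
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contains non-finite values")
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance time series at ROI index(es) {dead.tolist()}")
    return ts


def fc_vector(ts: np.ndarray, roi: int) -> np.ndarray:
    """Fisher-z connectivity of one ROI with all others (length n_roi-1)."""
    ts = _check_timeseries(ts)
    n_roi = ts.shape[0]
    if not 0 <= roi < n_roi:
        raise IndexError(f"roi {roi} outside 0..{n_roi - 1}")
    r = np.corrcoef(ts)[roi]
    return fisher_z(np.delete(r, roi))


def fc_features(timeseries: np.ndarray, roi_names: list[str] | None = None) -> ModalityFeatures:
    """Fisher-z FC block for all subjects: (n_subjects, n_roi, n_roi-1)."""
    timeseries = np.asarray(timeseries, dtype=float)
    n_sub, n_roi, _ = timeseries.shape
    if roi_names is None:
        roi_names = [f"ROI{i + 1}" for i in range(n_roi)]
    off = ~np.eye(n_roi, dtype=bool)
    data = np.empty((n_sub, n_roi, n_roi - 1))
    for s in range(n_sub):
        r = np.corrcoef(_check_timeseries(timeseries[s]))
        data[s] = fisher_z(r[off].reshape(n_roi, n_roi - 1))
    names = [
        [f"FC_{roi_names[j]}" for j in range(n_roi) if j != i] for i in range(n_roi)
    ]
    return ModalityFeatures(FMRI, data, names)


# ---------------------------------------------------------------------------
# diffusion scalars


def dti_scalars(eigenvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(FA, RD, MD) from diffusion-tensor eigenvalues l1 >= l2 >= l3.

    RD = (l2 + l3)/2, MD = (l1 + l2 + l3)/3 and FA is the normalised
    eigenvalue dispersion sqrt(3/2)*||l - mean(l)|| / ||l||, which lies in
    [0, 1].  Accepts a single triple or an array whose last axis has length 3.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.shape[-1] != 3:
        raise ValueError("expected eigenvalue triples on the last axis")
    if not np.all(np.isfinite(ev)):
        raise ValueError("non-finite eigenvalues")
    if np.any(np.diff(ev, axis=-1) > 1e-12):
        raise ValueError("eigenvalues must be sorted descending (l1 >= l2 >= l3)")
    if np.any(ev[..., 0] < 0):
        warnings.warn("negative leading eigenvalue(s); noisy tensor fit", stacklevel=2)
    md = ev.mean(axis=-1)
    rd = (ev[..., 1] + ev[..., 2]) / 2.0
    norm = np.linalg.norm(ev, axis=-1)
    dev = np.linalg.norm(ev - md[..., None], axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * dev / norm
    if np.any(norm == 0):
        warnings.warn("all-zero eigenvalue triple(s); FA set to 0", stacklevel=2)
        fa = np.where(norm == 0, 0.0, fa)
    return fa, rd, md


def smri_features(gm: np.ndarray, wm: np.ndarray) -> ModalityFeatures:
    data = np.stack([np.asarray(gm, float), np.asarray(wm, float)], axis=-1)
    names = [["GM", "WM"] for _ in range(data.shape[1])]
    return ModalityFeatures(SMRI, data, names)


def dti_features(fa: np.ndarray, rd: np.ndarray, md: np.ndarray) -> ModalityFeatures:
    data = np.stack(
        [np.asarray(fa, float), np.asarray(rd, float), np.asarray(md, float)], axis=-1
    )
    names = [["FA", "RD", "MD"] for _ in range(data.shape[1])]
    return ModalityFeatures(DTI, data, names)


# ---------------------------------------------------------------------------
# fusion assembly and normalisation


def assemble_fusion(
    *modalities: ModalityFeatures,
    subject_ids: list[str] | None = None,
    roi_names: list[str] | None = None,
) -> FusionFeatureSet:
    """Concatenate modality blocks per ROI in [fMRI | sMRI | DTI] order.

    Any nonempty subset of the three blocks may be given, supporting all
    seven modality combinations.
    """
    if not modalities:
        raise ValueError("need at least one modality block")
    seen = [m.modality for m in modalities]
    if len(set(seen)) != len(seen):
        raise ValueError(f"duplicate modality blocks: {seen}")
    ordered = sorted(modalities, key=lambda m: BLOCKS.index(m.modality))
    shapes = {(m.data.shape[0], m.data.shape[1]) for m in ordered}
    if len(shapes) != 1:
        raise ValueError(f"modality blocks disagree on (subjects, ROIs): {sorted(shapes)}")
    n_sub, n_roi = shapes.pop()
    data = np.concatenate([m.data for m in ordered], axis=2)
    blocks = np.concatenate(
        [np.full(m.data.shape[2], m.modality) for m in ordered]
    )
    feature_names = [
        sum((m.feature_names[r] for m in ordered), []) for r in range(n_roi)
    ]
    return FusionFeatureSet(
        data=data,
        blocks=blocks,
        feature_names=feature_names,
        subject_ids=subject_ids,
        roi_names=roi_names,
    )


def cohort_features(cohort, blocks: list[str] | None = None) -> FusionFeatureSet:
    """Build the fusion feature set straight from a MultimodalCohort."""
    blocks = list(BLOCKS) if blocks is None else blocks
    roi_names = (
        aal90_names() if cohort.n_roi == 90 else [f"ROI{i + 1}" for i in range(cohort.n_roi)]
    )
    mods = []
    if FMRI in blocks:
        mods.append(fc_features(cohort.timeseries, roi_names))
    if SMRI in blocks:
        mods.append(smri_features(cohort.scalars["gm"], cohort.scalars["wm"]))
    if DTI in blocks:
        mods.append(dti_features(cohort.scalars["fa"], cohort.scalars["rd"], cohort.scalars["md"]))
    return assemble_fusion(*mods, subject_ids=cohort.subject_ids, roi_names=roi_names)


class ROIStandardScaler(BaseEstimator, TransformerMixin):
    """Column-wise z-scoring of a subjects x ROI x feature array.

    Means and SDs are learned on the subjects passed to :meth:`fit` and
    applied unchanged to any subjects passed to :meth:`transform`, so a
    scaler fitted on training folds carries no information from test folds.
    """

    def fit(self, X: np.ndarray, y=None) -> "ROIStandardScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected a 3-d (subjects, ROI, feature) array")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0)
        zero = np.argwhere(self.scale_ == 0)
        if zero.size:
            r, c = zero[0]
            raise ValueError(f"zero-SD feature column (ROI {r}, feature {c}) cannot be scaled")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_


def zscore_normalize(
    fs: FusionFeatureSet, fit_on: np.ndarray | None = None
) -> FusionFeatureSet:
    """Z-score every feature column; statistics fitted on ``fit_on`` subjects."""
    idx = np.arange(fs.n_subjects) if fit_on is None else np.asarray(fit_on)
    if idx.size == 0:
        raise ValueError("fit_on must be nonempty")
    scaler = ROIStandardScaler().fit(fs.data[idx])
    return replace(fs, data=scaler.transform(fs.data), normalized=True, fit_subjects=idx)


class ROIBlockPCA(BaseEstimator, TransformerMixin):
    """Per-ROI PCA of the fMRI block of a subjects x ROI x feature array.

    Each ROI gets its own PCA basis (fitted on the subjects seen by
    :meth:`fit`); transform replaces the fMRI columns with the first
    ``n_components`` scores and leaves other blocks untouched.
    """

    def __init__(self, n_components: int = 5, columns: np.ndarray | None = None):
        self.n_components = n_components
        self.columns = columns

    def fit(self, X: np.ndarray, y=None) -> "ROIBlockPCA":
        X = np.asarray(X, dtype=float)
        cols = np.arange(X.shape[2]) if self.columns is None else np.asarray(self.columns)
        if not 1 <= self.n_components <= cols.size:
            raise ValueError(
                f"n_components={self.n_components} outside 1..{cols.size}"
            )
        self.columns_ = cols
        self.pcas_ = []
        self.explained_fraction_ = np.empty(X.shape[1])
        if self.n_components > min(X.shape[0] - 1, cols.size):
            raise ValueError(
                f"n_components={self.n_components} exceeds the rank bound "
                f"min(n_samples-1, n_features) = {min(X.shape[0] - 1, cols.size)}"
            )
        for r in range(X.shape[1]):
            block = X[:, r, :][:, cols]
            pca = PCA(n_components=self.n_components, svd_solver="full").fit(block)
            total_var = block.var(axis=0, ddof=1).sum()
            if pca.explained_variance_[-1] <= 1e-12 * max(total_var, 1e-300):
                raise ValueError(
                    f"n_components={self.n_components} exceeds the data rank at ROI {r}"
                )
            self.pcas_.append(pca)
            # cumulative share of the block's total variance, not of the kept rank
            self.explained_fraction_[r] = pca.explained_variance_.sum() / total_var
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        keep = np.setdiff1d(np.arange(X.shape[2]), self.columns_)
        out = np.empty((X.shape[0], X.shape[1], self.n_components + keep.size))
        for r in range(X.shape[1]):
            scores = self.pcas_[r].transform(X[:, r, :][:, self.columns_])
            out[:, r, :] = np.concatenate([scores, X[:, r, :][:, keep]], axis=1)
        return out


def pca_reduce_fmri_block(
    fs: FusionFeatureSet, k: int = 5, fit_on: np.ndarray | None = None
) -> tuple[FusionFeatureSet, np.ndarray]:
    """Replace the fMRI block with its first ``k`` principal-component scores.

    Returns the reduced feature set and the per-ROI cumulative explained
    variance fraction of the kept components.
    """
    cols = fs.block_columns(FMRI)
    if cols.size == 0:
        raise ValueError("feature set has no fMRI block")
    idx = np.arange(fs.n_subjects) if fit_on is None else np.asarray(fit_on)
    pca = ROIBlockPCA(n_components=k, columns=cols).fit(fs.data[idx])
    data = pca.transform(fs.data)
    keep = np.setdiff1d(np.arange(fs.width), cols)
    blocks = np.concatenate([np.full(k, FMRI), fs.blocks[keep]])
    names = [
        [f"FC_PC{i + 1}" for i in range(k)] + [fs.feature_names[r][j] for j in keep]
        for r in range(fs.n_roi)
    ]
    reduced = replace(
        fs, data=data, blocks=blocks, feature_names=names, fit_subjects=idx
    )
    return reduced, pca.explained_fraction_


# ---------------------------------------------------------------------------
# covariate confound screen


def confound_cca_screen(
    fs: FusionFeatureSet, covariate: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Canonical correlation of each ROI's features with one covariate.

    With a single covariate the (only) canonical correlation equals the
    multiple correlation of the covariate regressed on the ROI's features.
    Significance uses Bartlett's chi-square approximation
    chi2 = -(n - 1 - (p + q + 1)/2) * log(1 - r^2) on p*q = p degrees of
    freedom, with Benjamini-Hochberg correction across ROIs.
    """
    cov = np.asarray(covariate, dtype=float)
    if cov.ndim != 1 or cov.size != fs.n_subjects:
        raise ValueError("covariate must be one value per subject")
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariate contains non-finite values")
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant")
    n = fs.n_subjects
    p = fs.width
    rows = []
    yc = cov - cov.mean()
    for r in range(fs.n_roi):
        X = fs.data[:, r, :]
        Xc = X - X.mean(axis=0)
        coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        resid = yc - Xc @ coef
        r2 = max(0.0, 1.0 - resid @ resid / (yc @ yc))
        cc = float(np.sqrt(min(r2, 1.0)))
        scale = n - 1 - (p + 2) / 2.0
        if scale <= 0:
            raise ValueError(f"sample too small for the CCA test (n={n}, p={p})")
        chi2 = -scale * np.log(max(1.0 - r2, np.finfo(float).tiny))
        pval = float(stats.chi2.sf(chi2, df=p))
        rows.append((r, cc, pval))
    df = pd.DataFrame(rows, columns=["roi", "canonical_correlation", "p"])
    reject, p_adj, *_ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
    df["p_fdr"] = p_adj
    df["significant"] = reject
    if fs.roi_names is not None:
        df.insert(1, "roi_name", [fs.roi_names[r] for r in df["roi"]])
    return df
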