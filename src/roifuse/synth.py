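"""Synthetic two-group multimodal cohorts with known, injected group effects.

The generator emulates the kind of ROI-level data the fusion pipeline
consumes — per-subject BOLD time series over an atlas parcellation, plus
per-ROI grey/white-matter volumes and diffusion scalars (FA, RD, MD) — for
two groups (e.g. patients vs. controls).  Group differences are injected at
known ROIs either as mean shifts on a scalar modality (in pooled-SD units)
or as edits to the target ROI-ROI correlation matrix, so that recovery by
the downstream screening and classification stages can be verified against
ground truth.

Time series are produced by Cholesky colouring of i.i.d. standard-normal
innovations: draws are independent across time (no temporal autocorrelation
or haemodynamic structure), which is a deliberate simplification — the
screening statistics operate on cross-ROI correlations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SCALAR_MODALITIES",
    "EFFECT_MODALITIES",
    "Effect",
    "SynthCohortConfig",
    "GroundTruth",
    "MultimodalCohort",
    "constant_correlation",
    "generate_roi_timeseries",
    "generate_cohort",
]

SCALAR_MODALITIES = ("gm", "wm", "fa", "rd", "md")
EFFECT_MODALITIES = ("fc",) + SCALAR_MODALITIES

# Baseline per-ROI scalar distributions (mean, SD).  Volumes in cm^3,
# diffusivities in 1e-3 mm^2/s, FA dimensionless.  Chosen to sit in the
# range reported for adult AAL parcellations; the screening and
# classification stages are invariant to these scales after z-normalisation.
DEFAULT_SCALAR_MEANS = {"gm": 7.5, "wm": 5.0, "fa": 0.40, "rd": 0.60, "md": 0.80}
DEFAULT_SCALAR_SDS = {"gm": 1.0, "wm": 0.8, "fa": 0.04, "rd": 0.05, "md": 0.05}


@dataclass(frozen=True)
class Effect:
    """One injected group difference.

    For scalar modalities (``gm``/``wm``/``fa``/``rd``/``md``) the group-2
    mean at ``roi`` is shifted by ``size`` pooled SDs.  For ``fc`` the
    group-2 target correlation between ``roi`` and ``partner`` is shifted
    by ``size`` (a correlation delta), exercising the Fisher-z pipeline
    end to end rather than shifting features post hoc.
    """

    roi: int
    modality: str
    size: float
    partner: int | None = None


@dataclass
class SynthCohortConfig:
    n_per_group: int = 160
    n_roi: int = 90
    n_timepoints: int = 200
    base_rho: float = 0.1
    base_corr: np.ndarray | None = None  # overrides base_rho when given
    effects: list[Effect] = field(default_factory=list)
    scalar_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCALAR_MEANS))
    scalar_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCALAR_SDS))
    seed: int = 0


@dataclass
class GroundTruth:
    """The injected-effect map: which ROIs were perturbed, and how."""

    affected_rois: set[int]
    effects: list[Effect]

    def to_dict(self) -> dict:
        return {
            "affected_rois": sorted(r + 1 for r in self.affected_rois),
            "effects": [
                {
                    "roi": e.roi + 1,
                    "modality": e.modality,
                    "size": e.size,
                    "partner": None if e.partner is None else e.partner + 1,
                }
                for e in self.effects
            ],
        }


@dataclass
class MultimodalCohort:
    """Per-subject ROI time series plus per-ROI scalar modality tables."""

    timeseries: np.ndarray  # (n_subjects, n_roi, n_timepoints)
    scalars: dict[str, np.ndarray]  # modality -> (n_subjects, n_roi)
    labels: np.ndarray  # (n_subjects,) in {0, 1}
    subject_ids: list[str]

    @property
    def n_subjects(self) -> int:
        return self.timeseries.shape[0]

    @property
    def n_roi(self) -> int:
        return self.timeseries.shape[1]


def constant_correlation(n_roi: int, rho: float) -> np.ndarray:
    """Exchangeable correlation matrix with constant off-diagonal ``rho``."""
    if not -1.0 / (n_roi - 1) < rho < 1.0:
        raise ValueError(f"rho={rho} is not positive definite for {n_roi} ROIs")
    corr = np.full((n_roi, n_roi), float(rho))
    np.fill_diagonal(corr, 1.0)
    return corr


def _validate_correlation(corr: np.ndarray, what: str = "correlation matrix") -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError(f"{what} must be square, got shape {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError(f"{what} must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError(f"{what} must have unit diagonal")
    smallest = float(np.linalg.eigvalsh(corr)[0])
    if smallest <= 0:
        raise ValueError(
            f"{what} is not positive definite: smallest eigenvalue {smallest:.3e} <= 0"
        )
    return corr


def generate_roi_timeseries(
    target_corr: np.ndarray,
    n_timepoints: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw an ROI x time matrix whose rows have the given population correlation.

    Cholesky colouring of i.i.d. N(0, 1) innovations; columns (timepoints)
    are independent.
    """
    target_corr = _validate_correlation(target_corr, "target_corr")
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    chol = np.linalg.cholesky(target_corr)
    return chol @ rng.standard_normal((target_corr.shape[0], n_timepoints))


def _group_correlations(config: SynthCohortConfig) -> tuple[np.ndarray, np.ndarray]:
    if config.base_corr is not None:
        base = _validate_correlation(np.asarray(config.base_corr, dtype=float), "base_corr")
        if base.shape[0] != config.n_roi:
            raise ValueError(
                f"base_corr has {base.shape[0]} ROIs but config.n_roi={config.n_roi}"
            )
    else:
        base = constant_correlation(config.n_roi, config.base_rho)
    group2 = base.copy()
    for eff in config.effects:
        if eff.modality != "fc":
            continue
        if eff.partner is None:
            raise ValueError(f"fc effect at ROI {eff.roi} needs a partner ROI")
        group2[eff.roi, eff.partner] += eff.size
        group2[eff.partner, eff.roi] += eff.size
    _validate_correlation(group2, "group-2 correlation matrix (after fc deltas)")
    return base, group2


def _validate_effects(config: SynthCohortConfig) -> None:
    for eff in config.effects:
        if eff.modality not in EFFECT_MODALITIES:
            raise ValueError(
                f"unknown modality {eff.modality!r}; valid names: {', '.join(EFFECT_MODALITIES)}"
            )
        if not 0 <= eff.roi < config.n_roi:
            raise ValueError(f"effect ROI {eff.roi} outside 0..{config.n_roi - 1}")
        if not np.isfinite(eff.size):
            raise ValueError("effect size must be finite")


def generate_cohort(config: SynthCohortConfig) -> tuple[MultimodalCohort, GroundTruth]:
    """Generate a two-group cohort with the configured injected effects.

    Group 1 subjects are drawn from the baseline model; group 2 subjects
    from the model with scalar mean shifts (``size`` x modality SD) and fc
    correlation deltas applied.  Each subject has its own RNG stream spawned
    from ``config.seed`` and a (group, index) key, so changing the subject
    count never reshuffles earlier subjects.
    """
    _validate_effects(config)
    base_corr, group2_corr = _group_correlations(config)
    group_corrs = (base_corr, group2_corr)

    shift = {m: np.zeros(config.n_roi) for m in SCALAR_MODALITIES}
    for eff in config.effects:
        if eff.modality in SCALAR_MODALITIES:
            shift[eff.modality][eff.roi] += eff.size * config.scalar_sds[eff.modality]

    n = 2 * config.n_per_group
    timeseries = np.empty((n, config.n_roi, config.n_timepoints))
    scalars = {m: np.empty((n, config.n_roi)) for m in SCALAR_MODALITIES}
    labels = np.empty(n, dtype=int)
    subject_ids = []

    chols = [np.linalg.cholesky(c) for c in group_corrs]
    for group in (0, 1):
        for k in range(config.n_per_group):
            idx = group * config.n_per_group + k
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(group, k))
            )
            timeseries[idx] = chols[group] @ rng.standard_normal(
                (config.n_roi, config.n_timepoints)
            )
            for m in SCALAR_MODALITIES:
                vals = config.scalar_means[m] + config.scalar_sds[m] * rng.standard_normal(
                    config.n_roi
                )
                if group == 1:
                    vals = vals + shift[m]
                scalars[m][idx] = vals
            labels[idx] = group
            subject_ids.append(f"sub-{group + 1}{k + 1:04d}")

    truth = GroundTruth(
        affected_rois={e.roi for e in config.effects},
        effects=list(config.effects),
    )
    cohort = MultimodalCohort(
        timeseries=timeseries, scalars=scalars, labels=labels, subject_ids=subject_ids
    )
    return cohort, truth
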