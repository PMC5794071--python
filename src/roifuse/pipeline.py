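"""Top-level reproducible pipeline: simulate -> fuse -> screen -> classify
-> concord -> contribute.

A single YAML config drives the whole run; every stochastic step is seeded
from the config seed, and a manifest (seed, config, library versions) is
written next to the outputs so a run can be reproduced bit-identically.

User-facing ROI indices (YAML config, CSV/JSON outputs) are 1-based;
everything internal is 0-based.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import ClassifierConfig, nested_cv, permutation_test
from .concordance import pairwise_concordance, prediction_table
from .contribution import contribution_ratios
from .features import ROIBlockPCA, cohort_features, pca_reduce_fmri_block, zscore_normalize
from .io import read_cohort, write_cohort
from .manova import DEFAULT_MEASURE_SETS, screen_rois, tally_best_measure
from .synth import Effect, SynthCohortConfig, generate_cohort

log = logging.getLogger("roifuse")


@dataclass
class RunConfig:
    seed: int = 0
    out: str = "roifuse_run"
    cohort: str | None = None  # directory with an existing cohort
    synth: dict | None = None  # or parameters for the simulator
    measures: list[str] = field(default_factory=lambda: ["fmri", "smri", "dti", "fusion"])
    pca: int | None = None  # reduce the fMRI block to this many components
    global_norm: bool = False  # fit normalisation/PCA on all subjects (leaky, literal)
    classifier: dict = field(default_factory=dict)
    concordance_pairs: list[list[str]] | None = None
    ridge: float = 1e-4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def synth_config_from_dict(spec: dict, seed: int) -> SynthCohortConfig:
    """Build a simulator config from a YAML-style dict (1-based ROI indices)."""
    spec = dict(spec)
    effects = []
    for e in spec.pop("effects", []):
        effects.append(
            Effect(
                roi=int(e["roi"]) - 1,
                modality=e["modality"],
                size=float(e["size"]),
                partner=None if e.get("partner") is None else int(e["partner"]) - 1,
            )
        )
    return SynthCohortConfig(seed=seed, effects=effects, **spec)


def _measure_blocks(measure: str) -> list[str]:
    if measure not in DEFAULT_MEASURE_SETS:
        raise ValueError(
            f"unknown measure {measure!r}; choose from {sorted(DEFAULT_MEASURE_SETS)} "
        )
    return DEFAULT_MEASURE_SETS[measure]


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "load"
    try:
        if (cfg.cohort is None) == (cfg.synth is None):
            raise ValueError("config must give exactly one of 'cohort' or 'synth'")
        if cfg.synth is not None:
            stage = "simulate"
            scfg = synth_config_from_dict(cfg.synth, seed=cfg.seed)
            cohort, truth = generate_cohort(scfg)
            write_cohort(cohort, out / "cohort", truth=truth, seed=cfg.seed)
            log.info("simulated cohort: %d subjects, %d ROIs", cohort.n_subjects, cohort.n_roi)
        else:
            cohort = read_cohort(cfg.cohort)
            log.info("read cohort from %s: %d subjects", cfg.cohort, cohort.n_subjects)
        labels = cohort.labels

        stage = "fuse"
        fs_full = zscore_normalize(cohort_features(cohort))
        fs = fs_full
        if cfg.pca is not None:
            fs, explained = pca_reduce_fmri_block(fs_full, k=cfg.pca)
            fs = zscore_normalize(fs)
            log.info(
                "PCA-reduced fMRI block to %d components (mean explained %.3f)",
                cfg.pca, float(np.mean(explained)),
            )

        stage = "screen"
        screen = screen_rois(fs, labels)
        screen_out = screen.copy()
        screen_out["roi"] = screen_out["roi"] + 1
        screen_out.to_csv(out / "screen.csv", index=False)
        tally = tally_best_measure(screen)
        tally.to_csv(out / "tally.csv", header=True)
        log.info("screen: best-measure tally %s", tally.to_dict())

        stage = "classify"
        ccfg = ClassifierConfig(seed=cfg.seed, **{
            k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg.classifier.items()
        })
        predictions = {}
        for measure in cfg.measures:
            blocks = _measure_blocks(measure)
            reducer = None
            if cfg.pca is not None and not cfg.global_norm and "fmri" in blocks:
                # leakage-safe path: PCA refitted inside each training partition
                sub = fs_full.restrict(blocks)
                X = sub.data
                reducer = ROIBlockPCA(n_components=cfg.pca, columns=sub.block_columns("fmri"))
            else:
                X = fs.restrict(blocks).data.reshape(len(labels), -1)
            report = nested_cv(X, labels, ccfg, reducer=reducer)
            if ccfg.n_permutations > 0:
                report.permutation_p = permutation_test(
                    X, labels, ccfg, report.accuracy_mean, reducer=reducer
                )
            predictions[measure] = report.consensus_prediction
            (out / f"report_{measure}.json").write_text(
                json.dumps(report.to_dict(), indent=2)
            )
            log.info(
                "classify %s: accuracy %.4f +/- %.4f, AUC %.4f",
                measure, report.accuracy_mean, report.accuracy_sd, report.auc,
            )

        stage = "concord"
        table = prediction_table(labels, predictions, subject_ids=cohort.subject_ids)
        table.to_csv(out / "predictions.csv", index=False)
        pairs = (
            [tuple(p) for p in cfg.concordance_pairs]
            if cfg.concordance_pairs is not None
            else list(combinations(cfg.measures, 2))
        )
        if pairs:
            concord = pairwise_concordance(table, pairs)
            concord.to_csv(out / "concord.csv", index=False)

        stage = "contribute"
        X_by_mod = {
            b: fs.data[:, :, fs.block_columns(b)].reshape(len(labels), -1)
            for b in ("fmri", "smri", "dti")
            if fs.block_columns(b).size
        }
        contrib = contribution_ratios(X_by_mod, labels, ridge=cfg.ridge)
        (out / "contrib.json").write_text(
            json.dumps(
                {
                    "r2": contrib.r2,
                    "ratios": contrib.ratios,
                    "ridge": cfg.ridge,
                    "converged": {k: f.converged for k, f in contrib.fits.items()},
                },
                indent=2,
            )
        )
        log.info("contribution ratios: %s", contrib.ratios)

        stage = "manifest"
        manifest = {
            "seed": cfg.seed,
            "config": asdict(cfg),
            "config_hash": _config_hash(cfg),
            "roifuse_version": __version__,
            "numpy_version": np.__version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return out
    except Exception:
        log.exception("pipeline failed at stage %r; partial outputs kept in %s", stage, out)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
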