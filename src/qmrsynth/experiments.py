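"""The three replacement experiments and their agreement analysis.

Experiment I tests the full radiomic system (RS) on the four acquired
contrasts; Experiment II replaces one acquired contrast (FLAIR or T2w)
by its leave-one-out synthesized version at test time only; Experiment
III retrains an RS from scratch without that channel.  Predicted
probabilities of the pairs I-II and I-III are compared with the
identity-regression R^2, ICC and difference summaries.

The RS is fit exclusively on acquired images of the training cohort;
synthesized volumes enter only at test time (train/test firewall).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .phantom import CohortSpec, LesionSpec, TissueModel, generate_cohort
from .physics import WeightedImage
from .quality import icc_agreement, r2_identity
from .radiomics import FeatureConfig, build_feature_table, label_subjects, parse_feature_name
from .rs import NestedCVSurvivalClassifier, evaluate_rs, small_model_grid
from .synthnet import SYNTH_INPUTS, SynthNetConfig, leave_one_out_synthesize

__all__ = [
    "SYNTH_INPUTS",
    "ReplacementStudyConfig",
    "desk_config",
    "run_experiment_I",
    "run_experiment_II",
    "run_experiment_III",
    "compare_probabilities",
    "run_replacement_study",
]

class ContaminationError(RuntimeError):
    """A test subject appeared in its own synthesis training fold."""


@dataclass(frozen=True)
class ReplacementStudyConfig:
    """End-to-end configuration of one replacement study."""

    seed: int = 0
    replaced_contrast: str = "FLAIR"
    n_train: int = 120
    n_test: int = 24
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    lesion: LesionSpec = field(default_factory=LesionSpec)
    noise_sigma: float = 0.02
    threshold_days: int = 480
    tissue: TissueModel = field(default_factory=TissueModel)
    synth: SynthNetConfig = field(default_factory=lambda: SynthNetConfig())
    outer_folds: int = 5
    inner_folds: int = 10
    k_grid: tuple[int, ...] = (8, 16)
    mrmr_bins: int = 8
    use_small_grid: bool = False
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    # warm-start the LOO folds from a model pretrained on this many
    # training-cohort subjects (0 disables pretraining); fine-tuning uses
    # the synth config's own (smaller) learning rate
    synth_pretrain_subjects: int = 0
    synth_pretrain_epochs: int = 30
    synth_pretrain_lr: float = 3e-3


def desk_config(seed: int = 0, replaced_contrast: str = "FLAIR") -> ReplacementStudyConfig:
    """Scaled-down study (small grids, pointwise-scale synthesis net) that
    runs in tens of seconds per seed on one CPU while keeping every protocol
    element.  The noise level is set low enough that the Rician floor does
    not mask the planted texture contrast (it is the difficulty knob of the
    replacement experiment)."""
    grid = (32, 32, 10)
    # a prominent edema halo and strong planted texture: the desk-scale
    # incarnation of a strongly-planted-signal cohort
    lesion = LesionSpec(ed_radius=7.0, tc_radius=3.2, net_radius=1.8)
    # steady single-protocol cohort: modest between-subject class-mean
    # spread (the cross-subject ambiguity of the voxel-wise inversion is
    # proportional to it), strong planted edema texture
    tissue = TissueModel(ed_texture_amp=0.20, subject_jitter=0.015)
    synth = SynthNetConfig(
        input_contrasts=SYNTH_INPUTS[replaced_contrast],
        target_contrast=replaced_contrast,
        base_width=16, depth=0, kernel_size=1, learning_rate=2e-4, batch_size=8,
        max_epochs=2, early_stop_patience=2, seed=seed,
        min_slice_foreground=16, n_init_candidates=2, slice_stride=2,
        val_region="lesion")
    return ReplacementStudyConfig(
        seed=seed, replaced_contrast=replaced_contrast,
        n_train=96, n_test=10, grid_shape=grid, lesion=lesion, tissue=tissue,
        noise_sigma=0.005,
        synth=synth, outer_folds=3, inner_folds=5, k_grid=(2, 4), mrmr_bins=4,
        use_small_grid=True,
        # at this grid only the edema halo is large enough for stable
        # texture statistics; the core ROIs are mostly boundary voxels
        feature_config=FeatureConfig(rois=("ED",)),
        synth_pretrain_subjects=36, synth_pretrain_epochs=50)


def _labeled(records, threshold_days):
    table = pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "survival_days": [r.survival_days for r in records],
        "censored": [r.censored for r in records],
    })
    labels, excluded = label_subjects(table, threshold_days)
    kept = [r for r in records if r.subject_id in labels.index]
    return kept, labels.loc[[r.subject_id for r in kept]], excluded


def run_experiment_I(rs_full: NestedCVSurvivalClassifier, test_records,
                     test_labels, feature_config: FeatureConfig) -> dict:
    """Full RS on the four acquired contrasts."""
    feats = build_feature_table(test_records, feature_config=feature_config)
    return evaluate_rs(rs_full, feats, test_labels) | {"features": feats}


def run_experiment_II(rs_full: NestedCVSurvivalClassifier, test_records,
                      test_labels, synth_volumes: dict[str, WeightedImage],
                      replaced_contrast: str, feature_config: FeatureConfig,
                      folds: list[dict] | None = None) -> dict:
    """Full RS with the replaced channel's features recomputed from the
    synthesized volume; the other three channels are untouched."""
    if folds is not None:
        for fold in folds:
            if fold["test"] in fold["train"] or fold["test"] in fold["val"]:
                raise ContaminationError(
                    f"subject {fold['test']} overlaps its own synthesis fold")
    replaced = {r.subject_id: {replaced_contrast: synth_volumes[r.subject_id]}
                for r in test_records}
    feats = build_feature_table(test_records, feature_config=feature_config,
                                replaced_images=replaced)
    return evaluate_rs(rs_full, feats, test_labels) | {"features": feats}


def run_experiment_III(rs_reduced: NestedCVSurvivalClassifier, test_records,
                       test_labels, dropped_contrast: str,
                       feature_config: FeatureConfig) -> dict:
    """Reduced RS (trained from scratch) on the three remaining contrasts."""
    for f in rs_reduced.selected_features_:
        if parse_feature_name(f)[0] == dropped_contrast:
            raise ValueError(f"reduced model selected a {dropped_contrast} feature: {f}")
    contrasts = tuple(c for c in feature_config.contrasts if c != dropped_contrast)
    feats = build_feature_table(test_records, contrast_set=contrasts,
                                feature_config=feature_config)
    return evaluate_rs(rs_reduced, feats, test_labels) | {"features": feats}


def compare_probabilities(probs: dict[str, pd.Series]) -> dict:
    """Agreement of probability outputs for the pairs I-II and I-III."""
    out = {}
    for other in ("II", "III"):
        if other not in probs:
            continue
        common = probs["I"].index.intersection(probs[other].index)
        x = probs["I"].loc[common].to_numpy()
        y = probs[other].loc[common].to_numpy()
        d = y - x
        out[f"I-{other}"] = {
            "r2": r2_identity(x, y),
            "icc": icc_agreement(np.column_stack([x, y])),
            "median_diff": float(np.median(d)),
            "iqr_diff": float(np.percentile(d, 75) - np.percentile(d, 25)),
            "differences": d,
        }
    return out


def run_replacement_study(config: ReplacementStudyConfig) -> dict:
    """Generate cohorts, train the full and reduced RS, run the LOO
    synthesis and all three experiments; return the full report."""
    cfg = config
    fc = cfg.feature_config
    base = dict(grid_shape=cfg.grid_shape, noise_sigma=cfg.noise_sigma,
                threshold_days=cfg.threshold_days, lesion=cfg.lesion,
                tissue=cfg.tissue)
    train_records, _ = generate_cohort(
        CohortSpec(n_subjects=cfg.n_train, seed=cfg.seed * 2 + 1, **base), "train")
    # test follow-up fully observed: at desk scale every test subject must
    # contribute a label for the paired probability analysis
    test_records, _ = generate_cohort(
        CohortSpec(n_subjects=cfg.n_test, seed=cfg.seed * 2 + 2,
                   censor_rate=0.0, **base), "test")

    train_records, y_train, _ = _labeled(train_records, cfg.threshold_days)
    test_records, y_test, _ = _labeled(test_records, cfg.threshold_days)

    grid = small_model_grid(cfg.seed) if cfg.use_small_grid else None
    train_feats = build_feature_table(train_records, feature_config=fc)
    rs_full = NestedCVSurvivalClassifier(
        model_grid=grid, outer_folds=cfg.outer_folds, inner_folds=cfg.inner_folds,
        k_grid=cfg.k_grid, seed=cfg.seed,
        mrmr_bins=cfg.mrmr_bins).fit(train_feats, y_train)

    dropped = cfg.replaced_contrast
    reduced_contrasts = tuple(c for c in fc.contrasts if c != dropped)
    reduced_feats = build_feature_table(train_records, contrast_set=reduced_contrasts,
                                        feature_config=fc)
    rs_reduced = NestedCVSurvivalClassifier(
        model_grid=grid, outer_folds=cfg.outer_folds, inner_folds=cfg.inner_folds,
        k_grid=cfg.k_grid, seed=cfg.seed + 1,
        mrmr_bins=cfg.mrmr_bins).fit(reduced_feats, y_train)

    synth_cfg = dc_replace(cfg.synth,
                           input_contrasts=SYNTH_INPUTS[dropped],
                           target_contrast=dropped, seed=cfg.seed)
    pretrain = (train_records[:cfg.synth_pretrain_subjects]
                if cfg.synth_pretrain_subjects else None)
    synth_volumes, folds = leave_one_out_synthesize(
        test_records, synth_cfg, pretrain_records=pretrain,
        pretrain_epochs=cfg.synth_pretrain_epochs,
        pretrain_lr=cfg.synth_pretrain_lr)

    exp1 = run_experiment_I(rs_full, test_records, y_test, fc)
    exp2 = run_experiment_II(rs_full, test_records, y_test, synth_volumes,
                             dropped, fc, folds=folds)
    exp3 = run_experiment_III(rs_reduced, test_records, y_test, dropped, fc)

    probs = {"I": exp1["probabilities"], "II": exp2["probabilities"],
             "III": exp3["probabilities"]}
    agreement = compare_probabilities(probs)
    return {
        "config": cfg,
        "metrics": {"I": exp1["metrics"], "II": exp2["metrics"], "III": exp3["metrics"]},
        "probabilities": pd.DataFrame(probs),
        "agreement": agreement,
        "rs_full": rs_full,
        "rs_reduced": rs_reduced,
        "synth_volumes": synth_volumes,
        "folds": folds,
        "test_records": test_records,
        "test_labels": y_test,
    }
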