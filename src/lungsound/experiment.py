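"""End-to-end composition: corpus -> preprocessing -> features -> model.

These helpers tie the modules together for the seeded synthetic
experiments: subject-wise fold construction, train-fold-only
augmentation, featurization (with optional annotation-driven band
weighting), training, recording-level evaluation, the cross-dataset
protocol, and the feature-representation comparison harness.

Problem sizes: the experiments use 3.0 s recordings (one 2.5 s frame
each after trimming) so that a full corpus at the standard per-class
counts trains on a single CPU in minutes; the generator itself defaults
to 10 s recordings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .augment import AugmentPolicy, expand_class
from .explain import band_mass, grad_cam
from .features import (MelSpectrogram, WeightProfile, apply_weight_map, mfcc,
                       mel_spectrogram, stft_spectrogram)
from .model.network import ModelConfig
from .preprocess import PreprocessConfig, preprocess_recording
from .synth import (TABLE_ICBHI_COUNTS, AnnotatedRecording,
                    SyntheticDatasetConfig, generate_recordings)
from .train import TrainConfig, evaluate_model, kfold_split, train_model

__all__ = ["featurize_recordings", "build_manifest", "run_synthetic_experiment",
           "cross_dataset_protocol", "compare_feature_representations"]


def build_manifest(recordings: list[AnnotatedRecording]) -> pd.DataFrame:
    return pd.DataFrame({
        "label": [r.class_label for r in recordings],
        "subject_id": [r.subject_id for r in recordings],
        "dataset_tag": [r.dataset_tag for r in recordings],
        "crackle": [r.crackle_flag for r in recordings],
        "wheeze": [r.wheeze_flag for r in recordings],
        "augmented": [r.augmented for r in recordings],
    })


def _feature_matrix(frame, feature: str):
    if feature == "mel":
        return mel_spectrogram(frame)
    if feature == "mfcc":
        return mfcc(frame)
    if feature == "stft":
        return stft_spectrogram(frame)
    raise ValueError(f"unknown feature {feature!r}")


def featurize_recordings(recordings, class_labels,
                         preprocess_config: PreprocessConfig = PreprocessConfig(),
                         weighting: str = "off",
                         weight_profile: WeightProfile = WeightProfile(),
                         feature: str = "mel"):
    """Preprocess and featurize recordings.

    Returns (X, frame_recording, y, mel_center_freqs).  ``weighting``:
    "off" leaves features untouched; "features" applies the crackle/
    wheeze band weighting using each recording's annotation flags.
    """
    label_index = {lbl: i for i, lbl in enumerate(class_labels)}
    mats, frame_rec, y = [], [], []
    freqs = None
    for r_idx, rec in enumerate(recordings):
        y.append(label_index[rec.class_label])
        frames = preprocess_recording(rec.samples, rec.sample_rate,
                                      preprocess_config,
                                      recording_id=rec.subject_id)
        for frame in frames:
            feat = _feature_matrix(frame, feature)
            if feature == "mel":
                if weighting == "features":
                    feat = apply_weight_map(feat, rec.crackle_flag,
                                            rec.wheeze_flag, weight_profile)
                freqs = feat.mel_center_freqs
                mats.append(feat.values)
            else:
                mats.append(feat)
            frame_rec.append(r_idx)
    X = np.stack(mats).astype(np.float32)
    return X, np.asarray(frame_rec), np.asarray(y), freqs


def _augment_train(recordings, train_idx, seed):
    """Expand the training recordings class-by-class; originals untouched."""
    by_class: dict[str, list] = {}
    for i in train_idx:
        by_class.setdefault(recordings[i].class_label, []).append(recordings[i])
    out = []
    for label in sorted(by_class):
        policy = AugmentPolicy(seed=seed)
        out.extend(expand_class(by_class[label], policy))
    return out


def run_synthetic_experiment(seed: int = 0,
                             counts: dict | None = None,
                             duration: float = 3.0,
                             fold: int = 0,
                             max_epochs: int = 15,
                             model_config: ModelConfig | None = None,
                             train_config: TrainConfig | None = None,
                             weighting: str = "off",
                             n_gradcam: int = 20,
                             verbose: bool = False) -> dict:
    """Seeded corpus-to-metrics experiment on one cross-validation fold.

    Generates the synthetic corpus (per-class counts default to the
    standard composition 300/200/150/100), builds subject-wise folds,
    augments the training fold only, trains the fusion model, and
    evaluates recording-level metrics on the held-out test fold; also
    computes the Grad-CAM wheeze-band localization statistic over test
    inputs of the wheeze-bearing classes.

    With ``weighting="features"`` the crackle/wheeze band weighting is
    applied to training and validation features from their annotation
    flags; test features are then evaluated both *without* flags
    (``report`` -- annotations are unavailable at inference time and
    using them would leak labels) and *with* flags (``report_flags``)
    for comparison.  The default trains unweighted: a model trained on
    weighted features depends on the weight-induced amplitudes and does
    not transfer to unweighted inference inputs.  Grad-CAM always uses
    the unweighted test inputs.
    """
    counts = dict(TABLE_ICBHI_COUNTS) if counts is None else counts
    ds_config = SyntheticDatasetConfig(counts=counts, duration=duration,
                                       seed=seed, dataset_tag="icbhi-like")
    recordings = generate_recordings(ds_config)
    manifest = build_manifest(recordings)
    class_labels = sorted(manifest["label"].unique())

    split = kfold_split(manifest, k=5, seed=seed)
    train_idx, val_idx, test_idx = split.roles(fold)
    train_recs = _augment_train(recordings, train_idx, seed=seed + 1)
    val_recs = [recordings[i] for i in val_idx]
    test_recs = [recordings[i] for i in test_idx]

    pp = PreprocessConfig()
    feature_weighting = "features" if weighting == "features" else "off"
    # training is frame-level: recording labels replicated per frame
    Xtr, ftr, ytr, _ = featurize_recordings(train_recs, class_labels, pp,
                                            weighting=feature_weighting)
    ytr_frames = ytr[ftr]
    Xval, fval, yval, _ = featurize_recordings(val_recs, class_labels, pp,
                                               weighting=feature_weighting)
    yval_frames = yval[fval]
    Xte, fte, yte, mel_freqs = featurize_recordings(test_recs, class_labels, pp,
                                                    weighting="off")

    if model_config is None:
        model_config = ModelConfig(n_classes=len(class_labels))
    if train_config is None:
        class_weights = None
        if weighting == "loss":
            # loss-mode reading of the band weighting: per-class weights,
            # crackle-annotated classes 1.5, wheeze-annotated 1.3
            profile = WeightProfile()
            by_label = {r.class_label: r for r in recordings}
            class_weights = tuple(
                profile.crackle_weight if by_label[lbl].crackle_flag
                else profile.wheeze_weight if by_label[lbl].wheeze_flag
                else 1.0
                for lbl in class_labels)
        train_config = TrainConfig(epochs=max_epochs, seed=seed,
                                   class_weights=class_weights)
    params, history = train_model(Xtr, ytr_frames, Xval, yval_frames,
                                  train_config, model_config, verbose=verbose)
    report, probs, preds = evaluate_model(params, model_config, Xte, fte, yte,
                                          class_labels)
    report_flags = None
    if weighting == "features":
        Xte_w, fte_w, yte_w, _ = featurize_recordings(
            test_recs, class_labels, pp, weighting="features")
        report_flags, _, _ = evaluate_model(params, model_config, Xte_w,
                                            fte_w, yte_w, class_labels)

    # Grad-CAM localization over a seeded sample of wheeze-class test inputs
    wheeze_classes = {i for i, lbl in enumerate(class_labels)
                      if any(r.class_label == lbl and r.wheeze_flag
                             for r in test_recs)}
    candidates = [i for i in range(len(Xte)) if yte[fte[i]] in wheeze_classes]
    rng = np.random.default_rng(seed + 2)
    chosen = rng.choice(candidates, size=min(n_gradcam, len(candidates)),
                        replace=False) if candidates else []
    masses = []
    for i in chosen:
        rec_label = yte[fte[i]]
        spec = MelSpectrogram(Xte[i].astype(np.float64), mel_freqs)
        cam = grad_cam(params, model_config, spec, int(rec_label))
        masses.append(band_mass(cam, mel_freqs, (200.0, 800.0)))

    return {
        "class_labels": class_labels,
        "report": report,
        "report_flags": report_flags,
        "probs": probs,
        "preds": preds,
        "y_test": yte,
        "X_test": Xte,
        "frame_recording_test": fte,
        "mel_center_freqs": mel_freqs,
        "history": history,
        "params": params,
        "model_config": model_config,
        "gradcam_wheeze_masses": masses,
        "gradcam_wheeze_median": float(np.median(masses)) if masses else float("nan"),
        "n_recordings": len(recordings),
        "n_train_frames": len(Xtr),
    }


def cross_dataset_protocol(recordings_a, recordings_b,
                           seed: int = 0, max_epochs: int = 8,
                           model_config: ModelConfig | None = None,
                           val_fraction: float = 0.2) -> dict:
    """Train on corpus A, test on corpus B over shared classes (and back).

    Returns {"a_to_b": MetricsReport, "b_to_a": MetricsReport,
    "shared_classes": [...]}.
    """
    labels_a = {r.class_label for r in recordings_a}
    labels_b = {r.class_label for r in recordings_b}
    shared = sorted(labels_a & labels_b)
    if not shared:
        raise ValueError("datasets share no classes")

    def restrict(recs):
        return [r for r in recs if r.class_label in shared]

    def run(train_recs, test_recs, sub_seed):
        pp = PreprocessConfig()
        subjects = sorted({r.subject_id for r in train_recs})
        rng = np.random.default_rng(sub_seed)
        rng.shuffle(subjects)
        n_val = max(1, int(val_fraction * len(subjects)))
        val_subjects = set(subjects[:n_val])
        tr = [r for r in train_recs if r.subject_id not in val_subjects]
        va = [r for r in train_recs if r.subject_id in val_subjects]
        Xtr, ftr, ytr, _ = featurize_recordings(tr, shared, pp)
        Xva, fva, yva, _ = featurize_recordings(va, shared, pp)
        Xte, fte, yte, _ = featurize_recordings(test_recs, shared, pp)
        cfg = model_config or ModelConfig(n_classes=len(shared))
        params, _ = train_model(Xtr, ytr[ftr], Xva, yva[fva],
                                TrainConfig(epochs=max_epochs, seed=sub_seed),
                                cfg)
        report, _, _ = evaluate_model(params, cfg, Xte, fte, yte, shared)
        return report

    return {
        "shared_classes": shared,
        "a_to_b": run(restrict(recordings_a), restrict(recordings_b), seed),
        "b_to_a": run(restrict(recordings_b), restrict(recordings_a), seed),
    }


#: Downsampling grids that bring each representation to a comparable size
#: for the linear probe (rows, columns).
_PROBE_SLICES = {
    "mel": (slice(None, None, 2), slice(None, None, 5)),
    "mfcc": (slice(None), slice(None, None, 5)),
    "stft": (slice(None, None, 8), slice(None, None, 5)),
}


def compare_feature_representations(seed: int = 0,
                                    counts: dict | None = None,
                                    duration: float = 4.0) -> dict:
    """Held-out macro-F1 of a linear probe per input representation.

    A multinomial logistic regression on standardized, downsampled
    features -- the same probe capacity for every representation -- with
    segment probabilities averaged per recording.  A linear probe is the
    standard way to rank representations without confounding the
    comparison with per-representation network tuning.
    Returns {"mel": f1, "mfcc": f1, "stft": f1}.
    """
    from sklearn.linear_model import LogisticRegression

    counts = counts or {"healthy": 40, "pneumonia": 30, "asthma": 24,
                        "COPD": 16}
    ds = SyntheticDatasetConfig(counts=counts, duration=duration, seed=seed,
                                dataset_tag="cmp")
    recordings = generate_recordings(ds)
    manifest = build_manifest(recordings)
    class_labels = sorted(manifest["label"].unique())
    split = kfold_split(manifest, k=5, seed=seed)
    train_idx, val_idx, test_idx = split.roles(0)
    train_recs = [recordings[i] for i in np.r_[train_idx, val_idx]]
    test_recs = [recordings[i] for i in test_idx]
    pp = PreprocessConfig()

    out = {}
    for feature, (rs, cs) in _PROBE_SLICES.items():
        Xtr, ftr, ytr, _ = featurize_recordings(train_recs, class_labels, pp,
                                                feature=feature)
        Xte, fte, yte, _ = featurize_recordings(test_recs, class_labels, pp,
                                                feature=feature)
        A = Xtr[:, rs, cs].reshape(len(Xtr), -1)
        B = Xte[:, rs, cs].reshape(len(Xte), -1)
        mu, sd = A.mean(axis=0), A.std(axis=0) + 1e-6
        probe = LogisticRegression(max_iter=3000, random_state=seed)
        probe.fit((A - mu) / sd, ytr[ftr])
        probs = probe.predict_proba((B - mu) / sd)
        agg = np.zeros((len(yte), len(class_labels)))
        cnt = np.zeros(len(yte))
        np.add.at(agg, fte, probs)
        np.add.at(cnt, fte, 1)
        preds = (agg / cnt[:, None]).argmax(axis=1)
        cm = np.zeros((len(class_labels),) * 2, dtype=int)
        np.add.at(cm, (yte, preds), 1)
        from .train import metrics_from_confusion
        out[feature] = metrics_from_confusion(cm, class_labels).macro["f1"]
    return out
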