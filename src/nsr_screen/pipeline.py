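"""End-to-end convenience runs: render -> calibrate -> segment -> screen.

These helpers wire the stage modules together for benchmarking on the
synthetic cohort generator; they are what the acceptance script and the
worked examples call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classify as clf
from . import preprocess as pp
from . import quantify as qt
from . import segmentation as seg
from . import synthetic as syn


@dataclass
class SegBenchResult:
    test_dice: float
    test_iou: float
    history: dict
    n_train: int
    n_test: int


def segmentation_benchmark(
    seed: int = 0,
    cohort: syn.CohortConfig | None = None,
    n_train_images: int = 160,
    epochs: int = 5,
    model_config: seg.SegModelConfig | None = None,
) -> SegBenchResult:
    """Train a compact segmenter on the synthetic cohort and measure test Dice.

    Renders the full cohort, calibrates every image, splits 90/10/20 at the
    participant level, trains on a subsample of the training images (the
    synthetic scenes are homogeneous enough that a modest subsample
    saturates performance) and reports macro Dice/IoU on the held-out
    participants' images.
    """
    cohort = cohort or syn.CohortConfig(seed=seed)
    render = syn.RenderConfig(seed=seed)
    images, flush, labels, _, parts = syn.generate_image_dataset(
        cohort, syn.FlushKinetics(), render)
    prepped = [pp.preprocess_pair(im, lb, fl)
               for im, lb, fl in zip(images, labels, flush)]
    split = seg.split_by_participant([p.id for p in parts], seed=seed)
    sets: dict[str, tuple[list, list]] = {k: ([], []) for k in ("train", "val", "test")}
    for img, _, flm in prepped:
        part = split.split_of(img.participant_id)
        sets[part][0].append(img)
        sets[part][1].append(flm)
    rng = np.random.default_rng(seed)
    n_sub = min(n_train_images, len(sets["train"][0]))
    idx = rng.choice(len(sets["train"][0]), size=n_sub, replace=False)
    tr_im = [sets["train"][0][i] for i in idx]
    tr_m = [sets["train"][1][i] for i in idx]
    config = model_config or seg.SegModelConfig(
        encoder_depth=2, base_channels=8, epochs=epochs, batch_size=8,
        lr=2e-3, seed=seed)
    model = seg.build_segmenter(config)
    history = seg.train_segmenter(model, tr_im, tr_m,
                                  sets["val"][0][:24], sets["val"][1][:24])
    metrics = seg.evaluate(model, sets["test"][0], sets["test"][1])
    return SegBenchResult(test_dice=metrics.dice, test_iou=metrics.iou,
                          history=history, n_train=n_sub,
                          n_test=len(sets["test"][0]))


def overfit_single_image(seed: int = 0, epochs: int = 60) -> float:
    """Memorisation check: Dice after fitting one synthetic photograph."""
    cfg = syn.CohortConfig(n_hc=1, n_per_disorder=1, seed=seed)
    images, flush, labels, *_ = syn.generate_image_dataset(
        cfg, syn.FlushKinetics(), syn.RenderConfig(seed=seed))
    # last HC time point: well-developed flushing
    img, lbm, flm = pp.preprocess_pair(images[4], labels[4], flush[4])
    model = seg.build_segmenter(seg.SegModelConfig(
        encoder_depth=2, base_channels=8, epochs=epochs, batch_size=8,
        lr=2e-3, seed=seed))
    seg.train_segmenter(model, [img] * 8, [flm] * 8, [img], [flm])
    return seg.dice(seg.predict_mask(model, img), flm)


def screening_benchmark(
    seed: int = 0,
    cohort: syn.CohortConfig | None = None,
    scheme: str = "three_scale",
    patient_group: str = "DP",
    grid: clf.HyperGrid | None = None,
) -> clf.ScreeningResult:
    """Cross-validated screening on generator-truth feature vectors."""
    cohort = cohort or syn.CohortConfig(seed=seed)
    X, groups, _ = syn.generate_feature_table(cohort, scheme=scheme)
    sel = np.isin(groups, ["HC", patient_group])
    y = (groups[sel] == patient_group).astype(int)
    return clf.run_screening(X[sel], y, grid, clf.CvConfig(seed=seed),
                             comparison=f"HC vs. {patient_group}", scheme=scheme)


def features_from_masks(
    images, flush_masks, label_masks, participants,
    geometry: qt.SiteGeometry, scheme: str = "three_scale",
) -> tuple[np.ndarray, np.ndarray]:
    """Participant feature matrix from calibrated masks (predicted or truth)."""
    cells: dict[str, dict] = {}
    for img, lbm, flm in zip(images, label_masks, flush_masks):
        for m in qt.measure_image(flm, lbm, geometry, img.time_min):
            cells.setdefault(img.participant_id, {})[(m.concentration, m.time_min)] = m
    group_of = {p.id: p.group for p in participants}
    X, y = [], []
    for pid in sorted(cells):
        fv = qt.build_feature_vector(cells[pid], scheme=scheme, participant_id=pid)
        X.append(fv.values)
        y.append(group_of[pid])
    return np.vstack(X), np.array(y)
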