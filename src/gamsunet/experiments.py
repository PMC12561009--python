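"""Reusable desk-scale experiment: phantom cohort -> train -> evaluate.

This is the reduced-scale recovery study used by the validation suite:
12 phantom subjects (8 train / 4 test), the depth-3 width-(8,16,32)
network, slices processed on a 64x64 grid, a short training budget, and
the full per-slice metric / exclusion / volumetry protocol on the
held-out subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import extract_slices, split_subjects, znormalize
from .metrics_stats import (
    VolumeEstimate,
    filter_slices,
    slice_record,
    volume_regression,
    whole_brain_volume,
)
from .network import GAMSUNetPP, NetworkConfig
from .phantom import PhantomConfig, generate_phantom
from .train_infer import TrainConfig, predict_volume, train

_SEED_MOD = 2**31

REDUCED_NETWORK = NetworkConfig(depth=3, widths=(8, 16, 32))
RECOVERY_TARGET = 64
RECOVERY_EPOCHS = 8  # <= 20; the phantom task converges well before that
N_SUBJECTS = 12
N_TRAIN = 8
N_TEST = 4


@dataclass
class RecoveryResult:
    seed: int
    mean_dice: float
    per_subject_dice: dict[str, float]
    volume_ratios: dict[str, float]
    volume_r2: float
    n_included: int


def phantom_recovery(seed: int, epochs: int = RECOVERY_EPOCHS,
                     phantom_cfg: PhantomConfig | None = None) -> RecoveryResult:
    """Train the reduced network on 8 phantoms, evaluate on 4 held out."""
    seed = seed % _SEED_MOD
    cfg = phantom_cfg or PhantomConfig()
    child = np.random.SeedSequence(seed).generate_state(N_SUBJECTS) % _SEED_MOD
    subjects = []
    for i, s in enumerate(child):
        image, mask = generate_phantom(cfg, int(s))
        image.subject_id = mask.subject_id = f"sub-{i:03d}"
        subjects.append((image, mask))
    ids = [img.subject_id for img, _ in subjects]
    split = split_subjects(ids, N_TRAIN, N_TEST, seed)

    train_samples = []
    for image, mask in subjects:
        if image.subject_id in split.train_ids:
            train_samples += extract_slices(znormalize(image), mask, target=RECOVERY_TARGET)

    net = GAMSUNetPP(REDUCED_NETWORK, seed=seed)
    tc = TrainConfig(epochs=epochs, seed=seed, augment=True)
    net, _ = train(net, train_samples, tc)

    dices: list[float] = []
    per_subject: dict[str, float] = {}
    ratios: dict[str, float] = {}
    estimates: list[VolumeEstimate] = []
    for image, mask in subjects:
        if image.subject_id not in split.test_ids:
            continue
        pred = predict_volume(net, image, tc, target=RECOVERY_TARGET)
        gt_slices = extract_slices(znormalize(image), mask, target=RECOVERY_TARGET)
        records = [
            slice_record(pred.labels[:, :, s.slice_index], s.mask,
                         s.subject_id, s.slice_index)
            for s in gt_slices
        ]
        included = [r.dice for r in filter_slices(records) if r.included]
        per_subject[image.subject_id] = float(np.mean(included))
        dices += included
        dx, dy, _ = image.voxels.shape
        pv = whole_brain_volume(pred, (dx, dy), image.spacing)
        rv = whole_brain_volume(mask, (dx, dy), image.spacing)
        ratios[image.subject_id] = pv / rv
        estimates.append(VolumeEstimate(image.subject_id, pv, rv))

    return RecoveryResult(
        seed=seed,
        mean_dice=float(np.mean(dices)),
        per_subject_dice=per_subject,
        volume_ratios=ratios,
        volume_r2=volume_regression(estimates),
        n_included=len(dices),
    )
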