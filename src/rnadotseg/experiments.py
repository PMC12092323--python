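"""Desk-scale end-to-end experiment: generate, train, sweep, score.

This is the CPU-sized counterpart of the full study: a reduced ("tiny")
network trained on small seeded synthetic patches, followed by the
grey/area-threshold sweep and tolerance-matched F1 scoring.  It validates the
mechanism of the whole pipeline, not the headline numbers of a full-scale
GPU run.
"""

from __future__ import annotations

import numpy as np

from . import synthgen, trainer, dotcall, pipeline
from .netarch import NetworkConfig, build_network
from .trainer import LossConfig, OptimizerConfig, PhaseSpec

__all__ = ["make_synthetic_dataset", "run_desk_experiment",
           "DESK_GREY_RANGE", "DESK_AREA_RANGE"]

DESK_GREY_RANGE = (128, 160, 192, 208, 224, 240, 248, 252, 254)
DESK_AREA_RANGE = (0, 1, 2, 3, 4, 5)


def make_synthetic_dataset(n: int, shape: tuple[int, int], seed: int,
                           max_dots: int | None = None) -> list[synthgen.SyntheticPatch]:
    """n independent seeded patches; `max_dots` optionally caps the per-patch
    count so tiny patches do not overflow the placement budget."""
    patches = []
    for i in range(n):
        patch_seed = seed * 100_000 + i
        rng = np.random.default_rng(patch_seed)
        plan = synthgen.plan_patch(rng)
        if max_dots is not None and plan.n > max_dots:
            plan.n = max_dots
        patches.append(synthgen.generate_patch(shape=shape, seed=patch_seed,
                                               rng=rng, plan=plan))
    return patches


def run_desk_experiment(seed: int = 0, n_train: int = 64, n_held_out: int = 16,
                        shape: tuple[int, int] = (128, 128), epochs: int = 40,
                        alpha: float = 0.6, learning_rate: float = 2.0,
                        eps: float = 1e-4, grey_range=DESK_GREY_RANGE,
                        area_range=DESK_AREA_RANGE, tolerance: float = 5.0,
                        callback=None) -> dict:
    """Generate `n_train` + `n_held_out` synthetic patches, train the tiny
    network with Tversky loss, sweep post-processing thresholds on the
    held-out patches, and report the best F1.

    Returns a dict with `history`, `best` (grey, area, f1), `grid`, and the
    held-out probability maps.
    """
    train_patches = make_synthetic_dataset(n_train, shape, seed)
    held_out = make_synthetic_dataset(n_held_out, shape, seed + 7919)

    config = NetworkConfig(backbone_size="tiny", input_size=shape[0],
                           backbone_droppath=0.0, upscale_dropout=0.15,
                           final_section_mode="none")
    model = build_network(config, seed=seed)
    schedule = [PhaseSpec(real_samples_per_epoch=n_train,
                          generated_samples_per_epoch=0,
                          epochs=epochs, backbone_frozen=False)]
    # no augmentation here: the synthetic patches are already randomized, and
    # large early rotations slow convergence badly in short runs
    history = trainer.train(
        model, train_patches, [], schedule,
        loss=LossConfig(kind="tversky", alpha=alpha),
        optimizer=OptimizerConfig(learning_rate=learning_rate, rho=0.975,
                                  batch_size=4, eps=eps),
        seed=seed, augment_config=None, callback=callback)

    maps = [pipeline.predict_patch(model, p.image) for p in held_out]
    gts = [[(x, y) for x, y, _ in p.dots] for p in held_out]
    grid, best = dotcall.threshold_surface(maps, gts, grey_range, area_range,
                                           tolerance=tolerance)
    return {"model": model, "history": history, "maps": maps, "gts": gts,
            "grid": grid, "best": best}
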