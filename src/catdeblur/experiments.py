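"""Scaled-down study conditions shared by the test-suite and the
acceptance script.

The full-scale architecture (64-filter stems, nine residual blocks,
GPU-scale schedules) is far beyond a single CPU, so the smoke-scale
experiments keep the paper-faithful topology — same layer pattern,
stride plan, losses and optimizer — while narrowing the filter banks
and shortening the schedules: 64x64 fixtures, 16 training / 8 held-out
faces, >= 200 generator steps per GAN, learning rate 1e-3 for the short
schedules.  These conditions are fixed here, in one place, so every
consumer measures the same thing.
"""
from __future__ import annotations

import numpy as np

from .cat import CatParams, to_grayscale, run_cat
from .data import BlurSpec, FaceFixtureSpec, build_paired_corpus
from .deblur import NetworkSpec, TrainConfig, train_deblur, apply_deblur
from .metrics import ssim
from .translate import TranslatorSpec, train_translator, translate

IMAGE_SIZE = 64
N_TRAIN = 16
N_HELDOUT = 8
DEBLUR_GEN_STEPS = 320
TRANSLATOR_GEN_STEPS = 1000
HELDOUT_SEED_OFFSET = 10_000


def smoke_deblur_spec() -> NetworkSpec:
    # critic_norm="none": batch norm inside a gradient-penalty critic
    # couples the batch and destabilizes the smoke-scale runs, so the
    # documented escape hatch is used here (the full-scale default keeps
    # batch normalization).
    return NetworkSpec(initial_filters=8, down_filters=(16, 32), up_filters=(16, 8),
                       n_residual_blocks=3, disc_filters=(8, 16, 32, 64),
                       critic_norm="none")


def smoke_translator_spec() -> TranslatorSpec:
    # a single stride-2 stage keeps the residual trunk at 32x32, which
    # preserves far more spatial detail per CPU-step than the deep
    # 4-stage bottleneck of the full-scale architecture
    return TranslatorSpec(gen_down_filters=(32,), gen_up_filters=(32,),
                          n_residual_blocks=3, disc_filters=(8, 16, 32, 64))


def smoke_deblur_config(seed: int, gen_steps: int = DEBLUR_GEN_STEPS) -> TrainConfig:
    # slow generator against a well-trained critic (5 critic steps, the
    # WGAN convention) so the near-identity start is refined, not lost
    steps_per_epoch = N_TRAIN // 4
    return TrainConfig(lr_generator=5e-5, lr_discriminator=2e-4,
                       critic_steps_per_gen=5, batch_size=4,
                       epochs=max(1, gen_steps // steps_per_epoch), seed=seed)


def smoke_translator_config(seed: int, gen_steps: int = TRANSLATOR_GEN_STEPS) -> TrainConfig:
    steps_per_epoch = N_TRAIN // 4
    return TrainConfig(lr_generator=1e-3, lr_discriminator=2e-4,
                       critic_steps_per_gen=1, batch_size=4,
                       epochs=max(1, gen_steps // steps_per_epoch), seed=seed)


def build_smoke_corpora(seed: int, cat_params: CatParams | None = None,
                        blur: BlurSpec | None = None):
    """(train, held-out) paired corpora of face fixtures."""
    cat_params = cat_params or CatParams()
    blur = blur or BlurSpec()
    train = build_paired_corpus(FaceFixtureSpec(image_size=IMAGE_SIZE, seed=seed),
                                N_TRAIN, blur, cat_params)
    held = build_paired_corpus(
        FaceFixtureSpec(image_size=IMAGE_SIZE, seed=seed + HELDOUT_SEED_OFFSET),
        N_HELDOUT, blur, cat_params)
    return train, held


def deblur_pairs(samples, cat_params: CatParams | None = None, with_cat: bool = True):
    """(input sketch, target sketch) pairs for the deblurring stage.

    With CAT the input is the CAT sketch of the blurred photo and the
    target the CAT sketch of the clean photo; the ablation replaces CAT
    by the plain luminance grayscale.
    """
    cat_params = cat_params or CatParams()
    if with_cat:
        return [(run_cat(s.blurred, cat_params), s.sketch) for s in samples]
    return [(to_grayscale(s.blurred), to_grayscale(s.clean)) for s in samples]


def translator_pairs(samples, with_cat: bool = True, deblur_generator=None):
    """(sketch, clean photo) supervision for the translator stage.

    When a trained deblur generator is supplied the input sketches are
    the deblurred CAT sketches of the blurred photos — the translator
    then trains on exactly the domain it sees inside the pipeline.
    Without one, the clean CAT sketch is used.
    """
    cat_params = CatParams()
    if not with_cat:
        if deblur_generator is None:
            return [(to_grayscale(s.clean), s.clean) for s in samples]
        return [(apply_deblur(deblur_generator, to_grayscale(s.blurred)), s.clean)
                for s in samples]
    if deblur_generator is None:
        return [(s.sketch, s.clean) for s in samples]
    return [(apply_deblur(deblur_generator, run_cat(s.blurred, cat_params)), s.clean)
            for s in samples]


def run_deblur_smoke(seed: int, cat_params: CatParams | None = None,
                     with_cat: bool = True, gen_steps: int = DEBLUR_GEN_STEPS):
    """Train the sketch deblurrer at smoke scale and measure the
    held-out SSIM of its outputs against the target sketches.

    Returns a dict with the generator, the loss history and the mean
    held-out SSIM of the blurred input sketches (baseline) versus the
    deblurred outputs.
    """
    cat_params = cat_params or CatParams()
    train, held = build_smoke_corpora(seed, cat_params)
    gen, history = train_deblur(deblur_pairs(train, cat_params, with_cat),
                                smoke_deblur_spec(),
                                smoke_deblur_config(seed, gen_steps))
    held_pairs = deblur_pairs(held, cat_params, with_cat)
    ssim_in = float(np.mean([ssim(x, t) for x, t in held_pairs]))
    ssim_out = float(np.mean([ssim(apply_deblur(gen, x), t) for x, t in held_pairs]))
    return {"generator": gen, "history": history, "train": train, "held": held,
            "ssim_input": ssim_in, "ssim_output": ssim_out}


def run_translator_smoke(seed: int, with_cat: bool = True,
                         gen_steps: int = TRANSLATOR_GEN_STEPS,
                         deblur_generator=None):
    """Train the sketch-to-photo translator at smoke scale.

    With a trained deblur generator the supervision sketches are the
    pipeline's own deblurred sketches (the evaluation feeds the
    translator deblur-module output, so training on that domain avoids
    a train/inference shift); otherwise clean CAT sketches are used.
    Measures mean held-out SSIM of translated sketches against the
    clean photos, at initialization and after training.
    """
    train, held = build_smoke_corpora(seed)
    pairs = translator_pairs(train, with_cat, deblur_generator)
    held_pairs = translator_pairs(held, with_cat, deblur_generator)

    from .translate import TranslatorGenerator
    init_gen = TranslatorGenerator(smoke_translator_spec(), np.random.default_rng(seed))
    gen, history = train_translator(pairs, smoke_translator_spec(),
                                    cfg=smoke_translator_config(seed, gen_steps))
    ssim_init = float(np.mean([ssim(translate(init_gen, s), p) for s, p in held_pairs]))
    ssim_trained = float(np.mean([ssim(translate(gen, s), p) for s, p in held_pairs]))
    return {"generator": gen, "history": history, "train": train, "held": held,
            "ssim_init": ssim_init, "ssim_trained": ssim_trained}


def run_end_to_end(deblur_gen, translator_gen, held, cat_params: CatParams | None = None):
    """Full pipeline on held-out fixtures: blurred photo -> CAT -> deblur
    -> translate; compares SSIM(photo_out, clean) to SSIM(blurred, clean)."""
    cat_params = cat_params or CatParams()
    rows = []
    for s in held:
        sketch_b = run_cat(s.blurred, cat_params)
        sketch_d = apply_deblur(deblur_gen, sketch_b)
        photo = translate(translator_gen, sketch_d)
        rows.append({"ssim_blurred": ssim(s.blurred, s.clean),
                     "ssim_pipeline": ssim(photo, s.clean)})
    improved = sum(r["ssim_pipeline"] > r["ssim_blurred"] for r in rows)
    return {"rows": rows, "n_improved": improved, "n_total": len(rows),
            "improved_fraction": improved / len(rows)}
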