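"""End-to-end orchestration: blurred photo -> CAT sketch -> deblurred
sketch -> translated color photo, plus the with/without-CAT ablation
experiment and its two-condition metric report."""
from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cat import CatParams, GammaPolicy, GaussianKernelSpec, run_cat, to_grayscale
from .data import BlurSpec, FaceFixtureSpec
from .deblur import NetworkSpec, TrainConfig, apply_deblur, train_deblur
from .exceptions import CatDeblurError
from .metrics import (MetricReport, TABLE_METRICS, evaluate_corpus,
                      fit_brisque_model, fit_niqe_model)
from .translate import LossWeights, TranslatorSpec, train_translator, translate
from . import experiments


@dataclass(frozen=True)
class PipelineConfig:
    cat: CatParams = field(default_factory=CatParams)
    blur: BlurSpec = field(default_factory=BlurSpec)
    fixture: FaceFixtureSpec = field(default_factory=FaceFixtureSpec)
    deblur_spec: NetworkSpec = field(default_factory=experiments.smoke_deblur_spec)
    deblur_train: TrainConfig | None = None
    translator_spec: TranslatorSpec = field(default_factory=experiments.smoke_translator_spec)
    translator_train: TrainConfig | None = None
    loss_weights: LossWeights = field(default_factory=LossWeights)
    n_train: int = experiments.N_TRAIN
    n_test: int = experiments.N_HELDOUT
    seed: int = 0
    output_root: str = "catdeblur-out"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "cat" in raw:
            c = raw["cat"]
            kw["cat"] = CatParams(
                kernel=GaussianKernelSpec(**c.get("kernel", {})),
                gamma_policy=GammaPolicy(**c.get("gamma_policy", {})),
                dodge_blend=c.get("dodge_blend", False))
        for key, typ in (("blur", BlurSpec), ("fixture", FaceFixtureSpec),
                         ("deblur_spec", NetworkSpec), ("deblur_train", TrainConfig),
                         ("translator_spec", TranslatorSpec),
                         ("translator_train", TrainConfig), ("loss_weights", LossWeights)):
            if key in raw:
                val = raw[key]
                for seq in ("down_filters", "up_filters", "disc_filters",
                            "gen_down_filters", "gen_up_filters", "skin_tone"):
                    if isinstance(val.get(seq), list):
                        val[seq] = tuple(val[seq])
                kw[key] = typ(**val)
        for key in ("n_train", "n_test", "seed", "output_root"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True,
                                     default=str).encode()).hexdigest()[:16]


def write_manifest(path, cfg: PipelineConfig, extra: dict | None = None) -> dict:
    manifest = {"config": cfg.to_dict(), "config_hash": config_hash(cfg),
                "seed": cfg.seed, "package_version": __version__,
                "numpy_version": np.__version__,
                "python_version": platform.python_version()}
    manifest.update(extra or {})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def run_pipeline(blurred: np.ndarray, deblur_gen, translator_gen,
                 cat_params: CatParams | None = None):
    """Full inference pass; returns (blurred sketch, deblurred sketch, photo)."""
    if deblur_gen is None or translator_gen is None:
        raise CatDeblurError("both trained generators are required")
    sketch_blurred = run_cat(blurred, cat_params or CatParams())
    sketch_deblurred = apply_deblur(deblur_gen, sketch_blurred)
    photo = translate(translator_gen, sketch_deblurred)
    return sketch_blurred, sketch_deblurred, photo


def run_experiment(cfg: PipelineConfig, with_cat: bool = True,
                   output_root=None) -> MetricReport:
    """Train both stages on the fixture corpus and evaluate one condition.

    The "without CAT" ablation feeds the plain luminance grayscale in
    place of the CAT sketch at every stage.  The metric report follows
    the 9-row evaluation-table layout (the two learned-IQA rows are
    reported as unavailable).
    """
    from .data import build_paired_corpus
    from dataclasses import replace

    cat_params = cfg.cat
    train = build_paired_corpus(replace(cfg.fixture, seed=cfg.seed),
                                cfg.n_train, cfg.blur, cat_params)
    held = build_paired_corpus(
        replace(cfg.fixture, seed=cfg.seed + experiments.HELDOUT_SEED_OFFSET),
        cfg.n_test, cfg.blur, cat_params)

    deblur_cfg = cfg.deblur_train or experiments.smoke_deblur_config(cfg.seed)
    trans_cfg = cfg.translator_train or experiments.smoke_translator_config(cfg.seed)
    deblur_gen, _ = train_deblur(
        experiments.deblur_pairs(train, cat_params, with_cat), cfg.deblur_spec, deblur_cfg)
    translator_gen, _ = train_translator(
        experiments.translator_pairs(train, with_cat, deblur_gen),
        cfg.translator_spec, cfg.loss_weights, trans_cfg)

    # IQA reference models are fitted on the clean training corpus
    train_grays = [to_grayscale(s.clean) for s in train]
    brisque_model = fit_brisque_model(train_grays)
    niqe_model = fit_niqe_model(train_grays)

    candidates, references = [], []
    for s in held:
        if with_cat:
            sketch = run_cat(s.blurred, cat_params)
        else:
            sketch = to_grayscale(s.blurred)
        photo = translate(translator_gen, apply_deblur(deblur_gen, sketch))
        candidates.append(photo)
        references.append(s.clean)

    report = evaluate_corpus(candidates, references,
                             brisque_model=brisque_model, niqe_model=niqe_model,
                             config={"with_cat": with_cat, "seed": cfg.seed,
                                     "config_hash": config_hash(cfg)})
    if output_root is not None:
        root = Path(output_root)
        cond = "with_cat" if with_cat else "without_cat"
        root.mkdir(parents=True, exist_ok=True)
        report.to_json(root / f"report_{cond}.json")
        report.to_csv(root / f"report_{cond}.csv")
        write_manifest(root / f"manifest_{cond}.json", cfg, {"condition": cond})
    return report


def experiment_table(report_with: MetricReport, report_without: MetricReport) -> pd.DataFrame:
    """Two-condition summary with one row per evaluation-table metric."""
    rows = []
    sw, swo = report_with.summary(), report_without.summary()
    for metric in TABLE_METRICS:
        rows.append({"metric": metric, "with_cat": sw[metric], "without_cat": swo[metric]})
    return pd.DataFrame(rows).set_index("metric")
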