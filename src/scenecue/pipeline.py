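"""Orchestration of the two experiment analyses on synthetic inputs.

run_exp1: score-table construction, 2AFC simulation, confidence-ROC/AUC per
duration with the bootstrap AUC comparison, per-image realness, realness
ratings, fixed-effects regressions, and the layer-wise encoding comparison
for realness scores.

run_exp2: 5-AFC categorization simulation (consuming the realness scores
from Experiment 1 or synthesizing them), its regression table, and the
encoding comparison for per-image accuracy.

Every stage seed is derived from the single master seed and echoed to the
run manifest, so any output table can be regenerated from the manifest
alone. Images are presented at both durations (the within-participant
crossing of the counterbalanced design), so every image has trials at each
duration as the realness score requires.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import encoding as enc
from . import scores as sc
from . import sdt
from . import synthetic as syn
from .effects import EffectsModel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_exp1", "run_exp2", "build_stimuli", "child_seed"]


def child_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; round-trips losslessly to YAML/JSON."""

    seed: int = 0
    # stimulus world
    n_categories: int = 5
    images_per_category_per_condition: int = 30
    corpus_scenes_per_category: int = 200
    objects_per_category: int = 8
    # segmentation noise
    miss_rate: float = 0.1
    false_label_rate: float = 0.1
    prob_noise_sd: float = 0.1
    # observers
    n_participants_exp1: int = 50
    n_participants_exp2: int = 44
    participant_sd: float = 0.3
    # ratings generator
    rating_alpha: float = 3.5
    rating_beta_anchor: float = 0.15
    rating_beta_diag: float = -0.09
    rating_noise_sd: float = 1.0
    rating_participant_sd: float = 0.5
    # 5-AFC generator
    afc_b0: float = 0.5
    afc_b_diag: float = 0.53
    afc_b_realness: float = 0.48
    afc_b_duration: float = -1.07
    # encoding stage
    n_layers: int = 10
    feature_dim: int = 64
    srp_dim: int | None = None
    snr_profile: str = "sigmoid"
    snr_scale: float = 6.0
    n_trained_models: int = 7
    n_random_models: int = 7
    # inference machinery
    n_boot_auc: int = 2000
    n_perm: int = 10000
    n_boot: int = 1000
    fdr_alpha: float = 0.05
    bf_prior_scale: float = 0.707

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def build_stimuli(config: RunConfig) -> dict:
    """Build the labeled corpus, score table, and scored stimulus image set.

    Returns corpus, score table, and an image table (one row per image) with
    nominal category, condition (real/generated), raw and z-scored anchor/
    diagnosticity scores.
    """
    corpus_spec = syn.default_corpus_spec(
        child_seed(config.seed, "corpus"),
        n_categories=config.n_categories,
        objects_per_category=config.objects_per_category,
        n_scenes_per_category=config.corpus_scenes_per_category)
    corpus = syn.gen_corpus(corpus_spec)
    table = sc.compute_score_table(corpus)

    stim_spec = syn.default_corpus_spec(
        child_seed(config.seed, "stimuli"),
        n_categories=config.n_categories,
        objects_per_category=config.objects_per_category,
        n_scenes_per_category=2 * config.images_per_category_per_condition)
    stimuli = syn.gen_corpus(stim_spec)
    preds = syn.gen_segmentation(
        stimuli, miss_rate=config.miss_rate, false_label_rate=config.false_label_rate,
        prob_noise_sd=config.prob_noise_sd, seed=child_seed(config.seed, "segmentation"))
    filtered = sc.filter_predictions(preds)
    scene_scores = sc.assign_scene_scores(filtered, table)
    images = stimuli.scene_table.rename(columns={"scene_id": "image_id"}).merge(
        scene_scores.drop(columns=["category"]), on="image_id", how="left")
    for col in ("anchor_score", "diag_score"):
        images[col] = images[col].fillna(0.0)
    # first half of each category's scenes are "real", second half "generated"
    n_half = config.images_per_category_per_condition
    images["condition"] = "generated"
    images.loc[images.groupby("category").cumcount() < n_half, "condition"] = "real"
    images["z_anchor"] = sc.z_transform(images["anchor_score"].to_numpy())
    images["z_diag"] = sc.z_transform(images["diag_score"].to_numpy())
    return {"corpus": corpus, "score_table": table, "predictions": preds,
            "scene_scores": scene_scores, "images": images}


def _crossed_durations(images: pd.DataFrame) -> pd.DataFrame:
    out = pd.concat([images.assign(duration=50), images.assign(duration=500)],
                    ignore_index=True)
    return out


def _write(df: pd.DataFrame, out_dir: Path | None, name: str, outputs: dict) -> None:
    outputs[name] = df
    if out_dir is not None:
        df.to_csv(out_dir / f"{name}.csv", index=False)


def _manifest(config: RunConfig, stages: list[str], counts: dict,
              out_dir: Path | None, name: str) -> dict:
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "stage_seeds": {s: child_seed(config.seed, s) for s in stages},
        "row_counts": counts,
    }
    if out_dir is not None:
        (out_dir / name).write_text(json.dumps(manifest, indent=2))
    return manifest


def run_exp1(config: RunConfig, out_dir=None) -> dict:
    """Experiment 1 analysis bundle on the synthetic world."""
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}

    world = build_stimuli(config)
    images = world["images"]
    _write(world["score_table"].table, out_dir, "score_table", outputs)
    _write(world["scene_scores"], out_dir, "scene_scores", outputs)

    image_trials = _crossed_durations(images)
    observer = syn.ObserverSpec(n_participants=config.n_participants_exp1,
                                participant_sd=config.participant_sd,
                                seed=child_seed(config.seed, "observer"))
    trials = syn.simulate_2afc(image_trials, observer)
    _write(trials, out_dir, "trials_2afc", outputs)
    logger.info("exp1: %d 2AFC trials from %d images", len(trials), len(images))

    # ROC / AUC per duration + bootstrap comparison
    roc_rows, auc_rows = [], []
    for dur, sub in trials.groupby("duration"):
        curve = sdt.empirical_roc(sub, labels={"duration": dur, "grouping": "pooled"})
        roc_rows.append(pd.DataFrame({"duration": dur, "fa": curve.fa, "hit": curve.hit}))
        auc_rows.append({"duration": dur, "auc_pooled": curve.auc,
                         "auc_participant_mean": sdt.group_auc(sub)})
    _write(pd.concat(roc_rows, ignore_index=True), out_dir, "roc_points", outputs)
    _write(pd.DataFrame(auc_rows), out_dir, "auc", outputs)
    boot = sdt.auc_boot_test(trials[trials["duration"] == 500],
                             trials[trials["duration"] == 50],
                             n_boot=config.n_boot_auc,
                             seed=child_seed(config.seed, "auc_boot"))
    _write(pd.DataFrame([{k: (v if not isinstance(v, tuple) else str(v))
                          for k, v in boot.items()}]), out_dir, "auc_boot", outputs)

    realness = sdt.image_realness(trials)
    _write(realness, out_dir, "realness", outputs)

    # 2AFC regression (fixed-effects simplification)
    trials = trials.assign(resp_real=(trials["response"] == "real").astype(int))
    afc_fit = EffectsModel.from_dataframe(
        trials, "resp_real", factors=("condition", "duration"),
        continuous=("z_anchor", "z_diag"),
        interactions=(("condition", "duration"), ("condition", "z_diag")),
        family="logistic").fit()
    _write(afc_fit.to_frame().reset_index(names="term"), out_dir, "effects_2afc", outputs)
    _write(afc_fit.linear_trend("z_diag", "condition"), out_dir,
           "trends_2afc_diag", outputs)

    # realness ratings for generated images
    gen_images = images[images["condition"] == "generated"].reset_index(drop=True)
    ratings = syn.simulate_ratings(
        gen_images, alpha=config.rating_alpha, beta_anchor=config.rating_beta_anchor,
        beta_diag=config.rating_beta_diag, noise_sd=config.rating_noise_sd,
        participant_sd=config.rating_participant_sd,
        n_participants=config.n_participants_exp1,
        seed=child_seed(config.seed, "ratings"))
    _write(ratings, out_dir, "ratings", outputs)
    rating_fit = EffectsModel.from_dataframe(
        ratings, "rating", continuous=("z_anchor", "z_diag"),
        interactions=(("z_anchor", "z_diag"),), family="linear").fit()
    _write(rating_fit.to_frame().reset_index(names="term"), out_dir,
           "effects_ratings", outputs)

    # encoding analysis of mean realness ratings per generated image
    y = (ratings.groupby("image_id")["rating"].mean()
         .reindex(gen_images["image_id"]).to_numpy())
    feature_spec = syn.FeatureSpec(
        n_layers=config.n_layers, dims_per_layer=config.feature_dim,
        profile=config.snr_profile, snr_scale=config.snr_scale,
        n_trained_models=config.n_trained_models, n_random_models=config.n_random_models,
        seed=child_seed(config.seed, "features"))
    store = syn.gen_feature_store(y, feature_spec, image_ids=gen_images["image_id"].to_numpy())
    enc_res = enc.EncodingAnalysis(store, y, srp_dim=config.srp_dim,
                                   seed=child_seed(config.seed, "encoding")).fit(
        n_perm=config.n_perm, n_boot=config.n_boot,
        alpha=config.fdr_alpha, prior_scale=config.bf_prior_scale)
    _write(enc_res.scores, out_dir, "encoding_scores", outputs)
    _write(enc_res.comparison, out_dir, "encoding_realness_bins", outputs)

    stages = ["corpus", "stimuli", "segmentation", "observer", "auc_boot",
              "ratings", "features", "encoding"]
    counts = {k: len(v) for k, v in outputs.items()}
    outputs["manifest"] = _manifest(config, stages, counts, out_dir, "manifest_exp1.json")
    outputs["images"] = images
    return outputs


def run_exp2(config: RunConfig, out_dir=None, realness: pd.DataFrame | None = None,
             images: pd.DataFrame | None = None) -> dict:
    """Experiment 2 analysis bundle; reuses Experiment 1 realness scores when
    given, otherwise synthesizes them from a fresh 2AFC simulation."""
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}

    if realness is None or images is None:
        world = build_stimuli(config)
        images = world["images"]
        image_trials = _crossed_durations(images)
        observer = syn.ObserverSpec(n_participants=config.n_participants_exp1,
                                    participant_sd=config.participant_sd,
                                    seed=child_seed(config.seed, "observer"))
        realness = sdt.image_realness(syn.simulate_2afc(image_trials, observer))

    # all generated images plus a fixed subset of real images, both durations
    n_real = 10 * config.n_categories
    real_pool = images[images["condition"] == "real"]
    real_sub = real_pool.groupby("category", group_keys=False).head(
        max(1, n_real // config.n_categories))
    exp2_images = pd.concat([images[images["condition"] == "generated"], real_sub],
                            ignore_index=True)
    exp2_images = _crossed_durations(exp2_images).merge(
        realness, on=["image_id", "duration"], how="left")
    exp2_images["realness"] = exp2_images["realness"].fillna(0.5)
    exp2_images["z_realness"] = sc.z_transform(exp2_images["realness"].to_numpy())
    exp2_images["z_diag"] = sc.z_transform(exp2_images["diag_score"].to_numpy())
    exp2_images["z_anchor"] = sc.z_transform(exp2_images["anchor_score"].to_numpy())

    trials = syn.simulate_5afc(
        exp2_images, b0=config.afc_b0, b_diag=config.afc_b_diag,
        b_realness=config.afc_b_realness, b_duration=config.afc_b_duration,
        n_participants=config.n_participants_exp2,
        categories=tuple(sorted(images["category"].unique())),
        seed=child_seed(config.seed, "afc5"))
    _write(trials, out_dir, "trials_5afc", outputs)

    trials = trials.merge(exp2_images[["image_id", "duration", "condition"]].drop_duplicates(),
                          on=["image_id", "duration"], how="left")
    anchor_map = exp2_images.drop_duplicates(["image_id", "duration"])[
        ["image_id", "duration", "z_anchor"]]
    trials = trials.merge(anchor_map, on=["image_id", "duration"], how="left")
    fit = EffectsModel.from_dataframe(
        trials, "correct", factors=("condition", "duration"),
        continuous=("z_anchor", "z_diag", "z_realness"),
        family="logistic", guess_rate=0.2).fit()
    _write(fit.to_frame().reset_index(names="term"), out_dir, "effects_5afc", outputs)

    # encoding analysis of per-image categorization accuracy
    acc = trials.groupby("image_id")["correct"].mean()
    unique_images = exp2_images.drop_duplicates("image_id")
    y = acc.reindex(unique_images["image_id"]).to_numpy()
    feature_spec = syn.FeatureSpec(
        n_layers=config.n_layers, dims_per_layer=config.feature_dim,
        profile=config.snr_profile, snr_scale=config.snr_scale,
        n_trained_models=config.n_trained_models, n_random_models=config.n_random_models,
        seed=child_seed(config.seed, "features_exp2"))
    store = syn.gen_feature_store(y, feature_spec,
                                  image_ids=unique_images["image_id"].to_numpy())
    enc_res = enc.EncodingAnalysis(store, y, srp_dim=config.srp_dim,
                                   seed=child_seed(config.seed, "encoding_exp2")).fit(
        n_perm=config.n_perm, n_boot=config.n_boot,
        alpha=config.fdr_alpha, prior_scale=config.bf_prior_scale)
    _write(enc_res.scores, out_dir, "encoding_scores_5afc", outputs)
    _write(enc_res.comparison, out_dir, "encoding_accuracy_bins", outputs)

    stages = ["corpus", "stimuli", "segmentation", "observer", "afc5",
              "features_exp2", "encoding_exp2"]
    counts = {k: len(v) for k, v in outputs.items()}
    outputs["manifest"] = _manifest(config, stages, counts, out_dir, "manifest_exp2.json")
    return outputs
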