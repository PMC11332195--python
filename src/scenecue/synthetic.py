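"""Synthetic world generators for the scene-realism / categorization pipeline.

Every input the analysis consumes can be generated here with planted
ground-truth parameters: a labeled object-scene corpus (the source of
diagnosticity and anchor-status-frequency tables), noisy segmentation
predictions, behavioral trial tables from equal-variance Gaussian
signal-detection observers (2AFC + confidence, realness ratings, 5-AFC
categorization), and layer-wise feature stores with depth-dependent
signal for "trained" but not "random" model instances.

Defaults encode the stated experimental world: 5 indoor scene categories,
50 (Experiment 1) / 44 (Experiment 2) participants, presentation durations
of 50 and 500 ms with d' back-computed from the observed AUCs (0.6, 0.92)
via d' = sqrt(2) * Phi^-1(AUC), and effect sizes taken from the reported
regression estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CorpusSpec",
    "ObserverSpec",
    "FeatureSpec",
    "LabeledCorpus",
    "FeatureStore",
    "STRUCTURAL_ELEMENTS",
    "default_corpus_spec",
    "default_criteria",
    "gen_corpus",
    "gen_segmentation",
    "simulate_2afc",
    "simulate_ratings",
    "simulate_5afc",
    "gen_feature_store",
]

#: Structural (non-object) labels removed before scene scoring.
STRUCTURAL_ELEMENTS = frozenset({"window", "wall", "floor", "door"})

DEFAULT_CATEGORIES = ("bedroom", "conference_room", "dining_room", "kitchen", "living_room")

# d' implied by the observed group AUCs under equal-variance Gaussian SDT:
# AUC = Phi(d'/sqrt(2))  =>  d' = sqrt(2) * Phi^-1(AUC).
DPRIME_50MS = float(np.sqrt(2.0) * norm.ppf(0.6))
DPRIME_500MS = float(np.sqrt(2.0) * norm.ppf(0.92))


# ---------------------------------------------------------------------------
# corpus


@dataclass
class CorpusSpec:
    """Parameters of the labeled object-scene corpus generator.

    occurrence_probs has shape (n_objects, n_categories) with
    n_objects = n_categories * objects_per_category; anchor_flags marks,
    per (object, category), whether the object holds anchor status in
    scenes of that category.
    """

    n_categories: int = 5
    objects_per_category: int = 8
    n_scenes_per_category: int = 200
    occurrence_probs: np.ndarray | None = None
    anchor_flags: np.ndarray | None = None
    categories: tuple[str, ...] | None = None
    objects: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.categories is None:
            if self.n_categories == len(DEFAULT_CATEGORIES):
                self.categories = DEFAULT_CATEGORIES
            else:
                self.categories = tuple(f"category_{i}" for i in range(self.n_categories))
        if len(self.categories) != self.n_categories:
            raise ValueError("categories length must equal n_categories")
        n_objects = self.n_categories * self.objects_per_category
        if self.objects is None:
            self.objects = tuple(f"obj_{i:03d}" for i in range(n_objects))
        if self.occurrence_probs is not None:
            self.occurrence_probs = np.asarray(self.occurrence_probs, dtype=float)
            self.validate()

    def validate(self) -> None:
        p = self.occurrence_probs
        if p is None:
            return
        if p.shape != (len(self.objects), self.n_categories):
            raise ValueError(
                f"occurrence_probs shape {p.shape} != ({len(self.objects)}, {self.n_categories})"
            )
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("occurrence_probs entries must lie in [0, 1]")
        if np.any(p.sum(axis=0) == 0):
            raise ValueError("every category needs at least one object with nonzero probability")
        if self.anchor_flags is not None and np.asarray(self.anchor_flags).shape != p.shape:
            raise ValueError("anchor_flags must match occurrence_probs shape")


def default_corpus_spec(seed: int = 0, **overrides) -> CorpusSpec:
    """Realistic default world: each category owns a block of objects that occur
    often within it and rarely elsewhere; two owned objects per category are
    anchors (large stationary furniture in real scenes)."""
    spec = CorpusSpec(seed=seed, **{k: v for k, v in overrides.items()
                                    if k not in ("occurrence_probs", "anchor_flags")})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    n_obj = len(spec.objects)
    n_cat = spec.n_categories
    probs = rng.uniform(0.0, 0.15, size=(n_obj, n_cat))
    flags = np.zeros((n_obj, n_cat), dtype=bool)
    for c in range(n_cat):
        own = slice(c * spec.objects_per_category, (c + 1) * spec.objects_per_category)
        probs[own, c] = rng.uniform(0.5, 0.9, size=spec.objects_per_category)
        anchors = c * spec.objects_per_category + np.array([0, 1])
        flags[anchors, c] = True
    return replace(spec, occurrence_probs=probs, anchor_flags=flags)


@dataclass
class LabeledCorpus:
    """Scenes with category labels, object lists, and per-occurrence anchor flags.

    scene_table: one row per scene (scene_id, category) — empty scenes kept.
    object_table: one row per (scene_id, category, object, is_anchor).
    """

    scene_table: pd.DataFrame
    object_table: pd.DataFrame

    def validate(self) -> None:
        for col in ("scene_id", "category"):
            if col not in self.scene_table.columns:
                raise ValueError(f"scene_table missing column {col!r}")
        for col in ("scene_id", "category", "object", "is_anchor"):
            if col not in self.object_table.columns:
                raise ValueError(f"object_table missing column {col!r}")
        if len(self.scene_table) == 0:
            raise ValueError("corpus has no scenes")
        unknown = set(self.object_table["scene_id"]) - set(self.scene_table["scene_id"])
        if unknown:
            raise ValueError(f"object_table references unknown scenes: {sorted(unknown)[:5]}")

    def to_csv(self, scenes_path, objects_path) -> None:
        self.scene_table.to_csv(scenes_path, index=False)
        self.object_table.to_csv(objects_path, index=False)

    @classmethod
    def from_csv(cls, scenes_path, objects_path) -> "LabeledCorpus":
        corpus = cls(pd.read_csv(scenes_path), pd.read_csv(objects_path))
        corpus.validate()
        return corpus


def gen_corpus(spec: CorpusSpec) -> LabeledCorpus:
    """Draw scenes per category with objects present independently according to
    occurrence_probs. Empty scenes are retained (empty object list)."""
    if spec.occurrence_probs is None:
        spec = default_corpus_spec(spec.seed,
                                   n_categories=spec.n_categories,
                                   objects_per_category=spec.objects_per_category,
                                   n_scenes_per_category=spec.n_scenes_per_category)
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    anchor = (np.zeros_like(spec.occurrence_probs, dtype=bool)
              if spec.anchor_flags is None else np.asarray(spec.anchor_flags, dtype=bool))
    scene_rows, object_rows = [], []
    for c, cat in enumerate(spec.categories):
        present = rng.random((spec.n_scenes_per_category, len(spec.objects))) < spec.occurrence_probs[:, c]
        for s in range(spec.n_scenes_per_category):
            sid = f"{cat}_{s:04d}"
            scene_rows.append((sid, cat))
            for o in np.flatnonzero(present[s]):
                object_rows.append((sid, cat, spec.objects[o], bool(anchor[o, c])))
    scene_table = pd.DataFrame(scene_rows, columns=["scene_id", "category"])
    object_table = pd.DataFrame(object_rows, columns=["scene_id", "category", "object", "is_anchor"])
    if object_table.empty:
        object_table = pd.DataFrame(
            {"scene_id": pd.Series(dtype=str), "category": pd.Series(dtype=str),
             "object": pd.Series(dtype=str), "is_anchor": pd.Series(dtype=bool)})
    return LabeledCorpus(scene_table, object_table)


# ---------------------------------------------------------------------------
# segmentation predictions


def gen_segmentation(
    corpus: LabeledCorpus,
    miss_rate: float = 0.1,
    false_label_rate: float = 0.1,
    prob_noise_sd: float = 0.1,
    seed: int = 0,
    base_prob: float = 0.8,
    spurious_base_prob: float = 0.45,
    spurious_pool: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Emulate a segmentation network's per-image (label, probability) output.

    True objects are dropped with `miss_rate`; spurious labels — structural
    elements (windows/walls/floor/doors) and out-of-scene objects — are
    injected with `false_label_rate`; probabilities are a base value plus
    Gaussian noise, clipped to [0, 1].

    Returns a DataFrame with columns image_id, category, label, prob.
    """
    for name, rate in (("miss_rate", miss_rate), ("false_label_rate", false_label_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    vocab = sorted(set(corpus.object_table["object"])) if len(corpus.object_table) else []
    pool = tuple(sorted(STRUCTURAL_ELEMENTS) + vocab) if spurious_pool is None else spurious_pool
    objects_by_scene = (
        corpus.object_table.groupby("scene_id")["object"].agg(list).to_dict()
        if len(corpus.object_table) else {}
    )
    rows = []
    for sid, cat in corpus.scene_table.itertuples(index=False):
        true_objects = objects_by_scene.get(sid, [])
        for label in true_objects:
            if rng.random() >= miss_rate:
                p = float(np.clip(base_prob + rng.normal(0.0, prob_noise_sd), 0.0, 1.0))
                rows.append((sid, cat, label, p))
        present = set(true_objects)
        for label in pool:
            if label not in present and rng.random() < false_label_rate:
                p = float(np.clip(spurious_base_prob + rng.normal(0.0, prob_noise_sd), 0.0, 1.0))
                rows.append((sid, cat, label, p))
    return pd.DataFrame(rows, columns=["image_id", "category", "label", "prob"])


# ---------------------------------------------------------------------------
# signal-detection observers


def default_criteria(d_primes, n_criteria: int = 11) -> np.ndarray:
    """Confidence criteria at equal-mass quantiles of the observer's evidence
    mixture (equal parts noise N(0,1) and each signal N(d',1)).

    Observers are assumed to spread confidence categories so each is used
    about equally often — the usual convention in confidence-ROC work; the
    data-generating paper does not report criterion placement.
    """
    d_primes = np.atleast_1d(np.asarray(d_primes, dtype=float))
    means = np.concatenate([[0.0], d_primes])  # noise + each signal component
    qs = np.arange(1, n_criteria + 1) / (n_criteria + 1)
    xs = np.linspace(means.min() - 6.0, means.max() + 6.0, 20001)
    cdf = np.mean([norm.cdf(xs - m) for m in means], axis=0)
    return np.interp(qs, cdf, xs)


@dataclass
class ObserverSpec:
    """Equal-variance Gaussian SDT observer population for the 2AFC task.

    Evidence for one trial is N(mu, 1) with
    mu = d'(duration)*[condition == real] + beta_anchor*z_anchor
         + beta_diag[condition]*z_diag + participant intercept,
    the response is "real" iff evidence exceeds the middle criterion, and
    confidence is read off the position among the 11 ordered criteria
    (12 bins = 2 responses x 6 confidence levels).
    """

    d_prime_by_duration: dict[int, float] = field(
        default_factory=lambda: {50: DPRIME_50MS, 500: DPRIME_500MS})
    beta_anchor: float = 0.18
    beta_diag_by_condition: dict[str, float] = field(
        default_factory=lambda: {"real": 0.08, "generated": -0.15})
    criterion_centers: np.ndarray | None = None
    n_participants: int = 50
    participant_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for d, dp in self.d_prime_by_duration.items():
            if dp < 0:
                raise ValueError(f"d' must be >= 0 (duration {d})")
        if self.criterion_centers is None:
            self.criterion_centers = default_criteria(list(self.d_prime_by_duration.values()))
        self.criterion_centers = np.asarray(self.criterion_centers, dtype=float)
        if self.criterion_centers.shape != (11,):
            raise ValueError("criterion_centers must hold 11 values")
        if np.any(np.diff(self.criterion_centers) <= 0):
            raise ValueError("criterion_centers must be strictly increasing")


_2AFC_IMAGE_COLUMNS = ("image_id", "condition", "duration", "z_anchor", "z_diag")


def simulate_2afc(images: pd.DataFrame, spec: ObserverSpec) -> pd.DataFrame:
    """One trial per participant x image: binary real/generated response plus
    a 1-6 confidence rating, from the Gaussian evidence model in ObserverSpec.
    """
    missing = [c for c in _2AFC_IMAGE_COLUMNS if c not in images.columns]
    if missing:
        raise ValueError(f"image table missing columns: {missing}")
    bad_cond = set(images["condition"]) - {"real", "generated"}
    if bad_cond:
        raise ValueError(f"unknown conditions: {bad_cond}")
    bad_dur = set(images["duration"]) - set(spec.d_prime_by_duration)
    if bad_dur:
        raise ValueError(f"durations without d': {bad_dur}")

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    n_img = len(images)
    n_p = spec.n_participants
    intercepts = rng.normal(0.0, spec.participant_sd, size=n_p)

    d_eff = images["duration"].map(spec.d_prime_by_duration).to_numpy(float)
    is_real = (images["condition"] == "real").to_numpy()
    beta_diag = images["condition"].map(spec.beta_diag_by_condition).to_numpy(float)
    mu_img = (d_eff * is_real
              + spec.beta_anchor * images["z_anchor"].to_numpy(float)
              + beta_diag * images["z_diag"].to_numpy(float))

    mu = mu_img[None, :] + intercepts[:, None]            # (n_p, n_img)
    x = mu + rng.standard_normal((n_p, n_img))
    centers = spec.criterion_centers
    bins = np.searchsorted(centers, x)                    # 0..11
    response = np.where(bins >= 6, "real", "generated")
    confidence = np.where(bins >= 6, bins - 5, 6 - bins)  # 1..6 either side

    trials = pd.DataFrame({
        "participant": np.repeat(np.arange(n_p), n_img),
        "image_id": np.tile(images["image_id"].to_numpy(), n_p),
        "condition": np.tile(images["condition"].to_numpy(), n_p),
        "duration": np.tile(images["duration"].to_numpy(), n_p),
        "z_anchor": np.tile(images["z_anchor"].to_numpy(float), n_p),
        "z_diag": np.tile(images["z_diag"].to_numpy(float), n_p),
        "response": response.ravel(),
        "confidence": confidence.ravel().astype(int),
    })
    return trials


def simulate_ratings(
    images: pd.DataFrame,
    alpha: float = 3.5,
    beta_anchor: float = 0.15,
    beta_diag: float = -0.09,
    noise_sd: float = 1.0,
    participant_sd: float = 0.5,
    n_participants: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Realness ratings (1-6) for generated images: a linear model on z-scored
    anchor and diagnosticity scores, rounded and clipped to the scale."""
    for col in ("image_id", "condition", "z_anchor", "z_diag"):
        if col not in images.columns:
            raise ValueError(f"image table missing column {col!r}")
    if (images["condition"] != "generated").any():
        raise ValueError("ratings are collected for generated images only")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    n_img = len(images)
    intercepts = rng.normal(0.0, participant_sd, size=n_participants)
    latent = (alpha
              + beta_anchor * images["z_anchor"].to_numpy(float)
              + beta_diag * images["z_diag"].to_numpy(float))
    y = latent[None, :] + intercepts[:, None] + rng.normal(0.0, noise_sd, (n_participants, n_img))
    rating = np.clip(np.round(y), 1, 6).astype(int)
    return pd.DataFrame({
        "participant": np.repeat(np.arange(n_participants), n_img),
        "image_id": np.tile(images["image_id"].to_numpy(), n_participants),
        "z_anchor": np.tile(images["z_anchor"].to_numpy(float), n_participants),
        "z_diag": np.tile(images["z_diag"].to_numpy(float), n_participants),
        "rating": rating.ravel(),
    })


def simulate_5afc(
    images: pd.DataFrame,
    b0: float = 0.5,
    b_diag: float = 0.53,
    b_realness: float = 0.48,
    b_duration: float = -1.07,
    n_participants: int = 44,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
    seed: int = 0,
) -> pd.DataFrame:
    """5-AFC scene categorization with a guessing floor of 1/5:

    P(correct) = 0.2 + 0.8 * logistic(b0 + b_diag*z_diag
                 + b_realness*z_realness + b_duration*c_duration),

    c_duration the sum-coded duration (50 ms -> +1, 500 ms -> -1); wrong
    answers are uniform over the four remaining categories.
    """
    needed = ("image_id", "category", "duration", "z_diag", "z_realness")
    missing = [c for c in needed if c not in images.columns]
    if missing:
        raise ValueError(f"image table missing columns: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    c_dur = np.where(images["duration"].to_numpy() == 50, 1.0, -1.0)
    eta = (b0 + b_diag * images["z_diag"].to_numpy(float)
           + b_realness * images["z_realness"].to_numpy(float) + b_duration * c_dur)
    p_correct = 0.2 + 0.8 / (1.0 + np.exp(-eta))
    n_img = len(images)
    correct = rng.random((n_participants, n_img)) < p_correct[None, :]

    cat_arr = np.asarray(categories)
    cat_idx = {c: i for i, c in enumerate(cat_arr)}
    true_idx = images["category"].map(cat_idx).to_numpy()
    # wrong responses: uniform over the 4 non-true categories
    offset = rng.integers(1, len(cat_arr), size=(n_participants, n_img))
    wrong_idx = (true_idx[None, :] + offset) % len(cat_arr)
    resp_idx = np.where(correct, true_idx[None, :], wrong_idx)

    return pd.DataFrame({
        "participant": np.repeat(np.arange(n_participants), n_img),
        "image_id": np.tile(images["image_id"].to_numpy(), n_participants),
        "category": np.tile(images["category"].to_numpy(), n_participants),
        "duration": np.tile(images["duration"].to_numpy(), n_participants),
        "z_diag": np.tile(images["z_diag"].to_numpy(float), n_participants),
        "z_realness": np.tile(images["z_realness"].to_numpy(float), n_participants),
        "response_category": cat_arr[resp_idx].ravel(),
        "correct": correct.ravel().astype(int),
    })


# ---------------------------------------------------------------------------
# feature stores


@dataclass
class FeatureSpec:
    """Layer-wise feature-map generator: per model instance and layer,
    X = s(depth) * z(y) w^T + E with w a fixed random unit direction per model
    (so layers within a model are correlated, as in real networks) and E iid
    standard Gaussian. s(depth) = 0 for randomly initialized instances.
    """

    n_layers: int = 12
    dims_per_layer: int = 256
    profile: str = "sigmoid"          # 'linear' | 'sigmoid' | 'null'
    snr_scale: float = 1.0
    sigmoid_midpoint: float = 0.7
    sigmoid_steepness: float = 10.0
    n_trained_models: int = 7
    n_random_models: int = 7
    seed: int = 0

    def snr(self, depth: np.ndarray) -> np.ndarray:
        depth = np.asarray(depth, dtype=float)
        if self.profile == "null":
            return np.zeros_like(depth)
        if self.profile == "linear":
            return self.snr_scale * depth
        if self.profile == "sigmoid":
            return self.snr_scale / (1.0 + np.exp(-self.sigmoid_steepness * (depth - self.sigmoid_midpoint)))
        raise ValueError(f"unknown snr profile {self.profile!r}")

    @property
    def depths(self) -> np.ndarray:
        if self.n_layers == 1:
            return np.array([1.0])
        return np.arange(self.n_layers) / (self.n_layers - 1)


@dataclass
class FeatureStore:
    """Per (model instance, layer) image-by-feature matrices with metadata.

    meta columns: model, layer, depth (layer/(L-1) in [0,1]), trained.
    Image row order is identical across all entries.
    """

    features: dict[tuple[str, int], np.ndarray]
    meta: pd.DataFrame
    image_ids: np.ndarray

    def validate(self) -> None:
        n = len(self.image_ids)
        for key, X in self.features.items():
            if X.shape[0] != n:
                raise ValueError(f"feature matrix {key} has {X.shape[0]} rows, expected {n}")
        for col in ("model", "layer", "depth", "trained"):
            if col not in self.meta.columns:
                raise ValueError(f"meta missing column {col!r}")
        if np.any(self.meta["depth"] < 0) or np.any(self.meta["depth"] > 1):
            raise ValueError("depths must lie in [0, 1]")

    def matrix(self, model: str, layer: int) -> np.ndarray:
        return self.features[(model, layer)]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("image_ids", data=np.asarray(self.image_ids, dtype="S"))
            for (model, layer), X in self.features.items():
                row = self.meta[(self.meta["model"] == model) & (self.meta["layer"] == layer)].iloc[0]
                ds = f.create_dataset(f"{model}/layer_{layer:03d}", data=X)
                ds.attrs["depth"] = float(row["depth"])
                ds.attrs["trained"] = bool(row["trained"])
                ds.attrs["layer"] = int(layer)

    @classmethod
    def from_hdf5(cls, path) -> "FeatureStore":
        import h5py

        features: dict[tuple[str, int], np.ndarray] = {}
        meta_rows = []
        with h5py.File(path, "r") as f:
            image_ids = np.asarray([s.decode() for s in f["image_ids"][()]])
            for model in f:
                if model == "image_ids":
                    continue
                for name in f[model]:
                    ds = f[model][name]
                    layer = int(ds.attrs["layer"])
                    features[(model, layer)] = ds[()]
                    meta_rows.append((model, layer, float(ds.attrs["depth"]), bool(ds.attrs["trained"])))
        meta = pd.DataFrame(meta_rows, columns=["model", "layer", "depth", "trained"])
        meta = meta.sort_values(["model", "layer"]).reset_index(drop=True)
        store = cls(features, meta, image_ids)
        store.validate()
        return store

    def to_csv_dir(self, directory) -> None:
        """Plain-text fallback: one CSV per (model, layer) plus an index CSV."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.meta.to_csv(d / "index.csv", index=False)
        pd.Series(self.image_ids, name="image_id").to_csv(d / "image_ids.csv", index=False)
        for (model, layer), X in self.features.items():
            np.savetxt(d / f"{model}__layer_{layer:03d}.csv", X, delimiter=",")

    @classmethod
    def from_csv_dir(cls, directory) -> "FeatureStore":
        from pathlib import Path

        d = Path(directory)
        meta = pd.read_csv(d / "index.csv")
        image_ids = pd.read_csv(d / "image_ids.csv")["image_id"].to_numpy()
        features = {}
        for row in meta.itertuples(index=False):
            X = np.loadtxt(d / f"{row.model}__layer_{row.layer:03d}.csv", delimiter=",", ndmin=2)
            features[(row.model, int(row.layer))] = X
        store = cls(features, meta, image_ids)
        store.validate()
        return store


def gen_feature_store(image_scores, spec: FeatureSpec, image_ids=None) -> FeatureStore:
    """Generate trained and random model-instance feature maps whose linear
    signal about `image_scores` grows with normalized layer depth for trained
    instances and is zero for random instances."""
    y = np.asarray(image_scores, dtype=float)
    if y.ndim != 1:
        raise ValueError("image_scores must be a 1-D vector (one score per image)")
    if image_ids is None:
        image_ids = np.array([f"img_{i:04d}" for i in range(len(y))])
    sd = y.std()
    y_std = (y - y.mean()) / sd if sd > 0 else np.zeros_like(y)

    ss = np.random.SeedSequence([spec.seed, 5])
    model_seeds = ss.spawn(spec.n_trained_models + spec.n_random_models)
    depths = spec.depths
    snr = spec.snr(depths)

    features: dict[tuple[str, int], np.ndarray] = {}
    meta_rows = []
    idx = 0
    for group, n_models, trained in (("trained", spec.n_trained_models, True),
                                     ("random", spec.n_random_models, False)):
        for m in range(n_models):
            rng = np.random.default_rng(model_seeds[idx])
            idx += 1
            model = f"{group}_{m}"
            w = rng.standard_normal(spec.dims_per_layer)
            w /= np.linalg.norm(w)
            for layer in range(spec.n_layers):
                s = snr[layer] if trained else 0.0
                E = rng.standard_normal((len(y), spec.dims_per_layer))
                X = s * np.outer(y_std, w) + E
                features[(model, layer)] = X
                meta_rows.append((model, layer, depths[layer], trained))
    meta = pd.DataFrame(meta_rows, columns=["model", "layer", "depth", "trained"])
    store = FeatureStore(features, meta, np.asarray(image_ids))
    store.validate()
    return store
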