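"""Object-scene co-occurrence scores.

Two probabilities are attached to every (object, category) pair observed in a
labeled corpus:

* diagnosticity — P(scene category | object present): the fraction of scenes
  containing the object that belong to the category;
* anchor status frequency — P(object holds anchor status | category, object
  present): the fraction of the category's scenes containing the object in
  which it is flagged as an anchor.

Per-image scores are then the maximum table entry over the image's predicted
objects (after removing low-probability predictions and structural elements).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import STRUCTURAL_ELEMENTS, LabeledCorpus

__all__ = [
    "ScoreTable",
    "DegenerateInputError",
    "compute_score_table",
    "filter_predictions",
    "assign_scene_scores",
    "z_transform",
]


class DegenerateInputError(ValueError):
    """Raised for inputs on which the requested statistic is undefined."""


@dataclass
class ScoreTable:
    """(object, category) -> diagnosticity and anchor-status-frequency, with
    the support counts behind each fraction. Pairs never observed together
    are absent — a later lookup yields an explicit missing, not zero."""

    table: pd.DataFrame  # columns: object, category, diagnosticity, anchor_freq,
    #                               n_obj_cat, n_obj_total, n_anchor

    def __post_init__(self) -> None:
        self._index = self.table.set_index(["object", "category"])

    @property
    def categories(self) -> set:
        return set(self.table["category"])

    def lookup(self, obj: str, category: str) -> pd.Series | None:
        try:
            return self._index.loc[(obj, category)]
        except KeyError:
            return None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        return cls(pd.read_csv(path))


def compute_score_table(corpus: LabeledCorpus) -> ScoreTable:
    """Count-based estimates of diagnosticity and anchor status frequency.

    diagnosticity(o, c) = #scenes of category c containing o / #scenes containing o
    anchor_freq(o, c)   = #scenes of c where o is flagged anchor / #scenes of c containing o
    """
    corpus.validate()
    obj = corpus.object_table.drop_duplicates(["scene_id", "object"])
    if len(obj) == 0:
        raise ValueError("corpus contains no object occurrences")
    n_obj_total = obj.groupby("object")["scene_id"].nunique()
    grouped = obj.groupby(["object", "category"])
    n_obj_cat = grouped["scene_id"].nunique()
    n_anchor = grouped["is_anchor"].sum().astype(int)
    table = pd.DataFrame({
        "n_obj_cat": n_obj_cat,
        "n_anchor": n_anchor,
    }).reset_index()
    table["n_obj_total"] = table["object"].map(n_obj_total)
    table["diagnosticity"] = table["n_obj_cat"] / table["n_obj_total"]
    table["anchor_freq"] = table["n_anchor"] / table["n_obj_cat"]
    table = table[["object", "category", "diagnosticity", "anchor_freq",
                   "n_obj_cat", "n_obj_total", "n_anchor"]]
    return ScoreTable(table.sort_values(["object", "category"]).reset_index(drop=True))


def filter_predictions(
    preds: pd.DataFrame,
    threshold: float = 0.3,
    structural: frozenset | set = STRUCTURAL_ELEMENTS,
) -> pd.DataFrame:
    """Keep predictions with probability strictly above `threshold` whose label
    is not a structural element; row order is preserved."""
    if len(preds) == 0:
        return preds.copy()
    if (preds["prob"] < 0).any() or (preds["prob"] > 1).any():
        raise ValueError("prediction probabilities must lie in [0, 1]")
    keep = (preds["prob"] > threshold) & ~preds["label"].isin(structural)
    return preds[keep].copy()


def assign_scene_scores(
    preds: pd.DataFrame,
    table: ScoreTable,
    category: str | None = None,
) -> pd.DataFrame:
    """Per-image anchor and diagnosticity scores: the maximum table entry over
    the image's (already filtered) predicted objects, conditioned on the
    image's nominal category.

    Objects absent from the table for that category contribute nothing
    (absent evidence, not zero evidence); if no object survives, both scores
    are 0 and `empty` is flagged so downstream analyses keep the scene.

    `category` overrides the per-image `category` column when given.
    """
    preds = preds.copy()
    if category is not None:
        preds["category"] = category
    if "category" not in preds.columns:
        raise ValueError("predictions need a 'category' column or an explicit category")
    unknown = set(preds["category"]) - table.categories
    if unknown:
        raise ValueError(f"categories unknown to the score table: {sorted(unknown)}")

    rows = []
    for (image_id, cat), group in preds.groupby(["image_id", "category"], sort=False):
        anchor_best, anchor_obj = -np.inf, None
        diag_best, diag_obj = -np.inf, None
        n_used = 0
        for label in group["label"]:
            entry = table.lookup(label, cat)
            if entry is None:
                continue
            n_used += 1
            if entry["anchor_freq"] > anchor_best:
                anchor_best, anchor_obj = entry["anchor_freq"], label
            if entry["diagnosticity"] > diag_best:
                diag_best, diag_obj = entry["diagnosticity"], label
        empty = n_used == 0
        rows.append((image_id, cat,
                     0.0 if empty else float(anchor_best), anchor_obj,
                     0.0 if empty else float(diag_best), diag_obj,
                     len(group), empty))
    return pd.DataFrame(rows, columns=[
        "image_id", "category", "anchor_score", "anchor_object",
        "diag_score", "diag_object", "n_objects_after_filter", "empty"])


def z_transform(values) -> np.ndarray:
    """Center and rescale to sample mean 0, sample SD 1 (ddof=1).

    Raises DegenerateInputError on constant input (fewer than two distinct
    values), where the transform is undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("z_transform expects a 1-D vector")
    if len(x) < 2 or np.all(x == x[0]):
        raise DegenerateInputError("z_transform undefined for constant input")
    return (x - x.mean()) / x.std(ddof=1)
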