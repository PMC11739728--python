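"""Shapley-value attribution of the trained tree ensemble.

Attributions are exact tree-path Shapley values in class-margin
(log-odds) space, computed by the gradient-boosting library's polynomial
Tree SHAP routine, one value per test sample x feature x class plus a
per-class base value.  Local accuracy — base + sum of attributions equals
the model margin — holds to single-precision tolerance and is asserted in
tests.  Global importance is the mean absolute attribution per feature,
either pooled over classes or sliced to the moderate-intensive class
(the "MI-vs-rest" view: the MI class's attribution slice, not a refit
binary model).  Partial-dependence exports pair each test sample's
feature value with its attribution for scatter/trend plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb

from .labeling import CLASS_ORDER
from .pipeline import TrainedModel


@dataclass
class AttributionSet:
    values: np.ndarray          # (n_samples, n_classes, n_features)
    base: np.ndarray            # (n_samples, n_classes)
    feature_names: list[str]
    feature_values: np.ndarray  # (n_samples, n_features), for coloring
    class_order: tuple = CLASS_ORDER

    def class_slice(self, cls: str) -> np.ndarray:
        return self.values[:, self.class_order.index(cls), :]


def attribute(model: TrainedModel, X: pd.DataFrame) -> AttributionSet:
    """Exact per-class Tree SHAP values for every test sample."""
    booster = model.model.get_booster()
    arr = model.prepare(X)
    dm = xgb.DMatrix(arr, feature_names=model.features)
    contribs = np.asarray(booster.predict(dm, pred_contribs=True))
    if contribs.ndim == 2:  # binary/single-output layout
        contribs = contribs[:, None, :]
    return AttributionSet(
        values=contribs[:, :, :-1].astype(np.float64),
        base=contribs[:, :, -1].astype(np.float64),
        feature_names=list(model.features),
        feature_values=arr,
        class_order=model.present_classes,
    )


def margins(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Raw class-margin (log-odds) output, the quantity attributions sum to."""
    booster = model.model.get_booster()
    dm = xgb.DMatrix(model.prepare(X), feature_names=model.features)
    out = np.asarray(booster.predict(dm, output_margin=True))
    return out if out.ndim == 2 else out[:, None]


def local_accuracy_error(attr: AttributionSet, model: TrainedModel,
                         X: pd.DataFrame) -> float:
    """Max |base + sum(attributions) - margin| over samples and classes."""
    recon = attr.base + attr.values.sum(axis=2)
    return float(np.abs(recon - margins(model, X)).max())


def rank_features(attr: AttributionSet, class_focus: str | None = None
                  ) -> pd.DataFrame:
    """Mean-|attribution| importance ranking, descending.

    ``class_focus=None`` pools all classes; naming a class (typically
    "MI") ranks by that class's attribution slice alone.
    """
    if class_focus is None:
        v = np.abs(attr.values).mean(axis=(0, 1))
    else:
        v = np.abs(attr.class_slice(class_focus)).mean(axis=0)
    out = pd.DataFrame({"feature": attr.feature_names, "mean_abs_shap": v})
    return (out.sort_values(["mean_abs_shap", "feature"],
                            ascending=[False, True], kind="stable")
            .reset_index(drop=True))


def pdp_export(attr: AttributionSet, feature: str,
               class_focus: str = "MI",
               color_feature: str | None = None) -> pd.DataFrame:
    """(feature value, attribution) point set sorted by feature value.

    One point per test sample; an optional second feature supplies the
    interaction-coloring column.
    """
    j = attr.feature_names.index(feature)
    out = pd.DataFrame({
        "feature_value": attr.feature_values[:, j],
        "shap_value": attr.class_slice(class_focus)[:, j],
    })
    if color_feature is not None:
        k = attr.feature_names.index(color_feature)
        out["color_value"] = attr.feature_values[:, k]
    return out.sort_values("feature_value", kind="stable").reset_index(drop=True)


def plot_importance(ranking: pd.DataFrame, top: int = 30, ax=None):
    """Minimal horizontal bar chart of a mean-|SHAP| ranking."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    head = ranking.head(top).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.28 * len(head) + 1))
    ax.barh(head["feature"], head["mean_abs_shap"])
    ax.set_xlabel("mean |SHAP| (log-odds)")
    return ax
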