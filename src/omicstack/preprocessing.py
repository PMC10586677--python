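"""Per-datatype filtering, imputation and stacking.

The default pipeline per datatype is:

* F1 (mRNA):   drop features with zeros in >20% of samples, keep top-2000 by SD
* F2 (miRNA):  drop features with zeros in >20% of samples (no SD cut)
* F3 (methyl): drop probes missing in >10% of samples, drop chrX/chrY probes,
               keep top-2000 by SD (computed over observed values), KNN-impute (K=5)
* F4 (RPPA):   drop proteins missing in >10% of samples, KNN-impute (K=5)

then the retained layers are column-stacked over the samples common to all
datatypes. Filtering thresholds are strict ("more than"), so a feature
sitting exactly on the threshold is retained. No value is rescaled here;
normalization for the autoencoder happens in :mod:`omicstack.integration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.impute import KNNImputer

from .datatypes import MultiOmicsMatrix, OmicsLayer


def drop_high_zero(layer: OmicsLayer, max_zero_frac: float = 0.20) -> OmicsLayer:
    """Drop features whose zero fraction exceeds `max_zero_frac` (strictly).

    Intended for the count-like layers F1/F2, which must be complete.
    """
    if layer.datatype not in ("F1", "F2"):
        raise ValueError("zero filtering applies to F1/F2 layers")
    if np.isnan(layer.values).any():
        raise ValueError("zero filtering requires a complete layer")
    zero_frac = (layer.values == 0).mean(axis=0)
    keep = zero_frac <= max_zero_frac
    if not keep.any():
        raise ValueError("zero filter would drop every feature")
    return layer.subset_features(keep)


def drop_high_missing(layer: OmicsLayer, max_na_frac: float = 0.10) -> OmicsLayer:
    """Drop features missing in more than `max_na_frac` of the samples."""
    if layer.datatype not in ("F3", "F4"):
        raise ValueError("missingness filtering applies to F3/F4 layers")
    na_frac = np.isnan(layer.values).mean(axis=0)
    keep = na_frac <= max_na_frac
    if not keep.any():
        raise ValueError("missingness filter would drop every feature")
    return layer.subset_features(keep)


def drop_sex_chromosomes(layer: OmicsLayer) -> OmicsLayer:
    """Drop features annotated on chrX or chrY; every feature must be annotated."""
    if layer.annotation is None:
        raise ValueError("layer carries no chromosome annotation")
    missing = [f for f in layer.feature_ids if f not in layer.annotation]
    if missing:
        raise ValueError(f"no chromosome annotation for feature {missing[0]!r}")
    keep = np.array(
        [layer.annotation[f] not in ("chrX", "chrY") for f in layer.feature_ids]
    )
    return layer.subset_features(keep)


def top_variable(layer: OmicsLayer, k: int = 2000) -> OmicsLayer:
    """Keep the `k` features with the largest standard deviation.

    SD is computed over observed entries only (missing values ignored), so
    the cut can run before imputation. Ties are broken by original feature
    order (stable sort); if fewer than `k` features exist, all are kept.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if layer.n_features <= k:
        return layer.subset_features(np.arange(layer.n_features))
    sd = _nan_sd(layer.values)
    order = np.argsort(-sd, kind="stable")[:k]
    return layer.subset_features(np.sort(order))


def _nan_sd(values: np.ndarray) -> np.ndarray:
    n_obs = (~np.isnan(values)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(values, axis=0, ddof=1)
    sd[n_obs < 2] = 0.0
    return sd


def knn_impute(layer: OmicsLayer, k: int = 5) -> OmicsLayer:
    """Replace each missing cell by the mean of the feature in the k nearest samples.

    Distances are Euclidean over mutually observed features; only samples
    with the feature observed can donate. Observed values are untouched.
    """
    values = layer.values
    nan_mask = np.isnan(values)
    if not nan_mask.any():
        return layer.subset_features(np.arange(layer.n_features))
    n_obs = (~nan_mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = layer.feature_ids[int(np.argmax(n_obs == 0))]
        raise ValueError(f"feature {bad!r} is missing in every sample")
    needs = nan_mask.any(axis=0)
    if (n_obs[needs] < k).any():
        bad_idx = np.flatnonzero(needs & (n_obs < k))[0]
        raise ValueError(
            f"feature {layer.feature_ids[bad_idx]!r} has fewer than k={k} "
            "observed samples to donate values"
        )
    imputed = KNNImputer(n_neighbors=k, weights="uniform").fit_transform(values)
    out = values.copy()
    out[nan_mask] = imputed[nan_mask]
    return OmicsLayer(
        list(layer.sample_ids),
        list(layer.feature_ids),
        out,
        layer.datatype,
        dict(layer.annotation) if layer.annotation else None,
    )


def stack_layers(layers: list[OmicsLayer]) -> MultiOmicsMatrix:
    """Column-stack imputed layers over the intersection of their sample sets.

    Stacked feature IDs are prefixed with the source datatype
    (``F1:gene7``); sample order follows the first layer. Values are copied
    bit-exactly — no rescaling.
    """
    if not layers:
        raise ValueError("no layers to stack")
    for layer in layers:
        if np.isnan(layer.values).any():
            raise ValueError(f"layer {layer.datatype} must be imputed before stacking")
    common = set(layers[0].sample_ids)
    for layer in layers[1:]:
        common &= set(layer.sample_ids)
    if not common:
        raise ValueError("no samples common to all layers")
    sample_ids = [s for s in layers[0].sample_ids if s in common]

    blocks, feature_ids, provenance = [], [], {}
    for layer in layers:
        sub = layer.subset_samples(sample_ids)
        blocks.append(sub.values)
        for f in layer.feature_ids:
            fid = f"{layer.datatype}:{f}"
            feature_ids.append(fid)
            provenance[fid] = layer.datatype
    return MultiOmicsMatrix(sample_ids, feature_ids, np.hstack(blocks), provenance)


@dataclass
class FilterConfig:
    """Which filters run per datatype and their thresholds."""

    max_zero_frac: float = 0.20
    max_na_frac: float = 0.10
    top_k: int = 2000
    knn_k: int = 5
    sd_cut: dict[str, bool] = field(
        default_factory=lambda: {"F1": True, "F2": False, "F3": True, "F4": False}
    )


def preprocess_layer(layer: OmicsLayer, config: FilterConfig | None = None) -> OmicsLayer:
    """Run the datatype's standard filter sequence on one layer."""
    cfg = config or FilterConfig()
    out = layer
    if out.datatype in ("F1", "F2"):
        out = drop_high_zero(out, cfg.max_zero_frac)
    else:
        out = drop_high_missing(out, cfg.max_na_frac)
        if out.datatype == "F3":
            out = drop_sex_chromosomes(out)
    if cfg.sd_cut.get(out.datatype, False):
        out = top_variable(out, cfg.top_k)
    if out.datatype in ("F3", "F4"):
        out = knn_impute(out, cfg.knn_k)
    return out


def preprocess_study(
    layers: dict[str, OmicsLayer], config: FilterConfig | None = None
) -> tuple[dict[str, OmicsLayer], MultiOmicsMatrix]:
    """Filter every layer, then stack over the common samples."""
    processed = {tag: preprocess_layer(layer, config) for tag, layer in layers.items()}
    stacked = stack_layers([processed[t] for t in sorted(processed)])
    return processed, stacked
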