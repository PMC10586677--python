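"""Core containers shared across the pipeline.

Matrices are sample-major throughout: rows are samples, columns are
features. Datatype tags follow the convention F1 = mRNA expression
(FPKM-like), F2 = miRNA expression (RPKM-like), F3 = DNA-methylation beta
values, F4 = protein expression (RPPA-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DATATYPES = ("F1", "F2", "F3", "F4")


@dataclass
class OmicsLayer:
    """One datatype's sample x feature matrix.

    Parameters
    ----------
    sample_ids : list of str
        Ordered, unique sample identifiers (one per row).
    feature_ids : list of str
        Ordered, unique feature identifiers (one per column).
    values : ndarray of shape (n_samples, n_features)
        Measurements; NaN marks a missing value (allowed before imputation).
    datatype : str
        One of ``F1``..``F4``.
    annotation : dict, optional
        feature_id -> chromosome label (``chr1``..``chr22``, ``chrX``,
        ``chrY``); carried by methylation layers for sex-chromosome
        filtering.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    datatype: str
    annotation: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.datatype not in DATATYPES:
            raise ValueError(f"unknown datatype {self.datatype!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_features(self, keep: np.ndarray) -> "OmicsLayer":
        """Return a new layer keeping the (boolean or index) columns `keep`."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        fids = [self.feature_ids[i] for i in keep]
        ann = None
        if self.annotation is not None:
            ann = {f: self.annotation[f] for f in fids if f in self.annotation}
        return OmicsLayer(
            sample_ids=list(self.sample_ids),
            feature_ids=fids,
            values=self.values[:, keep].copy(),
            datatype=self.datatype,
            annotation=ann,
        )

    def subset_samples(self, keep_ids: list[str]) -> "OmicsLayer":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in keep_ids]
        return OmicsLayer(
            sample_ids=list(keep_ids),
            feature_ids=list(self.feature_ids),
            values=self.values[rows].copy(),
            datatype=self.datatype,
            annotation=dict(self.annotation) if self.annotation else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class MultiOmicsMatrix:
    """Column-stacked layers over the common sample set.

    Feature IDs are globally unique, prefixed ``<datatype>:``; `provenance`
    maps each stacked feature back to its source datatype. `n` and `p` name
    the sample and feature counts.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    provenance: dict[str, str]

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def p(self) -> int:
        return len(self.feature_ids)

    def columns_for(self, datatype: str) -> np.ndarray:
        """Indices of the stacked columns originating from `datatype`."""
        return np.array(
            [i for i, f in enumerate(self.feature_ids) if self.provenance[f] == datatype],
            dtype=int,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class SurvivalTable:
    """Per-sample time-to-event data with cluster labels.

    `time` is in days, `event` is 1 when the endpoint (death for OS,
    recurrence for DFS) was observed and 0 for censoring.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    endpoint: str = "OS"
    cluster: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(self.time < 0):
            raise ValueError("negative survival time")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event must be 0/1")
        if self.cluster is not None:
            self.cluster = np.asarray(self.cluster, dtype=int)

    def with_clusters(self, labels: np.ndarray) -> "SurvivalTable":
        return SurvivalTable(
            sample_ids=list(self.sample_ids),
            time=self.time.copy(),
            event=self.event.copy(),
            endpoint=self.endpoint,
            cluster=np.asarray(labels, dtype=int),
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"time": self.time, "event": self.event}
        if self.cluster is not None:
            d["cluster"] = self.cluster
        return pd.DataFrame(d, index=self.sample_ids)


@dataclass
class LatentRepresentation:
    """Low-dimensional embedding of the stacked matrix (rows match input order)."""

    sample_ids: list[str]
    values: np.ndarray
    source: str = "F_AE"  # F_AE, F_PCA or F_RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("latent representation contains missing values")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample_ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]
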