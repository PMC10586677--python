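"""TSV readers and writers for every artifact the pipeline exchanges.

All tables are tab-separated with a header row. Matrix files put samples on
rows with the sample ID in the first column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import LatentRepresentation, OmicsLayer, SurvivalTable


def write_layer(layer: OmicsLayer, path: str | Path) -> None:
    layer.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_layer(
    path: str | Path,
    datatype: str,
    annotation_path: str | Path | None = None,
) -> OmicsLayer:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ann = None
    if annotation_path is not None:
        ann = read_annotation(annotation_path)
    return OmicsLayer(
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        datatype=datatype,
        annotation=ann,
    )


def write_annotation(annotation: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"feature_id": list(annotation), "chromosome": list(annotation.values())}
    ).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["feature_id"], df["chromosome"]))


def write_survival(os_table: SurvivalTable, dfs_table: SurvivalTable, path: str | Path) -> None:
    if list(os_table.sample_ids) != list(dfs_table.sample_ids):
        raise ValueError("OS and DFS tables must share sample order")
    pd.DataFrame(
        {
            "sample_id": os_table.sample_ids,
            "os_time": os_table.time,
            "os_event": os_table.event,
            "dfs_time": dfs_table.time,
            "dfs_event": dfs_table.event,
        }
    ).to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> tuple[SurvivalTable, SurvivalTable]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    ids = list(df["sample_id"])
    os_t = SurvivalTable(ids, df["os_time"].to_numpy(), df["os_event"].to_numpy(), "OS")
    dfs_t = SurvivalTable(ids, df["dfs_time"].to_numpy(), df["dfs_event"].to_numpy(), "DFS")
    return os_t, dfs_t


def write_labels(sample_ids: list[str], labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "label": np.asarray(labels, dtype=int)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return list(df["sample_id"]), df["label"].to_numpy(dtype=int)


def write_latent(latent: LatentRepresentation, path: str | Path) -> None:
    cols = [f"dim{i + 1}" for i in range(latent.d)]
    pd.DataFrame(latent.values, index=latent.sample_ids, columns=cols).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_latent(path: str | Path, source: str = "F_AE") -> LatentRepresentation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LatentRepresentation(
        sample_ids=[str(s) for s in df.index],
        values=df.to_numpy(dtype=float),
        source=source,
    )
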