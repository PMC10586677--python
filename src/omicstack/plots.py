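"""Diagnostic plots: consensus CDFs, RCSI-vs-K, Kaplan-Meier curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_rcsi(per_k, path: str | Path) -> None:
    ks = [r.K for r in per_k]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ks, [r.rcsi for r in per_k], "o-")
    best = max(per_k, key=lambda r: (r.rcsi, -r.K))
    ax.axvline(best.K, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("K")
    ax.set_ylabel("RCSI")
    ax.set_title(f"Cluster stability (best K = {best.K})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_consensus_cdf(per_k, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for r in per_k:
        m = r.consensus.consensus_matrix
        vals = np.sort(m[np.triu_indices(m.shape[0], k=1)])
        cdf = np.arange(1, vals.size + 1) / vals.size
        ax.step(vals, cdf, where="post", label=f"K={r.K}")
    ax.set_xlabel("consensus value u")
    ax.set_ylabel("C(K, u)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_km(curves: dict, path: str | Path, endpoint: str = "OS") -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for cluster, df in sorted(curves.items()):
        ax.step(df["time"], df["survival"], where="post", label=f"C{cluster + 1}")
    ax.set_xlabel("time (days)")
    ax.set_ylabel(f"{endpoint} probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
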