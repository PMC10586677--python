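"""Synthetic multi-omics study generator.

Emulates the statistical structure the pipeline assumes in real
pan-cancer data: a latent cluster structure shared across datatypes, with
each datatype observing the latent state through its own nonlinear map
(random affine transform followed by a saturating tanh) plus noise. The
layers mimic the four measurement platforms:

* F1 (mRNA, FPKM-like) and F2 (miRNA, RPKM-like): positive, right-skewed
  values with zero inflation;
* F3 (DNA methylation): beta values squashed into [0, 1], with per-probe
  chromosome annotation and a mixture of low/high missingness rates so
  some probes exceed the 10% drop threshold;
* F4 (protein, RPPA-like): real-valued scores with missingness.

Survival times are exponential with a per-cluster hazard and independent
uniform censoring, so the clusters differ in outcome in a way a log-rank
test can detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .datatypes import OmicsLayer, SurvivalTable


@dataclass
class GeneratorConfig:
    """All knobs of the generator; defaults define the standard study conditions.

    Rates are probabilities in [0, 1]; hazards are per-day event rates.
    Cluster sizes are balanced (every cluster gets at least 2 samples).
    """

    n_samples: int = 500
    k_true: int = 5
    n_features: dict[str, int] = field(
        default_factory=lambda: {"F1": 300, "F2": 120, "F3": 300, "F4": 80}
    )
    latent_dim: int = 10
    cluster_sep: float = 3.0  # SD of cluster centers in latent space (within-cluster SD is 1)
    layer_noise: float = 0.3
    zero_rate: dict[str, float] = field(default_factory=lambda: {"F1": 0.05, "F2": 0.10})
    missing_low: float = 0.02
    missing_high: float = 0.15
    high_missing_frac: dict[str, float] = field(
        default_factory=lambda: {"F3": 0.20, "F4": 0.10}
    )
    sex_probe_frac: float = 0.05
    hazard_rates: tuple[float, ...] | None = None  # default: 1/1500 * 1.6**k per cluster
    censoring_rate: float = 0.3
    overlap_frac: float = 1.0

    def validate(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.k_true > self.n_samples:
            raise ValueError("k_true cannot exceed n_samples")
        if self.n_samples < 2 * self.k_true:
            raise ValueError("need at least 2 samples per cluster")
        for tag, p in self.n_features.items():
            if p <= 0:
                raise ValueError(f"non-positive feature count for {tag}")
        rates = [
            *self.zero_rate.values(),
            self.missing_low,
            self.missing_high,
            *self.high_missing_frac.values(),
            self.sex_probe_frac,
            self.censoring_rate,
            self.overlap_frac,
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.hazard_rates is not None:
            if len(self.hazard_rates) != self.k_true:
                raise ValueError("hazard_rates length must equal k_true")
            if any(h <= 0 for h in self.hazard_rates):
                raise ValueError("hazard rates must be positive")

    def hazards(self) -> np.ndarray:
        if self.hazard_rates is not None:
            return np.asarray(self.hazard_rates, dtype=float)
        return (1.0 / 1500.0) * 1.6 ** np.arange(self.k_true)


@dataclass
class SyntheticStudy:
    """A generated dataset: pre-filtering layers, ground truth and survival."""

    layers: dict[str, OmicsLayer]
    true_labels: np.ndarray
    survival: SurvivalTable          # overall survival
    survival_dfs: SurvivalTable      # disease-free survival
    generator_config: GeneratorConfig
    seed: int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.survival.sample_ids)


def _censoring_window(hazards: np.ndarray, target: float) -> float:
    """Uniform-censoring upper bound giving roughly the target censoring fraction.

    With event time T ~ Exp(h) and censor time C ~ U(0, w), the censoring
    probability is E[P(T > C)] = (1 - exp(-h w)) / (h w); we average over the
    cluster hazards and solve for w.
    """
    if target <= 0:
        return np.inf

    def frac(w: float) -> float:
        hw = hazards * w
        return float(np.mean((1.0 - np.exp(-hw)) / hw)) - target

    lo, hi = 1e-6, 1e9
    return float(brentq(frac, lo, hi))


def _draw_survival(
    rng: np.random.Generator,
    sample_ids: list[str],
    labels: np.ndarray,
    hazards: np.ndarray,
    censoring_rate: float,
    endpoint: str,
) -> SurvivalTable:
    lam = hazards[labels]
    t_event = rng.exponential(1.0 / lam)
    if censoring_rate <= 0:
        return SurvivalTable(sample_ids, t_event, np.ones_like(labels), endpoint)
    w = _censoring_window(hazards, censoring_rate)
    t_cens = rng.uniform(0.0, w, size=len(labels))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return SurvivalTable(sample_ids, time, event, endpoint)


def _chromosome_annotation(
    rng: np.random.Generator, feature_ids: list[str], sex_frac: float
) -> dict[str, str]:
    p = len(feature_ids)
    n_sex = int(np.ceil(sex_frac * p))
    order = rng.permutation(p)
    ann: dict[str, str] = {}
    autosomes = [f"chr{i}" for i in range(1, 23)]
    for rank, idx in enumerate(order):
        if rank < n_sex:
            ann[feature_ids[idx]] = "chrX" if rank % 2 == 0 else "chrY"
        else:
            ann[feature_ids[idx]] = autosomes[rank % 22]
    return {f: ann[f] for f in feature_ids}


def _missing_rates(
    rng: np.random.Generator, p: int, low: float, high: float, frac_high: float
) -> np.ndarray:
    rates = np.full(p, low)
    n_high = int(round(frac_high * p))
    hi_idx = rng.choice(p, size=n_high, replace=False)
    rates[hi_idx] = high
    return rates


def generate_dataset(config: GeneratorConfig, seed: int) -> SyntheticStudy:
    """Draw one synthetic multi-omics study.

    Every sample gets a latent vector ``z = center[cluster] + N(0, I)``;
    each layer observes ``tanh(z W + b)`` through its own random map, then
    a platform-specific link (exp for F1/F2, logistic squash for F3,
    identity for F4), with zeros / missing values injected afterwards.
    Fully reproducible given ``seed``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n, k, d = config.n_samples, config.k_true, config.latent_dim
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # balanced labels, shuffled: guarantees >= 2 samples per cluster
    labels = np.resize(np.arange(k), n)
    rng.shuffle(labels)

    centers = rng.normal(0.0, config.cluster_sep, size=(k, d))
    z = centers[labels] + rng.normal(0.0, 1.0, size=(n, d))

    layers: dict[str, OmicsLayer] = {}
    prefixes = {"F1": "gene", "F2": "mir", "F3": "probe", "F4": "prot"}
    for tag in ("F1", "F2", "F3", "F4"):
        p = config.n_features[tag]
        fids = [f"{prefixes[tag]}{j + 1}" for j in range(p)]
        w = rng.normal(0.0, 1.0, size=(d, p)) / np.sqrt(d)
        b = rng.normal(0.0, 0.5, size=p)
        h = np.tanh(z @ w + b) + rng.normal(0.0, config.layer_noise, size=(n, p))
        if tag in ("F1", "F2"):
            vals = np.exp(2.0 + 1.5 * h)  # positive, right-skewed abundance
            zero_mask = rng.random((n, p)) < config.zero_rate[tag]
            vals[zero_mask] = 0.0
        elif tag == "F3":
            vals = 1.0 / (1.0 + np.exp(-2.0 * h))  # beta values in (0, 1)
        else:
            vals = 2.0 * h
        ann = None
        if tag == "F3":
            ann = _chromosome_annotation(rng, fids, config.sex_probe_frac)
        if tag in ("F3", "F4"):
            rates = _missing_rates(
                rng, p, config.missing_low, config.missing_high,
                config.high_missing_frac[tag],
            )
            na_mask = rng.random((n, p)) < rates[None, :]
            # keep every feature observed somewhere so imputation stays defined
            full_cols = np.flatnonzero(na_mask.all(axis=0))
            na_mask[0, full_cols] = False
            vals = vals.copy()
            vals[na_mask] = np.nan
        kept_ids = sample_ids
        if config.overlap_frac < 1.0:
            keep = rng.random(n) < config.overlap_frac
            keep[rng.integers(n)] = True  # never an empty layer
            kept_ids = [s for s, kf in zip(sample_ids, keep) if kf]
            vals = vals[keep]
        layers[tag] = OmicsLayer(list(kept_ids), fids, vals, tag, ann)

    hazards = config.hazards()
    surv_os = _draw_survival(rng, sample_ids, labels, hazards, config.censoring_rate, "OS")
    surv_dfs = _draw_survival(
        rng, sample_ids, labels, 1.3 * hazards, config.censoring_rate, "DFS"
    )
    return SyntheticStudy(layers, labels, surv_os, surv_dfs, config, seed)


def toy_fixture() -> SyntheticStudy:
    """A fixed 12-sample, 10-features-per-layer study with hand-checkable filters.

    Constructed counts (per rule, strict thresholds):

    * F1: exactly 2 features with zero fraction > 0.20 (gene1: 3/12, gene2: 4/12)
    * F2: exactly 1 feature with zero fraction > 0.20 (mir1: 3/12)
    * F3: exactly 1 probe annotated chrX/chrY (probe1: chrX); exactly 1 probe
      with missing fraction > 0.10 (probe2: 2/12); probe3 has 1/12 missing
      (kept by the 10% rule)
    * F4: exactly 1 protein with missing fraction > 0.10 (prot1: 2/12)

    Two equal-size clusters of 6 with a strong hazard contrast.
    """
    rng = np.random.default_rng(20240613)  # filler values; violations injected below
    n, p = 12, 10
    sample_ids = [f"T{i + 1:02d}" for i in range(n)]

    def ids(prefix: str) -> list[str]:
        return [f"{prefix}{j + 1}" for j in range(p)]

    f1 = rng.uniform(1.0, 100.0, size=(n, p))
    f1[[0, 3, 7], 0] = 0.0            # gene1: 3 zeros -> 0.25 > 0.20
    f1[[1, 4, 6, 9], 1] = 0.0         # gene2: 4 zeros -> 0.33 > 0.20
    f1[[2, 5], 2] = 0.0               # gene3: 2 zeros -> 0.1667, retained

    f2 = rng.uniform(1.0, 50.0, size=(n, p))
    f2[[0, 2, 8], 0] = 0.0            # mir1: 3 zeros -> dropped

    f3 = rng.uniform(0.05, 0.95, size=(n, p))
    f3[[1, 5], 1] = np.nan            # probe2: 2/12 missing -> dropped
    f3[3, 2] = np.nan                 # probe3: 1/12 missing -> retained
    f3_ann = {f"probe{j + 1}": f"chr{j}" for j in range(1, p)}
    f3_ann["probe1"] = "chrX"

    f4 = rng.normal(0.0, 1.0, size=(n, p))
    f4[[4, 10], 0] = np.nan           # prot1: 2/12 missing -> dropped

    layers = {
        "F1": OmicsLayer(sample_ids, ids("gene"), f1, "F1"),
        "F2": OmicsLayer(sample_ids, ids("mir"), f2, "F2"),
        "F3": OmicsLayer(sample_ids, ids("probe"), f3, "F3", f3_ann),
        "F4": OmicsLayer(sample_ids, ids("prot"), f4, "F4"),
    }
    labels = np.array([0] * 6 + [1] * 6)
    time_os = np.array([900, 1400, 1100, 2000, 1700, 1300, 300, 150, 500, 90, 420, 260], float)
    event_os = np.array([0, 1, 0, 0, 1, 0, 1, 1, 1, 1, 0, 1])
    time_dfs = 0.8 * time_os
    event_dfs = np.array([0, 1, 1, 0, 1, 0, 1, 1, 1, 1, 1, 1])
    config = GeneratorConfig(n_samples=n, k_true=2,
                             n_features={t: p for t in layers})
    return SyntheticStudy(
        layers=layers,
        true_labels=labels,
        survival=SurvivalTable(sample_ids, time_os, event_os, "OS"),
        survival_dfs=SurvivalTable(sample_ids, time_dfs, event_dfs, "DFS"),
        generator_config=config,
        seed=0,
    )


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Write every layer, the F3 annotation, survival and true labels as TSV."""
    from pathlib import Path

    from . import io as oio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tag, layer in study.layers.items():
        oio.write_layer(layer, out / f"{tag}.tsv")
        if layer.annotation is not None:
            oio.write_annotation(layer.annotation, out / f"{tag}_annotation.tsv")
    oio.write_survival(study.survival, study.survival_dfs, out / "survival.tsv")
    oio.write_labels(study.sample_ids, study.true_labels, out / "true_labels.tsv")
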