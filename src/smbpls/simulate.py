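"""Synthetic multi-omics feeding-study generator with planted ground truth.

Emulates the structure of a two-diet longitudinal minipig trial: two diet
groups of 15 subjects each, sampled at weeks 4, 12 and 20, with three
untargeted LC-MS metabolomics blocks (log-normal intensities, correlated
feature clusters mimicking adduct/isotope redundancy, QC injections with
multiplicative signal drift over injection order, blank-only contaminant
features, and per-block missing samples), a fecal SCFA concentration
panel with diet and time multipliers, and a compositional taxa block
drawn from diet-shifted logistic-normal (or Dirichlet) distributions.

Planted effects are recorded in a :class:`GroundTruth` object so that a
recovery analysis can score any downstream feature selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diet import FECAL_SCFA, FECAL_EXTRA_ORGANIC, ScfaPanel
from .io import FeatureTable, ValidationError

logger = logging.getLogger(__name__)

DIETS = ("HR", "LR")
DEFAULT_WEEKS = ("week4", "week12", "week20")


@dataclass
class BlockSimConfig:
    """One metabolomics block's generator settings.

    ``effect_size_logsd`` is the planted diet shift in units of the
    baseline log-intensity SD; time markers drift linearly across weeks by
    ``time_effect_logsd`` per step.  ``cluster_size``/``cluster_rho`` give
    the block-diagonal feature correlation; ``drift_slope`` is the total
    fractional intensity gain across the injection sequence.
    """

    name: str = "plasma"
    n_features: int = 300
    n_diet_markers: int = 20
    n_time_markers: int = 10
    effect_size_logsd: float = 1.5
    time_effect_logsd: float = 1.0
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 1.0
    cluster_size: int = 10
    cluster_rho: float = 0.5
    missing_sample_rate: float = 0.05
    n_qc: int = 10
    n_blanks: int = 3
    n_blank_features: int = 10
    drift_slope: float = 0.3
    mode: str = "ESI+"

    def __post_init__(self) -> None:
        if self.n_diet_markers + self.n_time_markers > self.n_features:
            raise ValidationError(
                f"block {self.name!r}: marker counts exceed n_features"
            )
        if not 0.0 <= self.missing_sample_rate <= 1.0:
            raise ValidationError("missing_sample_rate must be in [0, 1]")
        if self.effect_size_logsd < 0 or self.time_effect_logsd < 0:
            raise ValidationError("effect sizes must be >= 0")


@dataclass
class ScfaSimConfig:
    """Fecal SCFA panel settings: baselines (mmol/kg) and multipliers.

    ``diet_multipliers`` scale the LR group (values > 1 plant an
    LR-elevated acid); ``time_multipliers`` scale weeks 12 and 20
    (values < 1 plant the observed decline of fecal SCFA over time).
    """

    baselines: dict[str, float] = field(default_factory=lambda: {
        "formic": 2.0, "acetic": 60.0, "propionic": 25.0, "isobutyric": 1.5,
        "n_butyric": 15.0, "isovaleric": 2.0, "n_valeric": 3.0,
        "isocaproic": 0.3, "n_caproic": 0.8, "heptanoic": 0.2,
        "sorbic": 0.1, "benzoic": 0.4, "dl_lactic": 4.0,
        "succinic": 2.5, "hippuric": 0.6,
    })
    diet_multipliers: dict[str, float] = field(default_factory=lambda: {
        "acetic": 1.5, "propionic": 1.25, "n_butyric": 1.2,
    })
    time_multipliers: dict[str, float] = field(default_factory=lambda: {
        "acetic": 0.85, "propionic": 0.85,
    })
    noise_cv: float = 0.25


@dataclass
class TaxaSimConfig:
    """Compositional taxa block: logistic-normal with diet-shifted means."""

    n_taxa: int = 50
    n_diet_shifted: int = 10
    shift_logsd: float = 1.5
    base_log_sd: float = 1.0
    distribution: str = "logistic-normal"   # or "dirichlet"
    concentration: float = 50.0             # Dirichlet only


@dataclass
class SimConfig:
    """Full study design: 2 diets x 15 subjects x 3 time points by default."""

    n_subjects_per_diet: int = 15
    time_points: tuple[str, ...] = DEFAULT_WEEKS
    blocks: tuple[BlockSimConfig, ...] = (
        BlockSimConfig(name="plasma"),
        BlockSimConfig(name="urine"),
        BlockSimConfig(name="feces"),
    )
    scfa: ScfaSimConfig = field(default_factory=ScfaSimConfig)
    taxa: TaxaSimConfig = field(default_factory=TaxaSimConfig)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_subjects_per_diet < 1 or len(self.time_points) < 1:
            raise ValidationError("counts must be positive")


@dataclass
class GroundTruth:
    """Planted effects: marker ids with signs, labels, SCFA multipliers."""

    diet_markers: dict[str, dict[str, int]]      # block -> feature_id -> sign
    time_markers: dict[str, dict[str, int]]
    class_labels: dict[str, str]                 # sample_id -> diet
    scfa_diet_multipliers: dict[str, float]
    taxa_shifted: dict[str, int]

    def to_dict(self) -> dict:
        return asdict(self)


def _design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for diet in DIETS:
        for s in range(1, config.n_subjects_per_diet + 1):
            subject = f"{diet}{s:02d}"
            for tp in config.time_points:
                rows.append({
                    "sample_id": f"{subject}_{tp}",
                    "subject_id": subject,
                    "class_label": diet,
                    "time_point": tp,
                    "role": "sample",
                })
    return pd.DataFrame(rows).set_index("sample_id")


def _correlated_noise(rng: np.random.Generator, n: int, p: int,
                      cluster_size: int, rho: float) -> np.ndarray:
    """Unit-variance noise with within-cluster correlation rho."""
    eps = rng.standard_normal((n, p))
    if rho <= 0 or cluster_size <= 1:
        return eps
    out = np.empty_like(eps)
    for start in range(0, p, cluster_size):
        end = min(start + cluster_size, p)
        shared = rng.standard_normal((n, 1))
        out[:, start:end] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps[:, start:end]
    return out


def _simulate_block(cfg: BlockSimConfig, design: pd.DataFrame,
                    rng: np.random.Generator) -> tuple[FeatureTable, dict[str, int], dict[str, int]]:
    n = len(design)
    p = cfg.n_features
    fids = [f"{cfg.name}_F{j + 1:04d}" for j in range(p)]
    blank_fids = [f"{cfg.name}_BLK{j + 1:03d}" for j in range(cfg.n_blank_features)]

    Z = cfg.baseline_log_mean + cfg.baseline_log_sd * _correlated_noise(
        rng, n, p, cfg.cluster_size, cfg.cluster_rho
    )

    # planted diet markers: first block of features, alternating sign, LR shifted
    diet_truth: dict[str, int] = {}
    lr = (design["class_label"] == "LR").to_numpy()
    for j in range(cfg.n_diet_markers):
        sign = 1 if j % 2 == 0 else -1
        Z[lr, j] += sign * cfg.effect_size_logsd * cfg.baseline_log_sd
        diet_truth[fids[j]] = sign

    # planted time markers: monotone linear trend over weeks
    time_truth: dict[str, int] = {}
    week_index = design["time_point"].map(
        {tp: i for i, tp in enumerate(sorted(set(design["time_point"]),
                                            key=list(design["time_point"]).index))}
    ).to_numpy()
    for jj in range(cfg.n_time_markers):
        j = cfg.n_diet_markers + jj
        sign = 1 if jj % 2 == 0 else -1
        Z[:, j] += sign * cfg.time_effect_logsd * cfg.baseline_log_sd * week_index
        time_truth[fids[j]] = sign

    intens = np.exp(Z)

    # QC rows: pooled-sample stand-ins near the feature geometric mean
    qc = np.exp(
        cfg.baseline_log_mean
        + 0.1 * cfg.baseline_log_sd * rng.standard_normal((cfg.n_qc, p))
    )
    # blank rows: real features at trace level
    blank = np.exp(
        cfg.baseline_log_mean - 6.0 * cfg.baseline_log_sd
        + 0.1 * rng.standard_normal((cfg.n_blanks, p))
    )

    # blank-only contaminant features: solvent-level intensity in blanks,
    # trace in samples/QCs
    blank_feat_samples = np.exp(
        cfg.baseline_log_mean - 6.0
        + 0.1 * rng.standard_normal((n + cfg.n_qc, cfg.n_blank_features))
    )
    blank_feat_blanks = np.exp(
        cfg.baseline_log_mean
        + 0.1 * rng.standard_normal((cfg.n_blanks, cfg.n_blank_features))
    )

    all_fids = fids + blank_fids
    mat = np.vstack([
        np.hstack([intens, blank_feat_samples[:n]]),
        np.hstack([qc, blank_feat_samples[n:]]),
        np.hstack([blank, blank_feat_blanks]),
    ])

    # injection sequence: QCs at regular intervals, blanks right after the
    # leading QCs, samples randomized in the remaining slots
    n_rows = mat.shape[0]
    orders = np.empty(n_rows, dtype=int)
    qc_slots = np.linspace(1, n_rows, cfg.n_qc).round().astype(int)
    qc_slots = np.unique(qc_slots)
    while qc_slots.size < cfg.n_qc:   # collisions from rounding
        extra = np.setdiff1d(np.arange(1, n_rows + 1), qc_slots)[:1]
        qc_slots = np.union1d(qc_slots, extra)
    remaining = np.setdiff1d(np.arange(1, n_rows + 1), qc_slots)
    blank_slots = remaining[: cfg.n_blanks]
    sample_slots = rng.permutation(remaining[cfg.n_blanks:])
    orders[:n] = sample_slots[:n]
    orders[n:n + cfg.n_qc] = qc_slots
    orders[n + cfg.n_qc:] = blank_slots

    # multiplicative linear drift over the whole run
    drift = 1.0 + cfg.drift_slope * (orders - 1) / max(n_rows - 1, 1)
    mat = mat * drift[:, None]

    meta = pd.concat([
        design[["subject_id", "class_label", "time_point", "role"]],
        pd.DataFrame({
            "subject_id": "QCpool", "class_label": "", "time_point": "",
            "role": "QC",
        }, index=[f"{cfg.name}_QC{i + 1:02d}" for i in range(cfg.n_qc)]),
        pd.DataFrame({
            "subject_id": "blank", "class_label": "", "time_point": "",
            "role": "blank",
        }, index=[f"{cfg.name}_BL{i + 1:02d}" for i in range(cfg.n_blanks)]),
    ])
    meta["injection_order"] = orders
    meta = meta[["subject_id", "class_label", "time_point", "injection_order", "role"]]

    var_meta = pd.DataFrame({
        "mz": rng.uniform(60.0, 690.0, len(all_fids)).round(4),
        "rt": rng.uniform(0.5, 14.5, len(all_fids)).round(3),
        "mode": cfg.mode,
    }, index=pd.Index(all_fids, name="feature_id"))

    table = FeatureTable(
        intensities=pd.DataFrame(mat, index=meta.index, columns=all_fids),
        sample_meta=meta,
        var_meta=var_meta,
        name=cfg.name,
    )

    # per-block missing samples (independent across blocks)
    if cfg.missing_sample_rate > 0:
        keep_mask = rng.random(n) >= cfg.missing_sample_rate
        keep_ids = list(design.index[keep_mask]) + list(meta.index[n:])
        dropped = n - int(keep_mask.sum())
        if dropped:
            logger.info("block %r: %d sample(s) missing", cfg.name, dropped)
        table = table.subset(sample_ids=keep_ids)
    return table, diet_truth, time_truth


def _simulate_scfa(cfg: ScfaSimConfig, design: pd.DataFrame,
                   time_points: Sequence[str], rng: np.random.Generator) -> ScfaPanel:
    acids = list(FECAL_SCFA) + list(FECAL_EXTRA_ORGANIC)
    week_rank = {tp: i for i, tp in enumerate(time_points)}
    rows = np.empty((len(design), len(acids)))
    lr = (design["class_label"] == "LR").to_numpy()
    week = design["time_point"].map(week_rank).to_numpy()
    for j, acid in enumerate(acids):
        mean = cfg.baselines.get(acid, 1.0)
        mult = np.ones(len(design))
        dm = cfg.diet_multipliers.get(acid)
        if dm is not None:
            mult[lr] *= dm
        tm = cfg.time_multipliers.get(acid)
        if tm is not None:
            mult *= tm ** week
        # log-normal noise with the configured CV around the scaled mean
        sigma = np.sqrt(np.log(1.0 + cfg.noise_cv ** 2))
        rows[:, j] = mean * mult * np.exp(
            sigma * rng.standard_normal(len(design)) - sigma ** 2 / 2.0
        )
    return ScfaPanel(
        concentrations=pd.DataFrame(rows, index=design.index, columns=acids),
        compartment="fecal",
    )


def _simulate_taxa(cfg: TaxaSimConfig, design: pd.DataFrame,
                   rng: np.random.Generator) -> tuple[FeatureTable, dict[str, int]]:
    names = [f"taxon_{j + 1:03d}" for j in range(cfg.n_taxa)]
    base_mu = rng.normal(0.0, 1.0, cfg.n_taxa)
    shifted: dict[str, int] = {}
    shift = np.zeros(cfg.n_taxa)
    for j in range(cfg.n_diet_shifted):
        sign = 1 if j % 2 == 0 else -1
        shift[j] = sign * cfg.shift_logsd
        shifted[names[j]] = sign
    lr = (design["class_label"] == "LR").to_numpy()
    n = len(design)
    if cfg.distribution == "logistic-normal":
        Z = base_mu + cfg.base_log_sd * rng.standard_normal((n, cfg.n_taxa))
        Z[lr] += shift
        expZ = np.exp(Z - Z.max(axis=1, keepdims=True))
        rel = expZ / expZ.sum(axis=1, keepdims=True)
    elif cfg.distribution == "dirichlet":
        base_p = np.exp(base_mu) / np.exp(base_mu).sum()
        rel = np.empty((n, cfg.n_taxa))
        for i in range(n):
            alpha = base_p * np.exp(shift if lr[i] else 0.0)
            alpha = cfg.concentration * alpha / alpha.sum()
            rel[i] = rng.dirichlet(alpha)
    else:
        raise ValidationError(f"unknown taxa distribution {cfg.distribution!r}")
    meta = design[["subject_id", "class_label", "time_point", "role"]].copy()
    meta["injection_order"] = np.arange(1, n + 1)
    meta = meta[["subject_id", "class_label", "time_point", "injection_order", "role"]]
    var_meta = pd.DataFrame(
        {"mz": np.nan, "rt": np.nan, "mode": "taxa"},
        index=pd.Index(names, name="feature_id"),
    )
    table = FeatureTable(
        intensities=pd.DataFrame(rel, index=design.index, columns=names),
        sample_meta=meta, var_meta=var_meta, name="taxa",
    )
    return table, shifted


def simulate_study(
    config: SimConfig | None = None, seed: int | None = None,
) -> tuple[list[FeatureTable], ScfaPanel, FeatureTable, GroundTruth]:
    """Generate a full synthetic study; same seed, bit-identical output.

    Returns the metabolomics blocks, the fecal SCFA panel, the taxa
    relative-abundance block and the planted ground truth.
    """
    config = config or SimConfig()
    if seed is not None:
        config.seed = seed
    rng = np.random.default_rng(config.seed)
    design = _design(config)

    tables: list[FeatureTable] = []
    diet_truth: dict[str, dict[str, int]] = {}
    time_truth: dict[str, dict[str, int]] = {}
    for bc in config.blocks:
        t, dt, tt = _simulate_block(bc, design, rng)
        tables.append(t)
        diet_truth[bc.name] = dt
        time_truth[bc.name] = tt

    scfa = _simulate_scfa(config.scfa, design, config.time_points, rng)
    taxa, shifted = _simulate_taxa(config.taxa, design, rng)

    truth = GroundTruth(
        diet_markers=diet_truth,
        time_markers=time_truth,
        class_labels=dict(zip(design.index, design["class_label"])),
        scfa_diet_multipliers=dict(config.scfa.diet_multipliers),
        taxa_shifted=shifted,
    )
    return tables, scfa, taxa, truth


def recovery_metrics(
    selected_ids: Sequence[str], planted_ids: Sequence[str],
) -> dict[str, Optional[float]]:
    """Recall, precision and false-discovery proportion of a selection."""
    sel = set(selected_ids)
    truth = set(planted_ids)
    hit = len(sel & truth)
    recall = hit / len(truth) if truth else None
    if not sel:
        logger.warning("recovery_metrics: empty selection; precision undefined")
        precision = None
        fdp = None
    else:
        precision = hit / len(sel)
        fdp = 1.0 - precision
    return {"recall": recall, "precision": precision, "fdp": fdp}
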