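"""Synthetic single-cell and bulk cohorts with known planted structure.

The generator emulates the shape of the study data every downstream stage
consumes: a droplet-style single-cell count matrix over eight annotated
pancreatic cell components with exclusive marker programs, and bulk cohorts
built as cell-fraction mixtures of the same cell-type profiles, with planted
coexpression modules, survival times whose log-hazard is linear in the planted
module activities, per-cohort batch shifts, and ligand-receptor co-expression
programs between stromal (fibroblast/endothelial) and tumor compartments.

Because every planted quantity is recorded in :class:`SyntheticTruth`, the
whole pipeline can be tested as a parameter-recovery problem without any
external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import CELL_TYPES, ExpressionMatrix, make_annotation

#: Canonical lineage reference gene per cell component (used both as planted
#: markers and, downstream, as denominators of the bulk communication score).
REFERENCE_GENES: Dict[str, str] = {
    "tumor": "EPCAM",
    "endothelial": "CDH5",
    "fibroblast": "COL1A2",
    "myeloid": "ITGAM",
    "acinar": "CPA1",
    "islet": "NEUROD1",
    "B": "MS4A1",
    "cytotoxic": "CD3E",
}

_TYPE_PREFIX = {
    "tumor": "TUM",
    "fibroblast": "FIB",
    "endothelial": "END",
    "myeloid": "MYE",
    "B": "BCL",
    "cytotoxic": "CTX",
    "acinar": "ACI",
    "islet": "ISL",
}

#: Default planted ligand-receptor programs: stromal ligands signalling onto a
#: tumor-cell integrin receptor (ligand, sender type, receptor, target type,
#: co-expression strength = loading on the hazard-linked module factor).
DEFAULT_LR_PROGRAMS: List[Tuple[str, str, str, str, float]] = [
    ("COL1A1", "fibroblast", "ITGA2", "tumor", 1.0),
    ("FN1", "fibroblast", "ITGA2", "tumor", 1.0),
    ("COL8A1", "endothelial", "ITGA2", "tumor", 1.0),
]


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Configuration of one synthetic study.

    Defaults describe the conditions the pipeline is exercised under: eight
    cell types with 25 exclusive markers each at log2 fold change 2, 150 cells
    per type, 300 bulk samples drawn from 3 sub-cohorts, two planted modules
    ("green", hazardous, beta=+0.7; "blue", protective, beta=-0.7) whose
    activities also separate three well-separated sample classes (adjacent
    class means 4.5 within-class SDs apart along one factor axis, so the
    planted partition is recoverable and clustering failures indicate
    pipeline defects rather than irreducible overlap), 30% censoring, and
    three stromal-to-tumor ligand-receptor programs riding on the green
    factor.
    """

    n_cell_types: int = 8
    cells_per_type: int = 150
    n_genes: int = 1200
    markers_per_type: int = 25
    marker_log2fc: float = 2.0
    nb_dispersion: float = 0.3  # var = mu + dispersion * mu^2
    n_bulk_samples: int = 300
    n_cohorts: int = 3
    fraction_concentration: Optional[Sequence[float]] = None  # Dirichlet alpha per type
    module_specs: Optional[List[Tuple[str, List[str], float]]] = None  # (name, genes, loading)
    survival_betas: Optional[Dict[str, float]] = None  # module -> log HR per unit activity
    censor_rate: float = 0.3
    batch_shift_sd: float = 0.3
    lr_programs: List[Tuple[str, str, str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_LR_PROGRAMS)
    )
    n_sample_classes: int = 3
    class_separation: float = 4.5  # shift of a module factor mean, in within-class SD units
    noise_sd: float = 0.3  # lognormal measurement noise, log2 scale
    baseline_median_survival: float = 365.0  # days, at zero module activity
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_types", "cells_per_type", "n_genes", "markers_per_type",
                     "n_bulk_samples", "n_cohorts"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_cell_types != len(CELL_TYPES):
            raise ConfigError(f"n_cell_types must be {len(CELL_TYPES)} (the declared vocabulary)")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        n_named = self.markers_per_type * self.n_cell_types + len(
            {p[0] for p in self.lr_programs} | {p[2] for p in self.lr_programs}
        )
        if self.n_genes < n_named:
            raise ConfigError(f"n_genes={self.n_genes} smaller than {n_named} named genes")
        if self.fraction_concentration is None:
            self.fraction_concentration = [10.0] * self.n_cell_types
        if len(list(self.fraction_concentration)) != self.n_cell_types:
            raise ConfigError("fraction_concentration needs one value per cell type")
        if self.module_specs is None:
            self.module_specs = self._default_module_specs()
        if self.survival_betas is None:
            self.survival_betas = {"green": 0.7, "blue": -0.7}
        known = {name for name, _, _ in self.module_specs}
        unknown = set(self.survival_betas) - known
        if unknown:
            raise ConfigError(f"survival_betas name unknown modules: {sorted(unknown)}")
        seen: set = set()
        for name, genes, _ in self.module_specs:
            overlap = seen & set(genes)
            if overlap:
                raise ConfigError(f"module {name!r} reuses genes: {sorted(overlap)[:5]}")
            seen |= set(genes)

    # -- deterministic gene naming ------------------------------------------------

    def marker_names(self, cell_type: str) -> List[str]:
        """Planted exclusive markers of one type (reference gene first)."""
        prefix = _TYPE_PREFIX[cell_type]
        synth = [f"{prefix}{i:03d}" for i in range(1, self.markers_per_type)]
        return [REFERENCE_GENES[cell_type]] + synth

    def lr_genes(self) -> Dict[str, str]:
        """Ligand/receptor gene -> the cell type it is planted in."""
        out: Dict[str, str] = {}
        for lig, sender, rec, target, _ in self.lr_programs:
            out[lig] = sender
            out[rec] = target
        return out

    def gene_names(self) -> List[str]:
        names: List[str] = []
        for ct in CELL_TYPES:
            names.extend(self.marker_names(ct))
        for g in self.lr_genes():
            if g not in names:
                names.append(g)
        i = 1
        while len(names) < self.n_genes:
            names.append(f"G{i:04d}")
            i += 1
        return names

    def _default_module_specs(self) -> List[Tuple[str, List[str], float]]:
        # green: stromal/immune-marker module carrying the hazard; also hosts the
        # LR program genes so that communication scores track the green factor.
        fib = self.marker_names("fibroblast")[1:]  # keep reference genes module-free
        mye = self.marker_names("myeloid")[1:]
        end = self.marker_names("endothelial")[1:]
        ctx = self.marker_names("cytotoxic")[1:]
        take = min(20, self.markers_per_type - 1)
        lr = sorted(self.lr_genes())
        green = fib[:take] + mye[:take] + lr
        blue = end[:take] + ctx[:take]
        # loading 0.5 keeps class-level expression shifts within a realistic
        # range (~5-fold) so module structure is not distorted by the TPM
        # compositional constraint
        return [("green", green, 0.5), ("blue", blue, 0.5)]


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for recovery tests."""

    marker_map: Dict[str, str]          # gene -> cell type
    module_map: Dict[str, str]          # gene -> planted module
    true_betas: Dict[str, float]        # module -> log hazard ratio
    true_fractions: Optional[pd.DataFrame] = None   # sample x cell type simplex
    lr_truth: Optional[pd.DataFrame] = None          # planted LR edges
    module_activity: Optional[pd.DataFrame] = None   # sample x module latent factor
    class_labels: Optional[pd.Series] = None         # sample -> planted class
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        # exclusivity of planted markers is a construction invariant
        assert len(self.marker_map) == len(set(self.marker_map)), "marker map not unique"

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "marker_map": self.marker_map,
            "module_map": self.module_map,
            "true_betas": self.true_betas,
            "true_fractions": None if self.true_fractions is None
            else self.true_fractions.round(10).to_dict(orient="index"),
            "lr_truth": None if self.lr_truth is None
            else self.lr_truth.to_dict(orient="records"),
            "module_activity": None if self.module_activity is None
            else self.module_activity.round(10).to_dict(orient="index"),
            "class_labels": None if self.class_labels is None
            else self.class_labels.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# internal building blocks
# ---------------------------------------------------------------------------


def _gene_model(cfg: SimConfig) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Baseline expression rates and per-type linear-scale mean profiles.

    Shared by the single-cell and bulk generators (seeded from cfg.seed alone)
    so markers learned on single-cell data transfer to the bulk mixtures.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 11]))
    genes = cfg.gene_names()
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    # lineage reference genes get a solid floor so ratios to them are stable
    idx = {g: i for i, g in enumerate(genes)}
    for g in REFERENCE_GENES.values():
        base[idx[g]] = max(base[idx[g]], 5.0)

    boost = np.ones((len(genes), len(CELL_TYPES)))
    fc = 2.0 ** cfg.marker_log2fc
    for t, ct in enumerate(CELL_TYPES):
        for g in cfg.marker_names(ct):
            boost[idx[g], t] = fc
    for g, ct in cfg.lr_genes().items():
        boost[idx[g], CELL_TYPES.index(ct)] = fc
    mean = base[:, None] * boost
    return genes, base, mean


def _marker_map(cfg: SimConfig) -> Dict[str, str]:
    mm: Dict[str, str] = {}
    for ct in CELL_TYPES:
        for g in cfg.marker_names(ct):
            mm[g] = ct
    for g, ct in cfg.lr_genes().items():
        mm.setdefault(g, ct)
    return mm


def _module_map(cfg: SimConfig) -> Dict[str, str]:
    return {g: name for name, gene_list, _ in cfg.module_specs for g in gene_list}


def _lr_truth(cfg: SimConfig) -> pd.DataFrame:
    return pd.DataFrame(
        cfg.lr_programs,
        columns=["ligand", "sender", "receptor", "target", "strength"],
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def simulate_single_cell(cfg: SimConfig) -> Tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate an annotated single-cell count matrix.

    Counts are negative binomial around each gene's cell-type mean
    (``var = mu + dispersion * mu^2``); planted markers (and LR program genes)
    are elevated by ``2**marker_log2fc`` in their own type only.
    """
    genes, _, mean = _gene_model(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 23]))

    n_cells = cfg.cells_per_type * cfg.n_cell_types
    counts = np.empty((len(genes), n_cells), dtype=np.int64)
    cell_types: List[str] = []
    size = 1.0 / cfg.nb_dispersion  # NB shape parameter
    for t, ct in enumerate(CELL_TYPES):
        mu = mean[:, t][:, None] * np.ones((1, cfg.cells_per_type))
        p = size / (size + mu)
        block = rng.negative_binomial(size, p)
        sl = slice(t * cfg.cells_per_type, (t + 1) * cfg.cells_per_type)
        counts[:, sl] = block
        cell_types.extend([ct] * cfg.cells_per_type)

    cell_ids = [f"C{i:05d}" for i in range(n_cells)]
    # two samples of origin, interleaved, so per-sample marker testing is possible
    samples = [f"P{(i % 2) + 1}" for i in range(n_cells)]
    expr = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=cell_ids), "counts")
    ann = make_annotation(cell_ids, cell_types, samples)
    truth = SyntheticTruth(
        marker_map=_marker_map(cfg),
        module_map=_module_map(cfg),
        true_betas=dict(cfg.survival_betas),
        lr_truth=_lr_truth(cfg),
        seed=cfg.seed,
    )
    return expr, ann, truth


def _calibrate_censor_bound(event_times: np.ndarray, censor_rate: float) -> float:
    """Upper bound of Uniform(0, c) censoring hitting the target censor rate.

    P(censored_i) = P(U < T_i) = min(T_i / c, 1); solve mean_i = censor_rate.
    """
    if censor_rate <= 0:
        return np.inf

    def rate(c: float) -> float:
        return float(np.mean(np.minimum(event_times / c, 1.0))) - censor_rate

    lo = float(event_times.min()) * 1e-6 + 1e-9
    hi = float(event_times.max()) * 1e6
    if rate(hi) > 0:  # even huge bounds censor too much (cannot happen for rate<1)
        return hi
    return float(brentq(rate, lo, hi))


def simulate_bulk_cohort(
    cfg: SimConfig, seed_offset: int = 0
) -> Tuple[ExpressionMatrix, pd.DataFrame, pd.Series, SyntheticTruth]:
    """Simulate a bulk TPM cohort with survival, batch labels and truth.

    Each sample is a Dirichlet cell-fraction mixture of the cell-type mean
    profiles; planted module latent factors (with class-specific means) are
    added on the log2 scale together with lognormal noise and a per-cohort
    batch shift; columns are rescaled to TPM (sum 1e6). Survival times are
    exponential with log-hazard ``sum_m beta_m * activity_m`` and independent
    Uniform(0, c) censoring calibrated to ``censor_rate``.

    ``seed_offset`` lets callers draw independent external cohorts from the
    same configured population.
    """
    genes, _, mean = _gene_model(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 37, int(seed_offset)]))
    n = cfg.n_bulk_samples
    sample_ids = [f"B{seed_offset}_{i:04d}" for i in range(n)]

    # per-type TPM profiles and mixture
    prof = mean / mean.sum(axis=0, keepdims=True) * 1e6  # gene x type
    fractions = rng.dirichlet(np.asarray(cfg.fraction_concentration, float), size=n)  # n x type
    mix = prof @ fractions.T  # gene x sample

    # planted classes shift module factor means; sign patterns are chosen so
    # the class structure adds zero covariance between module factors (class 0
    # sits at the origin, the others at +/-s sign patterns), keeping the
    # planted modules uncorrelated in the unsigned network
    classes = rng.integers(0, cfg.n_sample_classes, size=n)
    module_names = [name for name, _, _ in cfg.module_specs]
    m = len(module_names)
    class_means = np.zeros((cfg.n_sample_classes, m))
    s = cfg.class_separation
    if cfg.n_sample_classes == 2:
        class_means[1, 0] = s
    else:
        for c in range(1, cfg.n_sample_classes):
            for j in range(m):
                class_means[c, j] = -s if ((c - 1) >> j) & 1 else s

    activity = class_means[classes] + rng.standard_normal((n, len(module_names)))
    gene_idx = {g: i for i, g in enumerate(genes)}

    y = np.log2(mix + 1.0)
    for m, (name, gene_list, loading) in enumerate(cfg.module_specs):
        rows = [gene_idx[g] for g in gene_list]
        y[rows, :] += loading * activity[:, m][None, :]
    y += rng.normal(0.0, cfg.noise_sd, size=y.shape)

    # per-cohort additive batch shift on the log scale
    batches = pd.Series(
        [f"cohort{(i * cfg.n_cohorts) // n}" for i in range(n)], index=sample_ids, name="batch"
    )
    shift = rng.normal(0.0, cfg.batch_shift_sd, size=(len(genes), cfg.n_cohorts))
    for b in range(cfg.n_cohorts):
        cols = np.flatnonzero(batches.to_numpy() == f"cohort{b}")
        y[:, cols] += shift[:, b][:, None]

    tpm = np.clip(np.exp2(y) - 1.0, 0.0, None)
    tpm = tpm / tpm.sum(axis=0, keepdims=True) * 1e6
    expr = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=sample_ids), "tpm")

    # survival: exponential with planted log-hazard, uniform censoring
    betas = np.array([cfg.survival_betas.get(m, 0.0) for m in module_names])
    lam0 = np.log(2.0) / cfg.baseline_median_survival
    lam = lam0 * np.exp(activity @ betas)
    t_event = rng.exponential(1.0 / lam)
    c_bound = _calibrate_censor_bound(t_event, cfg.censor_rate)
    t_cens = rng.uniform(0.0, c_bound, size=n) if np.isfinite(c_bound) else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)
    surv = pd.DataFrame({"time": time, "event": event}, index=sample_ids)
    surv.index.name = "sample"

    truth = SyntheticTruth(
        marker_map=_marker_map(cfg),
        module_map=_module_map(cfg),
        true_betas=dict(cfg.survival_betas),
        true_fractions=pd.DataFrame(fractions, index=sample_ids, columns=list(CELL_TYPES)),
        lr_truth=_lr_truth(cfg),
        module_activity=pd.DataFrame(activity, index=sample_ids, columns=module_names),
        class_labels=pd.Series(classes, index=sample_ids, name="class"),
        seed=cfg.seed,
    )
    return expr, surv, batches, truth


def attach_response_labels(scores: pd.Series, link_beta: float, seed: int = 0) -> pd.Series:
    """Draw binary response labels from a logistic link on a standardized score.

    ``label ~ Bernoulli(sigmoid(link_beta * z(score)))``; ``link_beta = inf``
    degenerates to ``score > median``.
    """
    x = np.asarray(scores, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("scores must be finite")
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 53]))
    if np.isinf(link_beta):
        labels = (x > np.median(x)).astype(int)
    else:
        labels = rng.binomial(1, expit(link_beta * z))
    return pd.Series(labels, index=scores.index, name="response")
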