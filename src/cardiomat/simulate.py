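"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the downstream analysis
assumes: a bulk RNA-seq compendium (an in-house time-course/format contrast,
two adult-vs-fetal comparator datasets, and several independent "maturation
model" datasets) in which a known set of planted transcription factors and
their regulon targets shift; fluorescence traces with closed-form transient
kinetics; striation images with known orientation dispersion and spatial
period; and qPCR / plate-reader tables with known fold structure.

Every generator takes a :class:`SimulationConfig` and derives all randomness
from ``config.seed``; identical config + seed gives bit-identical outputs.
Ground truth for each planted effect is exported in a :class:`TruthTable`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SimulationConfig",
    "TraceParams",
    "ImageParams",
    "TruthTable",
    "kernel_peak_time",
    "transient_kernel",
    "kernel_truth_features",
    "simulate_regulons",
    "simulate_count_compendium",
    "simulate_traces",
    "simulate_striation_image",
    "simulate_assay_tables",
]

#: in-house culture conditions, ordered by maturation protocol stage
INHOUSE_CONDITIONS = ("D12", "2D_D26", "2D_D40", "3D_D26", "3D_D40")

CONFIDENCE_GRADES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class TraceParams:
    """Parameters of the synthetic calcium fluorescence trace model.

    The transient kernel is ``k(t) = (1 - exp(-t/tau_rise)) * exp(-t/tau_decay)``
    for ``t >= 0``, normalized to unit peak, so ``amplitude`` is directly the
    true peak ΔF/F0 of each transient.
    """

    f0: float = 100.0  # baseline fluorescence (a.u.)
    amplitude: float = 1.0  # peak ΔF/F0 per transient
    tau_rise: float = 0.05  # s
    tau_decay: float = 0.25  # s
    beat_period: float = 2.0  # s, ~0.5 Hz spontaneous beating
    noise_sd: float = 0.002  # additive Gaussian, in units of F0 (ROI-mean trace)
    drift_slope: float = 0.0  # a.u. per second
    duration: float = 10.0  # s
    sampling_rate: float = 100.0  # Hz
    first_beat: float = 0.5  # s, onset of first transient

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if min(self.tau_rise, self.tau_decay, self.beat_period) <= 0:
            raise ValueError("tau_rise, tau_decay and beat_period must be positive")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")


@dataclass(frozen=True)
class ImageParams:
    """Parameters of the synthetic striation (sarcomere grating) image."""

    period_um: float = 1.8  # striation spacing (µm)
    orientation_mean: float = 30.0  # degrees, axial in [0, 180)
    orientation_kappa: float = math.inf  # concentration; inf = perfectly aligned
    pixel_size: float = 0.1  # µm per pixel
    noise_sd: float = 0.0  # additive Gaussian on [0,1]-scaled intensity
    tile_size: int = 48  # px; shared with the analysis module
    n_tiles: tuple[int, int] = (8, 8)  # tile grid (rows, cols)
    amplitude: float = 0.4  # grating contrast around the 0.5 mean level

    def validate(self) -> None:
        if self.pixel_size <= 0 or self.period_um <= 0:
            raise ValueError("pixel_size and period_um must be positive")
        if self.period_um < 2.0 * self.pixel_size:
            raise ValueError(
                f"period {self.period_um} µm is below the Nyquist limit "
                f"2·pixel_size = {2 * self.pixel_size} µm"
            )
        if self.tile_size < 8:
            raise ValueError("tile_size must be >= 8 px")


@dataclass
class SimulationConfig:
    """Configuration for all synthetic-data generators.

    Count-model parameters follow the negative-binomial parameterization
    ``var = mu + dispersion * mu**2``; library factors are drawn log-uniform
    over ``libsize_range`` and baseline gene means are log-normal.
    """

    seed: int = 0
    n_genes: int = 6000
    n_tfs: int = 200
    regulon_size_range: tuple[int, int] = (20, 60)
    frac_repressive: float = 0.25
    confidence_probs: tuple[float, ...] = (0.15, 0.20, 0.30, 0.20, 0.15)
    conditions: dict[str, int] = field(
        default_factory=lambda: {
            "D12": 3,
            "2D_D26": 3,
            "2D_D40": 3,
            "3D_D26": 3,
            "3D_D40": 3,
            "fetal_1": 3,
            "adult_1": 3,
            "fetal_2": 3,
            "adult_2": 3,
        }
    )
    n_models: int = 6
    replicates_per_model_condition: int = 3
    planted_tfs: int = 10
    planted_log2fc: float = 1.0
    coupling: float = 0.5
    dispersion: float = 0.01
    libsize_range: tuple[float, float] = (0.7, 1.4)
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    planted_min_mean: float = 300.0
    model_response_prob: float = 0.5
    # per-model effect sizes, in units of planted_log2fc
    model_effect_range: tuple[float, float] = (1.0, 1.6)
    trace_params: TraceParams = field(default_factory=TraceParams)
    image_params: ImageParams = field(default_factory=ImageParams)

    def validate(self) -> None:
        for name in ("n_genes", "n_tfs", "planted_tfs", "n_models"):
            if getattr(self, name) < 0 or (name in ("n_genes", "n_tfs") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.frac_repressive <= 1.0:
            raise ValueError("frac_repressive must be in [0, 1]")
        if not 0.0 <= self.model_response_prob <= 1.0:
            raise ValueError("model_response_prob must be in [0, 1]")
        lo, hi = self.regulon_size_range
        if lo < 1 or hi < lo:
            raise ValueError("regulon_size_range must be a positive interval")
        if hi >= self.n_genes:
            raise ValueError(
                f"max regulon size {hi} infeasible for {self.n_genes} genes"
            )
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.libsize_range[0] <= 0 or self.libsize_range[1] < self.libsize_range[0]:
            raise ValueError("libsize_range must be a positive interval")
        if len(self.confidence_probs) != len(CONFIDENCE_GRADES):
            raise ValueError("confidence_probs must have one entry per grade A-E")
        if abs(sum(self.confidence_probs) - 1.0) > 1e-9:
            raise ValueError("confidence_probs must sum to 1")
        if self.planted_tfs > self.n_tfs:
            raise ValueError("planted_tfs cannot exceed n_tfs")
        self.trace_params.validate()
        self.image_params.validate()

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


@dataclass
class TruthTable:
    """Exported ground truth for planted effects.

    Attributes
    ----------
    planted_tf_ids:
        Gene ids of the planted transcription factors.
    tf_offsets:
        TF × condition matrix of true log2 expression offsets.
    gene_offsets:
        gene × condition matrix of true log2 offsets (TFs plus their targets).
    regulon_edges:
        Edge table (tf, target, mode, confidence), one row per edge.
    model_activation:
        TF × model boolean matrix of which planted TFs respond per model.
    model_effects:
        TF × model matrix of the true log2 effect in each model dataset.
    true_votes:
        Per planted TF, number of models in which it responds.
    extras:
        Generator-specific truth (trace kinetics, image orientations, ...).
    """

    planted_tf_ids: list[str] = field(default_factory=list)
    tf_offsets: pd.DataFrame | None = None
    gene_offsets: pd.DataFrame | None = None
    regulon_edges: pd.DataFrame | None = None
    model_activation: pd.DataFrame | None = None
    model_effects: pd.DataFrame | None = None
    true_votes: pd.Series | None = None
    extras: dict = field(default_factory=dict)


def _stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent, reproducible substream per generator."""
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


# stream ids: keep stable so adding generators never shifts existing draws
_STREAM_REGULONS = 1
_STREAM_COUNTS = 2
_STREAM_TRACES = 3
_STREAM_IMAGE = 4
_STREAM_ASSAYS = 5


# ---------------------------------------------------------------------------
# Regulons


def simulate_regulons(config: SimulationConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Draw a signed, graded TF→target network.

    Returns an edge table with columns ``tf, confidence, target, mor`` (the
    DoRothEA-style layout; ``mor`` is +1 activation / −1 repression) and a
    :class:`TruthTable` carrying the same edges. TFs are themselves genes
    drawn from the simulated universe; targets exclude the TF itself and are
    unique within a regulon.
    """
    config.validate()
    rng = _stream_rng(config.seed, _STREAM_REGULONS)
    genes = np.array(config.gene_ids())

    tf_idx = rng.choice(config.n_genes, size=config.n_tfs, replace=False)
    tf_ids = genes[np.sort(tf_idx)]

    lo, hi = config.regulon_size_range
    rows = []
    for tf in tf_ids:
        size = int(rng.integers(lo, hi + 1))
        pool = genes[genes != tf]
        targets = rng.choice(pool, size=size, replace=False)
        modes = np.where(rng.random(size) < config.frac_repressive, -1, 1)
        grades = rng.choice(CONFIDENCE_GRADES, size=size, p=config.confidence_probs)
        for t, m, g in zip(targets, modes, grades):
            rows.append((tf, g, t, int(m)))
    edges = pd.DataFrame(rows, columns=["tf", "confidence", "target", "mor"])

    truth = TruthTable(regulon_edges=edges.copy())
    return edges, truth


# ---------------------------------------------------------------------------
# Count compendium


def _condition_offsets(config: SimulationConfig) -> dict[str, float]:
    """True log2 offset multiplier per condition for a planted TF.

    Offsets are monotone along the 3D maturation arm and present in adult
    samples; the 2D arm and fetal comparators stay at baseline.
    """
    fc = config.planted_log2fc
    off = {c: 0.0 for c in config.conditions}
    for cond in config.conditions:
        if cond == "3D_D26":
            off[cond] = 0.5 * fc
        elif cond == "3D_D40":
            off[cond] = fc
        elif cond.startswith("adult"):
            off[cond] = fc
    return off


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + alpha*mu^2 (Poisson at alpha=0)."""
    if alpha <= 0:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_count_compendium(
    config: SimulationConfig, regulons: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate the full count compendium with planted maturation TFs.

    Returns ``(counts, design, truth)``: a gene × sample integer count
    matrix, a sample design table (columns ``condition, dataset, replicate``)
    and the ground truth. Counts are NB(mean = s_j · q_gj, var = mu+α·mu²)
    with sample library factors s_j log-uniform over ``libsize_range``.

    Planted TFs receive the monotone 3D-arm/adult offsets; each of their
    regulon targets shifts by ``mode · coupling · (TF offset)``. Each of the
    ``n_models`` model datasets (conditions ``model{i}_ctrl`` /
    ``model{i}_mat``) activates a random subset of the planted TFs with its
    own effect size.
    """
    config.validate()
    rng = _stream_rng(config.seed, _STREAM_COUNTS)
    genes = config.gene_ids()
    tf_ids = sorted(regulons["tf"].unique())
    missing = set(tf_ids) | set(regulons["target"])
    if not missing <= set(genes):
        raise ValueError("regulons reference genes outside the simulated universe")

    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    baseline = pd.Series(baseline, index=genes)

    # planted regulators are drawn from well-expressed TFs so the planted
    # signal reflects genes the analysis would actually consider
    eligible = [t for t in tf_ids if baseline[t] >= config.planted_min_mean]
    if len(eligible) < config.planted_tfs:
        eligible = list(
            pd.Series(baseline[tf_ids]).sort_values(ascending=False).index[: max(config.planted_tfs, 1)]
        )
    planted = sorted(rng.choice(eligible, size=config.planted_tfs, replace=False))

    cond_off = _condition_offsets(config)
    conditions = dict(config.conditions)
    model_names = [f"model{i + 1}" for i in range(config.n_models)]
    for m in model_names:
        conditions[f"{m}_ctrl"] = config.replicates_per_model_condition
        conditions[f"{m}_mat"] = config.replicates_per_model_condition

    # per-model activation of planted TFs and effect sizes
    activation = pd.DataFrame(False, index=planted, columns=model_names)
    effects = pd.DataFrame(0.0, index=planted, columns=model_names)
    lo_e, hi_e = config.model_effect_range
    for m in model_names:
        act = rng.random(len(planted)) < config.model_response_prob
        activation[m] = act
        effects.loc[act, m] = config.planted_log2fc * rng.uniform(lo_e, hi_e, int(act.sum()))
    if config.planted_log2fc == 0.0:
        activation.loc[:, :] = False  # a null compendium has no responders

    # true per-gene log2 offsets per condition; coupling shifts apply to
    # regulon targets only — a planted regulator's own expression offset is
    # the exported truth and is never overwritten by another TF's coupling
    offsets = pd.DataFrame(0.0, index=genes, columns=list(conditions))
    planted_set = set(planted)
    tf_edges = {}
    for tf, g in regulons.groupby("tf"):
        tf_edges[tf] = g[~g["target"].isin(planted_set)]
    for tf in planted:
        edges = tf_edges.get(tf)
        for cond, mult in cond_off.items():
            if mult == 0.0:
                continue
            offsets.loc[tf, cond] += mult
            if edges is not None:
                offsets.loc[edges["target"], cond] += (
                    edges["mor"].to_numpy() * config.coupling * mult
                )
        for m in model_names:
            if activation.loc[tf, m]:
                eff = effects.loc[tf, m]
                offsets.loc[tf, f"{m}_mat"] += eff
                if edges is not None:
                    offsets.loc[edges["target"], f"{m}_mat"] += (
                        edges["mor"].to_numpy() * config.coupling * eff
                    )

    sample_ids, cond_labels, dataset_labels, rep_idx = [], [], [], []
    for cond, n_rep in conditions.items():
        if cond in INHOUSE_CONDITIONS:
            ds = "inhouse"
        elif cond.endswith("_1"):
            ds = "adult_fetal_1"
        elif cond.endswith("_2"):
            ds = "adult_fetal_2"
        else:
            ds = cond.rsplit("_", 1)[0]
        for r in range(1, n_rep + 1):
            sample_ids.append(f"{cond}_r{r}")
            cond_labels.append(cond)
            dataset_labels.append(ds)
            rep_idx.append(r)
    design = pd.DataFrame(
        {"condition": cond_labels, "dataset": dataset_labels, "replicate": rep_idx},
        index=pd.Index(sample_ids, name="sample"),
    )

    lib = rng.uniform(np.log(config.libsize_range[0]), np.log(config.libsize_range[1]), len(sample_ids))
    size_factors = np.exp(lib)

    counts = np.empty((config.n_genes, len(sample_ids)), dtype=np.int64)
    base = baseline.to_numpy()
    for j, (cond, s_j) in enumerate(zip(cond_labels, size_factors)):
        mu = base * 2.0 ** offsets[cond].to_numpy() * s_j
        counts[:, j] = _nb_draw(rng, mu, config.dispersion)
    counts = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=sample_ids)

    truth = TruthTable(
        planted_tf_ids=list(planted),
        tf_offsets=offsets.loc[planted].copy(),
        gene_offsets=offsets,
        regulon_edges=regulons.copy(),
        model_activation=activation,
        model_effects=effects,
        true_votes=activation.sum(axis=1).astype(int),
        extras={
            "baseline_mean": baseline,
            "library_factors": pd.Series(size_factors, index=sample_ids),
        },
    )
    return counts, design, truth


# ---------------------------------------------------------------------------
# Calcium traces


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the peak of (1-exp(-t/τr))·exp(-t/τd)."""
    return tau_rise * math.log((tau_rise + tau_decay) / tau_rise)


def transient_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Rise-then-exponential-decay kernel, normalized to unit peak; 0 for t<0."""
    t = np.asarray(t, dtype=float)
    tp = kernel_peak_time(tau_rise, tau_decay)
    peak = (1.0 - math.exp(-tp / tau_rise)) * math.exp(-tp / tau_decay)
    k = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / tau_rise)) * np.exp(-np.maximum(t, 0) / tau_decay), 0.0)
    return k / peak


def kernel_truth_features(
    tau_rise: float,
    tau_decay: float,
    amplitude: float = 1.0,
    rise_bounds: tuple[float, float] = (0.10, 0.90),
    decay_bounds: tuple[float, float] = (0.90, 0.10),
) -> dict[str, float]:
    """True kinetic features of one transient of the unit-peak kernel.

    Level-crossing times are found by root-finding on the kernel itself, so
    these values serve as the exact reference for the trace feature extractor.
    """
    tp = kernel_peak_time(tau_rise, tau_decay)

    def k(t: float) -> float:
        return float(transient_kernel(np.array([t]), tau_rise, tau_decay)[0])

    t_hi = tp
    while k(t_hi) > 1e-6 * 1.0:
        t_hi *= 2.0

    def crossing(level: float, rising: bool) -> float:
        if rising:
            return brentq(lambda t: k(t) - level, 0.0, tp, xtol=1e-12)
        return brentq(lambda t: k(t) - level, tp, t_hi, xtol=1e-12)

    half_up = crossing(0.5, True)
    half_down = crossing(0.5, False)
    r0, r1 = rise_bounds
    d0, d1 = decay_bounds
    return {
        "peak_amplitude": amplitude,
        "peak_time": tp,
        "fwhm": half_down - half_up,
        "rise_time": crossing(r1, True) - crossing(r0, True),
        "decay_time": crossing(d1, False) - crossing(d0, False),
    }


def simulate_traces(
    config: SimulationConfig,
    group_params: dict[str, TraceParams] | None = None,
    n_videos: int = 3,
    n_cells: int = 8,
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate Fluo-4-style fluorescence traces with known kinetics.

    Returns a long-format table (``condition, video_id, cell_id, time_s,
    intensity``) and truth with the per-condition kernel features. The trace
    model is ``F(t) = F0·(1 + Σ_i A·k(t − t_i)) + drift·t + ε`` with iid
    Gaussian ε of sd ``noise_sd·F0``.
    """
    import warnings

    config.validate()
    rng = _stream_rng(config.seed, _STREAM_TRACES)
    if group_params is None:
        group_params = {"default": config.trace_params}

    frames = []
    truth_feats = {}
    for cond, tp in group_params.items():
        tp.validate()
        if tp.beat_period <= tp.tau_rise + tp.tau_decay:
            warnings.warn(
                f"beat period {tp.beat_period}s < tau_rise+tau_decay for '{cond}': "
                "transients will overlap",
                stacklevel=2,
            )
        truth_feats[cond] = kernel_truth_features(tp.tau_rise, tp.tau_decay, tp.amplitude)
        n = int(round(tp.duration * tp.sampling_rate))
        t = np.arange(n) / tp.sampling_rate
        beats = np.arange(tp.first_beat, tp.duration, tp.beat_period)
        clean = np.zeros(n)
        for tb in beats:
            clean += tp.amplitude * transient_kernel(t - tb, tp.tau_rise, tp.tau_decay)
        for v in range(1, n_videos + 1):
            for c in range(1, n_cells + 1):
                noise = rng.normal(0.0, tp.noise_sd * tp.f0, n)
                intensity = tp.f0 * (1.0 + clean) + tp.drift_slope * t + noise
                frames.append(
                    pd.DataFrame(
                        {
                            "condition": cond,
                            "video_id": f"{cond}_v{v}",
                            "cell_id": f"{cond}_v{v}_c{c}",
                            "time_s": t,
                            "intensity": intensity,
                        }
                    )
                )
    traces = pd.concat(frames, ignore_index=True)
    truth = TruthTable(extras={"trace_features": truth_feats, "group_params": group_params})
    return traces, truth


# ---------------------------------------------------------------------------
# Striation images


def _sample_axial(rng: np.random.Generator, mean_deg: float, kappa: float, size: int) -> np.ndarray:
    """Sample axial orientations in [0, 180) from a von Mises on doubled angles."""
    if math.isinf(kappa):
        return np.full(size, mean_deg % 180.0)
    doubled = rng.vonmises(np.deg2rad(2.0 * mean_deg), kappa, size)
    return (np.rad2deg(doubled) / 2.0) % 180.0


def simulate_striation_image(
    config: SimulationConfig,
) -> tuple[np.ndarray, TruthTable]:
    """Render a tiled sinusoidal grating emulating α-actinin striations.

    Each tile of ``tile_size`` px gets its own axial orientation drawn from a
    wrapped (von Mises on doubled angles) distribution with the configured
    mean and concentration κ; the grating spatial period and per-tile
    orientations are exported as truth. Gaussian pixel noise is added on the
    [0, 1] intensity scale.
    """
    config.validate()
    p = config.image_params
    rng = _stream_rng(config.seed, _STREAM_IMAGE)
    period_px = p.period_um / p.pixel_size
    nr, nc = p.n_tiles
    h, w = nr * p.tile_size, nc * p.tile_size

    orientations = _sample_axial(rng, p.orientation_mean, p.orientation_kappa, nr * nc).reshape(nr, nc)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    image = np.empty((h, w))
    centers = []
    for i in range(nr):
        for j in range(nc):
            sl = (slice(i * p.tile_size, (i + 1) * p.tile_size), slice(j * p.tile_size, (j + 1) * p.tile_size))
            theta = math.radians(orientations[i, j])
            # stripes run along theta; the wave vector is the normal
            phase = (xx[sl] * -math.sin(theta) + yy[sl] * math.cos(theta)) * 2.0 * math.pi / period_px
            image[sl] = 0.5 + p.amplitude * np.cos(phase)
            centers.append(((i + 0.5) * p.tile_size, (j + 0.5) * p.tile_size))
    if p.noise_sd > 0:
        image = image + rng.normal(0.0, p.noise_sd, image.shape)

    truth = TruthTable(
        extras={
            "period_um": p.period_um,
            "pixel_size": p.pixel_size,
            "tile_orientations": orientations,
            "tile_centers": np.array(centers),
            "tile_size": p.tile_size,
        }
    )
    return image, truth


# ---------------------------------------------------------------------------
# qPCR and plate assays


def simulate_assay_tables(
    config: SimulationConfig,
    gene_folds: dict[str, float] | None = None,
    atp_ratios: dict[str, float] | None = None,
    n_replicates: int = 3,
    housekeeping: str = "DDB1",
    reference_group: str = "control",
    ct_noise_sd: float = 0.05,
    plate_noise_cv: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate a qPCR Ct table and an ATP plate-reader table with known truth.

    ``gene_folds`` maps gene → true expression fold in the treated group
    relative to ``reference_group`` (Ct = base − log2(expression) + noise;
    the housekeeping gene has fold 1 by construction). ``atp_ratios`` maps
    group → true ATP level relative to the control group.
    """
    config.validate()
    rng = _stream_rng(config.seed, _STREAM_ASSAYS)
    if gene_folds is None:
        gene_folds = {"TNNT2": 2.0, "MYH7": 4.0, "PPARGC1A": 1.5, "NPPA": 0.5}
    if atp_ratios is None:
        atp_ratios = {"treated": 1.4}

    genes = [housekeeping, *gene_folds]
    groups = [reference_group, "treated"]
    samples = [f"{g}_r{r}" for g in groups for r in range(1, n_replicates + 1)]
    base_ct = {g: rng.uniform(18.0, 28.0) for g in genes}

    ct = pd.DataFrame(index=pd.Index(genes, name="gene"), columns=samples, dtype=float)
    for s in samples:
        grp = s.rsplit("_r", 1)[0]
        for g in genes:
            fold = 1.0 if (g == housekeeping or grp == reference_group) else gene_folds[g]
            ct.loc[g, s] = base_ct[g] - math.log2(fold) + rng.normal(0.0, ct_noise_sd)

    group_col = [s.rsplit("_r", 1)[0] for s in samples]
    ct_design = pd.DataFrame({"group": group_col}, index=pd.Index(samples, name="sample"))

    plate_groups = ["mCherry", *atp_ratios]
    rows = []
    base_lum = 1000.0
    for grp in plate_groups:
        ratio = 1.0 if grp == "mCherry" else atp_ratios[grp]
        for r in range(1, n_replicates + 1):
            absorbance = rng.uniform(0.4, 0.6)
            lum = base_lum * ratio * absorbance * (1.0 + rng.normal(0.0, plate_noise_cv))
            rows.append((grp, lum, absorbance, r))
    plate = pd.DataFrame(rows, columns=["group", "luminescence", "absorbance_595", "replicate"])

    truth = TruthTable(
        extras={
            "ddct_truth": {g: -math.log2(f) for g, f in gene_folds.items()},
            "relative_expression_truth": dict(gene_folds),
            "atp_truth": {"mCherry": 1.0, **atp_ratios},
            "housekeeping": housekeeping,
            "reference_group": reference_group,
            "ct_design": ct_design,
        }
    )
    return ct, plate, truth
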