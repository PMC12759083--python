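"""Planted-truth simulators for screens, flow samples and cell images.

Three generators emulate the three data modalities the downstream modules
consume, each emitting a :class:`SimTruth` record of the planted ground truth:

``simulate_screen``
    Per-guide sequencing read counts for the high/low FACS bins of one pooled
    CRISPRi screen.  Each cell's reporter value is the knockdown shift of its
    guide's gene (attenuated by a per-guide efficacy) plus lognormal reporter
    noise; bin membership is the empirical top/bottom ``sort_fraction``
    quantile of the pooled reporter distribution, and reads per guide per bin
    are negative-binomial around the guide's expected bin occupancy.

``simulate_flow_sample``
    Single-cell flow events with a guide-positive and a guide-negative
    subpopulation, each channel lognormal per subpopulation.

``simulate_cell_image``
    2D multi-channel images of curvilinear, mitochondria-like objects
    (random-walk skeletons dilated to 3-5 px) with a planted membrane-
    potential class per object.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from mitosense.errors import ConfigurationError, GenerationError

__all__ = [
    "ScreenSimConfig",
    "FlowSimConfig",
    "ImageSimConfig",
    "SimTruth",
    "EFFICACY_LADDER",
    "simulate_screen",
    "simulate_six_screens",
    "simulate_flow_sample",
    "degradation_flow_configs",
    "simulate_cell_image",
    "SCREEN_KEYS",
]

#: The six (cell line x treatment) screen conditions used throughout.
SCREEN_KEYS = (
    "HeLa_Parkin_NT",
    "HeLa_Parkin_AO",
    "HeLa_noParkin_NT",
    "HeLa_noParkin_AO",
    "HEK293_NT",
    "HEK293_AO",
)

#: Multiplicative per-guide knockdown efficacy, cycled over the guides of a
#: gene.  Heterogeneous potency stresses the guide->gene aggregation step.
EFFICACY_LADDER = (1.0, 0.8, 0.6, 0.4, 0.2)


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth for one simulated dataset.

    ``entities`` holds exactly one row per simulated unit (guide, event or
    object); ``params`` carries dataset-level planted values such as the true
    degradation percentage or the label image.
    """

    kind: str
    entities: pd.DataFrame
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenSimConfig:
    """Configuration for one FACS-bin screen simulation.

    Parameters
    ----------
    n_genes
        Number of genes in the library.
    guides_per_gene
        Guides per gene; efficacies cycle through :data:`EFFICACY_LADDER`.
    n_replicates
        Independent sort/sequencing replicates per bin.
    baseline_mean
        Expected reads per guide per bin for a null guide.
    dispersion
        Negative-binomial overdispersion ``alpha`` (variance = mu + mu^2/alpha).
    effect_table
        Map gene -> planted reporter log2 shift for this screen condition.
    sort_fraction
        Fraction of the population collected into each bin (0, 0.5].
    reporter_sd
        Log2-scale standard deviation of single-cell reporter noise.
    seed
        Seed for the generator; identical config + seed is byte-reproducible.
    """

    n_genes: int
    guides_per_gene: int = 5
    n_replicates: int = 2
    baseline_mean: float = 500.0
    dispersion: float = 5.0
    effect_table: Mapping[str, float] = field(default_factory=dict)
    sort_fraction: float = 0.30
    reporter_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.guides_per_gene < 1:
            raise ConfigurationError("guides_per_gene must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not 0.0 < self.sort_fraction <= 0.5:
            raise ConfigurationError(
                f"sort_fraction must be in (0, 0.5], got {self.sort_fraction}"
            )
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be > 0")
        if self.reporter_sd <= 0:
            raise ConfigurationError("reporter_sd must be > 0")


def _gene_names(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"GENE{i:0{width}d}" for i in range(1, n_genes + 1)]


def _guide_universe(config: ScreenSimConfig) -> pd.DataFrame:
    genes = _gene_names(config.n_genes)
    rows = []
    for gene in genes:
        shift = float(config.effect_table.get(gene, 0.0))
        for j in range(config.guides_per_gene):
            eff = EFFICACY_LADDER[j % len(EFFICACY_LADDER)]
            rows.append(
                {
                    "guide_id": f"{gene}_g{j + 1}",
                    "gene": gene,
                    "efficacy": eff,
                    "shift": shift,
                    "effective_shift": shift * eff,
                }
            )
    return pd.DataFrame(rows)


def _bin_probabilities(
    effective_shifts: np.ndarray, sd: float, sort_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-guide probability of a cell landing in the low / high sort bin.

    The pooled reporter distribution is an equal-weight mixture of normals
    (one component per guide); the bin cut-offs are the ``sort_fraction`` and
    ``1 - sort_fraction`` quantiles of that mixture, found numerically.
    """
    shifts, counts = np.unique(effective_shifts, return_counts=True)
    weights = counts / counts.sum()

    def mixture_cdf(x: float) -> float:
        return float(np.sum(weights * stats.norm.cdf(x, loc=shifts, scale=sd)))

    lo = float(shifts.min() - 10 * sd)
    hi = float(shifts.max() + 10 * sd)
    q_lo = optimize.brentq(lambda x: mixture_cdf(x) - sort_fraction, lo, hi)
    q_hi = optimize.brentq(lambda x: mixture_cdf(x) - (1 - sort_fraction), lo, hi)
    p_low = stats.norm.cdf(q_lo, loc=effective_shifts, scale=sd)
    p_high = stats.norm.sf(q_hi, loc=effective_shifts, scale=sd)
    return p_low, p_high


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial counts with variance mu + mu^2/alpha."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = alpha / (alpha + mean[pos])
        out[pos] = rng.negative_binomial(alpha, p)
    return out


def simulate_screen(
    config: ScreenSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate one screen, returning (high-bin table, low-bin table, truth).

    Both tables share the same guide universe and carry columns
    ``guide_id, gene, rep1..repN`` of non-negative integer read counts.  A
    negative planted shift depletes a gene's guides from the high bin, so the
    expected guide-level log2(high/low) is monotone in the shift.
    """
    rng = np.random.default_rng(config.seed)
    guides = _guide_universe(config)
    p_low, p_high = _bin_probabilities(
        guides["effective_shift"].to_numpy(), config.reporter_sd, config.sort_fraction
    )
    # Reads per guide scale with the guide's share of the sorted bin; a null
    # guide (p_bin = sort_fraction) lands at baseline_mean.
    mu_high = config.baseline_mean * p_high / config.sort_fraction
    mu_low = config.baseline_mean * p_low / config.sort_fraction

    rep_cols = [f"rep{r + 1}" for r in range(config.n_replicates)]
    high = guides[["guide_id", "gene"]].copy()
    low = guides[["guide_id", "gene"]].copy()
    for col in rep_cols:
        high[col] = _nb_draw(rng, mu_high, config.dispersion)
    for col in rep_cols:
        low[col] = _nb_draw(rng, mu_low, config.dispersion)

    entities = guides.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        entities["expected_log2fc"] = np.log2(p_high) - np.log2(p_low)
    entities["category"] = np.select(
        [entities["shift"] < 0, entities["shift"] > 0],
        ["depleted_from_high", "enriched_in_high"],
        default="null",
    )
    truth = SimTruth(
        kind="screen",
        entities=entities,
        params={"config": dataclasses.replace(config)},
    )
    return high, low, truth


def simulate_six_screens(
    n_genes: int,
    effects: Mapping[str, Mapping[str, float]],
    seed: int = 0,
    **config_kwargs,
) -> tuple[dict[str, tuple[pd.DataFrame, pd.DataFrame]], SimTruth]:
    """Simulate all six screen conditions with per-condition effect tables.

    ``effects`` maps a screen key from :data:`SCREEN_KEYS` to that screen's
    gene -> shift table; omitted screens are null.  Each screen gets an
    independent sub-seed derived from ``seed``.  Returns a dict screen key ->
    (high, low) count-table pair and a gene-level truth whose ``entities``
    record each gene's planted shift per screen.
    """
    unknown = set(effects) - set(SCREEN_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown screen keys in effects: {sorted(unknown)}")
    seeds = np.random.SeedSequence(seed).spawn(len(SCREEN_KEYS))
    tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    genes = _gene_names(n_genes)
    entities = pd.DataFrame({"gene": genes})
    for key, sub_seed in zip(SCREEN_KEYS, seeds):
        cfg = ScreenSimConfig(
            n_genes=n_genes,
            effect_table=dict(effects.get(key, {})),
            seed=int(sub_seed.generate_state(1)[0] % (2**31)),
            **config_kwargs,
        )
        high, low, _ = simulate_screen(cfg)
        tables[key] = (high, low)
        entities[f"shift_{key}"] = [
            float(effects.get(key, {}).get(g, 0.0)) for g in genes
        ]
    truth = SimTruth(kind="six_screens", entities=entities, params={"seed": seed})
    return tables, truth


# ---------------------------------------------------------------------------
# Flow-cytometry simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowSimConfig:
    """Configuration for one simulated flow-cytometry sample.

    ``channel_params`` maps a channel name to natural-log lognormal
    ``(log_mean, log_sd)`` pairs for the guide-positive and guide-negative
    subpopulations: ``{"CH": {"positive": (m, s), "negative": (m, s)}}``.
    """

    n_events: int
    channel_params: Mapping[str, Mapping[str, tuple[float, float]]]
    frac_guide_positive: float = 0.5
    true_degradation_pct: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ConfigurationError("n_events must be >= 1")
        if not 0.0 < self.frac_guide_positive < 1.0:
            raise ConfigurationError("frac_guide_positive must be in (0, 1)")
        for ch, pops in self.channel_params.items():
            for pop in ("positive", "negative"):
                if pop not in pops:
                    raise ConfigurationError(
                        f"channel {ch!r} missing {pop!r} subpopulation parameters"
                    )
                _, sd = pops[pop]
                if sd <= 0:
                    raise ConfigurationError(
                        f"channel {ch!r} {pop} log-sd must be > 0, got {sd}"
                    )


def simulate_flow_sample(config: FlowSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate one event table (one row per cell) with planted subpopulations.

    The returned table has one column per channel plus a boolean
    ``guide_positive`` column; truth entities record each event's
    subpopulation once.
    """
    rng = np.random.default_rng(config.seed)
    positive = rng.random(config.n_events) < config.frac_guide_positive
    table = pd.DataFrame({"guide_positive": positive})
    for ch, pops in config.channel_params.items():
        values = np.empty(config.n_events)
        for pop, mask in (("positive", positive), ("negative", ~positive)):
            m, s = pops[pop]
            values[mask] = rng.lognormal(mean=m, sigma=s, size=int(mask.sum()))
        table[ch] = values
    entities = pd.DataFrame(
        {"event": np.arange(config.n_events), "guide_positive": positive}
    )
    truth = SimTruth(
        kind="flow",
        entities=entities,
        params={
            "true_degradation_pct": config.true_degradation_pct,
            "frac_guide_positive": config.frac_guide_positive,
        },
    )
    return table, truth


def degradation_flow_configs(
    true_degradation_pct: float,
    n_events: int = 50_000,
    log_mean: float = 6.0,
    log_sd: float = 0.8,
    seed: int = 0,
) -> tuple[FlowSimConfig, FlowSimConfig]:
    """Build (sample, CTRL) configs planting a known MFN2 degradation %.

    The degradation statistic is, as reported, ``100 * (normint+ - normint-)
    / normint+`` with each population's mean MFN2 normalised to the matching
    CTRL population.  The planted truth is defined through that same formula:
    the Parkin+ population sits at the CTRL level (normint+ = 1) and the
    Parkin- population mean is scaled to ``1 - pct/100``, so the statistic
    evaluates to ``pct`` in expectation.  The ``guide_positive`` column marks
    the Parkin+ population.  The default reporter noise (``log_sd`` 0.8,
    arithmetic CV ~0.95) is typical of single-cell fluorescence and puts the
    sampling error of the estimate within ~1.2 percentage points at 50k
    events.
    """
    if not 0.0 <= true_degradation_pct < 100.0:
        raise ConfigurationError("true_degradation_pct must be in [0, 100)")
    ratio = 1.0 - true_degradation_pct / 100.0
    sample = FlowSimConfig(
        n_events=n_events,
        channel_params={
            "MFN2": {
                "positive": (log_mean, log_sd),
                "negative": (log_mean + float(np.log(ratio)), log_sd),
            }
        },
        frac_guide_positive=0.5,
        true_degradation_pct=true_degradation_pct,
        seed=seed,
    )
    ctrl = FlowSimConfig(
        n_events=n_events,
        channel_params={
            "MFN2": {"positive": (log_mean, log_sd), "negative": (log_mean, log_sd)}
        },
        frac_guide_positive=0.5,
        true_degradation_pct=0.0,
        seed=seed + 1,
    )
    return sample, ctrl


# ---------------------------------------------------------------------------
# Image simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSimConfig:
    """Configuration for a simulated multi-channel cell image.

    Channels rendered: ``MTS`` (matrix marker, all objects), ``MMP``
    (potential-dependent dye, high-MMP objects only) and ``PINK1``
    (per-class gain; by default brighter on depolarised objects).
    ``channel_gains`` accepts a scalar per channel, or for ``PINK1`` a
    ``{"high_mmp": g, "low_mmp": g}`` mapping.
    """

    shape: tuple[int, int] = (256, 256)
    n_mito: int = 25
    frac_low_mmp: float = 0.3
    channel_gains: Mapping[str, object] = field(
        default_factory=lambda: {
            "MTS": 200.0,
            "MMP": 200.0,
            "PINK1": {"high_mmp": 60.0, "low_mmp": 180.0},
        }
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mito < 0:
            raise ConfigurationError("n_mito must be >= 0")
        if not 0.0 <= self.frac_low_mmp <= 1.0:
            raise ConfigurationError("frac_low_mmp must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if len(self.shape) != 2 or min(self.shape) < 16:
            raise ConfigurationError("shape must be 2D and at least 16x16")


def _random_walk_skeleton(
    rng: np.random.Generator, shape: tuple[int, int], length: int
) -> np.ndarray | None:
    """Rounded pixel path of a 2D random walk with small angular diffusion."""
    h, w = shape
    margin = 6
    y = rng.uniform(margin, h - margin)
    x = rng.uniform(margin, w - margin)
    theta = rng.uniform(0, 2 * np.pi)
    pts = [(y, x)]
    for _ in range(length):
        theta += rng.normal(0, 0.35)
        y += np.sin(theta)
        x += np.cos(theta)
        if not (margin / 2 < y < h - margin / 2 and margin / 2 < x < w - margin / 2):
            return None
        pts.append((y, x))
    rows = np.clip(np.round([p[0] for p in pts]).astype(int), 0, h - 1)
    cols = np.clip(np.round([p[1] for p in pts]).astype(int), 0, w - 1)
    return np.stack([rows, cols], axis=1)


def _gain_for(config: ImageSimConfig, channel: str, mmp_class: str) -> float:
    gain = config.channel_gains.get(channel, 0.0)
    if isinstance(gain, Mapping):
        return float(gain.get(mmp_class, 0.0))
    return float(gain)


def simulate_cell_image(config: ImageSimConfig) -> tuple[dict[str, np.ndarray], SimTruth]:
    """Render a multi-channel image of disjoint curvilinear objects.

    Returns ``(channels, truth)`` where ``channels`` maps channel name to a
    float 2D array and ``truth.params['label_image']`` assigns every object
    pixel to its object id (one object per id; objects do not overlap).
    Truth entities carry each object's id, MMP class and pixel count.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    # ~40-step skeleton dilated to ~3-5 px width covers roughly 200 px.
    if config.n_mito * 200 > 0.6 * h * w:
        raise GenerationError(
            f"n_mito={config.n_mito} exceeds the capacity of a {h}x{w} frame"
        )
    label_image = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)  # objects + a separation buffer
    n_low = int(round(config.frac_low_mmp * config.n_mito))
    classes = np.array(["low_mmp"] * n_low + ["high_mmp"] * (config.n_mito - n_low))
    rng.shuffle(classes)

    records = []
    struct = ndimage.generate_binary_structure(2, 2)
    attempts = 0
    obj_id = 0
    while obj_id < config.n_mito:
        attempts += 1
        if attempts > 60 * max(config.n_mito, 1):
            raise GenerationError(
                "could not place all objects without overlap; frame too crowded"
            )
        length = int(rng.integers(15, 45))
        path = _random_walk_skeleton(rng, (h, w), length)
        if path is None:
            continue
        skel = np.zeros((h, w), dtype=bool)
        skel[path[:, 0], path[:, 1]] = True
        width_iters = int(rng.integers(1, 3))  # dilate 1-2x -> 3-5 px wide
        body = ndimage.binary_dilation(skel, structure=struct, iterations=width_iters)
        buffer = ndimage.binary_dilation(body, structure=struct, iterations=2)
        if np.any(occupied & buffer):
            continue
        obj_id += 1
        label_image[body] = obj_id
        occupied |= buffer
        records.append(
            {
                "object_id": obj_id,
                "mmp_class": classes[obj_id - 1],
                "area_px": int(body.sum()),
            }
        )

    channels: dict[str, np.ndarray] = {}
    for ch in config.channel_gains:
        img = np.zeros((h, w), dtype=float)
        for rec in records:
            gain = _gain_for(config, ch, rec["mmp_class"])
            if ch == "MMP" and rec["mmp_class"] == "low_mmp":
                gain = 0.0  # depolarised objects do not retain the dye
            img[label_image == rec["object_id"]] = gain
        if config.noise_sd > 0:
            img = np.clip(img + rng.normal(0, config.noise_sd, size=(h, w)), 0, None)
        channels[ch] = img

    entities = pd.DataFrame(
        records, columns=["object_id", "mmp_class", "area_px"]
    )
    truth = SimTruth(
        kind="image",
        entities=entities,
        params={"label_image": label_image, "config": dataclasses.replace(config)},
    )
    return channels, truth
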