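"""Single-cell flow-cytometry reporter statistics.

Implements the reporter arithmetic used across the mitophagy experiments:

* ``mfn2_degradation`` -- percent MFN2-Halo degradation from Parkin+ vs
  Parkin- populations, each CTRL-normalised, exactly as reported:
  ``100 * (normint+ - normint-) / normint+``.
* ``normalize_channel`` -- CTRL-normalised mean reporter intensity (PINK1-YFP,
  MTS-mCh, TMRE-vs-untreated all share this form).
* ``mitolite_normalize`` -- within-sample BFP+/BFP- ratio of the
  membrane-potential dye, then normalised to the CTRL-guide average.
* ``keima_mitophagy_fraction`` -- mt-Keima gating with a single spillover
  compensation term and a polygonal (triangular) mitophagy gate.
* ``quadrant_analysis`` -- PINK1-YFP x MMP quadrant fractions after the
  guide-negative-population normalisation factor.

Event tables are pandas DataFrames with one row per cell and one column per
channel (CSV on disk); population means are arithmetic means of raw
intensities, with medians exposed as an option where noted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from mitosense.errors import InputError

__all__ = [
    "GateSpec",
    "QuadrantResult",
    "mfn2_degradation",
    "normalize_channel",
    "mitolite_normalize",
    "keima_mitophagy_fraction",
    "quadrant_analysis",
    "KEIMA_NEUTRAL",
    "KEIMA_ACIDIC",
    "KEIMA_SPILL_SOURCE",
]

# mt-Keima channels: neutral mKeima (ex488), acidic mKeima (ex561), and the
# YFP channel whose bleed-through is compensated out of the neutral channel.
KEIMA_NEUTRAL = "ex488_em611"
KEIMA_ACIDIC = "ex561_em611"
KEIMA_SPILL_SOURCE = "ex488_em528"


@dataclass(frozen=True)
class GateSpec:
    """A gate on one or two channels.

    ``kind='threshold'``: ``channels=(name,)``, ``params`` is the cut value
    (events >= cut are inside).  ``kind='polygon'``: ``channels=(x, y)``,
    ``params`` is a list of (x, y) vertices with non-zero enclosed area.
    """

    kind: str
    channels: tuple[str, ...]
    params: object

    def __post_init__(self) -> None:
        if self.kind not in ("threshold", "polygon"):
            raise InputError(f"unknown gate kind {self.kind!r}")
        if self.kind == "polygon":
            verts = np.asarray(self.params, dtype=float)
            if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
                raise InputError("polygon gate needs >= 3 (x, y) vertices")
            if abs(_polygon_area(verts)) <= 0:
                raise InputError("polygon gate is degenerate (zero area)")

    def contains(self, table: pd.DataFrame) -> np.ndarray:
        if self.kind == "threshold":
            (channel,) = self.channels
            return _channel(table, channel) >= float(self.params)
        verts = np.asarray(self.params, dtype=float)
        x = _channel(table, self.channels[0])
        y = _channel(table, self.channels[1])
        path = MplPath(verts)
        return path.contains_points(np.column_stack([x, y]), radius=1e-9)


def _polygon_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class QuadrantResult:
    """Quadrant fractions on the (PINK1, MMP) plane plus the bookkeeping used."""

    q_low_low: float
    q_low_high: float
    q_high_low: float
    q_high_high: float
    pink1_cutoff: float
    mmp_cutoff: float
    normalization_factor: float

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "low_low": self.q_low_low,
            "low_high": self.q_low_high,
            "high_low": self.q_high_low,
            "high_high": self.q_high_high,
        }


def _channel(table: pd.DataFrame, channel: str) -> np.ndarray:
    if channel not in table.columns:
        raise InputError(f"channel {channel!r} missing from event table")
    values = table[channel].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise InputError(f"channel {channel!r} contains non-finite intensities")
    return values


def _population_mean(values: np.ndarray, statistic: str) -> float:
    if values.size == 0:
        raise InputError("population is empty")
    if statistic == "mean":
        return float(np.mean(values))
    if statistic == "median":
        return float(np.median(values))
    raise InputError(f"unknown statistic {statistic!r}")


def mfn2_degradation(
    parkin_pos: pd.DataFrame,
    parkin_neg: pd.DataFrame,
    ctrl_pos_mean: float,
    ctrl_neg_mean: float,
    channel: str = "MFN2",
    statistic: str = "mean",
) -> float:
    """Percent MFN2-Halo degradation of the Parkin+ vs Parkin- population.

    Each population's average raw MFN2 intensity is first normalised by the
    matching CTRL-guide average (``normint``); the statistic is then
    ``100 * (normint+ - normint-) / normint+``, sign convention preserved
    exactly as reported (Parkin-driven loss in the Parkin+ population makes
    the printed value negative; see the methods note).
    """
    if len(parkin_pos) == 0 or len(parkin_neg) == 0:
        raise InputError("both Parkin+ and Parkin- event sets must be non-empty")
    if ctrl_pos_mean <= 0 or ctrl_neg_mean <= 0:
        raise InputError("CTRL means must be > 0")
    normint_pos = _population_mean(_channel(parkin_pos, channel), statistic) / ctrl_pos_mean
    normint_neg = _population_mean(_channel(parkin_neg, channel), statistic) / ctrl_neg_mean
    if normint_pos == 0:
        raise InputError("Parkin+ normalised intensity is zero; percent undefined")
    return 100.0 * (normint_pos - normint_neg) / normint_pos


def normalize_channel(
    sample: pd.DataFrame,
    channel: str,
    ctrl_means,
    statistic: str = "mean",
) -> float:
    """Mean sample intensity divided by the average of the CTRL replicates."""
    ctrl = np.asarray(ctrl_means, dtype=float)
    if ctrl.size == 0:
        raise InputError("ctrl_means must be non-empty")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean <= 0:
        raise InputError("mean of ctrl_means must be > 0")
    return _population_mean(_channel(sample, channel), statistic) / ctrl_mean


def _within_sample_ratio(
    table: pd.DataFrame, channel: str, bfp_channel: str, bfp_cutoff: float, statistic: str
) -> float:
    bfp = _channel(table, bfp_channel)
    pos = bfp >= bfp_cutoff
    if not pos.any() or pos.all():
        raise InputError("sample must contain both BFP+ and BFP- events")
    values = _channel(table, channel)
    return _population_mean(values[pos], statistic) / _population_mean(
        values[~pos], statistic
    )


def mitolite_normalize(
    sample: pd.DataFrame,
    ctrl_samples: list[pd.DataFrame],
    channel: str = "MitoLite",
    bfp_channel: str = "BFP",
    bfp_cutoff: float = 1.0,
    statistic: str = "mean",
) -> float:
    """Within-sample (BFP+/BFP-) MitoLite ratio, normalised to CTRL guides.

    Controls for well-to-well dye-loading variability: (1) the BFP+ (guide
    positive) population mean is divided by the BFP- population mean within
    each sample; (2) the sample's ratio is divided by the average ratio of
    the CTRL-guide samples.
    """
    if not ctrl_samples:
        raise InputError("at least one CTRL sample is required")
    within = _within_sample_ratio(sample, channel, bfp_channel, bfp_cutoff, statistic)
    ctrl_within = [
        _within_sample_ratio(c, channel, bfp_channel, bfp_cutoff, statistic)
        for c in ctrl_samples
    ]
    return within / float(np.mean(ctrl_within))


def keima_mitophagy_fraction(
    sample: pd.DataFrame,
    gate: GateSpec,
    spillover: float = 0.10,
) -> float:
    """Percent of events inside the mitophagy gate on the mt-Keima plane.

    The neutral-mKeima channel is compensated for YFP bleed-through by
    subtracting ``spillover`` x the ex488-em528 channel (floored at zero);
    the gate polygon is evaluated on (corrected neutral, acidic) coordinates.
    """
    if not 0.0 <= spillover < 1.0:
        raise InputError("spillover must be in [0, 1)")
    if gate.kind != "polygon":
        raise InputError("mitophagy gate must be a polygon gate")
    neutral = _channel(sample, KEIMA_NEUTRAL)
    spill = _channel(sample, KEIMA_SPILL_SOURCE)
    acidic = _channel(sample, KEIMA_ACIDIC)
    corrected = np.maximum(neutral - spillover * spill, 0.0)
    plane = pd.DataFrame({"corrected_neutral": corrected, "acidic": acidic})
    gate_on_plane = GateSpec(
        kind="polygon", channels=("corrected_neutral", "acidic"), params=gate.params
    )
    inside = gate_on_plane.contains(plane)
    if len(plane) == 0:
        raise InputError("event table is empty")
    return 100.0 * float(inside.mean())


def quadrant_analysis(
    sample: pd.DataFrame,
    ctrl: pd.DataFrame,
    cutoffs: tuple[float, float],
    pink1_channel: str = "PINK1",
    mmp_channel: str = "MitoLite",
    bfp_channel: str = "BFP",
    bfp_cutoff: float = 1.0,
    statistic: str = "mean",
) -> QuadrantResult:
    """Quadrant fractions of (PINK1-YFP, MMP) after guide-negative normalisation.

    The guide-negative reference population of a table is events below the
    PINK1 cutoff AND below the BFP cutoff (non-transduced cells).  The
    sample's MMP values are divided by the normalisation factor
    ``mean MMP(reference in sample) / mean MMP(reference in CTRL)``; PINK1
    values are untouched.  Events are then partitioned by the fixed cutoffs,
    with boundary events (value == cutoff) assigned to the high side.

    Cutoff units: the PINK1 cutoff is in raw intensity units.  The MMP
    cutoff is dimensionless, expressed as a fold of the guide-negative
    reference level (an event is MMP-high when its raw MMP is at least
    ``mmp_cut`` times the sample's reference mean, i.e. when its normalised
    MMP is at least ``mmp_cut`` times the CTRL reference mean).  This is the
    same fixed-cutoff-for-every-sample rule, stated in units that make the
    fractions invariant to instrument gain.
    """
    pink1_cut, mmp_cut = cutoffs
    if pink1_cut <= 0 or mmp_cut <= 0:
        raise InputError("cutoffs must be > 0")

    def reference_mean(table: pd.DataFrame, name: str) -> float:
        pink1 = _channel(table, pink1_channel)
        bfp = _channel(table, bfp_channel)
        mmp = _channel(table, mmp_channel)
        ref = (pink1 < pink1_cut) & (bfp < bfp_cutoff)
        if not ref.any():
            raise InputError(
                f"empty guide-negative reference population in {name} "
                f"(PINK1 < {pink1_cut}, BFP < {bfp_cutoff})"
            )
        return _population_mean(mmp[ref], statistic)

    ref_sample = reference_mean(sample, "sample")
    ref_ctrl = reference_mean(ctrl, "ctrl")
    factor = ref_sample / ref_ctrl
    pink1 = _channel(sample, pink1_channel)
    mmp = _channel(sample, mmp_channel)
    pink1_high = pink1 >= pink1_cut
    # equivalent to (mmp / factor) >= mmp_cut * ref_ctrl; written this way the
    # comparison is exactly gain-free
    mmp_high = (mmp / ref_sample) >= mmp_cut
    n = len(sample)
    if n == 0:
        raise InputError("sample event table is empty")
    q = {
        (False, False): float(np.sum(~pink1_high & ~mmp_high)) / n,
        (False, True): float(np.sum(~pink1_high & mmp_high)) / n,
        (True, False): float(np.sum(pink1_high & ~mmp_high)) / n,
        (True, True): float(np.sum(pink1_high & mmp_high)) / n,
    }
    return QuadrantResult(
        q_low_low=q[(False, False)],
        q_low_high=q[(False, True)],
        q_high_low=q[(True, False)],
        q_high_high=q[(True, True)],
        pink1_cutoff=float(pink1_cut),
        mmp_cutoff=float(mmp_cut),
        normalization_factor=float(factor),
    )
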