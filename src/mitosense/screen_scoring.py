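"""Gene scoring and hit classification for FACS-bin CRISPRi screens.

The pipeline mirrors the published analysis of six MFN2-Halo reporter
screens (three CRISPRi cell lines x untreated / OXPHOS-inhibited):

1. guides with a zero read count in any replicate of either bin are dropped,
2. a guide-level high-vs-low differential is computed from median-of-ratios
   normalised counts (a transparent stand-in for the sgRNA-level output of a
   ranked screen-analysis pipeline),
3. guide p values are Bonferroni-corrected over the number of tested guides,
4. the gene score is (-log10 adjusted p) x log2 fold change,
5. genes are classified over the six screens into Parkin activators, Parkin
   facilitators, and Parkin-independent MFN2 down-/up-regulators,
6. gene symbols are harmonised and annotated against a MitoCarta-style table.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from mitosense.errors import InputError
from mitosense.synthetic_data import SCREEN_KEYS

__all__ = [
    "filter_zero_count_guides",
    "guide_differential",
    "bonferroni_correct",
    "gene_score",
    "aggregate_guides_to_gene",
    "classify_hits",
    "harmonize_and_annotate",
    "score_screen",
    "GENE_RENAMES",
    "HIT_CATEGORIES",
]

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5

#: Symbol harmonisation applied before MitoCarta annotation.
GENE_RENAMES = {"TIMM23B": "TIMM23", "HSPE1-MOB4": "HSPE1", "PARK2": "PRKN"}

HIT_CATEGORIES = (
    "parkin_activator",
    "parkin_facilitator",
    "mfn2_downregulator",
    "mfn2_upregulator",
    "none",
)


def _count_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c not in ("guide_id", "gene")]
    if not cols:
        raise InputError("count table has no replicate count columns")
    return cols


def filter_zero_count_guides(
    high: pd.DataFrame, low: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop guides with a zero count in any replicate of either bin.

    Returns the filtered (high, low) pair; guide order is preserved and the
    two tables keep an identical guide universe.
    """
    for name, table in (("high", high), ("low", low)):
        if not {"guide_id", "gene"}.issubset(table.columns):
            raise InputError(f"{name} table must have guide_id and gene columns")
    if not high["guide_id"].equals(low["guide_id"]):
        raise InputError("high and low tables must share the same guide universe")
    keep = np.ones(len(high), dtype=bool)
    for table in (high, low):
        counts = table[_count_columns(table)].to_numpy()
        keep &= (counts > 0).all(axis=1)
    return high.loc[keep].reset_index(drop=True), low.loc[keep].reset_index(drop=True)


def _median_of_ratios_factors(counts: np.ndarray) -> np.ndarray:
    """Per-column size factors from the median of ratios to a reference guide.

    The reference is the per-guide geometric mean across all columns; guides
    with a zero anywhere are excluded from the median (they carry no ratio
    information), matching standard count-normalisation practice.
    """
    positive = (counts > 0).all(axis=1)
    if not np.any(positive):
        raise InputError("no guide has positive counts in every column")
    logc = np.log(counts[positive].astype(float))
    ref = logc.mean(axis=1, keepdims=True)
    return np.exp(np.median(logc - ref, axis=0))


def guide_differential(high: pd.DataFrame, low: pd.DataFrame) -> pd.DataFrame:
    """Guide-level log2 fold change (high vs low bin) with a two-sided p value.

    Counts are size-normalised per replicate by median-of-ratios across
    guides (jointly over the high and low columns).  The fold change is
    ``log2((mean normalised high + 0.5) / (mean normalised low + 0.5))``.

    With >= 2 replicates the p value is a two-sided test of the per-replicate
    normalised log-ratios against zero, with the replicate variance pooled
    across all guides (a per-guide variance at 2 replicates has a single
    degree of freedom and no usable power).  With a single replicate the p
    value comes from the empirical permutation null over guide labels.
    """
    if not high["guide_id"].equals(low["guide_id"]):
        raise InputError("high and low tables must share the same guide universe")
    high_cols = _count_columns(high)
    low_cols = _count_columns(low)
    counts = np.concatenate(
        [high[high_cols].to_numpy(float), low[low_cols].to_numpy(float)], axis=1
    )
    factors = _median_of_ratios_factors(counts)
    norm = counts / factors
    n_high = len(high_cols)
    norm_high = norm[:, :n_high]
    norm_low = norm[:, n_high:]

    log2fc = np.log2(norm_high.mean(axis=1) + PSEUDOCOUNT) - np.log2(
        norm_low.mean(axis=1) + PSEUDOCOUNT
    )

    if n_high == len(low_cols) and n_high >= 2:
        # replicate-level log-ratios, pooled-variance test against zero
        ratios = np.log2(norm_high + PSEUDOCOUNT) - np.log2(norm_low + PSEUDOCOUNT)
        mean_ratio = ratios.mean(axis=1)
        resid = ratios - mean_ratio[:, None]
        df = ratios.shape[0] * (ratios.shape[1] - 1)
        pooled_var = float((resid**2).sum() / df)
        if pooled_var <= 0:
            p_raw = np.ones(len(mean_ratio))
        else:
            t = mean_ratio / np.sqrt(pooled_var / ratios.shape[1])
            p_raw = 2 * stats.t.sf(np.abs(t), df=df)
    else:
        # single replicate (or unbalanced design): permutation of guide labels
        # == empirical two-sided tail of each guide's log-ratio among all guides
        centred = log2fc - np.median(log2fc)
        abs_c = np.abs(centred)
        order = np.sort(abs_c)
        n = len(order)
        # p = fraction of guides at least as extreme (including self)
        ranks = np.searchsorted(order, abs_c, side="left")
        p_raw = (n - ranks) / n

    return pd.DataFrame(
        {
            "guide_id": high["guide_id"].to_numpy(),
            "gene": high["gene"].to_numpy(),
            "log2fc": log2fc,
            "p_raw": np.clip(p_raw, 0.0, 1.0),
        }
    )


def bonferroni_correct(
    p_raw, m: int | None = None, mode: str = "standard"
) -> np.ndarray:
    """Bonferroni correction of raw p values over ``m`` tests.

    ``standard`` returns ``min(1, p * m)``.  ``as_printed`` divides the raw p
    values by ``m`` instead -- reproducing a published description verbatim
    even though division shrinks p values; it is exposed for traceability and
    is not a multiplicity correction.  Default is ``standard``.
    """
    p = np.asarray(p_raw, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise InputError("m must be >= 1")
    if np.any((p < 0) | (p > 1)):
        raise InputError("p values must be in [0, 1]")
    if mode == "standard":
        return np.minimum(1.0, p * m)
    if mode == "as_printed":
        return p / m
    raise InputError(f"unknown bonferroni mode {mode!r}")


def gene_score(p_adj, log2fc):
    """Signed evidence score: (-log10 adjusted p) x log2 fold change."""
    p = np.asarray(p_adj, dtype=float)
    lfc = np.asarray(log2fc, dtype=float)
    if np.any(p == 0):
        warnings.warn(
            "p_adj of 0 clamped to the smallest positive float before log10",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.where(p == 0, np.finfo(float).tiny, p)
    if np.any((p < 0) | (p > 1)):
        raise InputError("p_adj must be in [0, 1]")
    out = -np.log10(p) * lfc
    if np.isscalar(p_adj) and np.isscalar(log2fc):
        return float(out)
    return out


def score_screen(
    high: pd.DataFrame,
    low: pd.DataFrame,
    bonferroni_mode: str = "standard",
    aggregation: str = "best_guide_pair",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full guide->gene scoring for one screen.

    Returns ``(guide_stats, gene_scores)``: the filtered guide-level table
    with ``log2fc, p_raw, p_adj, score`` and its gene-level aggregation.
    """
    high_f, low_f = filter_zero_count_guides(high, low)
    guide_stats = guide_differential(high_f, low_f)
    guide_stats["p_adj"] = bonferroni_correct(
        guide_stats["p_raw"], m=len(guide_stats), mode=bonferroni_mode
    )
    guide_stats["score"] = gene_score(guide_stats["p_adj"], guide_stats["log2fc"])
    return guide_stats, aggregate_guides_to_gene(guide_stats, method=aggregation)


def _best_guide_pair(group: pd.DataFrame) -> pd.Series:
    g = group.sort_values(
        ["score", "guide_id"],
        key=lambda s: -s.abs() if s.name == "score" else s,
    )
    top = g.iloc[0]
    if len(g) == 1:
        chosen = g.iloc[[0]]
    else:
        top_sign = np.sign(top["score"])
        same = g.iloc[1:][np.sign(g.iloc[1:]["score"]) == top_sign]
        if top_sign == 0 or same.empty:
            chosen = g.iloc[[0]]
        else:
            chosen = pd.concat([g.iloc[[0]], same.iloc[[0]]])
    return pd.Series(
        {
            "log2fc": chosen["log2fc"].mean(),
            "p_adj": chosen["p_adj"].max(),
            "n_guides": len(group),
        }
    )


def aggregate_guides_to_gene(
    stats: pd.DataFrame, method: str = "best_guide_pair"
) -> pd.DataFrame:
    """Aggregate guide-level stats to one row per gene.

    ``best_guide_pair`` (default): the gene log2fc is the mean of the two
    guides with the largest absolute score that agree in sign, and the gene
    p_adj is the max of that pair (ties broken by guide_id).  ``mean``: plain
    means of log2fc and p_adj.  A gene's score is recomputed from the
    aggregated values and ``significant`` flags gene p_adj < 0.05.
    """
    required = {"guide_id", "gene", "log2fc", "p_adj", "score"}
    if not required.issubset(stats.columns):
        raise InputError(f"guide stats must have columns {sorted(required)}")
    if method == "best_guide_pair":
        agg = stats.groupby("gene", sort=True).apply(
            _best_guide_pair, include_groups=False
        )
    elif method == "mean":
        agg = stats.groupby("gene", sort=True).agg(
            log2fc=("log2fc", "mean"), p_adj=("p_adj", "mean"), n_guides=("gene", "size")
        )
    else:
        raise InputError(f"unknown aggregation method {method!r}")
    agg = agg.reset_index()
    agg["p_adj"] = agg["p_adj"].clip(0.0, 1.0)
    agg["score"] = gene_score(agg["p_adj"], agg["log2fc"])
    agg["significant"] = agg["p_adj"] < 0.05
    agg["n_guides"] = agg["n_guides"].astype(int)
    return agg


def classify_hits(
    scores: dict[str, pd.DataFrame],
    activator_lfc: float = -1.0,
    activator_diff: float = -1.25,
    facilitator_lfc: float = 1.0,
    facilitator_diff: float = 1.0,
    regulator_lfc: float = 1.0,
) -> pd.DataFrame:
    """Apply the six-screen rule set to call hit categories per gene.

    ``scores`` maps each of the six screen keys to that screen's gene-level
    table.  Categories (mutually exclusive, applied in order):

    * ``parkin_activator``: significant with log2fc < -1 in untreated
      HeLa+Parkin, and at least 1.25 below the untreated HeLa-without-Parkin
      log2fc.
    * ``parkin_facilitator``: significant with log2fc > 1 in AO-treated
      HeLa+Parkin, and more than 1 above both the untreated HeLa+Parkin and
      the AO-treated HeLa-without-Parkin log2fc.
    * ``mfn2_downregulator`` / ``mfn2_upregulator``: significant with
      |log2fc| > 1 of the matching sign in both untreated HEK293 and
      untreated HeLa-without-Parkin, excluding activators / facilitators
      respectively.
    """
    missing = [k for k in SCREEN_KEYS if k not in scores]
    if missing:
        raise InputError(f"missing screen keys: {missing}")
    genes = None
    lfc = {}
    sig = {}
    for key in SCREEN_KEYS:
        tab = scores[key].set_index("gene")
        if genes is None:
            genes = tab.index
        else:
            genes = genes.intersection(tab.index)
    for key in SCREEN_KEYS:
        tab = scores[key].set_index("gene").loc[genes]
        lfc[key] = tab["log2fc"]
        sig[key] = tab["significant"].astype(bool)

    activator = (
        sig["HeLa_Parkin_NT"]
        & (lfc["HeLa_Parkin_NT"] < activator_lfc)
        & ((lfc["HeLa_Parkin_NT"] - lfc["HeLa_noParkin_NT"]) < activator_diff)
    )
    facilitator = (
        sig["HeLa_Parkin_AO"]
        & (lfc["HeLa_Parkin_AO"] > facilitator_lfc)
        & ((lfc["HeLa_Parkin_AO"] - lfc["HeLa_Parkin_NT"]) > facilitator_diff)
        & ((lfc["HeLa_Parkin_AO"] - lfc["HeLa_noParkin_AO"]) > facilitator_diff)
    )
    down = (
        sig["HEK293_NT"]
        & sig["HeLa_noParkin_NT"]
        & (lfc["HEK293_NT"] < -regulator_lfc)
        & (lfc["HeLa_noParkin_NT"] < -regulator_lfc)
        & ~activator
    )
    up = (
        sig["HEK293_NT"]
        & sig["HeLa_noParkin_NT"]
        & (lfc["HEK293_NT"] > regulator_lfc)
        & (lfc["HeLa_noParkin_NT"] > regulator_lfc)
        & ~facilitator
    )
    category = np.select(
        [activator, facilitator, down, up],
        ["parkin_activator", "parkin_facilitator", "mfn2_downregulator", "mfn2_upregulator"],
        default="none",
    )
    return pd.DataFrame({"gene": genes.to_numpy(), "category": category})


def harmonize_and_annotate(
    calls: pd.DataFrame, mitocarta: pd.DataFrame
) -> pd.DataFrame:
    """Harmonise gene symbols and flag mitochondrial genes.

    The three published renames (TIMM23B -> TIMM23, HSPE1-MOB4 -> HSPE1,
    PARK2 -> PRKN) are applied before the lookup; ``mitocarta`` must carry
    ``gene`` and boolean ``is_mitochondrial`` columns.  Genes absent from the
    annotation are flagged non-mitochondrial and counted in the log.
    """
    if not {"gene", "is_mitochondrial"}.issubset(mitocarta.columns):
        raise InputError("mitocarta table must have gene and is_mitochondrial columns")
    out = calls.copy()
    out["gene"] = out["gene"].replace(GENE_RENAMES)
    lookup = mitocarta.set_index("gene")["is_mitochondrial"].astype(bool)
    mapped = out["gene"].map(lookup)
    out["is_mitochondrial"] = mapped.where(mapped.notna(), False).astype(bool)
    n_unknown = int((~out["gene"].isin(lookup.index)).sum())
    if n_unknown:
        logger.info("%d genes absent from annotation; flagged non-mitochondrial", n_unknown)
    return out
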