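"""Downstream proteomics statistics and annotation.

Post-quantification analysis of label-free protein abundance matrices:
two-sided t tests with Benjamini-Hochberg FDR and the published significance
flag (FDR < 0.05 and |log2FC| above an experiment-specific cut), sample-wise
normalisation to the median of non-mitochondrial proteins, and the
strong-presequence annotation rule (matrix-targeted proteins with an MTS
score >= 2 starting within the first 20 residues).

Spectral search, DIA quantification and imputation are upstream of this
module; input is a protein x sample abundance table on the linear scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mitosense.errors import InputError

__all__ = [
    "differential_abundance",
    "normalize_to_nonmito_median",
    "annotate_strong_presequence",
]

logger = logging.getLogger(__name__)


def differential_abundance(
    a: pd.DataFrame,
    b: pd.DataFrame,
    lfc_cut: float = 1.0,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein differential abundance between two condition matrices.

    ``a`` and ``b`` are protein x replicate matrices of linear abundances
    (NaN = missing) sharing a protein index.  Per tested protein:
    ``log2fc`` of the condition means, a two-sided t test on log2
    abundances (classical Student by default; Welch with
    ``equal_var=False``), BH-adjusted FDR over all tested proteins, and
    ``significant = (fdr < 0.05) & (|log2fc| > lfc_cut)``.

    Proteins with fewer than 2 observed replicates, or missing in more than
    half of either condition's replicates, are excluded from testing and
    logged.
    """
    proteins = a.index.intersection(b.index)
    if len(proteins) == 0:
        raise InputError("condition matrices share no proteins")
    a = a.loc[proteins].astype(float)
    b = b.loc[proteins].astype(float)

    n_a = a.notna().sum(axis=1)
    n_b = b.notna().sum(axis=1)
    testable = (
        (n_a >= 2)
        & (n_b >= 2)
        & (n_a >= a.shape[1] / 2)
        & (n_b >= b.shape[1] / 2)
    )
    n_excluded = int((~testable).sum())
    if n_excluded:
        logger.info("%d proteins excluded from testing (insufficient replicates)", n_excluded)
    a = a.loc[testable]
    b = b.loc[testable]
    if len(a) == 0:
        raise InputError("no protein has enough replicates in both conditions")
    if (a.le(0) | b.le(0)).any().any():
        raise InputError("abundances must be positive on the linear scale")

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2(mean_a / mean_b)
    t_res = stats.ttest_ind(
        np.log2(a), np.log2(b), axis=1, equal_var=equal_var, nan_policy="omit"
    )
    p_raw = np.asarray(t_res.pvalue, dtype=float)
    # zero within-group variance with equal means gives an undefined t; no
    # evidence against the null, so p = 1
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    fdr = multipletests(p_raw, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_raw": p_raw,
            "fdr": fdr,
        },
        index=a.index,
    )
    out["significant"] = (out["fdr"] < 0.05) & (out["log2fc"].abs() > lfc_cut)
    return out


def normalize_to_nonmito_median(
    table: pd.DataFrame,
    abundance_columns: list[str],
    mito_column: str = "is_mitochondrial",
) -> pd.DataFrame:
    """Divide every abundance column by its median over non-mitochondrial proteins.

    After normalisation the non-mitochondrial median of every sample equals
    1, removing sample-loading differences while leaving the mitochondrial
    fraction free to shift (the readout of interest when mitochondrial mass
    changes).
    """
    if mito_column not in table.columns:
        raise InputError(f"table lacks the {mito_column!r} column")
    nonmito = ~table[mito_column].astype(bool)
    out = table.copy()
    for col in abundance_columns:
        if col not in table.columns:
            raise InputError(f"abundance column {col!r} missing")
        ref = table.loc[nonmito, col].dropna()
        if len(ref) == 0:
            raise InputError(
                f"no non-mitochondrial protein with abundance in sample {col!r}"
            )
        med = float(ref.median())
        if med <= 0:
            raise InputError(f"non-mitochondrial median of {col!r} is not positive")
        out[col] = table[col] / med
    return out


def annotate_strong_presequence(
    table: pd.DataFrame,
    mito_column: str = "is_mitochondrial",
    omm_column: str = "is_omm",
    score_column: str = "mts1_score",
    start_column: str = "mts1_start",
) -> pd.DataFrame:
    """Flag proteins with a predicted strong N-terminal presequence.

    A protein is flagged when it (1) localises to mitochondria but not
    primarily the outer membrane, (2) has an MTS score >= 2, and (3) its MTS
    start position is < 20 residues from the N terminus.  Rows with any of
    the four fields missing are flagged False and counted in the log.  Adds
    a boolean ``strong_presequence`` column; pure function of those fields.
    """
    for col in (mito_column, omm_column, score_column, start_column):
        if col not in table.columns:
            raise InputError(f"annotation column {col!r} missing")
    out = table.copy()
    fields = out[[mito_column, omm_column, score_column, start_column]]
    complete = fields.notna().all(axis=1)
    n_missing = int((~complete).sum())
    if n_missing:
        logger.info(
            "%d proteins with missing annotation fields flagged strong_presequence=False",
            n_missing,
        )
    flag = (
        out[mito_column].fillna(False).astype(bool)
        & ~out[omm_column].fillna(True).astype(bool)
        & (out[score_column] >= 2.0)
        & (out[start_column] < 20)
    )
    out["strong_presequence"] = (flag & complete).astype(bool)
    return out
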