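"""Differential methylation from U/M probe intensities.

A probe's methylation level is summarized by the beta-value

    beta = M / (U + M + 100),

where U and M are the unmethylated and methylated signal intensities; the
+100 regularizer keeps beta stable at low total intensity and strictly below
1. Probes are averaged to genes, and each gene is tested cancer vs normal
with a two-sample t-test (pooled-variance Student's t by default, Welch
optional) under Benjamini–Hochberg FDR control. Direction +1 means
hypermethylated in cancer.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .datatypes import CALL_COLUMNS, OmicsMatrix, validate_calls

BETA_OFFSET = 100.0


def compute_beta(U, M):
    """Beta-value M/(U+M+100) for scalar or array intensities (>= 0)."""
    U = np.asarray(U, dtype=float)
    M = np.asarray(M, dtype=float)
    if (U < 0).any() or (M < 0).any():
        raise ValueError("intensities must be non-negative")
    beta = M / (U + M + BETA_OFFSET)
    return float(beta) if beta.ndim == 0 else beta


def beta_matrix_from_um(um: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-form (probe, sample, U, M) rows into a probe×sample beta matrix."""
    um = um.copy()
    um["beta"] = compute_beta(um["U"].values, um["M"].values)
    mat = um.pivot(index="probe", columns="sample", values="beta")
    if mat.isna().any().any():
        raise ValueError("U/M table is not complete over probe × sample")
    return mat


def aggregate_probes_to_genes(beta: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Mean beta per gene over its mapped probes; unmapped probes dropped."""
    mapped = beta.loc[beta.index.intersection(probe_map.index)]
    genes = probe_map.reindex(mapped.index)
    out = mapped.groupby(genes.values).mean()
    out.index.name = "gene"
    return out


def call_dm_genes(
    beta_matrix: OmicsMatrix, fdr_target: float = 0.05, welch: bool = False
) -> pd.DataFrame:
    """Calls frame of differentially methylated genes at the given FDR.

    Genes with zero within-group variance in both groups have an undefined
    t statistic; they are excluded with a warning rather than called.
    """
    if not 0.0 < fdr_target <= 1.0:
        raise ValueError("fdr_target must be in (0, 1]")
    cancer = beta_matrix.group("cancer").to_numpy(dtype=float)
    normal = beta_matrix.group("normal").to_numpy(dtype=float)
    if cancer.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")

    effect = cancer.mean(axis=1) - normal.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = ttest_ind(cancer, normal, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} genes with zero variance in both groups excluded",
            stacklevel=2,
        )
    genes = np.asarray(beta_matrix.features)[~degenerate]
    p_ok, eff_ok = p[~degenerate], effect[~degenerate]
    if len(p_ok) == 0:
        return validate_calls(pd.DataFrame(columns=CALL_COLUMNS))
    _, q, _, _ = multipletests(p_ok, method="fdr_bh")
    hit = (q <= fdr_target) & (eff_ok != 0)
    calls = pd.DataFrame(
        {
            "gene": genes[hit],
            "direction": np.sign(eff_ok[hit]).astype(int),
            "statistic": eff_ok[hit],
            "q_value": q[hit],
            "dataset": beta_matrix.dataset,
            "modality": "methylation",
        }
    )[CALL_COLUMNS]
    return validate_calls(calls.reset_index(drop=True))
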