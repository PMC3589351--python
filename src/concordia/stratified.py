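"""Mutation-state-stratified expression testing.

The population-level direction of a gene's change mostly reflects its
wild-type copies, because mutation rates are low. To see what the mutant
itself does, cancer samples are stratified by the gene's mutation class
(activating, inactivating, undetermined, wild-type) and each stratum is
tested separately against the normal controls with a two-tailed two-sample
t-test. Strata with fewer than two samples are reported but left untested;
cancer samples without an annotation for the gene are excluded, never
defaulted to wild-type. No correction is applied across strata — the few
raw p-values are reported as such.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .datatypes import (
    CANCER,
    MUTATION_CLASSES,
    NORMAL,
    OmicsMatrix,
    validate_mutation_annotation,
)


def stratify_and_test(
    gene: str,
    matrix: OmicsMatrix,
    annotation: pd.DataFrame,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-stratum comparison of one gene's expression against normals.

    Returns a frame with one row per mutation class present (plus the
    normal reference row): columns mclass, n, mean, direction, p, tested.
    ``direction`` is the sign of stratum mean − normal mean (0 when equal).
    """
    validate_mutation_annotation(annotation)
    if gene not in matrix.features:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    expr = matrix.values.loc[gene]
    normals = expr[matrix.labels.index[matrix.labels == NORMAL]].to_numpy(dtype=float)
    if len(normals) < 2:
        raise ValueError("need >= 2 normal samples")
    cancer_samples = set(matrix.labels.index[matrix.labels == CANCER])

    ann = annotation[annotation["gene"] == gene]
    ann = ann[ann["sample"].isin(cancer_samples)]
    strata = {c: ann.loc[ann["mclass"] == c, "sample"].tolist() for c in MUTATION_CLASSES}

    rows = [
        {
            "mclass": "normal_reference",
            "n": len(normals),
            "mean": float(normals.mean()),
            "direction": 0,
            "p": np.nan,
            "tested": False,
        }
    ]
    for mclass in MUTATION_CLASSES:
        samples = strata[mclass]
        if not samples:
            continue
        x = expr[samples].to_numpy(dtype=float)
        mean = float(x.mean())
        direction = int(np.sign(mean - normals.mean()))
        if len(x) >= 2:
            p = float(ttest_ind(x, normals, equal_var=not welch).pvalue)
            tested = np.isfinite(p)
            p = p if tested else np.nan
        else:
            p, tested = np.nan, False
        rows.append(
            {
                "mclass": mclass,
                "n": len(x),
                "mean": mean,
                "direction": direction,
                "p": p,
                "tested": tested,
            }
        )
    return pd.DataFrame(rows, columns=["mclass", "n", "mean", "direction", "p", "tested"])


def reversal_report(stratum_results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Flag opposite-direction significance among a gene's strata.

    A reversal means two mutation-class strata are each significant at
    ``alpha`` but deregulated in opposite directions — the signature of a
    mutant behaving unlike its wild-type counterpart.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    sig = stratum_results[
        stratum_results["tested"] & (stratum_results["p"] <= alpha)
    ]
    up = sig.loc[sig["direction"] > 0, "mclass"].tolist()
    down = sig.loc[sig["direction"] < 0, "mclass"].tolist()
    return {
        "reversal": bool(up and down),
        "alpha": alpha,
        "significant_up": up,
        "significant_down": down,
    }
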