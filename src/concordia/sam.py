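"""SAM-style differential expression with permutation-estimated FDR.

Per gene the relative-difference statistic is

    d = (mean_cancer - mean_normal) / (s + s0)

with s the gene-specific pooled standard error,

    s = sqrt( (1/n1 + 1/n2) * (SS1 + SS2) / (n1 + n2 - 2) ),

and s0 a small "fudge" constant that damps the otherwise explosive d of
low-variance genes. s0 is either fixed or chosen by a percentile search that
minimizes the coefficient of variation of the spread of d across bins of s
(so that d's scale is independent of the gene's expression variability).

Significance is assessed by permuting the cancer/normal labels: at a
threshold on |d| (up- and down-regulation thresholded jointly), the
estimated FDR is the median count of permuted |d*| exceeding the threshold
divided by the observed count, with the true-null proportion conservatively
fixed at 1. Genes are called at the loosest threshold whose estimated FDR
stays at or below the target; the per-gene q-value is made monotone in the
|d| ranking so that a stricter target can only shrink the call list.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import CALL_COLUMNS, OmicsMatrix, validate_calls

DEGENERATE = "degenerate"  # zero spread and s0 == 0: d undefined


@dataclass
class SamConfig:
    """Tuning of the SAM-style caller.

    ``s0_strategy`` is ``"percentile-search"`` (default) or ``"fixed"``
    (then ``s0_value`` must be given). ``n_permutations`` label permutations
    build the null; all distinct assignments are enumerated instead when
    there are fewer of them.
    """

    s0_strategy: str = "percentile-search"
    s0_value: float | None = None
    n_permutations: int = 200
    fdr_target: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0_strategy not in ("fixed", "percentile-search"):
            raise ValueError(f"unknown s0_strategy {self.s0_strategy!r}")
        if self.s0_strategy == "fixed":
            if self.s0_value is None or self.s0_value < 0:
                raise ValueError("fixed strategy needs s0_value >= 0")
        if self.n_permutations < 10:
            raise ValueError("n_permutations must be >= 10")
        if not 0.0 < self.fdr_target <= 1.0:
            raise ValueError("fdr_target must be in (0, 1]")


def pooled_se(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Gene-specific pooled standard error of the mean difference.

    ``x1``, ``x2``: gene × sample arrays with at least 2 samples each.
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))


def sam_statistic(x1: np.ndarray, x2: np.ndarray, s0: float) -> np.ndarray:
    """Relative difference d per gene; NaN where s + s0 == 0 (degenerate)."""
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    denom = pooled_se(x1, x2) + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / denom
    d[denom == 0.0] = np.nan
    return d


def choose_s0(
    diff: np.ndarray,
    s: np.ndarray,
    percentiles: np.ndarray | None = None,
    n_bins: int = 10,
) -> float:
    """Percentile search for the fudge factor s0.

    Candidates are percentiles of the gene-wise s distribution; the chosen
    s0 minimizes the coefficient of variation, across s-quantile bins, of
    the median absolute spread of d. Falls back to median(s) when the
    search surface is flat (e.g. all genes share one variance).
    """
    if percentiles is None:
        percentiles = np.arange(0, 101, 5)
    ok = np.isfinite(s)
    s_ok, diff_ok = s[ok], diff[ok]
    if s_ok.size == 0:
        raise ValueError("no finite standard errors")
    candidates = np.percentile(s_ok, percentiles)
    # s-quantile bin of each gene, shared across candidates
    edges = np.unique(np.percentile(s_ok, np.linspace(0, 100, n_bins + 1)))
    if len(edges) < 3:  # effectively one variance class
        return float(np.median(s_ok))
    bins = np.clip(np.searchsorted(edges, s_ok, side="right") - 1, 0, len(edges) - 2)
    cvs = np.empty(len(candidates))
    for i, cand in enumerate(candidates):
        d = diff_ok / (s_ok + cand)
        spreads = [
            np.median(np.abs(d[bins == b] - np.median(d[bins == b])))
            for b in range(len(edges) - 1)
            if np.any(bins == b)
        ]
        spreads = np.asarray(spreads)
        mean_spread = spreads.mean()
        cvs[i] = spreads.std() / mean_spread if mean_spread > 0 else np.inf
    finite = np.isfinite(cvs)
    if not finite.any() or np.ptp(cvs[finite]) < 1e-12:
        return float(np.median(s_ok))
    return float(candidates[np.argmin(np.where(finite, cvs, np.inf))])


def _group_assignments(n_total: int, n1: int, cfg: SamConfig) -> np.ndarray:
    """Boolean matrix (perm × sample), True = sample plays "cancer".

    Enumerates all C(n_total, n1) assignments when that is at most the
    requested count (minus the observed one), else draws balanced random
    relabelings, seed-controlled.
    """
    total = math.comb(n_total, n1)
    if total - 1 <= cfg.n_permutations:
        warnings.warn(
            f"only {total - 1} distinct relabelings available; using all",
            stacklevel=3,
        )
        rows = []
        for idx in combinations(range(n_total), n1):
            row = np.zeros(n_total, dtype=bool)
            row[list(idx)] = True
            rows.append(row)
        mat = np.array(rows)
        # drop the observed assignment (samples ordered cancer-first below)
        observed = np.zeros(n_total, dtype=bool)
        observed[:n1] = True
        keep = ~(mat == observed).all(axis=1)
        return mat[keep]
    rng = np.random.default_rng(cfg.seed)
    rows = np.zeros((cfg.n_permutations, n_total), dtype=bool)
    for i in range(cfg.n_permutations):
        rows[i, rng.choice(n_total, size=n1, replace=False)] = True
    return rows


def sam_table(matrix: OmicsMatrix, cfg: SamConfig) -> pd.DataFrame:
    """Per-gene SAM statistics and monotone q-values.

    Columns: gene, d, s, q, degenerate. Degenerate genes (s + s0 == 0) get
    q = NaN and are never called.
    """
    x1 = matrix.group("cancer").to_numpy(dtype=float)
    x2 = matrix.group("normal").to_numpy(dtype=float)
    data = np.hstack([x1, x2])
    n1 = x1.shape[1]

    diff = x1.mean(axis=1) - x2.mean(axis=1)
    s = pooled_se(x1, x2)
    if cfg.s0_strategy == "fixed":
        s0 = float(cfg.s0_value)
    else:
        s0 = choose_s0(diff, s)
    denom = s + s0
    degenerate = denom == 0.0
    d = np.full(len(diff), np.nan)
    d[~degenerate] = diff[~degenerate] / denom[~degenerate]

    perms = _group_assignments(data.shape[1], n1, cfg)
    abs_null = np.empty((len(perms), int((~degenerate).sum())))
    for i, mask in enumerate(perms):
        d_star = sam_statistic(data[:, mask], data[:, ~mask], s0)
        abs_null[i] = np.abs(d_star[~degenerate])
    abs_null.sort(axis=1)

    abs_d = np.abs(d[~degenerate])
    order = np.argsort(-abs_d, kind="stable")  # most extreme first
    thresholds = abs_d[order]
    n_ok = len(thresholds)
    # null counts >= each threshold, per permutation, then median over perms
    counts = n_ok - np.stack(
        [np.searchsorted(row, thresholds, side="left") for row in abs_null]
    )
    null_med = np.median(counts, axis=0)
    observed = np.arange(1, n_ok + 1)
    fdr_hat = np.minimum(null_med / observed, 1.0)
    # monotone q: q_(i) = min_{j >= i} fdr_(j); stricter targets only shrink calls
    q_sorted = np.minimum.accumulate(fdr_hat[::-1])[::-1]
    q = np.empty(n_ok)
    q[order] = q_sorted

    out = pd.DataFrame(
        {
            "gene": matrix.features,
            "d": d,
            "s": s,
            "q": np.nan,
            "degenerate": degenerate,
        }
    )
    out.loc[~degenerate, "q"] = q
    out.attrs["s0"] = s0
    return out


def call_de_genes(matrix: OmicsMatrix, cfg: SamConfig) -> pd.DataFrame:
    """Calls frame of genes significant at cfg.fdr_target.

    Direction is the sign of the mean cancer − normal difference; degenerate
    genes are excluded.
    """
    table = sam_table(matrix, cfg)
    hit = (~table["degenerate"]) & (table["q"] <= cfg.fdr_target) & (table["d"] != 0)
    sub = table[hit]
    calls = pd.DataFrame(
        {
            "gene": sub["gene"].values,
            "direction": np.sign(sub["d"].values).astype(int),
            "statistic": sub["d"].values,
            "q_value": sub["q"].values,
            "dataset": matrix.dataset,
            "modality": matrix.modality,
        }
    )[CALL_COLUMNS]
    return validate_calls(calls.reset_index(drop=True))
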