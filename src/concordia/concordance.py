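"""Cross-dataset directional agreement and its binomial significance.

Two independent cancer-vs-normal cohorts each yield a list of differential
genes with a direction (up/down, hyper/hypo, amp/del). If the direction of a
truly altered gene is a fixed property of the cancer type, genes detected in
both cohorts should agree far more often than a fair coin predicts. With N
genes compared and m agreeing, the significance is the upper binomial tail

    p = sum_{k=m}^{N} C(N, k) p_r^k (1 - p_r)^(N - k),   p_r = 0.5,

i.e. the chance of at least m agreements when each gene's direction pair
matches at random. For the gene counts real cohorts produce (thousands), the
tail lies far below the double-precision floor, so the tail is evaluated in
exact rational arithmetic at p_r = 0.5 (and in log space otherwise), and
every report carries an exact log10 alongside the (possibly underflowed)
float.

Agreement-rate variants:

``shared``
    genes called in both cohorts; agreement = same direction.
``union``
    genes called in at least one cohort; a gene called in only one is scored
    against the sign of its (possibly non-significant) effect in the other.
``marginal``
    calls from one cohort restricted to genes at least marginally
    significant (two-sided p < p_cut) in the other; scored by sign match.
``third_dataset``
    calls unique to one cohort validated against calls in an independent
    third cohort.

:func:`merge_consistent` builds the downstream gene list: the union of both
cohorts' calls minus genes called in both with opposite directions.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import ttest_ind

from .datatypes import CALL_COLUMNS, ConcordanceReport, OmicsMatrix, validate_calls

_LOG10_2 = math.log10(2.0)


def _log10_int(n: int) -> float:
    """log10 of an arbitrarily large positive integer, to float precision."""
    if n <= 0:
        raise ValueError("need a positive integer")
    shift = max(n.bit_length() - 256, 0)
    return math.log10(n >> shift) + shift * _LOG10_2


def _tail_fraction_half(N: int, m: int) -> Fraction:
    """Exact upper tail at p_r = 1/2: (sum_{k>=m} C(N,k)) / 2^N."""
    total = sum(math.comb(N, k) for k in range(m, N + 1))
    return Fraction(total, 1 << N)


def _log_tail_general(N: int, m: int, p_r: float) -> float:
    """Natural-log upper tail via gammaln + logsumexp (underflow-safe)."""
    k = np.arange(m, N + 1)
    log_terms = (
        gammaln(N + 1)
        - gammaln(k + 1)
        - gammaln(N - k + 1)
        + k * math.log(p_r)
        + (N - k) * math.log1p(-p_r)
    )
    return float(logsumexp(log_terms))


def _check_counts(N: int, m: int, p_r: float) -> None:
    if N < 0:
        raise ValueError("N must be >= 0")
    if not 0 <= m <= N:
        raise ValueError(f"need 0 <= m <= N, got m={m}, N={N}")
    if not 0.0 < p_r < 1.0:
        raise ValueError("p_r must be in (0, 1)")


def binomial_consistency_pvalue(N: int, m: int, p_r: float = 0.5) -> float:
    """Upper-tail probability of at least m direction agreements out of N.

    Exact for ``p_r = 0.5`` (rational arithmetic), log-space otherwise. The
    returned float underflows to 0.0 when the tail is below ~1e-308; use
    :func:`binomial_consistency_log10` for those regimes.
    """
    _check_counts(N, m, p_r)
    if m == 0:
        return 1.0
    if p_r == 0.5:
        return float(_tail_fraction_half(N, m))
    return math.exp(_log_tail_general(N, m, p_r))


def binomial_consistency_log10(N: int, m: int, p_r: float = 0.5) -> float:
    """log10 of the upper binomial tail, exact to float precision at any N."""
    _check_counts(N, m, p_r)
    if m == 0:
        return 0.0
    if p_r == 0.5:
        total = sum(math.comb(N, k) for k in range(m, N + 1))
        return _log10_int(total) - N * _LOG10_2
    return _log_tail_general(N, m, p_r) / math.log(10.0)


def dataset_stats(matrix: OmicsMatrix, welch: bool = True) -> pd.DataFrame:
    """Per-feature effect and two-sided p for one cohort.

    Columns: gene, effect (mean cancer − mean normal), p (two-sample t,
    Welch by default). Used by the union/marginal agreement variants, which
    need a direction and a marginal significance for *every* gene, not only
    the called ones.
    """
    cancer = matrix.group("cancer").to_numpy()
    normal = matrix.group("normal").to_numpy()
    effect = cancer.mean(axis=1) - normal.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = ttest_ind(cancer, normal, axis=1, equal_var=not welch)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.DataFrame({"gene": matrix.features, "effect": effect, "p": p})


def _report(N: int, m: int, variant: str, modality: str, p_r: float = 0.5) -> ConcordanceReport:
    if N == 0:
        return ConcordanceReport(0, 0, None, None, None, variant, modality, p_r)
    return ConcordanceReport(
        N=N,
        m=m,
        agreement_rate=m / N,
        p_value=binomial_consistency_pvalue(N, m, p_r),
        log10_p_value=binomial_consistency_log10(N, m, p_r),
        variant=variant,
        modality=modality,
        p_r=p_r,
    )


def _modality_of(*call_frames: pd.DataFrame) -> str:
    tags = {m for calls in call_frames for m in calls["modality"].unique()}
    if len(tags) > 1:
        raise ValueError(f"calls mix modalities: {sorted(tags)}")
    return tags.pop() if tags else "expression"


def _direction_map(calls: pd.DataFrame) -> pd.Series:
    return pd.Series(calls["direction"].values, index=calls["gene"].values)


def shared_agreement(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> ConcordanceReport:
    """Agreement among genes called in both cohorts (the headline rate)."""
    validate_calls(calls_a)
    validate_calls(calls_b)
    modality = _modality_of(calls_a, calls_b)
    da, db = _direction_map(calls_a), _direction_map(calls_b)
    shared = da.index.intersection(db.index)
    m = int((da[shared] == db[shared]).sum())
    return _report(len(shared), m, "shared", modality)


def union_agreement(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
) -> ConcordanceReport:
    """Agreement over genes called in at least one cohort.

    A gene called in only one cohort is consistent iff its call direction
    matches the sign of its effect in the other cohort's full statistics; a
    zero effect there counts as inconsistent (conservative tie rule).
    """
    validate_calls(calls_a)
    validate_calls(calls_b)
    modality = _modality_of(calls_a, calls_b)
    da, db = _direction_map(calls_a), _direction_map(calls_b)
    eff_a = pd.Series(stats_a["effect"].values, index=stats_a["gene"].values)
    eff_b = pd.Series(stats_b["effect"].values, index=stats_b["gene"].values)
    union = da.index.union(db.index)
    m = 0
    for gene in union:
        if gene in da.index and gene in db.index:
            m += int(da[gene] == db[gene])
        elif gene in da.index:
            m += int(np.sign(eff_b.get(gene, 0.0)) == da[gene])
        else:
            m += int(np.sign(eff_a.get(gene, 0.0)) == db[gene])
    return _report(len(union), m, "union", modality)


def marginal_agreement(
    calls_a: pd.DataFrame, stats_b: pd.DataFrame, p_cut: float = 0.1
) -> ConcordanceReport:
    """Agreement of cohort-A calls with at-least-marginal changes in B.

    Restricted to A's called genes whose two-sided p in cohort B is below
    ``p_cut``; consistency is sign agreement with B's effect.
    """
    validate_calls(calls_a)
    if not 0.0 < p_cut <= 1.0:
        raise ValueError("p_cut must be in (0, 1]")
    modality = _modality_of(calls_a)
    da = _direction_map(calls_a)
    sb = stats_b.set_index("gene")
    genes = [g for g in da.index if g in sb.index and sb.at[g, "p"] < p_cut]
    m = sum(int(np.sign(sb.at[g, "effect"]) == da[g]) for g in genes)
    return _report(len(genes), m, "marginal", modality)


def third_dataset_agreement(
    nonoverlap_calls: pd.DataFrame, third_calls: pd.DataFrame
) -> ConcordanceReport:
    """Validate calls unique to one cohort against an independent third cohort.

    N counts the non-overlapping genes that are also called in the third
    cohort; m counts direction matches there.
    """
    validate_calls(nonoverlap_calls)
    validate_calls(third_calls)
    modality = _modality_of(nonoverlap_calls, third_calls)
    dn, dt = _direction_map(nonoverlap_calls), _direction_map(third_calls)
    genes = dn.index.intersection(dt.index)
    m = int((dn[genes] == dt[genes]).sum())
    return _report(len(genes), m, "third_dataset", modality)


def nonoverlapping_calls(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Calls of cohort A for genes not called in cohort B."""
    validate_calls(calls_a)
    validate_calls(calls_b)
    return calls_a[~calls_a["gene"].isin(set(calls_b["gene"]))].reset_index(drop=True)


def merge_consistent(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Union of calls minus genes called in both cohorts with opposite signs.

    A gene called in both with the same direction keeps cohort A's row; a
    gene called in one cohort keeps that cohort's row. The result has one
    row per gene.
    """
    validate_calls(calls_a)
    validate_calls(calls_b)
    _modality_of(calls_a, calls_b)
    da, db = _direction_map(calls_a), _direction_map(calls_b)
    both = da.index.intersection(db.index)
    conflicted = set(both[da[both] != db[both]])
    keep_a = calls_a[~calls_a["gene"].isin(conflicted)]
    only_b = calls_b[
        ~calls_b["gene"].isin(set(calls_a["gene"])) & ~calls_b["gene"].isin(conflicted)
    ]
    merged = pd.concat([keep_a, only_b], ignore_index=True)[CALL_COLUMNS]
    return validate_calls(merged.reset_index(drop=True))
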