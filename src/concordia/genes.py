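"""Direction-frequency analysis of candidate oncogenes and TSGs.

A candidate oncogene (or TSG) is a gene previously labeled as such for a
cancer type, without regard to which mutation defined it. An *event* is one
candidate gene showing one consistent direction of one modality's change in
its own cancer type. If candidate roles predicted direction, oncogene events
should be overwhelmingly up/hypo/amp and TSG events down/hyper/del; the
departure from a fair coin is tested with the same upper binomial tail the
concordance module uses.

Stability TSGs (DNA repair, cell-cycle checkpoint, DNA-damage response) are
analyzed apart from other TSGs, since their loss acts through genomic
instability rather than growth deregulation, and observed candidate
frequencies are compared against the background direction frequencies of
all retained differential genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .concordance import binomial_consistency_log10, binomial_consistency_pvalue
from .datatypes import DIRECTION_LABELS, validate_calls

EVENT_COLUMNS = ["gene", "cancer_type", "modality", "direction", "role", "stability"]


def classify_stability(catalog: pd.DataFrame, stability_genes: Iterable[str]) -> pd.DataFrame:
    """Set the stability flag from an externally supplied annotation list.

    ``stability_genes`` is the union of a curated stability-TSG list and
    genes annotated to DNA-repair / checkpoint / DNA-damage-response terms;
    it is consumed as data, never fetched.
    """
    flagged = set(stability_genes)
    out = catalog.copy()
    out["stability"] = out["gene"].isin(flagged)
    return out


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """No gene may be both oncogene and TSG for one cancer type."""
    long = explode_catalog(catalog)
    dup = long[long.duplicated(subset=["gene", "cancer_type"], keep=False)]
    conflict = dup.groupby(["gene", "cancer_type"])["role"].nunique()
    if (conflict > 1).any():
        bad = conflict[conflict > 1].index.tolist()[:5]
        raise ValueError(f"genes labeled both oncogene and TSG: {bad}")
    return catalog


def explode_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Long form: one row per (gene, cancer_type) with role and stability."""
    rows = []
    for r in catalog.itertuples(index=False):
        for ct in r.cancer_types:
            rows.append(
                {"gene": r.gene, "cancer_type": ct, "role": r.role, "stability": bool(r.stability)}
            )
    return pd.DataFrame(rows, columns=["gene", "cancer_type", "role", "stability"])


def count_direction_events(
    merged_calls: Mapping[tuple, pd.DataFrame], catalog: pd.DataFrame
) -> pd.DataFrame:
    """Event table from merged (consistent-direction) calls.

    ``merged_calls`` maps (cancer_type, modality) to a merged calls frame.
    An event is a candidate gene of that cancer type appearing in the
    frame; directions are translated to the modality's labels (up/down,
    hyper/hypo, amp/del). One row per (gene, cancer_type, modality).
    """
    validate_catalog(catalog)
    long = explode_catalog(catalog)
    rows = []
    for (cancer_type, modality), calls in sorted(merged_calls.items()):
        validate_calls(calls)
        cands = long[long["cancer_type"] == cancer_type]
        if cands.empty:
            continue
        hits = calls.merge(cands, on="gene")
        labels = DIRECTION_LABELS[modality]
        for r in hits.itertuples(index=False):
            rows.append(
                {
                    "gene": r.gene,
                    "cancer_type": cancer_type,
                    "modality": modality,
                    "direction": labels[int(r.direction)],
                    "role": r.role,
                    "stability": bool(r.stability),
                }
            )
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if events.duplicated(subset=["gene", "cancer_type", "modality"]).any():
        raise ValueError("more than one event for a (gene, cancer, modality)")
    return events


@dataclass
class BiasTestResult:
    """Directional bias of one gene class's events against a fair coin."""

    n_total: int
    n_favored: int
    frequency: float | None
    p_value: float | None
    log10_p_value: float | None
    favored_direction: str

    @property
    def empty(self) -> bool:
        return self.n_total == 0

    def to_dict(self) -> dict:
        return self.__dict__ | {"frequency": self.frequency}


def direction_bias_test(
    events: pd.DataFrame,
    favored_direction: str,
    role: str | None = None,
    stability: bool | None = None,
    modality: str | None = None,
) -> BiasTestResult:
    """Test whether a gene class's events favor one direction.

    Filters the event table by role/stability/modality, then computes the
    favored-direction frequency and the upper binomial tail of the favored
    count at success probability 0.5. Zero events yield a flagged empty
    result (undefined frequency), not a p-value.
    """
    sub = events
    if role is not None:
        sub = sub[sub["role"] == role]
    if stability is not None:
        sub = sub[sub["stability"] == stability]
    if modality is not None:
        sub = sub[sub["modality"] == modality]
    n = len(sub)
    if n == 0:
        return BiasTestResult(0, 0, None, None, None, favored_direction)
    fav = int((sub["direction"] == favored_direction).sum())
    return BiasTestResult(
        n_total=n,
        n_favored=fav,
        frequency=fav / n,
        p_value=binomial_consistency_pvalue(n, fav),
        log10_p_value=binomial_consistency_log10(n, fav),
        favored_direction=favored_direction,
    )


def background_frequency(merged_calls: pd.DataFrame, direction: int) -> float | None:
    """Fraction of ALL retained differential genes with the given direction.

    The expected frequency a candidate class would show if it behaved like
    any other differential gene of that cancer/modality.
    """
    validate_calls(merged_calls)
    if len(merged_calls) == 0:
        return None
    return float((merged_calls["direction"] == direction).mean())


def average_frequency(per_cancer: Mapping[str, tuple]) -> dict:
    """Average favored-direction frequency over cancer types, both ways.

    ``per_cancer`` maps cancer type → (favored events, total events).
    Returns the pooled frequency (events summed over cancers — the headline
    number) and the unweighted per-cancer mean, side by side; cancers with
    zero events are excluded from the mean.
    """
    fav = sum(f for f, _ in per_cancer.values())
    tot = sum(t for _, t in per_cancer.values())
    rates = [f / t for f, t in per_cancer.values() if t > 0]
    return {
        "pooled": fav / tot if tot else None,
        "per_cancer_mean": sum(rates) / len(rates) if rates else None,
        "n_events": tot,
        "n_cancers": len(rates),
    }
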