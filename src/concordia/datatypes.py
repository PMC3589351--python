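"""Core containers shared across the analysis modules.

The universal input is an :class:`OmicsMatrix`: a feature-by-sample numeric
matrix (genes for expression, probes/genes for methylation, markers for copy
number) with a cancer/normal label per sample and a modality tag.

Differential calls flow between modules as plain :class:`pandas.DataFrame`
objects with the columns listed in :data:`CALL_COLUMNS`; the
:class:`DifferentialCall` dataclass documents one row of that contract and
:func:`validate_calls` enforces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANCER = "cancer"
NORMAL = "normal"
GROUPS = (CANCER, NORMAL)

MODALITIES = ("expression", "methylation", "cna")

#: Required columns of a calls frame (one row per called gene).
CALL_COLUMNS = ["gene", "direction", "statistic", "q_value", "dataset", "modality"]

#: Human-readable direction labels per modality, keyed by the sign convention
#: direction=+1 means higher in cancer (up / hypermethylated / amplified).
DIRECTION_LABELS = {
    "expression": {1: "up", -1: "down"},
    "methylation": {1: "hyper", -1: "hypo"},
    "cna": {1: "amp", -1: "del"},
}


@dataclass(frozen=True)
class DifferentialCall:
    """One per-gene differential call (a row of a calls frame)."""

    gene: str
    direction: int  # +1 higher in cancer, -1 lower
    statistic: float
    q_value: float
    dataset: str
    modality: str

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value must be in [0, 1], got {self.q_value}")


def empty_calls() -> pd.DataFrame:
    return pd.DataFrame(columns=CALL_COLUMNS)


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Check the calls-frame contract; returns the frame unchanged."""
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"calls frame missing columns: {missing}")
    if len(calls):
        if not calls["direction"].isin([1, -1]).all():
            raise ValueError("calls direction must be +1 or -1")
        q = calls["q_value"].to_numpy(dtype=float)
        if np.nanmin(q) < 0 or np.nanmax(q) > 1:
            raise ValueError("q_value out of [0, 1]")
        if calls["gene"].duplicated().any():
            raise ValueError("duplicate genes in calls frame")
    return calls


@dataclass
class OmicsMatrix:
    """Feature-by-sample numeric matrix with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id (gene, probe or marker) with one
        column per sample.
    labels
        Series mapping sample id to ``"cancer"`` or ``"normal"``. Every
        column of ``values`` must be labelled. A copy-number matrix of
        tumour-only log2 ratios labels every sample ``"cancer"``.
    modality
        One of ``expression``, ``methylation``, ``cna``.
    dataset
        Free-form cohort identifier carried into downstream calls.
    """

    values: pd.DataFrame
    labels: pd.Series
    modality: str = "expression"
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])[:5]
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.labels.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group(self, name: str) -> pd.DataFrame:
        """Submatrix of samples belonging to one group."""
        if name not in GROUPS:
            raise ValueError(f"unknown group {name!r}")
        cols = self.labels.index[self.labels == name]
        return self.values[cols]

    def n_group(self, name: str) -> int:
        return int((self.labels == name).sum())

    def swap_groups(self) -> "OmicsMatrix":
        """Return a copy with cancer and normal labels exchanged."""
        swapped = self.labels.map({CANCER: NORMAL, NORMAL: CANCER})
        return OmicsMatrix(self.values.copy(), swapped, self.modality, self.dataset)


@dataclass
class ConcordanceReport:
    """Cross-dataset directional agreement of one modality's calls.

    ``N`` genes were compared, ``m`` of them agree in direction; the
    significance of at least ``m`` agreements under a fair-coin null is the
    upper binomial tail. ``log10_p_value`` is always finite and exact even
    when the tail underflows double precision (agreement among thousands of
    genes routinely produces p far below 1e-300).
    """

    N: int
    m: int
    agreement_rate: float | None
    p_value: float | None
    log10_p_value: float | None
    variant: str  # shared | union | marginal | third_dataset
    modality: str
    p_r: float = 0.5

    @property
    def empty(self) -> bool:
        return self.N == 0

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "m": self.m,
            "agreement_rate": self.agreement_rate,
            "p_value": self.p_value,
            "log10_p_value": self.log10_p_value,
            "variant": self.variant,
            "modality": self.modality,
            "p_r": self.p_r,
        }


@dataclass(frozen=True)
class CnaRegion:
    """Maximal contiguous run of significant markers of one alteration type."""

    marker_start: int  # 0-based, half-open
    marker_end: int
    kind: str  # "amplification" | "deletion"
    g_score: float  # mean marker G over the region
    q_value: float  # min marker q over the region
    genes: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.marker_start < self.marker_end:
            raise ValueError("region start must be < end")
        if self.kind not in ("amplification", "deletion"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.g_score < 0:
            raise ValueError("G-score must be >= 0")


MUTATION_CLASSES = ("activating", "inactivating", "undetermined", "wild_type")


def validate_mutation_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Annotation frame: columns sample, gene, mclass; one class per pair."""
    for col in ("sample", "gene", "mclass"):
        if col not in ann.columns:
            raise ValueError(f"mutation annotation missing column {col!r}")
    bad = set(ann["mclass"].unique()) - set(MUTATION_CLASSES)
    if bad:
        raise ValueError(f"unknown mutation classes: {sorted(bad)}")
    if ann.duplicated(subset=["sample", "gene"]).any():
        raise ValueError("multiple mutation classes for one (sample, gene)")
    return ann
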