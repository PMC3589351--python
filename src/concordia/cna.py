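"""Copy-number alteration calling from marker-level log2 ratios.

Each marker is scored per alteration type with a G-score: the fraction f of
samples altered beyond a noise threshold (default |log2 ratio| > 0.1) times
the mean amplitude a over those altered samples,

    G_amp = f * mean(x | x >  thr),      G_del computed on -x symmetrically.

Significance comes from an empirical null built by permuting marker values
within each sample (preserving every sample's amplitude distribution while
destroying marker identity): null G-scores are pooled over markers and
permutations, each observed marker gets an empirical p, and
Benjamini–Hochberg q-values are thresholded. Significant markers are then
grouped into maximal contiguous regions per type, and genes are attached
via the marker→gene map. A gene overlapping both an amplification and a
deletion region in one dataset is reported as ambiguous and excluded from
direction calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import CALL_COLUMNS, CnaRegion, validate_calls

NOISE_THRESHOLD = 0.1  # log2-ratio magnitude below which a sample is unaltered


def gscore(marker_values, kind: str, threshold: float = NOISE_THRESHOLD) -> float:
    """Frequency × mean-amplitude score of one marker; 0 when nothing exceeds."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    x = np.asarray(marker_values, dtype=float)
    if kind == "deletion":
        x = -x
    elif kind != "amplification":
        raise ValueError(f"unknown alteration kind {kind!r}")
    altered = x > threshold
    if not altered.any():
        return 0.0
    f = altered.mean()
    a = x[altered].mean()
    return float(f * a)


def gscores(matrix: np.ndarray, kind: str, threshold: float = NOISE_THRESHOLD) -> np.ndarray:
    """Vectorized G-score per marker row of a marker×sample array."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    x = np.asarray(matrix, dtype=float)
    if kind == "deletion":
        x = -x
    elif kind != "amplification":
        raise ValueError(f"unknown alteration kind {kind!r}")
    altered = x > threshold
    n_alt = altered.sum(axis=1)
    total = np.where(altered, x, 0.0).sum(axis=1)
    # f * a = (n_alt / n) * (total / n_alt); guard the empty-marker case
    return np.where(n_alt > 0, (n_alt / x.shape[1]) * (total / np.maximum(n_alt, 1)), 0.0)


@dataclass
class CnaCallResult:
    """Regions plus per-gene calls and ambiguity bookkeeping."""

    regions: list
    calls: pd.DataFrame
    ambiguous_genes: list
    marker_q: pd.DataFrame  # marker, g_amp, g_del, q_amp, q_del


def _runs(mask: np.ndarray):
    """Maximal contiguous True runs as (start, end) half-open pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def call_cna_regions(
    matrix: pd.DataFrame,
    gene_map: pd.Series,
    fdr_target: float = 0.05,
    n_permutations: int = 500,
    seed: int = 0,
    threshold: float = NOISE_THRESHOLD,
    dataset: str = "",
) -> CnaCallResult:
    """Call amplification/deletion regions and their genes.

    ``matrix``: marker×sample log2 ratios (marker order = genomic order);
    ``gene_map``: Series marker id → gene id.
    """
    if not 0.0 < fdr_target <= 1.0:
        raise ValueError("fdr_target must be in (0, 1]")
    if len(matrix) < 10:
        raise ValueError("need >= 10 markers")
    x = matrix.to_numpy(dtype=float)
    n_markers, n_samples = x.shape
    if n_permutations * n_markers < 10 / fdr_target:
        warnings.warn("few permutations for the requested FDR resolution", stacklevel=2)

    obs = {k: gscores(x, k, threshold) for k in ("amplification", "deletion")}

    rng = np.random.default_rng(seed)
    null = {"amplification": [], "deletion": []}
    perm = x.copy()
    for _ in range(n_permutations):
        for j in range(n_samples):  # permute markers within each sample
            rng.shuffle(perm[:, j])
        for k in null:
            null[k].append(gscores(perm, k, threshold))
    null_sorted = {k: np.sort(np.concatenate(null[k])) for k in null}

    q = {}
    for k in null:
        n_null = null_sorted[k].size
        # empirical upper-tail p with add-one correction
        ge = n_null - np.searchsorted(null_sorted[k], obs[k], side="left")
        p = (1.0 + ge) / (1.0 + n_null)
        _, q[k], _, _ = multipletests(p, method="fdr_bh")

    regions: list[CnaRegion] = []
    gene_dirs: dict[str, set] = {}
    region_q: dict[tuple, float] = {}
    markers = np.asarray(matrix.index)
    for kind, sign in (("amplification", 1), ("deletion", -1)):
        for start, end in _runs(q[kind] <= fdr_target):
            run_markers = markers[start:end]
            genes = tuple(
                sorted(set(gene_map.reindex(run_markers).dropna().astype(str)))
            )
            reg = CnaRegion(
                marker_start=int(start),
                marker_end=int(end),
                kind=kind,
                g_score=float(obs[kind][start:end].mean()),
                q_value=float(q[kind][start:end].min()),
                genes=genes,
            )
            regions.append(reg)
            for g in genes:
                gene_dirs.setdefault(g, set()).add(sign)
                key = (g, sign)
                region_q[key] = min(region_q.get(key, 1.0), reg.q_value)

    ambiguous = sorted(g for g, dirs in gene_dirs.items() if len(dirs) > 1)
    rows = []
    for g, dirs in sorted(gene_dirs.items()):
        if len(dirs) > 1:
            continue
        (sign,) = dirs
        rows.append(
            {
                "gene": g,
                "direction": sign,
                "statistic": np.nan,  # filled below from the gene's own markers
                "q_value": region_q[(g, sign)],
                "dataset": dataset,
                "modality": "cna",
            }
        )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if len(calls):
        # statistic: best G over the gene's own markers, signed by direction
        stat = []
        marker_index = pd.Index(markers)
        for g, sign in zip(calls["gene"], calls["direction"]):
            own = marker_index.get_indexer(gene_map.index[gene_map == g])
            own = own[own >= 0]
            key = "amplification" if sign > 0 else "deletion"
            stat.append(float(obs[key][own].max()) if own.size else 0.0)
        calls["statistic"] = stat
        calls["direction"] = calls["direction"].astype(int)
    marker_q = pd.DataFrame(
        {
            "marker": markers,
            "g_amp": obs["amplification"],
            "g_del": obs["deletion"],
            "q_amp": q["amplification"],
            "q_del": q["deletion"],
        }
    )
    return CnaCallResult(
        regions=regions,
        calls=validate_calls(calls.reset_index(drop=True)),
        ambiguous_genes=ambiguous,
        marker_q=marker_q,
    )
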