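"""Seeded generators for two-cohort cancer-vs-normal study designs.

The analysis assumes, per cancer type, two independent cohorts of the same
modality with a shared gene universe, some fraction of truly differential
genes, and a controllable probability that a true differential points the
same way in both cohorts. The generators below plant exactly that structure
and always return a truth table alongside the data, so recovery tests never
have to re-infer what was planted.

Expression is simulated on the log2 scale with Gaussian noise; methylation
as beta-values converted to U/M intensities around a fixed total intensity;
copy number as marker-level log2 ratios with planted contiguous
amplification/deletion segments carried by a subset of samples. Mutation
classes (activating/inactivating/undetermined) are assigned per candidate
gene and sample, and mutated strata receive class-specific expression
shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CANCER, NORMAL, OmicsMatrix
from .methylation import BETA_OFFSET


@dataclass
class CohortSpec:
    """Design of one two-cohort comparison.

    ``effect_size`` is the mean shift of a true differential on the
    modality's natural scale (log2 units for expression and copy number,
    beta units for methylation); ``consistency`` is the probability that a
    planted gene keeps the same sign in both cohorts.
    """

    n_genes: int = 2000
    n_cancer: int = 30
    n_normal: int = 30
    frac_de: float = 0.1
    effect_size: float = 1.0
    noise_sd: float = 0.5
    consistency: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_cancer < 2 or self.n_normal < 2:
            raise ValueError("sample counts must be >= 2")
        for name in ("frac_de", "consistency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.frac_de > 0 and round(self.frac_de * self.n_genes) < 1:
            raise ValueError("frac_de > 0 but fewer than one gene would be planted")


@dataclass
class CatalogSpec:
    """Design of the candidate-gene catalog and per-sample mutations."""

    n_oncogenes: int = 20
    n_tsgs: int = 20
    frac_stability: float = 0.3
    mutation_rate: float = 0.1
    activating_shift: float = 2.0
    inactivating_shift: float = -2.0
    undetermined_shift: float = 0.0
    wildtype_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.n_oncogenes < 0 or self.n_tsgs < 0:
            raise ValueError("gene counts must be >= 0")
        for name in ("frac_stability", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class CohortPair:
    """Two cohorts over one gene universe plus the planted truth."""

    cohort_a: OmicsMatrix
    cohort_b: OmicsMatrix
    truth: pd.DataFrame  # gene, planted (bool), direction_a, direction_b (0 if null)
    gene_map: pd.Series | None = None  # marker→gene, CNA only
    extra: dict = field(default_factory=dict)


def _gene_ids(n: int, prefix: str = "G") -> list[str]:
    width = len(str(max(n - 1, 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _sample_ids(prefix: str, n_cancer: int, n_normal: int):
    cancer = [f"{prefix}_T{i:03d}" for i in range(n_cancer)]
    normal = [f"{prefix}_N{i:03d}" for i in range(n_normal)]
    return cancer, normal


def _labels(cancer, normal) -> pd.Series:
    return pd.Series(
        [CANCER] * len(cancer) + [NORMAL] * len(normal), index=list(cancer) + list(normal)
    )


def _planted_directions(spec: CohortSpec, rng: np.random.Generator):
    """Choose planted genes, their cohort-A sign, and the cohort-B sign.

    Sign flips between cohorts are sampled independently per gene with
    probability 1 − consistency, matching the binomial null the concordance
    test assumes.
    """
    n_planted = int(round(spec.frac_de * spec.n_genes))
    planted = rng.choice(spec.n_genes, size=n_planted, replace=False)
    dir_a = rng.choice([1, -1], size=n_planted)
    keep = rng.random(n_planted) < spec.consistency
    dir_b = np.where(keep, dir_a, -dir_a)
    return planted, dir_a, dir_b


def generate_expression_pair(spec: CohortSpec) -> CohortPair:
    """Two log2 expression cohorts with planted differential genes."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    planted, dir_a, dir_b = _planted_directions(spec, rng)
    baseline = rng.normal(8.0, 2.0, size=spec.n_genes)

    cohorts = []
    for tag, dirs in (("A", dir_a), ("B", dir_b)):
        shift = np.zeros(spec.n_genes)
        shift[planted] = dirs * spec.effect_size
        cancer_ids, normal_ids = _sample_ids(tag, spec.n_cancer, spec.n_normal)
        cancer = (
            baseline[:, None]
            + shift[:, None]
            + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_cancer))
        )
        normal = baseline[:, None] + rng.normal(
            0.0, spec.noise_sd, size=(spec.n_genes, spec.n_normal)
        )
        values = pd.DataFrame(
            np.hstack([cancer, normal]), index=pd.Index(genes, name="gene"),
            columns=cancer_ids + normal_ids,
        )
        cohorts.append(
            OmicsMatrix(values, _labels(cancer_ids, normal_ids), "expression", tag)
        )

    truth = pd.DataFrame({"gene": genes, "planted": False, "direction_a": 0, "direction_b": 0})
    truth.loc[planted, "planted"] = True
    truth.loc[planted, "direction_a"] = dir_a
    truth.loc[planted, "direction_b"] = dir_b
    return CohortPair(cohorts[0], cohorts[1], truth)


def generate_methylation_pair(
    spec: CohortSpec, total_intensity: float = 2000.0
) -> CohortPair:
    """Two U/M-intensity cohorts with planted beta-value shifts.

    ``spec.effect_size`` and ``spec.noise_sd`` are on the beta scale (a
    planted probe's cancer mean moves by ±effect_size). Betas are clipped to
    the range attainable at the chosen total intensity and converted back to
    U and M with M = beta·(T+100), U = T − M ≥ 0.
    """
    rng = np.random.default_rng(spec.seed)
    probes = _gene_ids(spec.n_genes, prefix="cg")
    genes = _gene_ids(spec.n_genes)
    planted, dir_a, dir_b = _planted_directions(spec, rng)
    beta_max = total_intensity / (total_intensity + BETA_OFFSET)
    base_beta = rng.uniform(0.15, 0.85, size=spec.n_genes)

    cohorts, um_tables = [], {}
    for tag, dirs in (("A", dir_a), ("B", dir_b)):
        shift = np.zeros(spec.n_genes)
        shift[planted] = dirs * spec.effect_size
        cancer_ids, normal_ids = _sample_ids(tag, spec.n_cancer, spec.n_normal)
        beta_cancer = np.clip(
            base_beta[:, None]
            + shift[:, None]
            + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_cancer)),
            0.0,
            beta_max,
        )
        beta_normal = np.clip(
            base_beta[:, None]
            + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_normal)),
            0.0,
            beta_max,
        )
        beta = np.hstack([beta_cancer, beta_normal])
        samples = cancer_ids + normal_ids
        M = beta * (total_intensity + BETA_OFFSET)
        U = total_intensity - M
        long = pd.DataFrame(
            {
                "probe": np.repeat(probes, len(samples)),
                "sample": np.tile(samples, spec.n_genes),
                "U": U.ravel(),
                "M": M.ravel(),
            }
        )
        um_tables[tag] = long
        values = pd.DataFrame(
            beta, index=pd.Index(genes, name="gene"), columns=samples
        )
        cohorts.append(
            OmicsMatrix(values, _labels(cancer_ids, normal_ids), "methylation", tag)
        )

    truth = pd.DataFrame({"gene": genes, "planted": False, "direction_a": 0, "direction_b": 0})
    truth.loc[planted, "planted"] = True
    truth.loc[planted, "direction_a"] = dir_a
    truth.loc[planted, "direction_b"] = dir_b
    probe_map = pd.Series(genes, index=pd.Index(probes, name="probe"), name="gene")
    return CohortPair(
        cohorts[0],
        cohorts[1],
        truth,
        extra={"um_tables": um_tables, "probe_map": probe_map},
    )


def generate_cna_profiles(
    spec: CohortSpec,
    segment_length: int = 25,
    carrier_frac: float = 0.4,
) -> CohortPair:
    """Two marker×sample log2-ratio matrices with planted CNA segments.

    Markers map 1:1 to genes in genomic order. Planted segments are
    contiguous runs of ``segment_length`` markers covering about
    ``frac_de`` of the genome; each segment is amplified or deleted by
    ``effect_size`` in a ``carrier_frac`` fraction of samples (rounded).
    The truth direction flips between cohorts with probability
    1 − consistency, per segment.
    """
    if not 0.0 < carrier_frac <= 1.0:
        raise ValueError("carrier_frac must be in (0, 1]")
    if segment_length < 1 or segment_length > spec.n_genes:
        raise ValueError("segment_length out of range")
    rng = np.random.default_rng(spec.seed)
    n_markers = spec.n_genes
    markers = _gene_ids(n_markers, prefix="M")
    genes = _gene_ids(n_markers)
    gene_map = pd.Series(genes, index=pd.Index(markers, name="marker"), name="gene")

    n_segments = int(round(spec.frac_de * n_markers / segment_length))
    slots = n_markers // segment_length
    seg_slots = rng.choice(slots, size=min(n_segments, slots), replace=False)
    seg_dir_a = rng.choice([1, -1], size=len(seg_slots))
    keep = rng.random(len(seg_slots)) < spec.consistency
    seg_dir_b = np.where(keep, seg_dir_a, -seg_dir_a)

    n_carriers = max(int(round(carrier_frac * spec.n_cancer)), 1)
    cohorts = []
    truth_rows = []
    for tag, seg_dirs in (("A", seg_dir_a), ("B", seg_dir_b)):
        cancer_ids, _ = _sample_ids(tag, spec.n_cancer, 2)
        x = rng.normal(0.0, spec.noise_sd, size=(n_markers, spec.n_cancer))
        for slot, d in zip(seg_slots, seg_dirs):
            start = slot * segment_length
            carriers = rng.choice(spec.n_cancer, size=n_carriers, replace=False)
            x[start : start + segment_length][:, carriers] += d * spec.effect_size
            if tag == "A":
                truth_rows.append(
                    {
                        "segment_start": start,
                        "segment_end": start + segment_length,
                        "direction_a": int(d),
                    }
                )
        values = pd.DataFrame(
            x, index=pd.Index(markers, name="marker"), columns=cancer_ids
        )
        labels = pd.Series(CANCER, index=cancer_ids)
        cohorts.append(OmicsMatrix(values, labels, "cna", tag))

    truth = pd.DataFrame(
        truth_rows, columns=["segment_start", "segment_end", "direction_a"]
    )
    truth["direction_b"] = seg_dir_b[: len(truth)].astype(int)
    truth["genes"] = [
        ";".join(genes[r.segment_start : r.segment_end]) for r in truth.itertuples()
    ]
    return CohortPair(cohorts[0], cohorts[1], truth, gene_map=gene_map)


def generate_catalog_and_mutations(
    cspec: CatalogSpec, pair: CohortPair, cancer_type: str = "cancer1", seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign candidate roles to genes and plant mutation-class shifts.

    Returns ``(catalog, annotation)``. Candidate genes are drawn from the
    cohorts' gene universe; every cancer sample of cohort A gets a mutation
    class per candidate gene (mutated with probability ``mutation_rate``,
    class uniform over activating/inactivating/undetermined) and cohort A's
    expression is shifted in place by the class-specific amount. Exactly
    ``round(frac_stability × n_tsgs)`` TSGs carry the stability flag.
    """
    rng = np.random.default_rng(seed)
    genes = list(pair.cohort_a.features)
    n_cand = cspec.n_oncogenes + cspec.n_tsgs
    if n_cand > len(genes):
        raise ValueError("more candidates requested than genes available")
    chosen = rng.choice(len(genes), size=n_cand, replace=False)
    onco = [genes[i] for i in chosen[: cspec.n_oncogenes]]
    tsg = [genes[i] for i in chosen[cspec.n_oncogenes :]]
    n_stab = int(round(cspec.frac_stability * cspec.n_tsgs))
    stab_idx = set(rng.choice(cspec.n_tsgs, size=n_stab, replace=False)) if cspec.n_tsgs else set()
    catalog = pd.DataFrame(
        {
            "gene": onco + tsg,
            "role": ["oncogene"] * len(onco) + ["TSG"] * len(tsg),
            "stability": [False] * len(onco)
            + [i in stab_idx for i in range(len(tsg))],
            "cancer_types": [(cancer_type,)] * n_cand,
        }
    )

    shifts = {
        "activating": cspec.activating_shift,
        "inactivating": cspec.inactivating_shift,
        "undetermined": cspec.undetermined_shift,
        "wild_type": cspec.wildtype_shift,
    }
    cancer_samples = list(
        pair.cohort_a.labels.index[pair.cohort_a.labels == CANCER]
    )
    rows = []
    for gene in catalog["gene"]:
        mutated = rng.random(len(cancer_samples)) < cspec.mutation_rate
        classes = np.where(
            mutated,
            rng.choice(["activating", "inactivating", "undetermined"], size=len(cancer_samples)),
            "wild_type",
        )
        for s, c in zip(cancer_samples, classes):
            rows.append({"sample": s, "gene": gene, "mclass": c})
            delta = shifts[str(c)]
            if delta:
                pair.cohort_a.values.loc[gene, s] += delta
    annotation = pd.DataFrame(rows, columns=["sample", "gene", "mclass"])
    return catalog, annotation
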