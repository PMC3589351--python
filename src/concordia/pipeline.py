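"""End-to-end orchestration: simulate → call → concord → merge → gene analysis.

A run is driven by one YAML/dict config and one root seed. Every stage draws
its randomness from a named seed stream derived from the root seed and the
stage path, so two runs with the same config and seed produce byte-identical
report bundles, and no stage mutates another stage's outputs.

The bundle contains:

``concordance_long.tsv``
    every agreement report (cancer × modality × variant) with N, m, rate,
    p and exact log10 p.
``agreement_table.tsv``
    the shared-variant rates pivoted to one row per cancer type, formatted
    ``"99.12% (1234)"``.
``merged_calls.tsv``, ``events.tsv``
    retained consistent-direction calls and the candidate-gene event table.
``bias_tests.json``
    direction-frequency tests per gene class and modality, with pooled and
    per-cancer average frequencies and background frequencies.
``stratified.json``
    mutation-class-stratified expression tests and reversal flags.
``provenance.json``
    canonical config, root seed, derived stage seeds, package versions.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cna import call_cna_regions
from .concordance import (
    dataset_stats,
    marginal_agreement,
    merge_consistent,
    nonoverlapping_calls,
    shared_agreement,
    union_agreement,
)
from .datatypes import DIRECTION_LABELS
from .genes import (
    average_frequency,
    background_frequency,
    count_direction_events,
    direction_bias_test,
)
from .methylation import call_dm_genes
from .sam import SamConfig, call_de_genes
from .stratified import reversal_report, stratify_and_test
from .synthetic import (
    CatalogSpec,
    CohortSpec,
    generate_catalog_and_mutations,
    generate_cna_profiles,
    generate_expression_pair,
    generate_methylation_pair,
)

#: Favored direction per (role-or-class, modality) for the bias battery:
#: the direction the candidate label would predict.
FAVORED = {
    ("oncogene", "expression"): "up",
    ("oncogene", "methylation"): "hypo",
    ("oncogene", "cna"): "amp",
    ("TSG", "expression"): "down",
    ("TSG", "methylation"): "hyper",
    ("TSG", "cna"): "del",
}


def stage_seed(root_seed: int, *tags: str) -> int:
    """Deterministic per-stage seed from the root seed and a stage path."""
    crc = zlib.crc32("/".join(tags).encode())
    return int(np.random.SeedSequence([int(root_seed), crc]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Full-run configuration (see README for the YAML schema)."""

    seed: int = 0
    cancer_types: dict = field(default_factory=dict)  # name -> {modality: CohortSpec kwargs}
    catalog: dict = field(default_factory=dict)  # CatalogSpec kwargs
    fdr: dict = field(
        default_factory=lambda: {"expression": 0.05, "methylation": 0.05, "cna": 0.05}
    )
    cna_fdr_override: dict = field(default_factory=dict)  # cancer_type -> stricter FDR
    marginal_p_cut: float = 0.1
    sam_permutations: int = 100
    cna_permutations: int = 100
    segment_length: int = 25
    carrier_frac: float = 0.4
    stratify_genes: list | None = None

    def __post_init__(self) -> None:
        for name, v in [("marginal_p_cut", self.marginal_p_cut), *self.fdr.items()]:
            if not 0.0 < float(v) < 1.0:
                raise ValueError(f"threshold {name} must be in (0, 1)")
        if not self.cancer_types:
            raise ValueError("config needs at least one cancer type")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def canonical(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)


def _report_row(report, cancer_type: str) -> dict:
    d = report.to_dict()
    d["cancer_type"] = cancer_type
    d["agreement_pct"] = (
        f"{100 * d['agreement_rate']:.2f}" if d["agreement_rate"] is not None else "NA"
    )
    return d


def _concord_all(calls_a, calls_b, stats_a, stats_b, p_cut):
    reports = [shared_agreement(calls_a, calls_b)]
    if stats_a is not None and stats_b is not None:
        reports.append(union_agreement(calls_a, calls_b, stats_a, stats_b))
        reports.append(marginal_agreement(calls_a, stats_b, p_cut))
    return reports


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole pipeline; returns {filename: text content}."""
    root = int(config.seed)
    concord_rows: list[dict] = []
    merged_frames: list[pd.DataFrame] = []
    merged_by_key: dict[tuple, pd.DataFrame] = {}
    seeds_used: dict[str, int] = {}

    catalog = None
    annotation = None
    expr_pair_first = None

    for cancer_type, modal_specs in sorted(config.cancer_types.items()):
        # expression
        if "expression" in modal_specs:
            seed = stage_seed(root, cancer_type, "expression", "simulate")
            seeds_used[f"{cancer_type}/expression"] = seed
            spec = CohortSpec(**{**modal_specs["expression"], "seed": seed})
            pair = generate_expression_pair(spec)
            if expr_pair_first is None:
                expr_pair_first = (cancer_type, pair)
                if config.catalog:
                    cseed = stage_seed(root, cancer_type, "catalog")
                    seeds_used[f"{cancer_type}/catalog"] = cseed
                    catalog, annotation = generate_catalog_and_mutations(
                        CatalogSpec(**config.catalog), pair, cancer_type, seed=cseed
                    )
            cfg = SamConfig(
                n_permutations=config.sam_permutations,
                fdr_target=config.fdr["expression"],
                seed=stage_seed(root, cancer_type, "expression", "sam"),
            )
            calls_a = call_de_genes(pair.cohort_a, cfg)
            calls_b = call_de_genes(pair.cohort_b, cfg)
            stats_a = dataset_stats(pair.cohort_a)
            stats_b = dataset_stats(pair.cohort_b)
            for rep in _concord_all(calls_a, calls_b, stats_a, stats_b, config.marginal_p_cut):
                concord_rows.append(_report_row(rep, cancer_type))
            merged = merge_consistent(calls_a, calls_b)
            merged["cancer_type"] = cancer_type
            merged_frames.append(merged)
            merged_by_key[(cancer_type, "expression")] = merged

        # methylation
        if "methylation" in modal_specs:
            seed = stage_seed(root, cancer_type, "methylation", "simulate")
            seeds_used[f"{cancer_type}/methylation"] = seed
            spec = CohortSpec(**{**modal_specs["methylation"], "seed": seed})
            pair = generate_methylation_pair(spec)
            calls_a = call_dm_genes(pair.cohort_a, config.fdr["methylation"])
            calls_b = call_dm_genes(pair.cohort_b, config.fdr["methylation"])
            stats_a = dataset_stats(pair.cohort_a)
            stats_b = dataset_stats(pair.cohort_b)
            for rep in _concord_all(calls_a, calls_b, stats_a, stats_b, config.marginal_p_cut):
                concord_rows.append(_report_row(rep, cancer_type))
            merged = merge_consistent(calls_a, calls_b)
            merged["cancer_type"] = cancer_type
            merged_frames.append(merged)
            merged_by_key[(cancer_type, "methylation")] = merged

        # copy number
        if "cna" in modal_specs:
            seed = stage_seed(root, cancer_type, "cna", "simulate")
            seeds_used[f"{cancer_type}/cna"] = seed
            spec = CohortSpec(**{**modal_specs["cna"], "seed": seed})
            pair = generate_cna_profiles(
                spec, segment_length=config.segment_length, carrier_frac=config.carrier_frac
            )
            fdr = config.cna_fdr_override.get(cancer_type, config.fdr["cna"])
            res_a = call_cna_regions(
                pair.cohort_a.values,
                pair.gene_map,
                fdr_target=fdr,
                n_permutations=config.cna_permutations,
                seed=stage_seed(root, cancer_type, "cna", "permA"),
                dataset="A",
            )
            res_b = call_cna_regions(
                pair.cohort_b.values,
                pair.gene_map,
                fdr_target=fdr,
                n_permutations=config.cna_permutations,
                seed=stage_seed(root, cancer_type, "cna", "permB"),
                dataset="B",
            )
            concord_rows.append(_report_row(shared_agreement(res_a.calls, res_b.calls), cancer_type))
            merged = merge_consistent(res_a.calls, res_b.calls)
            merged["cancer_type"] = cancer_type
            merged_frames.append(merged)
            merged_by_key[(cancer_type, "cna")] = merged

    concordance_long = pd.DataFrame(concord_rows)[
        [
            "cancer_type",
            "modality",
            "variant",
            "N",
            "m",
            "agreement_pct",
            "agreement_rate",
            "p_value",
            "log10_p_value",
        ]
    ]
    shared = concordance_long[concordance_long["variant"] == "shared"].copy()
    shared["cell"] = shared.apply(
        lambda r: f"{r['agreement_pct']}% ({r['N']})" if r["N"] else "NA", axis=1
    )
    table1 = shared.pivot(index="cancer_type", columns="modality", values="cell").fillna("NA")

    merged_all = (
        pd.concat(merged_frames, ignore_index=True) if merged_frames else pd.DataFrame()
    )

    bias: dict = {}
    events = pd.DataFrame()
    if catalog is not None:
        events = count_direction_events(merged_by_key, catalog)
        for (role, modality), favored in sorted(FAVORED.items()):
            key = f"{role}/{modality}/{favored}"
            bias[key] = direction_bias_test(
                events, favored, role=role, modality=modality
            ).to_dict()
        # stability split, expression + methylation
        for stab, tag in ((True, "stability_TSG"), (False, "non_stability_TSG")):
            for modality in ("expression", "methylation"):
                favored = (
                    DIRECTION_LABELS[modality][1] if stab else DIRECTION_LABELS[modality][-1]
                )
                key = f"{tag}/{modality}/{favored}"
                bias[key] = direction_bias_test(
                    events, favored, role="TSG", stability=stab, modality=modality
                ).to_dict()
        # average frequencies and backgrounds per class/modality
        averages: dict = {}
        backgrounds: dict = {}
        for (role, modality), favored in sorted(FAVORED.items()):
            per_cancer = {}
            for ct in sorted(config.cancer_types):
                sub = events[
                    (events["role"] == role)
                    & (events["modality"] == modality)
                    & (events["cancer_type"] == ct)
                ]
                if len(sub):
                    per_cancer[ct] = (int((sub["direction"] == favored).sum()), len(sub))
            averages[f"{role}/{modality}/{favored}"] = average_frequency(per_cancer)
            sign = {v: k for k, v in DIRECTION_LABELS[modality].items()}[favored]
            bg = {}
            for ct in sorted(config.cancer_types):
                key = (ct, modality)
                if key in merged_by_key and len(merged_by_key[key]):
                    bg[ct] = background_frequency(merged_by_key[key], sign)
            backgrounds[f"{role}/{modality}/{favored}"] = bg
        bias = {"tests": bias, "average_frequencies": averages, "background_frequencies": backgrounds}

    stratified: dict = {}
    if catalog is not None and annotation is not None and expr_pair_first is not None:
        _, pair = expr_pair_first
        genes = config.stratify_genes or catalog["gene"].head(3).tolist()
        for gene in genes:
            res = stratify_and_test(gene, pair.cohort_a, annotation)
            records = res.where(pd.notna(res), None).to_dict(orient="records")
            stratified[gene] = {
                "strata": records,
                "reversal": reversal_report(res),
            }

    provenance = {
        "config": json.loads(config.canonical()),
        "root_seed": root,
        "stage_seeds": seeds_used,
        "versions": {
            "concordia": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    def _tsv(df: pd.DataFrame) -> str:
        return df.to_csv(sep="\t", index=False, float_format="%.6g")

    bundle = {
        "concordance_long.tsv": _tsv(concordance_long),
        "agreement_table.tsv": table1.to_csv(sep="\t"),
        "merged_calls.tsv": _tsv(merged_all),
        "events.tsv": _tsv(events),
        "bias_tests.json": json.dumps(bias, indent=2, sort_keys=True),
        "stratified.json": json.dumps(stratified, indent=2, sort_keys=True),
        "provenance.json": json.dumps(provenance, indent=2, sort_keys=True),
    }
    return bundle


def write_bundle(bundle: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, content in sorted(bundle.items()):
        (outdir / name).write_text(content)
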