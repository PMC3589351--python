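import numpy as np
import pandas as pd
import pytest

from concordia.datatypes import CALL_COLUMNS, OmicsMatrix
from concordia.synthetic import CohortSpec, generate_expression_pair


def calls_frame(rows, dataset="A", modality="expression"):
    """Build a calls frame from (gene, direction) or full tuples."""
    out = []
    for r in rows:
        gene, direction = r[0], r[1]
        out.append(
            {
                "gene": gene,
                "direction": direction,
                "statistic": float(direction),
                "q_value": 0.01,
                "dataset": dataset,
                "modality": modality,
            }
        )
    return pd.DataFrame(out, columns=CALL_COLUMNS)


def small_matrix(values, n_cancer, n_normal, modality="expression", dataset="A"):
    """OmicsMatrix from a gene→row-of-values dict; cancer columns first."""
    genes = list(values)
    arr = np.array([values[g] for g in genes], dtype=float)
    samples = [f"T{i}" for i in range(n_cancer)] + [f"N{i}" for i in range(n_normal)]
    labels = pd.Series(["cancer"] * n_cancer + ["normal"] * n_normal, index=samples)
    df = pd.DataFrame(arr, index=pd.Index(genes, name="gene"), columns=samples)
    return OmicsMatrix(df, labels, modality, dataset)


@pytest.fixture(scope="session")
def planted_pair():
    """One moderately sized expression pair with 95% planted consistency."""
    spec = CohortSpec(
        n_genes=2000,
        n_cancer=30,
        n_normal=30,
        frac_de=0.1,
        effect_size=1.5,
        noise_sd=0.5,
        consistency=0.95,
        seed=7,
    )
    return spec, generate_expression_pair(spec)
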