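import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import endotrio as et
from endotrio.cohort import TrioCohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def universe():
    return et.generate_gene_universe(300, seed=101)


@pytest.fixture(scope="session")
def norms():
    from endotrio.synthetic_data import default_norms

    return default_norms()


@pytest.fixture(scope="session")
def small_cohort(universe):
    spec = et.CohortSpec(n_trios=25, n_genes=300, seed=202)
    return et.generate_trio_cohort(spec, universe)


def build_cohort(variant_rows, gt, dp=None, child_sex=None):
    """Hand-built cohort: variant_rows is a list of dicts (chrom, pos, ref,
    alt, gene, func_class, dscore, maf, optionally filter_tag/mean_depth),
    gt an (n_sites, n_trios, 3) nested list."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_trios = gt.shape[0], gt.shape[1]
    defaults = {
        "ref": "A",
        "alt": "G",
        "consequence": "nonsynonymous SNV",
        "func_class": "missense",
        "dscore": 5,
        "maf": 0.001,
        "filter_tag": "PASS",
        "mean_depth": 60.0,
    }
    rows = []
    for i, r in enumerate(variant_rows):
        row = {"chrom": "1", "pos": 1000 + i, "gene": "GENE1", **defaults, **r}
        rows.append(row)
    variants = pd.DataFrame(rows)[
        ["chrom", "pos", "ref", "alt", "gene", "consequence", "func_class",
         "dscore", "maf", "filter_tag", "mean_depth"]
    ]
    fam = [f"fam{i:03d}" for i in range(n_trios)]
    trios = pd.DataFrame(
        {
            "trio_id": fam,
            "father_id": [f + ".fa" for f in fam],
            "mother_id": [f + ".mo" for f in fam],
            "child_id": [f + ".p1" for f in fam],
            "child_sex": child_sex or ["female"] * n_trios,
        }
    )
    if dp is None:
        dp = np.full(gt.shape, 60, dtype=np.int32)
    return TrioCohort(variants=variants, trios=trios, gt=gt, dp=np.asarray(dp, dtype=np.int32))
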