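import numpy as np
import pandas as pd
import pytest

import swabcohort as sc
from swabcohort.taxonomy import Lineage


def make_lineage(family="Enterococcaceae", genus="Enterococcus"):
    return Lineage(kingdom="Bacteria", phylum="Firmicutes", class_="Bacilli",
                   order="Lactobacillales", family=family, genus=genus)


def make_table(counts: dict, lineages: dict | None = None,
               taxon_ids=None) -> sc.TaxonCountTable:
    """Small count table from {sample: [counts...]} column dict."""
    frame = pd.DataFrame(counts)
    if taxon_ids is None:
        taxon_ids = [f"T{i + 1}" for i in range(len(frame))]
    frame.index = pd.Index(taxon_ids, name="taxon_id")
    if lineages is None:
        lineages = {t: make_lineage() for t in taxon_ids}
    return sc.TaxonCountTable(frame, lineages)


@pytest.fixture(scope="session")
def three_leaf_tree() -> sc.PhyloTree:
    """((A:1,B:1):1,C:2):0; — total branch length 5."""
    from io import StringIO

    from skbio import TreeNode
    return sc.PhyloTree(TreeNode.read(StringIO("((A:1,B:1):1,C:2):0;")))


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (seed 1), QC'd and classified."""
    cfg = sc.SyntheticCohortConfig(seed=1)
    table, records, intervals, tree, truth = sc.generate_cohort(cfg)
    report, rarefied = sc.run_qc_cascade(table, records, seed=1)
    return {
        "config": cfg, "table": table, "records": records,
        "intervals": intervals, "tree": tree, "truth": truth,
        "report": report, "rarefied": rarefied,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
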