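import numpy as np
import pandas as pd
import pytest

from soilshift import OtuTable, SampleGroups
from soilshift.otu_report import RANKS, UNCLASSIFIED


def make_table(counts, lineages=None, otu_ids=None, sample_ids=None) -> OtuTable:
    """Build an OtuTable from a plain count matrix, defaulting lineages."""
    counts = np.asarray(counts)
    n_otus, n_samples = counts.shape
    otu_ids = otu_ids or [f"otu{i}" for i in range(n_otus)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    if lineages is None:
        lineages = [
            ["Bacteria", "PhyX", "ClsX", "OrdX", "FamX", f"Gen{i}"]
            for i in range(n_otus)
        ]
    return OtuTable(
        pd.DataFrame(counts, index=otu_ids, columns=sample_ids),
        pd.DataFrame(lineages, index=otu_ids, columns=list(RANKS)),
    )


def make_groups(sample_ids, soils, treatments, replicates=None) -> SampleGroups:
    replicates = replicates or list(range(1, len(sample_ids) + 1))
    frame = pd.DataFrame(
        {"soil": soils, "treatment": treatments, "replicate": replicates},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SampleGroups(frame)


@pytest.fixture
def mixed_lineage_table() -> OtuTable:
    """Five OTUs covering two phyla, shared genera and unclassified bins."""
    lineages = [
        ["Bacteria", "Proteobacteria", "Alphaproteobacteria", "Sphingomonadales",
         "Sphingomonadaceae", "Sphingomonas"],
        ["Bacteria", "Proteobacteria", "Alphaproteobacteria", "Sphingomonadales",
         "Sphingomonadaceae", "Sphingomonas"],
        ["Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales",
         "Comamonadaceae", UNCLASSIFIED],
        ["Bacteria", "Actinobacteria", "Actinobacteridae", "Corynebacterineae",
         "Mycobacteriaceae", UNCLASSIFIED],
        ["Bacteria", "Actinobacteria", UNCLASSIFIED, UNCLASSIFIED,
         UNCLASSIFIED, UNCLASSIFIED],
    ]
    counts = [
        [3, 1, 0, 2],
        [4, 0, 1, 1],
        [2, 5, 3, 0],
        [1, 2, 0, 4],
        [0, 2, 6, 3],
    ]
    return make_table(counts, lineages=lineages)
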