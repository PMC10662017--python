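import numpy as np
import pandas as pd
import pytest

from tumbiome.taxa import TaxonCountTable, TaxonLineage

KRAKEN_REPORT_A = """\
 50.00\t500\t0\tR\t1\troot
 45.00\t450\t0\tD\t2759\t  Eukaryota
 45.00\t450\t450\tS\t9606\t    Homo sapiens
 40.00\t400\t0\tD\t2\t  Bacteria
 30.00\t300\t0\tG\t561\t    Escherichia
 20.00\t200\t200\tS\t562\t      Escherichia coli
 10.00\t100\t100\tS\t564\t      Escherichia fergusonii
 10.00\t100\t100\tS\t1351\t    Enterococcus faecalis
"""

KRAKEN_REPORT_B = """\
 50.00\t600\t0\tR\t1\troot
 45.00\t300\t300\tS\t9606\t  Homo sapiens
 40.00\t300\t0\tD\t2\t  Bacteria
 30.00\t300\t0\tG\t561\t    Escherichia
 30.00\t300\t300\tS\t562\t      Escherichia coli
"""


@pytest.fixture
def kraken_paths(tmp_path):
    pa = tmp_path / "sampleA.report"
    pb = tmp_path / "sampleB.report"
    pa.write_text(KRAKEN_REPORT_A)
    pb.write_text(KRAKEN_REPORT_B)
    return {"A": pa, "B": pb}


def make_table(counts: dict, human: dict, lineages: dict | None = None) -> TaxonCountTable:
    """Hand-rolled TaxonCountTable with flat species lineages by default."""
    df = pd.DataFrame(counts)
    if lineages is None:
        lineages = {
            t: TaxonLineage(taxid=t, name=f"species{t}", rank="species", parent_taxid=None)
            for t in df.index
        }
    return TaxonCountTable(counts=df, lineages=lineages, human_reads=pd.Series(human))


@pytest.fixture
def toy_table():
    counts = {
        "s1": pd.Series({10: 8, 11: 0, 12: 30}),
        "s2": pd.Series({10: 0, 11: 12, 12: 5}),
        "s3": pd.Series({10: 7, 11: 9, 12: 100}),
    }
    return make_table(counts, {"s1": 100, "s2": 200, "s3": 400})
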