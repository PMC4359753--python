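"""Small bundled example datasets.

Currently one table: karyotype counts from a published laboratory
thermal-selection experiment in *Drosophila melanogaster*, in which polytene
karyotyping of 275 chromosomes scored six cosmopolitan inversions in a base
population and in three replicate populations per selection regime ('hot',
generation 60; 'cold', generation 34).
"""

from __future__ import annotations

from importlib import resources

from poolinv.io_formats import KaryotypeCountTable, read_karyotype_counts

#: Replicate population labels per selection regime in the bundled table.
LNS_REGIMES = {
    "cold": ["Cold - R1", "Cold - R2", "Cold - R3"],
    "hot": ["Hot - R1", "Hot - R2", "Hot - R3"],
}


def lns_karyotype_counts() -> KaryotypeCountTable:
    """Karyotype counts of the thermal-selection experiment (Base + 6 replicates)."""
    ref = resources.files("poolinv") / "data" / "karyotype_counts_lns.tsv"
    with resources.as_file(ref) as path:
        return read_karyotype_counts(path)
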