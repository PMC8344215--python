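#!/usr/bin/env python
"""Infer the ancestral mitochondrial karyotype of Polyplax lice.

Runs the two-rule parsimony reconstruction on the fixed sucking-louse
phylogeny with the three Polyplax karyotypes as the ingroup and the
sucking-louse ancestral karyotype as the outgroup-side reference.  The
result has 11 minichromosomes with a single equally parsimonious ambiguity
(the S1-S2 cluster: upstream of rrnS, or downstream of nad1).  Writes one
.kyt file per variant plus a per-character change-count table under
results/analysis/.
"""

from pathlib import Path

import pandas as pd

from lousemito.fixtures import (
    POLYPLAX_TAXA,
    polyplax_karyotypes,
    sucking_lice_mrca,
    sucking_lice_tree,
)
from lousemito.karyotype import write_karyotype
from lousemito.parsimony import infer_ancestor

OUT = Path("results/analysis")


def main() -> None:
    res = infer_ancestor(
        sucking_lice_tree(),
        polyplax_karyotypes(),
        ingroup=set(POLYPLAX_TAXA),
        outgroup_reference=sucking_lice_mrca(),
        taxon="Polyplax_MRCA",
    )
    print(f"variants: {len(res.variants)} (each {len(res.variants[0].minichromosomes)} minichromosomes)")
    for i, v in enumerate(res.variants, 1):
        print(f"variant {i}: {v}")
    for unit, options in res.alternatives:
        print(f"equally parsimonious placements for {'-'.join(unit)}: {len(options)}")
    OUT.mkdir(parents=True, exist_ok=True)
    for i, v in enumerate(res.variants, 1):
        (OUT / f"02_polyplax_mrca_variant{i}.kyt").write_text(write_karyotype(v))
    pd.DataFrame(
        {
            "character": ["-".join(u) for u in sorted(res.per_character_changes)],
            "min_changes": [
                res.per_character_changes[u]
                for u in sorted(res.per_character_changes)
            ],
        }
    ).to_csv(OUT / "02_character_changes.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
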