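"""Quantify PSI per event x tissue x replicate x allele set and apply the
expression (min 20 reads/replicate), constitutive (PSI always >0.9 or
<0.1) and allelic-consistency filters."""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from _util import make_parser, require_dataset

from allelesplice import psi as ps
from allelesplice.io import write_tsv


def main() -> None:
    args = make_parser(__doc__).parse_args()
    ds = require_dataset(args)
    out = os.path.join(args.results, "psi")

    psi = ps.psi_table(ds.counts, ds.config.lengths)
    write_tsv(psi, os.path.join(out, "psi.tsv"))
    exp_total = ps.is_expressed(ds.counts, "total", n_replicates=ds.config.replicates)
    exp_allelic = ps.is_expressed(ds.counts, "allelic", n_replicates=ds.config.replicates)
    write_tsv(exp_total, os.path.join(out, "expressed_total.tsv"))
    write_tsv(exp_allelic, os.path.join(out, "expressed_allelic.tsv"))
    constit = ps.filter_constitutive(psi, exp_total, mode="total")
    write_tsv(constit, os.path.join(out, "constitutive.tsv"))
    consistency = ps.consistency_filter(ds.counts, ds.config.lengths)
    write_tsv(consistency, os.path.join(out, "consistency.tsv"))

    n_expr = int(exp_total["expressed"].sum())
    print(f"{len(psi)} PSI cells; {n_expr} expressed event x tissue cells "
          f"(total mode); {int(constit['constitutive'].sum())} constitutive events "
          f"dropped; {int((~consistency['consistent']).sum())} cells fail the "
          f"allelic-consistency check")


if __name__ == "__main__":
    main()
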