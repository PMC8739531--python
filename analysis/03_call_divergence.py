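"""Call per-tissue allelic divergence (moderated beta-binomial LRT,
BH within tissue, FDR < 0.05 and |dPSI| >= 0.1), group events across
tissues and score genes (SDS)."""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from _util import make_parser, require_dataset

from allelesplice import pipeline as pl
from allelesplice.io import write_tsv


def main() -> None:
    args = make_parser(__doc__).parse_args()
    ds = require_dataset(args)
    out = os.path.join(args.results, "divergence")

    res = pl.run_divergence(ds)
    write_tsv(res.calls, os.path.join(out, "calls.tsv"))
    write_tsv(res.groups, os.path.join(out, "groups.tsv"))
    write_tsv(res.gene_sds, os.path.join(out, "gene_sds.tsv"))
    write_tsv(res.switch, os.path.join(out, "switch.tsv"))
    write_tsv(res.scenarios, os.path.join(out, "scenarios.tsv"))

    n_div = int(res.calls["divergent"].sum())
    print(f"{len(res.calls)} event x tissue tests, {n_div} divergent; "
          f"groups: {res.groups['group'].value_counts().to_dict()}; "
          f"gene SDS groups: {res.gene_sds['group'].value_counts().to_dict()}")


if __name__ == "__main__":
    main()
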