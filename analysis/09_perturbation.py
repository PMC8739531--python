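"""Compare allelic divergence between the DMSO control and the
pladienolide-B-treated cell line: classify events as divergent in both,
treatment only, control only or neither, and check whether treatment-only
divergence points in the same direction as the tissue-level divergence."""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from _util import make_parser, require_dataset

from allelesplice import pipeline as pl
from allelesplice.io import write_tsv


def main() -> None:
    args = make_parser(__doc__).parse_args()
    ds = require_dataset(args)
    out = os.path.join(args.results, "perturbation")

    res = pl.run_divergence(ds)
    prt = pl.run_perturbation(ds, res)
    write_tsv(prt["per_event"], os.path.join(out, "per_event.tsv"))
    import pandas as pd
    write_tsv(pd.DataFrame([prt["summary"]]), os.path.join(out, "summary.tsv"))

    s = prt["summary"]
    print(f"{s['n_shared']} events in both conditions: "
          f"both {s['n_both']}, treatment-only {s['n_treatment_only']}, "
          f"control-only {s['n_control_only']}, neither {s['n_neither']}; "
          f"direction consistency of treatment-only events "
          f"{s['direction_consistency']:.1%}")


if __name__ == "__main__":
    main()
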