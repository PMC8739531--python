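"""Generate the synthetic F1-hybrid dataset under the standard study
conditions: 2,000 skipped-exon events, 7 tissues, 2 replicates, 2 alleles
plus common reads, a DMSO/pladB perturbation pair, variants, conservation,
gene annotations and out-group PSI observations, with full ground truth."""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from _util import data_dir, make_parser

from allelesplice.simulate import SimulationConfig, simulate_dataset, write_dataset


def main() -> None:
    parser = make_parser(__doc__)
    parser.add_argument("--n-events", type=int, default=None,
                        help="override the number of events")
    args = parser.parse_args()
    cfg = SimulationConfig() if args.n_events is None else \
        SimulationConfig(n_events=args.n_events)
    ds = simulate_dataset(cfg, seed=args.seed)
    out = data_dir(args)
    write_dataset(ds, out)
    n_cis = int((ds.truth_events["cis_effect"].abs() > 0).sum())
    print(f"wrote {len(ds.events)} events ({n_cis} with cis effects, "
          f"{int(ds.truth_events['microexon'].sum())} micro-exons), "
          f"{len(ds.counts)} count rows, {len(ds.variants)} variants -> {out}")


if __name__ == "__main__":
    main()
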