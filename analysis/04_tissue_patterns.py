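"""Classify tissue-dependent allelic divergence into the four scenarios,
summarize scenario magnitudes, micro-exon enrichment, per-tissue pairwise
divergence patterns and the switch-group / divergence-group concordance."""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from _util import make_parser, require_dataset, require_table

from allelesplice import patterns as pt
from allelesplice import psi as ps
from allelesplice.io import write_tsv


def main() -> None:
    args = make_parser(__doc__).parse_args()
    ds = require_dataset(args)
    calls = require_table(args, "divergence/calls.tsv")
    scenarios = require_table(args, "divergence/scenarios.tsv")
    out = os.path.join(args.results, "patterns")

    medians, p23 = pt.scenario_magnitudes(scenarios)
    write_tsv(medians.rename("median_dpsi_t").reset_index(),
              os.path.join(out, "scenario_magnitudes.tsv"))

    micro = ds.truth_events[["event_id", "microexon"]]
    cats = scenarios[["event_id", "scenario"]].rename(columns={"scenario": "category"})
    enrich = pt.microexon_enrichment(cats, micro)
    write_tsv(enrich, os.path.join(out, "microexon_by_scenario.tsv"))

    rows = []
    for tissue in ds.config.tissues:
        props = pt.pairwise_divergence_pattern(tissue, calls)
        if not props.empty:
            rows.append(props.rename(tissue))
    write_tsv(pd.DataFrame(rows).rename_axis("tissue").reset_index(),
              os.path.join(out, "pairwise_patterns.tsv"))

    # per-allele switch groups vs divergence groups
    psi = ps.psi_table(ds.counts, ds.config.lengths, allele_sets=("BL6", "SPR"))
    mean_psi = ps.replicate_mean_psi(psi)
    per_allele = []
    for allele in ("BL6", "SPR"):
        sw = pt.switch_score(mean_psi[mean_psi["allele_set"] == allele])
        sw["allele"] = allele
        per_allele.append(sw)
    groups = require_table(args, "divergence/groups.tsv")
    concord = pt.allele_switch_concordance(pd.concat(per_allele), groups)
    write_tsv(concord.reset_index(), os.path.join(out, "switch_vs_divergence.tsv"))

    print(f"scenarios: {scenarios['scenario'].value_counts().to_dict()}; "
          f"median tissue change scenario 2 vs 3: "
          f"{medians.get(2, float('nan')):.3f} vs {medians.get(3, float('nan')):.3f} "
          f"(one-sided rank-sum p = {p23:.2e})")


if __name__ == "__main__":
    main()
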