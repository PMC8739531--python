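"""Annotate every event with variant density, splice-site variant
presence, PWM splice-site strength deltas between alleles, CDS overlap,
exon conservation, and build conservation meta-profiles per divergence
group."""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from _util import make_parser, require_dataset, require_table

import pandas as pd

from allelesplice import features as ft
from allelesplice.io import parse_cds, write_tsv


def main() -> None:
    args = make_parser(__doc__).parse_args()
    ds = require_dataset(args)
    out = os.path.join(args.results, "features")

    cds_by_gene = {r.gene_id: parse_cds(r.cds) for r in ds.genes.itertuples(index=False)}
    feats = ft.event_features(ds.events, ds.variants, track=ds.conservation,
                              cds_by_gene=cds_by_gene)

    # PWM scorer trained on the BL6 windows of the whole event set
    seqs = ds.site_seqs.pivot(index="event_id", columns="allele",
                              values=["donor_seq", "acceptor_seq"])
    scorer = ft.PwmScorer.train(list(seqs["donor_seq"]["BL6"]),
                                list(seqs["acceptor_seq"]["BL6"]))
    deltas = [
        ft.splice_strength_delta(seqs["donor_seq"]["BL6"].loc[ev],
                                 seqs["acceptor_seq"]["BL6"].loc[ev],
                                 seqs["donor_seq"]["SPR"].loc[ev],
                                 seqs["acceptor_seq"]["SPR"].loc[ev], scorer)
        for ev in feats["event_id"]
    ]
    feats["splice_strength_delta"] = deltas
    write_tsv(feats, os.path.join(out, "features.tsv"))

    groups = require_table(args, "divergence/groups.tsv")
    group_map = dict(zip(groups["event_id"], groups["group"]))
    profile = ft.conservation_profile(ds.events, ds.conservation, group_map)
    write_tsv(profile, os.path.join(out, "conservation_profile.tsv"))

    with_delta = feats[feats["splice_strength_delta"] > 0]
    print(f"{len(feats)} events annotated; mean variant density "
          f"{feats['variant_density'].mean():.4f}/nt; "
          f"{int(feats['has_splice_site_variant'].sum())} with splice-site "
          f"variants; {len(with_delta)} with nonzero strength delta; "
          f"profile groups: {sorted(profile['group'].unique())}")


if __name__ == "__main__":
    main()
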