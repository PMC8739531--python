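"""Out-group comparison: orthologous-event matching and classification of
the BL6 / SPR alleles as ancestral (conserved) or derived.

The F1 design shows that the alleles differ, but not which one moved.
Comparing each allele's PSI with the orthologous event in out-group
species (M. caroli, M. pahari) polarizes the change: the allele whose
splicing matches the out-group carries the ancestral pattern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERMEDIATE_BAND = 0.05
OUTGROUP_TISSUES = ("cortex", "heart", "kidney", "liver")
# host tissue -> out-group tissue naming (cortex was profiled as whole brain)
TISSUE_MAP = {"cortex": "brain"}


def sequence_identity(a: str, b: str) -> float:
    """Ungapped end-to-end identity of two same-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    if not a:
        raise ValueError("empty sequence")
    return sum(x == y for x, y in zip(a.upper(), b.upper())) / len(a)


def match_ortholog(event_exon_seqs: list[str], candidate_exon_seqs: list[str],
                   min_identity: float = 0.90) -> bool:
    """True iff each of the three host exons (upstream, alternative,
    downstream, in transcript order) has a same-size out-group exon with
    identity > min_identity, occurring in the same order.

    candidate_exon_seqs: the out-group gene's exon sequences in transcript
    order (any number of exons).
    """
    if len(event_exon_seqs) != 3:
        raise ValueError("an event supplies exactly three exon sequences")
    pos = 0
    for host in event_exon_seqs:
        found = None
        for j in range(pos, len(candidate_exon_seqs)):
            cand = candidate_exon_seqs[j]
            if len(cand) == len(host) and sequence_identity(host, cand) > min_identity:
                found = j
                break
        if found is None:
            return False
        pos = found + 1
    return True


def classify_tissue(psi_bl6: float, psi_spr: float,
                    outgroup_psis: dict,
                    band: float = INTERMEDIATE_BAND) -> str | None:
    """Per-tissue ancestry label from one or two out-group observations.

    outgroup_psis: species -> PSI of the orthologous event in the matched
    tissue. An out-group value within mean(allele PSIs) +/- band (closed
    interval) is "intermediate"; otherwise it is labeled after the closer
    allele (an exact tie resolves to intermediate). Two out-groups must
    agree; a disagreement (or two intermediates) is "ambiguous". Returns
    None with no out-group data.
    """
    if not outgroup_psis:
        return None
    if not (np.isfinite(psi_bl6) and np.isfinite(psi_spr)):
        return None
    avg = 0.5 * (psi_bl6 + psi_spr)
    labels = []
    for og in outgroup_psis.values():
        if abs(og - avg) <= band:
            labels.append("intermediate")
        else:
            d_b = abs(og - psi_bl6)
            d_s = abs(og - psi_spr)
            if d_b == d_s:
                labels.append("intermediate")
            else:
                labels.append("BL6-like" if d_b < d_s else "SPR-like")
    if len(labels) == 1:
        return labels[0] if labels[0] != "intermediate" else "ambiguous"
    a, b = labels
    if a == b:
        return "ambiguous" if a == "intermediate" else a
    if "intermediate" in (a, b):
        other = a if b == "intermediate" else b
        return other
    return "ambiguous"  # one BL6-like, one SPR-like


def classify_overall(label_1: str, label_2: str,
                     abs_delta_1: float, abs_delta_2: float) -> str:
    """Overall ancestry call from the two tissues of the max-ddPSI pair.

    label_i in {BL6-like, SPR-like, ambiguous}; abs_delta_i is
    |dPSI_allelic| in that tissue (breaks the one-ambiguous case).
    """
    conserved = {"BL6-like": "BL6-conserved", "SPR-like": "SPR-conserved"}
    amb1 = label_1 == "ambiguous"
    amb2 = label_2 == "ambiguous"
    if amb1 and amb2:
        return "ambiguous"
    if not amb1 and not amb2:
        if label_1 == label_2:
            return conserved[label_1]
        return "excluded"
    decided = label_2 if amb1 else label_1
    # one ambiguous: take the unambiguous tissue, unless the ambiguous one
    # has the larger allelic divergence, in which case no call can be made
    larger_is_ambiguous = (abs_delta_1 > abs_delta_2) if amb1 else (abs_delta_2 > abs_delta_1)
    if larger_is_ambiguous:
        return "ambiguous"
    return conserved[decided]


def ancestry_calls(calls: pd.DataFrame, outgroup: pd.DataFrame,
                   band: float = INTERMEDIATE_BAND) -> pd.DataFrame:
    """Overall ancestry per event from the divergence-call table and the
    out-group PSI observations.

    calls: per event x tissue with psi_bl6, psi_spr, delta_psi (baseline).
    outgroup: (species, tissue, event_id, psi) with out-group tissue
    names. Only the four tissues with out-group data are used; the tissue
    pair with the largest ddPSI decides the overall call.
    """
    og_by_event: dict = {}
    for r in outgroup.itertuples(index=False):
        og_by_event.setdefault(r.event_id, {}).setdefault(r.tissue, {})[r.species] = r.psi

    rows = []
    for event_id, sub in calls.groupby("event_id"):
        if event_id not in og_by_event:
            continue
        sub = sub[sub["tissue"].isin(OUTGROUP_TISSUES)].dropna(subset=["psi_bl6", "psi_spr"])
        per_tissue = {}
        for r in sub.itertuples(index=False):
            og_tissue = TISSUE_MAP.get(r.tissue, r.tissue)
            ogs = og_by_event[event_id].get(og_tissue, {})
            lab = classify_tissue(r.psi_bl6, r.psi_spr, ogs, band)
            if lab is not None:
                per_tissue[r.tissue] = (lab, abs(r.delta_psi), r.delta_psi)
        if len(per_tissue) < 2:
            if len(per_tissue) == 1:
                (lab, _, _), = per_tissue.values()
                overall = {"BL6-like": "BL6-conserved", "SPR-like": "SPR-conserved",
                           "ambiguous": "ambiguous"}[lab]
                rows.append((event_id, overall))
            continue
        # tissue pair with the largest ddPSI among labeled tissues
        tissues = sorted(per_tissue)
        best = None
        for i in range(len(tissues)):
            for j in range(i + 1, len(tissues)):
                dd = abs(per_tissue[tissues[i]][2] - per_tissue[tissues[j]][2])
                if best is None or dd > best[0]:
                    best = (dd, tissues[i], tissues[j])
        _, t1, t2 = best
        overall = classify_overall(per_tissue[t1][0], per_tissue[t2][0],
                                   per_tissue[t1][1], per_tissue[t2][1])
        rows.append((event_id, overall))
    return pd.DataFrame(rows, columns=["event_id", "ancestry"])


def variable_allele_conservation(scenarios: pd.DataFrame,
                                 ancestry: pd.DataFrame) -> dict:
    """Among scenario-3 events with an ancestry call, how often does the
    variable (tissue-dependent) allele versus the stable allele carry the
    conserved (out-group-like) pattern?

    In scenario 3 exactly one allele changes between tissues; the event's
    conserved allele comes from the ancestry call. Returns the two
    proportions and the event count.
    """
    s3 = scenarios[scenarios["scenario"] == 3].merge(ancestry, on="event_id")
    s3 = s3[s3["ancestry"].isin(("BL6-conserved", "SPR-conserved"))]
    if s3.empty:
        return {"variable_conserved": np.nan, "stable_conserved": np.nan, "n": 0}
    variable_is_bl6 = s3["dpsi_t_bl6"].abs() > s3["dpsi_t_spr"].abs()
    variable_allele = np.where(variable_is_bl6, "BL6", "SPR")
    conserved_allele = np.where(s3["ancestry"] == "BL6-conserved", "BL6", "SPR")
    var_cons = float(np.mean(variable_allele == conserved_allele))
    return {"variable_conserved": var_cons, "stable_conserved": 1.0 - var_cons,
            "n": int(len(s3))}
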