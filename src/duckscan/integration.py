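"""Combine selection-scan and differential-expression evidence.

A candidate gene is one that is both a positively selected gene (PSG) and a
DEG in at least one of the four contrasts.  Candidates are classified from
their contrast-membership pattern: between-breed DE at 3 weeks points to
muscle growth (fibre phenotypes differ at that age), between-breed DE at
6 weeks to lipid deposition (intramuscular fat differs then), and DE only
across ages within a breed to overall breast growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Column order of the output candidate matrix.
CONTRAST_FLAGS = ["BD3vBD6", "CD3vCD6", "BD3vCD3", "BD6vCD6"]

LABEL_MUSCLE = "muscle-growth"
LABEL_LIPID = "lipid-deposition"
LABEL_BREAST = "breast-growth"


@dataclass
class CandidateRecord:
    gene_id: str
    psg: bool
    memberships: dict[str, bool]
    directions: dict[str, str] = field(default_factory=dict)
    labels: list[str] = field(default_factory=list)
    label_support: dict[str, list[str]] = field(default_factory=dict)
    pathways: str = ""


def combine_psg_deg(
    psgs, deg_sets: dict[str, dict[str, str] | set], pathways: dict[str, str] | None = None
) -> list[CandidateRecord]:
    """One record per gene in ``psgs`` that is a DEG in any contrast.

    ``deg_sets`` maps contrast name -> DEG ids (optionally with directions).
    Pathway strings, if supplied, are carried as free-text annotation.
    """
    psg_ids = list(dict.fromkeys(psgs))
    records = []
    for gene in psg_ids:
        memberships = {c: gene in deg_sets.get(c, ()) for c in CONTRAST_FLAGS}
        if not any(memberships.values()):
            continue
        directions = {}
        for c, members in deg_sets.items():
            if isinstance(members, dict) and gene in members:
                directions[c] = members[gene]
        records.append(
            CandidateRecord(
                gene_id=gene,
                psg=True,
                memberships=memberships,
                directions=directions,
                pathways=(pathways or {}).get(gene, ""),
            )
        )
    return records


def classify_candidates(records: list[CandidateRecord]) -> list[CandidateRecord]:
    """Label candidates from their membership pattern (pure function of it).

    muscle-growth when DE between breeds at 3 weeks; lipid-deposition when DE
    between breeds at 6 weeks; breast-growth when DE only within a breed
    across ages.  Multiple labels are permitted.
    """
    for rec in records:
        labels: list[str] = []
        support: dict[str, list[str]] = {}
        if rec.memberships.get("BD3vCD3"):
            labels.append(LABEL_MUSCLE)
            support[LABEL_MUSCLE] = ["BD3vCD3"]
        if rec.memberships.get("BD6vCD6"):
            labels.append(LABEL_LIPID)
            support[LABEL_LIPID] = ["BD6vCD6"]
        within = [c for c in ("BD3vBD6", "CD3vCD6") if rec.memberships.get(c)]
        between = [c for c in ("BD3vCD3", "BD6vCD6") if rec.memberships.get(c)]
        if within and not between:
            labels.append(LABEL_BREAST)
            support[LABEL_BREAST] = within
        rec.labels = labels
        rec.label_support = support
    return records


def candidate_table(records: list[CandidateRecord]) -> pd.DataFrame:
    """Candidate matrix in the check-mark layout of the combined analysis."""
    rows = []
    for rec in records:
        row = {"gene_id": rec.gene_id}
        for c in CONTRAST_FLAGS:
            row[f"DEG_{c}"] = rec.memberships.get(c, False)
        row["z_fst"] = rec.psg
        row["tajima_d"] = rec.psg
        row["labels"] = ";".join(rec.labels)
        row["pathways"] = rec.pathways
        rows.append(row)
    cols = (
        ["gene_id"] + [f"DEG_{c}" for c in CONTRAST_FLAGS]
        + ["z_fst", "tajima_d", "labels", "pathways"]
    )
    return pd.DataFrame(rows, columns=cols)
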