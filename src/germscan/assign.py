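"""Assigning genes to the germline-restricted (GSR) or somatic compartment.

A gene belongs to the GSR iff its span overlaps any germline-enriched
segment by at least one base (bedtools-intersect default semantics).
Before assignment, same-name gene records with overlapping spans are
collapsed to a single canonical record (longest span); same-name records on
disjoint spans are kept — they are paralogs, and family bookkeeping counts
copies per compartment by shared gene name.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .formats import GeneModel
from .scan import Segment

__all__ = [
    "dedupe_canonical",
    "assign_compartment",
    "family_summary",
]

DEFAULT_BIOTYPES = ("protein_coding",)


def dedupe_canonical(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Collapse same-name overlapping gene records to the canonical one.

    Within each (name, sequence) group, records whose spans overlap by >= 1 bp
    (transitively: overlap clusters) are reduced to the record with the
    longest span; ties break to the lexicographically smallest gene id.
    Disjoint same-name records all survive.  Output preserves input order.
    """
    keep: set[str] = set()
    by_group: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_group.setdefault((g.name, g.seq), []).append(g)
    for members in by_group.values():
        members_sorted = sorted(members, key=lambda g: (g.start, g.end, g.gene_id))
        # sweep for transitive overlap clusters
        cluster: list[GeneModel] = []
        cluster_end = -1
        clusters: list[list[GeneModel]] = []
        for g in members_sorted:
            if cluster and g.start < cluster_end:
                cluster.append(g)
                cluster_end = max(cluster_end, g.end)
            else:
                if cluster:
                    clusters.append(cluster)
                cluster = [g]
                cluster_end = g.end
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            best = min(cl, key=lambda g: (-(g.span), g.gene_id))
            keep.add(best.gene_id)
    return [g for g in genes if g.gene_id in keep]


def assign_compartment(
    genes: Sequence[GeneModel],
    enriched_segments: Iterable[Segment],
    biotypes: Sequence[str] | None = DEFAULT_BIOTYPES,
) -> pd.DataFrame:
    """Build the compartment table: one row per retained gene.

    genes must already be deduplicated.  biotypes restricts the table
    (default: protein_coding only — rRNA/tRNA/lncRNA records are dropped);
    pass None to keep every biotype.  A gene is 'GSR' iff it overlaps any
    enriched segment by >= 1 bp, else 'somatic'.

    Returns a DataFrame indexed by gene id with columns
    name, seq, start, end, strand, biotype, compartment, canonical.
    """
    trees: dict[str, IntervalTree] = {}
    seg_seqs: set[str] = set()
    for s in enriched_segments:
        trees.setdefault(s.seq, IntervalTree()).addi(s.start, s.end)
        seg_seqs.add(s.seq)
    known_seqs = seg_seqs | {g.seq for g in genes}

    rows = []
    for g in genes:
        if g.seq not in known_seqs:  # pragma: no cover — defensive
            raise ValueError(f"gene {g.gene_id!r} on unknown sequence {g.seq!r}")
        if biotypes is not None and g.biotype not in biotypes:
            continue
        tree = trees.get(g.seq)
        in_gsr = bool(tree is not None and tree.overlap(g.start, g.end))
        rows.append(
            {
                "gene_id": g.gene_id,
                "name": g.name,
                "seq": g.seq,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "biotype": g.biotype,
                "compartment": "GSR" if in_gsr else "somatic",
                "canonical": True,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "name",
            "seq",
            "start",
            "end",
            "strand",
            "biotype",
            "compartment",
            "canonical",
        ],
    ).set_index("gene_id")
    return table


def family_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-family copy counts by compartment.

    Family = shared gene name.  Returns a DataFrame indexed by family name
    with columns gsr_copies, somatic_copies, single_copy_gsr (exactly one GSR
    copy) and has_somatic_paralog (copies in both compartments).  Only
    families with at least one copy are listed.
    """
    counts = (
        table.groupby(["name", "compartment"]).size().unstack(fill_value=0)
    )
    for col in ("GSR", "somatic"):
        if col not in counts.columns:
            counts[col] = 0
    out = pd.DataFrame(
        {
            "gsr_copies": counts["GSR"],
            "somatic_copies": counts["somatic"],
        }
    )
    out["single_copy_gsr"] = out["gsr_copies"] == 1
    out["has_somatic_paralog"] = (out["gsr_copies"] >= 1) & (out["somatic_copies"] >= 1)
    out.index.name = "family"
    return out.sort_index()
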