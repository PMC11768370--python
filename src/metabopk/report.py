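"""Integrated report: network communities joined with pathway enrichment.

One record per retained association edge, annotated with the metabolite's
Leiden module and every enriched pathway containing it. Metabolites outside
any enriched pathway are kept (left join) with an empty pathway list and a
flag — dropping them would misstate the network's output shape.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["integrate", "write_report_markdown"]


def integrate(
    edges: pd.DataFrame,
    partition: dict,
    enrichment: pd.DataFrame,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Join retained edges with enriched-pathway membership.

    ``edges`` is a build_edges table (retained rows are used), ``partition``
    a node → module mapping, ``enrichment`` an enrich_report table. Raises
    when the id spaces are fully disjoint (no edge metabolite appears in any
    tested pathway), which indicates a misconfigured id mapping.
    """
    retained = edges[edges["retained"]] if "retained" in edges.columns else edges
    pathway_of: dict[str, list[str]] = {}
    if len(enrichment) > 0:
        rows = (
            enrichment[enrichment["significant"]]
            if significant_only
            else enrichment
        )
        for _, row in rows.iterrows():
            for hit in str(row["hit_ids"]).split(";"):
                if hit:
                    pathway_of.setdefault(hit, []).append(row["pathway_id"])
        tested_universe = {
            hit
            for ids in enrichment["hit_ids"]
            for hit in str(ids).split(";")
            if hit
        }
        edge_mets = set(retained["metabolite_id"])
        if edge_mets and tested_universe and not (edge_mets & tested_universe):
            raise ValueError(
                "no overlap between edge metabolites and enrichment hits; "
                "check the metabolite id mapping between the two inputs"
            )
    records = []
    for _, row in retained.iterrows():
        met = row["metabolite_id"]
        pws = sorted(pathway_of.get(met, []))
        records.append(
            {
                "module": partition.get(met, -1),
                "metabolite_id": met,
                "parameter_name": row["parameter_name"],
                "parameter_class": row["parameter_class"],
                "d": row["d"],
                "sign": row["sign"],
                "q": row["q"],
                "pathway_ids": ";".join(pws),
                "no_enriched_pathway": len(pws) == 0,
            }
        )
    out = pd.DataFrame(
        records,
        columns=[
            "module",
            "metabolite_id",
            "parameter_name",
            "parameter_class",
            "d",
            "sign",
            "q",
            "pathway_ids",
            "no_enriched_pathway",
        ],
    )
    return out.sort_values(
        ["module", "metabolite_id", "parameter_name"], kind="stable"
    ).reset_index(drop=True)


def write_report_markdown(records: pd.DataFrame, path) -> None:
    """Markdown rendering of the integrated table, one section per module."""
    lines = ["# Integrated network–pathway report", ""]
    if len(records) == 0:
        lines.append("No retained edges.")
    for module, grp in records.groupby("module", sort=True):
        lines.append(f"## Module {module}")
        lines.append("")
        lines.append("| Metabolite | Parameter | Class | d | sign | q | Pathways |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, row in grp.iterrows():
            pw = row["pathway_ids"] or "(none enriched)"
            lines.append(
                f"| {row['metabolite_id']} | {row['parameter_name']} | "
                f"{row['parameter_class']} | {row['d']:.3f} | {row['sign']} | "
                f"{row['q']:.3g} | {pw} |"
            )
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
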