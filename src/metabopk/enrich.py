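"""Metabolite-set over-representation analysis (ORA).

Tests each pathway for over-representation of a selected metabolite set with
the one-sided (upper-tail) hypergeometric test, equivalent to one-sided
Fisher's exact on the 2×2 membership table. Pathways are testable when their
database size falls in [min_size, max_size] and they hit the selected set at
least ``min_hits`` times; BH-FDR is computed over the tested pathways only.

The background universe defaults to the measured features (those surviving
preprocessing) that appear anywhere in the database; the test counts pathway
membership within that background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats

from .diffabund import bh_adjust

__all__ = [
    "Pathway",
    "PathwayDB",
    "read_gmt",
    "write_gmt",
    "filter_pathways",
    "hypergeom_test",
    "enrich_report",
]


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    source: str
    members: frozenset

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")


class PathwayDB:
    """Pathway id → member metabolite ids, with a source label per pathway."""

    def __init__(self, pathways: Iterable[Pathway]):
        self.pathways: dict[str, Pathway] = {}
        for pw in pathways:
            if pw.pathway_id in self.pathways:
                raise ValueError(f"duplicate pathway id {pw.pathway_id!r}")
            self.pathways[pw.pathway_id] = pw
        if not self.pathways:
            raise ValueError("empty pathway database")

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self.pathways[pathway_id]

    def universe(self) -> set:
        out: set = set()
        for pw in self.pathways.values():
            out |= pw.members
        return out


def read_gmt(path) -> PathwayDB:
    """Read a GMT file: pathway_id <tab> source/description <tab> members..."""
    pathways = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            pathways.append(
                Pathway(
                    pathway_id=parts[0],
                    source=parts[1],
                    members=frozenset(parts[2:]),
                )
            )
    return PathwayDB(pathways)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(db.pathways):
            pw = db.pathways[pid]
            members = "\t".join(sorted(pw.members))
            fh.write(f"{pid}\t{pw.source}\t{members}\n")


def filter_pathways(
    db: PathwayDB,
    selected: set,
    min_size: int = 5,
    max_size: int = 150,
    min_hits: int = 1,
) -> list[str]:
    """Pathway ids testable under the size window and minimum-hit rule."""
    selected = set(selected)
    out = []
    for pid in sorted(db.pathways):
        pw = db.pathways[pid]
        size = len(pw.members)
        if size < min_size or size > max_size:
            continue
        if len(pw.members & selected) < min_hits:
            continue
        out.append(pid)
    return out


def hypergeom_test(
    n_hits: int, pathway_size: int, selected_size: int, background_size: int
) -> float:
    """One-sided upper-tail p = P(X ≥ n_hits) for the 2×2 overlap table.

    X ~ Hypergeometric(background_size, pathway_size, selected_size).
    """
    if not (
        0 <= n_hits <= min(pathway_size, selected_size)
        and pathway_size <= background_size
        and selected_size <= background_size
    ):
        raise ValueError(
            "inconsistent counts: hits={} pathway={} selected={} background={}".format(
                n_hits, pathway_size, selected_size, background_size
            )
        )
    return float(
        stats.hypergeom.sf(n_hits - 1, background_size, pathway_size, selected_size)
    )


def enrich_report(
    db: PathwayDB,
    selected: Iterable[str],
    background: Iterable[str] | None = None,
    alpha: float = 0.05,
    min_size: int = 5,
    max_size: int = 150,
    min_hits: int = 1,
    background_all_db: bool = False,
) -> pd.DataFrame:
    """ORA over all testable pathways, BH-adjusted and sorted by (q, p, id).

    ``background`` is the measured-feature universe (e.g. features surviving
    preprocessing); it is intersected with the database universe unless
    ``background_all_db`` forces the whole database as background. The
    selected set is clipped to the background.
    """
    universe = db.universe()
    if background is None or background_all_db:
        bg = set(universe)
    else:
        bg = set(background) & universe
    sel = set(selected) & bg
    columns = [
        "pathway_id",
        "source",
        "n_hits",
        "pathway_size",
        "background_size",
        "p",
        "q",
        "significant",
        "hit_ids",
    ]
    if not sel:
        return pd.DataFrame(columns=columns)
    testable = filter_pathways(
        db, sel, min_size=min_size, max_size=max_size, min_hits=min_hits
    )
    rows = []
    for pid in testable:
        pw = db.pathways[pid]
        members_bg = pw.members & bg
        hits = sorted(members_bg & sel)
        p = hypergeom_test(len(hits), len(members_bg), len(sel), len(bg))
        rows.append(
            {
                "pathway_id": pid,
                "source": pw.source,
                "n_hits": len(hits),
                "pathway_size": len(pw.members),
                "background_size": len(bg),
                "p": p,
                "hit_ids": ";".join(hits),
            }
        )
    if not rows:
        return pd.DataFrame(columns=columns)
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] <= alpha
    out = out.sort_values(["q", "p", "pathway_id"], kind="stable").reset_index(
        drop=True
    )
    return out[columns]
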