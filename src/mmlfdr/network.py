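"""Hub and direction summaries of a significant-edge set.

Once links have been selected at a given FDR level, the result is an
undirected graph over brain regions.  The reporting conventions are:

* **direction** — an edge is *hyper*connectivity when its FC statistic is
  positive (disease > control) and *hypo*connectivity when negative;
* **primary hub** — the region of maximal degree in the significant
  subgraph (ties reported as a list);
* **secondary hubs** — every other region with degree >= 2, i.e. at
  least two significantly higher or lower FCs to other regions.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .connectivity_io import canonical_pairs

logger = logging.getLogger(__name__)


@dataclass
class NetworkSummary:
    """Significant-edge network with degrees and hubs."""

    edges: pd.DataFrame             # region1, region2, tF, direction
    degree: dict                    # region -> count of incident edges
    primary_hub: list               # max-degree region(s)
    secondary_hubs: list            # degree >= 2, primary excluded
    n_hyper: int
    n_hypo: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def direction_counts(edges: pd.DataFrame) -> tuple[int, int]:
    """Count (hyper, hypo) edges by the sign of tF; zeros count as neither."""
    t = edges["tF"]
    n_zero = int((t == 0).sum())
    if n_zero:
        logger.warning("%d edge(s) with tF == 0 counted as neither direction", n_zero)
    return int((t > 0).sum()), int((t < 0).sum())


def summarize(edges: pd.DataFrame) -> NetworkSummary:
    """Summarize a decided edge list (columns region1, region2, tF).

    Edge order and within-edge region order are irrelevant.  An empty
    edge list yields an empty summary with no hubs.
    """
    edges = edges.loc[:, ["region1", "region2", "tF"]].copy()
    if len(edges):
        edges["region1"], edges["region2"] = canonical_pairs(
            edges["region1"], edges["region2"]
        )
        if edges.duplicated(subset=["region1", "region2"]).any():
            raise ValueError("duplicate edges in the decision set")
        edges = edges.sort_values(["region1", "region2"], kind="stable").reset_index(drop=True)
        edges["direction"] = ["hyper" if t > 0 else "hypo" if t < 0 else "none"
                              for t in edges["tF"]]
    else:
        edges = pd.DataFrame(columns=["region1", "region2", "tF", "direction"])

    deg = Counter(edges["region1"]) + Counter(edges["region2"])
    degree = dict(deg)
    if degree:
        max_deg = max(degree.values())
        primary = sorted(r for r, d in degree.items() if d == max_deg)
        secondary = [
            r for r, d in degree.items() if d >= 2 and r not in primary
        ]
        secondary.sort(key=lambda r: (-degree[r], r))
    else:
        primary, secondary = [], []

    n_hyper, n_hypo = direction_counts(edges) if len(edges) else (0, 0)
    return NetworkSummary(
        edges=edges,
        degree=degree,
        primary_hub=primary,
        secondary_hubs=secondary,
        n_hyper=n_hyper,
        n_hypo=n_hypo,
    )


def overlap_rate(n_overlap: int, n_reference: int) -> float:
    """Percentage of a reference decision set recovered by another.

    E.g. 77 links shared between a 122-link and a 90-link analysis give
    ``overlap_rate(77, 90) = 85.6`` (rounded to one decimal).
    """
    if n_reference <= 0:
        raise ValueError("reference set must be non-empty")
    if not 0 <= n_overlap <= n_reference:
        raise ValueError("overlap must be between 0 and the reference size")
    return round(100.0 * n_overlap / n_reference, 1)


def report(
    summary: NetworkSummary,
    path: str | os.PathLike,
    edge_csv: str | os.PathLike | None = None,
    networks: dict | None = None,
) -> None:
    """Write a human-readable report and (optionally) a plain edge CSV.

    The report lists edges split into hyper-/hypoconnectivity blocks with
    their statistics, then a hub section.  ``networks`` is an optional
    region -> network-label mapping (e.g. DMN/CEN/SN) echoed into the
    report; it is annotation only, never computed.
    """
    lines = ["region1\tregion2\ttF"]
    for block, name in (("hyper", "Hyperconnectivity:"), ("hypo", "Hypoconnectivity:")):
        sub = summary.edges[summary.edges["direction"] == block]
        if len(sub) == 0 and summary.n_edges == 0:
            continue
        lines.append(name)
        for row in sub.itertuples(index=False):
            ann = ""
            if networks:
                tags = [networks.get(row.region1, ""), networks.get(row.region2, "")]
                ann = "\t" + "/".join(x for x in tags if x)
            lines.append(f"{row.region1}\t{row.region2}\t{row.tF:.3f}{ann}")
    lines.append("")
    lines.append("Hubs")
    lines.append(f"primary\t{','.join(summary.primary_hub) or '-'}")
    lines.append(f"secondary\t{','.join(summary.secondary_hubs) or '-'}")
    lines.append("degree\t" + ",".join(
        f"{r}:{d}" for r, d in sorted(summary.degree.items(), key=lambda kv: (-kv[1], kv[0]))
    ))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    if edge_csv is not None:
        summary.edges.to_csv(edge_csv, index=False, float_format="%.12g")
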