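"""Dense-rank aggregation of the three node analyses and shortlisting.

Each node is ranked under three analyses — hub (degree), perturbation and
disruption — with dense ("1223") ranks: tied values share a rank and the
next distinct value takes the next integer.  The per-node average of the
three ranks is then itself dense-ranked (lower is better) to give the
cumulative, final rank.  Tie detection is exact: averages are compared as
integer rank sums, never as rounded decimals; the printed 2-decimal average
is display only (half-up rounding, so 28/3 prints 9.33).

The shortlist takes the smallest prefix of cumulative-rank classes covering
at least ``ceil(fraction · N)`` nodes — tie classes are never split, so the
shortlist may exceed the nominal fraction.
"""

from __future__ import annotations

import csv
import math
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import pandas as pd

RANK_COLUMNS = [
    "hub_rank",
    "perturbation_rank",
    "disruption_rank",
    "average_rank",
    "cumulative_rank",
]


def dense_rank(
    values: Mapping[str, float], direction: str = "higher"
) -> dict[str, int]:
    """Dense ranks of ``values``: best value gets 1, ties share ranks.

    ``direction`` is ``"higher"`` (larger value ranks better; the case for
    degree and the deletion scores) or ``"lower"`` (used for the cumulative
    rank over averages).
    """
    if not values:
        raise ValueError("cannot rank an empty value map")
    if direction not in ("higher", "lower"):
        raise ValueError(f"direction must be 'higher' or 'lower', got {direction!r}")
    for node, x in values.items():
        if not math.isfinite(x):
            raise ValueError(f"non-finite value {x!r} for node {node!r}")
    distinct = sorted(set(values.values()), reverse=(direction == "higher"))
    rank_of = {x: r for r, x in enumerate(distinct, start=1)}
    return {node: rank_of[x] for node, x in values.items()}


def _display_average(rank_sum: int) -> float:
    return float(
        (Decimal(rank_sum) / Decimal(3)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def aggregate_ranks(
    hub: Mapping[str, int],
    pert: Mapping[str, int],
    disr: Mapping[str, int],
) -> pd.DataFrame:
    """Combine the three per-metric rank maps into the final rank table.

    Returns a DataFrame indexed by node with columns ``hub_rank``,
    ``perturbation_rank``, ``disruption_rank``, ``average_rank`` (the mean
    of the three, rounded half-up to 2 decimals for display) and
    ``cumulative_rank`` (dense rank of the exact average, ascending), sorted
    by cumulative rank then node.
    """
    sets = set(hub), set(pert), set(disr)
    if not (sets[0] == sets[1] == sets[2]):
        union = sets[0] | sets[1] | sets[2]
        inter = sets[0] & sets[1] & sets[2]
        raise ValueError(
            f"rank maps disagree on nodes: symmetric difference {sorted(union - inter)}"
        )
    sums = {v: hub[v] + pert[v] + disr[v] for v in hub}
    cumulative = dense_rank({v: float(s) for v, s in sums.items()}, "lower")
    nodes = sorted(hub, key=lambda v: (cumulative[v], v))
    return pd.DataFrame(
        {
            "hub_rank": [hub[v] for v in nodes],
            "perturbation_rank": [pert[v] for v in nodes],
            "disruption_rank": [disr[v] for v in nodes],
            "average_rank": [_display_average(sums[v]) for v in nodes],
            "cumulative_rank": [cumulative[v] for v in nodes],
        },
        index=pd.Index(nodes, name="protein"),
    )


def rank_scores(score_table: pd.DataFrame) -> pd.DataFrame:
    """Rank a node score table (from :func:`netprio.scoring.score_nodes`).

    Hub analysis ranks degree, the other two rank the perturbation and
    disruption scores; higher is better for all three.
    """
    hub = dense_rank(score_table["degree"].astype(float).to_dict())
    pert = dense_rank(score_table["perturbation"].to_dict())
    disr = dense_rank(score_table["disruption"].to_dict())
    return aggregate_ranks(hub, pert, disr)


def shortlist_top_fraction(
    table: pd.DataFrame, fraction: float = 0.05
) -> list[str]:
    """Top-``fraction`` shortlist by cumulative rank, tie classes intact.

    Whole cumulative-rank classes are taken in order until at least
    ``ceil(fraction · N)`` nodes are covered; the result is ordered by
    cumulative rank then node name.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if table.empty:
        raise ValueError("rank table is empty")
    need = math.ceil(fraction * len(table))
    out: list[str] = []
    for _, cls in table.groupby("cumulative_rank", sort=True):
        out.extend(sorted(cls.index))
        if len(out) >= need:
            break
    return out


def write_rank_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the rank table as TSV mirroring the report layout."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["protein", *RANK_COLUMNS])
        for node, row in table.iterrows():
            writer.writerow(
                [
                    node,
                    int(row["hub_rank"]),
                    int(row["perturbation_rank"]),
                    int(row["disruption_rank"]),
                    f"{row['average_rank']:.2f}",
                    int(row["cumulative_rank"]),
                ]
            )
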