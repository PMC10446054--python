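"""Dispersal-event classification and functional-connectivity statistics.

A triad (offspring + two assigned parents, all with coordinates) becomes a
*dispersal event*: the parent closest to the offspring is taken as the seed
(maternal) parent — seeds fall by gravity near the mother — and the farthest
parent as the pollen donor. An event is *between-patch* when the pollen
parent's patch differs from the offspring's patch. Functional connectivity
is the percentage of between-patch events; per-patch outbound/inbound/total
rates, per-year rates, a patch-pairwise matrix and a Spearman distance-decay
test complete the report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import records_to_frame
from .pedigree import PedigreeGraph

logger = logging.getLogger(__name__)


@dataclass
class DispersalEvent:
    offspring: str
    seed_parent: str
    pollen_parent: str
    seed_distance: float
    pollen_distance: float
    offspring_patch: int
    seed_parent_patch: int
    pollen_parent_patch: int
    between_patch: bool
    year: int


def events_to_frame(events: Sequence[DispersalEvent]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in events])


@dataclass
class EventExtraction:
    events: list[DispersalEvent]
    n_excluded_no_coords: int
    n_ties: int
    #: events whose *closest* parent sits on a different patch than the
    #: offspring — the seed-parent-is-local assumption would be violated
    n_seed_parent_elsewhere: int


def events_from_pedigree(ped: PedigreeGraph) -> EventExtraction:
    """Classify every coordinate-complete triad into a dispersal event.

    Parents are ordered by Euclidean distance to the offspring; equidistant
    parents are tie-broken by lexicographic id (logged). Triads with any
    missing coordinate are excluded and counted.
    """
    rec = ped.records
    events: list[DispersalEvent] = []
    n_excluded = n_ties = n_elsewhere = 0
    for off, (p1, p2) in sorted(ped.parents.items()):
        rows = rec.loc[[off, p1, p2]]
        if rows[["x", "y"]].isna().any().any():
            n_excluded += 1
            continue
        ox, oy = rows.loc[off, ["x", "y"]]
        d1 = math.hypot(rows.loc[p1, "x"] - ox, rows.loc[p1, "y"] - oy)
        d2 = math.hypot(rows.loc[p2, "x"] - ox, rows.loc[p2, "y"] - oy)
        if d1 == d2:
            n_ties += 1
            seed, pollen = sorted((p1, p2))
            ds, dp = d1, d2
        elif d1 < d2:
            seed, pollen, ds, dp = p1, p2, d1, d2
        else:
            seed, pollen, ds, dp = p2, p1, d2, d1
        opatch = int(rows.loc[off, "patch"])
        spatch = int(rec.loc[seed, "patch"])
        ppatch = int(rec.loc[pollen, "patch"])
        if spatch != opatch:
            n_elsewhere += 1
        events.append(
            DispersalEvent(
                offspring=off,
                seed_parent=seed,
                pollen_parent=pollen,
                seed_distance=ds,
                pollen_distance=dp,
                offspring_patch=opatch,
                seed_parent_patch=spatch,
                pollen_parent_patch=ppatch,
                between_patch=ppatch != opatch,
                year=int(rows.loc[off, "first_year"]),
            )
        )
    if n_ties:
        logger.info("%d equidistant-parent ties broken lexicographically", n_ties)
    if n_elsewhere:
        logger.warning(
            "%d events have the closest parent on a different patch", n_elsewhere
        )
    logger.info(
        "%d dispersal events (%d triads excluded for missing coordinates)",
        len(events), n_excluded,
    )
    return EventExtraction(
        events=events,
        n_excluded_no_coords=n_excluded,
        n_ties=n_ties,
        n_seed_parent_elsewhere=n_elsewhere,
    )


# ---------------------------------------------------------------------------
# connectivity statistics
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityReport:
    global_pct: float
    n_between: int
    n_total: int
    per_patch: pd.DataFrame  # outbound/inbound/total/self-recruitment %, counts
    per_year: pd.DataFrame  # year, n_events, n_between, pct
    pairwise_pct: pd.DataFrame  # % with zero diagonal
    pairwise_counts: pd.DataFrame
    denominator: str = "involving"


def connectivity_stats(
    events: Sequence[DispersalEvent] | pd.DataFrame,
    patches: Sequence[int] | None = None,
    denominator: str = "involving",
) -> ConnectivityReport:
    """Compute the full connectivity report from classified events.

    Global % = 100 × between / total. Per patch (denominator = the patch's
    offspring-event count): inbound % counts between-patch events recruiting
    on the patch, outbound % counts between-patch events whose pollen parent
    sits on the patch, total = inbound + outbound, self-recruitment =
    100 − inbound. Patches without events report NaN.

    Pairwise % for patches (i, j) = 100 × (events linking i and j) / (events
    involving i or j); ``denominator="located"`` instead divides by events
    whose *offspring* is on i or j.
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    if len(df) == 0:
        raise ValueError("empty event list")
    if denominator not in ("involving", "located"):
        raise ValueError("denominator must be 'involving' or 'located'")
    n_total = len(df)
    n_between = int(df["between_patch"].sum())
    global_pct = 100.0 * n_between / n_total
    if patches is None:
        patches = sorted(
            set(df["offspring_patch"]) | set(df["pollen_parent_patch"])
        )
    rows = []
    for p in patches:
        on_p = df["offspring_patch"] == p
        n_events = int(on_p.sum())
        n_in = int((on_p & df["between_patch"]).sum())
        n_out = int(((df["pollen_parent_patch"] == p) & df["between_patch"]).sum())
        if n_events == 0:
            rows.append(
                {
                    "patch": p, "n_events": 0, "n_inbound": n_in, "n_outbound": n_out,
                    "inbound_pct": np.nan, "outbound_pct": np.nan,
                    "total_pct": np.nan, "self_recruitment_pct": np.nan,
                }
            )
            continue
        inbound = 100.0 * n_in / n_events
        outbound = 100.0 * n_out / n_events
        rows.append(
            {
                "patch": p, "n_events": n_events,
                "n_inbound": n_in, "n_outbound": n_out,
                "inbound_pct": inbound, "outbound_pct": outbound,
                "total_pct": inbound + outbound,
                "self_recruitment_pct": 100.0 - inbound,
            }
        )
    per_patch = pd.DataFrame(rows).set_index("patch")
    yr = (
        df.groupby("year")
        .agg(n_events=("between_patch", "size"), n_between=("between_patch", "sum"))
        .reset_index()
    )
    yr["pct"] = 100.0 * yr["n_between"] / yr["n_events"]
    per_year = yr.set_index("year")
    counts = pd.DataFrame(0, index=patches, columns=patches, dtype=int)
    for _, e in df[df["between_patch"]].iterrows():
        a, b = int(e["offspring_patch"]), int(e["pollen_parent_patch"])
        counts.loc[a, b] += 1
        counts.loc[b, a] += 1
    # counts is symmetric: cell (i, j) = events linking i and j
    pair_pct = pd.DataFrame(0.0, index=patches, columns=patches)
    for i, a in enumerate(patches):
        for b in patches[i + 1 :]:
            link = counts.loc[a, b]
            if denominator == "involving":
                denom = int(
                    (
                        df["offspring_patch"].isin([a, b])
                        | (df["pollen_parent_patch"].isin([a, b]) & df["between_patch"])
                    ).sum()
                )
            else:
                denom = int(df["offspring_patch"].isin([a, b]).sum())
            val = 100.0 * link / denom if denom else np.nan
            pair_pct.loc[a, b] = pair_pct.loc[b, a] = val
    np.fill_diagonal(pair_pct.values, 0.0)
    return ConnectivityReport(
        global_pct=global_pct,
        n_between=n_between,
        n_total=n_total,
        per_patch=per_patch,
        per_year=per_year,
        pairwise_pct=pair_pct,
        pairwise_counts=counts,
        denominator=denominator,
    )


def within_events_at_between_scale(
    events: Sequence[DispersalEvent] | pd.DataFrame,
    scale_m: float | None = None,
) -> tuple[int, int, float]:
    """Within-patch events whose pollen distance reaches the between-patch
    spatial scale.

    ``scale_m`` defaults to the shortest pollen distance observed among
    between-patch events. Returns (count, total within-patch events, %).
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    within = df[~df["between_patch"]]
    if scale_m is None:
        between = df[df["between_patch"]]
        if between.empty:
            raise ValueError("no between-patch events to define the spatial scale")
        scale_m = float(between["pollen_distance"].min())
    n = int((within["pollen_distance"] >= scale_m).sum())
    total = int(len(within))
    pct = 100.0 * n / total if total else float("nan")
    return n, total, pct


def distance_decay(
    pairwise_pct: pd.DataFrame, distances: pd.DataFrame
) -> tuple[float, float]:
    """Spearman correlation between pairwise connectivity and patch distance.

    Uses the P(P−1)/2 unordered pairs; ties mid-ranked; two-sided p-value.
    Raises ``ValueError`` when fewer than 3 pairs or all rates identical.
    """
    patches = list(pairwise_pct.index)
    vals, dist = [], []
    for i, a in enumerate(patches):
        for b in patches[i + 1 :]:
            v = pairwise_pct.loc[a, b]
            if not np.isnan(v):
                vals.append(float(v))
                dist.append(float(distances.loc[a, b]))
    if len(vals) < 3:
        raise ValueError("need at least 3 patch pairs for a distance-decay test")
    if len(set(vals)) == 1:
        raise ValueError("all pairwise rates identical; correlation undefined")
    rho, p = stats.spearmanr(dist, vals)
    return float(rho), float(p)


def patch_distances(records) -> pd.DataFrame:
    """Within/between mean-distance matrix (meters).

    Off-diagonal: distance between patch barycenters. Diagonal: mean pairwise
    distance among located plants of the patch (NaN when < 2 plants).
    """
    rec = records_to_frame(records)
    rec = rec.dropna(subset=["x", "y"])
    patches = sorted(rec["patch"].unique().tolist())
    out = pd.DataFrame(np.nan, index=patches, columns=patches)
    bary = {}
    for p in patches:
        sub = rec[rec["patch"] == p]
        xy = sub[["x", "y"]].to_numpy()
        bary[p] = xy.mean(axis=0)
        if len(xy) >= 2:
            d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
            iu = np.triu_indices(len(xy), k=1)
            out.loc[p, p] = float(d[iu].mean())
    for i, a in enumerate(patches):
        for b in patches[i + 1 :]:
            d = float(np.hypot(*(bary[a] - bary[b])))
            out.loc[a, b] = out.loc[b, a] = d
    return out


def write_report(
    report: ConnectivityReport, out_dir: str | Path, prefix: str = "connectivity"
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "per_patch": out / f"{prefix}_per_patch.tsv",
        "per_year": out / f"{prefix}_per_year.tsv",
        "pairwise": out / f"{prefix}_pairwise_pct.tsv",
    }
    report.per_patch.round(1).to_csv(paths["per_patch"], sep="\t", na_rep="NA")
    report.per_year.round(1).to_csv(paths["per_year"], sep="\t", na_rep="NA")
    report.pairwise_pct.round(1).to_csv(paths["pairwise"], sep="\t", na_rep="NA")
    return paths
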