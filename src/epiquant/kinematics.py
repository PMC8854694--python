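"""Daughter-cell kinematics after apical divisions in the epiblast.

In the E6.5 mouse epiblast, cells divide at the apical surface and both
daughters normally re-integrate basally into the pseudostratified epithelium.
This module quantifies that behaviour from manually tracked time-lapse data:

* per-frame jitter correction relative to the embryonic-region centre,
* net daughter displacement d (um) from the mother's position immediately
  prior to division to the daughter's final tracked position,
* direction angle theta (degrees) between the mother-to-centre reference
  vector and the daughter movement vector; theta < 90 means the daughter
  moved apically (toward the centre of the embryonic region / the lumen),
  theta > 90 basally (back into the tissue),
* per-pair sibling labels (the daughter nearer the centre immediately after
  division is the "apical" daughter),
* division geometry: the division-axis angle relative to the apical-basal
  direction, and the division position relative to the basement membrane,
* contingency tables of apical/basal movement proportions per genotype.

All geometry is 2D (the midsagittal imaging plane); an optional z column in
track tables is carried through but ignored by angle computations.
Coordinates are in um, angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TRACK_COLUMNS = [
    "embryo_id", "track_id", "role", "frame", "t_min",
    "x_um", "y_um", "centre_x_um", "centre_y_um",
]

#: Default fold-angle bin edges (degrees) for division-orientation summaries.
ORIENTATION_EDGES = (30.0, 60.0)


@dataclass
class DivisionEvent:
    """A mother's pre-division state and the identities of her daughters."""

    embryo_id: str
    division_id: str
    division_frame: int
    mother_final_position: np.ndarray  # (x, y) um at division_frame - 1
    daughter_ids: tuple
    centre_at_division: np.ndarray = None  # (x, y) um, reference-vector target
    basement_reference: object = None

    def __post_init__(self):
        if len(self.daughter_ids) != 2:
            raise ValueError("a division event has exactly two daughters")
        self.mother_final_position = np.asarray(self.mother_final_position, float)


def correct_jitter(table: pd.DataFrame) -> pd.DataFrame:
    """Express coordinates relative to the per-frame embryonic-region centre.

    Rigid per-frame jitter of the whole field (sample drift, stage motion)
    shifts points and centre alike, so subtracting the centre removes it.
    After correction the centre columns are identically zero.
    """
    _require_columns(table, TRACK_COLUMNS)
    missing = table[table[["centre_x_um", "centre_y_um"]].isna().any(axis=1)]
    if len(missing):
        frames = sorted(missing["frame"].unique().tolist())
        raise ValueError(f"embryonic-region centre missing for frame(s) {frames}")
    out = table.copy()
    out["x_um"] = table["x_um"] - table["centre_x_um"]
    out["y_um"] = table["y_um"] - table["centre_y_um"]
    out["centre_x_um"] = 0.0
    out["centre_y_um"] = 0.0
    return out


def daughter_displacement(event: DivisionEvent, daughter_track: pd.DataFrame,
                          horizon_min: Optional[float] = None):
    """Net displacement of one daughter from the mother's final position.

    Returns ``(d, movement_vector)`` where d is the Euclidean distance (um)
    between the daughter's final tracked position and the mother's position
    immediately prior to division. The final position is the last tracked
    frame, or the last frame within ``horizon_min`` minutes of the division
    when a bounded follow-up is requested.
    """
    post = daughter_track[daughter_track["frame"] >= event.division_frame]
    if post.empty:
        raise ValueError(
            f"daughter has no frames at/after division frame {event.division_frame}"
        )
    if horizon_min is not None:
        t0 = float(post["t_min"].min())
        post = post[post["t_min"] <= t0 + horizon_min]
    final = post.loc[post["frame"].idxmax(), ["x_um", "y_um"]].to_numpy(float)
    vec = final - event.mother_final_position
    return float(np.hypot(*vec)), vec


def direction_angle(movement_vector, reference_vector) -> float:
    """Angle (degrees, in [0, 180]) between movement and reference vectors.

    The reference vector points from the mother's final position to the
    centre of the embryonic region, so 0 deg is movement straight toward the
    centre (apical) and 180 deg straight away from it (basal).
    """
    m = np.asarray(movement_vector, float)
    r = np.asarray(reference_vector, float)
    nm, nr = np.linalg.norm(m), np.linalg.norm(r)
    if nm == 0 or nr == 0:
        raise ValueError("direction angle undefined for zero-length vector")
    c = np.clip(np.dot(m, r) / (nm * nr), -1.0, 1.0)
    return math.degrees(math.acos(c))


def classify_direction(theta: float, return_tie: bool = False):
    """Classify a movement angle as apical (theta < 90) or basal (theta > 90).

    theta = 90 exactly is assigned basal and flagged as a tie (the
    published binning overlaps at 90 deg; the event has measure zero).
    """
    if not np.isfinite(theta) or theta < 0 or theta > 180:
        raise ValueError(f"theta must lie in [0, 180], got {theta}")
    tie = theta == 90.0
    label = "apical" if theta < 90.0 else "basal"
    return (label, tie) if return_tie else label


def assign_sibling_positions(event: DivisionEvent, daughter_positions: dict,
                             centre) -> dict:
    """Label each daughter apical_daughter / basal_daughter.

    ``daughter_positions`` maps daughter id -> (x, y) at the first
    post-division frame. The daughter nearer ``centre`` is the apical one.
    Exact ties are broken toward the lower track id and flagged.
    """
    centre = np.asarray(centre, float)
    ids = sorted(daughter_positions)
    if set(ids) != set(event.daughter_ids):
        raise ValueError("daughter_positions must cover exactly the two daughters")
    d = {i: float(np.linalg.norm(np.asarray(daughter_positions[i], float) - centre))
         for i in ids}
    tie = d[ids[0]] == d[ids[1]]
    apical = ids[0] if d[ids[0]] <= d[ids[1]] else ids[1]
    basal = ids[1] if apical == ids[0] else ids[0]
    return {apical: "apical_daughter", basal: "basal_daughter", "tie": tie}


def division_angle(daughter_positions: Sequence, centre) -> float:
    """Division-axis angle (degrees, folded to [0, 90]).

    The axis is the vector joining the two daughters immediately after
    division; it is compared with the vector from the midpoint between the
    daughters to the centre of the embryonic region (the local apical
    direction). The raw angle is folded (a -> min(a, 180 - a)) because the
    axis is undirected: 0 deg means the daughters are stacked along the
    apical-basal direction, 90 deg means the axis is perpendicular to it.
    """
    p1, p2 = (np.asarray(p, float) for p in daughter_positions)
    if np.allclose(p1, p2):
        raise ValueError("division angle undefined for coincident daughters")
    axis = p2 - p1
    midpoint = 0.5 * (p1 + p2)
    to_centre = np.asarray(centre, float) - midpoint
    raw = direction_angle(axis, to_centre)
    return min(raw, 180.0 - raw)


def bin_division_angle(angle_deg: float, edges=ORIENTATION_EDGES) -> str:
    """Bin a folded division angle into parallel / oblique / orthogonal.

    Default edges 30 and 60 deg: parallel < 30, oblique 30-60,
    orthogonal > 60 (edges are configurable and echoed in run reports).
    """
    lo, hi = edges
    if angle_deg < lo:
        return "parallel"
    if angle_deg <= hi:
        return "oblique"
    return "orthogonal"


def division_position(event: DivisionEvent, basement_reference,
                      centre=None) -> float:
    """Distance (um) from the mother's final position to the epiblast base.

    ``basement_reference`` may be a circle model ``{"radius": r}`` around
    the embryonic-region centre, a single (x, y) point, or an (n, 2)
    polyline sampled along the basement membrane.
    """
    if basement_reference is None:
        raise ValueError("basement_reference is required")
    p = event.mother_final_position
    if isinstance(basement_reference, dict):
        r = float(basement_reference["radius"])
        c = basement_reference.get("centre", centre)
        if c is None:
            c = event.centre_at_division
        if c is None:
            raise ValueError("circle basement model needs a centre")
        return abs(float(np.linalg.norm(p - np.asarray(c, float))) - r)
    ref = np.asarray(basement_reference, float)
    if ref.ndim == 1:
        return float(np.linalg.norm(p - ref))
    from shapely.geometry import LineString, Point

    return float(LineString(ref).distance(Point(*p)))


def divisions_from_table(table: pd.DataFrame) -> list:
    """Build :class:`DivisionEvent` objects from a track table.

    Requires a ``division_id`` column linking each mother to her two
    daughters. The division frame is the daughters' first tracked frame; the
    mother's final position is taken at her last tracked frame.
    """
    _require_columns(table, TRACK_COLUMNS + ["division_id"])
    events = []
    for (embryo, div), grp in table.groupby(["embryo_id", "division_id"], sort=True):
        mother = grp[grp["role"] == "mother"]
        daughters = grp[grp["role"].str.startswith("daughter")]
        if mother.empty or daughters["track_id"].nunique() != 2:
            raise ValueError(
                f"division {div!r} in embryo {embryo!r} needs one mother "
                "track and exactly two daughter tracks"
            )
        m_last = mother.loc[mother["frame"].idxmax()]
        division_frame = int(daughters["frame"].min())
        events.append(DivisionEvent(
            embryo_id=embryo,
            division_id=div,
            division_frame=division_frame,
            mother_final_position=m_last[["x_um", "y_um"]].to_numpy(float),
            daughter_ids=tuple(sorted(daughters["track_id"].unique())),
            centre_at_division=m_last[["centre_x_um", "centre_y_um"]].to_numpy(float),
        ))
    return events


def analyze_divisions(table: pd.DataFrame, horizon_min: Optional[float] = None,
                      basement_reference=None, genotype_col: str = "genotype",
                      orientation_edges=ORIENTATION_EDGES):
    """Run the full per-division quantification on a track table.

    Returns ``(outcomes, geometry, report)``:

    * ``outcomes`` — one row per daughter with d (um), theta (deg), the
      apical/basal movement call and the sibling-position label;
    * ``geometry`` — one row per division with the folded division angle,
      its orientation bin, and (when a basement reference is given) the
      division distance from the epiblast base;
    * ``report`` — exclusions (with reasons), tie flags, parameter echo.
    """
    events = divisions_from_table(table)
    outcome_rows, geometry_rows, exclusions, ties = [], [], [], []
    for ev in events:
        grp = table[(table["embryo_id"] == ev.embryo_id)]
        genotype = None
        if genotype_col in table.columns:
            gvals = grp.loc[grp["track_id"].isin(ev.daughter_ids), genotype_col]
            genotype = gvals.iloc[0] if len(gvals) else None
        centre = ev.centre_at_division
        first_positions = {}
        ok = True
        for did in ev.daughter_ids:
            dt = grp[grp["track_id"] == did]
            at_first = dt[dt["frame"] == ev.division_frame]
            if at_first.empty:
                exclusions.append({
                    "embryo_id": ev.embryo_id, "division_id": ev.division_id,
                    "reason": f"daughter {did} missing at first post-division "
                              f"frame {ev.division_frame}",
                })
                ok = False
                break
            first_positions[did] = at_first.iloc[0][["x_um", "y_um"]].to_numpy(float)
        if not ok:
            continue

        sib = assign_sibling_positions(ev, first_positions, centre)
        if sib.pop("tie"):
            ties.append({"embryo_id": ev.embryo_id, "division_id": ev.division_id,
                         "flag": "equidistant daughters"})

        try:
            ang = division_angle(list(first_positions.values()), centre)
            geometry_rows.append({
                "embryo_id": ev.embryo_id, "division_id": ev.division_id,
                "genotype": genotype,
                "division_angle_deg": ang,
                "orientation": bin_division_angle(ang, orientation_edges),
                "division_distance_um": (
                    division_position(ev, basement_reference)
                    if basement_reference is not None else np.nan),
            })
        except ValueError as exc:
            exclusions.append({"embryo_id": ev.embryo_id,
                               "division_id": ev.division_id,
                               "reason": f"division angle: {exc}"})

        reference = centre - ev.mother_final_position
        for did in ev.daughter_ids:
            dt = grp[grp["track_id"] == did]
            try:
                d, vec = daughter_displacement(ev, dt, horizon_min=horizon_min)
                theta = direction_angle(vec, reference)
                label, tie = classify_direction(theta, return_tie=True)
            except ValueError as exc:
                exclusions.append({"embryo_id": ev.embryo_id,
                                   "division_id": ev.division_id,
                                   "daughter_id": did, "reason": str(exc)})
                continue
            if tie:
                ties.append({"embryo_id": ev.embryo_id,
                             "division_id": ev.division_id,
                             "daughter_id": did, "flag": "theta == 90"})
            outcome_rows.append({
                "embryo_id": ev.embryo_id, "division_id": ev.division_id,
                "daughter_id": did, "genotype": genotype,
                "d_um": d, "theta_deg": theta, "direction": label,
                "sibling_position": sib[did],
            })
    outcomes = pd.DataFrame(outcome_rows)
    geometry = pd.DataFrame(geometry_rows)
    report = {
        "n_divisions": len(events),
        "n_daughters_classified": len(outcomes),
        "exclusions": exclusions,
        "tie_flags": ties,
        "parameters": {
            "horizon_min": horizon_min,
            "orientation_edges": list(orientation_edges),
            "basement_reference": "set" if basement_reference is not None else None,
        },
    }
    return outcomes, geometry, report


def direction_contingency(outcomes: pd.DataFrame, group_col: str = "genotype"):
    """2x2 group x direction count tables, overall and per sibling position.

    Returns a dict with keys ``overall``, ``apical_daughter`` and
    ``basal_daughter`` (the latter two only when sibling labels are
    present); each value is a DataFrame with groups as rows and columns
    [apical, basal]. Counts conserve totals: every classified daughter
    appears in exactly one cell of the overall table.
    """
    if outcomes.empty:
        raise ValueError("no classified outcomes")
    if outcomes[group_col].isna().any():
        raise ValueError(f"missing {group_col!r} label on some outcomes")

    def crosstab(df):
        tab = pd.crosstab(df[group_col], df["direction"])
        for col in ("apical", "basal"):
            if col not in tab.columns:
                tab[col] = 0
        tab = tab[["apical", "basal"]]
        if (tab.sum(axis=1) == 0).any():
            raise ValueError("empty group in contingency table")
        return tab

    tables = {"overall": crosstab(outcomes)}
    if "sibling_position" in outcomes.columns:
        for pos in ("apical_daughter", "basal_daughter"):
            sub = outcomes[outcomes["sibling_position"] == pos]
            if len(sub):
                tables[pos] = crosstab(sub)
    return tables


def _require_columns(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"track table is missing column(s) {missing}")
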