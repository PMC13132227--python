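"""CSV readers/writers for the study's tabular formats, with validation.

Timestamps may be ISO-8601 strings or plain seconds; internally everything
is seconds (POSIX seconds for ISO input).
"""

from __future__ import annotations

from collections.abc import Mapping
from pathlib import Path

import pandas as pd

from .datatypes import AGE_CLASSES, OPTIONS, SEX_CLASSES, UNMARKED, ChoiceEvent, GroupScan, Individual
from .nbda import Diffusion, DiffusionRecord
from .techniques import OpeningSequence


class ValidationError(ValueError):
    """A structured input failed a schema or referential-integrity check."""


def _require_columns(df: pd.DataFrame, cols: set[str], path: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")


def _parse_time(value, path: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        pass
    try:
        return pd.Timestamp(value).timestamp()
    except (TypeError, ValueError) as err:
        raise ValidationError(
            f"{path}: row {row}: cannot parse time {value!r} "
            "(expected seconds or ISO-8601)"
        ) from err


def read_individuals(path: str | Path) -> dict[str, Individual]:
    df = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(df, {"id", "age_class", "sex_class"}, str(path))
    out: dict[str, Individual] = {}
    for row, rec in df.iterrows():
        iid = rec["id"]
        if iid in out:
            raise ValidationError(f"{path}: row {row}: duplicate id {iid!r}")
        age = rec["age_class"] or "unknown"
        sex = rec["sex_class"] or "unknown"
        if age not in AGE_CLASSES:
            raise ValidationError(
                f"{path}: row {row}: age_class {age!r} not in {AGE_CLASSES}")
        if sex not in SEX_CLASSES:
            raise ValidationError(
                f"{path}: row {row}: sex_class {sex!r} not in {SEX_CLASSES}")
        tutored = rec.get("tutored_option", "") or None
        if tutored is not None and tutored not in OPTIONS:
            raise ValidationError(
                f"{path}: row {row}: tutored_option {tutored!r} "
                f"not in {OPTIONS}")
        out[iid] = Individual(
            id=iid, age_class=age, sex_class=sex,
            roost=rec.get("roost", "") or None, tutored_option=tutored,
        )
    return out


def read_scans(path: str | Path) -> list[GroupScan]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, {"scan_id", "datetime", "site", "individual_id"},
                     str(path))
    scans = []
    for (scan_id, when, site), grp in df.groupby(
            ["scan_id", "datetime", "site"], sort=True):
        t = _parse_time(when, str(path), int(grp.index[0]))
        present = list(grp["individual_id"])
        if len(set(present)) != len(present):
            raise ValidationError(
                f"{path}: scan {scan_id!r} lists an individual twice")
        scans.append(GroupScan(scan_id=scan_id, time=t, site=site,
                               present=frozenset(present)))
    scans.sort(key=lambda s: (s.time, s.scan_id))
    return scans


def read_events(path: str | Path) -> list[ChoiceEvent]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, {"time", "site", "individual_id", "option",
                          "success"}, str(path))
    events = []
    for row, rec in df.iterrows():
        t = _parse_time(rec["time"], str(path), row)
        if rec["option"] not in OPTIONS:
            raise ValidationError(
                f"{path}: row {row}: option {rec['option']!r} not in {OPTIONS}")
        if rec["success"] not in ("0", "1"):
            raise ValidationError(
                f"{path}: row {row}: success must be 0 or 1")
        events.append(ChoiceEvent(
            individual=rec["individual_id"], time=t, site=rec["site"],
            option=rec["option"], payoff=int(rec["success"]),
        ))
    times = [e.time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValidationError(f"{path}: events are not sorted by time")
    return events


def read_diffusion(path: str | Path) -> DiffusionRecord:
    df = pd.read_csv(path, dtype={"site": str, "individual_id": str,
                                  "event_index": int, "status": str})
    _require_columns(df, {"site", "event_index", "individual_id", "status"},
                     str(path))
    bad = set(df["status"]) - {"learner", "seeded", "present_only"}
    if bad:
        raise ValidationError(f"{path}: unknown status values {sorted(bad)}")
    diffusions = []
    for site, grp in df.groupby("site", sort=True):
        learners = grp[grp.status == "learner"].sort_values("event_index")
        seeded = frozenset(grp[grp.status == "seeded"]["individual_id"])
        risk = frozenset(grp[grp.status != "seeded"]["individual_id"])
        diffusions.append(Diffusion(
            site=site, learners=tuple(learners["individual_id"]),
            risk_set=risk, seeded_informed=seeded,
        ))
    return DiffusionRecord(tuple(diffusions))


def read_openings(path: str | Path) -> list[OpeningSequence]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, {"individual_id", "site", "unshell", "crack",
                          "extract"}, str(path))
    out = []
    for row, rec in df.iterrows():
        if rec["unshell"] not in ("0", "1"):
            raise ValidationError(
                f"{path}: row {row}: unshell must be 0 or 1")
        duration = rec.get("duration_s", "")
        out.append(OpeningSequence(
            individual=rec["individual_id"], site=rec["site"],
            unshell=rec["unshell"] == "1", crack=rec["crack"],
            extract=rec["extract"],
            duration=float(duration) if duration not in ("", None) and
            not pd.isna(duration) else None,
        ))
    return out


def read_sites(path: str | Path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path)
    _require_columns(df, {"site", "lat", "lon"}, str(path))
    return {str(r["site"]): (float(r["lat"]), float(r["lon"]))
            for _, r in df.iterrows()}


def write_edge_list(net, path: str | Path) -> None:
    net.to_edge_list().to_csv(path, index=False)


def validate_bundle(paths: Mapping[str, str | Path]) -> dict:
    """Schema + referential-integrity validation of an input bundle.

    Checks that every event/opening individual is in the roster (or
    UNMARKED), that event times are monotone, and that diffusion learners
    are known.  Returns a report dict; raises ValidationError on failure.
    """
    report: dict = {"checked": [], "counts": {}}
    individuals = read_individuals(paths["individuals"])
    report["checked"].append("individuals")
    report["counts"]["individuals"] = len(individuals)

    if "scans" in paths:
        scans = read_scans(paths["scans"])
        for s in scans:
            unknown = set(s.present) - set(individuals)
            if unknown:
                raise ValidationError(
                    f"scans: scan {s.scan_id!r} has unknown individuals "
                    f"{sorted(unknown)}")
        report["checked"].append("scans")
        report["counts"]["scans"] = len(scans)
    if "events" in paths:
        events = read_events(paths["events"])
        for k, e in enumerate(events):
            if e.individual != UNMARKED and e.individual not in individuals:
                raise ValidationError(
                    f"events: row {k}: unknown individual {e.individual!r}")
        report["checked"].append("events")
        report["counts"]["events"] = len(events)
    if "diffusion" in paths:
        record = read_diffusion(paths["diffusion"])
        for d in record.diffusions:
            unknown = (set(d.learners) | set(d.seeded_informed)) - set(individuals)
            if unknown:
                raise ValidationError(
                    f"diffusion at {d.site!r}: unknown individuals "
                    f"{sorted(unknown)}")
        report["checked"].append("diffusion")
        report["counts"]["diffusion_events"] = record.n_events
    if "openings" in paths:
        openings = read_openings(paths["openings"])
        for k, o in enumerate(openings):
            if o.individual not in individuals:
                raise ValidationError(
                    f"openings: row {k}: unknown individual {o.individual!r}")
        report["checked"].append("openings")
        report["counts"]["openings"] = len(openings)
    if "sites" in paths:
        read_sites(paths["sites"])
        report["checked"].append("sites")
    report["ok"] = True
    return report
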