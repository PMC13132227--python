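"""Synthetic study generator with known ground truth.

Emulates the structure of a multi-roost urban parrot population: communal
roosts whose members forage in fluid subgroups (group scans -> a modular
association network), a two-option/control diffusion experiment seeded by
trained demonstrators, per-solve colour choices generated under EWA dynamics
with age-dependent conformity, and almond-opening sequences with individual
consistency plus site-level profiles that drift along a geographic gradient.

Every output is reproducible byte-for-byte from the master seed, and the
generative parameters are written to a sidecar ``truth.json`` so recovery
tests can compare estimates against them.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import OPTIONS, UNMARKED, ChoiceEvent, Individual
from .ewa import simulate_choices
from .nbda import NBDAParameters, simulate_diffusion
from .network import AssociationNetwork, build_sri_network
from .techniques import CRACK_OPTIONS, EXTRACT_OPTIONS

#: Five roost sites on a realistic urban-harbour geometry (roughly 1-7 km
#: apart).  The first three are "main" sites with social data and diffusion
#: sessions; the last two are secondary.
DEFAULT_SITES: dict[str, tuple[float, float]] = {
    "R1": (-33.828494, 151.253983),
    "R2": (-33.841444, 151.252889),
    "R3": (-33.817167, 151.221694),
    "R4": (-33.796200, 151.282786),
    "R5": (-33.864776, 151.220025),
}

#: Study-scale composition of (age, sex) cells, as observed counts.
DEFAULT_CELL_COUNTS: dict[tuple[str, str], int] = {
    ("adult", "male"): 78, ("adult", "female"): 55,
    ("juvenile", "male"): 21, ("juvenile", "female"): 16,
    ("juvenile", "unknown"): 44, ("unknown", "male"): 17,
    ("unknown", "female"): 5, ("unknown", "unknown"): 102,
}

#: Generative EWA parameters per age class (shared across sexes): juveniles
#: conformist (f = 2), adults unbiased (f = 1), everyone with moderate
#: memory (phi = 0.22), modest social weight (gamma = 0.15) and sensitivity
#: lambda = 2.5.
DEFAULT_EWA_CELLS: dict[str, dict[str, float]] = {
    "juvenile": {"lambda": 2.5, "phi": 0.22, "gamma": 0.15, "f": 2.0},
    "adult": {"lambda": 2.5, "phi": 0.22, "gamma": 0.15, "f": 1.0},
    "unknown": {"lambda": 2.5, "phi": 0.22, "gamma": 0.15, "f": 1.5},
}


@dataclass
class SyntheticConfig:
    n_main_roosts: int = 3
    n_secondary_roosts: int = 2
    individuals_per_roost: int = 100
    cell_counts: dict = field(default_factory=lambda: dict(DEFAULT_CELL_COUNTS))
    between_roost_mixing: float = 0.10    # chance a scan member is a visitor
    n_scans: int = 864
    mean_subgroup_size: float = 25.0
    demonstrators_per_seeded_roost: int = 2
    diffusion_s: float = 5.0              # social transmission rate
    ewa_cells: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_EWA_CELLS.items()})
    individual_offset_sd: float = 0.2     # link-scale sd of varying effects
    p_success: float = 0.9
    unmarked_fraction: float = 0.10
    n_days: int = 10
    session_seconds: float = 7200.0       # two-hour sessions
    solves_per_day: float = 3.0
    technique_gradient: float = 1.2       # site-profile logit shift per km
    individual_consistency: float = 0.7
    master_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.cell_counts.values())
        if total <= 0:
            raise ValueError("cell counts must be positive")
        if self.n_main_roosts < 1:
            raise ValueError("need at least one main roost")

    @property
    def sites(self) -> dict[str, tuple[float, float]]:
        names = list(DEFAULT_SITES)
        wanted = self.n_main_roosts + self.n_secondary_roosts
        if wanted > len(names):
            raise ValueError("at most five roost sites are parameterized")
        return {k: DEFAULT_SITES[k] for k in names[:wanted]}

    @property
    def main_sites(self) -> list[str]:
        return list(self.sites)[: self.n_main_roosts]


def _rng_for(cfg: SyntheticConfig, stream: str) -> np.random.Generator:
    import zlib

    ss = np.random.SeedSequence(
        [cfg.master_seed, zlib.crc32(stream.encode()) % (2 ** 31)]
    )
    return np.random.default_rng(ss)


def generate_population(cfg: SyntheticConfig) -> pd.DataFrame:
    """Roster with age/sex cells, home roosts and tutored demonstrators.

    The first main roost is seeded with demonstrators tutored on blue, the
    second on red; the third main roost is the unseeded control.
    """
    rng = _rng_for(cfg, "population")
    cells = list(cfg.cell_counts)
    probs = np.array([cfg.cell_counts[c] for c in cells], dtype=float)
    probs /= probs.sum()
    rows = []
    counter = 0
    for roost in cfg.sites:
        for _ in range(cfg.individuals_per_roost):
            age, sex = cells[rng.choice(len(cells), p=probs)]
            rows.append({
                "id": f"bird{counter:04d}", "age_class": age,
                "sex_class": sex, "roost": roost, "tutored_option": "",
            })
            counter += 1
    roster = pd.DataFrame(rows)
    # seed up to two main roosts (one blue, one red); the last main roost
    # stays unseeded as the control when there are at least two
    n_seeded = max(1, min(2, cfg.n_main_roosts - 1))
    for r_idx, colour in list(enumerate(("blue", "red")))[:n_seeded]:
        site = cfg.main_sites[r_idx]
        adults = roster.index[(roster.roost == site)
                              & (roster.age_class == "adult")]
        chosen = rng.choice(adults, size=cfg.demonstrators_per_seeded_roost,
                            replace=False)
        roster.loc[chosen, "tutored_option"] = colour
    return roster


def roster_to_individuals(roster: pd.DataFrame) -> dict[str, Individual]:
    out = {}
    for _, row in roster.iterrows():
        out[row["id"]] = Individual(
            id=row["id"], age_class=row["age_class"],
            sex_class=row["sex_class"], roost=row["roost"],
            tutored_option=row["tutored_option"] or None,
        )
    return out


def generate_scans(cfg: SyntheticConfig, roster: pd.DataFrame) -> pd.DataFrame:
    """Group scans at the main sites producing a modular SRI network.

    Each scan draws a site and a foraging subgroup: home-roost members join
    with a common probability, members of other roosts with that probability
    scaled by the mixing rate, so within-roost dyads co-occur far more often.
    """
    rng = _rng_for(cfg, "scans")
    ids = roster["id"].to_numpy()
    home = roster["roost"].to_numpy()
    rows = []
    base_time = pd.Timestamp("2019-07-08T07:00:00")
    for s in range(cfg.n_scans):
        site = cfg.main_sites[int(rng.integers(cfg.n_main_roosts))]
        p_home = min(1.0, cfg.mean_subgroup_size
                     / max((home == site).sum(), 1))
        p = np.where(home == site, p_home, p_home * cfg.between_roost_mixing)
        present = ids[rng.random(len(ids)) < p]
        if present.size == 0:
            present = ids[[int(rng.integers(len(ids)))]]
        when = (base_time + pd.Timedelta(minutes=10 * s)).isoformat()
        for ind in present:
            rows.append({"scan_id": f"scan{s:04d}", "datetime": when,
                         "site": site, "individual_id": ind})
    return pd.DataFrame(rows)


def scans_to_groupscans(scans: pd.DataFrame) -> list:
    from .datatypes import GroupScan

    out = []
    for (scan_id, when, site), grp in scans.groupby(
            ["scan_id", "datetime", "site"], sort=True):
        t = pd.Timestamp(when).timestamp()
        out.append(GroupScan(scan_id=scan_id, time=t, site=site,
                             present=frozenset(grp["individual_id"])))
    out.sort(key=lambda s: s.scan_id)
    return out


def _individual_param_table(
    cfg: SyntheticConfig, roster: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Natural-scale per-bird EWA parameters: cell means plus link-scale
    individual offsets with sd ``individual_offset_sd``."""
    def link(val: float, kind: str) -> float:
        if kind == "log":
            return float(np.log(val))
        return float(np.log(val / (1 - val)))       # logit

    def inv(val: float, kind: str) -> float:
        return float(np.exp(val)) if kind == "log" else 1 / (1 + np.exp(-val))

    links = {"lambda": "log", "phi": "logit", "gamma": "logit", "f": "log"}
    rows = {}
    for _, row in roster.iterrows():
        cell = cfg.ewa_cells[row["age_class"]]
        vals = {}
        for name, kind in links.items():
            eta = link(cell[name], kind) + rng.normal(
                scale=cfg.individual_offset_sd)
            vals[name] = inv(eta, kind)
        rows[row["id"]] = vals
    return pd.DataFrame.from_dict(rows, orient="index")


def generate_experiment(
    cfg: SyntheticConfig,
    roster: pd.DataFrame,
    network: AssociationNetwork,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Seeded diffusion plus per-solve choice events.

    The acquisition order at each main site follows the diffusion simulator
    at the configured social transmission rate; sites run sequentially, and
    birds that learned at an earlier site count as already-informed movers
    where they attend later.  Informed birds then solve in daily two-hour
    sessions, colours drawn under the generative frequency-dependent EWA
    parameters; a configurable fraction of solves come from unmarked birds.
    """
    rng = _rng_for(cfg, "experiment")
    inds = roster_to_individuals(roster)
    home = dict(zip(roster["id"], roster["roost"]))

    # site attendance: home members plus movers
    attendance: dict[str, list[str]] = {}
    for site in cfg.main_sites:
        members = [i for i in roster["id"] if home[i] == site]
        movers = [i for i in roster["id"]
                  if home[i] != site
                  and rng.random() < cfg.between_roost_mixing]
        attendance[site] = members + movers

    informed_global: set[str] = set()
    diff_rows = []
    acq_day: dict[tuple[str, str], int] = {}
    params = NBDAParameters(s=cfg.diffusion_s)
    for site in cfg.main_sites:
        seeded = {i for i in attendance[site]
                  if inds[i].tutored_option is not None and home[i] == site}
        seeded |= {i for i in attendance[site] if i in informed_global}
        risk = [i for i in attendance[site] if i not in seeded]
        n_learn = int(round(0.7 * len(risk)))
        diff = simulate_diffusion(
            network, params, risk_set=risk, seeded_informed=seeded,
            site=site, n_events=n_learn,
            rng=np.random.default_rng(rng.integers(2 ** 31)),
        )
        for i in sorted(seeded):
            diff_rows.append({"site": site, "event_index": 0,
                              "individual_id": i, "status": "seeded"})
        for e, learner in enumerate(diff.learners, start=1):
            diff_rows.append({"site": site, "event_index": e,
                              "individual_id": learner, "status": "learner"})
            acq_day[(site, learner)] = min(
                cfg.n_days - 1, int(e * 0.8 * cfg.n_days / max(len(risk), 1)))
        for i in sorted(set(risk) - set(diff.learners)):
            diff_rows.append({"site": site, "event_index": 0,
                              "individual_id": i, "status": "present_only"})
        informed_global |= set(diff.learners) | seeded
        for i in seeded:
            acq_day.setdefault((site, i), 0)

    # solve schedule: sessions staggered across sites within each day
    schedule: list[tuple[str, float, str]] = []
    for d in range(cfg.n_days):
        for s_idx, site in enumerate(cfg.main_sites):
            start = d * 86400.0 + 7 * 3600 + s_idx * (cfg.session_seconds + 600)
            solvers = []
            for (st, i), day0 in acq_day.items():
                if st == site and day0 <= d:
                    n = rng.poisson(cfg.solves_per_day)
                    solvers.extend([i] * n)
            n_unmarked = rng.poisson(cfg.unmarked_fraction * len(solvers))
            solvers.extend([UNMARKED] * n_unmarked)
            times = np.sort(rng.uniform(0, cfg.session_seconds, len(solvers)))
            order = rng.permutation(len(solvers))
            for t, who in zip(times, [solvers[k] for k in order]):
                schedule.append((who, start + float(t), site))
    schedule.sort(key=lambda x: x[1])

    param_table = _individual_param_table(
        cfg, roster, np.random.default_rng(rng.integers(2 ** 31)))
    events = simulate_choices(
        inds, schedule, param_table, strategy="frequency",
        p_success=cfg.p_success,
        rng=np.random.default_rng(rng.integers(2 ** 31)),
    )
    events_df = pd.DataFrame({
        "time": [e.time for e in events],
        "site": [e.site for e in events],
        "individual_id": [e.individual for e in events],
        "option": [e.option for e in events],
        "success": [e.payoff for e in events],
    })
    truth = {
        "diffusion_s": cfg.diffusion_s,
        "ewa_cells": cfg.ewa_cells,
        "individual_offset_sd": cfg.individual_offset_sd,
        "p_success": cfg.p_success,
        "strategy": "frequency",
        "attendance": {k: sorted(v) for k, v in attendance.items()},
    }
    return pd.DataFrame(diff_rows), events_df, truth


def generate_openings(cfg: SyntheticConfig, roster: pd.DataFrame) -> pd.DataFrame:
    """Opening sequences with individual consistency and a spatial gradient.

    Each site gets technique profiles whose logits drift along the east-west
    axis at ``technique_gradient`` per km, so nearby sites share similar
    profiles.  Each bird draws a personal favourite from its site profile
    and repeats it with probability ``individual_consistency``.
    """
    from .techniques import great_circle_km

    rng = _rng_for(cfg, "openings")
    sites = cfg.sites
    ref = next(iter(sites.values()))
    east_km = {
        s: great_circle_km(ref[0], ref[1], ref[0], lon) * np.sign(lon - ref[1])
        for s, (lat, lon) in sites.items()
    }

    def profile(n_opts: int, site: str, stream: int) -> np.ndarray:
        base = np.linspace(-0.5, 0.5, n_opts) * ((-1) ** stream)
        shift = cfg.technique_gradient * east_km[site]
        logits = base + shift * np.sin(np.arange(n_opts) + stream)
        e = np.exp(logits - logits.max())
        return e / e.sum()

    rows = []
    for _, row in roster.iterrows():
        n_obs = int(min(17, 1 + rng.poisson(2.5)))
        if rng.random() > 0.45:          # not every bird was filmed opening
            continue
        site = row["roost"]
        p_crack = profile(len(CRACK_OPTIONS), site, 0)
        p_extract = profile(len(EXTRACT_OPTIONS), site, 1)
        p_unshell = 1 / (1 + np.exp(-(0.2 + 0.5 * cfg.technique_gradient
                                      * east_km[site])))
        fav_crack = CRACK_OPTIONS[rng.choice(len(CRACK_OPTIONS), p=p_crack)]
        fav_extract = EXTRACT_OPTIONS[rng.choice(len(EXTRACT_OPTIONS),
                                                 p=p_extract)]
        fav_unshell = bool(rng.random() < p_unshell)
        for _ in range(n_obs):
            if rng.random() < cfg.individual_consistency:
                crack, extract, unshell = fav_crack, fav_extract, fav_unshell
            else:
                crack = CRACK_OPTIONS[rng.choice(len(CRACK_OPTIONS), p=p_crack)]
                extract = EXTRACT_OPTIONS[rng.choice(len(EXTRACT_OPTIONS),
                                                     p=p_extract)]
                unshell = bool(rng.random() < p_unshell)
            duration = float(np.round(rng.gamma(4.0, 20.0), 1))
            rows.append({
                "individual_id": row["id"], "site": site,
                "unshell": int(unshell), "crack": crack, "extract": extract,
                "duration_s": duration,
            })
    return pd.DataFrame(rows)


def simulate_all(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the full synthetic bundle: individuals, scans, diffusion,
    events, openings, sites and the ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roster = generate_population(cfg)
    scans = generate_scans(cfg, roster)
    net = build_sri_network(scans_to_groupscans(scans), ids=list(roster["id"]))
    diffusion, events, truth = generate_experiment(cfg, roster, net)
    openings = generate_openings(cfg, roster)
    sites = pd.DataFrame(
        [{"site": s, "lat": lat, "lon": lon}
         for s, (lat, lon) in cfg.sites.items()]
    )
    paths = {}
    for name, frame in [("individuals", roster), ("scans", scans),
                        ("diffusion", diffusion), ("events", events),
                        ("openings", openings), ("sites", sites)]:
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["cell_counts"] = {f"{age}|{sex}": v
                               for (age, sex), v in cfg.cell_counts.items()}
    truth["config"] = cfg_dict
    tp = out / "truth.json"
    tp.write_text(json.dumps(truth, indent=2, sort_keys=True))
    paths["truth"] = tp
    return paths


# --------------------------------------------------------------------------
# focused generators used by the recovery studies

def generate_choice_study(
    n_per_cell: Mapping[str, int],
    n_choices: int,
    cell_params: Mapping[str, Mapping[str, float]] | None = None,
    strategy: str = "frequency",
    individual_offset_sd: float = 0.2,
    p_success: float = 0.9,
    spacing_s: float = 10.0,
    n_sessions: int = 10,
    n_tutored: int = 4,
    unmarked_fraction: float = 0.0,
    unmarked_bias: float = 0.5,
    two_roosts: bool = False,
    seed: int = 0,
) -> tuple[dict[str, Individual], list[ChoiceEvent], pd.DataFrame]:
    """Single-site choice stream for parameter-recovery studies.

    ``n_per_cell`` maps age classes (e.g. ``"juvenile"``) or explicit
    ``"age,sex"`` cells (e.g. ``"adult,female"``) to counts; each
    daily session schedules every bird ``n_choices / n_sessions`` times at
    ``spacing_s`` second intervals, mixed with a stream of unmarked
    demonstrators.  The unmarked stream leans towards one colour
    (``unmarked_bias``) on alternating days, emulating the day-scale swings
    in locally demonstrated colour seen at a busy dispenser; marked birds'
    choices are generated exactly by the EWA dynamics, for which the
    windows are exogenous inputs.  Lopsided-but-mixed windows are what make
    the frequency exponent identifiable, so this schedule is deliberately
    dense.  The first ``n_tutored`` adults are tutored demonstrators (half
    red, half blue).  Returns the roster, the simulated events, and the
    per-bird generative parameter table.
    """
    cell_params = cell_params or DEFAULT_EWA_CELLS
    rng = np.random.default_rng(seed)
    roster: dict[str, Individual] = {}
    rows = []
    n_tut = 0
    for cell, count in n_per_cell.items():
        age, _, sex = cell.partition(",")
        sex = sex or "unknown"
        for i in range(count):
            iid = f"{age[:3]}{sex[:1]}{i:03d}"
            tutored = None
            if age == "adult" and n_tut < n_tutored:
                tutored = "red" if n_tut < (n_tutored + 1) // 2 else "blue"
                n_tut += 1
            roost = "R2" if (two_roosts and i % 2) else "R1"
            roster[iid] = Individual(id=iid, age_class=age, sex_class=sex,
                                     roost=roost, tutored_option=tutored)
            rows.append({"id": iid, "age_class": age, "sex_class": sex,
                         "roost": roost, "tutored_option": tutored or ""})
    roster_df = pd.DataFrame(rows)
    cfg = SyntheticConfig(individual_offset_sd=individual_offset_sd,
                          ewa_cells={k: dict(v) for k, v in cell_params.items()})
    params = _individual_param_table(
        cfg, roster_df, np.random.default_rng(rng.integers(2 ** 31)))

    ids = list(roster)
    n_sessions = min(n_sessions, n_choices)
    per_session = max(1, round(n_choices / n_sessions))
    schedule: list[tuple[str, float, str]] = []
    unmarked_red: list[float] = []
    t = 0.0
    for s in range(n_sessions):
        entries: list[str] = []
        for iid in ids:
            entries += [iid] * per_session
        n_unm = int(unmarked_fraction * len(entries))
        p_red = unmarked_bias if s % 2 == 0 else 1.0 - unmarked_bias
        entries += [UNMARKED] * n_unm
        order = rng.permutation(len(entries))
        for k in order:
            schedule.append((entries[k], t, "R1"))
            unmarked_red.append(p_red)
            t += spacing_s
        t += 3600.0
    events = simulate_choices(
        roster, schedule, params, strategy=strategy, p_success=p_success,
        unmarked_p=dict(zip((s[1] for s in schedule), unmarked_red)),
        rng=np.random.default_rng(rng.integers(2 ** 31)),
    )
    return roster, events, params
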