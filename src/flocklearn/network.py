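"""Association networks from group scans.

Builds the weighted social network with the simple ratio index (SRI) under
the gambit of the group, estimates between-roost movement rates from site
attendance overlap, and assigns roost membership from pre-dawn roost counts.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GroupScan


class AssociationNetwork:
    """Symmetric weighted network of dyadic association strengths.

    Edge weights are SRI values in [0, 1]: the proportion of scans containing
    either member of a dyad in which both were present.  Individuals never
    scanned are retained as isolated nodes so that downstream diffusion risk
    sets can include them.
    """

    def __init__(self, ids: Sequence[str], weights: np.ndarray):
        ids = list(ids)
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(ids), len(ids)):
            raise ValueError("weight matrix shape does not match id list")
        if not np.allclose(weights, weights.T):
            raise ValueError("weight matrix must be symmetric")
        if (weights < -1e-12).any() or (weights > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")
        np.fill_diagonal(weights, 0.0)
        self.ids = ids
        self._index = {i: k for k, i in enumerate(ids)}
        self.weights = np.clip(weights, 0.0, 1.0)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, individual: str) -> bool:
        return individual in self._index

    def sri(self, a: str, b: str) -> float:
        """Association strength between two individuals."""
        return float(self.weights[self._index[a], self._index[b]])

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        """Weight matrix restricted to ``ids`` (missing ids -> isolated)."""
        out = np.zeros((len(ids), len(ids)))
        for i, a in enumerate(ids):
            ka = self._index.get(a)
            if ka is None:
                continue
            for j, b in enumerate(ids):
                kb = self._index.get(b)
                if kb is not None:
                    out[i, j] = self.weights[ka, kb]
        return out

    def to_edge_list(self) -> pd.DataFrame:
        """Upper-triangle non-zero edges as a tidy frame (id_i, id_j, sri)."""
        iu, ju = np.triu_indices(len(self.ids), k=1)
        keep = self.weights[iu, ju] > 0
        return pd.DataFrame(
            {
                "id_i": [self.ids[i] for i in iu[keep]],
                "id_j": [self.ids[j] for j in ju[keep]],
                "sri": self.weights[iu[keep], ju[keep]],
            }
        )

    @classmethod
    def from_edge_list(
        cls, edges: pd.DataFrame, ids: Iterable[str] | None = None
    ) -> "AssociationNetwork":
        cols = {"id_i", "id_j", "sri"}
        if not cols.issubset(edges.columns):
            raise ValueError(f"edge list needs columns {sorted(cols)}")
        all_ids = list(dict.fromkeys(ids)) if ids is not None else []
        for col in ("id_i", "id_j"):
            for i in edges[col].astype(str):
                if i not in all_ids:
                    all_ids.append(i)
        net = cls(all_ids, np.zeros((len(all_ids), len(all_ids))))
        for _, row in edges.iterrows():
            a, b = net._index[str(row["id_i"])], net._index[str(row["id_j"])]
            net.weights[a, b] = net.weights[b, a] = float(row["sri"])
        if (net.weights > 1).any():
            raise ValueError("edge list contains SRI values above 1")
        return net

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        for _, row in self.to_edge_list().iterrows():
            g.add_edge(row["id_i"], row["id_j"], weight=row["sri"])
        return g


class MovementMatrix:
    """Symmetric site-by-site movement rates in [0, 1].

    ``m[A][B]`` is the attendance-set overlap between two sites; the diagonal
    is 1 by convention (a roost fully "overlaps" itself).
    """

    def __init__(self, sites: Sequence[str], m: np.ndarray):
        sites = list(sites)
        m = np.asarray(m, dtype=float)
        if m.shape != (len(sites), len(sites)):
            raise ValueError("movement matrix shape mismatch")
        if not np.allclose(m, m.T):
            raise ValueError("movement matrix must be symmetric")
        if (m < 0).any() or (m > 1 + 1e-12).any():
            raise ValueError("movement rates must lie in [0, 1]")
        np.fill_diagonal(m, 1.0)
        self.sites = sites
        self._index = {s: k for k, s in enumerate(sites)}
        self.m = m

    def rate(self, a: str, b: str) -> float:
        return float(self.m[self._index[a], self._index[b]])


def build_sri_network(
    scans: Sequence[GroupScan], ids: Iterable[str] | None = None
) -> AssociationNetwork:
    """Simple-ratio-index network from pooled group scans.

    For a dyad (i, j), SRI = x / (x + y_i + y_j) where x is the number of
    scans containing both and y_i the number containing only i.  The
    denominator counts scans in which at least one member appears anywhere
    (scans are pooled over sites and observation periods).  With a roster
    supplied, never-scanned individuals become isolated nodes.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("at least one scan is required")
    seen_ids = [s.scan_id for s in scans]
    if len(set(seen_ids)) != len(seen_ids):
        dup = sorted({i for i in seen_ids if seen_ids.count(i) > 1})
        raise ValueError(f"duplicate scan ids: {dup}")

    roster = list(dict.fromkeys(ids)) if ids is not None else []
    roster_set = set(roster)
    for scan in scans:
        for ind in scan.present:
            if ids is not None and ind not in roster_set:
                raise ValueError(
                    f"scan {scan.scan_id!r}: individual {ind!r} not in roster"
                )
            if ids is None and ind not in roster_set:
                roster.append(ind)
                roster_set.add(ind)

    index = {i: k for k, i in enumerate(roster)}
    presence = np.zeros((len(scans), len(roster)), dtype=bool)
    for r, scan in enumerate(scans):
        for ind in scan.present:
            presence[r, index[ind]] = True

    p = presence.astype(np.int64)
    joint = p.T @ p                      # scans with both present
    n_each = p.sum(axis=0)               # scans with each present
    either = n_each[:, None] + n_each[None, :] - joint
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(either > 0, joint / np.maximum(either, 1), 0.0)
    np.fill_diagonal(sri, 0.0)
    return AssociationNetwork(roster, sri)


def movement_rates(attendance: Mapping[str, set[str]]) -> MovementMatrix:
    """Between-site movement rates m_AB = n_ov / (n_A + n_B - n_ov).

    ``attendance`` maps each site to the set of individuals recorded there
    during the experimental period.  The rate is the Jaccard overlap of the
    two attendance sets: birds foraging at both roosts raise it.
    """
    sites = list(attendance)
    for site in sites:
        if not attendance[site]:
            raise ValueError(f"site {site!r} has an empty attendance set")
    n = len(sites)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = attendance[sites[i]], attendance[sites[j]]
            n_ov = len(a & b)
            m[i, j] = m[j, i] = n_ov / (len(a) + len(b) - n_ov)
    return MovementMatrix(sites, m)


def assign_roost_membership(
    roost_counts: Mapping[str, Mapping[str, int]],
    marking_site: Mapping[str, str] | None = None,
    ids: Iterable[str] | None = None,
) -> dict[str, str]:
    """Assign each individual to a roost from three census counts.

    A bird recorded at the same roost in at least two of three pre-dawn
    counts is a member there.  Birds without such a site fall back to the
    site where they were first marked; failing both, membership is
    ``"unknown"``.  Counts of >=2 at two different sites indicate overlapping
    censuses and raise an error.
    """
    marking_site = dict(marking_site or {})
    all_ids = list(ids) if ids is not None else sorted(
        set(roost_counts) | set(marking_site)
    )
    out: dict[str, str] = {}
    for ind in all_ids:
        counts = roost_counts.get(ind, {})
        for site, c in counts.items():
            if c not in (0, 1, 2, 3):
                raise ValueError(
                    f"individual {ind!r}: count {c!r} at {site!r} outside 0..3"
                )
        qualifying = [s for s, c in counts.items() if c >= 2]
        if len(qualifying) > 1:
            raise ValueError(
                f"individual {ind!r} recorded >=2 counts at multiple sites "
                f"{sorted(qualifying)}; census visits appear to overlap"
            )
        if qualifying:
            out[ind] = qualifying[0]
        elif ind in marking_site:
            out[ind] = marking_site[ind]
        else:
            out[ind] = "unknown"
    return out
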