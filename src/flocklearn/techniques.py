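"""Opening-technique dissimilarity and its social/spatial predictors.

Each observed almond opening is a short categorical sequence: an optional
unshelling step, the location of the first crack (tip/seam/hilum/middle),
and the extraction method (nibble/split/other), optionally with a duration.
Sequences are one-hot encoded, column-standardized and compared by Euclidean
distance; partial Mantel permutation tests then ask whether sequence
dissimilarity tracks individual identity, geographic distance between
roosts, between-roost movement, social association, or relatedness while
controlling for a confounder matrix.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency

from .network import AssociationNetwork, MovementMatrix

CRACK_OPTIONS = ("tip", "seam", "hilum", "middle")
EXTRACT_OPTIONS = ("nibble", "split", "other")


@dataclass(frozen=True)
class OpeningSequence:
    individual: str
    site: str
    unshell: bool
    crack: str
    extract: str
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.crack not in CRACK_OPTIONS:
            raise ValueError(
                f"opening by {self.individual!r}: crack {self.crack!r} "
                f"not in {CRACK_OPTIONS}"
            )
        if self.extract not in EXTRACT_OPTIONS:
            raise ValueError(
                f"opening by {self.individual!r}: extract {self.extract!r} "
                f"not in {EXTRACT_OPTIONS}"
            )


def encode_sequences(
    seqs: Sequence[OpeningSequence], include_duration: bool = False
) -> np.ndarray:
    """Numeric design matrix: binary unshell, one-hot crack and extract
    blocks, optional z-scored duration; every column standardized (constant
    columns become zeros and thus contribute nothing to distances)."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    cols: list[np.ndarray] = [np.array([float(s.unshell) for s in seqs])]
    for opt in CRACK_OPTIONS:
        cols.append(np.array([float(s.crack == opt) for s in seqs]))
    for opt in EXTRACT_OPTIONS:
        cols.append(np.array([float(s.extract == opt) for s in seqs]))
    if include_duration:
        durations = [s.duration for s in seqs]
        if any(d is None for d in durations):
            raise ValueError("include_duration=True but some durations missing")
        cols.append(np.array(durations, dtype=float))
    x = np.column_stack(cols)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def sequence_dissimilarity(encoded: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between encoded sequences."""
    if not np.isfinite(encoded).all():
        raise ValueError("encoded matrix contains non-finite values")
    from scipy.spatial.distance import pdist

    return squareform(pdist(encoded, metric="euclidean"))


EARTH_RADIUS_KM = 6371.0


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance in kilometres."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


PREDICTOR_KINDS = (
    "same_individual", "site_distance", "site_movement", "association",
    "relatedness",
)


def build_predictor_matrix(
    seqs: Sequence[OpeningSequence],
    kind: str,
    site_coords: Mapping[str, tuple[float, float]] | None = None,
    movement: MovementMatrix | None = None,
    network: AssociationNetwork | None = None,
    relatedness: pd.DataFrame | None = None,
) -> np.ndarray:
    """Sequence-level predictor matrix, oriented as a dissimilarity.

    All kinds return larger values for pairs expected to be *less* similar,
    so a positive Mantel correlation with the technique dissimilarity reads
    "similar sequences go with same-individual / nearby / connected /
    associated / related pairs".  Dyads with no association or relatedness
    value are NaN and dropped pairwise by the Mantel test.
    """
    n = len(seqs)
    out = np.zeros((n, n))
    if kind == "same_individual":
        for i, j in itertools.combinations(range(n), 2):
            out[i, j] = out[j, i] = float(seqs[i].individual != seqs[j].individual)
    elif kind == "site_distance":
        if site_coords is None:
            raise ValueError("site_distance needs site_coords")
        for i, j in itertools.combinations(range(n), 2):
            la1, lo1 = site_coords[seqs[i].site]
            la2, lo2 = site_coords[seqs[j].site]
            out[i, j] = out[j, i] = great_circle_km(la1, lo1, la2, lo2)
    elif kind == "site_movement":
        if movement is None:
            raise ValueError("site_movement needs a MovementMatrix")
        off_diag = movement.m[~np.eye(len(movement.sites), dtype=bool)]
        m_max = off_diag.max() if off_diag.size else 1.0
        m_max = m_max if m_max > 0 else 1.0
        for i, j in itertools.combinations(range(n), 2):
            if seqs[i].site == seqs[j].site:
                rate = m_max
            else:
                rate = movement.rate(seqs[i].site, seqs[j].site)
            out[i, j] = out[j, i] = 1.0 - rate / m_max
    elif kind == "association":
        if network is None:
            raise ValueError("association needs an AssociationNetwork")
        for i, j in itertools.combinations(range(n), 2):
            a, b = seqs[i].individual, seqs[j].individual
            if a == b:
                out[i, j] = out[j, i] = 0.0
            elif a in network and b in network:
                out[i, j] = out[j, i] = 1.0 - network.sri(a, b)
            else:
                out[i, j] = out[j, i] = np.nan
    elif kind == "relatedness":
        if relatedness is None:
            raise ValueError("relatedness needs a relatedness matrix")
        r_max = float(np.nanmax(relatedness.values))
        for i, j in itertools.combinations(range(n), 2):
            a, b = seqs[i].individual, seqs[j].individual
            if a in relatedness.index and b in relatedness.columns:
                r = relatedness.loc[a, b]
                out[i, j] = out[j, i] = (r_max - float(r)
                                         if np.isfinite(r) else np.nan)
            else:
                out[i, j] = out[j, i] = np.nan
    else:
        raise ValueError(f"unknown predictor kind {kind!r}; "
                         f"expected one of {PREDICTOR_KINDS}")
    return out


def _check_square_symmetric(mat: np.ndarray, name: str, n: int) -> None:
    if mat.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got {mat.shape}")
    finite = np.isfinite(mat)
    if not np.array_equal(finite, finite.T) or not np.allclose(
        np.where(finite, mat, 0.0), np.where(finite, mat, 0.0).T
    ):
        raise ValueError(f"{name} must be symmetric")


def _partial_r(y: np.ndarray, x: np.ndarray, z: np.ndarray) -> float:
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ValueError(
            "degenerate control matrix: |correlation with control| = 1"
        )
    return (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))


def partial_mantel(
    d_y: np.ndarray,
    d_x: np.ndarray,
    d_z: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    tail: str = "greater",
    exhaustive: bool = False,
) -> dict:
    """Partial Mantel test of corr(d_y, d_x) controlling for d_z.

    r is the partial Pearson correlation of the lower-triangle vectors,
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)); the null
    distribution permutes rows and columns of ``d_y`` simultaneously, and
    p = (#{r_perm >= r_obs} + 1) / (n_perm + 1) for tail="greater".
    NaN cells (missing dyads) are deleted pairwise from the triangle vectors.
    With ``exhaustive=True`` all n! permutations are enumerated instead.
    """
    d_y = np.asarray(d_y, dtype=float)
    d_x = np.asarray(d_x, dtype=float)
    n = d_y.shape[0]
    _check_square_symmetric(d_y, "d_y", n)
    _check_square_symmetric(d_x, "d_x", n)
    if d_z is None:
        d_z = np.zeros((n, n))
    else:
        d_z = np.asarray(d_z, dtype=float)
        _check_square_symmetric(d_z, "d_z", n)
    if not exhaustive and n_perm < 99:
        raise ValueError("n_perm must be at least 99")

    iu = np.triu_indices(n, k=1)

    def tri(mat: np.ndarray, order: np.ndarray | None = None) -> np.ndarray:
        if order is not None:
            mat = mat[np.ix_(order, order)]
        return mat[iu]

    def stat(y_order: np.ndarray | None) -> float:
        yv, xv, zv = tri(d_y, y_order), tri(d_x), tri(d_z)
        keep = np.isfinite(yv) & np.isfinite(xv) & np.isfinite(zv)
        yv, xv, zv = yv[keep], xv[keep], zv[keep]
        if zv.size == 0 or np.allclose(zv, zv[0]):
            return float(np.corrcoef(xv, yv)[0, 1])
        return _partial_r(yv, xv, zv)

    r_obs = stat(None)
    if exhaustive:
        import itertools as it

        perms = [stat(np.array(p)) for p in it.permutations(range(n))]
        r_perm = np.array(perms)
        n_perm_eff = len(perms)
        if tail == "greater":
            p = float(np.mean(r_perm >= r_obs - 1e-12))
        elif tail == "less":
            p = float(np.mean(r_perm <= r_obs + 1e-12))
        else:
            p = float(np.mean(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        greater = lesser = 0
        for _ in range(n_perm):
            order = rng.permutation(n)
            r_p = stat(order)
            if r_p >= r_obs - 1e-12:
                greater += 1
            if r_p <= r_obs + 1e-12:
                lesser += 1
        n_perm_eff = n_perm
        if tail == "greater":
            p = (greater + 1) / (n_perm + 1)
        elif tail == "less":
            p = (lesser + 1) / (n_perm + 1)
        else:
            p = (min(greater, lesser) * 2 + 1) / (n_perm + 1)
            p = min(p, 1.0)
    return {"r": r_obs, "p": p, "n_perm": n_perm_eff, "tail": tail}


def contingency_posthoc(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Omnibus chi-square plus per-category collapsed post hoc tests.

    ``table`` is categories (rows) by groups (columns) of counts.  Each
    category is tested 2 x groups (that category vs all others pooled) and
    its p-value Bonferroni-multiplied by the number of categories.  No
    continuity correction is applied.
    """
    counts = table.to_numpy()
    if (counts < 0).any() or not np.issubdtype(counts.dtype, np.number):
        raise ValueError("table must contain non-negative counts")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("table must contain integer counts")
    chi2, p, dof, expected = chi2_contingency(counts, correction=False)
    warn_msgs = []
    if (expected < 1).any():
        warn_msgs.append("omnibus: some expected cell counts are below 1")
    n_cat = table.shape[0]
    rows = []
    for cat in table.index:
        collapsed = np.vstack([
            table.loc[cat].to_numpy(),
            counts.sum(axis=0) - table.loc[cat].to_numpy(),
        ])
        c2, pc, _, exp_c = chi2_contingency(collapsed, correction=False)
        if (exp_c < 1).any():
            warn_msgs.append(f"category {cat!r}: expected cell count below 1")
        rows.append({
            "category": cat, "chi2": float(c2), "p_raw": float(pc),
            "p_adjusted": float(min(pc * n_cat, 1.0)),
            "significant": bool(min(pc * n_cat, 1.0) < alpha),
        })
    for msg in warn_msgs:
        warnings.warn(msg, stacklevel=2)
    return {
        "omnibus": {"chi2": float(chi2), "p": float(p), "dof": int(dof)},
        "posthoc": pd.DataFrame(rows).set_index("category"),
        "warnings": warn_msgs,
    }
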