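"""2D projection of a map from geodesic (jump) distances.

Classical (Torgerson) multidimensional scaling is applied to the all-pairs
jump-distance matrix of the map's largest connected component: the squared
distances are double-centred and the top two eigenpairs of the resulting
Gram matrix give coordinates in which Euclidean distance approximates jump
distance.  This is the Isomap construction with the graph itself supplying
the geodesics.  Classical MDS is deterministic; the remaining sign
ambiguity of each eigenvector is fixed by a convention (each axis is
flipped, if needed, so that the coordinate of the lexicographically
smallest node id is >= 0), which makes embeddings bit-reproducible.

A metric-SMACOF variant (scikit-learn) is available for comparison, and a
landmark (Nystrom) approximation for maps too large for a dense all-pairs
matrix; both are documented approximations, not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from .graph import CellMap, largest_component

logger = logging.getLogger(__name__)


@dataclass
class Embedding2D:
    """2D coordinates per protein id plus a stress diagnostic.

    ``stress`` is the normalised residual
    sqrt(sum (d_emb - d_geo)^2 / sum d_geo^2) over all embedded pairs
    (0 = geodesics perfectly reproduced).  ``component_note`` lists ids of
    the input map that were excluded as disconnected from the largest
    component.
    """

    coords: dict[str, tuple[float, float]]
    stress: float
    component_note: list[str] = field(default_factory=list)
    method: str = "classical"

    @property
    def ids(self) -> list[str]:
        return list(self.coords)

    def array(self, ids=None) -> np.ndarray:
        ids = self.ids if ids is None else list(ids)
        return np.array([self.coords[i] for i in ids], dtype=float)


def _geodesic_matrix(component: CellMap) -> tuple[list[str], np.ndarray]:
    ids = sorted(component.node_ids)
    index = {n: i for i, n in enumerate(ids)}
    g = component.graph
    rows, cols = [], []
    for a, b in g.edges():
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
    n = len(ids)
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    return ids, dist


def _classical_mds(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Top-2 classical-MDS coordinates and the eigenvalues used."""
    n = dist.shape[0]
    d2 = dist**2
    # double centring: B = -1/2 J D^2 J
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    b = -0.5 * (d2 - row - col + d2.mean())
    b = (b + b.T) / 2.0
    from scipy.linalg import eigh

    vals, vecs = eigh(b, subset_by_index=(max(n - 2, 0), n - 1))
    order = np.argsort(vals)[::-1]  # descending
    vals, vecs = vals[order], vecs[:, order]
    lam = np.clip(vals, 0.0, None)
    coords = vecs * np.sqrt(lam)[None, :]
    if coords.shape[1] < 2:  # n == 1 cannot happen (guarded), keep shape safe
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    return coords[:, :2], lam[:2]


def _apply_sign_convention(coords: np.ndarray) -> np.ndarray:
    """Flip each axis so the first (lexicographically smallest) id has
    nonnegative coordinates; ties at exactly 0 are left as-is."""
    out = coords.copy()
    for k in range(out.shape[1]):
        if out[0, k] < 0:
            out[:, k] = -out[:, k]
    return out


def _stress(dist: np.ndarray, coords: np.ndarray) -> float:
    diff = coords[:, None, :] - coords[None, :, :]
    demb = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(dist.shape[0], k=1)
    denom = float((dist[iu] ** 2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(((demb[iu] - dist[iu]) ** 2).sum() / denom))


def geodesic_mds(
    cell_map: CellMap,
    seed: int = 0,
    method: str = "classical",
    n_landmarks: int | None = None,
) -> Embedding2D:
    """Embed the map's largest component in 2D from jump distances.

    ``method="classical"`` (default) is fully deterministic; ``seed`` is
    used only by the ``"smacof"`` method and by landmark selection.
    ``n_landmarks`` switches on the Nystrom landmark approximation when the
    component is larger than the given landmark count.
    """
    component = largest_component(cell_map)
    if len(component) < 2:
        raise ValueError("map largest component must have >= 2 nodes")
    excluded = sorted(cell_map.node_ids - component.node_ids)

    if n_landmarks is not None and len(component) > n_landmarks:
        return _landmark_mds(cell_map, component, excluded, n_landmarks, seed)

    ids, dist = _geodesic_matrix(component)
    if method == "classical":
        coords, _ = _classical_mds(dist)
        coords = coords - coords.mean(axis=0, keepdims=True)
        coords = _apply_sign_convention(coords)
    elif method == "smacof":
        from sklearn.manifold import MDS

        mds = MDS(
            n_components=2,
            metric="precomputed",
            init="random",
            random_state=seed,
            normalized_stress=False,
        )
        coords = mds.fit_transform(dist)
        coords = coords - coords.mean(axis=0, keepdims=True)
        coords = _apply_sign_convention(coords)
    else:
        raise ValueError(f"unknown method {method!r}")

    return Embedding2D(
        coords={i: (float(x), float(y)) for i, (x, y) in zip(ids, coords)},
        stress=_stress(dist, coords),
        component_note=excluded,
        method=method,
    )


def _landmark_mds(cell_map, component, excluded, n_landmarks, seed) -> Embedding2D:
    """Nystrom landmark MDS: classical MDS on a seeded landmark subset,
    remaining nodes triangulated from their distances to the landmarks."""
    ids = sorted(component.node_ids)
    rng = np.random.default_rng(seed)
    landmarks = sorted(rng.choice(len(ids), size=n_landmarks, replace=False))
    land_ids = [ids[i] for i in landmarks]

    from .graph import bfs_jumps

    # distances landmark x all
    dl = np.empty((n_landmarks, len(ids)))
    for r, lid in enumerate(land_ids):
        d = bfs_jumps(component, {lid})
        dl[r] = [d[i] for i in ids]
    dll = dl[:, landmarks]
    lcoords, lam = _classical_mds(dll)
    lcoords = lcoords - lcoords.mean(axis=0, keepdims=True)
    # triangulation (Landmark-MDS): x = -1/2 L# (delta_x - delta_mean)
    safe = np.where(lam > 1e-12, lam, np.inf)
    pseudo = (lcoords / safe[None, :]).T  # 2 x m
    delta_mean = (dll**2).mean(axis=1)
    coords = (-0.5 * pseudo @ (dl**2 - delta_mean[:, None])).T
    coords = coords - coords.mean(axis=0, keepdims=True)
    coords = _apply_sign_convention(coords)
    emb = Embedding2D(
        coords={i: (float(x), float(y)) for i, (x, y) in zip(ids, coords)},
        stress=float("nan"),  # full pairwise stress not computed in landmark mode
        component_note=excluded,
        method=f"landmark-{n_landmarks}",
    )
    return emb


def distance_preservation(
    embedding: Embedding2D, cell_map: CellMap, n_pairs: int = 1000, seed: int = 0
) -> dict:
    """Spearman correlation between jump and embedded Euclidean distance.

    ``n_pairs`` node pairs are sampled (seeded, without replacement when
    possible); returns a dict with the correlation (NaN if undefined, e.g.
    a single pair), the p-value and the sample size used.
    """
    from scipy.stats import spearmanr

    from .graph import bfs_jumps

    ids = embedding.ids
    component = largest_component(cell_map)
    rng = np.random.default_rng(seed)
    n = len(ids)
    pairs = set()
    n_pairs = min(n_pairs, n * (n - 1) // 2)
    while len(pairs) < n_pairs:
        i, j = rng.integers(0, n, size=2)
        if i != j:
            pairs.add((min(i, j), max(i, j)))
    pairs = sorted(pairs)
    jump, emb = [], []
    cache: dict[int, dict[str, int]] = {}
    xy = embedding.array(ids)
    for i, j in pairs:
        if i not in cache:
            cache[i] = bfs_jumps(component, {ids[i]})
        jump.append(cache[i][ids[j]])
        # rounding stabilises rank ties that exact arithmetic would produce
        # (e.g. equal geodesics on a path) against eigensolver noise
        emb.append(round(float(np.hypot(*(xy[i] - xy[j]))), 9))
    if len(pairs) < 2:
        return {"spearman": float("nan"), "p_value": float("nan"), "n_pairs": len(pairs)}
    rho, p = spearmanr(jump, emb)
    return {"spearman": float(rho), "p_value": float(p), "n_pairs": len(pairs)}
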