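"""Seeded random-walker segmentation with a combined intensity/probability
edge weight.

Each pixel is a graph node; lattice neighbours (4-connectivity in 2-D,
6 in 3-D by default) are joined by edges weighted

    w_ij = exp( -beta * ( (1-alpha) * (T_i - T_j)^2 + alpha * (p_i - p_j)^2 ) )

where T is the intensity image rescaled to [0, 1], p the classifier's
liver-probability image, alpha in [0, 1] mixes the two terms and beta sets
the contrast sensitivity.  alpha = 0 recovers the classic intensity-only
random walker.  The walker potential x_i — the probability that a random
walk started at i reaches a liver seed before a background seed — is the
solution of the combinatorial Dirichlet problem

    argmin_x  x^T L x,   x = 1 on liver seeds, 0 on background seeds,

with L the graph Laplacian.  Unseeded potentials solve the reduced SPD
system L_U x_U = -B^T x_S; pixels with x > 1/2 are labelled liver (ties go
to background).  A small weight floor keeps the system positive definite at
large beta.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import cg

from .boosted_classifier import ProbabilityMap
from .errors import ConfigError, WalkerError
from .image_io import ImageGrid, LabelMask, rescale_intensity
from .seed_selection import LIVER, SeedMask

__all__ = ["WalkConfig", "WalkResult", "edge_weight", "build_laplacian", "solve_walker", "segment"]

_DENSE_LIMIT = 2500  # unseeded-node count below which a dense solve is used


@dataclass(frozen=True)
class WalkConfig:
    """Walker parameters.

    alpha : probability-term mixing weight in [0, 1] (0 = classic walker).
    beta : contrast sensitivity (the reference operating point is 150).
    connectivity : 4 or 8 in 2-D, 6 or 26 in 3-D; None picks 4/6.
    tol : relative tolerance of the iterative solve.
    weight_floor : lower bound on edge weights for numerical stability.
    """

    alpha: float = 0.5
    beta: float = 150.0
    connectivity: int | None = None
    tol: float = 1e-8
    weight_floor: float = 1e-6

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha must be in [0, 1]")
        if self.beta <= 0:
            raise ConfigError("beta must be > 0")
        if self.tol <= 0 or self.weight_floor <= 0:
            raise ConfigError("tol and weight_floor must be > 0")
        if self.connectivity not in (None, 4, 8, 6, 26):
            raise ConfigError("connectivity must be 4/8 (2-D) or 6/26 (3-D)")


@dataclass
class WalkResult:
    potentials: np.ndarray  # x_i in [0, 1], liver seeds 1, background seeds 0
    labels: np.ndarray  # x > 1/2
    energy: float  # x^T L x at the solution


def edge_weight(Ti, Tj, pi, pj, config: WalkConfig):
    """Eq.-style combined weight; scalar or array inputs, floored below."""
    dT = np.asarray(Ti, dtype=np.float64) - np.asarray(Tj, dtype=np.float64)
    dp = np.asarray(pi, dtype=np.float64) - np.asarray(pj, dtype=np.float64)
    w = np.exp(-config.beta * ((1.0 - config.alpha) * dT**2 + config.alpha * dp**2))
    return np.maximum(w, config.weight_floor)


def _lattice_offsets(ndim: int, connectivity: int | None):
    """Half-space neighbour offsets (each undirected edge listed once)."""
    if connectivity is None:
        connectivity = 4 if ndim == 2 else 6
    if (ndim, connectivity) not in ((2, 4), (2, 8), (3, 6), (3, 26)):
        raise ConfigError(f"connectivity {connectivity} invalid for {ndim}-D")
    full = connectivity in (8, 26)
    offs = []
    from itertools import product

    for off in product((-1, 0, 1), repeat=ndim):
        if all(o == 0 for o in off):
            continue
        nonzero = [o for o in off if o != 0]
        if nonzero[0] < 0:  # keep one representative per undirected edge
            continue
        if not full and sum(abs(o) for o in off) != 1:
            continue
        offs.append(off)
    return offs


def _edges_and_weights(T: np.ndarray, p: np.ndarray, config: WalkConfig):
    shape = T.shape
    idx = np.arange(T.size).reshape(shape)
    rows, cols, weights = [], [], []
    for off in _lattice_offsets(T.ndim, config.connectivity):
        src = tuple(
            slice(max(0, -o), s - max(0, o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), s - max(0, -o)) for o, s in zip(off, shape)
        )
        i = idx[src].ravel()
        j = idx[dst].ravel()
        w = edge_weight(T[src].ravel(), T[dst].ravel(), p[src].ravel(), p[dst].ravel(), config)
        rows.append(i)
        cols.append(j)
        weights.append(w)
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(weights)


def build_laplacian(
    image: ImageGrid | np.ndarray,
    probability_map: ProbabilityMap | np.ndarray | None,
    seed_mask: SeedMask,
    config: WalkConfig,
):
    """Assemble the reduced Dirichlet system for the unseeded nodes.

    Returns a dict with the reduced SPD matrix ``L_uu``, the right-hand
    side, index bookkeeping, and the full Laplacian (for the energy).
    Connected components of the lattice that contain no seed are assigned
    the background label with a warning.
    """
    T = image.values if isinstance(image, ImageGrid) else np.asarray(image, dtype=np.float64)
    if probability_map is None:
        p = np.zeros_like(T)
    else:
        p = (
            probability_map.values
            if isinstance(probability_map, ProbabilityMap)
            else np.asarray(probability_map, dtype=np.float64)
        )
    states = seed_mask.states
    if T.shape != p.shape or T.shape != states.shape:
        raise ConfigError("image, probability map and seeds must share a shape")
    seed_mask.validate()

    n = T.size
    rows, cols, w = _edges_and_weights(T, p, config)
    W = sparse.coo_matrix((np.concatenate([w, w]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))), shape=(n, n)).tocsr()
    degree = np.asarray(W.sum(axis=1)).ravel()
    L = sparse.diags(degree) - W

    seeded = states.ravel() >= 0
    seed_values = (states.ravel() == LIVER).astype(np.float64)

    # components with no seed at all: label background, solve the rest
    n_comp, comp = connected_components(W, directed=False)
    orphan = np.zeros(n, dtype=bool)
    if n_comp > 1:
        seeded_comps = np.unique(comp[seeded])
        orphan = ~np.isin(comp, seeded_comps)
        if orphan.any():
            warnings.warn(
                f"{int(orphan.sum())} nodes are disconnected from all seeds; "
                "assigning them the background label",
                stacklevel=2,
            )

    unseeded = ~seeded & ~orphan
    L_csr = L.tocsr()
    L_uu = L_csr[unseeded][:, unseeded]
    B = L_csr[unseeded][:, seeded]
    rhs = -B @ seed_values[seeded]
    return {
        "L": L,
        "L_uu": L_uu.tocsr(),
        "rhs": rhs,
        "seeded": seeded,
        "unseeded": unseeded,
        "orphan": orphan,
        "seed_values": seed_values,
        "shape": T.shape,
        "tol": config.tol,
    }


def solve_walker(system: dict, tolerance: float | None = None) -> WalkResult:
    """Solve the reduced system and threshold potentials at 1/2."""
    tol = system["tol"] if tolerance is None else tolerance
    L_uu, rhs = system["L_uu"], system["rhs"]
    n_u = rhs.shape[0]
    if n_u == 0:
        x_u = np.empty(0)
    elif n_u <= _DENSE_LIMIT:
        x_u = np.linalg.solve(L_uu.toarray(), rhs)
    else:
        M = sparse.diags(1.0 / L_uu.diagonal())
        x_u, info = cg(L_uu, rhs, rtol=tol, maxiter=10 * n_u, M=M)
        if info != 0:
            resid = float(np.linalg.norm(L_uu @ x_u - rhs))
            if resid > tol * max(1.0, float(np.linalg.norm(rhs))) * 100:
                raise WalkerError(
                    f"walker solve did not converge (info={info}, residual={resid:.3e})"
                )

    n = int(np.prod(system["shape"]))
    x = np.zeros(n)
    x[system["seeded"]] = system["seed_values"][system["seeded"]]
    if n_u:
        x[system["unseeded"]] = x_u
    # the maximum principle bounds the exact solution in [0, 1]; clip
    # the solver's rounding residue
    x = np.clip(x, 0.0, 1.0)
    energy = float(x @ (system["L"] @ x))
    labels = (x > 0.5).astype(np.uint8)  # strict: ties go to background
    return WalkResult(
        potentials=x.reshape(system["shape"]),
        labels=labels.reshape(system["shape"]),
        energy=energy,
    )


def segment(
    image: ImageGrid,
    probability_map: ProbabilityMap | None,
    seed_mask: SeedMask,
    config: WalkConfig | None = None,
) -> LabelMask:
    """Full walker segmentation of one grid (2-D or full 3-D lattice).

    Intensities are rescaled to [0, 1] first so the two difference terms in
    the edge weight share a scale.  With ``probability_map=None`` or
    alpha = 0 this is the classic intensity-only random walker.
    """
    config = config or WalkConfig()
    rescaled = rescale_intensity(image, (0.0, 1.0))
    system = build_laplacian(rescaled, probability_map, seed_mask, config)
    result = solve_walker(system)
    return LabelMask(labels=result.labels, spacing=image.spacing)


def segment_with_result(image, probability_map, seed_mask, config=None):
    """Like :func:`segment` but also returns the :class:`WalkResult`."""
    config = config or WalkConfig()
    rescaled = rescale_intensity(image, (0.0, 1.0))
    system = build_laplacian(rescaled, probability_map, seed_mask, config)
    result = solve_walker(system)
    return LabelMask(labels=result.labels, spacing=image.spacing), result
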