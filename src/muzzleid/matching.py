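"""Deterministic, weights-free coarse-to-fine correspondence matching.

The matcher mirrors the stage structure of detector-free learned matchers
(coarse feature grid -> candidate matching -> fine refinement -> match
filtering) but replaces every learned component with classical normalized
cross-correlation, making it deterministic, dependency-light and seed-free:

1. ``coarse_match`` tiles both canonical images into ``cell_size`` cells and
   keeps mutual-nearest-neighbour cell pairs (within a search radius) whose
   zero-mean unit-norm correlation reaches ``c_coarse``.
2. ``fine_refine`` re-localizes each candidate at pixel resolution by
   correlating a ``fine_window`` patch over ``+-fine_search`` offsets,
   keeping peaks above ``c_fine``.
3. ``geometric_consensus`` keeps correspondences whose displacement agrees
   with the component-wise median displacement within ``consensus_tolerance``
   — a deterministic robust filter (no random sampling).

``match_pair`` composes the three stages and reports both the inlier
key-point count and a normalized similarity in [0, 1]:
``n_keypoints / min(valid cells in a, valid cells in b)``.  An adapter hook
lets an external (e.g. pretrained neural) matcher drop into the identical
pipeline contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .errors import MatcherContractError


@dataclass(frozen=True)
class MatcherConfig:
    cell_size: int = 8
    search_radius: int = 10           # cells (Chebyshev window)
    c_coarse: float = 0.6
    c_fine: float = 0.7
    fine_window: int = 16             # pixels
    fine_search: int = 4              # +- pixels
    consensus_tolerance: float = 12.0 # pixels
    flat_cell_variance: float = 1e-4


DEFAULT_MATCHER = MatcherConfig()


class CoarsePair(NamedTuple):
    cell_a: tuple[int, int]  # (row, col)
    cell_b: tuple[int, int]
    score: float


@dataclass
class Correspondence:
    point_a: tuple[float, float]  # (x, y) sub-pixel coordinates
    point_b: tuple[float, float]
    coarse_score: float
    fine_score: float
    inlier: bool = False


@dataclass
class MatchResult:
    correspondences: list[Correspondence]
    n_keypoints: int
    similarity: float


# ---------------------------------------------------------------------------
# Stage 1: coarse cell matching
# ---------------------------------------------------------------------------

def _cell_descriptors(img: np.ndarray, cfg: MatcherConfig):
    """Zero-mean unit-norm per-cell descriptors plus a validity mask."""
    h, w = img.shape
    cs = cfg.cell_size
    if h % cs or w % cs:
        raise ValueError(f"cell size {cs} does not tile image shape {(h, w)}")
    gh, gw = h // cs, w // cs
    cells = (
        img.reshape(gh, cs, gw, cs).transpose(0, 2, 1, 3).reshape(gh, gw, cs * cs)
    ).astype(np.float32)
    mean = cells.mean(axis=2, keepdims=True)
    centered = cells - mean
    var = (centered**2).mean(axis=2)
    valid = var >= cfg.flat_cell_variance
    norm = np.sqrt((centered**2).sum(axis=2, keepdims=True))
    norm[norm == 0] = 1.0
    desc = centered / norm
    desc[~valid] = 0.0
    return desc, valid


def count_valid_cells(img: np.ndarray, cfg: MatcherConfig = DEFAULT_MATCHER) -> int:
    return int(_cell_descriptors(img, cfg)[1].sum())


def count_candidate_cells(img: np.ndarray, cfg: MatcherConfig = DEFAULT_MATCHER) -> int:
    """Valid cells that fine refinement could actually retain.

    Cells whose centre sits closer than ``fine_window/2 + fine_search`` to
    the border can never survive the refinement stage, so they are excluded
    from the similarity denominator (otherwise a perfect self-match could
    not reach similarity 1).
    """
    valid = _cell_descriptors(img, cfg)[1]
    gh, gw = valid.shape
    cs = cfg.cell_size
    m = cfg.fine_window // 2 + cfg.fine_search
    centers = np.arange(gh) * cs + cs // 2
    rows_ok = (centers >= m) & (centers + m <= img.shape[0])
    centers = np.arange(gw) * cs + cs // 2
    cols_ok = (centers >= m) & (centers + m <= img.shape[1])
    return int((valid & rows_ok[:, None] & cols_ok[None, :]).sum())


def coarse_match(
    a: np.ndarray, b: np.ndarray, cfg: MatcherConfig = DEFAULT_MATCHER
) -> list[CoarsePair]:
    """Mutual-nearest-neighbour cell correspondences within the search radius.

    Implemented as a loop over the (2R+1)^2 cell displacements, maintaining
    each cell's running best partner — equivalent to a full masked
    correlation matrix but far cheaper at the 60 x 80 default grid.
    """
    da, va = _cell_descriptors(a, cfg)
    db, vb = _cell_descriptors(b, cfg)
    gh, gw = da.shape[:2]
    if db.shape[:2] != (gh, gw):
        raise ValueError("coarse matching requires equally shaped images")
    n = gh * gw
    best_ab = np.full((gh, gw), -np.inf, dtype=np.float32)
    best_ab_idx = np.full((gh, gw), -1, dtype=np.int64)
    best_ba = np.full((gh, gw), -np.inf, dtype=np.float32)
    best_ba_idx = np.full((gh, gw), -1, dtype=np.int64)
    flat = np.arange(n).reshape(gh, gw)

    r = cfg.search_radius
    for di in range(-r, r + 1):
        a_i0, a_i1 = max(0, -di), gh - max(0, di)
        if a_i1 <= a_i0:
            continue
        for dj in range(-r, r + 1):
            a_j0, a_j1 = max(0, -dj), gw - max(0, dj)
            if a_j1 <= a_j0:
                continue
            sa = (slice(a_i0, a_i1), slice(a_j0, a_j1))
            sb = (slice(a_i0 + di, a_i1 + di), slice(a_j0 + dj, a_j1 + dj))
            corr = np.einsum("ijk,ijk->ij", da[sa], db[sb])
            upd = corr > best_ab[sa]
            best_ab[sa] = np.where(upd, corr, best_ab[sa])
            best_ab_idx[sa] = np.where(upd, flat[sb], best_ab_idx[sa])
            upd = corr > best_ba[sb]
            best_ba[sb] = np.where(upd, corr, best_ba[sb])
            best_ba_idx[sb] = np.where(upd, flat[sa], best_ba_idx[sb])

    pairs: list[CoarsePair] = []
    ai, aj = np.nonzero(va & (best_ab >= cfg.c_coarse) & (best_ab_idx >= 0))
    for i, j in zip(ai.tolist(), aj.tolist()):
        bflat = best_ab_idx[i, j]
        bi, bj = divmod(int(bflat), gw)
        if not vb[bi, bj]:
            continue
        if best_ba_idx[bi, bj] == flat[i, j]:  # mutual nearest neighbour
            pairs.append(CoarsePair((i, j), (bi, bj), float(best_ab[i, j])))
    return pairs


# ---------------------------------------------------------------------------
# Stage 2: fine refinement
# ---------------------------------------------------------------------------

def fine_refine(
    a: np.ndarray,
    b: np.ndarray,
    coarse_pairs: Sequence[CoarsePair],
    cfg: MatcherConfig = DEFAULT_MATCHER,
) -> list[Correspondence]:
    """Pixel-resolution re-localization of coarse candidates.

    For each coarse pair, a ``fine_window`` patch centred on the cell in
    ``a`` is correlated against all integer offsets within
    ``+-fine_search`` around the partner cell centre in ``b``; the peak
    offset refines the point and the pair is kept iff the peak correlation
    reaches ``c_fine``.  Windows that would leave the image are dropped
    (on either side, using the same ``fine_window/2 + fine_search`` margin
    that defines candidate cells).
    """
    if not coarse_pairs:
        return []
    cs, fw, s = cfg.cell_size, cfg.fine_window, cfg.fine_search
    half = fw // 2
    m = half + s
    h, w = a.shape
    centers_a = np.array(
        [(p.cell_a[0] * cs + cs // 2, p.cell_a[1] * cs + cs // 2) for p in coarse_pairs]
    )
    centers_b = np.array(
        [(p.cell_b[0] * cs + cs // 2, p.cell_b[1] * cs + cs // 2) for p in coarse_pairs]
    )
    ok = np.ones(len(coarse_pairs), dtype=bool)
    for centers in (centers_a, centers_b):
        ok &= (
            (centers[:, 0] >= m)
            & (centers[:, 0] + m <= h)
            & (centers[:, 1] >= m)
            & (centers[:, 1] + m <= w)
        )
    idx = np.nonzero(ok)[0]
    if not len(idx):
        return []
    n = len(idx)
    ca, cb = centers_a[idx], centers_b[idx]
    rows = np.arange(fw)
    sup_rows = np.arange(fw + 2 * s)
    pa = a[
        (ca[:, 0, None, None] - half) + rows[None, :, None],
        (ca[:, 1, None, None] - half) + rows[None, None, :],
    ].reshape(n, -1)
    pa = pa - pa.mean(axis=1, keepdims=True)
    na = np.sqrt((pa**2).sum(axis=1))
    sup = b[
        (cb[:, 0, None, None] - half - s) + sup_rows[None, :, None],
        (cb[:, 1, None, None] - half - s) + sup_rows[None, None, :],
    ]  # (n, fw + 2s, fw + 2s)
    best_val = np.full(n, -np.inf, dtype=np.float64)
    best_off = np.zeros((n, 2), dtype=np.int64)
    # one vectorized correlation per offset; first-seen wins ties (row-major)
    for oy in range(2 * s + 1):
        for ox in range(2 * s + 1):
            win = sup[:, oy : oy + fw, ox : ox + fw].reshape(n, -1)
            wc = win - win.mean(axis=1, keepdims=True)
            wn = np.sqrt((wc**2).sum(axis=1))
            denom = na * wn
            corr = np.where(denom > 0, (pa * wc).sum(axis=1) / np.where(denom > 0, denom, 1.0), -np.inf)
            upd = corr > best_val
            best_val[upd] = corr[upd]
            best_off[upd] = (oy - s, ox - s)
    out: list[Correspondence] = []
    for k in np.nonzero(best_val >= cfg.c_fine)[0]:
        p = coarse_pairs[idx[k]]
        out.append(
            Correspondence(
                point_a=(float(ca[k, 1]), float(ca[k, 0])),
                point_b=(float(cb[k, 1] + best_off[k, 1]), float(cb[k, 0] + best_off[k, 0])),
                coarse_score=p.score,
                fine_score=float(best_val[k]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Stage 3: geometric consensus
# ---------------------------------------------------------------------------

def geometric_consensus(
    correspondences: Sequence[Correspondence], cfg: MatcherConfig = DEFAULT_MATCHER
) -> list[Correspondence]:
    """Flag inliers by distance to the median displacement (deterministic)."""
    if not correspondences:
        return []
    disp = np.array(
        [
            (c.point_b[0] - c.point_a[0], c.point_b[1] - c.point_a[1])
            for c in correspondences
        ]
    )
    consensus = np.median(disp, axis=0)
    dist = np.hypot(*(disp - consensus).T)
    out = []
    for c, d in zip(correspondences, dist):
        out.append(
            Correspondence(c.point_a, c.point_b, c.coarse_score, c.fine_score,
                           inlier=bool(d <= cfg.consensus_tolerance))
        )
    return out


# ---------------------------------------------------------------------------
# Full pair matching
# ---------------------------------------------------------------------------

def match_pair(
    a: np.ndarray, b: np.ndarray, cfg: MatcherConfig = DEFAULT_MATCHER
) -> MatchResult:
    """Coarse -> fine -> consensus matching of two canonical images.

    ``similarity = n_inliers / min(candidate cells in a, candidate cells
    in b)`` where candidate cells are the valid (non-flat) cells that fine
    refinement could retain.  The argument order is canonicalized
    internally (lexicographic on image bytes), which makes the score
    exactly symmetric.
    """
    flipped = b.tobytes() < a.tobytes()
    if flipped:
        a, b = b, a
    n_candidates = min(count_candidate_cells(a, cfg), count_candidate_cells(b, cfg))
    if n_candidates == 0:
        return MatchResult([], 0, 0.0)
    coarse = coarse_match(a, b, cfg)
    fine = fine_refine(a, b, coarse, cfg)
    flagged = geometric_consensus(fine, cfg)
    if flipped:
        flagged = [
            Correspondence(c.point_b, c.point_a, c.coarse_score, c.fine_score, c.inlier)
            for c in flagged
        ]
    n_inliers = sum(c.inlier for c in flagged)
    return MatchResult(flagged, n_inliers, n_inliers / n_candidates)


class CoarseToFineMatcher:
    """The built-in matcher as a reusable callable ``(a, b) -> MatchResult``."""

    def __init__(self, cfg: MatcherConfig = DEFAULT_MATCHER):
        self.cfg = cfg

    def __call__(self, a: np.ndarray, b: np.ndarray) -> MatchResult:
        return match_pair(a, b, self.cfg)


class ExternalMatcherAdapter:
    """Wrap an external matcher into the pipeline's matcher contract.

    The wrapped callable must map two canonical images to either a
    :class:`MatchResult` or a ``(correspondences, similarity)`` tuple,
    deterministically for fixed inputs.  Similarity outside [0, 1] raises
    :class:`MatcherContractError`.
    """

    def __init__(self, fn: Callable):
        self._fn = fn

    def __call__(self, a: np.ndarray, b: np.ndarray) -> MatchResult:
        res = self._fn(a, b)
        if isinstance(res, MatchResult):
            corr, sim = res.correspondences, res.similarity
        else:
            corr, sim = res
            corr = list(corr)
        if not (0.0 <= float(sim) <= 1.0) or not np.isfinite(sim):
            raise MatcherContractError(f"external matcher returned similarity {sim!r}")
        n_inl = sum(getattr(c, "inlier", True) for c in corr)
        return MatchResult(list(corr), int(n_inl), float(sim))


def draw_matches(
    a: np.ndarray, b: np.ndarray, result: MatchResult, path, max_lines: int = 200
) -> None:
    """Write a side-by-side visualization with inlier correspondence lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h, w = a.shape
    canvas = np.concatenate([a, b], axis=1)
    fig, ax = plt.subplots(figsize=(10, 7))
    ax.imshow(canvas, cmap="gray")
    inliers = [c for c in result.correspondences if c.inlier][:max_lines]
    for c in inliers:
        ax.plot(
            [c.point_a[0], c.point_b[0] + w],
            [c.point_a[1], c.point_b[1]],
            lw=0.5,
            color="lime",
        )
    ax.set_title(f"{result.n_keypoints} key points, similarity {result.similarity:.3f}")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
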