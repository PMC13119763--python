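"""One-to-one IR-VIS marker correspondence by constrained RANSAC.

The two modalities see the same coplanar markers through rigidly mounted,
nearly parallel cameras, so the true correspondence is orientation
preserving, order preserving along both image axes, and well approximated
by an affine map.  The matcher exploits all three facts:

* candidate pairs are pre-filtered by scale-normalised nearest-neighbour
  distance signatures;
* RANSAC samples LWIR triplets paired with shortlisted VIS triplets, and a
  hypothesis is discarded outright if the triangle orientations disagree,
  the fitted affine has non-positive determinant (a reflection), or the
  Spearman rank correlations of matched x / y coordinates fall below a
  permissive floor;
* for every surviving hypothesis the projected LWIR points are assigned to
  VIS points by an optimal rectangular assignment with an explicit
  non-assignment cost, so missing and spurious detections are tolerated.

The best hypothesis (most inliers, ties broken by total residual) is
refined on all inliers and re-assigned under stricter distance and
monotonicity thresholds until the pair set is a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

__all__ = [
    "Affine2D",
    "CorrespondenceSet",
    "MatchConfig",
    "NoMatchError",
    "neighbor_signature",
    "shortlist",
    "oriented_area_sign",
    "estimate_affine",
    "ransac_match",
    "monotonicity_check",
    "refine_and_finalize",
]

_BIG = 1e12


@dataclass
class Affine2D:
    """2D affine map p -> linear @ p + translation."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=np.float64).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(2)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=np.float64) @ self.linear.T + self.translation

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.linear))

    @property
    def scale(self) -> float:
        """Isotropic scale factor sqrt(|det|)."""
        return float(np.sqrt(abs(self.det)))

    @property
    def rotation_deg(self) -> float:
        """Rotation angle of the polar decomposition of the linear part."""
        u, _s, vt = np.linalg.svd(self.linear)
        R = u @ vt
        if np.linalg.det(R) < 0:   # reflection: report the improper angle
            R = R @ np.diag([1.0, -1.0])
        return float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))

    @property
    def anisotropy(self) -> float:
        """Ratio of the larger to the smaller singular value (>= 1)."""
        s = np.linalg.svd(self.linear, compute_uv=False)
        return float(s[0] / s[1]) if s[1] > 0 else np.inf

    def as_matrix(self) -> np.ndarray:
        M = np.eye(3)
        M[:2, :2] = self.linear
        M[:2, 2] = self.translation
        return M


@dataclass
class CorrespondenceSet:
    """One-to-one (ir_index, vis_index) pairs with the fitted affine map."""

    pairs: list[tuple[int, int]]
    transform: Affine2D
    residuals: np.ndarray
    rho_x: float
    rho_y: float
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        irs = [i for i, _ in self.pairs]
        viss = [j for _, j in self.pairs]
        if len(set(irs)) != len(irs) or len(set(viss)) != len(viss):
            raise ValueError("pairs must be one-to-one on both sides")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


class NoMatchError(RuntimeError):
    """No hypothesis survived the geometric constraints."""

    def __init__(self, diagnostics: dict):
        self.diagnostics = diagnostics
        super().__init__(f"no-match: {diagnostics}")


@dataclass
class MatchConfig:
    k: int = 4                      # signature neighbours
    shortlist_m: int = 5
    n_iterations: int = 2000
    inlier_radius: float = 5.0      # permissive, LWIR px scaled to VIS frame
    strict_radius: float = 2.0      # final assignment, LWIR px scaled
    # Spearman floors: with ~8 markers arranged in rows/columns, coordinates
    # within a row are near-tied and localization noise scrambles their rank
    # order on perfectly correct matches (worst-case rho ~0.8 for two
    # reversed three-marker rows), so the strict floor matches the
    # permissive one; the strict *distance* radius is the discriminating
    # final filter, monotonicity guards gross crossings and mirrors.
    rho_min: float = 0.8
    rho_min_strict: float = 0.8
    # a hypothesis must generalise beyond its own defining triplet, and a
    # valid registration must explain the majority of detected markers
    # (the protocol assumes at most ~25% missing/spurious detections, so
    # the true correspondence always covers >= 75% of the smaller set)
    min_inliers: int = 4
    min_inlier_frac: float = 0.55
    # rigid mounting with nearly parallel optical axes: the IR->VIS map is
    # close to an axis-aligned scaling, so hypotheses with substantial
    # rotation or anisotropic stretch are physically impossible
    max_rotation_deg: float = 15.0
    max_anisotropy: float = 1.5
    early_exit: bool = True


def neighbor_signature(points: np.ndarray, k: int = 4) -> np.ndarray:
    """Per-point sorted distances to the k nearest same-modality neighbours,
    normalised by their mean (scale invariant by construction)."""
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} points for k={k} signatures, got {n}")
    D = cdist(pts, pts)
    np.fill_diagonal(D, np.inf)
    sigs = np.sort(D, axis=1)[:, :k]
    return sigs / sigs.mean(axis=1, keepdims=True)


def shortlist(sig_ir: np.ndarray, sig_vis: np.ndarray, m: int = 5) -> np.ndarray:
    """Indices of the m most signature-similar VIS points per IR point."""
    if sig_ir.shape[1] != sig_vis.shape[1]:
        raise ValueError("signatures must use the same k")
    D = cdist(sig_ir, sig_vis)
    m = min(m, sig_vis.shape[0])
    return np.argsort(D, axis=1)[:, :m]


def oriented_area_sign(p1, p2, p3) -> int:
    """Sign of the cross product (p2-p1) x (p3-p1); 0 for collinear points."""
    p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3))
    cross = ((p2[0] - p1[0]) * (p3[1] - p1[1])
             - (p2[1] - p1[1]) * (p3[0] - p1[0]))
    return int(np.sign(cross))


def estimate_affine(ir_pts: np.ndarray, vis_pts: np.ndarray) -> Affine2D:
    """Least-squares affine minimising sum ||A p_ir + t - p_vis||^2."""
    ir = np.asarray(ir_pts, dtype=np.float64)
    vis = np.asarray(vis_pts, dtype=np.float64)
    if len(ir) < 3:
        raise ValueError("need at least 3 point pairs")
    X = np.column_stack([ir, np.ones(len(ir))])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("degenerate (collinear) point configuration")
    coeffs, *_ = np.linalg.lstsq(X, vis, rcond=None)
    return Affine2D(linear=coeffs[:2].T, translation=coeffs[2])


def monotonicity_check(pairs, ir_pts, vis_pts, rho_min: float
                       ) -> tuple[float, float, bool]:
    """Spearman rank correlation of matched x and y coordinates.

    The nearly parallel camera axes mean the relative ordering of markers
    along each image axis must be preserved; ties get average ranks.
    """
    ir = np.asarray(ir_pts, dtype=np.float64)
    vis = np.asarray(vis_pts, dtype=np.float64)
    ii = [i for i, _ in pairs]
    jj = [j for _, j in pairs]
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    rho_x = float(spearmanr(ir[ii, 0], vis[jj, 0]).statistic)
    rho_y = float(spearmanr(ir[ii, 1], vis[jj, 1]).statistic)
    ok = rho_x >= rho_min and rho_y >= rho_min
    return rho_x, rho_y, ok


def _assign(projected: np.ndarray, vis_pts: np.ndarray, cap: float
            ) -> list[tuple[int, int]]:
    """Optimal one-to-one assignment with non-assignment cost = cap.

    Rectangular assignment on an augmented square matrix: any point may
    stay unmatched at cost ``cap``, so a pair is formed only if its
    distance beats the cap.
    """
    M, N = len(projected), len(vis_pts)
    D = cdist(projected, vis_pts)
    C = np.full((M + N, N + M), _BIG)
    C[:M, :N] = D
    C[:M, N:] = np.where(np.eye(M, dtype=bool), cap, _BIG)
    C[M:, :N] = np.where(np.eye(N, dtype=bool), cap, _BIG)
    C[M:, N:] = 0.0
    rows, cols = linear_sum_assignment(C)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if r < M and c < N and D[r, c] <= cap]


def _greedy_assign(projected: np.ndarray, vis_pts: np.ndarray, cap: float
                   ) -> list[tuple[int, int]]:
    """Greedy nearest-first fallback (speed over optimality)."""
    D = cdist(projected, vis_pts)
    order = np.argsort(D, axis=None)
    used_r, used_c, pairs = set(), set(), []
    for flat in order:
        r, c = np.unravel_index(flat, D.shape)
        if D[r, c] > cap:
            break
        if r in used_r or c in used_c:
            continue
        pairs.append((int(r), int(c)))
        used_r.add(r)
        used_c.add(c)
    return pairs


def _ransac_phase(ir, vis, short, rng, cfg, assign, required, diag,
                  phase, n_iter, best=None):
    """One sampling phase; returns the best ((score), pairs, affine) found."""
    M, N = len(ir), len(vis)
    for _ in range(n_iter):
        diag["iterations"] += 1
        tri = rng.choice(M, size=3, replace=False)
        if phase == "shortlist":
            cand = np.array([short[i][rng.integers(len(short[i]))]
                             for i in tri])
            if len(set(cand.tolist())) < 3:
                diag["degenerate"] += 1
                continue
        else:
            cand = rng.choice(N, size=3, replace=False)
        s_ir = oriented_area_sign(*ir[tri])
        s_vis = oriented_area_sign(*vis[cand])
        if s_ir == 0 or s_vis == 0:
            diag["degenerate"] += 1
            continue
        if s_ir != s_vis:
            diag["orientation"] += 1
            continue
        try:
            A = estimate_affine(ir[tri], vis[cand])
        except ValueError:
            diag["degenerate"] += 1
            continue
        if A.det <= 0:
            diag["determinant"] += 1
            continue
        if (abs(A.rotation_deg) > cfg.max_rotation_deg
                or A.anisotropy > cfg.max_anisotropy):
            diag["geometry"] += 1
            continue
        cap = cfg.inlier_radius * A.scale
        proj = A(ir)
        pairs = assign(proj, vis, cap)
        if len(pairs) < required:
            diag["too_few_inliers"] += 1
            continue
        _, _, ok = monotonicity_check(pairs, ir, vis, cfg.rho_min)
        if not ok:
            diag["monotonicity"] += 1
            continue
        resid = np.linalg.norm(proj[[i for i, _ in pairs]]
                               - vis[[j for _, j in pairs]], axis=1)
        key = (len(pairs), -float(resid.sum()))
        if best is None or key > best[0]:
            best = (key, pairs, A)
            if (cfg.early_exit and len(pairs) == min(M, N)
                    and resid.mean() < 0.1 * cap):
                break
    return best


def ransac_match(ir_pts: np.ndarray, vis_pts: np.ndarray,
                 config: MatchConfig | None = None,
                 seed: int | None = 0,
                 greedy: bool = False) -> CorrespondenceSet:
    """Constrained RANSAC over shortlisted triplets; deterministic per seed.

    Raises :class:`NoMatchError` with rejection-reason counts when no
    hypothesis satisfies the orientation, determinant, and monotonicity
    constraints with at least ``min_inliers`` assigned pairs.
    """
    cfg = config or MatchConfig()
    ir = np.asarray(ir_pts, dtype=np.float64)
    vis = np.asarray(vis_pts, dtype=np.float64)
    M, N = len(ir), len(vis)
    diag = {"orientation": 0, "determinant": 0, "degenerate": 0,
            "geometry": 0, "too_few_inliers": 0, "monotonicity": 0,
            "iterations": 0}
    if M < 3 or N < 3:
        raise NoMatchError({**diag, "reason": "fewer than 3 points in a modality"})

    k = min(cfg.k, M - 1, N - 1)
    short = shortlist(neighbor_signature(ir, k), neighbor_signature(vis, k),
                      cfg.shortlist_m)
    rng = np.random.default_rng(seed)
    assign = _greedy_assign if greedy else _assign
    required = max(cfg.min_inliers,
                   int(np.ceil(cfg.min_inlier_frac * min(M, N))))

    # Phase 1 samples candidate partners from the signature shortlists;
    # if no hypothesis survives (spurious detections can corrupt the
    # signatures of nearby points), phase 2 widens the candidate pool to
    # every VIS point.  The shortlist only prunes the search space; the
    # geometric constraints alone decide validity.
    best = None  # ((n_inliers, -resid_sum), pairs, affine)
    plan = [("shortlist", cfg.n_iterations), ("uniform", 4 * cfg.n_iterations)]
    for phase, n_iter in plan:
        if phase == "uniform" and best is not None:
            break   # the widened search is only a rescue path
        best = _ransac_phase(ir, vis, short, rng, cfg, assign, required,
                             diag, phase, n_iter)

    if best is None:
        raise NoMatchError(diag)
    _, pairs, A = best
    result = refine_and_finalize(pairs, ir, vis, cfg, diagnostics=diag,
                                 greedy=greedy)
    result.seed = seed
    return result


def refine_and_finalize(pairs, ir_pts, vis_pts, cfg: MatchConfig | None = None,
                        diagnostics: dict | None = None,
                        greedy: bool = False) -> CorrespondenceSet:
    """Refit on all inliers and re-assign under strict thresholds to a
    fixed point (a second pass changes no pair)."""
    cfg = cfg or MatchConfig()
    ir = np.asarray(ir_pts, dtype=np.float64)
    vis = np.asarray(vis_pts, dtype=np.float64)
    assign = _greedy_assign if greedy else _assign
    diag = diagnostics or {}

    current = sorted(pairs)
    A = None
    for _ in range(20):
        if len(current) < cfg.min_inliers:
            raise NoMatchError({**diag, "reason": "inlier collapse during refinement"})
        A = estimate_affine(ir[[i for i, _ in current]],
                            vis[[j for _, j in current]])
        if A.det <= 0:
            raise NoMatchError({**diag, "reason": "refined transform is a reflection"})
        new = sorted(assign(A(ir), vis, cfg.strict_radius * A.scale))
        if new == current:
            break
        current = new
    if len(current) < cfg.min_inliers:
        raise NoMatchError({**diag, "reason": "inlier collapse during refinement"})
    rho_x, rho_y, ok = monotonicity_check(current, ir, vis, cfg.rho_min_strict)
    if not ok:
        raise NoMatchError({**diag, "reason": "strict monotonicity failed",
                            "rho_x": rho_x, "rho_y": rho_y})
    proj = A(ir[[i for i, _ in current]])
    resid = np.linalg.norm(proj - vis[[j for _, j in current]], axis=1)
    return CorrespondenceSet(pairs=current, transform=A, residuals=resid,
                             rho_x=rho_x, rho_y=rho_y, diagnostics=diag)
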