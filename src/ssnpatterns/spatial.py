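"""Geographic occurrence patterns, community dissimilarity and RDA.

Spatial questions asked of the connected components (CCs):

* in which sea regions, and in which depth layers of each region, does a CC
  occur (any positive relative abundance counts as presence);
* how many CCs follow each exact region combination (endemic, pairwise
  shared, ubiquitous, ...);
* how compositionally similar are two regions, via Bray-Curtis dissimilarity
  B and its Jaccard transform J = 2B/(1+B) on per-region composite vectors;
* how much CC abundance variation is explained by the environmental
  variables, via redundancy analysis (RDA) with permutation ANOVA and greedy
  forward selection of explanatory variables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _sp_braycurtis

from .core import DEPTH_TYPES, SampleMetadata, TaxonomyPath
from .network import ConnectedComponent, cc_abundance

__all__ = [
    "OccurrenceProfile",
    "RDAResult",
    "occurrence_profiles",
    "combination_counts",
    "depth_sharing_matrix",
    "bray_curtis",
    "jaccard_from_bray",
    "region_dissimilarity",
    "rda_fit",
    "rda_anova",
    "forward_select_env",
]


@dataclass
class OccurrenceProfile:
    """Where one CC occurs: regions, and depth layers within each region."""

    cc_id: str
    regions: frozenset[str]
    layers_by_region: dict[str, frozenset[str]] = field(default_factory=dict)


@dataclass
class RDAResult:
    """Redundancy analysis summary.

    ``constrained_proportion`` is the share of total community variance
    explained by the environmental predictors; ``axis_proportions`` splits it
    over canonical axes.
    """

    constrained_proportion: float
    axis_proportions: list[float]
    site_scores: np.ndarray
    variable_scores: np.ndarray
    pseudo_F: float
    p_value: float | None = None


def occurrence_profiles(
    ccs: list[ConnectedComponent],
    table: pd.DataFrame,
    metadata: list[SampleMetadata],
) -> list[OccurrenceProfile]:
    """Region and depth-layer occupancy of each CC from positive abundances."""
    meta = {s.sample_id: s for s in metadata}
    unknown = sorted(set(table.columns) - set(meta))
    if unknown:
        raise ValueError(f"samples without metadata: {unknown[:10]}")
    profiles = []
    for cc in ccs:
        vec = cc_abundance(cc, table)
        positive = vec.index[vec.to_numpy() > 0]
        regions: set[str] = set()
        layers: dict[str, set[str]] = {}
        for sid in positive:
            s = meta[sid]
            regions.add(s.region)
            layers.setdefault(s.region, set()).add(s.depth_type)
        profiles.append(
            OccurrenceProfile(
                cc_id=cc.cc_id,
                regions=frozenset(regions),
                layers_by_region={r: frozenset(v) for r, v in layers.items()},
            )
        )
    return profiles


def combination_counts(
    profiles: list[OccurrenceProfile],
) -> dict[frozenset[str], int]:
    """Count CCs per exact region combination (a CC counts once, for its
    full region set)."""
    return dict(Counter(p.regions for p in profiles if p.regions))


def depth_sharing_matrix(
    profiles: list[OccurrenceProfile],
    region_x: str,
    region_y: str,
    restrict: set[str],
    layers: tuple[str, ...] = DEPTH_TYPES,
) -> pd.DataFrame:
    """Percentage of CCs present in layer pairs of two regions.

    ``restrict`` is the id set of CCs exclusively shared between the two
    regions.  Cell (layer_y, layer_x) = 100 * |CCs present in layer_x of
    region_x and layer_y of region_y| / |restrict|.  A CC occupying several
    layers contributes to several cells, so the matrix can sum past 100%.
    """
    if not restrict:
        raise ValueError("empty restriction set for depth-layer sharing")
    chosen = [p for p in profiles if p.cc_id in restrict]
    missing = restrict - {p.cc_id for p in chosen}
    if missing:
        raise KeyError(f"profiles missing for {sorted(missing)[:10]}")
    mat = pd.DataFrame(0.0, index=list(layers), columns=list(layers))
    for p in chosen:
        for lx in p.layers_by_region.get(region_x, ()):
            for ly in p.layers_by_region.get(region_y, ()):
                mat.loc[ly, lx] += 1
    return 100.0 * mat / len(restrict)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity B = sum|x-y| / sum(x+y) of two non-negative
    abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_sp_braycurtis(x, y))


def jaccard_from_bray(b: float) -> float:
    """Abundance-based Jaccard dissimilarity J = 2B/(1+B)."""
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"Bray-Curtis value {b} outside [0, 1]")
    return 2.0 * b / (1.0 + b)


def region_dissimilarity(
    table: pd.DataFrame,
    taxonomy: dict[str, TaxonomyPath],
    division: str,
    metadata: list[SampleMetadata],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise region dissimilarity (B and J) for one taxonomic division.

    Per region, the division's metabarcode abundances are averaged over that
    region's samples into a composite vector (the mean neutralizes unequal
    sample counts per region); B and J are computed between composites.
    Returns ``(bray_matrix, jaccard_matrix)``.
    """
    ids = [
        rid
        for rid in table.index
        if rid in taxonomy and taxonomy[rid]["division"] == division
    ]
    if not ids:
        raise ValueError(f"no metabarcodes of division {division!r} in table")
    sub = table.loc[ids]
    by_region: dict[str, list[str]] = {}
    for s in metadata:
        if s.sample_id in sub.columns:
            by_region.setdefault(s.region, []).append(s.sample_id)
    regions = sorted(r for r, cols in by_region.items() if cols)
    composites = {r: sub[by_region[r]].mean(axis=1).to_numpy() for r in regions}
    bmat = pd.DataFrame(0.0, index=regions, columns=regions)
    jmat = pd.DataFrame(0.0, index=regions, columns=regions)
    for i, ra in enumerate(regions):
        for rb in regions[i + 1 :]:
            b = bray_curtis(composites[ra], composites[rb])
            j = jaccard_from_bray(b)
            bmat.loc[ra, rb] = bmat.loc[rb, ra] = b
            jmat.loc[ra, rb] = jmat.loc[rb, ra] = j
    return bmat, jmat


def _ss(m: np.ndarray) -> float:
    return float((m * m).sum())


def _prepare_xy(
    Y: np.ndarray, X: np.ndarray, check_rank: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Complete-case filtering, centering of Y, centering+standardization of X."""
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim != 2 or X.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise ValueError("Y and X must be 2-D with matching row counts")
    ok = ~np.isnan(X).any(axis=1) & ~np.isnan(Y).any(axis=1)
    Y, X = Y[ok], X[ok]
    n, q = X.shape
    if n <= q + 1:
        raise ValueError(f"need n > q+1 rows after complete-case filtering (n={n}, q={q})")
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    degenerate = [int(j) for j in np.nonzero(sd == 0)[0]]
    if degenerate:
        raise ValueError(f"zero-variance predictor column(s) at index {degenerate}")
    Xs = Xc / sd
    rank = np.linalg.matrix_rank(Xs)
    if check_rank and rank < q:
        collinear = []
        for j in range(1, q):
            r = np.linalg.lstsq(Xs[:, :j], Xs[:, j], rcond=None)[1]
            if r.size and float(r[0]) < 1e-10 * _ss(Xs[:, j]):
                collinear.append(j)
        raise ValueError(f"rank-deficient predictors; collinear column index {collinear}")
    return Yc, Xs


def rda_fit(Y: np.ndarray, X: np.ndarray) -> RDAResult:
    """Redundancy analysis of a community matrix on environmental predictors.

    Y (samples x CCs) is column-centered; X (samples x q) is centered and
    standardized.  The fitted values Yhat = X (X'X)^-1 X' Y are decomposed by
    SVD into canonical axes; the constrained proportion is SS(Yhat)/SS(Y).
    """
    Yc, Xs = _prepare_xy(Y, X)
    n, q = Xs.shape
    coef, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    Yhat = Xs @ coef
    ss_total = _ss(Yc)
    if ss_total == 0:
        raise ValueError("response matrix has no variance")
    ss_fit = _ss(Yhat)
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    keep = s > s.max() * 1e-12 if s.size else np.zeros(0, dtype=bool)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    resid_df = n - q - 1
    ss_resid = ss_total - ss_fit
    pseudo_f = (ss_fit / q) / (ss_resid / resid_df) if ss_resid > 0 else np.inf
    site_scores = U * s
    # variable scores: correlation of each predictor with each canonical axis
    denom = np.linalg.norm(Xs, axis=0)[:, None] * np.linalg.norm(site_scores, axis=0)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        var_scores = np.where(denom > 0, (Xs.T @ site_scores) / denom, 0.0)
    return RDAResult(
        constrained_proportion=ss_fit / ss_total,
        axis_proportions=[float(v) for v in (s**2) / ss_total],
        site_scores=site_scores,
        variable_scores=var_scores,
        pseudo_F=float(pseudo_f),
    )


def rda_anova(
    Y: np.ndarray,
    X: np.ndarray,
    n_perm: int = 999,
    scope: str = "global",
    n_axes: int = 2,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Permutation ANOVA for the global RDA or its leading axes.

    Global test: pseudo-F = (SS(Yhat)/q) / (SS(Y-Yhat)/(n-q-1)); rows of Y
    are permuted without restriction and p = (1 + #{F* >= F}) / (1 + n_perm).
    Axis tests are sequential: for axis i the variance explained by earlier
    axes is held fixed and the residual rows are permuted.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(rng)
    Yc, Xs = _prepare_xy(Y, X)
    n, q = Xs.shape
    hat = Xs @ np.linalg.pinv(Xs)
    resid_df = n - q - 1

    def f_global(Ym: np.ndarray) -> float:
        Ym = Ym - Ym.mean(axis=0)
        fit = _ss(hat @ Ym)
        res = max(_ss(Ym) - fit, 0.0)  # guard against cancellation at perfect fit
        if res == 0.0:
            return np.inf
        return (fit / q) / (res / resid_df)

    if scope == "global":
        f_obs = f_global(Yc)
        hits = sum(
            f_global(Yc[rng.permutation(n)]) >= f_obs for _ in range(n_perm)
        )
        return {"pseudo_F": f_obs, "p_value": (1 + hits) / (1 + n_perm)}
    if scope != "axes":
        raise ValueError("scope must be 'global' or 'axes'")

    out = []
    Yhat = hat @ Yc
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    ss_resid = _ss(Yc) - _ss(Yhat)
    for i in range(min(n_axes, s.size)):
        # held-fixed part: fit of axes < i; permuted part: everything else
        fixed = (U[:, :i] * s[:i]) @ Vt[:i] if i else np.zeros_like(Yc)
        remainder = Yc - fixed
        f_obs = (s[i] ** 2) / (ss_resid / resid_df)
        hits = 0
        for _ in range(n_perm):
            Yp = fixed + remainder[rng.permutation(n)]
            Yp = Yp - Yp.mean(axis=0)
            fit_p = hat @ Yp
            sp = np.linalg.svd(fit_p, compute_uv=False)
            res_p = _ss(Yp) - _ss(fit_p)
            f_p = (sp[i] ** 2) / (res_p / resid_df) if sp.size > i else 0.0
            if f_p >= f_obs:
                hits += 1
        out.append({"axis": i + 1, "pseudo_F": float(f_obs), "p_value": (1 + hits) / (1 + n_perm)})
    return {"axes": out}


def forward_select_env(
    Y: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    alpha: float = 0.05,
    n_perm: int = 199,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Greedy forward selection of environmental variables for the RDA.

    At each step the candidate adding the most constrained variance is
    admitted if its partial pseudo-F is significant at ``alpha`` under row
    permutation of the current-model residuals; selection stops otherwise.
    """
    rng = np.random.default_rng(rng)
    # collinear candidates are tolerated here: a redundant variable adds no
    # variance and is simply never admitted
    Yc, Xs = _prepare_xy(Y, X, check_rank=False)
    n, q = Xs.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(q)]
    if len(names) != q:
        raise ValueError("names length must match predictor count")
    selected: list[int] = []
    remaining = list(range(q))
    ss_total = _ss(Yc)

    def fit_ss(cols: list[int]) -> float:
        if not cols:
            return 0.0
        Xsub = Xs[:, cols]
        coef, *_ = np.linalg.lstsq(Xsub, Yc, rcond=None)
        return _ss(Xsub @ coef)

    while remaining:
        ss_cur = fit_ss(selected)
        gains = [(fit_ss(selected + [j]) - ss_cur, j) for j in remaining]
        gain, best = max(gains)
        if gain <= ss_total * 1e-12:
            break
        k_new = len(selected) + 1
        ss_new = ss_cur + gain
        f_obs = gain / ((ss_total - ss_new) / (n - k_new - 1))
        # Freedman-Lane style: permute residuals of the current model
        if selected:
            Xcur = Xs[:, selected]
            coef, *_ = np.linalg.lstsq(Xcur, Yc, rcond=None)
            fitted = Xcur @ coef
        else:
            fitted = np.zeros_like(Yc)
        resid = Yc - fitted
        hits = 0
        for _ in range(n_perm):
            Yp = fitted + resid[rng.permutation(n)]
            Yp = Yp - Yp.mean(axis=0)
            ssc = fit_ss_perm(Yp, Xs, selected)
            ssn = fit_ss_perm(Yp, Xs, selected + [best])
            f_p = (ssn - ssc) / ((_ss(Yp) - ssn) / (n - k_new - 1))
            if f_p >= f_obs:
                hits += 1
        if (1 + hits) / (1 + n_perm) >= alpha:
            break
        selected.append(best)
        remaining.remove(best)
    return [names[j] for j in selected]


def fit_ss_perm(Yp: np.ndarray, Xs: np.ndarray, cols: list[int]) -> float:
    if not cols:
        return 0.0
    Xsub = Xs[:, cols]
    coef, *_ = np.linalg.lstsq(Xsub, Yp, rcond=None)
    return _ss(Xsub @ coef)
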