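"""Subject- and group-level GLM activation mapping with cluster inference.

Two subject-level models are provided:

* **boxcar** — ordinary least squares on ``[intercept, stimulus boxcar]``;
  in the rodent brain the hemodynamic response is fast enough that the
  unconvolved boxcar fits better than a canonical HRF.  The per-voxel
  statistic is the signed t of the boxcar coefficient, mapped to a z score.
* **FIR** — the stimulus boxcar convolved with a finite-impulse-response
  basis (default 4 lag bins over a 16-s window), assessed with an omnibus
  F-test that all FIR coefficients are zero, mapped to a one-sided
  (always positive) z score.  Polarity is assigned later from the response
  shape, not from the F statistic.

Cluster-extent correction uses a permutation null of the maximum cluster
extent, built by circularly shifting the stimulus timing and recomputing
the GLM — self-contained and assumption-light, in place of Gaussian
random-field theory.  Supra-threshold voxels are grouped by
26-connectivity, separately for positive and negative excursions.

Group-level maps are one-sample t-tests across subject z maps, mapped back
to z, with a sign-flipping permutation null for cluster correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.special import ndtri_exp

from .paradigm import StimulationParadigm, build_stimulus_timecourse

__all__ = [
    "GLMResult",
    "ClusterMask",
    "boxcar_glm",
    "fir_design",
    "fir_glm",
    "cluster_correct",
    "group_level_map",
    "group_cluster_correct",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_Z_CAP = 8.0
_Z_MAX = 40.0  # numerical ceiling of the statistic->z quantile map


def _t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Signed t -> z through matched tail probabilities (numerically stable)."""
    t = np.asarray(t, dtype=float)
    logp = stats.t.logsf(np.abs(t), dof)
    z = np.clip(-ndtri_exp(logp), 0.0, _Z_MAX)
    return np.sign(t) * z


def _f_to_z(f: np.ndarray, dfn: int, dfd: int) -> np.ndarray:
    """F -> one-sided positive z through the upper tail probability."""
    logp = stats.f.logsf(np.asarray(f, dtype=float), dfn, dfd)
    return np.clip(-ndtri_exp(logp), 0.0, _Z_MAX)


@dataclass
class GLMResult:
    """Per-voxel GLM fit and z-statistic map for one series."""

    design: pd.DataFrame           # time x named regressors (incl. intercept)
    beta: np.ndarray               # (x, y, z, n_regressors)
    sigma2: np.ndarray             # residual variance map
    z_map: np.ndarray              # 3-D statistic map
    dof: int
    kind: str                      # "boxcar" | "fir"
    tr_s: float
    valid_mask: np.ndarray
    paradigm: StimulationParadigm | None = None

    def __post_init__(self) -> None:
        if self.dof <= 0:
            raise ValueError("degrees of freedom must be positive")


@dataclass
class ClusterMask:
    """Surviving supra-threshold clusters after extent correction."""

    labels: np.ndarray             # 3-D int: 0 background, 1..k surviving clusters
    table: pd.DataFrame            # label, extent, sign, p
    z_threshold: float
    alpha: float
    n_perm: int
    seed: int

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_clusters(self) -> int:
        return int(len(self.table))


def _prepare(data: np.ndarray, valid_mask: np.ndarray | None):
    if data.ndim != 4:
        raise ValueError("series data must be 4-D (x, y, z, t)")
    shape3d = data.shape[:3]
    if valid_mask is None:
        valid_mask = ~np.any(np.isnan(data), axis=3)
    flat = data[valid_mask]            # (n_vox, n_t)
    return shape3d, valid_mask, flat.T  # (n_t, n_vox)


def boxcar_glm(
    data: np.ndarray,
    paradigm: StimulationParadigm,
    tr_s: float,
    valid_mask: np.ndarray | None = None,
) -> GLMResult:
    """OLS of each voxel time course on [intercept, stimulus boxcar]."""
    shape3d, valid_mask, y = _prepare(data, valid_mask)
    n_t = y.shape[0]
    box = build_stimulus_timecourse(paradigm, tr_s)
    if len(box) != n_t:
        raise ValueError(f"series has {n_t} samples, paradigm implies {len(box)}")
    if np.ptp(box) == 0:
        raise ValueError("stimulus boxcar is constant: design is rank deficient")
    design = pd.DataFrame({"intercept": np.ones(n_t), "boxcar": box})
    X = design.to_numpy()
    dof = n_t - 2

    beta, rss = _ols(X, y)
    sigma2 = rss / dof
    xd = box - box.mean()
    se = np.sqrt(sigma2 / (xd @ xd))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    z = _t_to_z(t, dof)

    return GLMResult(
        design=design,
        beta=_unflatten(beta.T, shape3d, valid_mask),
        sigma2=_unflatten(sigma2, shape3d, valid_mask),
        z_map=_unflatten(z, shape3d, valid_mask),
        dof=dof, kind="boxcar", tr_s=tr_s, valid_mask=valid_mask,
        paradigm=paradigm,
    )


def fir_design(
    paradigm: StimulationParadigm,
    tr_s: float,
    n_impulses: int = 4,
    window_s: float = 16.0,
) -> pd.DataFrame:
    """Design matrix of the stimulus boxcar convolved with an FIR basis.

    Regressor ``fir_j`` is the boxcar convolved with the indicator of lag
    bin ``[j*w, (j+1)*w)`` seconds, ``w = window_s / n_impulses``, truncated
    to the series length.  An intercept column is included.
    """
    if n_impulses < 1:
        raise ValueError("n_impulses must be >= 1")
    w = window_s / n_impulses
    bin_samples = w / tr_s
    if abs(bin_samples - round(bin_samples)) > 1e-9 or round(bin_samples) < 1:
        raise ValueError(
            f"window {window_s} s / {n_impulses} impulses gives a bin of "
            f"{w} s, not a whole number (>= 1) of {tr_s}-s samples"
        )
    bin_samples = round(bin_samples)
    box = build_stimulus_timecourse(paradigm, tr_s)
    n_t = len(box)
    cols = {"intercept": np.ones(n_t)}
    for j in range(n_impulses):
        kernel = np.zeros((j + 1) * bin_samples)
        kernel[j * bin_samples:] = 1.0
        cols[f"fir_{j}"] = np.convolve(box, kernel)[:n_t]
    return pd.DataFrame(cols)


def fir_glm(
    data: np.ndarray,
    paradigm: StimulationParadigm,
    tr_s: float,
    n_impulses: int = 4,
    window_s: float = 16.0,
    valid_mask: np.ndarray | None = None,
) -> GLMResult:
    """FIR GLM with an omnibus F-test of all FIR coefficients.

    The z map is one-sided and always positive; response polarity is
    assigned downstream from the epoch-averaged shape.
    """
    shape3d, valid_mask, y = _prepare(data, valid_mask)
    n_t = y.shape[0]
    design = fir_design(paradigm, tr_s, n_impulses, window_s)
    if len(design) != n_t:
        raise ValueError(f"series has {n_t} samples, design has {len(design)}")
    X = design.to_numpy()
    q = X.shape[1] - 1
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("FIR design is rank deficient")
    dof = n_t - X.shape[1]

    beta, rss1 = _ols(X, y)
    ym = y - y.mean(axis=0)
    rss0 = np.einsum("ij,ij->j", ym, ym)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(rss1 > 0, ((rss0 - rss1) / q) / (rss1 / dof), 0.0)
    f = np.clip(f, 0.0, None)
    z = _f_to_z(f, q, dof)

    return GLMResult(
        design=design,
        beta=_unflatten(beta.T, shape3d, valid_mask),
        sigma2=_unflatten(rss1 / dof, shape3d, valid_mask),
        z_map=_unflatten(z, shape3d, valid_mask),
        dof=dof, kind="fir", tr_s=tr_s, valid_mask=valid_mask,
        paradigm=paradigm,
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares for many RHS; returns (beta, residual sum of squares)."""
    q, r = np.linalg.qr(X)
    qty = q.T @ y
    beta = np.linalg.solve(r, qty)
    yss = np.einsum("ij,ij->j", y, y)
    rss = np.clip(yss - np.einsum("ij,ij->j", qty, qty), 0.0, None)
    return beta, rss


def _unflatten(values: np.ndarray, shape3d, valid_mask: np.ndarray) -> np.ndarray:
    if values.ndim == 1:
        out = np.full(shape3d, np.nan)
        out[valid_mask] = values
    else:
        out = np.full((*shape3d, values.shape[1]), np.nan)
        out[valid_mask] = values
    return out


# --------------------------------------------------------------------------
# cluster-extent correction by circular-shift permutation
# --------------------------------------------------------------------------

def _cluster_extents(stat: np.ndarray, thr: float, signed: bool):
    """Connected components above +thr and (if signed) below -thr.

    Returns a list of (sign, extent, voxel-index-array) and the max extent.
    """
    clusters = []
    excursions = [(1, stat > thr)]
    if signed:
        excursions.append((-1, stat < -thr))
    for sign, excursion in excursions:
        lab, n = ndimage.label(excursion, structure=_STRUCT26)
        for k in range(1, n + 1):
            idx = np.nonzero(lab == k)
            clusters.append((sign, len(idx[0]), idx))
    return clusters


def _max_extent(stat: np.ndarray, thr: float, signed: bool) -> int:
    best = 0
    excursions = [stat > thr]
    if signed:
        excursions.append(stat < -thr)
    for excursion in excursions:
        lab, n = ndimage.label(excursion, structure=_STRUCT26)
        if n:
            best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def _null_max_extents_boxcar(
    resid: np.ndarray, box: np.ndarray, dof: int, t_thr: float,
    perms: list[np.ndarray], shape3d, valid_mask: np.ndarray,
) -> np.ndarray:
    """Max |t| cluster extents of the boxcar GLM on permuted residuals.

    ``resid`` are the full-model residuals; permuting the residual series
    in time equals permuting the regressor by the inverse ordering, so all
    permutations reduce to one matmul of permuted regressors.
    """
    xd = np.stack([box[p] for p in perms])
    xd = xd - xd.mean(axis=1, keepdims=True)
    xd /= np.linalg.norm(xd, axis=1, keepdims=True)
    em = resid - resid.mean(axis=0)
    enorm = np.linalg.norm(em, axis=0)
    enorm[enorm == 0] = np.inf
    r = (xd @ em) / enorm                      # (n_perm, n_vox) correlations
    r = np.clip(r, -0.999999999, 0.999999999)
    t = r * np.sqrt(dof / (1.0 - r * r))
    out = np.empty(len(perms), dtype=int)
    stat = np.zeros(shape3d)
    for i in range(len(perms)):
        stat[valid_mask] = t[i]
        out[i] = _max_extent(stat, t_thr, signed=True)
    return out


def _null_max_extents_fir(
    resid: np.ndarray, design: pd.DataFrame, dof: int, f_thr: float,
    perms: list[np.ndarray], shape3d, valid_mask: np.ndarray,
) -> np.ndarray:
    """Max F-cluster extents of the FIR GLM on permuted residuals."""
    fir_cols = [c for c in design.columns if c != "intercept"]
    base = design[fir_cols].to_numpy()
    n_t = base.shape[0]
    q_reg = len(fir_cols)
    em = resid - resid.mean(axis=0)
    rss0 = np.einsum("ij,ij->j", em, em)
    out = np.empty(len(perms), dtype=int)
    stat = np.zeros(shape3d)
    ones = np.ones((n_t, 1))
    for i, p in enumerate(perms):
        X = np.hstack([ones, base[p]])
        _, rss1 = _ols(X, em)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(rss1 > 0, ((rss0 - rss1) / q_reg) / (rss1 / dof), 0.0)
        stat[valid_mask] = f
        out[i] = _max_extent(stat, f_thr, signed=False)
    return out


def cluster_correct(
    result: GLMResult,
    data: np.ndarray,
    z_threshold: float = 2.3,
    alpha: float = 0.05,
    n_perm: int = 500,
    seed: int = 0,
) -> ClusterMask:
    """Cluster-extent correction with a circular-shift permutation null.

    Supra-threshold voxels of the z map (|z| > ``z_threshold``; one-sided
    for FIR maps) are grouped by 26-connectivity.  The null distribution of
    the maximum cluster extent is built by randomly permuting the series in
    time against the stimulus timing and recomputing the GLM for each of
    ``n_perm`` permutations.  The permuted series is the full-model
    residual (Freedman-Lane scheme): a raw permutation of the data would
    scatter any true response into the null, and with a periodic block
    design even circular shifts stay aligned with the stimulus-locked
    subspace, whereas the residuals are signal-free by construction.
    Exchangeability of time points assumes temporally white noise after
    drift removal; autocorrelation modeling is out of scope.  A cluster
    survives when its extent p-value is below ``alpha``.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for usable extent p-values")
    shape3d, valid_mask, y = _prepare(data, result.valid_mask)
    rng = np.random.default_rng(seed)
    n_t = y.shape[0]
    perms = [rng.permutation(n_t) for _ in range(n_perm)]

    z_map = np.where(np.isfinite(result.z_map), result.z_map, 0.0)
    signed = result.kind == "boxcar"
    observed = _cluster_extents(z_map, z_threshold, signed=signed)

    labels = np.zeros(shape3d, dtype=np.int32)
    rows = []
    if observed:
        # Residuals are the exchangeable units of the null.  For the boxcar
        # statistic the residualizing model is augmented with the FIR basis:
        # the boxcar deliberately under-models the response shape, and its
        # own residuals would retain block-edge transients that correlate
        # with shifted regressors, contaminating the null.
        X = result.design.to_numpy()
        if result.kind == "boxcar" and result.paradigm is not None:
            try:
                X = fir_design(result.paradigm, result.tr_s).to_numpy()
            except ValueError:
                pass
        beta, _ = _ols(X, y)
        resid = y - X @ beta
        # map the z threshold to the native statistic for the permutations
        p_tail = stats.norm.sf(z_threshold)
        if result.kind == "boxcar":
            t_thr = stats.t.isf(p_tail, result.dof)
            null_max = _null_max_extents_boxcar(
                resid, result.design["boxcar"].to_numpy(), result.dof, t_thr,
                perms, shape3d, valid_mask,
            )
        else:
            q_reg = result.design.shape[1] - 1
            f_thr = stats.f.isf(p_tail, q_reg, result.dof)
            null_max = _null_max_extents_fir(
                resid, result.design, result.dof, f_thr, perms, shape3d, valid_mask,
            )
        next_label = 1
        for sign, extent, idx in sorted(observed, key=lambda c: -c[1]):
            p = (1.0 + np.sum(null_max >= extent)) / (n_perm + 1.0)
            if p < alpha:
                labels[idx] = next_label
                rows.append(
                    {"label": next_label, "extent": extent, "sign": sign, "p": p}
                )
                next_label += 1
    table = pd.DataFrame(rows, columns=["label", "extent", "sign", "p"])
    return ClusterMask(
        labels=labels, table=table, z_threshold=z_threshold,
        alpha=alpha, n_perm=n_perm, seed=seed,
    )


# --------------------------------------------------------------------------
# group level
# --------------------------------------------------------------------------

def group_level_map(z_maps: list[np.ndarray]) -> np.ndarray:
    """One-sample t across subject z maps per voxel, mapped back to z.

    Synthetic subjects share the grid, standing in for template
    registration.  Voxels with zero across-subject variance are capped at
    |z| = 8; voxels invalid (NaN) in any subject are NaN.
    """
    if len(z_maps) < 2:
        raise ValueError("need at least 2 subjects")
    shapes = {m.shape for m in z_maps}
    if len(shapes) != 1:
        raise ValueError(f"geometry mismatch across subjects: {shapes}")
    stack = np.stack(z_maps)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    z = _t_to_z(np.where(np.isfinite(t), t, 0.0), n - 1)
    z = np.where(np.isfinite(t), z, np.sign(mean) * _Z_CAP)
    z[np.isnan(mean)] = np.nan
    return np.clip(z, -_Z_CAP * 5, _Z_CAP * 5)


def group_cluster_correct(
    z_maps: list[np.ndarray],
    z_threshold: float = 1.5,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterMask:
    """Cluster correction of the group map with a sign-flipping null.

    Under the null of no group effect the subject z maps are symmetric
    about zero, so random sign flips of whole subjects generate the null
    distribution of the maximum cluster extent.
    """
    group_z = group_level_map(z_maps)
    stack = np.stack([np.where(np.isfinite(m), m, 0.0) for m in z_maps])
    rng = np.random.default_rng(seed)
    n_sub = stack.shape[0]
    null_max = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        flipped = [s * m for s, m in zip(signs, stack)]
        gz = group_level_map(list(flipped))
        null_max[i] = _max_extent(np.nan_to_num(gz), z_threshold, signed=True)

    observed = _cluster_extents(np.nan_to_num(group_z), z_threshold, signed=True)
    labels = np.zeros(group_z.shape, dtype=np.int32)
    rows = []
    next_label = 1
    for sign, extent, idx in sorted(observed, key=lambda c: -c[1]):
        p = (1.0 + np.sum(null_max >= extent)) / (n_perm + 1.0)
        if p < alpha:
            labels[idx] = next_label
            rows.append({"label": next_label, "extent": extent, "sign": sign, "p": p})
            next_label += 1
    table = pd.DataFrame(rows, columns=["label", "extent", "sign", "p"])
    return ClusterMask(
        labels=labels, table=table, z_threshold=z_threshold,
        alpha=alpha, n_perm=n_perm, seed=seed,
    )
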