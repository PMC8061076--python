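"""Coverage-weighted local-polynomial smoothing of methylation fractions.

The smoother follows the BSmooth scheme: at each cytosine a weighted
polynomial (degree 2 by default) of the raw fractions M/Cov against genomic
position is fit over a symmetric window, with weights equal to a tricube
kernel in scaled distance times the read coverage.  The window at locus i is
the smallest symmetric extension satisfying BOTH a minimum width in bp and a
minimum locus count; windows are truncated one-sidedly at chromosome ends.

Three presets mirror the standard analysis configurations:

=========  ============  =========
preset     min width     min loci
=========  ============  =========
cg_small     1,000 bp       70
cg_block    20,000 bp      500
ch           3,000 bp      200
=========  ============  =========

The small-CpG minimum width is the smoother's own default (the count
constraint dominates at realistic CpG densities); the other values are the
window constraints of the block and non-CpG analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MethylationDataset, SmoothedDataset

_PRESETS = {
    "cg_small": (1_000, 70),
    "cg_block": (20_000, 500),
    "ch": (3_000, 200),
}


@dataclass(frozen=True)
class SmoothingConfig:
    min_width_bp: int
    min_loci: int
    kernel: str = "tricube"
    degree: int = 2
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.min_width_bp < 1:
            raise ValueError("min_width_bp must be >= 1")
        if self.min_loci < self.degree + 2:
            raise ValueError("min_loci must be >= degree + 2")
        if self.kernel != "tricube":
            raise ValueError(f"unsupported kernel {self.kernel!r}")


def preset(name: str) -> SmoothingConfig:
    """Named smoothing configuration (``cg_small``, ``cg_block``, ``ch``)."""
    try:
        width, loci = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown smoothing preset {name!r}") from None
    return SmoothingConfig(min_width_bp=width, min_loci=loci, name=name)


def _window_bounds(pos: np.ndarray, min_width_bp: int, min_loci: int) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive window index bounds [lo, hi] per locus on one chromosome.

    The window is the union of (a) all loci within +/- min_width_bp/2 and
    (b) the symmetric count window of ceil((min_loci-1)/2) loci to each side,
    truncated at chromosome ends.
    """
    n = len(pos)
    half_bp = min_width_bp / 2.0
    lo_w = np.searchsorted(pos, pos - half_bp, side="left")
    hi_w = np.searchsorted(pos, pos + half_bp, side="right") - 1
    half_n = -(-(min_loci - 1) // 2)  # ceil
    idx = np.arange(n)
    lo_c = np.maximum(idx - half_n, 0)
    hi_c = np.minimum(idx + half_n, n - 1)
    return np.minimum(lo_w, lo_c), np.maximum(hi_w, hi_c)


try:  # optional JIT fast path; the numpy implementation is the reference
    import numba as _numba
except Exception:  # pragma: no cover
    _numba = None


def _smooth_chromosome(
    pos: np.ndarray, frac: np.ndarray, cov: np.ndarray, cfg: SmoothingConfig
) -> np.ndarray:
    """Smooth one chromosome; frac/cov are (L, S), frac is 0 where cov == 0."""
    L, S = frac.shape
    deg = cfg.degree
    if L <= cfg.min_loci:
        lo = np.zeros(L, np.intp)
        hi = np.full(L, L - 1, np.intp)
    else:
        lo, hi = _window_bounds(pos, cfg.min_width_bp, cfg.min_loci)
    if _numba is not None:
        out = np.full((L, S), np.nan)
        _smooth_kernel(
            pos.astype(np.float64), lo.astype(np.int64), hi.astype(np.int64),
            cov.astype(np.float64), frac.astype(np.float64), deg, out,
        )
        np.clip(out, 0.0, 1.0, out=out)
        return out
    return _smooth_chromosome_numpy(pos, frac, cov, cfg, lo, hi)


if _numba is not None:

    @_numba.njit(cache=True)
    def _smooth_kernel(pos, lo, hi, cov, frac, deg, out):  # pragma: no cover - jitted
        L, S = cov.shape
        d1 = deg + 1
        nm = 2 * deg + 1
        T = np.empty(nm)
        rhs = np.empty(d1)
        A = np.empty((d1, d1))
        b = np.empty(d1)
        maxw = 0
        for i in range(L):
            w = hi[i] - lo[i] + 1
            if w > maxw:
                maxw = w
        xs_buf = np.empty(maxw)
        k_buf = np.empty(maxw)
        for i in range(L):
            l, h = lo[i], hi[i]
            w = h - l + 1
            hw = max(max(abs(pos[l] - pos[i]), abs(pos[h] - pos[i])), 1.0) + 1.0
            for j in range(w):
                x = (pos[l + j] - pos[i]) / hw
                xs_buf[j] = x
                ax = abs(x) ** 3
                k_buf[j] = (1.0 - ax) ** 3
            for s in range(S):
                for m in range(nm):
                    T[m] = 0.0
                for m in range(d1):
                    rhs[m] = 0.0
                npos = 0
                for j in range(w):
                    c = cov[l + j, s]
                    if c <= 0.0:
                        continue
                    npos += 1
                    k = k_buf[j] * c
                    y = frac[l + j, s]
                    p = 1.0
                    for m in range(nm):
                        T[m] += k * p
                        if m < d1:
                            rhs[m] += k * p * y
                        p *= xs_buf[j]
                if npos == 0 or T[0] <= 0.0:
                    out[i, s] = np.nan
                elif npos < d1:
                    out[i, s] = rhs[0] / T[0]
                else:
                    # solve the (d1 x d1) normal equations by Gaussian
                    # elimination with partial pivoting
                    for r in range(d1):
                        for cidx in range(d1):
                            A[r, cidx] = T[r + cidx]
                        b[r] = rhs[r]
                    ok = True
                    for col in range(d1):
                        piv = col
                        for r in range(col + 1, d1):
                            if abs(A[r, col]) > abs(A[piv, col]):
                                piv = r
                        if A[piv, col] == 0.0:
                            ok = False
                            break
                        if piv != col:
                            for cidx in range(d1):
                                tmp = A[col, cidx]
                                A[col, cidx] = A[piv, cidx]
                                A[piv, cidx] = tmp
                            tmp = b[col]
                            b[col] = b[piv]
                            b[piv] = tmp
                        for r in range(col + 1, d1):
                            f = A[r, col] / A[col, col]
                            for cidx in range(col, d1):
                                A[r, cidx] -= f * A[col, cidx]
                            b[r] -= f * b[col]
                    if not ok:
                        out[i, s] = rhs[0] / T[0]
                        continue
                    for r in range(d1 - 1, -1, -1):
                        acc = b[r]
                        for cidx in range(r + 1, d1):
                            acc -= A[r, cidx] * b[cidx]
                        b[r] = acc / A[r, r]
                    out[i, s] = b[0]


def _smooth_chromosome_numpy(
    pos: np.ndarray,
    frac: np.ndarray,
    cov: np.ndarray,
    cfg: SmoothingConfig,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    """Vectorized reference implementation of the per-chromosome smoother.

    The normal equations of every (locus, sample) fit share the window
    moments sum_w weight * x^k, so the whole chromosome reduces to two
    batched matrix products per window-size class.
    """
    L, S = frac.shape
    deg = cfg.degree
    out = np.full((L, S), np.nan)
    widths = hi - lo + 1
    posf = pos.astype(float)
    powers = np.arange(2 * deg + 1)
    ii, jj = np.indices((deg + 1, deg + 1))
    eye = np.eye(deg + 1)
    # single-precision for the large gathered tensors: windows hold <= a few
    # hundred weights in [0, ~lambda], so the moment sums keep ~6-7 digits
    covf = cov.astype(np.float32)
    fracf = frac.astype(np.float32)

    for w in np.unique(widths):
        centers = np.flatnonzero(widths == w)
        chunk = max(1, 200_000 // int(w))
        for block in np.array_split(centers, max(1, -(-len(centers) // chunk))):
            win = lo[block][:, None] + np.arange(w)[None, :]  # (n, w)
            x = posf[win] - posf[block][:, None]
            # kernel half-width: farthest member + 1 bp so endpoints keep a
            # small positive weight
            h = np.maximum(np.abs(x).max(axis=1), 1.0)[:, None] + 1.0
            xs = (x / h).astype(np.float32)
            kern = (1.0 - np.abs(xs) ** 3) ** 3
            c = covf[win]  # (n, w, S)
            cy = c * fracf[win]
            K = kern[:, None, :] * xs[:, None, :] ** powers[None, :, None]  # (n, 2deg+1, w)
            T = K @ c  # moments sum kern*cov*xs^k  -> (n, 2deg+1, S)
            R = K[: , : deg + 1] @ cy  # rhs moments  -> (n, deg+1, S)
            npos = (c > 0).sum(axis=1)  # (n, S)

            xtx = np.moveaxis(T[:, ii + jj, :], 3, 1).astype(float)  # (n, S, d+1, d+1)
            xty = np.moveaxis(R, 2, 1).astype(float)  # (n, S, d+1)
            ok = npos >= deg + 1
            xtx = np.where(ok[..., None, None], xtx, eye)
            with np.errstate(all="ignore"):
                try:
                    coef = np.linalg.solve(xtx, xty[..., None])[..., 0]
                except np.linalg.LinAlgError:
                    coef = (np.linalg.pinv(xtx) @ xty[..., None])[..., 0]
                vals = coef[..., 0]  # fitted value at x = 0
                T0 = T[:, 0, :]
                wmean = np.where(T0 > 0, R[:, 0, :] / np.where(T0 > 0, T0, 1.0), np.nan)
            # fall back to the weighted window mean where the polynomial fit
            # is underdetermined (or numerically failed)
            vals = np.where(ok & np.isfinite(vals), vals, np.where(npos >= 1, wmean, np.nan))
            out[block] = vals
    np.clip(out, 0.0, 1.0, out=out)
    return out


def smooth(d: MethylationDataset, cfg: SmoothingConfig) -> SmoothedDataset:
    """Smooth raw methylation fractions for every sample.

    Loci with zero coverage receive the neighborhood fit; a locus/sample
    whose whole window has zero coverage is marked missing (NaN).  Smoothed
    values are clamped to [0, 1].
    """
    if d.n_loci == 0:
        return SmoothedDataset(
            d.loci, np.zeros((0, d.samples.n)), d.samples, cfg, d.fingerprint()
        )
    frac = d.fractions()
    frac = np.where(np.isnan(frac), 0.0, frac)
    beta = np.empty((d.n_loci, d.samples.n))
    chroms = d.loci["chrom"].to_numpy()
    pos = d.loci["pos"].to_numpy(np.int64)
    for chrom in _unique_in_order(chroms):
        idx = np.flatnonzero(chroms == chrom)
        beta[idx] = _smooth_chromosome(pos[idx], frac[idx], d.Cov[idx], cfg)
    return SmoothedDataset(d.loci, beta, d.samples, cfg, d.fingerprint())


def _unique_in_order(values: np.ndarray) -> list:
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out
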