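"""Diphthong quantification: spectral-peak distances and 1-D Gaussian
mixture models selected by BIC.

For each coda and peak index, ``c1dist`` is the mean signed Hz distance of
every non-initial click's peak from the corresponding peak of the first
click, and ``cndist`` the mean signed distance from the preceding click.
Distances are signed so level codas center at zero with two-sided spread.
Bimodality of the pooled distances is tested with univariate Gaussian
mixtures fitted by EM for k = 1..5 and compared by BIC
(-2 logL + (3k - 1) ln n, lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import logger


@dataclass
class TrajectoryStats:
    coda_id: str
    peak_index: int  # 1 or 2
    c1dist_hz: float
    cndist_hz: float
    n_clicks_used: int
    n_clicks_skipped: int


@dataclass
class GmmFit:
    k: int
    weights: np.ndarray
    means_hz: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    bic: float
    log_likelihood_trace: list[float]


# ---------------------------------------------------------------------------
# Peak distances
# ---------------------------------------------------------------------------

def peak_distances(peaks_per_click, coda_id: str = "", peak_index: int = 1
                   ) -> TrajectoryStats:
    """c1dist / cndist for one coda and one peak index.

    ``peaks_per_click`` is a sequence (one entry per click, in click order)
    of peak-frequency lists; entry ``peak_index - 1`` of each list is used.
    Clicks missing that peak are skipped and counted; at least two usable
    clicks (including the first) are required.
    """
    values = []
    skipped = 0
    for peaks in peaks_per_click:
        if peaks is not None and len(peaks) >= peak_index:
            values.append(float(peaks[peak_index - 1]))
        else:
            skipped += 1
    if len(values) < 2:
        raise ValueError(f"coda {coda_id}: fewer than 2 clicks carry peak {peak_index}")
    p = np.asarray(values)
    c1dist = float(np.mean(p[1:] - p[0]))
    cndist = float(np.mean(np.diff(p)))
    return TrajectoryStats(coda_id=coda_id, peak_index=peak_index,
                           c1dist_hz=c1dist, cndist_hz=cndist,
                           n_clicks_used=len(values), n_clicks_skipped=skipped)


def distances_frame(codas_peaks: dict[str, list], peak_index: int = 1) -> pd.DataFrame:
    """Tabulate c1dist/cndist over many codas, skipping unusable ones."""
    rows = []
    for coda_id, peaks in codas_peaks.items():
        try:
            s = peak_distances(peaks, coda_id=coda_id, peak_index=peak_index)
        except ValueError:
            continue
        rows.append({"coda_id": coda_id, "peak_index": s.peak_index,
                     "c1dist_hz": s.c1dist_hz, "cndist_hz": s.cndist_hz,
                     "n_used": s.n_clicks_used, "n_skipped": s.n_clicks_skipped})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture by EM, model order by BIC
# ---------------------------------------------------------------------------

def _em_1d(x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300,
           tol: float = 1e-8, var_floor: float | None = None) -> GmmFit:
    n = len(x)
    if var_floor is None:
        var_floor = max(1e-6 * np.var(x), 1e-12)
    # k-means-style init: random distinct points as seed means, one assignment pass
    means = np.sort(rng.choice(x, size=k, replace=False))
    for _ in range(2):
        assign = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)
        for j in range(k):
            if np.any(assign == j):
                means[j] = x[assign == j].mean()
    variances = np.full(k, max(np.var(x) / k, var_floor))
    weights = np.full(k, 1.0 / k)

    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        # E step
        log_comp = (np.log(weights)[None, :]
                    - 0.5 * np.log(2 * np.pi * variances)[None, :]
                    - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :])
        m = log_comp.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        collapsed = variances < var_floor
        if np.any(collapsed):
            logger.warning("GMM k=%d: %d component(s) hit the variance floor",
                           k, int(collapsed.sum()))
            variances = np.maximum(variances, var_floor)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    p = 3 * k - 1
    bic = -2 * trace[-1] + p * np.log(n)
    order = np.argsort(means)
    return GmmFit(k=k, weights=weights[order], means_hz=means[order],
                  variances=variances[order], log_likelihood=trace[-1], bic=float(bic),
                  log_likelihood_trace=trace)


def fit_gmm_bic(values, k_range=range(1, 6), n_restarts: int = 5, seed: int = 0,
                ) -> tuple[list[GmmFit], int]:
    """Fit mixtures for each k and select the minimum-BIC model.

    Each k gets ``n_restarts`` independent EM runs (random k-means-style
    initialization); the best log-likelihood run represents that k.
    Requires ``n >= 10 * max(k)``.
    """
    x = np.asarray(values, dtype=float)
    ks = list(k_range)
    if len(x) < 10 * max(ks):
        raise ValueError(f"insufficient data: n={len(x)} < 10 * k_max={10 * max(ks)}")
    rng = np.random.default_rng(seed)
    fits = []
    for k in ks:
        best = None
        for _ in range(n_restarts):
            fit = _em_1d(x, k, rng)
            if best is None or fit.log_likelihood > best.log_likelihood:
                best = fit
        fits.append(best)
    selected = ks[int(np.argmin([f.bic for f in fits]))]
    return fits, selected


def gmm_report(fits, selected_k: int) -> dict:
    return {
        "selected_k": selected_k,
        "models": [{
            "k": f.k, "bic": f.bic, "log_likelihood": f.log_likelihood,
            "weights": f.weights.tolist(), "means_hz": f.means_hz.tolist(),
            "variances": f.variances.tolist(),
        } for f in fits],
    }


# ---------------------------------------------------------------------------
# Shape labels
# ---------------------------------------------------------------------------

def diphthong_flags(peak_sequence, threshold_hz: float = 300.0) -> str:
    """Label a per-click peak sequence as level / rising / falling /
    rise_fall / fall_rise.

    Monotone trends are read off ``cndist``; a direction change with small
    net drift is detected by a single sign change among the significant
    click-to-click steps.  ``threshold_hz`` separates noise from real
    movement (free parameter; the reference analysis classifies visually).
    """
    p = np.asarray(peak_sequence, dtype=float)
    if len(p) < 2:
        raise ValueError("need at least two clicks")
    cndist = float(np.mean(np.diff(p)))
    diffs = np.diff(p)
    step_thr = threshold_hz / max(len(p) - 1, 1)
    signs = [int(np.sign(d)) for d in diffs if abs(d) >= step_thr]
    if abs(cndist) >= threshold_hz / max(len(p) - 1, 1):
        return "rising" if cndist > 0 else "falling"
    if not signs:
        return "level"
    changes = sum(1 for a, b in zip(signs, signs[1:]) if a != b)
    if changes == 1:
        return "rise_fall" if signs[0] > 0 else "fall_rise"
    return "level"
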