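"""Elongation-wave front estimation from binned nascent-transcription signal.

After release from a transcription block (DRB washout, with or without UV),
RNA polymerase II advances into gene bodies as a synchronized wave: bins
upstream of the wave front carry nascent signal, bins downstream are still
silent.  Each gene's binned profile is modeled with a two-state left-to-right
hidden Markov chain:

* state ON (transcribed) emits Poisson(lambda_on) counts per bin,
* state OFF (not yet reached) emits Poisson(lambda_off),
* the chain may switch ON -> OFF once (probability 1 - p_stay_on per bin)
  and OFF is absorbing, so every state path is a single changepoint k —
  the number of ON bins — with prior P(k) = (1 - p) p^k (k < n) and
  P(n) = p^n (wave past the region, censored).

The switch is allowed before the first bin, so a fully silent gene decodes
to front 0.  Parameters are fit by exact EM pooled across genes (the E-step
posterior over k is computed in closed form), and each gene's front is the
Viterbi changepoint under the fitted parameters.  Wave speed is the
least-squares slope of the per-timepoint median front against time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .signal_engine import BinnedSignal
from .stats_core import TestResult, paired_t


@dataclass(frozen=True)
class WaveHMMParams:
    lambda_on: float
    lambda_off: float
    p_stay_on: float

    def __post_init__(self) -> None:
        if not (self.lambda_on > self.lambda_off >= 0):
            raise ValueError("need lambda_on > lambda_off >= 0")
        if not (0 < self.p_stay_on < 1):
            raise ValueError("p_stay_on must be in (0, 1)")


@dataclass(frozen=True)
class WaveFront:
    gene_id: str
    timepoint: float  # minutes
    front_bp: int
    censored: bool


@dataclass(frozen=True)
class WaveSpeed:
    cell_line: str
    condition: str
    speed: float  # kb/min
    intercept: float  # kb
    n_timepoints: int


def _signal_matrix(signals: Sequence[BinnedSignal]) -> np.ndarray:
    n = len(signals[0].values)
    bs = signals[0].bin_size
    for s in signals:
        if len(s.values) != n or s.bin_size != bs:
            raise ValueError("signals must share bin_size and length")
    return np.stack([s.values for s in signals]).astype(float)


def _pois_loglik(x: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise Poisson log-pmf, exact at lam = 0 (point mass at 0)."""
    if lam == 0:
        return np.where(x == 0, 0.0, -np.inf)
    return x * np.log(lam) - lam - gammaln(x + 1)


def _changepoint_logpost(x: np.ndarray, params: WaveHMMParams) -> np.ndarray:
    """(G, n+1) unnormalized log-posterior over the changepoint k per gene."""
    G, n = x.shape
    ll_on = _pois_loglik(x, params.lambda_on)
    ll_off = _pois_loglik(x, params.lambda_off)
    pre = np.concatenate([np.zeros((G, 1)), np.cumsum(ll_on, axis=1)], axis=1)
    # reverse cumsum (not total-minus-prefix) so -inf entries at lambda_off=0
    # never produce inf - inf
    suf = np.concatenate(
        [np.cumsum(ll_off[:, ::-1], axis=1)[:, ::-1], np.zeros((G, 1))], axis=1
    )
    k = np.arange(n + 1, dtype=float)
    p = params.p_stay_on
    log_prior = k * np.log(p)
    log_prior[:-1] += np.log1p(-p)
    return log_prior[None, :] + pre + suf


def fit_wave_hmm(
    signals: Sequence[BinnedSignal],
    init: Optional[WaveHMMParams] = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    min_lambda_off: float = 1e-3,
) -> tuple[WaveHMMParams, list[float]]:
    """Fit (lambda_on, lambda_off, p_stay_on) by EM pooled over genes.

    Returns the fitted parameters and the per-iteration total log-likelihood
    trace (monotone non-decreasing).  Initialization is deterministic from
    data quantiles: lambda_on from the top-decile bins, lambda_off from the
    bottom half.  lambda_off is floored at ``min_lambda_off`` during the fit:
    an exact zero is a degenerate fixed point that forces the decoded front
    past every stray nonzero bin (zero-inflated decoding stays available by
    passing explicit params with lambda_off = 0 to call_front).
    """
    x = _signal_matrix(signals)
    if np.all(x == 0):
        raise ValueError("degenerate input: all signals are zero")
    G, n = x.shape

    if init is None:
        flat = np.sort(x.ravel())
        lam_on = float(flat[int(0.9 * flat.size):].mean())
        lam_off = max(float(flat[: max(1, flat.size // 2)].mean()), min_lambda_off)
        if lam_on <= lam_off:
            lam_on = lam_off + 1.0
        init = WaveHMMParams(lam_on, lam_off, 1.0 - 1.0 / (0.5 * n + 1.0))

    params = init
    trace: list[float] = []
    cum_x = np.concatenate([np.zeros((G, 1)), np.cumsum(x, axis=1)], axis=1)
    total_x = cum_x[:, -1:]
    k = np.arange(n + 1, dtype=float)

    for _ in range(max_iter):
        logpost = _changepoint_logpost(x, params)
        ll = float(logsumexp(logpost, axis=1).sum())
        trace.append(ll)
        w = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))

        exp_on_bins = float((w * k).sum())
        exp_on_counts = float((w * cum_x).sum())
        exp_off_bins = float((w * (n - k)).sum())
        exp_off_counts = float((w * (total_x - cum_x)).sum())
        lam_on = exp_on_counts / exp_on_bins if exp_on_bins > 0 else params.lambda_on
        lam_off = (exp_off_counts / exp_off_bins if exp_off_bins > 0 else 0.0)
        lam_off = max(lam_off, min_lambda_off)
        # ON->ON transitions = k per path; ON->OFF = 1 unless censored
        n_switch = float(w[:, :-1].sum())
        p_stay = exp_on_bins / (exp_on_bins + n_switch)
        p_stay = min(max(p_stay, 1e-6), 1 - 1e-6)
        if lam_on <= lam_off:
            lam_on = lam_off + 1e-9
        new = WaveHMMParams(lam_on, lam_off, p_stay)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            params = new
            break
        params = new
    return params, trace


def call_front(sig: BinnedSignal, params: WaveHMMParams, timepoint: float = 0.0) -> WaveFront:
    """Viterbi front call for one gene: bp from TSS of the last ON bin's end."""
    x = sig.values[None, :].astype(float)
    logpost = _changepoint_logpost(x, params)[0]
    k_hat = int(np.argmax(logpost))
    n = len(sig.values)
    return WaveFront(
        gene_id=sig.gene_id,
        timepoint=timepoint,
        front_bp=k_hat * sig.bin_size,
        censored=(k_hat == n),
    )


def call_fronts(
    signals: Sequence[BinnedSignal], params: WaveHMMParams, timepoint: float = 0.0
) -> list[WaveFront]:
    return [call_front(s, params, timepoint) for s in signals]


def fit_and_call(
    signals: Sequence[BinnedSignal], timepoint: float = 0.0, **fit_kwargs
) -> tuple[WaveHMMParams, list[WaveFront]]:
    """Convenience: pooled EM fit for one timepoint, then per-gene decodes."""
    params, _ = fit_wave_hmm(signals, **fit_kwargs)
    return params, call_fronts(signals, params, timepoint)


def wave_summary(fronts_by_timepoint: dict[float, Sequence[WaveFront]]):
    """Per-timepoint median and quartiles of the called fronts (bp)."""
    import pandas as pd

    rows = []
    for t in sorted(fronts_by_timepoint):
        f = np.array([w.front_bp for w in fronts_by_timepoint[t]], float)
        rows.append(
            {
                "timepoint": t,
                "n": len(f),
                "n_censored": sum(w.censored for w in fronts_by_timepoint[t]),
                "q1_bp": float(np.percentile(f, 25)),
                "median_bp": float(np.median(f)),
                "q3_bp": float(np.percentile(f, 75)),
            }
        )
    return pd.DataFrame(rows)


def estimate_speed(summary, cell_line: str = "", condition: str = "") -> WaveSpeed:
    """Least-squares slope of median front (kb) vs time (min), free intercept."""
    if len(summary) < 2:
        raise ValueError("speed estimation needs >= 2 timepoints")
    t = summary["timepoint"].to_numpy(float)
    med_kb = summary["median_bp"].to_numpy(float) / 1000.0
    res = stats.linregress(t, med_kb)
    return WaveSpeed(cell_line, condition, float(res.slope), float(res.intercept),
                     len(summary))


def compare_fronts(
    fronts_a: Sequence[WaveFront],
    fronts_b: Sequence[WaveFront],
    test: str = "paired_t",
) -> TestResult:
    """Compare per-gene fronts between two cell lines on shared genes.

    ``paired_t``: two-sided paired t-test on front differences.
    ``pearson``: Pearson correlation between the paired fronts with its
    two-sided p-value (the alternative reading of the published figure).
    """
    a = {f.gene_id: f.front_bp for f in fronts_a}
    b = {f.gene_id: f.front_bp for f in fronts_b}
    shared = sorted(a.keys() & b.keys())
    if not shared:
        raise ValueError("no shared genes")
    if len(shared) < 10:
        raise ValueError("need >= 10 shared genes")
    va = np.array([a[g] for g in shared], float)
    vb = np.array([b[g] for g in shared], float)
    if test == "paired_t":
        return paired_t(va, vb)
    if test == "pearson":
        r, p = stats.pearsonr(va, vb)
        return TestResult(float(r), float(p), "pearson", len(va), len(vb))
    raise ValueError(f"unknown test {test!r}")
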