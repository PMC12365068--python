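"""Detection-noise and signal-to-noise model for multi-probe RNA counting.

Detection of each transcript by each probe is approximated as a binomial
trial.  With N transcripts per cell (Poisson-distributed), n detection
chances (probes) per transcript, and per-chance efficiency e, the expected
UMI count and its noise are

    C = N n e,        Noise_C = sqrt(N n e),      SNR_C = sqrt(N n e)

and on the expression scale M = C / n = N e,

    Noise_M = sqrt(M / n) + b,     SNR_M = M / Noise_M

where b is a constant baseline standard deviation absorbing cell-to-cell
biological heterogeneity, independent of probe number.

The sqrt(Nne) noise treats per-probe detections as independent events; a
mechanistic simulation that draws T ~ Poisson(N) transcripts and then
Binomial(T n, e) detections has the larger variance N n e (1 - e + n e) for
n > 1.  Both simulation modes are provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .schema import CountMatrix

logger = logging.getLogger("splitprobe")


@dataclass(frozen=True)
class ModelParams:
    N: float  # mean transcripts per cell
    n: int  # probes (detection chances) per transcript
    e: float  # per-chance detection efficiency
    b: float = 0.0  # baseline (biology) standard deviation
    snr_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.N < 0 or self.n < 0 or self.b < 0:
            raise ValueError("N, n, b must be nonnegative")
        if not 0.0 <= self.e <= 1.0:
            raise ValueError("e must be in [0, 1]")


@dataclass(frozen=True)
class ModelPrediction:
    C: float
    noise_C: float
    snr_C: float
    M: float
    noise_M: float
    snr_M: float


def predict(params: ModelParams) -> ModelPrediction:
    """Evaluate the count- and expression-scale model quantities."""
    C = params.N * params.n * params.e
    noise_C = float(np.sqrt(C))
    snr_C = noise_C  # C / sqrt(C) = sqrt(C)
    if params.n == 0:
        M = noise_M = snr_M = float("nan")
    else:
        M = params.N * params.e
        noise_M = float(np.sqrt(M / params.n)) + params.b
        snr_M = M / noise_M if noise_M > 0 else float("inf")
    return ModelPrediction(C, noise_C, snr_C, M, noise_M, snr_M)


def min_detectable_N(
    e: float,
    n: int = 1,
    snr_threshold: float = 2.0,
    convention: str = "truncate",
) -> int:
    """Lowest transcript copy number per cell detectable at the SNR threshold.

    Solves sqrt(N n e) = threshold for N, i.e. N* = threshold^2 / (n e).
    ``convention='truncate'`` truncates N* to its integer part (matching the
    printed detection limits); ``'strict'`` returns the smallest integer N
    whose SNR actually reaches the threshold (ceiling).
    """
    if e <= 0 or n < 1:
        raise ValueError("require e > 0 and n >= 1")
    n_star = snr_threshold**2 / (n * e)
    if convention == "truncate":
        return int(n_star)
    if convention == "strict":
        return int(np.ceil(n_star - 1e-12))
    raise ValueError(f"unknown convention {convention!r}")


def fit_baseline_b(
    n_values: np.ndarray, sd_observed: np.ndarray, M_fixed: float
) -> float:
    """Fit the baseline noise b in Noise_M(n) = sqrt(M/n) + b.

    M is held at its experimentally determined value (slope of the
    UMIs/cell-versus-n line); b >= 0 is the only free parameter.  Bounded
    scalar least squares; the analytic solution is the clipped mean
    residual, used as fallback and cross-check.
    """
    n_values = np.asarray(n_values, dtype=float)
    sd_observed = np.asarray(sd_observed, dtype=float)
    if n_values.size < 2 or np.unique(n_values).size < 2:
        raise ValueError("need >= 2 distinct n values")
    residual = sd_observed - np.sqrt(M_fixed / n_values)
    # the objective is quadratic in b, so the constrained optimum is the
    # mean residual clipped at zero; numeric minimization is a cross-check
    analytic = max(0.0, float(residual.mean()))
    upper = max(1.0, float(np.abs(residual).max()) * 2 + 1.0)
    res = scipy.optimize.minimize_scalar(
        lambda b: float(((sd_observed - (np.sqrt(M_fixed / n_values) + b)) ** 2).sum()),
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if res.success and abs(float(res.x) - analytic) > 1e-6:
        logger.warning(
            "bounded least squares (%g) disagrees with analytic optimum (%g)",
            res.x, analytic,
        )
    return analytic


def simulate_detection(
    params: ModelParams,
    cells: int,
    mode: str = "poisson",
    seed: int = 0,
) -> np.ndarray:
    """Per-cell UMI counts under the model.

    ``poisson`` (model-faithful): counts ~ Poisson(N n e), so mean and
    variance both equal N n e.  ``mechanistic``: T ~ Poisson(N) transcripts
    then Binomial(T n, e) detections, variance N n e (1 - e + n e).
    """
    rng = np.random.default_rng(seed)
    if mode == "poisson":
        return rng.poisson(params.N * params.n * params.e, size=cells)
    if mode == "mechanistic":
        t = rng.poisson(params.N, size=cells)
        return rng.binomial(t * params.n, params.e)
    raise ValueError(f"unknown mode {mode!r}")


def subsample_snr(
    matrix: CountMatrix,
    probe_ids: list[str],
    reps: int = 10_000,
    seed: int = 0,
    normalize: bool = True,
) -> dict:
    """Bootstrap signal/noise/SNR curves versus probe number.

    Cells are first normalized so each cell's whole-panel total equals the
    population median UMIs/cell (isolating measurement noise from
    cell-to-cell expression differences).
    For each n from 1 to the probe count, ``reps`` random with-replacement
    draws of n probes are taken; each draw yields the mean UMIs/cell
    (signal), the SD across cells (noise), and the expression SNR — the
    ratio of mean expression (UMIs/cell/n) to the SD of expression, which
    equals mean/SD of the summed counts.  Reported per n: mean and SD over
    replicates of each statistic.
    """
    if not probe_ids:
        raise ValueError("need at least one probe")
    cols = [matrix.features.index(p) for p in probe_ids]
    sub = matrix.counts[:, cols].toarray().astype(float)
    if normalize:
        # scale each cell by its whole-panel total (not just these probes),
        # so the per-transcript noise structure is preserved
        totals = matrix.total_umis_per_cell().astype(float)
        keep = totals > 0
        sub = sub[keep]
        totals = totals[keep]
        traces = sub * (np.median(totals) / totals)[:, None]
    else:
        traces = sub
    n_probes = traces.shape[1]
    rng = np.random.default_rng(seed)
    out = {
        "n": np.arange(1, n_probes + 1),
        "signal_mean": np.empty(n_probes),
        "signal_sd": np.empty(n_probes),
        "noise_mean": np.empty(n_probes),
        "noise_sd": np.empty(n_probes),
        "snr_mean": np.empty(n_probes),
        "snr_sd": np.empty(n_probes),
    }
    chunk = max(1, 4_000_000 // (traces.shape[0] * n_probes + 1))
    for n in range(1, n_probes + 1):
        draws = rng.integers(0, n_probes, size=(reps, n))
        signals = np.empty(reps)
        noises = np.empty(reps)
        for lo in range(0, reps, chunk):
            idx = draws[lo : lo + chunk]  # (c, n)
            summed = traces[:, idx].sum(axis=2)  # cells x c
            signals[lo : lo + chunk] = summed.mean(axis=0)
            noises[lo : lo + chunk] = summed.std(axis=0, ddof=1)
        with np.errstate(divide="ignore"):
            snrs = np.where(noises > 0, signals / noises, np.inf)
        i = n - 1
        out["signal_mean"][i] = signals.mean()
        out["signal_sd"][i] = signals.std(ddof=1) if reps > 1 else 0.0
        out["noise_mean"][i] = noises.mean()
        out["noise_sd"][i] = noises.std(ddof=1) if reps > 1 else 0.0
        finite = np.isfinite(snrs)
        out["snr_mean"][i] = snrs[finite].mean() if finite.any() else np.inf
        out["snr_sd"][i] = (
            snrs[finite].std(ddof=1) if finite.sum() > 1 else 0.0
        )
    return out


def fit_snr_curves(curves: dict) -> dict:
    """Fit M (slope of signal vs n through the origin) and baseline b from
    bootstrap curves produced by :func:`subsample_snr`."""
    n = np.asarray(curves["n"], dtype=float)
    signal = np.asarray(curves["signal_mean"], dtype=float)
    # least-squares slope through the origin of UMIs/cell vs probe number
    M = float((n * signal).sum() / (n * n).sum())
    # noise curve is on the expression scale: SD(sum)/n
    sd_expression = np.asarray(curves["noise_mean"], dtype=float) / n
    b = fit_baseline_b(n, sd_expression, M) if n.size >= 2 else 0.0
    return {"M": M, "b": b}
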