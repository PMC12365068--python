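"""Matplotlib figure helpers for QC output (barcode-rank knee, tiling
traces, bootstrap SNR curves).  Figures are returned; callers save them."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def barcode_rank_plot(umi_totals, threshold: float | None = None):
    totals = np.sort(np.asarray(list(umi_totals), dtype=float))[::-1]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.loglog(np.arange(1, len(totals) + 1), np.maximum(totals, 1e-1))
    if threshold is not None:
        ax.axhline(threshold, color="red", ls="--", lw=1, label="threshold")
        ax.legend(frameon=False)
    ax.set_xlabel("barcode rank")
    ax.set_ylabel("UMIs per barcode")
    fig.tight_layout()
    return fig


def tiling_trace_plot(traces: np.ndarray, probe_mean: np.ndarray):
    fig, ax = plt.subplots(figsize=(5, 3))
    x = np.arange(1, traces.shape[1] + 1)
    for row in traces[: min(len(traces), 200)]:
        ax.plot(x, row, color="gray", alpha=0.15, lw=0.5)
    ax.plot(x, probe_mean, color="tab:blue", lw=2, label="mean")
    ax.set_xlabel("probe (tile index)")
    ax.set_ylabel("normalized UMIs/cell")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def snr_curve_plot(curves: dict, snr_threshold: float = 2.0):
    fig, axes = plt.subplots(1, 3, figsize=(10, 3))
    n = curves["n"]
    for ax, stat, label in zip(
        axes,
        ("signal", "noise", "snr"),
        ("UMIs/cell", "noise (SD)", "SNR"),
    ):
        ax.errorbar(n, curves[f"{stat}_mean"], yerr=curves[f"{stat}_sd"], fmt="o-")
        ax.set_xlabel("probes sampled (n)")
        ax.set_ylabel(label)
    axes[2].axhline(snr_threshold, color="tab:blue", ls="--", lw=1)
    fig.tight_layout()
    return fig
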