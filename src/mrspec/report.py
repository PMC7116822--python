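"""Static fit reports: PNG panels, text summary and CSV tables."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .fitting import FitResult

__all__ = ["write_report"]


def _plot_panels(result: FitResult, outdir: Path) -> list:
    import matplotlib
    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    written = []
    axis = result.axis
    cfg = result.config_echo
    lo, hi = cfg.get("ppm_fit_range", (0.2, 4.2))
    mask = axis.ppm_mask(lo, hi)
    ppm = axis.ppm[mask]
    fit = result.fit_spectrum[mask]
    data = fit + result.residual

    fig, ax = plt.subplots(2, 1, figsize=(8, 6), sharex=True,
                           height_ratios=[3, 1])
    ax[0].plot(ppm, data.real, "k", lw=0.8, label="data")
    ax[0].plot(ppm, fit.real, "r", lw=1.0, label="fit")
    ax[0].legend(); ax[0].set_ylabel("real signal")
    ax[1].plot(ppm, result.residual.real, "0.4", lw=0.8)
    ax[1].set_xlabel("chemical shift (ppm)"); ax[1].set_ylabel("residual")
    for a in ax:
        a.invert_xaxis()
    fig.tight_layout()
    p = outdir / "fit.png"
    fig.savefig(p, dpi=110); plt.close(fig)
    written.append(p)

    if result.has_samples:
        n = result.samples.shape[1]
        ncol = 4
        nrow = int(np.ceil(n / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow))
        for k, name in enumerate(result.param_names):
            a = axes.flat[k]
            a.hist(result.samples[:, k], bins=40, color="steelblue")
            a.set_title(name, fontsize=8)
        for k in range(n, nrow * ncol):
            axes.flat[k].axis("off")
        fig.tight_layout()
        p = outdir / "posteriors.png"
        fig.savefig(p, dpi=100); plt.close(fig)
        written.append(p)

        fig, a = plt.subplots(figsize=(6, 5))
        corr = np.corrcoef(result.samples, rowvar=False)
        im = a.imshow(corr, vmin=-1, vmax=1, cmap="RdBu_r")
        a.set_xticks(range(len(result.param_names)))
        a.set_xticklabels(result.param_names, rotation=90, fontsize=6)
        a.set_yticks(range(len(result.param_names)))
        a.set_yticklabels(result.param_names, fontsize=6)
        fig.colorbar(im)
        fig.tight_layout()
        p = outdir / "correlations.png"
        fig.savefig(p, dpi=100); plt.close(fig)
        written.append(p)
    return written


def write_report(result: FitResult, outdir, qc_table=None) -> list:
    """Write PNG panels, a text summary and a CSV of concentrations.

    Falls back to text-only output (with a warning) if plotting fails,
    e.g. when no matplotlib backend is usable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        written += _plot_panels(result, outdir)
    except Exception as exc:
        warnings.warn(f"plotting unavailable ({exc}); writing text-only report")

    df = result.as_dataframe()
    csv_path = outdir / "concentrations.csv"
    df.to_csv(csv_path, index=False)
    written.append(csv_path)

    lines = ["fit summary", "===========", ""]
    lines.append(df.to_string(index=False))
    if qc_table is not None:
        lines += ["", "quality control", "---------------",
                  qc_table.to_string(index=False)]
    if result.has_samples:
        lines += ["", f"posterior samples: {result.samples.shape[0]}",
                  f"seed: {result.seed}"]
    else:
        lines += ["", "algorithm: newton (no posterior samples)"]
    txt_path = outdir / "summary.txt"
    txt_path.write_text("\n".join(lines) + "\n")
    written.append(txt_path)
    return written
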