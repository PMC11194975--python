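"""Basic figures: PSA scatter, CEAC, tornado. Matplotlib, Agg-safe."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .sensitivity import CEACCurve, PSAResult, TornadoEntry


def plot_psa_scatter(psa: PSAResult, comparison: tuple[str, str],
                     threshold: float, path: str | Path) -> None:
    dc, dq = psa.deltas(comparison)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(dq, dc, s=4, alpha=0.3)
    lim = max(abs(dq).max(), 1e-9)
    ax.plot([-lim, lim], [-threshold * lim, threshold * lim], "r--", lw=1,
            label=f"threshold {threshold:,.0f}/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    ax.set_title(f"{comparison[0]} vs {comparison[1]}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CEACCurve, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for j, s in enumerate(curve.strategies):
        ax.plot(curve.thresholds, curve.probabilities[:, j], label=s)
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("P(highest net monetary benefit)")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(entries: Sequence[TornadoEntry], base_icer: float,
                 path: str | Path) -> None:
    entries = [e for e in entries if e.icer_at_low is not None and e.icer_at_high is not None]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1.5))
    for i, e in enumerate(reversed(entries)):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - lo, left=lo, height=0.6)
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.param_id for e in reversed(entries)], fontsize=8)
    ax.set_xlabel("ICER (USD/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
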