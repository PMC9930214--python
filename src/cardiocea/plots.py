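"""Plot helpers: tornado diagram, CE-plane scatter, acceptability curve.

All functions write a file and return the path; they use the Agg backend so
they are safe headless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .sensitivity import CEACCurve, PSAResult, TornadoEntry


def plot_tornado(entries: Sequence[TornadoEntry], path: str | Path,
                 base_outcome: float | None = None, top: int = 15) -> Path:
    """Horizontal tornado diagram of incremental-NMB swings (widest on top)."""
    entries = list(entries)[:top]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(entries) + 1.5))
    for i, e in enumerate(reversed(entries)):
        lo, hi = sorted((e.outcome_at_low, e.outcome_at_high))
        ax.barh(i, hi - lo, left=lo, height=0.7, color="#4878d0")
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.param_id for e in reversed(entries)], fontsize=8)
    if base_outcome is not None:
        ax.axvline(base_outcome, color="k", lw=0.8, ls="--")
    ax.set_xlabel("incremental net monetary benefit (USD)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ce_plane(psa: PSAResult, wtp: float, path: str | Path) -> Path:
    """Scatter of per-trial (dQALY, dCost) with the WTP threshold ray."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qaly, psa.delta_cost, s=4, alpha=0.3, color="#4878d0")
    lim = max(abs(psa.delta_qaly).max(), 1e-9)
    xs = [-lim * 1.1, lim * 1.1]
    ax.plot(xs, [wtp * x for x in xs], color="k", lw=0.8, ls="--",
            label=f"WTP = {wtp:,.0f} $/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("incremental QALYs (CABG - PCI)")
    ax.set_ylabel("incremental cost, USD (CABG - PCI)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ceac(curve: CEACCurve, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.probability, color="#4878d0")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("willingness to pay (USD per QALY)")
    ax.set_ylabel("P(CABG cost-effective)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
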