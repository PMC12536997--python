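"""Plain matplotlib renderings: tornado diagram, CE plane, CEAC."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .cea import Effect  # noqa: E402

_EFFECT_LABEL = {
    Effect.BED_DAYS_SAVED: "bed days saved",
    Effect.QALY: "QALYs gained",
}


def _finish(fig, path):
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def tornado_plot(results, path=None, max_bars=None):
    """Horizontal-bar tornado: INMB swing per parameter around base case."""
    entries = results.entries if max_bars is None else results.entries[:max_bars]
    entries = list(reversed(entries))  # widest on top
    fig, ax = plt.subplots(figsize=(7, 0.35 * max(len(entries), 4) + 1.2))
    y = range(len(entries))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.inmb_low, e.inmb_high))
        ax.barh(i, hi - lo, left=lo, color="#4878b0", height=0.6)
    ax.axvline(results.base_inmb, color="black", lw=1, ls="--",
               label=f"base INMB AU${results.base_inmb:,.0f}")
    ax.set_yticks(list(y))
    ax.set_yticklabels([e.parameter for e in entries], fontsize=8)
    ax.set_xlabel(f"Incremental NMB (AU$) at WTP AU${results.wtp:,.0f} "
                  f"per {_EFFECT_LABEL[results.effect].rstrip('s')}")
    ax.legend(loc="lower right", fontsize=8)
    ax.set_title("One-way sensitivity analysis")
    fig.tight_layout()
    return _finish(fig, path)


def ce_plane_plot(results, effect=Effect.BED_DAYS_SAVED, path=None):
    """Scatter of per-draw (delta effect, delta cost) pairs."""
    df = results.ce_plane(effect)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["delta_effect"], df["delta_cost"], s=4, alpha=0.25,
               color="#4878b0", edgecolors="none")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel(f"Incremental effect ({_EFFECT_LABEL[Effect(effect)]})")
    ax.set_ylabel("Incremental cost (AU$)")
    ax.set_title("Cost-effectiveness plane (day surgery vs conventional)")
    fig.tight_layout()
    return _finish(fig, path)


def ceac_plot(results, effect=Effect.BED_DAYS_SAVED, path=None):
    """Probability of cost-effectiveness across willingness-to-pay values."""
    df = results.ceac(effect)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["wtp"], df["probability"], color="#4878b0")
    ax.set_ylim(0, 1)
    ax.set_xlabel(f"Willingness to pay (AU$ per {_EFFECT_LABEL[Effect(effect)].rstrip('s')})")
    ax.set_ylabel("Probability cost-effective")
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    return _finish(fig, path)
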