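"""Profile plots: cumulative % of dose collected versus time."""

from __future__ import annotations

from typing import Sequence


def _get_axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(6, 4))
    return ax


def plot_profile(result, ax=None, label: str | None = None, **kwargs):
    """Plot one cumulative-permeation profile (% of dose vs minutes)."""
    ax = _get_axes(ax)
    if label is None:
        md = result.metadata
        label = (f"{md['drug']['name']} ({md['run']['dose_form']}, "
                 f"{md['run']['stirring'].replace('_', '-')})")
    ax.plot(result.times, result.pct_collected, label=label, **kwargs)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cumulative drug collected (% of dose)")
    ax.set_ylim(0, 105)
    ax.legend(fontsize=8)
    return ax


def plot_profiles(results: Sequence, labels: Sequence[str] | None = None, ax=None):
    """Overlay several profiles on one axes."""
    ax = _get_axes(ax)
    labels = labels or [None] * len(results)
    for result, label in zip(results, labels):
        plot_profile(result, ax=ax, label=label)
    return ax


def plot_sweep(sweep_result, ax=None):
    """Overlay the profiles of a sweep, labelled by the swept value."""
    ax = _get_axes(ax)
    name = sweep_result.spec.parameter.value
    for value, result in zip(sweep_result.spec.values, sweep_result.results):
        plot_profile(result, ax=ax, label=f"{name} = {value:g}")
    return ax


def save_figure(ax, path) -> None:
    """Save the figure owning ``ax`` to ``path``."""
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
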