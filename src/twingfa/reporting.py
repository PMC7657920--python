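"""Component diagrams: per-component multi-panel heatmaps.

Each retained component is pictured as up to five small heatmaps, one
per active view, showing the original (pre-scaling) within-pair
difference values of the variables with the largest posterior-mean
loadings.  Pairs are ordered by the component score, so the structure
the component captures reads top-to-bottom; positive differences
render red, negative blue, on a symmetric diverging scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .component_analysis import component_activity, prune_empty_components
from .gibbs_sampler import PosteriorSummary
from .twin_preprocess import DifferenceMatrix

__all__ = ["ComponentDiagram", "assemble_component_diagram", "render_heatmaps"]

# stable SVG ids so repeated renders are byte-identical
matplotlib.rcParams["svg.hashsalt"] = "twingfa"


@dataclass
class ComponentDiagram:
    """Data behind one component's multi-panel heatmap.

    ``panels`` maps view name -> pairs x variables frame of difference
    values, restricted to the selected variables and with rows in
    ``pair_order`` (descending posterior-mean score) — identical across
    panels.
    """

    component: int
    pair_order: list[str]
    scores: np.ndarray
    panels: dict[str, pd.DataFrame]
    loadings: dict[str, pd.Series]


def assemble_component_diagram(
    posterior: PosteriorSummary,
    views: dict[str, DifferenceMatrix],
    k: int,
    top_n: int = 10,
    threshold: float = 0.5,
) -> ComponentDiagram:
    """Select variables and order pairs for component ``k``.

    Per active view the ``top_n`` variables by absolute posterior-mean
    loading are selected and shown in descending signed-loading order;
    pairs are sorted by descending posterior-mean score.  Raises if the
    component is empty (pruned) at the given activity threshold.
    """
    retained = prune_empty_components(posterior, threshold)
    if k not in retained:
        raise ValueError(f"component {k} is empty at threshold {threshold}")
    _, active = component_activity(posterior, threshold)

    scores = posterior.z_mean[:, k]
    order = np.argsort(-scores, kind="stable")

    panels: dict[str, pd.DataFrame] = {}
    loadings: dict[str, pd.Series] = {}
    pair_order: list[str] | None = None
    for m, view_name in enumerate(posterior.view_names):
        if not active[m, k] or view_name not in views:
            continue
        dm = views[view_name]
        w = pd.Series(posterior.w_mean[m][:, k], index=posterior.var_names[m])
        w = w[[c for c in w.index if c in dm.values.columns]]
        top = w.reindex(w.abs().sort_values(ascending=False).index).head(top_n)
        top = top.sort_values(ascending=False)
        sub = dm.values.iloc[order][top.index]
        panels[view_name] = sub
        loadings[view_name] = top
        if pair_order is None:
            pair_order = list(sub.index)
    if pair_order is None:  # pragma: no cover - retained implies >= 1 active view
        raise ValueError(f"component {k} has no active view with data")
    return ComponentDiagram(
        component=k,
        pair_order=pair_order,
        scores=scores[order],
        panels=panels,
        loadings=loadings,
    )


def render_heatmaps(
    diagram: ComponentDiagram,
    outfile: str | Path,
    vmax_quantile: float = 0.98,
) -> Path:
    """Write the multi-panel heatmap to ``outfile`` (PNG or SVG).

    Each panel uses a diverging red/blue palette centered at zero with
    a symmetric range capped at the ``vmax_quantile`` of |values| to
    keep outliers from washing out the scale.  Output is deterministic:
    rendering the same diagram twice yields identical bytes.
    """
    outfile = Path(outfile)
    try:
        outfile.parent.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory for {outfile}") from exc

    names = list(diagram.panels)
    widths = [max(diagram.panels[v].shape[1], 1) for v in names]
    fig, axes = plt.subplots(
        1,
        len(names),
        figsize=(1.2 + 0.32 * sum(widths), 1.5 + 0.14 * len(diagram.pair_order)),
        gridspec_kw={"width_ratios": widths},
        squeeze=False,
    )
    for ax, view in zip(axes[0], names):
        block = diagram.panels[view].to_numpy(dtype=float)
        finite = np.abs(block[np.isfinite(block)])
        vmax = float(np.quantile(finite, vmax_quantile)) if finite.size else 1.0
        if vmax <= 0:
            vmax = 1.0
        ax.imshow(
            np.ma.masked_invalid(block),
            cmap="RdBu_r",
            vmin=-vmax,
            vmax=vmax,
            aspect="auto",
            interpolation="nearest",
        )
        ax.set_title(view, fontsize=8)
        ax.set_xticks(range(block.shape[1]))
        ax.set_xticklabels(diagram.panels[view].columns, rotation=90, fontsize=6)
        ax.set_yticks([])
    axes[0][0].set_yticks(range(len(diagram.pair_order)))
    axes[0][0].set_yticklabels(diagram.pair_order, fontsize=5)
    fig.suptitle(f"component {diagram.component}", fontsize=9)
    fig.tight_layout()
    fig.savefig(outfile, metadata=_deterministic_metadata(outfile))
    plt.close(fig)
    return outfile


def _deterministic_metadata(outfile: Path) -> dict | None:
    suffix = outfile.suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": None}
    return None
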