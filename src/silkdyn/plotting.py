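"""Figure data and rendering: dynamics curves with bands, model graphs.

Conventions follow the field's presentation of SILK data: observed RIA dots
sized proportionally to the square root of the heavy-label intensity, the
model curve(s) in front, a vertical marker at the end of tracer injection
(9 h), and gray pointwise 95% credibility bands when a posterior is
available. The compartment-graph rendering encodes each rate's posterior
mean as edge width and its relative CI95 (interval range divided by the
estimate) as edge color.
"""

from __future__ import annotations

import numpy as np

from .models import get_model, integrate
from .protocols import InfusionProtocol

__all__ = ["render_dynamics_plot", "render_model_graph", "make_figure"]

# edges of each model variant: (source, target, rate name)
_MODEL_EDGES = {
    "three_bc_full": [
        ("tracer", "plasma", "syn_plasma"),
        ("tracer", "cns", "syn_cns"),
        ("plasma", "out", "elim_plasma"),
        ("cns", "out", "elim_cns"),
        ("csf", "out", "elim_csf"),
        ("plasma", "csf", "k_plasma_csf"),
        ("csf", "plasma", "k_csf_plasma"),
        ("cns", "csf", "k_cns_csf"),
        ("csf", "cns", "k_csf_cns"),
        ("plasma", "cns", "k_plasma_cns"),
        ("cns", "plasma", "k_cns_plasma"),
    ],
    "three_bc_simplified": [
        ("tracer", "plasma", "syn_plasma"),
        ("tracer", "cns", "syn_cns"),
        ("plasma", "out", "elim_plasma"),
        ("cns", "out", "elim_cns"),
        ("plasma", "csf", "k_plasma_csf"),
        ("csf", "plasma", "k_csf_plasma"),
        ("cns", "csf", "k_cns_csf"),
        ("csf", "cns", "k_csf_cns"),
    ],
    "two_bc": [
        ("tracer", "plasma", "a"),
        ("plasma", "out", "b"),
        ("plasma", "csf", "k_plasma_csf"),
        ("csf", "plasma", "k_csf_plasma"),
    ],
    "single": [
        ("tracer", "plasma", "a"),
        ("plasma", "out", "b"),
    ],
}


def render_dynamics_plot(observations, fit=None, posterior_bands=None,
                         protocol: InfusionProtocol | None = None,
                         grid=None) -> dict:
    """Assemble plot data for one protein's dynamics.

    Returns a dict with observed dots (positions and sizes proportional to
    sqrt(I6)), per-fluid model curves when a point fit is supplied,
    credibility bands when posterior band data is supplied, and the 9 h
    end-of-injection marker. Rendering to a matplotlib figure is done by
    ``make_figure``.
    """
    protocol = protocol or InfusionProtocol()
    if grid is None:
        grid = np.arange(0.0, 36.2 + 0.1, 0.1)
    grid = np.asarray(grid, float)

    dots = {}
    for obs in observations:
        ria = obs.ria
        ok = ~np.isnan(ria)
        dots.setdefault(obs.fluid, []).append({
            "t": obs.times[ok],
            "ria": ria[ok],
            "size": np.sqrt(np.where(obs.i6[ok] > 0, obs.i6[ok], 0.0)),
            "key": obs.key,
        })

    curves = {}
    if fit is not None:
        spec = get_model(fit.model)
        rates = [fit.params[k] for k in spec.rate_names]
        traj = integrate(spec, rates, protocol, grid, method="expm")
        curves["g"] = traj.g
        for fl in fit.fluids or spec.fluids:
            state = spec.fluids[0] if len(spec.fluids) == 1 else fl
            curves[fl] = traj.r(state) + fit.shifts[fl]

    bands = {}
    if posterior_bands is not None:
        for state, band in posterior_bands["bands"].items():
            bands[state] = {"lo": band["lo"], "hi": band["hi"],
                            "median": band["median"],
                            "grid": posterior_bands["grid"]}

    return {"grid": grid, "dots": dots, "curves": curves, "bands": bands,
            "label_end": protocol.total_label_window}


def render_model_graph(posterior_summary: dict, model) -> dict:
    """Graph specification of a fitted compartment model.

    Nodes are compartments; each edge carries the rate's posterior mean
    (mapped to line width) and its relative CI95 (mapped to a color value,
    0 = coldest/most certain).
    """
    spec = get_model(model)
    edges = []
    means = [posterior_summary[r]["mean"] for _, _, r in _MODEL_EDGES[spec.name]
             if r in posterior_summary]
    max_mean = max(means) if means else 1.0
    for src, dst, rate in _MODEL_EDGES[spec.name]:
        if rate not in posterior_summary:
            continue
        entry = posterior_summary[rate]
        edges.append({
            "source": src, "target": dst, "rate": rate,
            "mean": float(entry["mean"]),
            "width": 0.5 + 4.0 * float(entry["mean"]) / max(max_mean, 1e-12),
            "rel_ci95": float(entry.get("rel_ci95", np.nan)),
        })
    nodes = sorted({e["source"] for e in edges}
                   | {e["target"] for e in edges})
    return {"model": spec.name, "nodes": nodes, "edges": edges}


def make_figure(plot_data: dict, title: str = ""):
    """Render dynamics plot data to a matplotlib figure (Agg-safe)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fluids = sorted(set(plot_data["dots"]) | set(
        k for k in plot_data["curves"] if k != "g"))
    fig, axes = plt.subplots(1, max(len(fluids), 1), squeeze=False,
                             figsize=(5 * max(len(fluids), 1), 4))
    for ax, fl in zip(axes[0], fluids):
        band = plot_data["bands"].get(fl)
        if band is not None:
            ax.fill_between(band["grid"], band["lo"], band["hi"],
                            color="0.8", label="95% credibility")
        for dot in plot_data["dots"].get(fl, []):
            smax = float(np.max(dot["size"])) or 1.0
            ax.scatter(dot["t"], dot["ria"], s=5 + 40 * (dot["size"] / smax) ** 2,
                       alpha=0.6, color="salmon", edgecolors="none")
        if fl in plot_data["curves"]:
            ax.plot(plot_data["grid"], plot_data["curves"][fl], "k-", lw=1.5)
        if "g" in plot_data["curves"]:
            ax.plot(plot_data["grid"], plot_data["curves"]["g"], "b--", lw=1,
                    alpha=0.5)
        ax.axvline(plot_data["label_end"], color="0.5", lw=0.8)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("RIA")
        ax.set_title(f"{title} {fl}".strip())
    fig.tight_layout()
    return fig
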