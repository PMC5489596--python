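"""Assembly of result tables, figures and a run summary.

``build_report`` accepts whatever pipeline stages completed and writes a
self-contained bundle: CSV tables (behavioral summaries, parameter
estimates by distance, DIC comparison, contrast probabilities, PPC
summaries), PNG figures, and a Markdown report embedding run metadata
(config, seeds, package version).  Missing stages are listed explicitly in
the report rather than silently skipped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .pipeline import AnalysisResult
from .ppc import QuantileSummary

__all__ = ["build_report"]


def _fig_behavior(behavior: pd.DataFrame, path: Path) -> None:
    rolled = behavior[(behavior["difficulty"] == "(all)")]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for anchor, style in (("error", "o-"), ("correct", "s--")):
        sub = rolled[rolled["anchor"] == anchor].sort_values("distance")
        axes[0].errorbar(sub["distance"], sub["mean_rt_ms"],
                         yerr=sub["sem_rt_ms"], fmt=style, capsize=3,
                         label=f"post-{anchor}")
        axes[1].plot(sub["distance"], 100 * sub["accuracy"], style,
                     label=f"post-{anchor}")
    axes[0].set(xlabel="distance to anchor", ylabel="mean RT (ms)")
    axes[1].set(xlabel="distance to anchor", ylabel="accuracy (%)")
    for ax in axes:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_params_by_distance(params: pd.DataFrame, path: Path) -> None:
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax, p in zip(axes, ("a", "v", "t_er")):
        for cond, style in (("PE", "o-"), ("PC", "s--")):
            sub = params[(params["parameter"] == p)
                         & (params["condition"] == cond)].sort_values("distance")
            ax.errorbar(sub["distance"], sub["mean"], yerr=sub["sd"],
                        fmt=style, capsize=3, label=cond)
        ax.set(xlabel="distance", title=p)
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_ppc(ppc: QuantileSummary, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    choice = ppc.choice.set_index("condition")
    for cond, sub in ppc.quantiles.groupby("condition"):
        for boundary, bsub in sub.groupby("boundary"):
            p = choice.loc[cond, "observed"]
            x = p if boundary == "upper" else 1.0 - p
            ax.errorbar([x] * len(bsub), bsub["predicted_mean"],
                        yerr=2 * bsub["predicted_sd"], fmt="o", alpha=0.5,
                        label=f"{cond} {boundary} predicted")
            ax.plot([x] * len(bsub), bsub["observed"], "k+", ms=10)
    ax.set(xlabel="choice probability", ylabel="RT quantile (s)",
           title="quantile-probability check (+ observed, o predicted ±2 SD)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def build_report(out_dir,
                 behavior: Optional[pd.DataFrame] = None,
                 analyses: Optional[Mapping[str, AnalysisResult]] = None,
                 params_by_distance: Optional[pd.DataFrame] = None,
                 ppcs: Optional[Mapping[str, QuantileSummary]] = None,
                 metadata: Optional[dict] = None) -> Path:
    """Write the report bundle into ``out_dir``; returns the report path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# pesddm run report", ""]
    gaps = []

    meta = dict(metadata or {})
    meta["pesddm_version"] = __version__
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2,
                                                      default=str))
    lines += ["```json", json.dumps(meta, indent=2, default=str), "```", ""]

    if behavior is not None and len(behavior):
        behavior.to_csv(out / "behavior_summary.csv", index=False)
        _fig_behavior(behavior, out / "behavior_by_distance.png")
        lines += ["## Behavioral summary",
                  "See `behavior_summary.csv` and `behavior_by_distance.png`.", ""]
    else:
        gaps.append("behavioral summary")

    if params_by_distance is not None and len(params_by_distance):
        params_by_distance.to_csv(out / "params_by_distance.csv", index=False)
        _fig_params_by_distance(params_by_distance,
                                out / "params_by_distance.png")
        lines += ["## Parameter estimates by distance",
                  "See `params_by_distance.csv` and `params_by_distance.png`.", ""]
    else:
        gaps.append("parameter-by-distance table")

    if analyses:
        for name, res in analyses.items():
            res.comparison.to_csv(out / f"dic_{name}.csv", index=False)
            res.contrasts.to_csv(out / f"contrasts_{name}.csv", index=False)
            res.full_fit.summary().to_csv(out / f"posterior_{name}.csv")
            winner = res.comparison.loc[res.comparison["winner"], "model"].iloc[0]
            lines += [f"## Analysis {name}",
                      f"- condition sizes: {res.data_sizes}",
                      f"- best model by DIC: `{winner}`",
                      f"- tables: `dic_{name}.csv`, `contrasts_{name}.csv`, "
                      f"`posterior_{name}.csv`", ""]
    else:
        gaps.append("model fits")

    if ppcs:
        for name, ppc in ppcs.items():
            ppc.quantiles.to_csv(out / f"ppc_quantiles_{name}.csv", index=False)
            ppc.choice.to_csv(out / f"ppc_choice_{name}.csv", index=False)
            _fig_ppc(ppc, out / f"ppc_{name}.png")
            lines += [f"## Posterior predictive check ({name})",
                      f"- coverage within ±2 predictive SD: {ppc.coverage():.3f}",
                      f"- tables: `ppc_quantiles_{name}.csv`, `ppc_choice_{name}.csv`", ""]
    else:
        gaps.append("posterior predictive checks")

    if gaps:
        lines += ["## Missing stages",
                  *[f"- {g} (not run)" for g in gaps], ""]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
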