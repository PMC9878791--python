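"""Publication plots and their machine-readable TSV twins.

Nine outputs per analysis model, written into folders named for drop-in
comparison with the original tooling's output tree: ``partialAxes_Plot1``,
``groupContribution_Plot2``, ``individualCoordinates_Plot3`` (2D plus an
interactive-HTML 3D view), ``sqload_Plot4``,
``quantitativeVarCoordinates_Plot5``, ``levelsComponents_Plot6``,
``paralelPlot`` (sic — the misspelling is preserved deliberately),
``importance_variables`` and ``cumulativeVariance``.  Every figure has a TSV
twin holding exactly the plotted numbers.
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from phenodisc.classify import GroupSummary, ImportanceTable
from phenodisc.factor_core import FactorResult, MFAResult, cumulative_variance
from phenodisc.selection import SelectionReport

FOLDER_NAMES = (
    "partialAxes_Plot1",
    "groupContribution_Plot2",
    "individualCoordinates_Plot3",
    "sqload_Plot4",
    "quantitativeVarCoordinates_Plot5",
    "levelsComponents_Plot6",
    "paralelPlot",
    "importance_variables",
    "cumulativeVariance",
)

_FALLBACK = plt.get_cmap("tab10")


@dataclass
class StyleSpec:
    colors: dict[str, str] = field(default_factory=dict)
    figsize: tuple[float, float] = (6.0, 5.0)
    font_scale: float = 1.0
    formats: tuple[str, ...] = ("png", "svg")

    def color_for(self, name: str, position: int) -> str:
        if name in self.colors:
            return self.colors[name]
        return matplotlib.colors.to_hex(_FALLBACK(position % 10))


def _save(fig, folder: Path, stem: str, style: StyleSpec, manifest: list[str]) -> None:
    folder.mkdir(parents=True, exist_ok=True)
    for fmt in style.formats:
        target = folder / f"{stem}.{fmt}"
        fig.savefig(target, dpi=300, bbox_inches="tight")
        manifest.append(str(target))
    plt.close(fig)


def _twin(frame: pd.DataFrame, folder: Path, stem: str, manifest: list[str]) -> None:
    folder.mkdir(parents=True, exist_ok=True)
    target = folder / f"{stem}.tsv"
    frame.to_csv(target, sep="\t", index=True)
    manifest.append(str(target))


def parallel_plot_data(
    summaries: GroupSummary,
    scaled: bool,
    subset: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Stratum-by-variable mean table behind the parallel-coordinates plot.

    One row per dependent-level x sex stratum, one column per variable.
    ``subset`` keeps only strata whose dependent level is listed (for
    pairwise-genotype panels); ``scaled`` is recorded so the twin TSV states
    which scale the caller's summaries were computed on.
    """
    frame = summaries.frame.pivot(index="stratum", columns="variable", values="mean")
    if subset is not None:
        keep = [s for s in frame.index if s.split("|")[0] in subset]
        frame = frame.loc[keep]
    frame.attrs["scaled"] = scaled
    return frame


def render_all(
    mfa: FactorResult,
    selection: SelectionReport | None,
    importances: list[ImportanceTable] | None,
    summaries: GroupSummary | None,
    style: StyleSpec,
    outdir: str | Path,
    class_labels: pd.Series | None = None,
    summaries_scaled: GroupSummary | None = None,
) -> dict:
    """Write the nine plot folders; returns a manifest of written files.

    Any missing upstream result skips its plot (with the reason recorded in
    the manifest) and the others are still produced.
    """
    outdir = Path(outdir)
    files: list[str] = []
    skipped: dict[str, str] = {}
    dims = list(mfa.scores.columns)
    d2 = min(2, len(dims))

    # 1 — partial axes -------------------------------------------------------
    folder = outdir / "partialAxes_Plot1"
    if isinstance(mfa, MFAResult) and mfa.partial_axes is not None and len(mfa.partial_axes):
        pa = mfa.partial_axes.iloc[:, :max(d2, 1)]
        fig, ax = plt.subplots(figsize=style.figsize)
        for i, name in enumerate(pa.index):
            x = pa.iloc[i, 0]
            y = pa.iloc[i, 1] if d2 > 1 else 0.0
            ax.annotate("", xy=(x, y), xytext=(0, 0),
                        arrowprops={"arrowstyle": "->", "color": style.color_for(name, i)})
            ax.text(x, y, name, fontsize=8 * style.font_scale)
        circle = plt.Circle((0, 0), 1.0, fill=False, linestyle="--", color="grey")
        ax.add_patch(circle)
        ax.set_xlim(-1.1, 1.1); ax.set_ylim(-1.1, 1.1)
        ax.set_xlabel(dims[0]); ax.set_ylabel(dims[1] if d2 > 1 else "")
        ax.set_title("Group partial axes")
        _save(fig, folder, "partialAxes", style, files)
        _twin(mfa.partial_axes, folder, "partialAxes", files)
    else:
        skipped["partialAxes_Plot1"] = "no MFA partial axes available"

    # 2 — group contributions ------------------------------------------------
    folder = outdir / "groupContribution_Plot2"
    if isinstance(mfa, MFAResult) and mfa.group_contributions is not None:
        gc = mfa.group_contributions.iloc[:, : min(3, len(dims))]
        fig, ax = plt.subplots(figsize=style.figsize)
        gc.plot.bar(ax=ax)
        ax.set_ylabel("contribution to eigenvalue")
        ax.set_title("Group contributions")
        _save(fig, folder, "groupContribution", style, files)
        _twin(mfa.group_contributions, folder, "groupContribution", files)
    else:
        skipped["groupContribution_Plot2"] = "no group contributions available"

    # 3 — individual coordinates (2D + 3D HTML) ------------------------------
    folder = outdir / "individualCoordinates_Plot3"
    labels = class_labels if class_labels is not None else pd.Series("all", index=mfa.scores.index)
    fig, axes = plt.subplots(1, 2 if len(dims) >= 3 else 1,
                             figsize=(style.figsize[0] * 2, style.figsize[1]), squeeze=False)
    pairs = [(0, 1)] + ([(1, 2)] if len(dims) >= 3 else [])
    for ax, (i, j) in zip(axes[0], pairs):
        for k, level in enumerate(sorted(labels.astype(str).unique())):
            mask = (labels.astype(str) == level).to_numpy()
            ax.scatter(mfa.scores.iloc[mask, i], mfa.scores.iloc[mask, j],
                       s=18, label=level, color=style.color_for(level, k))
        ax.set_xlabel(dims[i]); ax.set_ylabel(dims[j]); ax.legend(fontsize=7)
    fig.suptitle("Individual coordinates")
    _save(fig, folder, "individualCoordinates_2D", style, files)
    twin = mfa.scores.copy()
    twin["class"] = labels.astype(str).to_numpy()
    _twin(twin, folder, "individualCoordinates", files)
    if len(dims) >= 3:
        files.append(str(_scatter3d_html(mfa.scores, labels, style, folder)))

    # 4 — squared loadings ---------------------------------------------------
    folder = outdir / "sqload_Plot4"
    sq = mfa.squared_loadings.iloc[:, :d2]
    fig, ax = plt.subplots(figsize=style.figsize)
    for i, var in enumerate(sq.index):
        x = sq.iloc[i, 0]
        y = sq.iloc[i, 1] if d2 > 1 else 0.0
        ax.scatter([x], [y], color=style.color_for(var, i))
        ax.text(x, y, var, fontsize=8 * style.font_scale)
    ax.set_xlabel(f"{dims[0]} squared loading")
    ax.set_ylabel(f"{dims[1]} squared loading" if d2 > 1 else "")
    ax.set_title("Squared loadings")
    _save(fig, folder, "sqload", style, files)
    _twin(mfa.squared_loadings, folder, "sqload", files)

    # 5 — quantitative variable correlations ---------------------------------
    folder = outdir / "quantitativeVarCoordinates_Plot5"
    if len(mfa.quant_correlations):
        qc = mfa.quant_correlations.iloc[:, :d2]
        fig, ax = plt.subplots(figsize=style.figsize)
        for i, var in enumerate(qc.index):
            x = qc.iloc[i, 0]
            y = qc.iloc[i, 1] if d2 > 1 else 0.0
            ax.annotate("", xy=(x, y), xytext=(0, 0),
                        arrowprops={"arrowstyle": "->", "color": style.color_for(var, i)})
            ax.text(x, y, var, fontsize=8 * style.font_scale)
        ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, linestyle="--", color="grey"))
        ax.set_xlim(-1.1, 1.1); ax.set_ylim(-1.1, 1.1)
        ax.set_xlabel(dims[0]); ax.set_ylabel(dims[1] if d2 > 1 else "")
        ax.set_title("Quantitative variable correlations")
        _save(fig, folder, "quantitativeVarCoordinates", style, files)
        _twin(mfa.quant_correlations, folder, "quantitativeVarCoordinates", files)
    else:
        skipped["quantitativeVarCoordinates_Plot5"] = "no quantitative variables"

    # 6 — qualitative level coordinates --------------------------------------
    folder = outdir / "levelsComponents_Plot6"
    if len(mfa.level_coordinates):
        lc = mfa.level_coordinates.iloc[:, :d2]
        fig, ax = plt.subplots(figsize=style.figsize)
        for i, level in enumerate(lc.index):
            x = lc.iloc[i, 0]
            y = lc.iloc[i, 1] if d2 > 1 else 0.0
            ax.scatter([x], [y], color=style.color_for(level, i))
            ax.text(x, y, level, fontsize=8 * style.font_scale)
        ax.axhline(0, color="grey", lw=0.5); ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel(dims[0]); ax.set_ylabel(dims[1] if d2 > 1 else "")
        ax.set_title("Qualitative level coordinates")
        _save(fig, folder, "levelsComponents", style, files)
        _twin(mfa.level_coordinates, folder, "levelsComponents", files)
    else:
        skipped["levelsComponents_Plot6"] = "no qualitative variables"

    # 7 — parallel coordinates ----------------------------------------------
    folder = outdir / "paralelPlot"
    if summaries is not None and len(summaries.frame):
        for stem, summ, scaled in (
            ("paralelPlot_raw", summaries, False),
            ("paralelPlot_scaled", summaries_scaled, True),
        ):
            if summ is None:
                continue
            pdata = parallel_plot_data(summ, scaled=scaled)
            fig, ax = plt.subplots(figsize=(style.figsize[0] * 1.6, style.figsize[1]))
            for k, stratum in enumerate(pdata.index):
                ax.plot(range(pdata.shape[1]), pdata.loc[stratum], marker="o",
                        label=stratum, color=style.color_for(stratum, k))
            ax.set_xticks(range(pdata.shape[1]))
            ax.set_xticklabels(pdata.columns, rotation=45, ha="right",
                               fontsize=7 * style.font_scale)
            ax.set_ylabel("scaled mean" if scaled else "mean")
            ax.legend(fontsize=7)
            ax.set_title("Parallel coordinates of stratum means")
            _save(fig, folder, stem, style, files)
            _twin(pdata, folder, stem, files)
    else:
        skipped["paralelPlot"] = "no group summaries available"

    # 8 — classifier importances ---------------------------------------------
    folder = outdir / "importance_variables"
    if importances:
        long = pd.concat(
            [t.frame.assign(classifier=t.classifier) for t in importances],
            ignore_index=True,
        )
        classes = sorted(long["class"].unique())
        fig, axes = plt.subplots(1, len(classes),
                                 figsize=(style.figsize[0] * len(classes), style.figsize[1]),
                                 squeeze=False, sharey=True)
        variables = sorted(long["variable"].unique())
        ypos = {v: i for i, v in enumerate(variables)}
        for ax, cls in zip(axes[0], classes):
            sub = long[long["class"] == cls]
            for k, clf_name in enumerate(sorted(sub["classifier"].unique())):
                part = sub[sub["classifier"] == clf_name]
                ax.scatter(part["scaled"], [ypos[v] for v in part["variable"]],
                           label=clf_name, color=style.color_for(clf_name, k), s=22)
            ax.set_title(str(cls)); ax.set_xlabel("scaled importance")
            ax.set_yticks(range(len(variables))); ax.set_yticklabels(variables, fontsize=7)
        axes[0][0].legend(fontsize=7)
        _save(fig, folder, "importance_variables", style, files)
        _twin(long.set_index(["classifier", "class", "variable"]),
              folder, "importance_variables", files)
    else:
        skipped["importance_variables"] = "no classifier importances available"

    # 9 — cumulative variance ------------------------------------------------
    folder = outdir / "cumulativeVariance"
    cv = cumulative_variance(mfa, 10)
    fig, ax = plt.subplots(figsize=style.figsize)
    ax.bar(cv["dimension"], cv["variance_pct"], color="#4477aa", label="per dimension")
    ax.plot(cv["dimension"], cv["cumulative_pct"], "o-", color="#cc6644", label="cumulative")
    ax.set_xlabel("dimension"); ax.set_ylabel("% variance explained")
    ax.set_ylim(0, 105); ax.legend()
    ax.set_title("Variance explained (top 10 dimensions)")
    _save(fig, folder, "cumulativeVariance", style, files)
    _twin(cv.set_index("dimension"), folder, "cumulativeVariance", files)

    return {"files": files, "skipped": skipped}


def _scatter3d_html(scores: pd.DataFrame, labels: pd.Series, style: StyleSpec, folder: Path) -> Path:
    """Standalone HTML 3D view (static render embedded; no external assets)."""
    from mpl_toolkits.mplot3d import Axes3D  # noqa: F401 - registers 3d projection

    fig = plt.figure(figsize=(style.figsize[0], style.figsize[1]))
    ax = fig.add_subplot(projection="3d")
    dims = list(scores.columns[:3])
    for k, level in enumerate(sorted(labels.astype(str).unique())):
        mask = (labels.astype(str) == level).to_numpy()
        ax.scatter(scores.iloc[mask, 0], scores.iloc[mask, 1], scores.iloc[mask, 2],
                   s=16, label=level, color=style.color_for(level, k))
    ax.set_xlabel(dims[0]); ax.set_ylabel(dims[1]); ax.set_zlabel(dims[2])
    ax.legend(fontsize=7)
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=150, bbox_inches="tight")
    plt.close(fig)
    payload = base64.b64encode(buf.getvalue()).decode("ascii")
    rows = "\n".join(
        f"[{scores.iloc[i, 0]:.4f},{scores.iloc[i, 1]:.4f},{scores.iloc[i, 2]:.4f},"
        f"\"{labels.astype(str).iloc[i]}\"]," for i in range(len(scores))
    )
    html = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>3D individual coordinates</title></head><body>"
        f"<img alt='3D PCA scatter' src='data:image/png;base64,{payload}'/>"
        f"<script>var coordinates=[\n{rows}\n];</script>"
        "</body></html>"
    )
    target = folder / "individualCoordinates_3D.html"
    target.write_text(html)
    return target
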