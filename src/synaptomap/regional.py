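"""Laminae-resolved aggregation: densities, sizes, heat maps, correlation.

Puncta (or classified synapses) are assigned to atlas regions by the
pixel containing their centroid, summarised per region into densities
(per 100 µm²) and mean areas, compared between cohorts as
percent-of-control heat-map tables, and related across regions by the
astrocytic-contact-fraction vs tripartite-loss correlation.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coloc import SynapseRecord
from .detection import PunctaSet
from .synthetic import RegionAtlas

__all__ = [
    "assign_region",
    "synapse_table",
    "compute_region_stats",
    "percent_difference",
    "contact_loss_correlation",
    "heatmap_figure",
]

_MEASURES = {
    "density": ("all", "density_per_100um2"),
    "mean_area": ("all", "mean_area_um2"),
    "tripartite_density": ("tripartite", "density_per_100um2"),
    "non_tripartite_density": ("non_tripartite", "density_per_100um2"),
}


def assign_region(puncta: PunctaSet, atlas: RegionAtlas) -> pd.DataFrame:
    """Label each punctum with the atlas region containing its centroid.

    The centroid is snapped to its nearest pixel and that pixel's label
    decides ownership (boundary pixels included).  Puncta whose centroid
    pixel carries no label are tagged ``outside``.
    """
    if puncta.label_image.shape != atlas.shape:
        raise ValueError(
            f"shape mismatch: puncta {puncta.label_image.shape} vs atlas {atlas.shape}"
        )
    df = puncta.to_dataframe()
    h, w = atlas.shape
    rows = np.clip(np.round(df["centroid_row"].to_numpy()).astype(int), 0, h - 1)
    cols = np.clip(np.round(df["centroid_col"].to_numpy()).astype(int), 0, w - 1)
    labels = atlas.label_image[rows, cols]
    names = np.array(["outside", *atlas.region_names], dtype=object)
    df["region"] = names[labels]
    return df


def synapse_table(
    records: Iterable[SynapseRecord], psd: PunctaSet, atlas: RegionAtlas
) -> pd.DataFrame:
    """Tidy per-synapse table: PSD geometry, region, and class."""
    labelled = assign_region(psd, atlas).set_index("id")
    rec = list(records)
    df = pd.DataFrame(
        {
            "psd_id": [r.psd_id for r in rec],
            "synapse_class": [r.synapse_class for r in rec],
        }
    )
    for col in ("centroid_row", "centroid_col", "area_um2", "region"):
        df[col] = labelled.loc[df["psd_id"], col].to_numpy()
    return df


def compute_region_stats(
    labelled: pd.DataFrame,
    atlas: RegionAtlas,
    subject: str = "s1",
    genotype: str = "control",
    **metadata,
) -> pd.DataFrame:
    """Per-region counts, densities and mean areas for one subject.

    ``labelled`` must carry a ``region`` column (from :func:`assign_region`
    or :func:`synapse_table`) and optionally ``synapse_class``; with
    classes present, per-class rows are emitted alongside the ``all``
    rows.  Density is count per 100 µm² of region area.  Empty regions
    yield count 0, density 0 and a missing mean area.  Puncta labelled
    ``outside`` are excluded.
    """
    areas = atlas.region_area_um2()
    if not areas or all(a == 0 for a in areas.values()):
        raise ValueError("atlas has no labelled regions")
    inside = labelled[labelled["region"] != "outside"]
    classes = ["all"]
    if "synapse_class" in labelled.columns:
        classes += sorted(inside["synapse_class"].unique())
    rows = []
    for region in atlas.region_names:
        area = areas[region]
        in_region = inside[inside["region"] == region]
        for cls in classes:
            sub = in_region if cls == "all" else in_region[
                in_region["synapse_class"] == cls
            ]
            n = len(sub)
            rows.append(
                {
                    "subject": subject,
                    "genotype": genotype,
                    **metadata,
                    "region": region,
                    "synapse_class": cls,
                    "n": n,
                    "region_area_um2": area,
                    "density_per_100um2": (n / area * 100.0) if area > 0 else 0.0,
                    "mean_area_um2": float(sub["area_um2"].mean())
                    if n and "area_um2" in sub.columns
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _subject_means(
    stats: pd.DataFrame, synapse_class: str, column: str
) -> pd.DataFrame:
    """One value per (subject, region): the subject's regional measure."""
    sub = stats[stats["synapse_class"] == synapse_class]
    if sub.empty:
        raise ValueError(f"no rows with synapse_class={synapse_class!r}")
    return (
        sub.groupby(["subject", "region"], sort=False)[column]
        .mean()
        .reset_index()
    )


def percent_difference(
    case_stats: pd.DataFrame,
    control_stats: pd.DataFrame,
    measure: str = "density",
) -> pd.DataFrame:
    """Per-region case-vs-control percent difference (heat-map table).

    For each region: (mean over case subjects − mean over control
    subjects) / control mean × 100, on subject-level regional values.
    Regions with control mean 0 are reported as NaN.
    """
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}; one of {sorted(_MEASURES)}")
    cls, column = _MEASURES[measure]
    case = _subject_means(case_stats, cls, column).groupby("region", sort=False)[column].mean()
    control = (
        _subject_means(control_stats, cls, column)
        .groupby("region", sort=False)[column]
        .mean()
    )
    regions = [r for r in control.index]
    rows = []
    for region in regions:
        c = control.get(region, np.nan)
        k = case.get(region, np.nan)
        pct = (k - c) / c * 100.0 if c and np.isfinite(c) and c != 0 else np.nan
        rows.append(
            {
                "region": region,
                "measure": measure,
                "control_mean": c,
                "case_mean": k,
                "percent_difference": pct,
            }
        )
    return pd.DataFrame(rows)


def contact_loss_correlation(
    case_stats: pd.DataFrame, control_stats: pd.DataFrame
) -> tuple[float, float, pd.DataFrame]:
    """Correlate astrocytic contact fraction with tripartite loss across regions.

    x: control per-region percentage of synapses classified tripartite
    (mean over control subjects of the per-subject percentage).
    y: per-region percent difference in tripartite density, case vs
    control (signed; losses are negative).

    Returns (Pearson r, two-sided p, per-region table).  Requires >= 3
    regions with defined values and non-constant x.
    """
    tri = _subject_means(control_stats, "tripartite", "n").rename(columns={"n": "n_tri"})
    tot = _subject_means(control_stats, "all", "n").rename(columns={"n": "n_all"})
    merged = tri.merge(tot, on=["subject", "region"])
    merged = merged[merged["n_all"] > 0]
    merged["pct_contacted"] = merged["n_tri"] / merged["n_all"] * 100.0
    x = merged.groupby("region", sort=False)["pct_contacted"].mean()
    loss = percent_difference(case_stats, control_stats, "tripartite_density")
    table = loss.merge(
        x.rename("pct_synapses_contacted").reset_index(), on="region", how="inner"
    ).dropna(subset=["percent_difference", "pct_synapses_contacted"])
    if len(table) < 3:
        raise ValueError("need >= 3 regions with defined values for correlation")
    xv = table["pct_synapses_contacted"].to_numpy()
    yv = table["percent_difference"].to_numpy()
    if np.allclose(xv, xv[0]):
        raise ValueError("contact fraction is constant across regions; r undefined")
    r, p = sps.pearsonr(xv, yv)
    return float(r), float(p), table


def heatmap_figure(tables: dict[str, pd.DataFrame], vmax: float = 100.0):
    """Render percent-of-control heat maps (one column per measure).

    ``tables`` maps measure names to :func:`percent_difference` outputs.
    Returns a matplotlib figure; the caller saves it (PNG/SVG).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    measures = list(tables)
    regions = list(tables[measures[0]]["region"])
    data = np.column_stack(
        [tables[m]["percent_difference"].to_numpy() for m in measures]
    )
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(measures), 0.45 * len(regions) + 1.2))
    im = ax.imshow(data, cmap="coolwarm_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_yticks(range(len(regions)), regions)
    ax.set_xticks(range(len(measures)), measures, rotation=30, ha="right")
    for i in range(len(regions)):
        for j in range(len(measures)):
            if np.isfinite(data[i, j]):
                ax.text(j, i, f"{data[i, j]:+.0f}%", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="% of control")
    fig.tight_layout()
    return fig
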