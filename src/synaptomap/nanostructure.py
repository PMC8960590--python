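"""Paired confocal / g-STED nanostructural analysis.

Objects resolved in the STED frame are PSD95 nanoclusters (NCs); the
larger diffraction-limited objects in the co-registered confocal frame
are whole PSDs.  NCs are assigned to PSDs, and synapses are subtyped by
their NC count (1, 2, 3+).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import PunctaSet

__all__ = [
    "NanoAssignment",
    "SubtypeDistribution",
    "assign_nanoclusters",
    "nc_metrics",
    "subtype_distribution",
]


@dataclass
class NanoAssignment:
    """Mapping of STED-resolved NCs onto confocal-resolved PSDs.

    Each NC belongs to at most one PSD; NCs matching no PSD are orphans.
    """

    nc_by_psd: dict[int, list[int]]
    orphan_nc_ids: list[int]
    nc_diameter_nm: dict[int, float]
    psd_ids: list[int] = field(default_factory=list)

    def nc_count(self, psd_id: int) -> int:
        return len(self.nc_by_psd.get(psd_id, []))

    @property
    def assigned_nc_ids(self) -> list[int]:
        return [nc for ncs in self.nc_by_psd.values() for nc in ncs]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for psd_id, ncs in self.nc_by_psd.items():
            for nc in ncs:
                rows.append(
                    {"nc_id": nc, "psd_id": psd_id, "diameter_nm": self.nc_diameter_nm[nc]}
                )
        for nc in self.orphan_nc_ids:
            rows.append(
                {"nc_id": nc, "psd_id": -1, "diameter_nm": self.nc_diameter_nm[nc]}
            )
        return pd.DataFrame(rows, columns=["nc_id", "psd_id", "diameter_nm"])


@dataclass(frozen=True)
class SubtypeDistribution:
    """Synapse subtypes by NC count: classes 1, 2 and 3+."""

    counts: dict[str, int]  # keys "1", "2", "3+"
    frequencies: dict[str, float]
    mean_nc_per_psd: float
    n_psd_with_nc: int
    n_psd_without_nc: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequencies)


def assign_nanoclusters(psd_set: PunctaSet, nc_set: PunctaSet) -> NanoAssignment:
    """Assign each NC to a PSD: centroid containment, then maximal overlap.

    An NC whose centroid pixel lies inside a PSD mask belongs to that PSD.
    Failing that, if its mask overlaps one or more PSDs it goes to the PSD
    with the largest shared-pixel count (ties broken by nearer PSD
    centroid, then lower PSD id).  NCs touching no PSD are orphans.
    """
    if psd_set.label_image.shape != nc_set.label_image.shape:
        raise ValueError(
            f"shape mismatch: PSD {psd_set.label_image.shape} vs NC {nc_set.label_image.shape}"
        )
    psd_labels = psd_set.label_image
    psd_centroids = {p.id: np.asarray(p.centroid_px) for p in psd_set.puncta}
    nc_by_psd: dict[int, list[int]] = {p.id: [] for p in psd_set.puncta}
    orphans: list[int] = []
    diameters: dict[int, float] = {}
    for nc in nc_set.puncta:
        diameters[nc.id] = nc.equivalent_diameter_nm
        r = int(round(nc.centroid_px[0]))
        c = int(round(nc.centroid_px[1]))
        r = min(max(r, 0), psd_labels.shape[0] - 1)
        c = min(max(c, 0), psd_labels.shape[1] - 1)
        owner = int(psd_labels[r, c])
        if owner == 0:
            overlap_ids = psd_labels[nc.coords[:, 0], nc.coords[:, 1]]
            overlap_ids = overlap_ids[overlap_ids > 0]
            if overlap_ids.size:
                ids, counts = np.unique(overlap_ids, return_counts=True)
                best = counts.max()
                candidates = ids[counts == best]
                if len(candidates) > 1:
                    nc_centroid = np.asarray(nc.centroid_px)
                    dists = np.array(
                        [
                            np.linalg.norm(psd_centroids[int(i)] - nc_centroid)
                            for i in candidates
                        ]
                    )
                    candidates = candidates[dists == dists.min()]
                owner = int(candidates.min())
        if owner:
            nc_by_psd[owner].append(nc.id)
        else:
            orphans.append(nc.id)
    return NanoAssignment(
        nc_by_psd=nc_by_psd,
        orphan_nc_ids=orphans,
        nc_diameter_nm=diameters,
        psd_ids=[p.id for p in psd_set.puncta],
    )


def nc_metrics(assignment: NanoAssignment) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-NC diameters and per-PSD summaries.

    NC equivalent circular diameter is 2·sqrt(area/π) (already attached at
    detection time).  The per-PSD table reports NC count and mean NC
    diameter for every PSD, including those with zero assigned NCs.
    """
    nc_table = assignment.to_dataframe()
    rows = []
    for psd_id in assignment.psd_ids:
        ncs = assignment.nc_by_psd.get(psd_id, [])
        rows.append(
            {
                "psd_id": psd_id,
                "nc_count": len(ncs),
                "mean_nc_diameter_nm": float(
                    np.mean([assignment.nc_diameter_nm[n] for n in ncs])
                )
                if ncs
                else np.nan,
            }
        )
    return nc_table, pd.DataFrame(rows, columns=["psd_id", "nc_count", "mean_nc_diameter_nm"])


def subtype_distribution(assignment: NanoAssignment) -> SubtypeDistribution:
    """Bin PSDs into 1 / 2 / 3+ NC subtypes.

    Frequencies are over PSDs carrying at least one NC; PSDs with no
    assigned NC are excluded and reported separately (their NC content is
    below the detection floor, not zero by definition).
    """
    counts_per_psd = [len(v) for v in assignment.nc_by_psd.values()]
    with_nc = [c for c in counts_per_psd if c > 0]
    n_zero = len(counts_per_psd) - len(with_nc)
    if not with_nc:
        raise ValueError("no PSD has an assigned nanocluster")
    counts = {
        "1": sum(1 for c in with_nc if c == 1),
        "2": sum(1 for c in with_nc if c == 2),
        "3+": sum(1 for c in with_nc if c >= 3),
    }
    n = len(with_nc)
    return SubtypeDistribution(
        counts=counts,
        frequencies={k: v / n for k, v in counts.items()},
        mean_nc_per_psd=float(np.mean(with_nc)),
        n_psd_with_nc=n,
        n_psd_without_nc=n_zero,
    )
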