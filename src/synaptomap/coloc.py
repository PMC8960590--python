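"""Object-based colocalisation and tripartite-synapse classification.

Colocalisation between channels is decided on binarised punctum masks
with the criterion of overlap by at least one pixel.  A PSD punctum that
overlaps a presynaptic punctum is a synapse; a synapse whose PSD also
overlaps a perisynaptic-astrocyte (PAP) punctum is a tripartite synapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .detection import PunctaSet

__all__ = ["OverlapPair", "SynapseRecord", "overlap_map", "classify_synapses"]


@dataclass(frozen=True)
class OverlapPair:
    """A pair of puncta (one per channel) sharing >= 1 pixel."""

    id_a: int
    id_b: int
    overlap_px: int


@dataclass(frozen=True)
class SynapseRecord:
    """Classification of one PSD punctum."""

    psd_id: int
    matched_presyn_ids: tuple[int, ...]
    matched_pap_ids: tuple[int, ...]
    synapse_class: str  # "tripartite" | "non_tripartite"
    mode: str  # "triple" | "psd_pap"
    pap_marker: str = "pap"

    @property
    def is_tripartite(self) -> bool:
        return self.synapse_class == "tripartite"


def _check_shapes(a: PunctaSet, b: PunctaSet) -> None:
    if a.label_image.shape != b.label_image.shape:
        raise ValueError(
            f"image shape mismatch: {a.label_image.shape} vs {b.label_image.shape}"
        )
    if not np.isclose(a.pixel_size_nm, b.pixel_size_nm):
        raise ValueError("pixel size mismatch between punctum sets")


def overlap_map(a: PunctaSet, b: PunctaSet) -> list[OverlapPair]:
    """Every (a, b) punctum pair whose masks share at least one pixel.

    Symmetric up to swapping the id roles: the same pairs are found from
    either argument order.
    """
    _check_shapes(a, b)
    both = (a.label_image > 0) & (b.label_image > 0)
    if not both.any():
        return []
    ids_a = a.label_image[both].astype(np.int64)
    ids_b = b.label_image[both].astype(np.int64)
    key = ids_a * (b.label_image.max() + 1) + ids_b
    uniq, counts = np.unique(key, return_counts=True)
    base = b.label_image.max() + 1
    return [
        OverlapPair(id_a=int(k // base), id_b=int(k % base), overlap_px=int(c))
        for k, c in zip(uniq, counts)
    ]


def classify_synapses(
    psd: PunctaSet,
    presyn: Optional[PunctaSet],
    pap: PunctaSet,
    mode: str = "triple",
    pap_marker: str = "pap",
    either_partner: bool = False,
) -> list[SynapseRecord]:
    """Classify PSD puncta as tripartite / non-tripartite synapses.

    ``triple`` mode requires a presynaptic channel: only PSDs overlapping
    at least one presynaptic punctum count as synapses, and among those,
    PAP overlap decides the class.  ``psd_pap`` mode treats every PSD as a
    synapse and classifies by PAP overlap alone (the two-channel analysis
    used for e.g. human tissue or enzyme-expression counting).

    With ``either_partner`` (triple mode only) a PAP punctum overlapping
    the synapse's presynaptic punctum also confers tripartite status, not
    just PAP-PSD overlap.
    """
    if mode not in ("triple", "psd_pap"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "triple" and presyn is None:
        raise ValueError("triple mode requires a presynaptic PunctaSet")
    psd_pap_pairs = overlap_map(psd, pap)
    pap_by_psd: dict[int, list[int]] = {}
    for pair in psd_pap_pairs:
        pap_by_psd.setdefault(pair.id_a, []).append(pair.id_b)

    if mode == "psd_pap":
        records = []
        for p in psd.puncta:
            paps = tuple(sorted(pap_by_psd.get(p.id, [])))
            records.append(
                SynapseRecord(
                    psd_id=p.id,
                    matched_presyn_ids=(),
                    matched_pap_ids=paps,
                    synapse_class="tripartite" if paps else "non_tripartite",
                    mode=mode,
                    pap_marker=pap_marker,
                )
            )
        return records

    assert presyn is not None
    presyn_by_psd: dict[int, list[int]] = {}
    for pair in overlap_map(psd, presyn):
        presyn_by_psd.setdefault(pair.id_a, []).append(pair.id_b)
    pap_by_presyn: dict[int, list[int]] = {}
    if either_partner:
        for pair in overlap_map(presyn, pap):
            pap_by_presyn.setdefault(pair.id_a, []).append(pair.id_b)

    records = []
    for p in psd.puncta:
        presyns = tuple(sorted(presyn_by_psd.get(p.id, [])))
        if not presyns:
            continue  # not a synapse: no presynaptic partner
        paps = set(pap_by_psd.get(p.id, []))
        if either_partner:
            for v in presyns:
                paps.update(pap_by_presyn.get(v, []))
        paps_t = tuple(sorted(paps))
        records.append(
            SynapseRecord(
                psd_id=p.id,
                matched_presyn_ids=presyns,
                matched_pap_ids=paps_t,
                synapse_class="tripartite" if paps_t else "non_tripartite",
                mode=mode,
                pap_marker=pap_marker,
            )
        )
    return records


def records_to_dataframe(records: list[SynapseRecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "psd_id": [r.psd_id for r in records],
            "synapse_class": [r.synapse_class for r in records],
            "n_presyn": [len(r.matched_presyn_ids) for r in records],
            "n_pap": [len(r.matched_pap_ids) for r in records],
            "mode": [r.mode for r in records],
            "pap_marker": [r.pap_marker for r in records],
        }
    )


def class_counts(records: list[SynapseRecord]) -> dict[str, int]:
    """Counts per class; tripartite + non_tripartite always equals total."""
    tri = sum(r.is_tripartite for r in records)
    return {
        "tripartite": tri,
        "non_tripartite": len(records) - tri,
        "synapses": len(records),
    }
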