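"""Nuclear-shape morphometry: deformation classes, bleb frequency, CTCF.

A nuclear *bleb* is a herniation still 4-connected to the nuclear body; a
*micronucleus* is a detached object of similar size to blebs; a *rupture* is
a nucleus no longer intact (accepted from upstream labels — the criterion is
visual, not derivable from a mask). Per-field-of-view bleb percentages with
condition-level mean ± s.e.m. follow the replicate structure of
immunofluorescence counting, and corrected total cell fluorescence (CTCF)
uses the standard background-subtracted integrated density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "DeformationRecord",
    "classify_deformations",
    "bleb_frequency",
    "ctcf",
]

_FOUR_CONN = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]


@dataclass
class DeformationRecord:
    """Classification of one cell's nuclear deformations."""

    cell_id: str = ""
    fov_id: str = ""
    condition: str = ""
    deformation_class: str = "intact"   # intact | blebbed | micronucleated | ruptured
    n_blebs: int = 0
    n_micronuclei: int = 0
    bleb_areas: list = field(default_factory=list)       # px
    micronucleus_areas: list = field(default_factory=list)
    micronucleated: bool = False        # may co-occur with blebbed
    ruptured: bool = False


def classify_deformations(label_image, cell_id: str = "", fov_id: str = "",
                          condition: str = "", ruptured: bool = False,
                          micronucleus_size_window: tuple = (0.25, 4.0),
                          reference_bleb_area: float | None = None
                          ) -> DeformationRecord:
    """Classify one cell's labeled mask into deformation classes.

    Positive non-body components 4-connected to the body (label 1) count as
    blebs; disconnected objects (any non-body label, including negative
    micronucleus codes) count as micronuclei when their area falls within
    ``micronucleus_size_window`` times the median bleb area (falling back to
    ``reference_bleb_area``, or accepting any size when neither is
    available). Rupture is taken from the upstream flag only.
    """
    if hasattr(label_image, "label_image"):
        label_image = label_image.label_image
    label_image = np.asarray(label_image)
    if label_image.size == 0 or not (label_image != 0).any():
        raise ValueError("empty label image")
    body = label_image == 1
    if not body.any():
        raise ValueError("no nuclear body (label 1) present")
    rec = DeformationRecord(cell_id=cell_id, fov_id=fov_id,
                            condition=condition, ruptured=bool(ruptured))
    other = (label_image != 0) & ~body
    comp, n_comp = ndimage.label(other, structure=_FOUR_CONN)
    detached_areas = []
    for c in range(1, n_comp + 1):
        m = comp == c
        area = int(m.sum())
        touches_body = (ndimage.binary_dilation(m, structure=_FOUR_CONN)
                        & body).any()
        if touches_body:
            rec.n_blebs += 1
            rec.bleb_areas.append(area)
        else:
            detached_areas.append(area)
    ref = (float(np.median(rec.bleb_areas)) if rec.bleb_areas
           else reference_bleb_area)
    lo, hi = micronucleus_size_window
    for area in detached_areas:
        if ref is None or lo * ref <= area <= hi * ref:
            rec.n_micronuclei += 1
            rec.micronucleus_areas.append(area)
    rec.micronucleated = rec.n_micronuclei > 0
    if rec.ruptured:
        rec.deformation_class = "ruptured"
    elif rec.n_blebs > 0:
        rec.deformation_class = "blebbed"
    elif rec.micronucleated:
        rec.deformation_class = "micronucleated"
    else:
        rec.deformation_class = "intact"
    return rec


def bleb_frequency(records: list[DeformationRecord] | pd.DataFrame
                   ) -> pd.DataFrame:
    """Per-FOV bleb percentages and condition mean ± s.e.m. over FOVs.

    Each field of view contributes ``100 * blebbed / nuclei``; the condition
    summary treats FOVs as replicates (the dots of a per-FOV scatter). FOVs
    with zero nuclei are excluded (noted in the ``excluded_fovs`` attribute
    of the returned frame).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            [{"fov_id": r.fov_id, "condition": r.condition,
              "blebbed": r.deformation_class == "blebbed"} for r in records])
    if df.empty:
        raise ValueError("no records supplied")
    per_fov = (df.groupby(["condition", "fov_id"])
               .agg(n_nuclei=("blebbed", "size"), n_blebbed=("blebbed", "sum"))
               .reset_index())
    excluded = per_fov.loc[per_fov.n_nuclei == 0, "fov_id"].tolist()
    per_fov = per_fov[per_fov.n_nuclei > 0].copy()
    per_fov["pct_blebbed"] = 100.0 * per_fov.n_blebbed / per_fov.n_nuclei
    summary = (per_fov.groupby("condition")["pct_blebbed"]
               .agg(mean="mean",
                    sem=lambda v: (v.std(ddof=1) / np.sqrt(len(v))
                                   if len(v) > 1 else np.nan),
                    n_fov="size")
               .reset_index())
    out = per_fov.merge(summary, on="condition", suffixes=("", "_condition"))
    out.attrs["excluded_fovs"] = excluded
    out.attrs["condition_summary"] = summary
    return out


def ctcf(image, cell_mask, background_mask) -> float:
    """Corrected total cell fluorescence.

    ``CTCF = integrated density over the cell - area(cell) * mean(background)``.
    """
    image = np.asarray(image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if (cell_mask & background_mask).any():
        raise ValueError("cell and background masks must be disjoint")
    if not background_mask.any():
        raise ValueError("empty background region")
    integrated = float(image[cell_mask].sum())
    return integrated - cell_mask.sum() * float(image[background_mask].mean())
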