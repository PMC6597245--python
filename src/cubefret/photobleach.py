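"""Acceptor-photobleaching FRET quantification.

Destroying the acceptor (YFP) releases donor (CFP) quenching, so donor
intensity rises in bleached cells if FRET was present.  This module assigns
cells to bleached/control groups from the bleach-region ROI (the closed
field diaphragm), checks bleach depth (acceptor must fall below 10% of its
initial intensity), computes the percentage change of donor intensity, and
compares groups.

ROI intensities are taken from background-subtracted, *non-blurred* images:
the bleaching assay reads wide-field intensities directly rather than the
map-processing chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ParameterError, StatisticsError
from .imageops import roi_reduce
from .io_core import RoiSet
from . import timecourse_stats

log = logging.getLogger(__name__)


@dataclass
class BleachResult:
    """Donor/acceptor ROI means before and after acceptor bleaching."""

    cell_id: str
    group: str                      # "bleached" | "control"
    cfp_before: float
    cfp_after: float
    yfp_before: float
    yfp_after: float

    @property
    def delta_cfp_pct(self) -> float:
        return delta_cfp(self.cfp_before, self.cfp_after)

    @property
    def bleach_depth(self) -> float:
        return 1.0 - self.yfp_after / self.yfp_before


def assign_groups(rois: RoiSet, overlap_bleached: float = 0.8,
                  overlap_control: float = 0.05) -> dict:
    """Group each cell ROI by overlap with the single bleach-region ROI.

    A cell is "bleached" if at least ``overlap_bleached`` of its pixels lie
    inside the bleach region, "control" if at most ``overlap_control``;
    intermediate (straddling) cells are excluded with a log entry.

    Returns ``{roi_id: "bleached" | "control"}``.
    """
    regions = rois.of_kind("bleach_region")
    if len(regions) != 1:
        raise ConfigurationError(
            f"need exactly one bleach_region ROI, found {len(regions)}")
    region = regions[0].mask
    groups = {}
    for cell in rois.of_kind("cell"):
        frac = float((cell.mask & region).sum() / max(cell.mask.sum(), 1))
        if frac >= overlap_bleached:
            groups[cell.roi_id] = "bleached"
        elif frac <= overlap_control:
            groups[cell.roi_id] = "control"
        else:
            log.info("cell %s straddles the bleach region (%.0f%%); excluded",
                     cell.roi_id, 100 * frac)
    return groups


def bleach_qc(yfp_before: float, yfp_after: float, ceiling: float = 0.10,
              group: str = "bleached") -> bool:
    """Bleach-depth quality control: acceptor must fall below the ceiling.

    Pass iff ``yfp_after / yfp_before < ceiling`` (strict, per the "below
    10%" criterion) for bleached cells; control cells are exempt.
    """
    if yfp_before <= 0:
        raise ParameterError("yfp_before must be positive")
    if group == "control":
        return True
    return yfp_after / yfp_before < ceiling


def delta_cfp(cfp_before: float, cfp_after: float) -> float:
    """Percentage change of donor intensity, ``100*(after-before)/before``."""
    if cfp_before <= 0:
        raise ParameterError("cfp_before must be positive")
    return 100.0 * (cfp_after - cfp_before) / cfp_before


def measure_bleach(pre_stack, post_stack, rois: RoiSet, groups: dict,
                   background_level: float = 0.0) -> list:
    """Per-cell before/after ROI means from pre/post three-cube stacks.

    CFP is the donor channel (I_DD), YFP the acceptor channel (I_AA);
    intensities are background-subtracted (constant offset) with no blurring.
    """
    out = []
    pre_dd = np.clip(pre_stack.i_dd[0] - background_level, 0, None)
    post_dd = np.clip(post_stack.i_dd[0] - background_level, 0, None)
    pre_aa = np.clip(pre_stack.i_aa[0] - background_level, 0, None)
    post_aa = np.clip(post_stack.i_aa[0] - background_level, 0, None)
    for cell in rois.of_kind("cell"):
        if cell.roi_id not in groups:
            continue
        cfp_b, _ = roi_reduce(pre_dd, cell.mask)
        cfp_a, _ = roi_reduce(post_dd, cell.mask)
        yfp_b, _ = roi_reduce(pre_aa, cell.mask)
        yfp_a, _ = roi_reduce(post_aa, cell.mask)
        out.append(BleachResult(cell_id=cell.roi_id, group=groups[cell.roi_id],
                                cfp_before=cfp_b, cfp_after=cfp_a,
                                yfp_before=yfp_b, yfp_after=yfp_a))
    return out


def bleach_compare(results) -> dict:
    """Group means +/- s.e.m. of delta-CFP and a two-tailed unpaired t-test.

    Requires at least two cells per group; the significance label follows the
    standard convention (n.s., *, **, ***).
    """
    bleached = [r.delta_cfp_pct for r in results if r.group == "bleached"]
    control = [r.delta_cfp_pct for r in results if r.group == "control"]
    if len(bleached) < 2 or len(control) < 2:
        raise StatisticsError("need >= 2 cells per group for comparison")
    t, df, p, label = timecourse_stats.two_tailed_t(bleached, control,
                                                    paired=False)
    def summ(v):
        v = np.asarray(v, dtype=float)
        return {"mean": float(v.mean()),
                "sem": float(v.std(ddof=1) / np.sqrt(len(v))),
                "n": int(len(v))}
    return {"bleached": summ(bleached), "control": summ(control),
            "t": t, "df": df, "p": p, "label": label}
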