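"""Cross-population transfer of segment-wise mixture-occupancy counts.

A source population's fitted chain yields, per genome segment, the posterior
mean number of markers assigned to each of the four effect distributions.
Scaled by a weight factor, these counts become the Dirichlet parameters
alpha_s of the target population's segment-specific priors. Because the
counts sum to the number of markers, an unscaled prior carries as much
weight as the target data themselves; the conventional weight sweep is
{0.2, 0.4, 0.6, 0.8, 1.0, 1.25, 1.5}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MarkerMap
from .segments import SegmentPartition, partition

__all__ = [
    "DirichletPriorTable",
    "SCALE_SWEEP",
    "extract_counts",
    "make_prior",
    "align_prior",
]

SCALE_SWEEP = (0.2, 0.4, 0.6, 0.8, 1.0, 1.25, 1.5)

#: floor keeping Dirichlet parameters strictly positive when a component's
#: posterior count is exactly zero; negligible against segment sizes >= 100
EPSILON = 1e-3


@dataclass
class DirichletPriorTable:
    """Per-segment Dirichlet parameters alpha_s with their provenance."""

    alphas: np.ndarray            # (S, 4), strictly positive
    coords: pd.DataFrame          # chrom, start_bp, end_bp per segment
    scale: float = 1.0
    provenance: dict = field(default_factory=dict)
    marker_ids: tuple | None = None
    segment_size: object | None = None

    def __post_init__(self):
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.alphas.ndim != 2 or self.alphas.shape[1] != 4:
            raise ValueError("alphas must be an (S, 4) matrix")
        if np.any(self.alphas <= 0):
            raise ValueError("Dirichlet parameters must be strictly positive")
        if len(self.coords) != self.alphas.shape[0]:
            raise ValueError("coords rows do not match alpha rows")
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def n_segments(self) -> int:
        return self.alphas.shape[0]


def extract_counts(summary) -> DirichletPriorTable:
    """Raw posterior occupancy counts per reporting segment of a fitted chain.

    Each row is the posterior mean, over kept sweeps, of the number of
    markers in that segment assigned to each mixture component; rows sum to
    the segment's marker count.
    """
    counts = getattr(summary, "seg_counts", None)
    part = getattr(summary, "report_partition", None)
    if counts is None or part is None:
        raise ValueError("summary lacks per-segment occupancy counts")
    sizes = part.sizes()
    if not np.allclose(counts.sum(axis=1), sizes, atol=1e-9):
        raise ValueError(
            "occupancy counts do not sum to segment sizes; summary was built "
            "on a different reporting partition"
        )
    cfg = summary.config
    return DirichletPriorTable(
        alphas=np.maximum(counts, EPSILON),
        coords=part.coords(),
        scale=1.0,
        provenance={
            "seed": cfg.seed,
            "n_iter": cfg.n_iter,
            "burn_in": cfg.burn_in,
            "sigma_g2": summary.sigma_g2,
            "kind": "raw_counts",
        },
        marker_ids=tuple(summary.map.marker_id),
        segment_size=part.segment_size,
    )


def make_prior(counts: DirichletPriorTable, scale: float,
               add_uniform: bool = False) -> DirichletPriorTable:
    """Scale raw occupancy counts into a transferable Dirichlet prior table.

    ``alpha_s = max(scale * count_s, EPSILON)`` per component. The uniform
    pseudo-count (1,1,1,1) is *not* added by default — the scaled counts are
    themselves the prior parameters; ``add_uniform`` exists for sensitivity
    analysis.
    """
    if not scale > 0:
        raise ValueError("scale must be positive")
    alphas = np.maximum(scale * counts.alphas, EPSILON)
    if add_uniform:
        alphas = alphas + 1.0
    prov = dict(counts.provenance)
    prov["kind"] = "scaled_prior"
    prov["add_uniform"] = add_uniform
    return DirichletPriorTable(
        alphas=alphas,
        coords=counts.coords.copy(),
        scale=float(scale) * counts.scale,
        provenance=prov,
        marker_ids=counts.marker_ids,
        segment_size=counts.segment_size,
    )


def align_prior(prior: DirichletPriorTable, target_map: MarkerMap,
                segment_size) -> tuple[DirichletPriorTable, SegmentPartition]:
    """Bind a prior table to a target panel, verifying the panels agree.

    The prior's segment layout is only meaningful when the target carries
    the identical marker panel in the identical order (segments are defined
    by marker order). When the prior records its marker ids, identity is
    checked id by id; a prior loaded from a bare count file is checked on
    segment count and coordinates instead. Any mismatch is an error telling
    the user to intersect the panels first.
    """
    part = partition(target_map, segment_size)
    if prior.segment_size is not None and prior.segment_size != segment_size:
        raise ValueError(
            f"prior was built with segment_size={prior.segment_size}, "
            f"requested {segment_size}"
        )
    if prior.marker_ids is not None:
        target_ids = tuple(target_map.marker_id)
        if target_ids != prior.marker_ids:
            raise ValueError(
                "marker panels differ between prior source and target "
                "(ids or order); run intersect_markers on both populations first"
            )
    if prior.n_segments != part.n_segments:
        raise ValueError(
            f"prior has {prior.n_segments} segments but the target partition "
            f"has {part.n_segments}; run intersect_markers first"
        )
    if prior.marker_ids is None:
        tc = part.coords()
        pc = prior.coords.reset_index(drop=True)
        same = (
            list(tc["chrom"].astype(str)) == list(pc["chrom"].astype(str))
            and list(tc["start_bp"].astype(int)) == list(pc["start_bp"].astype(int))
            and list(tc["end_bp"].astype(int)) == list(pc["end_bp"].astype(int))
        )
        if not same:
            raise ValueError(
                "prior segment coordinates do not match the target partition; "
                "run intersect_markers first"
            )
    return (
        DirichletPriorTable(
            alphas=prior.alphas.copy(),
            coords=part.coords(),
            scale=prior.scale,
            provenance=dict(prior.provenance),
            marker_ids=tuple(target_map.marker_id),
            segment_size=segment_size,
        ),
        part,
    )
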