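"""Convenience compositions of the pipeline stages.

These are the in-memory equivalents of chaining the CLI stages: track
every protocol of a phantom brain, build its tract matrix on the 2 mm
coarse grid, run surface-seeded tractography and assemble the
connectivity blueprint.
"""

from __future__ import annotations

import dataclasses

from .blueprints import ConnectivityBlueprint, TractMatrix, build_blueprint, \
    build_tract_matrix
from .imaging import downsample_mask
from .phantom import PhantomBrain
from .tracking import TrackingConfig, run_protocol_tractography, \
    run_surface_seeded_tractography
from .tract_metrics import NormalisedPathDistribution, normalise

__all__ = ["track_all_protocols", "blueprint_of_brain"]


def track_all_protocols(
    brain: PhantomBrain, config: TrackingConfig
) -> list[NormalisedPathDistribution]:
    """Protocol tractography for every tract, normalised by n_valid."""
    out = []
    for p in brain.protocols.protocols:
        pd_ = run_protocol_tractography(brain.field, p.rois,
                                        brain.brain_mask, config)
        out.append(normalise(pd_, tract=p.name,
                             template=brain.protocols.template))
    return out


def blueprint_of_brain(
    brain: PhantomBrain,
    config: TrackingConfig,
    seed: int | None = None,
    coarse_mm: float = 2.0,
) -> tuple[ConnectivityBlueprint, TractMatrix]:
    """Full blueprint for one brain (optionally overriding the seed)."""
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    coarse = downsample_mask(brain.brain_mask, coarse_mm)
    npds = track_all_protocols(brain, config)
    tm = build_tract_matrix(npds, coarse)
    conn = run_surface_seeded_tractography(
        brain.field, brain.surface, brain.brain_mask, coarse, config)
    return build_blueprint(conn, tm), tm
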