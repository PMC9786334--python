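"""Composed operations: count one image, or simulate and analyze a study.

These are the exact compositions the command line exposes, so CLI results are
reproducible through the API with the same :class:`~gelmaquant.config.RunConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .segmentation import (
    BinaryMask,
    LabelMap,
    binarize_channel,
    drop_border_labels,
    split_nuclei,
)
from .synthetic import ChannelStack, SceneSpec, generate_micrograph
from .viability import (
    GroupStats,
    NucleusRecord,
    ViabilityResult,
    aggregate_condition,
    classify_nuclei,
    compute_viability,
)

__all__ = ["CountResult", "count_image", "records_frame", "simulate_viability_study"]


@dataclass
class CountResult:
    """Everything produced by counting one image."""

    labels: LabelMap
    masks: dict[str, BinaryMask]
    records: list[NucleusRecord]
    result: ViabilityResult

    @property
    def thresholds(self) -> dict[str, float | None]:
        return {role: mask.threshold for role, mask in self.masks.items()}


def count_image(stack: ChannelStack, config: RunConfig | None = None) -> CountResult:
    """Binarize, watershed, classify, and count one three-channel image."""
    cfg = config or RunConfig()
    channels = {"nuclei": stack.blue, "viable": stack.green, "dead": stack.red}
    masks = {
        role: binarize_channel(
            channel,
            role=role,
            min_object_area=cfg.effective_min_object_area,
            threshold_override=cfg.threshold_override.get(role),
            connectivity=cfg.connectivity,
        )
        for role, channel in channels.items()
    }
    labels = split_nuclei(
        masks["nuclei"],
        min_seed_distance=cfg.effective_min_seed_distance,
        h=cfg.h_maxima,
        connectivity=cfg.connectivity,
    )
    if cfg.exclude_border:
        labels = drop_border_labels(labels)
    records = classify_nuclei(
        labels,
        masks["viable"],
        masks["dead"],
        overlap_threshold=cfg.overlap_threshold,
        mode=cfg.classify_mode,
    )
    return CountResult(labels, masks, records, compute_viability(records))


def records_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    """Nucleus records as a table (one row per segmented nucleus)."""
    return pd.DataFrame(
        {
            "label": [r.label for r in records],
            "row": [r.centroid[0] for r in records],
            "col": [r.centroid[1] for r in records],
            "area_px": [r.area for r in records],
            "overlap_green": [r.overlap_green for r in records],
            "overlap_red": [r.overlap_red for r in records],
            "klass": [r.klass for r in records],
        }
    )


def simulate_viability_study(
    true_viabilities: dict[str, float],
    n_replicates: int = 3,
    cells_per_replicate: int = 500,
    image_shape: tuple[int, int] = (640, 640),
    seed: int = 0,
    bernoulli: bool = True,
    alpha: float = 0.05,
    config: RunConfig | None = None,
    scene_kwargs: dict | None = None,
) -> GroupStats:
    """Simulate a multi-condition viability study through the full pipeline.

    For each condition (name -> true viability) and replicate, one scene of
    ``cells_per_replicate`` cells is rendered, counted, and classified; the
    replicate viabilities are then aggregated with Jarque–Bera screening and
    one-way ANOVA.  ``bernoulli=True`` draws each cell's viability
    independently, which models the biological sampling variation between
    replicates; the exact-count mode makes every replicate's ground truth
    identical instead.
    """
    rng = np.random.default_rng(seed)
    per_image: list[tuple[str, ViabilityResult]] = []
    grouping: dict[str, str] = {}
    extra = scene_kwargs or {}
    for cond, p in true_viabilities.items():
        for rep in range(n_replicates):
            spec = SceneSpec(
                image_shape=image_shape,
                n_cells=cells_per_replicate,
                true_viability=p,
                bernoulli_viability=bernoulli,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
                **extra,
            )
            stack, _ = generate_micrograph(spec)
            sample = f"{cond}-rep{rep + 1}"
            per_image.append((sample, count_image(stack, config).result))
            grouping[sample] = cond
    return aggregate_condition(per_image, grouping, alpha=alpha)
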