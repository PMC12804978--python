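"""Pipeline configuration.

A single flat parameter set drives every stage (wall preprocessing, spot
detection, parent search, reporting) so that the exact configuration of a run
can be serialized verbatim into ``analysis.json`` and replayed bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis pipeline.

    Attributes
    ----------
    pixel_size_override:
        µm per pixel; overrides image metadata when set.
    wall_smoothing_sigma:
        Gaussian sigma (px) applied to the wall channel before thresholding.
    wall_threshold_method:
        ``"otsu"`` (automatic global threshold) or ``"fixed"``.
    wall_threshold_value:
        Threshold in intensity units; required when method is ``"fixed"``.
    wall_invert:
        Set when walls are dark on a bright background.
    prune_length_px:
        Skeleton spurs strictly shorter than this many pixels are removed.
    junction_merge_gap_px:
        Branch-pixel clusters joined by skeleton chains of at most this many
        pixels are merged into one junction (absorbs thinning artifacts at
        fat junctions; keep below the shortest real wall chain).
    puncta_smoothing_sigma:
        Gaussian sigma (px) applied to the puncta channel before detection.
    background_radius_px:
        Radius (px) of the rolling-background estimate subtracted before
        maxima detection; 0 disables subtraction.
    min_peak_intensity:
        Absolute detection threshold on the preprocessed puncta channel.
        ``None`` selects an automatic robust threshold
        (median + ``auto_threshold_k`` * sigma-from-MAD).
    auto_threshold_k:
        Multiplier for the automatic detection threshold.
    min_separation_px:
        Minimum distance between two retained maxima (brighter one wins).
    integration_radius_px:
        Disk radius (px) for integrated punctum intensity on the raw channel.
    parent_search_tolerance_um:
        Maximum punctum-to-wall distance (µm) for parent assignment; beyond
        it the punctum is an orphan.
    """

    pixel_size_override: Optional[float] = None

    # wall_network
    wall_smoothing_sigma: float = 1.0
    wall_threshold_method: str = "otsu"
    wall_threshold_value: Optional[float] = None
    wall_invert: bool = False
    prune_length_px: int = 5
    junction_merge_gap_px: int = 3

    # puncta_detect
    puncta_smoothing_sigma: float = 1.0
    background_radius_px: int = 15
    min_peak_intensity: Optional[float] = None
    auto_threshold_k: float = 5.0
    min_separation_px: float = 3.0
    integration_radius_px: int = 3

    # relational_graph
    parent_search_tolerance_um: float = 0.5

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build a config from a mapping; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a JSON config file."""
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
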