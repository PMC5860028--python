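"""Run configuration: every stage parameter in one validated record.

Defaults follow the protocol's published constants (0.5 Å fragment cluster
radius, top 25 fragments, top 250 poses per fragment, 3.5 Å pose cluster
radius, 4.0 Å acceptance threshold, 30% identity exclusion, 100-1000 library
window, 5-residue minimum motif length); grid and rotation parameters are
package policies.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ValidationError
from .fftdock import WEIGHT_SETS, WeightSet


@dataclass
class RunConfig:
    frag_cluster_radius: float = 0.5     # Å, fragment clustering
    max_fragment_clusters: int = 25      # cluster centers kept for docking
    keep_per_fragment: int = 250         # poses pooled per fragment
    pose_cluster_radius: float = 3.5     # Å, pose clustering
    capri_threshold: float = 4.0         # Å, acceptable-accuracy cutoff
    identity_threshold: float = 0.30     # sequence-identity exclusion
    library_low: int = 100               # target library size window
    library_high: int = 1000
    min_motif_length: int = 5            # shorter motifs are wildcard-padded
    max_library_iter: int = 20
    weight_set: str = "standard"
    grid_spacing: float = 1.0            # Å per voxel
    core_radius: float = 1.8             # Å, repulsive core
    shell_width: float = 3.0             # Å, attractive shell
    n_rotations: int = 64
    contact_cutoff: float = 5.0          # Å, interface-overlap removal
    max_report: int = 20                 # clusters reported
    max_tail: int = 10                   # tail-trimming cap (0 disables)
    seed: int = 0

    def __post_init__(self):
        positive = ("frag_cluster_radius", "pose_cluster_radius", "capri_threshold",
                    "grid_spacing", "core_radius", "shell_width", "contact_cutoff")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("max_fragment_clusters", "keep_per_fragment", "n_rotations",
                     "max_report", "library_low", "library_high",
                     "min_motif_length", "max_library_iter"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValidationError("identity_threshold must be in (0, 1]")
        if self.library_low >= self.library_high:
            raise ValidationError("library_low must be < library_high")
        if self.max_tail < 0:
            raise ValidationError("max_tail must be >= 0")
        if self.weight_set not in WEIGHT_SETS:
            raise ValidationError(
                f"unknown weight set {self.weight_set!r}; "
                f"choose from {sorted(WEIGHT_SETS)}")

    @property
    def weights(self) -> WeightSet:
        return WEIGHT_SETS[self.weight_set]

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a YAML (or flat ``key = value``) file; unknown keys are
        rejected."""
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ValidationError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ValidationError(f"config {path} must be a mapping")
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        coerced = {}
        defaults = cls()
        for key, value in data.items():
            target = type(getattr(defaults, key))
            try:
                coerced[key] = target(value)
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"config key {key}: {exc}") from exc
        return cls(**coerced)
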