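"""Pipeline configuration.

A single flat document of thresholds read once at CLI start; every value can
be overridden by a command-line flag. Defaults encode the structural MITE
definition (TIRs >= 10 bp, TSDs 2-10 bp, element < 1 kb), the 80%/80%
intact-copy and >80%/>50% read-mapping thresholds, the 2 kb genic window, the
5 kb TSS/TTS profile window and the molecular-clock substitution rate
r = 1.30e-8 substitutions/site/year used for insertion dating.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "DEFAULT_SUPERFAMILY_RULES"]

# TSD signatures diagnostic of class II superfamilies. Only the 8 bp -> hAT
# rule is load-bearing for classification of the families this package
# targets; the rest are conventional defaults and user-editable.
DEFAULT_SUPERFAMILY_RULES: dict[str, dict] = {
    "motifs": {"TA": "Tc1/mariner", "TTA": "PIF/Harbinger", "TAA": "PIF/Harbinger"},
    "lengths": {8: "hAT", 9: "Mutator", 10: "Mutator", 11: "Mutator"},
}


@dataclass
class PipelineConfig:
    # structural element definition
    min_tir_len: int = 10
    max_tir_len: int = 40
    tsd_len_range: tuple[int, int] = (2, 10)
    min_element_len: int = 100
    max_element_len: int = 1000
    at_rich_threshold: float = 0.60
    # homology thresholds (assembly: >=, reads: strict >)
    intact_min_identity: float = 0.80
    intact_min_coverage: float = 0.80
    read_min_identity: float = 0.80
    read_min_coverage: float = 0.50
    # genic context
    genic_window: int = 2000
    tss_profile_window: int = 5000
    # dating / phylogenetics
    substitution_rate_r: float = 1.30e-8
    bootstrap_replicates: int = 1000
    # seeding
    seed_len_assembly: int = 12
    seed_len_read: int = 16
    # family building
    min_family_size: int = 3
    # insertion-polymorphism typing
    flank_len: int = 300
    # reproducibility
    rng_seed: int = 42
    superfamily_rules: dict = field(
        default_factory=lambda: {
            "motifs": dict(DEFAULT_SUPERFAMILY_RULES["motifs"]),
            "lengths": dict(DEFAULT_SUPERFAMILY_RULES["lengths"]),
        }
    )

    def __post_init__(self) -> None:
        self.tsd_len_range = tuple(self.tsd_len_range)  # type: ignore[assignment]
        lo, hi = self.tsd_len_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid tsd_len_range {self.tsd_len_range}")
        if self.min_tir_len < 1:
            raise ValueError("min_tir_len must be >= 1")
        if not (0 < self.min_element_len <= self.max_element_len):
            raise ValueError("invalid element length bounds")
        for name in (
            "intact_min_identity",
            "intact_min_coverage",
            "read_min_identity",
            "read_min_coverage",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.substitution_rate_r <= 0:
            raise ValueError("substitution_rate_r must be positive")

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["tsd_len_range"] = list(self.tsd_len_range)
        # YAML mapping keys must be plain; length rules keyed by int are fine
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "superfamily_rules" in doc:
            rules = doc["superfamily_rules"]
            rules["lengths"] = {int(k): v for k, v in rules.get("lengths", {}).items()}
        return cls(**doc)
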