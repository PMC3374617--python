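"""Single source of truth for every threshold the validation pipeline applies.

Thresholds live in :class:`ValidationConfig` and are serialized as a flat
``key=value`` file.  Per-dataset overrides use ``key@DATASET_TAG=value``
lines (for example a stricter breadth requirement for shotgun candidates
than for amplicon candidates).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .records import DatasetTag


@dataclass
class ValidationConfig:
    """All tunable cutoffs of the discovery/validation pipeline.

    Defaults encode the published protocol: a read is a novelty candidate
    when its nearest database neighbor is below 97% identity (strict),
    qualifying neighbor alignments must be >=100 bp with <=5 bp unaligned
    query ends (unless the end overhangs the target), dereplication
    collapses 100%-identity matches over 95% of the shorter read, support
    alignments are perfect and >=60 bp, shotgun candidates need 100%
    breadth while amplicon candidates need strictly more than 95%, the
    valley detector uses a 70 bp floor against 90 bp shoulders, the tiling
    chain requires 20 bp overlap and 20 bp extension, and the spanning-pair
    test applies only above median depth 500 and length 200 with a 90%
    span requirement.
    """

    novelty_identity_max: float = 0.97
    nn_min_align_len: int = 100
    nn_max_unaligned_end: int = 5
    derep_identity: float = 1.00
    derep_coverage: float = 0.95
    support_min_len: int = 60
    support_breadth_wgs: float = 1.00
    support_breadth_amplicon: float = 0.95
    valley_floor: int = 70
    valley_shoulder: int = 90
    tiling_min_overlap: int = 20
    tiling_min_extend: int = 20
    pair_span_frac: float = 0.90
    pair_test_min_depth: int = 500
    pair_test_min_len: int = 200
    extended_cluster_identity: float = 0.97
    extended_cluster_coverage: float = 0.95
    primer_word_size: int = 7
    insert_min: int = 100
    insert_max: int = 500
    median_covered_only: bool = False

    overrides: dict[str, dict[str, float]] = field(default_factory=dict)

    _FRACTIONS = (
        "novelty_identity_max",
        "derep_identity",
        "derep_coverage",
        "support_breadth_wgs",
        "support_breadth_amplicon",
        "pair_span_frac",
        "extended_cluster_identity",
        "extended_cluster_coverage",
    )
    _COUNTS = (
        "nn_min_align_len",
        "nn_max_unaligned_end",
        "support_min_len",
        "valley_floor",
        "valley_shoulder",
        "tiling_min_overlap",
        "tiling_min_extend",
        "pair_test_min_depth",
        "pair_test_min_len",
        "primer_word_size",
        "insert_min",
        "insert_max",
    )

    def __post_init__(self) -> None:
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        for name in self._COUNTS:
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name}={v!r} is not a positive integer")
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min > insert_max")

    # -- per-dataset resolution -------------------------------------------

    def resolved(self, tag: DatasetTag) -> "ValidationConfig":
        """Return a copy with any ``key@TAG`` overrides applied."""
        ov = self.overrides.get(tag.value, {})
        if not ov:
            return self
        kwargs = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        kwargs.update(ov)
        kwargs["overrides"] = {}
        return ValidationConfig(**kwargs)

    def breadth_passes(self, breadth: float, tag: DatasetTag) -> bool:
        """Dataset-specific breadth rule.

        Shotgun candidates must be covered over 100% of their length
        (inclusive bound); amplicon candidates over strictly more than the
        amplicon threshold (the protocol phrase is "greater than 95%").
        """
        cfg = self.resolved(tag)
        if tag.is_amplicon:
            return breadth > cfg.support_breadth_amplicon
        return breadth >= cfg.support_breadth_wgs

    # -- flat key=value serialization -------------------------------------

    def to_file(self, path: Union[str, Path]) -> None:
        lines = []
        for f in dataclasses.fields(self):
            if f.name == "overrides":
                continue
            lines.append(f"{f.name}={getattr(self, f.name)}")
        for tag, ov in sorted(self.overrides.items()):
            for key, val in sorted(ov.items()):
                lines.append(f"{key}@{tag}={val}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ValidationConfig":
        kwargs: dict = {}
        overrides: dict[str, dict[str, float]] = {}
        field_types = {f.name: f.type for f in dataclasses.fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if "@" in key:
                base, _, tag = key.partition("@")
                DatasetTag(tag)  # validate
                overrides.setdefault(tag, {})[base] = _coerce(base, value, field_types)
            else:
                kwargs[key] = _coerce(key, value, field_types)
        kwargs["overrides"] = overrides
        return cls(**kwargs)


def _coerce(name: str, value: str, field_types: dict) -> Union[int, float, bool]:
    if name not in field_types:
        raise KeyError(f"unknown config key {name!r}")
    if name in ValidationConfig._COUNTS:
        return int(value)
    if name == "median_covered_only":
        return value.lower() in ("1", "true", "yes")
    return float(value)
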