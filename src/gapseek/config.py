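"""Engine configuration: every scoring threshold in one overridable place.

The defaults encode the published operating point of the method: candidate
search at >=30% identity and E < 0.01; high confidence at >40% identity,
>80% subject coverage and a +10-bit margin over the best conflicting hit;
medium confidence at >40%/>70% (unconditionally) or >30%/>80% (if the bit
score beats the conflicting hit); low confidence at >=50% coverage.  HMM
candidates are high confidence at >=80% model coverage unless a strong
conflicting hit exists (>=40% identity and >=75% coverage).  Split proteins
are joined with a +10-bit margin per part, <=20% alignment overlap and
>=70% combined subject coverage.  Genome relatedness requires >=10 retained
marker hits with a median identity >=75% (each hit >=50% identity, >=70%
coverage).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class EngineConfig:
    # candidate search (protein vs reference database)
    min_identity: float = 30.0
    max_evalue: float = 0.01

    # high-confidence rule for alignment-based candidates
    high_identity: float = 40.0
    high_coverage: float = 0.80
    high_bit_margin: float = 10.0

    # medium-confidence rules
    medium_identity_strong: float = 40.0
    medium_coverage_strong: float = 0.70
    medium_identity_weak: float = 30.0
    medium_coverage_weak: float = 0.80

    # low-confidence rule
    low_coverage: float = 0.50

    # HMM candidate rules
    hmm_high_coverage: float = 0.80
    hmm_other_identity: float = 40.0
    hmm_other_coverage: float = 0.75

    # split-protein joining
    split_bit_margin: float = 10.0
    split_max_overlap: float = 0.20
    split_min_coverage: float = 0.70

    # fraction of the candidate's relevant region a conflicting hit must
    # overlap to count; set to 0 to disable the region restriction
    min_region_overlap: float = 0.50

    # genome relatedness via ribosomal markers
    related_min_identity: float = 50.0
    related_min_coverage: float = 0.70
    related_min_hits: int = 10
    related_min_median: float = 75.0

    # curated-subset clustering
    cluster_identity: float = 0.60

    # pathway expansion guard
    expansion_cap: int = 10_000

    backend: str = "builtin"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "EngineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "EngineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


DEFAULT_CONFIG = EngineConfig()
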