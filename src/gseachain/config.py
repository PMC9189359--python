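"""Run configuration with validation and YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Pipeline parameters; every default is the study constant.

    tpm_floor
        minimum TPM in every compared sample (genes below are excluded).
    weight_p
        exponent on |δ| in the running-sum hit weight, in [0, 1].
    permutations
        number of gene-order permutations v per enrichment run.
    alpha
        raw-p significance threshold selecting enriched pathways.
    min_support
        minimum transaction count for a chain to be frequent.
    max_chain_len
        maximum number of genes in a transaction.
    leading_edge_mode
        "inclusive" (hits at/before a positive peak) or "strict".
    """

    tpm_floor: float = 1.0e-6
    weight_p: float = 1.0
    permutations: int = 1000
    alpha: float = 0.05
    min_support: int = 3
    max_chain_len: int = 4
    leading_edge_mode: str = "inclusive"
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the configuration is usable."""
    problems = []
    if not 0.0 <= config.weight_p <= 1.0:
        problems.append(f"weight_p must be in [0, 1], got {config.weight_p}")
    if config.permutations < 1:
        problems.append(f"permutations must be >= 1, got {config.permutations}")
    if not 0.0 < config.alpha <= 1.0:
        problems.append(f"alpha must be in (0, 1], got {config.alpha}")
    if config.min_support < 1:
        problems.append(f"min_support must be >= 1, got {config.min_support}")
    if config.max_chain_len < 1:
        problems.append(
            f"max_chain_len must be >= 1, got {config.max_chain_len}")
    if config.tpm_floor < 0:
        problems.append(f"tpm_floor must be >= 0, got {config.tpm_floor}")
    if config.leading_edge_mode not in ("inclusive", "strict"):
        problems.append(
            f"leading_edge_mode must be 'inclusive' or 'strict', "
            f"got {config.leading_edge_mode!r}")
    return problems
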