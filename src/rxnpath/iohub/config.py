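"""Serializable run configuration: one YAML document describes one exploration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ..explorer import ExplorationConfig
from ..potentials.u import UParams


@dataclass
class RunConfig:
    """Everything a run needs: exploration knobs, U parameters, paths, backend."""

    exploration: ExplorationConfig = field(default_factory=ExplorationConfig)
    uparams: UParams = field(default_factory=UParams)
    rules_file: str | None = None
    seeds: list[str] = field(default_factory=list)   # SMILES strings or XYZ paths
    output_dir: str = "rxnpath_out"

    def to_dict(self) -> dict:
        d = {
            "exploration": asdict(self.exploration),
            "uparams": {"a": self.uparams.a, "b": self.uparams.b, "n": self.uparams.n,
                        "r_bond": {"-".join(sorted(k)): v
                                   for k, v in self.uparams.r_bond.items()}},
            "rules_file": self.rules_file,
            "seeds": list(self.seeds),
            "output_dir": self.output_dir,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        up = d.get("uparams", {})
        r_bond = {frozenset(k.split("-")): float(v)
                  for k, v in (up.get("r_bond") or {}).items()}
        return cls(
            exploration=ExplorationConfig(**d.get("exploration", {})),
            uparams=UParams(a=up.get("a", 1.0), b=up.get("b", 0.3),
                            n=up.get("n", 4), r_bond=r_bond),
            rules_file=d.get("rules_file"),
            seeds=list(d.get("seeds", [])),
            output_dir=d.get("output_dir", "rxnpath_out"),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
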