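"""Run configuration: flat key=value files with CLI overrides.

A resolved copy of the configuration is written into the output directory
of every full run, so a run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from datetime import date
from pathlib import Path

from .errors import ConfigurationError


@dataclass
class RunConfig:
    source_dir: str = "out/source"
    vocab_dir: str = "out/vocab"
    defs_dir: str = "out/defs"
    cdm_dir: str = "out/cdm"
    reports_dir: str = "out/reports"
    study_end: date = date(2016, 3, 8)
    era_gap_days: int = 30
    drug_duration_days: int = 30
    pct_places: int = 2
    n_patients: int = 2000
    seed: int = 0

    def validate(self) -> None:
        paths = [self.source_dir, self.vocab_dir, self.defs_dir,
                 self.cdm_dir, self.reports_dir]
        if len(set(map(str, paths))) != len(paths):
            raise ConfigurationError("paths", "directories must be distinct")
        for name in ("era_gap_days", "drug_duration_days", "pct_places", "n_patients"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(name, "must be positive")
        if self.seed < 0:
            raise ConfigurationError("seed", "must be non-negative")

    def to_text(self) -> str:
        lines = []
        for f in dc_fields(self):
            value = getattr(self, f.name)
            if isinstance(value, date):
                value = value.isoformat()
            lines.append(f"{f.name}={value}")
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text(), encoding="utf-8")

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs = {}
        valid = {f.name: f for f in dc_fields(cls)}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not sep or key not in valid:
                raise ConfigurationError("config", f"line {lineno}: {line!r}")
            if key == "study_end":
                kwargs[key] = date.fromisoformat(value)
            elif valid[key].type in ("int", int):
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))

    def with_overrides(self, **overrides) -> "RunConfig":
        kwargs = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        for key, value in overrides.items():
            if value is not None:
                kwargs[key] = value
        return RunConfig(**kwargs)
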