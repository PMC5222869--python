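"""Pipeline configuration: defaults, key=value config files, provenance headers."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

from .errors import ConfigurationError

__all__ = ["PipelineConfig", "read_config_file"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and flags shared by the pipeline stages.

    min_anchor / min_nonredundant implement the junction criteria ("more than
    6 nt" perfect flanking match; "> 3 non-redundant reads in both groups");
    fc_log2 / fdr implement the DEG thresholds.
    """

    min_anchor: int = 7
    min_nonredundant: int = 4
    fc_log2: float = 1.0
    fdr: float = 0.05
    weight_p1: float = 0.5
    weight_p2: float = 0.5
    pseudocount: float = 1.0
    include_mxe: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.min_anchor < 1:
            raise ConfigurationError("min_anchor must be ≥ 1")
        if self.min_nonredundant < 0:
            raise ConfigurationError("min_nonredundant must be ≥ 0")
        if self.fc_log2 < 0:
            raise ConfigurationError("fc_log2 must be ≥ 0")
        if not (0.0 < self.fdr <= 1.0):
            raise ConfigurationError("fdr must lie in (0, 1]")
        if self.weight_p1 < 0 or self.weight_p2 < 0 or self.weight_p1 + self.weight_p2 <= 0:
            raise ConfigurationError("combination weights must be non-negative, not both zero")
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be positive")

    def as_items(self) -> list[tuple[str, str]]:
        out = []
        for f in fields(self):
            v = getattr(self, f.name)
            out.append((f.name, str(int(v)) if isinstance(v, bool) else str(v)))
        return out

    def header_lines(self, extra: dict[str, str] | None = None) -> list[str]:
        from . import __version__

        lines = [f"# asflow version={__version__}"]
        for k, v in self.as_items():
            lines.append(f"# {k}={v}")
        for k, v in (extra or {}).items():
            lines.append(f"# {k}={v}")
        return lines


def read_config_file(path, base: PipelineConfig | None = None) -> PipelineConfig:
    """Parse a ``key = value`` text file into a :class:`PipelineConfig`."""
    cfg = base or PipelineConfig()
    known = {f.name: f.type for f in fields(PipelineConfig)}
    updates: dict[str, object] = {}
    with open(path) as fh:
        for line_number, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}, line {line_number}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ConfigurationError(f"{path}, line {line_number}: unknown key {key!r}")
            current = getattr(cfg, key)
            try:
                if isinstance(current, bool):
                    updates[key] = value.lower() in ("1", "true", "yes", "on")
                elif isinstance(current, int):
                    updates[key] = int(value)
                else:
                    updates[key] = float(value)
            except ValueError:
                raise ConfigurationError(
                    f"{path}, line {line_number}: bad value {value!r} for {key}"
                ) from None
    cfg = replace(cfg, **updates)
    cfg.validate()
    return cfg
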