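"""Flat key=value run configuration.

One documented table of defaults; round-trips losslessly through
serialization and is echoed into output file headers so that every
artifact records how to reproduce it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with the desk-preset defaults."""

    # biology / scaling
    ne_actual: float = 1.72e6
    n_model: int = 200
    mu: float = 5.49e-9
    r: float = 2.23e-8
    genome_length: int = 20_000
    # scenario
    scenario: str = "continuous"  # continuous | secondary
    nem: float = 0.0
    migration_mode: str = "symmetric"  # symmetric | unidirectional
    recomb_factor_p2: float = 1.0
    # durations (actual generations; None = study defaults)
    burn_in_actual: float | None = None
    isolation_actual: float | None = None
    post_div_actual: float | None = None
    sampling_interval_actual: float | None = None
    n_sample: int = 25
    # estimator
    table_path: str | None = None
    table_n: int = 20
    table_mc: int = 20_000
    maf_min: float = 0.1
    d_max: float = 2_500
    max_pairs: int = 1_500
    n_subsamples: int = 5
    # run control
    n_replicates: int = 10
    out_dir: str = "results"
    seed: int = 1
    verbosity: int = 1

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            val = getattr(self, f.name)
            lines.append(f"{f.name} = {'' if val is None else val}")
        return "\n".join(lines) + "\n"


_TYPES = {f.name: f.type for f in fields(RunConfig)}


def _parse_value(name: str, raw: str):
    raw = raw.strip()
    if raw == "":
        return None
    t = _TYPES[name]
    if t in ("int", "int | None"):
        return int(float(raw))
    if t in ("float", "float | None"):
        return float(raw)
    return raw


def load_config(path) -> RunConfig:
    """Parse a flat key=value file (``#`` comments, blank lines allowed)."""
    values: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in _TYPES:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _parse_value(key, raw)
    return RunConfig(**values)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(cfg.to_text())
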