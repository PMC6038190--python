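"""Flat key-value run configuration for the pipeline CLI."""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .quantify import MATCH_MODES
from .simulate import SCENARIOS


@dataclass
class RunConfig:
    """Everything a signature run needs; defaults follow the call rule.

    Either ``scenario`` (synthetic inputs are generated under
    ``out_dir/inputs``) or the four input paths (reference, annotation,
    counts, sample_sheet) must be set. ``covariates`` is a comma-separated
    list applied to every contrast; per-cell-type overrides use keys like
    ``covariates_neuron``.
    """

    out_dir: Path = Path("pirsig_out")
    scenario: str | None = None
    reference: Path | None = None
    annotation: Path | None = None
    counts: Path | None = None
    sample_sheet: Path | None = None
    snorna: Path | None = None
    contrast_column: str = "group"
    reference_level: str | None = None
    split_column: str | None = "cell_type"
    covariates: tuple[str, ...] = ("sex",)
    covariates_by_cell_type: dict[str, tuple[str, ...]] = field(default_factory=dict)
    lfc_min: float = 0.6
    padj_max: float = 0.1
    top_variable_n: int = 2000
    top_de_n: int = 100
    top_abundant_n: int = 20
    mode: str = "all"
    direction_matched_memory: bool = False
    memory_reference_cell_type: str = "fibroblast"
    seed: int = 0

    def validate(self) -> None:
        if self.lfc_min <= 0 or self.padj_max <= 0:
            raise ValueError("thresholds must be positive")
        if self.padj_max > 1:
            raise ValueError("padj_max must be <= 1")
        for n in (self.top_variable_n, self.top_de_n, self.top_abundant_n):
            if n < 1:
                raise ValueError("top-N values must be >= 1")
        if self.mode not in MATCH_MODES:
            raise ValueError(f"mode must be one of {MATCH_MODES}")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario is None:
            needed = {
                "reference": self.reference,
                "annotation": self.annotation,
                "counts": self.counts,
                "sample_sheet": self.sample_sheet,
            }
            missing = [k for k, v in needed.items() if v is None]
            if missing:
                raise ValueError(
                    f"config needs either 'scenario' or input paths; missing: {missing}"
                )
            gone = [k for k, v in needed.items() if v is not None and not Path(v).exists()]
            if gone:
                raise FileNotFoundError(f"configured input paths do not exist: {gone}")

    def covariates_for(self, cell_type: str | None) -> tuple[str, ...]:
        if cell_type is not None and cell_type in self.covariates_by_cell_type:
            return self.covariates_by_cell_type[cell_type]
        return self.covariates


_PATH_KEYS = {"out_dir", "reference", "annotation", "counts", "sample_sheet", "snorna"}
_FLOAT_KEYS = {"lfc_min", "padj_max"}
_INT_KEYS = {"top_variable_n", "top_de_n", "top_abundant_n", "seed"}
_BOOL_KEYS = {"direction_matched_memory"}
_STR_KEYS = {
    "scenario",
    "contrast_column",
    "reference_level",
    "split_column",
    "mode",
    "memory_reference_cell_type",
}


def _parse_bool(v: str) -> bool:
    s = v.strip().lower()
    if s in ("true", "yes", "1", "on"):
        return True
    if s in ("false", "no", "0", "off"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


def validate_config(path: str | Path) -> RunConfig:
    """Parse and type-check a flat ``key = value`` config file.

    Lines starting with ``#`` and blank lines are ignored; unknown keys are
    rejected. Empty string values for optional keys mean "unset".
    """
    cfg = RunConfig()
    seen: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in seen:
            raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
        seen.add(key)
        if key == "covariates":
            cfg.covariates = tuple(c.strip() for c in value.split(",") if c.strip())
        elif key.startswith("covariates_"):
            ct = key[len("covariates_"):]
            cfg.covariates_by_cell_type[ct] = tuple(
                c.strip() for c in value.split(",") if c.strip()
            )
        elif key in _PATH_KEYS:
            setattr(cfg, key, Path(value) if value else None)
        elif key in _FLOAT_KEYS:
            setattr(cfg, key, float(value))
        elif key in _INT_KEYS:
            setattr(cfg, key, int(value))
        elif key in _BOOL_KEYS:
            setattr(cfg, key, _parse_bool(value))
        elif key in _STR_KEYS:
            setattr(cfg, key, value if value else None)
        else:
            known = sorted(
                _PATH_KEYS | _FLOAT_KEYS | _INT_KEYS | _BOOL_KEYS | _STR_KEYS
                | {"covariates", "covariates_<cell_type>"}
            )
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}; known keys: {known}")
    if cfg.out_dir is None:
        raise ValueError("out_dir must be set")
    cfg.validate()
    return cfg


def config_as_dict(cfg: RunConfig) -> dict:
    """JSON-serializable view of a config (for the run manifest)."""
    out = {}
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, Path):
            v = str(v)
        elif isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, dict):
            v = {k: list(t) for k, t in v.items()}
        out[f.name] = v
    return out
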