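"""End-to-end runs with config, logging and versioned, manifest-backed output.

A :class:`RunConfig` collects everything tunable (anchor overrides, threshold
overrides, burn-in, bin count, output directory, seed) from a plain
``key = value`` text file, so the constants a run used are reviewable in one
place.  :func:`run_pipeline` executes one analysis mode, writes TSV tables
and JSON reports into the output directory, and records a
:class:`RunManifest` with input checksums, the full config snapshot and
per-stage status; identical manifests reproduce identical outputs.

Config schema (all keys optional)::

    anchors.catalytic_lysine = 483        # any AnchorMap field
    thresholds.hbond_cutoff = 3.5         # any Thresholds field
    burn_in_fraction = 0.4
    n_bins = 50
    outputs = runs/out
    log_level = INFO
    seed = 0

Tuple-valued anchor fields take comma-separated integers
(``anchors.dfg_dihedral_residues = 592,593,594,595``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

from . import __version__
from .anchors import AnchorMap, Thresholds
from .errors import ConfigError

logger = logging.getLogger("protomerscope")

MODES = ("metrics", "fingerprint", "classify", "ensemble", "dcna", "simulate")


@dataclass
class RunConfig:
    anchors: AnchorMap = field(default_factory=AnchorMap)
    thresholds: Thresholds = field(default_factory=Thresholds)
    burn_in_fraction: float = 0.4
    n_bins: int = 50
    outputs: str = "protomerscope_out"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.burn_in_fraction < 1:
            raise ConfigError("burn_in_fraction must be in [0, 1)")
        if self.n_bins < 1:
            raise ConfigError("n_bins must be positive")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"unknown log_level {self.log_level!r}")

    def snapshot(self) -> dict:
        return {
            "anchors": dataclasses.asdict(self.anchors),
            "thresholds": dataclasses.asdict(self.thresholds),
            "burn_in_fraction": self.burn_in_fraction,
            "n_bins": self.n_bins,
            "outputs": self.outputs,
            "log_level": self.log_level,
            "seed": self.seed,
        }


def _coerce(current, text: str):
    if isinstance(current, tuple):
        return tuple(int(x) for x in text.split(","))
    if isinstance(current, bool):
        return text.strip().lower() in ("1", "true", "yes", "on")
    return type(current)(text.strip())


def load_config(path=None, **overrides) -> RunConfig:
    """Parse a ``key = value`` config file into a :class:`RunConfig`."""
    anchors_kw: dict = {}
    thresholds_kw: dict = {}
    top_kw: dict = {}
    if path is not None:
        defaults_a, defaults_t = AnchorMap(), Thresholds()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (s.strip() for s in line.split("=", 1))
                try:
                    if key.startswith("anchors."):
                        f = key.split(".", 1)[1]
                        anchors_kw[f] = _coerce(getattr(defaults_a, f), value)
                    elif key.startswith("thresholds."):
                        f = key.split(".", 1)[1]
                        thresholds_kw[f] = _coerce(getattr(defaults_t, f), value)
                    elif key in ("burn_in_fraction",):
                        top_kw[key] = float(value)
                    elif key in ("n_bins", "seed"):
                        top_kw[key] = int(value)
                    elif key in ("outputs", "log_level"):
                        top_kw[key] = value
                    else:
                        raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
                except (AttributeError, ValueError, TypeError) as exc:
                    raise ConfigError(f"{path}:{lineno}: {exc}") from exc
    top_kw.update(overrides)
    try:
        return RunConfig(
            anchors=AnchorMap(**anchors_kw),
            thresholds=Thresholds(**thresholds_kw),
            **top_kw,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


@dataclass
class RunManifest:
    mode: str
    package_version: str
    config: dict
    inputs: dict
    outputs: list
    stages: dict

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, mode: str, inputs: dict) -> RunManifest:
    """Execute one analysis mode end to end.

    ``inputs`` is mode-specific: ``structure`` (path) for metrics /
    fingerprint / classify (plus ``ligand`` name for the latter two),
    ``topology`` + ``frames`` (list of paths) for ensemble (plus ``metric``,
    optional ``ligand``), ``topology`` absent but ``apo`` / ``holo`` frame
    lists + ``topology`` for dcna, and a ``spec`` config path for simulate.
    Outputs are written under ``config.outputs``; the manifest is saved as
    ``manifest.json`` there and returned.
    """
    if mode not in MODES:
        raise ConfigError(f"unknown mode {mode!r}; choose from {MODES}")
    logging.basicConfig(level=config.log_level.upper())
    logger.info("thresholds in effect: %s", dataclasses.asdict(config.thresholds))
    logger.info("anchors in effect: %s", dataclasses.asdict(config.anchors))
    os.makedirs(config.outputs, exist_ok=True)

    input_sums = {}
    for key, value in inputs.items():
        paths = value if isinstance(value, (list, tuple)) else [value]
        for p in paths:
            if isinstance(p, (str, os.PathLike)) and os.path.exists(os.fspath(p)):
                input_sums[os.fspath(p)] = _checksum(p)

    stages: dict = {}
    outputs: list = []
    try:
        from . import stages as _stages

        runner = getattr(_stages, f"stage_{mode}")
        outputs = runner(config, inputs)
        stages[mode] = "ok"
    except Exception as exc:
        stages[mode] = f"failed: {exc}"
        logger.error("stage %s failed: %s", mode, exc)
        raise
    finally:
        manifest = RunManifest(
            mode=mode,
            package_version=__version__,
            config=config.snapshot(),
            inputs=input_sums,
            outputs=[os.fspath(o) for o in outputs],
            stages=stages,
        )
        manifest.write(os.path.join(config.outputs, "manifest.json"))
    return manifest
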