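"""Flat key=value configuration files, merge rules, and run directories.

Precedence is defaults < config file < command-line flags.  Unknown keys are
fatal (silent typos in experiment configs are worse than crashes).  Every CLI
run echoes its effective merged configuration to the log and saves it next to
the outputs, so a run can be reproduced from its own artifacts.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .exceptions import ConfigurationError

log = logging.getLogger("staincut.config")


def load_config_file(path: str | Path) -> dict[str, str]:
    """Parse ``KEY = VALUE`` lines; ``#`` starts a comment."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    out: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected KEY = VALUE")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def _coerce(value, like):
    if isinstance(like, bool):
        if str(value).lower() in ("1", "true", "yes", "on"):
            return True
        if str(value).lower() in ("0", "false", "no", "off"):
            return False
        raise ConfigurationError(f"cannot read {value!r} as a boolean")
    if like is None:
        return value
    return type(like)(value)


def merge_config(
    defaults: dict,
    file_config: dict | None = None,
    flag_config: dict | None = None,
) -> dict:
    """Merge with precedence defaults < file < flags; unknown keys are fatal."""
    merged = dict(defaults)
    for source, name in ((file_config, "config file"), (flag_config, "flags")):
        if not source:
            continue
        for key, value in source.items():
            if key not in defaults:
                raise ConfigurationError(
                    f"unknown configuration key {key!r} from {name}; "
                    f"known keys: {sorted(defaults)}"
                )
            if value is None:
                continue
            merged[key] = _coerce(value, defaults[key])
    return merged


def echo_config(config: dict, out_dir: str | Path | None = None) -> str:
    """Log the effective config and (optionally) save it beside the outputs."""
    text = "\n".join(f"{k} = {config[k]}" for k in sorted(config))
    for line in text.splitlines():
        log.info("config %s", line)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "effective_config.txt").write_text(text + "\n")
    return text
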