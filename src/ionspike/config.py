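"""Run configuration files and reproducibility metadata.

Configurations are YAML (JSON-compatible) mappings with one block per
module; unknown keys are rejected so typos fail loudly.  Every CLI run
writes a metadata record (config echo, seed, package version, timing)
sufficient to re-execute it.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import yaml

KNOWN_BLOCKS = {
    "lattice": {
        "size", "n_na", "n_k", "frac_unsaturated", "temperature_c", "v_m_mv",
        "sweeps", "q_gate", "eps_g", "j_lipid", "j_sensor_lipid",
        "j_sensor_sensor", "gamma_ps", "e_rev_mv", "move_mix",
    },
    "cable": {
        "morph", "max_len", "dt", "t_stop", "clamp_pa", "clamp_on", "clamp_off",
        "record", "c_m", "r_a", "g_leak", "e_leak", "hh_densities", "e_na",
        "e_k", "v_init", "temperature_c", "q10", "threshold", "min_isi",
    },
    "synapses": {
        "variants", "baseline", "placement", "correlated", "rate", "weight",
        "G_list", "duration", "n_synapses", "radius", "tau_rise", "tau_decay",
        "e_rev", "calibrate",
    },
    "coupling": {
        "exchange_dt", "sweeps_per_ms", "n_replicas", "temperatures",
        "clamp_pa", "clamp_on", "clamp_off", "t_stop", "dt", "area_scale",
    },
    "permeation": {
        "traj", "z_lower", "z_upper", "radius", "axis_xy", "ion_charge",
        "v_m_mv", "n_blocks",
    },
    "fixtures": {
        "kind", "depth", "branch_prob", "seg_len_range", "trunk_diam",
        "taper", "soma_diam", "n_ions", "duration_ns", "dt_ps", "drift",
        "diffusion",
    },
    "global": {"seed", "out", "log_level"},
}


def load_config(path: str | Path) -> dict:
    """Load and validate a run configuration; unknown blocks or keys raise."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    for block, values in raw.items():
        if block not in KNOWN_BLOCKS:
            raise ValueError(f"unknown config block {block!r}")
        if values is None:
            continue
        unknown = set(values) - KNOWN_BLOCKS[block]
        if unknown:
            raise ValueError(f"unknown keys in block {block!r}: {sorted(unknown)}")
    return raw


def setup_logging(level: str = "INFO", log_file: Path | None = None) -> logging.Logger:
    logger = logging.getLogger("ionspike")
    logger.setLevel(level.upper())
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger


def write_run_metadata(
    out_dir: str | Path,
    command: str,
    config: dict,
    seed: int | None,
    started: float,
) -> Path:
    """JSON record of a run: command, echoed config, seed, version, timing."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "config": config,
        "seed": seed,
        "ionspike_version": __version__,
        "elapsed_s": round(time.time() - started, 3),
        "argv": sys.argv,
    }
    path = out_dir / "run_metadata.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
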